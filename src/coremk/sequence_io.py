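"""FASTA input/output, codon-aware containers and back-translation.

The unit of analysis is a per-gene in-frame codon alignment of single-copy
orthologs: one FASTA record per genome, record IDs are genome labels, and
every file in a run shares the same label set.  Sequences are kept as plain
uppercase strings over ``{A, C, G, T, -}`` (plus IUPAC ambiguity codes on
input, which are masked to whole-codon gaps before any counting).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, ConsistencyError, FrameError, InputError

logger = logging.getLogger(__name__)

GAP_CODON = "---"
_VALID_NT = frozenset("ACGT")
_VALID_CHARS = frozenset("ACGT-")


class GeneticCode:
    """A codon -> amino acid map backed by the NCBI translation tables.

    Defaults to table 11 (bacterial/archaeal/plant plastid), whose internal
    codon assignments are identical to the standard code; only start-codon
    conventions differ, which do not matter here.
    """

    def __init__(self, table_id: int = 11):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self._aa: Dict[str, str] = dict(table.forward_table)
        for codon in table.stop_codons:
            self._aa[codon] = "*"
        if len(self._aa) != 64:
            raise ValueError(f"translation table {table_id} does not map 64 codons")

    def translate_codon(self, codon: str) -> str:
        """Amino acid for one codon; stop codons translate to ``*``."""
        try:
            return self._aa[codon]
        except KeyError:
            raise ValueError(f"cannot translate ambiguous codon {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return self._aa.get(codon) == "*"

    def translate(self, cds: str) -> str:
        """Translate an ungapped in-frame CDS (stops included as ``*``)."""
        if len(cds) % 3 != 0:
            raise FrameError(f"CDS length {len(cds)} not divisible by 3")
        return "".join(self.translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))

    @property
    def sense_codons(self) -> List[str]:
        return sorted(c for c, aa in self._aa.items() if aa != "*")


@lru_cache(maxsize=None)
def get_code(table_id: int = 11) -> GeneticCode:
    return GeneticCode(table_id)


@dataclass(frozen=True)
class CodonSequence:
    """One genome's sequence within a gene alignment (in-frame, gappable)."""

    genome_label: str
    nucleotides: str

    def __post_init__(self):
        if len(self.nucleotides) % 3 != 0:
            raise FrameError(
                f"{self.genome_label}: length {len(self.nucleotides)} not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    def codons(self) -> Iterator[str]:
        nt = self.nucleotides
        for i in range(0, len(nt), 3):
            yield nt[i : i + 3]


class GeneAlignment:
    """An equal-length codon alignment of one ortholog across genomes."""

    def __init__(self, gene_id: str, sequences: Sequence[CodonSequence]):
        if len(sequences) < 2:
            raise InputError(f"{gene_id}: an alignment needs at least 2 sequences")
        labels = [s.genome_label for s in sequences]
        if len(set(labels)) != len(labels):
            raise InputError(f"{gene_id}: duplicate genome labels")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"{gene_id}: unequal sequence lengths {sorted(lengths)}")
        self.gene_id = gene_id
        self._seqs: "OrderedDict[str, CodonSequence]" = OrderedDict(
            (s.genome_label, s) for s in sequences
        )

    @classmethod
    def from_dict(cls, gene_id: str, mapping: Mapping[str, str]) -> "GeneAlignment":
        return cls(gene_id, [CodonSequence(k, v.upper()) for k, v in mapping.items()])

    @property
    def sequences(self) -> "OrderedDict[str, CodonSequence]":
        return self._seqs

    @property
    def labels(self) -> List[str]:
        return list(self._seqs)

    @property
    def length(self) -> int:
        return len(next(iter(self._seqs.values())))

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def n_sequences(self) -> int:
        return len(self._seqs)

    def __getitem__(self, label: str) -> str:
        return self._seqs[label].nucleotides

    def items(self) -> Iterator[Tuple[str, str]]:
        for label, seq in self._seqs.items():
            yield label, seq.nucleotides

    def subset(self, labels: Iterable[str], gene_id: Optional[str] = None) -> "GeneAlignment":
        labels = list(labels)
        missing = [l for l in labels if l not in self._seqs]
        if missing:
            raise InputError(f"{self.gene_id}: labels not in alignment: {missing}")
        return GeneAlignment(gene_id or self.gene_id, [self._seqs[l] for l in labels])

    def to_matrix(self, labels: Optional[Sequence[str]] = None) -> np.ndarray:
        """Byte matrix (n_sequences x length) of ASCII codes, row order = labels."""
        labels = list(labels) if labels is not None else self.labels
        rows = [np.frombuffer(self._seqs[l].nucleotides.encode(), dtype=np.uint8) for l in labels]
        return np.vstack(rows)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> "OrderedDict[str, str]":
    """Read FASTA into an ordered label -> sequence map (first header token)."""
    out: "OrderedDict[str, str]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise InputError(f"{path}: duplicate sequence ID {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(mapping: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for label, seq in mapping.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_alignment(path, gene_id: Optional[str] = None) -> GeneAlignment:
    """Read and validate one per-gene codon alignment from FASTA."""
    records = read_fasta(path)
    if len(records) < 2:
        raise InputError(f"{path}: fewer than 2 sequences")
    gid = gene_id or Path(str(path)).stem
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    length = lengths.pop()
    if length % 3 != 0:
        raise FrameError(f"{path}: alignment length {length} not divisible by 3")
    return GeneAlignment.from_dict(gid, records)


def write_gene_alignment(alignment: GeneAlignment, path) -> None:
    write_fasta(dict(alignment.items()), path)


# ---------------------------------------------------------------------------
# Codon hygiene


def mask_ambiguous_codons(alignment: GeneAlignment) -> Tuple[GeneAlignment, int]:
    """Replace every codon containing a non-ACGT, non-gap character — or a
    partial gap — with a whole-codon gap ``---``.

    Masking is conservative: downstream counting simply skips gapped codons.
    Returns the cleaned alignment and the number of codons masked.
    """
    n_masked = 0
    cleaned: Dict[str, str] = {}
    for label, seq in alignment.items():
        out = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            chars = set(codon)
            if chars <= _VALID_NT or codon == GAP_CODON:
                out.append(codon)
            else:
                out.append(GAP_CODON)
                n_masked += 1
        cleaned[label] = "".join(out)
    if n_masked:
        logger.info("%s: masked %d ambiguous/partially-gapped codons", alignment.gene_id, n_masked)
    return GeneAlignment.from_dict(alignment.gene_id, cleaned), n_masked


def find_internal_stops(alignment: GeneAlignment, code: GeneticCode) -> List[Tuple[str, int]]:
    """(label, codon index) pairs for stop codons before the final codon column."""
    hits = []
    last = alignment.n_codons - 1
    for label, seq in alignment.items():
        for j in range(last):
            codon = seq[3 * j : 3 * j + 3]
            if set(codon) <= _VALID_NT and code.is_stop(codon):
                hits.append((label, j))
    return hits


def handle_internal_stops(
    alignment: GeneAlignment, code: GeneticCode, mask: bool = False
) -> GeneAlignment:
    """Error on internal stop codons, or mask them to gaps when ``mask``."""
    hits = find_internal_stops(alignment, code)
    if not hits:
        return alignment
    if not mask:
        raise InputError(f"{alignment.gene_id}: internal stop codons at {hits[:5]}")
    logger.info("%s: masked %d internal stop codons", alignment.gene_id, len(hits))
    masked = {label: list(seq) for label, seq in alignment.items()}
    for label, j in hits:
        masked[label][3 * j : 3 * j + 3] = GAP_CODON
    return GeneAlignment.from_dict(alignment.gene_id, {k: "".join(v) for k, v in masked.items()})


# ---------------------------------------------------------------------------
# Back-translation and concatenation


def back_translate(
    protein_alignment: Mapping[str, str],
    cds: Mapping[str, str],
    gene_id: str = "gene",
    code: Optional[GeneticCode] = None,
) -> GeneAlignment:
    """Project an aligned protein FASTA back onto unaligned CDS sequences.

    Each amino-acid column becomes one codon column; a protein gap becomes a
    whole-codon gap.  A trailing stop codon on the CDS is stripped.  Raises
    :class:`ConsistencyError` when a protein row is not the translation of
    its CDS.
    """
    code = code or get_code()
    if set(protein_alignment) != set(cds):
        raise InputError("protein alignment and CDS map have different label sets")
    rows: Dict[str, str] = {}
    for label, prot in protein_alignment.items():
        prot = prot.upper()
        nt = cds[label].upper()
        ungapped = prot.replace("-", "")
        if len(nt) == 3 * (len(ungapped) + 1) and code.is_stop(nt[-3:]):
            nt = nt[:-3]
        if len(nt) != 3 * len(ungapped):
            raise ConsistencyError(
                f"{gene_id}/{label}: CDS length {len(nt)} does not match "
                f"{len(ungapped)} aligned residues"
            )
        translated = code.translate(nt)
        if translated != ungapped:
            raise ConsistencyError(
                f"{gene_id}/{label}: CDS translation does not match protein alignment"
            )
        out = []
        k = 0
        for aa in prot:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(nt[3 * k : 3 * k + 3])
                k += 1
        rows[label] = "".join(out)
    return GeneAlignment.from_dict(gene_id, rows)


def concatenate(alignments: Sequence[GeneAlignment], gene_id: str = "concatemer") -> GeneAlignment:
    """Concatenate gene alignments per genome, in sorted gene_id order.

    The sort makes the concatemer independent of the order in which gene
    files were read.
    """
    if not alignments:
        raise InputError("nothing to concatenate")
    label_set = set(alignments[0].labels)
    for aln in alignments:
        if set(aln.labels) != label_set:
            raise InputError(
                f"label-set mismatch between {alignments[0].gene_id} and {aln.gene_id}"
            )
    ordered = sorted(alignments, key=lambda a: a.gene_id)
    labels = sorted(label_set)
    rows = {label: "".join(a[label] for a in ordered) for label in labels}
    return GeneAlignment.from_dict(gene_id, rows)
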