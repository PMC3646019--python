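"""Site-frequency spectrum and nucleotide diversity for the ingroup.

All statistics are computed on nucleotide columns where every ingroup
sequence carries an unambiguous base (pi additionally uses per-pair
deletion, so pairs can rescue columns that are gapped in other strains).
pi and Watterson's theta are reported per usable site so genes of different
length are comparable.

The unfolded spectrum is polarized by the outgroup representative: a
biallelic site enters bin k when the derived allele (the one the outgroup
does not carry) is present in k ingroup strains.  Sites where the outgroup
carries neither ingroup allele cannot be polarized and contribute only to
the folded spectrum; triallelic sites are counted in S and pi but excluded
from both spectra.  Synonymous/non-synonymous split spectra classify each
biallelic change in the consensus codon background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .sequence_io import GeneAlignment, GeneticCode, get_code

_ACGT = frozenset("ACGT")
_ACGT_CODES = tuple(ord(c) for c in "ACGT")


@dataclass(frozen=True)
class DiversityStats:
    n_sequences: int
    sites_used: int
    S: int
    pi: float
    theta_w: float
    sfs_unfolded: Tuple[int, ...]       # bins 1..n-1, polarizable biallelic sites
    sfs_folded: Tuple[int, ...]         # bins 1..n//2, all biallelic sites
    sfs_unfolded_syn: Tuple[int, ...]
    sfs_unfolded_nonsyn: Tuple[int, ...]
    n_polarizable: int


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / (a_{n-1} * L)."""
    if n < 2:
        raise InputError("Watterson's theta needs n >= 2")
    if L < 1:
        raise InputError("Watterson's theta needs L >= 1")
    return S / (harmonic_number(n - 1) * L)


def _ingroup_matrix(alignment: GeneAlignment, ingroup: Optional[Sequence[str]]):
    labels = sorted(ingroup) if ingroup is not None else alignment.labels
    if len(labels) < 2:
        raise InputError("need at least 2 ingroup sequences")
    return labels, alignment.to_matrix(labels)


def segregating_sites(
    alignment: GeneAlignment, ingroup: Optional[Sequence[str]] = None
) -> Tuple[int, int]:
    """(S, sites_used): segregating and usable nucleotide columns.

    Usable columns carry an unambiguous base in every ingroup sequence;
    a column is segregating when it holds >= 2 distinct bases (triallelic
    columns still count once).
    """
    _, m = _ingroup_matrix(alignment, ingroup)
    valid = np.isin(m, np.array(_ACGT_CODES, dtype=np.uint8)).all(axis=0)
    varying = (m != m[0:1]).any(axis=0)
    return int((valid & varying).sum()), int(valid.sum())


def nucleotide_diversity(
    alignment: GeneAlignment, ingroup: Optional[Sequence[str]] = None
) -> float:
    """Mean pairwise difference proportion over all ingroup pairs.

    Each pair is compared over the columns where both members carry an
    unambiguous base (pairwise deletion); pairs with no comparable column
    are skipped.
    """
    _, m = _ingroup_matrix(alignment, ingroup)
    valid = np.isin(m, np.array(_ACGT_CODES, dtype=np.uint8))
    n = m.shape[0]
    vals: List[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            tot = int(ok.sum())
            if tot == 0:
                continue
            vals.append(float(((m[i] != m[j]) & ok).sum()) / tot)
    return float(np.mean(vals)) if vals else 0.0


def consensus_codon(codons: Sequence[str]) -> Optional[str]:
    """Majority-rule consensus: the unique plurality codon, else None."""
    counts: Dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    winners = sorted(c for c, k in counts.items() if k == best)
    return winners[0] if len(winners) == 1 else None


def outgroup_representative(
    alignment: GeneAlignment, outgroup: Sequence[str], mode: str = "consensus"
) -> str:
    """Representative outgroup sequence, codon by codon.

    ``consensus``: majority-rule consensus codon over clean outgroup codons;
    columns without a unique winner (or no clean codon) become ``NNN``.
    ``first``: the lexicographically first outgroup strain's sequence.
    """
    outgroup = sorted(outgroup)
    if not outgroup:
        raise InputError("empty outgroup")
    if mode == "first":
        return alignment[outgroup[0]]
    if mode != "consensus":
        raise InputError(f"unknown outgroup mode {mode!r}")
    seqs = [alignment[l] for l in outgroup]
    out = []
    for j in range(0, alignment.length, 3):
        codons = [s[j : j + 3] for s in seqs]
        clean = [c for c in codons if set(c) <= _ACGT]
        rep = consensus_codon(clean) if clean else None
        out.append(rep if rep is not None else "NNN")
    return "".join(out)


def _classify_site(
    column_alleles: Tuple[str, str],
    site: int,
    ingroup_seqs: Sequence[str],
    code: GeneticCode,
) -> Optional[bool]:
    """True if the biallelic change at ``site`` is synonymous, None if the
    codon context cannot be resolved (ambiguity or stop codon involved)."""
    codon_start = 3 * (site // 3)
    offset = site - codon_start
    background = []
    for k in range(3):
        if k == offset:
            background.append(None)
            continue
        chars = [s[codon_start + k] for s in ingroup_seqs if s[codon_start + k] in _ACGT]
        if not chars:
            return None
        counts: Dict[str, int] = {}
        for ch in chars:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values())
        winners = sorted(c for c, v in counts.items() if v == best)
        background.append(winners[0])
    codons = []
    for allele in column_alleles:
        codon = "".join(
            allele if k == offset else background[k] for k in range(3)
        )
        if code.is_stop(codon):
            return None
        codons.append(codon)
    return code.translate_codon(codons[0]) == code.translate_codon(codons[1])


def site_frequency_spectrum(
    alignment: GeneAlignment,
    ingroup: Sequence[str],
    outgroup: Optional[Sequence[str]] = None,
    code: Optional[GeneticCode] = None,
    outgroup_mode: str = "consensus",
) -> Dict[str, Tuple[int, ...]]:
    """Unfolded (outgroup-polarized) and folded spectra for one gene.

    Returns a dict with keys ``unfolded``, ``folded``, ``unfolded_syn``,
    ``unfolded_nonsyn`` and ``n_polarizable``.
    """
    code = code or get_code()
    labels, m = _ingroup_matrix(alignment, ingroup)
    n = len(labels)
    seqs = [alignment[l] for l in labels]
    rep = (
        outgroup_representative(alignment, outgroup, outgroup_mode)
        if outgroup
        else None
    )
    valid = np.isin(m, np.array(_ACGT_CODES, dtype=np.uint8)).all(axis=0)
    varying = (m != m[0:1]).any(axis=0)

    unfolded = [0] * (n - 1)
    folded = [0] * (n // 2)
    syn = [0] * (n - 1)
    nonsyn = [0] * (n - 1)
    n_polarizable = 0

    for site in np.flatnonzero(valid & varying):
        site = int(site)
        col = [chr(m[i, site]) for i in range(n)]
        alleles = sorted(set(col))
        if len(alleles) != 2:
            continue  # triallelic: in S and pi, but not in the spectra
        count_a = col.count(alleles[0])
        counts = {alleles[0]: count_a, alleles[1]: n - count_a}
        folded[min(counts.values()) - 1] += 1
        anc = rep[site] if rep is not None else "N"
        if anc not in alleles:
            continue
        derived = alleles[1] if anc == alleles[0] else alleles[0]
        k = counts[derived]
        unfolded[k - 1] += 1
        n_polarizable += 1
        is_syn = _classify_site((anc, derived), site, seqs, code)
        if is_syn is True:
            syn[k - 1] += 1
        elif is_syn is False:
            nonsyn[k - 1] += 1

    return {
        "unfolded": tuple(unfolded),
        "folded": tuple(folded),
        "unfolded_syn": tuple(syn),
        "unfolded_nonsyn": tuple(nonsyn),
        "n_polarizable": n_polarizable,
    }


def diversity_stats(
    alignment: GeneAlignment,
    ingroup: Sequence[str],
    outgroup: Optional[Sequence[str]] = None,
    code: Optional[GeneticCode] = None,
    outgroup_mode: str = "consensus",
) -> DiversityStats:
    """All per-gene ingroup diversity summaries in one pass."""
    labels = sorted(ingroup)
    S, sites_used = segregating_sites(alignment, labels)
    pi = nucleotide_diversity(alignment, labels)
    theta = watterson_theta(S, len(labels), sites_used) if sites_used else 0.0
    sfs = site_frequency_spectrum(alignment, labels, outgroup, code, outgroup_mode)
    return DiversityStats(
        n_sequences=len(labels),
        sites_used=sites_used,
        S=S,
        pi=pi,
        theta_w=theta,
        sfs_unfolded=sfs["unfolded"],
        sfs_folded=sfs["folded"],
        sfs_unfolded_syn=sfs["unfolded_syn"],
        sfs_unfolded_nonsyn=sfs["unfolded_nonsyn"],
        n_polarizable=sfs["n_polarizable"],
    )
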