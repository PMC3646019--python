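"""Alignment trimming and quality control.

Orthologs enter as in-frame codon alignments that may carry ragged, gappy
ends (from aligning genes of unequal length) and internal indels.  Trimming
removes leading and trailing codon columns in which any genome has a gap, so
the retained flanks are gap-free; interior columns are left untouched.  Two
user-set thresholds then decide whether a gene is kept: the fraction of
codon columns that are gap-free in every genome (alignment overlap) and the
longest run of gap-containing codon columns (indel length, in codons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, QCError
from .sequence_io import GeneAlignment


@dataclass(frozen=True)
class QCParams:
    """Thresholds for ortholog exclusion.

    min_overlap_fraction: minimum share of codon columns gap-free in all
        genomes (default 0.85).
    max_indel_codons: longest tolerated run of gap-containing codon columns
        (default 15).
    """

    min_overlap_fraction: float = 0.85
    max_indel_codons: int = 15

    def __post_init__(self):
        if not 0.0 <= self.min_overlap_fraction <= 1.0:
            raise ConfigError("min_overlap_fraction must be in [0, 1]")
        if self.max_indel_codons < 1:
            raise ConfigError("max_indel_codons must be >= 1")


@dataclass(frozen=True)
class QCReport:
    gene_id: str
    original_length_codons: int
    trimmed_length_codons: int
    overlap_fraction: float
    longest_indel_codons: int
    passed: bool


def _gapped_codon_columns(alignment: GeneAlignment) -> np.ndarray:
    """Boolean per codon column: does any sequence carry a gap there?"""
    m = alignment.to_matrix()
    gaps = m == ord("-")
    n_codons = alignment.length // 3
    return gaps.reshape(m.shape[0], n_codons, 3).any(axis=(0, 2))


def trim(alignment: GeneAlignment) -> GeneAlignment:
    """Strip leading/trailing codon columns containing any gap."""
    gapped = _gapped_codon_columns(alignment)
    clean = np.flatnonzero(~gapped)
    if clean.size == 0:
        raise QCError(f"{alignment.gene_id}: no gap-free codon column remains after trimming")
    first, last = int(clean[0]), int(clean[-1])
    lo, hi = 3 * first, 3 * (last + 1)
    rows = {label: seq[lo:hi] for label, seq in alignment.items()}
    return GeneAlignment.from_dict(alignment.gene_id, rows)


def longest_gap_run(alignment: GeneAlignment) -> int:
    """Longest run of consecutive codon columns containing at least one gap."""
    gapped = _gapped_codon_columns(alignment)
    best = run = 0
    for g in gapped:
        run = run + 1 if g else 0
        best = max(best, run)
    return best


def evaluate_qc(alignment: GeneAlignment, params: QCParams) -> QCReport:
    """Score a (trimmed) alignment against the overlap/indel thresholds."""
    gapped = _gapped_codon_columns(alignment)
    n = gapped.size
    overlap = float((~gapped).sum()) / n
    longest = longest_gap_run(alignment)
    passed = overlap >= params.min_overlap_fraction and longest <= params.max_indel_codons
    return QCReport(
        gene_id=alignment.gene_id,
        original_length_codons=n,
        trimmed_length_codons=n,
        overlap_fraction=overlap,
        longest_indel_codons=longest,
        passed=passed,
    )


def trim_and_evaluate(alignment: GeneAlignment, params: QCParams) -> tuple[GeneAlignment, QCReport]:
    """Trim, then score; the report records pre- and post-trim codon counts."""
    trimmed = trim(alignment)
    report = evaluate_qc(trimmed, params)
    report = QCReport(
        gene_id=report.gene_id,
        original_length_codons=alignment.n_codons,
        trimmed_length_codons=trimmed.n_codons,
        overlap_fraction=report.overlap_fraction,
        longest_indel_codons=report.longest_indel_codons,
        passed=report.passed,
    )
    return trimmed, report
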