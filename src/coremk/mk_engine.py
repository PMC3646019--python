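"""McDonald-Kreitman counting and the core-genome neutrality statistics.

Per gene, codon columns are classified into within-ingroup polymorphism
(P_N non-synonymous, P_S synonymous) and ingroup/outgroup fixed differences
(D_N, D_S).  Codons that differ at more than one position are resolved by
averaging over all shortest mutational pathways that avoid stop codons
(Nei-Gojobori-style pathway counting), which is why the counts are reals.

Per-gene summaries:

    NI  = (P_N / P_S) / (D_N / D_S)          neutrality index
    DoS = D_N/(D_N+D_S) - P_N/(P_N+P_S)      direction of selection

NI is undefined when P_S == 0 or D_N == 0 (computed in the cross-multiplied
form P_N*D_S / (P_S*D_N), so D_S == 0 with a defined denominator yields 0).
DoS is undefined when either margin P_N+P_S or D_N+D_S is zero.  Deviation
from neutrality is tested on the rounded 2x2 table with a chi-squared test
(no continuity correction), falling back to Fisher's exact test when any
expected cell is below 5.

Across genes, the weighted core-genome neutrality index pools the per-gene
2x2 tables Mantel-Haenszel style:

    NI_TG = sum_i[ D_Si * P_Ni / (P_Si + D_Si) ]
          / sum_i[ P_Si * D_Ni / (P_Si + D_Si) ]

Genes with P_S + D_S == 0 carry no weight and are skipped.  The 95% CI is a
seeded nonparametric bootstrap over genes (percentile method).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import AggregateError, CountError, InputError
from .popgen import (
    DiversityStats,
    consensus_codon,
    diversity_stats,
    outgroup_representative,
)
from .recombination import phi_test
from .sequence_io import GeneAlignment, GeneticCode, get_code
from .phylo import TaxonSplit, first_split, is_congruent, jc69_distance, upgma
from .errors import DistanceError

Number = Union[int, float]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class MKCounts:
    """The 2x2 McDonald-Kreitman table for one gene."""

    gene_id: str
    P_N: float
    P_S: float
    D_N: float
    D_S: float
    codons_used: int = 0

    def __post_init__(self):
        for name in ("P_N", "P_S", "D_N", "D_S"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Codon pathway counting

_PATHWAY_CACHE: Dict[Tuple[str, str, int], Tuple[float, float]] = {}


def pathway_counts(codon_a: str, codon_b: str, code: GeneticCode) -> Tuple[float, float]:
    """(non-synonymous, synonymous) changes between two codons, averaged over
    all shortest mutational pathways whose intermediate codons are not stops.

    If every shortest pathway passes through a stop codon, the average is
    taken over all shortest pathways instead (rare; logged nowhere, the
    fallback keeps the totals conserved).
    """
    key = (codon_a, codon_b, code.table_id)
    cached = _PATHWAY_CACHE.get(key)
    if cached is not None:
        return cached
    diff = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff:
        _PATHWAY_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0

    def walk(allow_stops: bool) -> List[Tuple[int, int]]:
        paths = []
        for order in permutations(diff):
            cur = list(codon_a)
            n_nonsyn = n_syn = 0
            ok = True
            for step, pos in enumerate(order):
                prev = "".join(cur)
                cur[pos] = codon_b[pos]
                now = "".join(cur)
                if not allow_stops and step < len(order) - 1 and code.is_stop(now):
                    ok = False
                    break
                if code.translate_codon(prev) == code.translate_codon(now):
                    n_syn += 1
                else:
                    n_nonsyn += 1
            if ok:
                paths.append((n_nonsyn, n_syn))
        return paths

    paths = walk(allow_stops=False)
    if not paths:
        paths = walk(allow_stops=True)
    n = sum(p[0] for p in paths) / len(paths)
    s = sum(p[1] for p in paths) / len(paths)
    _PATHWAY_CACHE[key] = (n, s)
    return n, s


# ---------------------------------------------------------------------------
# Counting


def count_mk(
    alignment: GeneAlignment,
    ingroup: Iterable[str],
    outgroup: Iterable[str],
    code: Optional[GeneticCode] = None,
    outgroup_mode: str = "consensus",
) -> MKCounts:
    """Classify codon columns of one gene into the MK 2x2 table.

    Bookkeeping rules:

    * a codon column with a gap or ambiguity in any counted sequence is
      skipped entirely;
    * a column segregating within the ingroup contributes only to
      polymorphism: each distinct minor codon is connected to the ingroup
      majority codon by pathway counting (one contribution per distinct
      variant, not per strain);
    * at ingroup-monomorphic columns, the difference to the outgroup
      representative (majority-rule consensus by default) is counted as
      divergence; consensus-less columns are skipped for divergence.
    """
    code = code or get_code()
    ingroup = sorted(set(ingroup))
    outgroup = sorted(set(outgroup))
    if len(ingroup) < 2:
        raise InputError("ingroup must contain at least 2 sequences")
    if len(outgroup) < 1:
        raise InputError("outgroup must contain at least 1 sequence")
    if set(ingroup) & set(outgroup):
        raise InputError("ingroup and outgroup overlap")
    for label in (*ingroup, *outgroup):
        if label not in alignment.sequences:
            raise InputError(f"label {label!r} not in alignment {alignment.gene_id}")

    rows = list(ingroup) + list(outgroup)
    m = alignment.to_matrix(rows)
    n_in = len(ingroup)
    n_codons = alignment.length // 3

    valid = np.isin(m, np.array([ord(c) for c in "ACGT"], dtype=np.uint8))
    uniform = (m == m[0:1]).all(axis=0) & valid.all(axis=0)
    codon_uniform = uniform.reshape(n_codons, 3).all(axis=1)

    if outgroup_mode not in ("consensus", "first"):
        raise InputError(f"unknown outgroup mode {outgroup_mode!r}")
    use_first = outgroup_mode == "first"
    P_N = P_S = D_N = D_S = 0.0
    usable = int(codon_uniform.sum())

    for j in np.flatnonzero(~codon_uniform):
        j = int(j)
        lo = 3 * j
        codons = [bytes(m[i, lo : lo + 3]).decode() for i in range(m.shape[0])]
        if any(not set(c) <= _ACGT for c in codons):
            continue
        usable += 1
        ing = codons[:n_in]
        out = codons[n_in:]
        distinct = sorted(set(ing))
        if len(distinct) > 1:
            counts: Dict[str, int] = {}
            for c in ing:
                counts[c] = counts.get(c, 0) + 1
            major = min(sorted(counts), key=lambda c: (-counts[c], c))
            for c in distinct:
                if c == major:
                    continue
                n, s = pathway_counts(major, c, code)
                P_N += n
                P_S += s
        else:
            ref = distinct[0]
            if use_first or len(out) == 1:
                rep = out[0]
            else:
                rep = consensus_codon(out)
                if rep is None:
                    continue
            if rep != ref:
                n, s = pathway_counts(ref, rep, code)
                D_N += n
                D_S += s

    if usable == 0:
        raise CountError(f"{alignment.gene_id}: no usable codon columns")
    return MKCounts(alignment.gene_id, P_N, P_S, D_N, D_S, codons_used=usable)


# ---------------------------------------------------------------------------
# Per-gene statistics


def _all_integral(*values: Number) -> bool:
    return all(float(v).is_integer() for v in values)


def neutrality_index(counts: MKCounts) -> Optional[float]:
    """NI = (P_N/P_S)/(D_N/D_S); None when P_S == 0 or D_N == 0.

    Computed as P_N*D_S / (P_S*D_N) so that D_S == 0 (with a non-zero
    denominator) gives 0 rather than a division error.  Integer-valued
    tables are evaluated with exact rational arithmetic.
    """
    if counts.P_S == 0 or counts.D_N == 0:
        return None
    if _all_integral(counts.P_N, counts.P_S, counts.D_N, counts.D_S):
        return float(
            Fraction(int(counts.P_N) * int(counts.D_S), int(counts.P_S) * int(counts.D_N))
        )
    return (counts.P_N * counts.D_S) / (counts.P_S * counts.D_N)


def direction_of_selection(counts: MKCounts) -> Optional[float]:
    """DoS = D_N/(D_N+D_S) - P_N/(P_N+P_S); None when either margin is 0."""
    p_tot = counts.P_N + counts.P_S
    d_tot = counts.D_N + counts.D_S
    if p_tot == 0 or d_tot == 0:
        return None
    if _all_integral(counts.P_N, counts.P_S, counts.D_N, counts.D_S):
        return float(
            Fraction(int(counts.D_N), int(d_tot)) - Fraction(int(counts.P_N), int(p_tot))
        )
    return counts.D_N / d_tot - counts.P_N / p_tot


def mk_significance(counts: MKCounts) -> Tuple[Optional[float], Optional[str]]:
    """P-value for departure from equal P_N:P_S and D_N:D_S ratios.

    The (fractional) counts are rounded to the nearest integer for the 2x2
    table.  Chi-squared without continuity correction is used unless any
    expected cell is below 5, in which case Fisher's exact test substitutes.
    Returns (p, test-name), or (None, None) for an all-zero table.
    """
    table = np.rint(
        [[counts.P_N, counts.P_S], [counts.D_N, counts.D_S]]
    ).astype(np.int64)
    total = int(table.sum())
    if total == 0:
        return None, None
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / total
    if (expected < 5).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), "chi2"


# ---------------------------------------------------------------------------
# Core-genome pooling


@dataclass
class GeneResult:
    gene_id: str
    counts: MKCounts
    NI: Optional[float]
    DoS: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float]
    test_used: Optional[str]
    diversity: Optional[DiversityStats]
    congruent: Optional[bool]
    phi_p: Optional[float]
    included: bool = True


@dataclass
class CoreGenomeResult:
    direction_label: str
    NI_TG: float
    ci_low: float
    ci_high: float
    n_genes_included: int
    n_genes_excluded: int = 0
    per_gene: List[GeneResult] = field(default_factory=list)
    failed_genes: List[str] = field(default_factory=list)
    ingroup: FrozenSet[str] = frozenset()
    outgroup: FrozenSet[str] = frozenset()


def ni_tg_terms(counts: MKCounts) -> Optional[Tuple[float, float]]:
    """Mantel-Haenszel style (numerator, denominator) weight terms for a gene."""
    w = counts.P_S + counts.D_S
    if w == 0:
        return None
    return (counts.D_S * counts.P_N / w, counts.P_S * counts.D_N / w)


def ni_tg(
    all_counts: Sequence[MKCounts],
    n_bootstrap: int = 10_000,
    seed: int = 0,
    direction_label: str = "",
    ci_level: float = 0.95,
) -> CoreGenomeResult:
    """Pool per-gene MK tables into the weighted core-genome neutrality index.

    Genes with P_S + D_S == 0 carry zero weight and are skipped (counted as
    excluded).  The point estimate uses exact rational arithmetic when every
    retained table is integer-valued.  The CI resamples genes with
    replacement (percentile method, seeded); resamples whose denominator sum
    is zero are dropped.
    """
    included: List[MKCounts] = []
    excluded = 0
    for c in all_counts:
        if c.P_S + c.D_S == 0:
            excluded += 1
        else:
            included.append(c)
    if not included:
        raise AggregateError("no gene carries synonymous weight (all P_S + D_S == 0)")

    if all(
        _all_integral(c.P_N, c.P_S, c.D_N, c.D_S) for c in included
    ):
        num = sum(
            Fraction(int(c.D_S) * int(c.P_N), int(c.P_S) + int(c.D_S)) for c in included
        )
        den = sum(
            Fraction(int(c.P_S) * int(c.D_N), int(c.P_S) + int(c.D_S)) for c in included
        )
        if den == 0:
            raise AggregateError("NI_TG denominator sum is zero")
        point = float(num / den)
    else:
        terms = [ni_tg_terms(c) for c in included]
        num_f = sum(t[0] for t in terms)
        den_f = sum(t[1] for t in terms)
        if den_f == 0:
            raise AggregateError("NI_TG denominator sum is zero")
        point = num_f / den_f

    num_arr = np.array([ni_tg_terms(c)[0] for c in included])
    den_arr = np.array([ni_tg_terms(c)[1] for c in included])
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        k = len(included)
        idx = rng.integers(0, k, size=(n_bootstrap, k))
        num_sums = num_arr[idx].sum(axis=1)
        den_sums = den_arr[idx].sum(axis=1)
        ok = den_sums > 0
        ratios = num_sums[ok] / den_sums[ok]
        if ratios.size:
            alpha = 100.0 * (1.0 - ci_level) / 2.0
            ci_low, ci_high = np.percentile(ratios, [alpha, 100.0 - alpha])
        else:
            ci_low = ci_high = float("nan")
    else:
        ci_low = ci_high = float("nan")

    return CoreGenomeResult(
        direction_label=direction_label,
        NI_TG=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_genes_included=len(included),
        n_genes_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# One full test direction


@dataclass(frozen=True)
class MKConfig:
    """Settings for one analysis direction."""

    table_id: int = 11
    outgroup_mode: str = "consensus"
    n_bootstrap: int = 10_000
    seed: int = 0
    check_congruency: bool = True
    exclude_incongruent: bool = True
    run_phi: bool = True
    phi_window: int = 100
    phi_permutations: int = 1000
    phi_alpha: float = 0.05
    exclude_recombinants: bool = False


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-stage/per-gene seed derived from the top-level seed."""
    return (int(seed) * 2_654_435_761 + zlib.crc32(name.encode())) % (2**31 - 1)


def benjamini_hochberg(pvals: Sequence[Optional[float]]) -> List[Optional[float]]:
    """BH q-values, passing None entries through."""
    defined = [(i, p) for i, p in enumerate(pvals) if p is not None]
    out: List[Optional[float]] = [None] * len(pvals)
    if defined:
        qs = stats.false_discovery_control([p for _, p in defined], method="bh")
        for (i, _), q in zip(defined, qs):
            out[i] = float(q)
    return out


def run_direction(
    genes: Sequence[GeneAlignment],
    split: TaxonSplit,
    ingroup: FrozenSet[str],
    config: MKConfig = MKConfig(),
    direction_label: Optional[str] = None,
) -> CoreGenomeResult:
    """Per-gene MK analysis plus pooled NI_TG for one choice of ingroup clade.

    The other clade of ``split`` is the outgroup.  Genes flagged by the
    congruency filter (and, if configured, the recombination filter) or
    carrying no synonymous weight are excluded from the pooled statistic but
    kept in the per-gene table.
    """
    ingroup = frozenset(ingroup)
    if ingroup == split.clade_a:
        outgroup = split.clade_b
    elif ingroup == split.clade_b:
        outgroup = split.clade_a
    else:
        raise InputError("ingroup must be one clade of the split")
    if len(ingroup) < 2:
        raise InputError("ingroup clade must have at least 2 members")
    label = direction_label or ("ingroup=" + "+".join(sorted(ingroup)))
    code = get_code(config.table_id)

    results: List[GeneResult] = []
    failed: List[str] = []
    for gene in genes:
        congruent: Optional[bool] = None
        if config.check_congruency:
            try:
                gene_tree = upgma(jc69_distance(gene))
                congruent = is_congruent(gene_tree, split)
            except DistanceError:
                congruent = None
        phi_p: Optional[float] = None
        if config.run_phi:
            phi = phi_test(
                gene,
                n_permutations=config.phi_permutations,
                seed=substream_seed(config.seed, f"phi:{gene.gene_id}"),
                window=config.phi_window,
            )
            phi_p = phi.p_value
        try:
            counts = count_mk(
                gene, ingroup, outgroup, code=code, outgroup_mode=config.outgroup_mode
            )
        except CountError:
            failed.append(gene.gene_id)
            continue
        div = diversity_stats(
            gene, ingroup, outgroup, code=code, outgroup_mode=config.outgroup_mode
        )
        p, test = mk_significance(counts)
        results.append(
            GeneResult(
                gene_id=gene.gene_id,
                counts=counts,
                NI=neutrality_index(counts),
                DoS=direction_of_selection(counts),
                p_value=p,
                q_value=None,
                test_used=test,
                diversity=div,
                congruent=congruent,
                phi_p=phi_p,
            )
        )

    qvals = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = q

    for r in results:
        r.included = True
        if r.counts.P_S + r.counts.D_S == 0:
            r.included = False
        if config.exclude_incongruent and r.congruent is False:
            r.included = False
        if (
            config.exclude_recombinants
            and r.phi_p is not None
            and r.phi_p <= config.phi_alpha
        ):
            r.included = False

    pooled = ni_tg(
        [r.counts for r in results if r.included],
        n_bootstrap=config.n_bootstrap,
        seed=substream_seed(config.seed, f"bootstrap:{label}"),
        direction_label=label,
    )
    pooled.per_gene = results
    pooled.failed_genes = failed
    pooled.n_genes_excluded = len(results) - sum(r.included for r in results)
    pooled.ingroup = ingroup
    pooled.outgroup = outgroup
    return pooled
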