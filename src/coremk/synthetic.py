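"""Forward simulator for core-genome ortholog sets with known truth.

Each gene starts from a random stop-free ancestral CDS.  The outgroup
lineage accumulates fixed differences: nucleotide proposals (K80-like, 2:1
transition bias by default) are accepted with probability 1 when synonymous
and ``omega_divergence`` when non-synonymous; proposals creating a stop
codon are always rejected.  Ingroup strains then receive segregating
mutations whose expected number is theta-scaled (theta * sites * a_{n-1},
the Watterson expectation), with non-synonymous acceptance
``omega_polymorphism``.  Setting the two omegas equal gives a neutral MK
contrast; omega_divergence > omega_polymorphism emulates adaptive
divergence.

Two genealogy models assign mutation carriers within the ingroup:

* ``star``: each mutation hits a uniformly random subset of k strains with
  P(k) proportional to 1/k (the neutral frequency spectrum).  Carrier sets
  are independent across mutations, so recurrent sharing patterns are not
  tree-consistent — fine for MK counting, not for homoplasy-sensitive
  statistics.
* ``coalescent``: a Kingman coalescent genealogy is drawn per gene and
  mutations fall on branches proportionally to branch length, giving
  tree-consistent (homoplasy-free, up to recurrent mutation at a site)
  polymorphism — the right null for the PHI test.

Recombinant genes come in two flavours: ``inter`` replaces a contiguous
half-gene block of one ingroup strain with the outgroup-lineage sequence
(breaking the gene tree's first split, the signal the congruency filter
looks for), while ``intra`` evolves the two halves of the ingroup on two
independent coalescent genealogies (crossing splits between halves, the
signal PHI looks for).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .popgen import harmonic_number
from .sequence_io import GeneAlignment, GeneticCode, get_code, write_gene_alignment

_NT = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated core genome."""

    n_genes: int = 200
    gene_length_codons: int = 300
    n_ingroup: int = 6
    n_outgroup: int = 2
    divergence_subs_per_site: float = 0.03
    polymorphism_theta: float = 0.01
    omega_divergence: float = 1.0
    omega_polymorphism: float = 1.0
    recombinant_fraction: float = 0.0
    recombinant_kind: str = "inter"  # "inter" | "intra"
    genealogy: str = "star"  # "star" | "coalescent"
    transition_bias: float = 2.0
    table_id: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.gene_length_codons < 1:
            raise ConfigError("n_genes and gene_length_codons must be positive")
        if self.n_ingroup < 2 or self.n_outgroup < 1:
            raise ConfigError("need >= 2 ingroup and >= 1 outgroup strains")
        if self.divergence_subs_per_site < 0 or self.polymorphism_theta < 0:
            raise ConfigError("rates must be non-negative")
        if not 0 <= self.recombinant_fraction <= 1:
            raise ConfigError("recombinant_fraction must be in [0, 1]")
        if self.omega_divergence < 0 or self.omega_polymorphism < 0:
            raise ConfigError("omegas must be non-negative")
        if self.recombinant_kind not in ("inter", "intra"):
            raise ConfigError("recombinant_kind must be 'inter' or 'intra'")
        if self.genealogy not in ("star", "coalescent"):
            raise ConfigError("genealogy must be 'star' or 'coalescent'")
        if self.transition_bias <= 0:
            raise ConfigError("transition_bias must be positive")


@dataclass(frozen=True)
class GeneTruth:
    """Per-gene ground truth recorded while mutations were applied."""

    gene_id: str
    p_n: int
    p_s: int
    d_n: int
    d_s: int
    recombinant: bool


@dataclass(frozen=True)
class RecoveryReport:
    """Truth-vs-pipeline comparison across genes."""

    corr_p_n: float
    corr_p_s: float
    corr_d_n: float
    corr_d_s: float
    congruency_confusion: Dict[str, int]
    phi_confusion: Dict[str, int]


# ---------------------------------------------------------------------------
# Mutation machinery


def _random_cds(rng: np.random.Generator, n_codons: int, code: GeneticCode) -> List[str]:
    sense = code.sense_codons
    idx = rng.integers(0, len(sense), size=n_codons)
    return list("".join(sense[i] for i in idx))


def _propose_nt(rng: np.random.Generator, old: str, kappa: float) -> str:
    """K80-like proposal: transition with weight kappa, transversions 1 each."""
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[old]
    return _TRANSVERSIONS[old][int(rng.integers(0, 2))]


def _codon_at(seq: List[str], pos: int) -> Tuple[int, str]:
    start = 3 * (pos // 3)
    return start, "".join(seq[start : start + 3])


def _mutate_lineage(
    rng: np.random.Generator,
    seq: List[str],
    n_proposals: int,
    omega: float,
    code: GeneticCode,
    kappa: float,
) -> Tuple[int, int]:
    """Apply accepted substitutions in place; returns (non-syn, syn) counts."""
    d_n = d_s = 0
    L = len(seq)
    for _ in range(n_proposals):
        pos = int(rng.integers(0, L))
        old = seq[pos]
        new = _propose_nt(rng, old, kappa)
        start, codon = _codon_at(seq, pos)
        mutated = codon[: pos - start] + new + codon[pos - start + 1 :]
        if code.is_stop(mutated):
            continue
        syn = code.translate_codon(codon) == code.translate_codon(mutated)
        if not syn and rng.random() >= omega:
            continue
        seq[pos] = new
        if syn:
            d_s += 1
        else:
            d_n += 1
    return d_n, d_s


def _star_carriers(rng: np.random.Generator, n: int) -> np.ndarray:
    ks = np.arange(1, n)
    probs = (1.0 / ks) / (1.0 / ks).sum()
    k = int(rng.choice(ks, p=probs))
    return rng.choice(n, size=k, replace=False)


def _coalescent_edges(
    rng: np.random.Generator, n: int
) -> Tuple[List[FrozenSet[int]], np.ndarray]:
    """Kingman coalescent: branch leaf-sets and lengths (proper subsets only)."""
    active: Dict[int, FrozenSet[int]] = {i: frozenset([i]) for i in range(n)}
    birth: Dict[int, float] = {i: 0.0 for i in range(n)}
    sets: List[FrozenSet[int]] = []
    lengths: List[float] = []
    t = 0.0
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        k = len(ids)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = ids[min(i, j)], ids[max(i, j)]
        for node in (a, b):
            sets.append(active[node])
            lengths.append(t - birth[node])
        merged = active[a] | active[b]
        ids = [x for x in ids if x not in (a, b)] + [next_id]
        active[next_id] = merged
        birth[next_id] = t
        next_id += 1
    return sets, np.asarray(lengths)


class _CarrierSampler:
    """Draws carrier index sets for segregating mutations."""

    def __init__(self, rng: np.random.Generator, n: int, genealogy: str):
        self.rng = rng
        self.n = n
        self.genealogy = genealogy
        if genealogy == "coalescent":
            self.sets, lengths = _coalescent_edges(rng, n)
            self.probs = lengths / lengths.sum()

    def draw(self) -> np.ndarray:
        if self.genealogy == "star":
            return _star_carriers(self.rng, self.n)
        idx = int(self.rng.choice(len(self.sets), p=self.probs))
        return np.fromiter(self.sets[idx], dtype=int)


def _apply_polymorphism(
    rng: np.random.Generator,
    seqs: List[List[str]],
    n_proposals: int,
    omega: float,
    code: GeneticCode,
    kappa: float,
    sampler: "_CarrierSampler",
    positions: Optional[np.ndarray] = None,
) -> Tuple[int, int]:
    """Add segregating mutations in place; returns accepted (non-syn, syn)."""
    p_n = p_s = 0
    L = len(seqs[0])
    for _ in range(n_proposals):
        pos = int(positions[rng.integers(0, len(positions))]) if positions is not None else int(
            rng.integers(0, L)
        )
        carriers = sampler.draw()
        old = seqs[carriers[0]][pos]
        new = _propose_nt(rng, old, kappa)
        # classify and stop-check in each carrier's current codon context
        syn = None
        blocked = False
        for c in carriers:
            seq = seqs[c]
            if seq[pos] != old:
                blocked = True  # recurrent mutation altered the context; skip
                break
            start, codon = _codon_at(seq, pos)
            mutated = codon[: pos - start] + new + codon[pos - start + 1 :]
            if code.is_stop(mutated):
                blocked = True
                break
            this_syn = code.translate_codon(codon) == code.translate_codon(mutated)
            syn = this_syn if syn is None else (syn and this_syn)
        if blocked:
            continue
        if not syn and rng.random() >= omega:
            continue
        for c in carriers:
            seqs[c][pos] = new
        if syn:
            p_s += 1
        else:
            p_n += 1
    return p_n, p_s


# ---------------------------------------------------------------------------
# Gene-level and genome-level simulation


def ingroup_labels(config: SimulationConfig) -> List[str]:
    return [f"ing{i:02d}" for i in range(config.n_ingroup)]


def outgroup_labels(config: SimulationConfig) -> List[str]:
    return [f"out{i:02d}" for i in range(config.n_outgroup)]


def simulate_gene(
    gene_id: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    recombinant: bool = False,
) -> Tuple[GeneAlignment, GeneTruth]:
    code = get_code(config.table_id)
    L = 3 * config.gene_length_codons
    kappa = config.transition_bias
    anc = _random_cds(rng, config.gene_length_codons, code)

    out_lineage = list(anc)
    n_div = int(rng.poisson(config.divergence_subs_per_site * L))
    d_n, d_s = _mutate_lineage(
        rng, out_lineage, n_div, config.omega_divergence, code, kappa
    )

    n = config.n_ingroup
    seqs_in = [list(anc) for _ in range(n)]
    n_poly = int(rng.poisson(config.polymorphism_theta * L * harmonic_number(n - 1)))
    if recombinant and config.recombinant_kind == "intra":
        bp = 3 * (config.gene_length_codons // 2)
        left = np.arange(0, bp)
        right = np.arange(bp, L)
        sampler_a = _CarrierSampler(rng, n, "coalescent")
        sampler_b = _CarrierSampler(rng, n, "coalescent")
        n_left = int(rng.binomial(n_poly, bp / L))
        p_n1, p_s1 = _apply_polymorphism(
            rng, seqs_in, n_left, config.omega_polymorphism, code, kappa, sampler_a, left
        )
        p_n2, p_s2 = _apply_polymorphism(
            rng, seqs_in, n_poly - n_left, config.omega_polymorphism, code, kappa,
            sampler_b, right,
        )
        p_n, p_s = p_n1 + p_n2, p_s1 + p_s2
    else:
        sampler = _CarrierSampler(rng, n, config.genealogy)
        p_n, p_s = _apply_polymorphism(
            rng, seqs_in, n_poly, config.omega_polymorphism, code, kappa, sampler
        )

    m = config.n_outgroup
    seqs_out = [list(out_lineage) for _ in range(m)]
    if m >= 2:
        n_poly_out = int(
            rng.poisson(config.polymorphism_theta * L * harmonic_number(m - 1))
        )
        sampler_out = _CarrierSampler(rng, m, config.genealogy)
        _apply_polymorphism(
            rng, seqs_out, n_poly_out, config.omega_polymorphism, code, kappa, sampler_out
        )

    if recombinant and config.recombinant_kind == "inter":
        target = int(rng.integers(0, n))
        bp = 3 * (config.gene_length_codons // 2)
        if rng.random() < 0.5:
            lo, hi = 0, bp
        else:
            lo, hi = bp, L
        seqs_in[target][lo:hi] = out_lineage[lo:hi]

    rows = {
        label: "".join(seq)
        for label, seq in zip(ingroup_labels(config), seqs_in)
    }
    rows.update(
        {label: "".join(seq) for label, seq in zip(outgroup_labels(config), seqs_out)}
    )
    aln = GeneAlignment.from_dict(gene_id, rows)
    return aln, GeneTruth(gene_id, p_n, p_s, d_n, d_s, recombinant)


def simulate_core_genome(
    config: SimulationConfig,
) -> Tuple[List[GeneAlignment], List[GeneTruth]]:
    """Simulate all genes; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_rec = int(round(config.recombinant_fraction * config.n_genes))
    rec_idx = set(
        rng.choice(config.n_genes, size=n_rec, replace=False).tolist()
    ) if n_rec else set()
    genes: List[GeneAlignment] = []
    truths: List[GeneTruth] = []
    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        aln, truth = simulate_gene(gene_id, config, rng, recombinant=g in rec_idx)
        genes.append(aln)
        truths.append(truth)
    return genes, truths


def write_simulation(
    genes: Sequence[GeneAlignment], truths: Sequence[GeneTruth], out_dir
) -> None:
    """Write per-gene FASTA files plus a truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for aln in genes:
        write_gene_alignment(aln, out / f"{aln.gene_id}.fasta")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("gene_id\tp_n\tp_s\td_n\td_s\trecombinant\n")
        for t in truths:
            fh.write(
                f"{t.gene_id}\t{t.p_n}\t{t.p_s}\t{t.d_n}\t{t.d_s}\t{int(t.recombinant)}\n"
            )


# ---------------------------------------------------------------------------
# Random ultrametric trees (for stressing the clustering stage)


def random_ultrametric_tree(rng: np.random.Generator, labels: Sequence[str]):
    """Random topology by sequential joins; parent heights strictly exceed
    child heights, so the tree is a valid ultrametric clustering tree."""
    from .phylo import Tree, TreeNode

    nodes = [TreeNode(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        h = max(a.height, b.height) + float(rng.uniform(0.05, 0.3))
        nodes.append(TreeNode(height=h, children=[a, b]))
    return Tree(nodes[0])


# ---------------------------------------------------------------------------
# Truth vs pipeline


def _corr(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def truth_vs_estimate(
    truths: Sequence[GeneTruth],
    gene_results,
    phi_alpha: float = 0.05,
) -> RecoveryReport:
    """Correlate true and counted P/D and tabulate recombinant detection.

    ``gene_results`` is a list of :class:`coremk.mk_engine.GeneResult` for
    the same genes (matched by gene_id).
    """
    by_id = {r.gene_id: r for r in gene_results}
    paired = [(t, by_id[t.gene_id]) for t in truths if t.gene_id in by_id]
    cc = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    pc = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for t, r in paired:
        flagged_tree = r.congruent is False
        flagged_phi = r.phi_p is not None and r.phi_p <= phi_alpha
        cc["tp" if (t.recombinant and flagged_tree) else
           "fn" if t.recombinant else
           "fp" if flagged_tree else "tn"] += 1
        pc["tp" if (t.recombinant and flagged_phi) else
           "fn" if t.recombinant else
           "fp" if flagged_phi else "tn"] += 1
    return RecoveryReport(
        corr_p_n=_corr([t.p_n for t, _ in paired], [r.counts.P_N for _, r in paired]),
        corr_p_s=_corr([t.p_s for t, _ in paired], [r.counts.P_S for _, r in paired]),
        corr_d_n=_corr([t.d_n for t, _ in paired], [r.counts.D_N for _, r in paired]),
        corr_d_s=_corr([t.d_s for t, _ in paired], [r.counts.D_S for _, r in paired]),
        congruency_confusion=cc,
        phi_confusion=pc,
    )
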