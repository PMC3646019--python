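"""Pairwise homoplasy index (PHI) permutation test for recombination.

For a pair of parsimony-informative sites, the refined incompatibility
score is the number of extra state changes (beyond the one-per-extra-state
minimum) that any tree must spend to explain both characters jointly.  It
is computed as the cycle rank of the partition-intersection graph whose
vertices are the observed states of the two characters and whose edges are
the observed joint state pairs: a score of 0 means the pair is compatible
with some tree, and for two binary characters a score of 1 is exactly the
four-gamete condition.

PHI is the mean score over informative-site pairs that lie within a window
of each other (default 100 nt).  Recombination inflates incompatibility
between distant sites while leaving nearby sites concordant, so the
observed windowed statistic is LOW relative to the same statistic after
permuting the order of the informative sites; the permutation p-value is
therefore the lower tail, p = (1 + #{perm <= obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .sequence_io import GeneAlignment

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class PhiResult:
    gene_id: str
    informative_sites: int
    phi_observed: Optional[float]
    p_value: Optional[float]
    n_permutations: int


def pairwise_incompatibility(site_i: Sequence[str], site_j: Sequence[str]) -> int:
    """Refined incompatibility score of two character columns.

    Rows where either column carries a gap/ambiguity are dropped for the
    pair.  Score = E - V + C of the state-pair graph (cycle rank), i.e. 0
    iff the two characters fit on a single tree without extra homoplasy.
    """
    pairs = set()
    for a, b in zip(site_i, site_j):
        if a in _ACGT and b in _ACGT:
            pairs.add((a, b))
    if not pairs:
        return 0
    left = {a for a, _ in pairs}
    right = {b for _, b in pairs}
    vertices = [("L", a) for a in left] + [("R", b) for b in right]
    index = {v: i for i, v in enumerate(vertices)}
    parent = list(range(len(vertices)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(index[("L", a)]), find(index[("R", b)])
        if ra != rb:
            parent[ra] = rb
    components = len({find(i) for i in range(len(vertices))})
    return len(pairs) - len(vertices) + components


def informative_site_indices(alignment: GeneAlignment) -> List[int]:
    """Columns with >= 2 states each carried by >= 2 sequences (gaps ignored)."""
    m = alignment.to_matrix()
    out: List[int] = []
    codes = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    for site in range(m.shape[1]):
        col = m[:, site]
        col = col[np.isin(col, codes)]
        if col.size < 4:
            continue
        _, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            out.append(site)
    return out


def _score_matrix(alignment: GeneAlignment, sites: Sequence[int]) -> np.ndarray:
    m = alignment.to_matrix()
    cols = ["".join(chr(c) for c in m[:, s]) for s in sites]
    k = len(sites)
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            scores[i, j] = scores[j, i] = pairwise_incompatibility(cols[i], cols[j])
    return scores


def phi_statistic(
    scores: np.ndarray, positions: Sequence[int], window: int = 100
) -> Optional[float]:
    """Mean incompatibility over site pairs at most ``window`` nt apart."""
    pos = np.asarray(positions)
    diff = np.abs(pos[:, None] - pos[None, :])
    mask = np.triu((diff > 0) & (diff <= window))
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        return None
    return float(scores[mask].sum()) / n_pairs


def phi_test(
    alignment: GeneAlignment,
    n_permutations: int = 1000,
    seed: int = 0,
    window: int = 100,
) -> PhiResult:
    """Windowed PHI with a site-order permutation p-value.

    Genes with fewer than two informative sites (or no in-window pair) get
    ``p_value=None`` — they pass any downstream filter by default.
    """
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    sites = informative_site_indices(alignment)
    k = len(sites)
    if k < 2:
        return PhiResult(alignment.gene_id, k, None, None, n_permutations)
    scores = _score_matrix(alignment, sites)
    observed = phi_statistic(scores, sites, window)
    if observed is None:
        return PhiResult(alignment.gene_id, k, None, None, n_permutations)

    pos = np.asarray(sites)
    diff = np.abs(pos[:, None] - pos[None, :])
    mask = np.triu((diff > 0) & (diff <= window))
    n_pairs = int(mask.sum())
    rng = np.random.default_rng(seed)
    n_low = 0
    tol = 1e-12
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        stat = float(scores[np.ix_(perm, perm)][mask].sum()) / n_pairs
        if stat <= observed + tol:
            n_low += 1
    p = (1.0 + n_low) / (n_permutations + 1.0)
    return PhiResult(alignment.gene_id, k, observed, p, n_permutations)
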