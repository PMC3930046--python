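"""Population-genetic summaries: allele frequencies, Latter's F_ST distance,
Weir–Cockerham theta, and UPGMA population trees with locus bootstrap.

Latter's distance between two populations with per-locus allele-frequency
vectors x, y (here biallelic, x = (1-p, p)) is

    D = [ sum_loci sum_alleles (x - y)^2 / 2 ] / [ sum_loci (1 - sum_alleles x y) ],

the squared frequency difference normalised by the expected
between-population heterozygosity — the F_ST-style distance used by
population tree builders. Weir & Cockerham's (1984) theta is computed from
the standard a/b/c variance components, per locus and multilocus as the
ratio of summed components.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .types import (
    MISSING,
    GenotypeMatrix,
    PopDistanceMatrix,
    PopTree,
    PopTreeNode,
    PopulationFrequencies,
)

logger = logging.getLogger(__name__)


def allele_frequencies(matrix: GenotypeMatrix) -> PopulationFrequencies:
    """Per-population B-allele frequencies from functionally diploid calls.

    freq_b = (n_het + 2 n_homB) / (2 n_obs) per population per locus; NaN
    where a population has no non-missing call at a locus.
    """
    labels = matrix.pop_labels
    P, L = len(labels), matrix.n_loci
    freq = np.full((P, L), np.nan)
    n_obs = np.zeros((P, L), dtype=int)
    for k, label in enumerate(labels):
        calls = matrix.calls[matrix.pop_indices(label)]
        obs = calls != MISSING
        n_obs[k] = obs.sum(axis=0)
        b_copies = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(n_obs[k] > 0, b_copies / (2.0 * n_obs[k]), np.nan)
    return PopulationFrequencies(labels, list(matrix.loci), freq, n_obs)


def latter_fst_distance(freqs: PopulationFrequencies, pop_x, pop_y) -> float:
    """Latter's F_ST distance between two populations.

    Loci where either population's frequency is undefined are excluded from
    numerator and denominator alike. Identically fixed populations (zero
    expected between-population heterozygosity at every shared locus) get
    distance 0 by convention.
    """
    ix = freqs.pop_index(pop_x) if isinstance(pop_x, str) else int(pop_x)
    iy = freqs.pop_index(pop_y) if isinstance(pop_y, str) else int(pop_y)
    px, py = freqs.freq_b[ix], freqs.freq_b[iy]
    ok = ~(np.isnan(px) | np.isnan(py))
    if not ok.any():
        raise ValueError("no locus with defined frequencies in both populations")
    px, py = px[ok], py[ok]
    # biallelic: sum over both alleles of (x-y)^2 / 2 == (px-py)^2
    numerator = float(np.sum((px - py) ** 2))
    denominator = float(np.sum(1.0 - (px * py + (1.0 - px) * (1.0 - py))))
    if denominator == 0.0:
        logger.info(
            "populations %s and %s identically fixed at all shared loci; "
            "distance set to 0", pop_x, pop_y,
        )
        return 0.0
    return numerator / denominator


def latter_fst_matrix(freqs: PopulationFrequencies) -> PopDistanceMatrix:
    """All pairwise Latter distances as a :class:`PopDistanceMatrix`."""
    k = len(freqs.pop_labels)
    values = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        values[i, j] = values[j, i] = latter_fst_distance(freqs, i, j)
    return PopDistanceMatrix(list(freqs.pop_labels), values)


def wc_fst(matrix: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Weir & Cockerham (1984) theta, per locus and multilocus.

    Per locus the a (among-population), b (among individuals within
    population) and c (within individual) variance components are computed
    from sample sizes, allele frequencies and observed heterozygosity;
    theta = a / (a + b + c). Loci monomorphic overall, or typed in fewer
    than two populations, give NaN and are excluded from the multilocus
    ratio-of-sums estimate.

    Returns ``(theta_per_locus, theta_multilocus)``.
    """
    labels = matrix.pop_labels
    if len(labels) < 2:
        raise ValueError("need >=2 populations")
    L = matrix.n_loci
    pops = [matrix.calls[matrix.pop_indices(lbl)] for lbl in labels]

    # per population per locus: sample size, freq, observed het proportion
    n = np.zeros((len(pops), L))
    p = np.zeros((len(pops), L))
    h = np.zeros((len(pops), L))
    for k, calls in enumerate(pops):
        obs = calls != MISSING
        n[k] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n[k])
            h[k] = np.where(obs, calls == 1, False).sum(axis=0) / n[k]

    a = np.full(L, np.nan)
    b = np.full(L, np.nan)
    c = np.full(L, np.nan)
    for j in range(L):
        use = n[:, j] > 0
        r = int(use.sum())
        nj, pj, hj = n[use, j], p[use, j], h[use, j]
        if r < 2:
            continue
        nbar = nj.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (nj**2).sum() / (r * nbar)) / (r - 1)
        pbar = (nj * pj).sum() / (r * nbar)
        if pbar in (0.0, 1.0):
            continue  # monomorphic overall: theta undefined
        s2 = (nj * (pj - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (nj * hj).sum() / (r * nbar)
        if nc == 0:
            continue
        a[j] = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b[j] = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c[j] = hbar / 2

    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    ok = ~np.isnan(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    multilocus = float(a[ok].sum() / denom) if ok.any() and denom != 0 else float("nan")
    return theta, multilocus


def _cluster_rep(node: PopTreeNode) -> str:
    """Lexicographically smallest leaf label, the cluster's tie-break key."""
    return min(node.leaves())


def upgma(dist: PopDistanceMatrix) -> PopTree:
    """UPGMA (size-weighted average linkage) tree from a distance matrix.

    Each merge joins the pair of clusters at minimal average distance; the
    new node's height is half that distance, so the result is ultrametric
    with heights non-decreasing toward the root. Among tied minimal pairs
    the one whose (smallest-leaf-label) pair sorts first lexicographically
    is merged, making the tree deterministic.
    """
    labels = dist.labels
    if len(labels) < 2:
        raise ValueError("need >=2 labels")
    nodes: dict[int, PopTreeNode] = {
        i: PopTreeNode(height=0.0, label=lbl) for i, lbl in enumerate(labels)
    }
    sizes: dict[int, int] = {i: 1 for i in nodes}
    d: dict[tuple[int, int], float] = {
        (i, j): dist.values[i, j]
        for i, j in itertools.combinations(range(len(labels)), 2)
    }
    next_id = len(labels)
    while len(nodes) > 1:
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((_cluster_rep(nodes[kv[0][0]]), _cluster_rep(nodes[kv[0][1]])))),
            ),
        )
        (i, j), dij = best
        left, right = sorted((nodes[i], nodes[j]), key=_cluster_rep)
        parent = PopTreeNode(height=dij / 2.0, children=[left, right])
        ni, nj = sizes.pop(i), sizes.pop(j)
        del nodes[i], nodes[j]
        # size-weighted average distance from the merged cluster to the rest
        new_d: dict[int, float] = {}
        for k in nodes:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            new_d[k] = (ni * dik + nj * djk) / (ni + nj)
        del d[(i, j)]
        nodes[next_id] = parent
        sizes[next_id] = ni + nj
        for k, v in new_d.items():
            d[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return PopTree(root=next(iter(nodes.values())))


def bootstrap_tree(
    matrix: GenotypeMatrix, n_reps: int = 1000, seed: int = 0
) -> PopTree:
    """Full-data UPGMA tree with locus-bootstrap clade supports.

    Loci are resampled with replacement ``n_reps`` times; each replicate is
    rerun through frequencies -> Latter distances -> UPGMA, and each
    internal node of the full-data tree gets the percentage of replicates
    (rounded to integer) containing its leaf set as a clade. The root, whose
    clade is every leaf, keeps support ``None``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    full = upgma(latter_fst_matrix(allele_frequencies(matrix)))
    counts: dict[frozenset, int] = {clade: 0 for clade in full.clades()}
    L = matrix.n_loci
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep = GenotypeMatrix(
            matrix.individuals,
            matrix.populations,
            [f"r{c}" for c in range(L)],  # resampled loci need unique ids
            matrix.calls[:, idx],
        )
        rep_clades = upgma(latter_fst_matrix(allele_frequencies(rep))).clades()
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    for node in full.internal_nodes():
        if node is full.root:
            continue
        clade = frozenset(node.leaves())
        node.support = int(round(100.0 * counts[clade] / n_reps))
    return full
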