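"""Frequencies, Latter distances, Weir-Cockerham theta, UPGMA, bootstrap."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octopop import (
    GenotypeMatrix,
    PopDistanceMatrix,
    PopSimConfig,
    allele_frequencies,
    bootstrap_tree,
    latter_fst_distance,
    latter_fst_matrix,
    newick_string,
    sim_genotypes,
    sim_population_frequencies,
    upgma,
    wc_fst,
)
from octopop.types import MISSING, PopulationFrequencies

from conftest import make_matrix, paired_pop_matrix


def freqs_from(rows, labels=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or [f"p{i+1}" for i in range(rows.shape[0])]
    return PopulationFrequencies(
        pop_labels=labels,
        loci=[f"L{j+1}" for j in range(rows.shape[1])],
        freq_b=rows,
        n_obs=np.full(rows.shape, 10, dtype=int),
    )


# ---------------------------------------------------------------------------
# allele frequencies

def test_allele_frequency_arithmetic():
    m = make_matrix([[1], [2]], ["p1", "p1"])
    f = allele_frequencies(m)
    assert f.freq_b[0, 0] == pytest.approx(0.75)  # (1 + 2*1) / 4


def test_allele_frequency_all_reference_is_zero():
    m = make_matrix([[0, 0], [0, 0]], ["p1", "p1"])
    assert (allele_frequencies(m).freq_b == 0.0).all()


def test_allele_frequency_missing_population_is_nan():
    m = make_matrix([[1, "NA"], [0, "NA"], [1, 2]], ["p1", "p1", "p2"])
    f = allele_frequencies(m)
    assert np.isnan(f.freq_b[0, 1])
    assert f.n_obs[0, 1] == 0
    assert f.freq_b[1, 1] == pytest.approx(1.0)


def test_allele_frequencies_match_counting_oracle():
    rng = np.random.default_rng(17)
    calls = rng.choice([0, 1, 2, MISSING], size=(12, 7)).astype(np.int8)
    pops = ["a"] * 5 + ["b"] * 7
    m = make_matrix(calls.tolist(), pops)
    f = allele_frequencies(m)
    for k, label in enumerate(["a", "b"]):
        rows = [i for i, p in enumerate(pops) if p == label]
        for j in range(7):
            vals = [calls[i, j] for i in rows if calls[i, j] != MISSING]
            if not vals:
                assert np.isnan(f.freq_b[k, j])
            else:
                assert f.freq_b[k, j] == pytest.approx(
                    sum(vals) / (2 * len(vals))
                )
            assert f.n_obs[k, j] == len(vals)


# ---------------------------------------------------------------------------
# Latter distance

def test_latter_distance_zero_for_identical_frequencies():
    f = freqs_from([[0.3, 0.7, 0.5], [0.3, 0.7, 0.5]])
    assert latter_fst_distance(f, "p1", "p2") == pytest.approx(0.0, abs=1e-12)


def test_latter_distance_opposite_fixation_is_one():
    # x=(1,0), y=(0,1): numerator 1, denominator 1
    f = freqs_from([[0.0], [1.0]])
    assert latter_fst_distance(f, 0, 1) == pytest.approx(1.0, abs=1e-12)


def test_latter_distance_fixed_vs_intermediate():
    # x=(1,0), y=(0.5,0.5): 0.25 / 0.5
    f = freqs_from([[0.0], [0.5]])
    assert latter_fst_distance(f, 0, 1) == pytest.approx(0.5, abs=1e-12)


def test_latter_distance_identically_fixed_convention_zero():
    f = freqs_from([[1.0, 0.0], [1.0, 0.0]])
    assert latter_fst_distance(f, 0, 1) == 0.0


def test_latter_distance_skips_loci_undefined_in_either_population():
    f = freqs_from([[0.0, 0.2], [0.5, np.nan]])
    assert latter_fst_distance(f, 0, 1) == pytest.approx(0.5, abs=1e-12)


_freq = st.floats(0, 1, allow_nan=False).map(lambda v: round(v, 6))


@given(st.lists(st.tuples(_freq, _freq), min_size=1, max_size=8))
def test_latter_distance_symmetric_nonnegative(pairs):
    x = [a for a, _ in pairs]
    y = [b for _, b in pairs]
    f = freqs_from([x, y])
    d_xy = latter_fst_distance(f, 0, 1)
    d_yx = latter_fst_distance(f, 1, 0)
    assert d_xy == pytest.approx(d_yx, abs=1e-12)
    assert d_xy >= 0
    # zero iff the frequency vectors coincide at every locus
    if x == y:
        assert d_xy == pytest.approx(0.0, abs=1e-12)
    else:
        assert d_xy > 0


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

def test_wc_theta_near_one_for_alternative_fixation():
    calls = [[0] * 10] * 20 + [[2] * 10] * 20
    m = make_matrix(calls, ["p1"] * 20 + ["p2"] * 20)
    _, multilocus = wc_fst(m)
    assert abs(multilocus - 1.0) <= 0.01


def test_wc_theta_null_split_near_zero():
    # one panmictic population split arbitrarily in two
    cfg = PopSimConfig(n_pops=2, pop_sizes=(500, 500), n_loci=500,
                       divergence=0.0, seed=31, pop_labels=("x", "y"))
    freqs = sim_population_frequencies(cfg)
    m = sim_genotypes(freqs, (500, 500), seed=32)
    theta, multilocus = wc_fst(m)
    # 3 SE of the per-locus estimates around 0
    se = np.nanstd(theta) / np.sqrt(np.sum(~np.isnan(theta)))
    assert abs(multilocus) <= 3 * se


def test_wc_theta_recovers_balding_nichols_parameter():
    cfg = PopSimConfig(n_pops=2, pop_sizes=(100, 100), n_loci=2000,
                       divergence=0.2, seed=33, pop_labels=("x", "y"))
    freqs = sim_population_frequencies(cfg)
    m = sim_genotypes(freqs, (100, 100), seed=34)
    _, multilocus = wc_fst(m)
    assert abs(multilocus - 0.2) <= 0.03


def test_wc_theta_monomorphic_locus_is_excluded():
    m = make_matrix([[0, 0], [0, 1], [0, 2], [0, 1]], ["p1", "p1", "p2", "p2"])
    theta, multilocus = wc_fst(m)
    assert np.isnan(theta[0])
    assert not np.isnan(theta[1])
    assert not np.isnan(multilocus)


# ---------------------------------------------------------------------------
# UPGMA

def oracle_upgma(labels, values):
    """Independent UPGMA: cluster distance recomputed from scratch as the
    plain mean of original leaf-pair distances (equivalent to the weighted
    update), lexicographic tie-break on smallest-leaf representatives.
    Returns nested ((clusters), height) tuples."""
    clusters = {frozenset([l]): (l, 0.0) for l in labels}
    trees = {frozenset([l]): l for l in labels}
    d = {(i, j): values[i][j] for i in range(len(labels)) for j in range(len(labels))}

    def cdist(a, b):
        pairs = [
            d[(labels.index(x), labels.index(y))] for x in a for y in b
        ]
        return sum(pairs) / len(pairs)

    while len(clusters) > 1:
        best = min(
            (
                (cdist(a, b), tuple(sorted((min(a), min(b)))), a, b)
                for a, b in itertools.combinations(clusters, 2)
            ),
            key=lambda t: (t[0], t[1]),
        )
        dist, _, a, b = best
        left, right = sorted((a, b), key=min)
        node = ((trees[left], trees[right]), dist / 2.0)
        merged = a | b
        for c in (a, b):
            del clusters[c], trees[c]
        clusters[merged] = (min(merged), dist / 2.0)
        trees[merged] = node
    return trees.popitem()[1]


def tree_to_tuple(node):
    if node.is_leaf:
        return node.label
    kids = sorted(
        (tree_to_tuple(c) for c in node.children),
        key=lambda t: t if isinstance(t, str) else str(t),
    )
    return (tuple(kids), round(node.height, 10))


def oracle_to_tuple(t):
    if isinstance(t, str):
        return t
    (a, b), h = t
    kids = sorted(
        (oracle_to_tuple(a), oracle_to_tuple(b)),
        key=lambda x: x if isinstance(x, str) else str(x),
    )
    return (tuple(kids), round(h, 10))


def test_upgma_two_population_cherry():
    dm = PopDistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
    tree = upgma(dm)
    assert newick_string(tree) == "(A:0.2,B:0.2);"
    assert tree.root.height == pytest.approx(0.2)


def test_upgma_tied_minimal_pairs_resolved_lexicographically():
    # all off-diagonal distances equal: first merge must be (A, B)
    values = np.ones((4, 4)) - np.eye(4)
    dm = PopDistanceMatrix(["D", "C", "B", "A"], values)
    tree = upgma(dm)
    cherries = [
        frozenset(n.leaves())
        for n in tree.internal_nodes()
        if len(n.leaves()) == 2
    ]
    assert frozenset({"A", "B"}) in cherries


def test_upgma_matches_bruteforce_oracle_on_random_matrices():
    rng = np.random.default_rng(55)
    for trial in range(500):
        k = int(rng.integers(2, 6))
        labels = [f"P{i}" for i in range(k)]
        # continuous distances: exact ties have probability zero, so the two
        # implementations' float paths cannot disagree on the merge order
        v = rng.uniform(0.01, 1.0, size=(k, k))
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        dm = PopDistanceMatrix(labels, v)
        tree = upgma(dm)
        assert tree.is_ultrametric(tol=1e-12)
        assert tree_to_tuple(tree.root) == oracle_to_tuple(
            oracle_upgma(labels, v.tolist())
        )


def test_upgma_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        PopDistanceMatrix(["A", "B"], np.array([[0, 0.5], [0.4, 0]]))


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_supports_high_for_well_separated_pairs():
    m = paired_pop_matrix(seed=71)
    tree = bootstrap_tree(m, n_reps=100, seed=72)
    supports = {
        frozenset(n.leaves()): n.support
        for n in tree.internal_nodes()
        if n.support is not None
    }
    assert supports[frozenset({"A1", "A2"})] >= 95
    assert supports[frozenset({"B1", "B2"})] >= 95


def test_bootstrap_single_replicate_supports_are_zero_or_hundred():
    m = paired_pop_matrix(seed=73, n_loci=60)
    tree = bootstrap_tree(m, n_reps=1, seed=74)
    for n in tree.internal_nodes():
        if n.support is not None:
            assert n.support in (0, 100)


def test_bootstrap_deterministic_under_seed():
    m = paired_pop_matrix(seed=75, n_loci=80)
    t1 = bootstrap_tree(m, n_reps=30, seed=76)
    t2 = bootstrap_tree(m, n_reps=30, seed=76)
    assert newick_string(t1) == newick_string(t2)


def test_tree_groups_same_lineage_populations():
    # end-to-end: high-divergence simulation analysed by the full pipeline
    m = paired_pop_matrix(seed=77, f_between=0.35)
    tree = upgma(latter_fst_matrix(allele_frequencies(m)))
    clades = tree.clades()
    assert frozenset({"A1", "A2"}) in clades
    assert frozenset({"B1", "B2"}) in clades
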