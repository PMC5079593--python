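"""Nei DA distances, UPGMA trees, bootstrap support and Newick round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from germdiv.genodata import MISSING, GroupAssignment
from germdiv.neitree import (
    DistanceMatrix,
    bootstrap_support,
    cophenetic_matrix,
    distance_matrix,
    nei_da,
    read_newick,
    to_newick,
    upgma,
    write_newick,
)
from germdiv.simdata import SimConfig, simulate_admixed

from conftest import make_matrix, oracle_nei_da


# ---------------------------------------------------------------------------
# Nei DA


def test_da_identical_profiles_is_zero():
    x = [0.2, 0.7, 0.5]
    assert nei_da(x, x) == pytest.approx(0.0, abs=1e-12)


def test_da_fixed_opposite_is_one():
    assert nei_da([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0, abs=1e-12)


def test_da_hand_worked_single_locus():
    # x = (0.5, 0.5), y fixed: 1 - sqrt(0.5)
    assert nei_da([0.5], [1.0]) == pytest.approx(1 - np.sqrt(0.5), abs=1e-12)


def test_da_literal_typeset_variant_violates_self_distance():
    x = [0.5, 0.5]
    assert nei_da(x, x, literal=True) == pytest.approx(0.5, abs=1e-12)


def test_da_no_shared_loci():
    with pytest.raises(ValueError, match="shared"):
        nei_da([np.nan, 0.5], [0.5, np.nan])


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0.0, max_value=1.0),
            st.floats(min_value=0.0, max_value=1.0),
        ),
        min_size=1,
        max_size=20,
    )
)
@settings(deadline=None, max_examples=200)
def test_da_axioms(pairs):
    x = [a for a, _ in pairs]
    y = [b for _, b in pairs]
    d = nei_da(x, y)
    assert 0.0 <= d <= 1.0 + 1e-12
    assert nei_da(y, x) == pytest.approx(d, abs=1e-12)
    assert nei_da(x, x) == pytest.approx(0.0, abs=1e-9)
    # invariance to locus order
    perm = list(reversed(range(len(x))))
    assert nei_da([x[i] for i in perm], [y[i] for i in perm]) == pytest.approx(
        d, abs=1e-12
    )


def test_distance_matrix_matches_oracle():
    rng = np.random.default_rng(19)
    calls = rng.integers(0, 3, size=(3, 15)).astype(np.int8)
    gm = make_matrix(calls)
    d = distance_matrix(gm, units="individuals")
    freqs = 1.0 - calls / 2.0
    for i in range(3):
        for j in range(3):
            expect = 0.0 if i == j else oracle_nei_da(freqs[i], freqs[j])
            assert d.values[i, j] == pytest.approx(expect, abs=1e-12)


def test_identical_individuals_zero_distance():
    gm = make_matrix([[0, 1, 2], [0, 1, 2]])
    d = distance_matrix(gm)
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_all_missing_unit_is_error():
    gm = make_matrix([[0, 1], [MISSING, MISSING]])
    with pytest.raises(ValueError, match="i2"):
        distance_matrix(gm)


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_textbook_three_taxa():
    d = DistanceMatrix(labels=["A", "B", "C"],
                       values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
    t = upgma(d)
    assert sorted(t.leaves()) == ["A", "B", "C"]
    assert t.height == pytest.approx(2.0)
    inner = [c for c in t.children if not c.is_leaf][0]
    assert sorted(inner.leaves()) == ["A", "B"]
    assert inner.height == pytest.approx(1.0)


def test_upgma_two_leaves():
    d = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 0.5], [0.5, 0.0]]))
    t = upgma(d)
    assert t.height == pytest.approx(0.25)
    assert sorted(t.leaves()) == ["A", "B"]


def test_upgma_equal_distances_tie_break():
    n = 4
    vals = np.ones((n, n)) - np.eye(n)
    d = DistanceMatrix(labels=["d", "c", "b", "a"], values=vals)
    t = upgma(d)
    # all merge heights equal; first merge is the lexicographically
    # smallest pair (a, b)
    heights = sorted(nd.height for nd in t.internal_nodes())
    assert np.allclose(heights, 0.5)
    first = min(t.internal_nodes(), key=lambda nd: len(nd.leaves()))
    assert sorted(first.leaves()) == ["a", "b"]


def test_upgma_deterministic_under_label_order():
    rng = np.random.default_rng(2)
    n = 6
    m = rng.uniform(0.1, 1.0, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    labels = [f"L{i}" for i in range(n)]
    t1 = upgma(DistanceMatrix(labels=labels, values=m))
    perm = rng.permutation(n)
    t2 = upgma(DistanceMatrix(labels=[labels[i] for i in perm],
                              values=m[np.ix_(perm, perm)]))
    assert set(map(frozenset, t1.clusters())) == set(map(frozenset, t2.clusters()))


def test_upgma_ultrametric_and_matches_scipy():
    rng = np.random.default_rng(23)
    for _ in range(20):
        n = rng.integers(3, 9)
        m = rng.uniform(0.05, 1.0, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"u{i}" for i in range(n)]
        t = upgma(DistanceMatrix(labels=labels, values=m))
        coph = cophenetic_matrix(t, labels)
        # ultrametric: the two largest of any triple are equal
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    trip = sorted([coph[i, j], coph[i, k], coph[j, k]])
                    assert trip[1] == pytest.approx(trip[2], abs=1e-9)
        # independent oracle: scipy average linkage cophenetic distances
        z = average(squareform(m))
        expect = squareform(cophenet(z))
        assert np.allclose(coph, expect, atol=1e-9)


def test_upgma_recovers_ultrametric_input():
    # input already ultrametric -> cophenetic distance equals it exactly
    d = np.array(
        [[0, 0.2, 0.6, 0.6],
         [0.2, 0, 0.6, 0.6],
         [0.6, 0.6, 0, 0.4],
         [0.6, 0.6, 0.4, 0.0]]
    )
    labels = list("ABCD")
    t = upgma(DistanceMatrix(labels=labels, values=d))
    assert np.allclose(cophenetic_matrix(t, labels), d, atol=1e-12)


def test_upgma_rejects_nonfinite():
    vals = np.array([[0.0, np.inf], [np.inf, 0.0]])
    with pytest.raises(ValueError):
        DistanceMatrix(labels=["A", "B"], values=vals)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_identical_columns_full_support():
    col = np.array([0, 0, 1, 2, 2], dtype=np.int8)
    gm = make_matrix(np.tile(col[:, None], (1, 12)))
    t = bootstrap_support(gm, n_reps=30, seed=4)
    for nd in t.internal_nodes():
        assert nd.support == pytest.approx(100.0)


def test_bootstrap_deterministic_under_seed():
    rng = np.random.default_rng(8)
    gm = make_matrix(rng.integers(0, 3, size=(6, 40)).astype(np.int8))
    t1 = bootstrap_support(gm, n_reps=60, seed=9)
    t2 = bootstrap_support(gm, n_reps=60, seed=9)
    assert to_newick(t1) == to_newick(t2)


def test_bootstrap_two_separated_pairs():
    cfg = SimConfig(n_markers=200, K=2, F=0.4, n_per_population=2,
                    alpha="pure", seed=21)
    gm, _ = simulate_admixed(cfg)
    t = bootstrap_support(gm, n_reps=200, seed=5)
    supports = {frozenset(nd.leaves()): nd.support for nd in t.internal_nodes()}
    pair1 = frozenset(gm.individuals[:2])
    pair2 = frozenset(gm.individuals[2:])
    assert supports[pair1] >= 95.0
    assert supports[pair2] >= 95.0


def test_bootstrap_guards():
    gm = make_matrix([[0, 1], [1, 2], [2, 0]])
    with pytest.raises(ValueError):
        bootstrap_support(gm, n_reps=0)


# ---------------------------------------------------------------------------
# Newick


def test_newick_two_leaf_shape():
    d = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 0.5], [0.5, 0.0]]))
    t = upgma(d)
    t.support = 100.0
    assert to_newick(t) == "(A:0.25,B:0.25)100;"


def test_newick_roundtrip(tmp_path):
    rng = np.random.default_rng(31)
    gm = make_matrix(rng.integers(0, 3, size=(5, 30)).astype(np.int8))
    t = bootstrap_support(gm, n_reps=50, seed=13)
    path = tmp_path / "tree.nwk"
    write_newick(t, path)
    back = read_newick(path)
    assert set(map(frozenset, back.clusters())) == set(map(frozenset, t.clusters()))
    assert back.height == pytest.approx(t.height, abs=1e-9)
    sup_a = {frozenset(nd.leaves()): nd.support for nd in t.internal_nodes()}
    sup_b = {frozenset(nd.leaves()): nd.support for nd in back.internal_nodes()}
    assert sup_a == sup_b


def test_newick_quotes_labels_with_spaces():
    d = DistanceMatrix(labels=["hyb A", "hyb B"],
                       values=np.array([[0, 0.2], [0.2, 0.0]]))
    nwk = to_newick(upgma(d))
    assert "'hyb A'" in nwk
    back = read_newick(nwk)
    assert sorted(back.leaves()) == ["hyb A", "hyb B"]
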