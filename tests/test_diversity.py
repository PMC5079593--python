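"""Diversity statistics, group summaries, private alleles and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germdiv.diversity import (
    GenotypeCounts,
    allele_freq_correlation,
    allele_frequency_table,
    correlation_matrix,
    gene_diversity,
    group_summary,
    heterozygosity,
    locus_stats,
    minor_allele_frequency,
    pic,
    private_alleles,
)
from germdiv.genodata import MISSING, GroupAssignment

from conftest import make_matrix, oracle_locus_stats, oracle_pearson, random_matrix


# ---------------------------------------------------------------------------
# scalar statistics


@pytest.mark.parametrize(
    "freqs,expected",
    [((0.5, 0.5), 0.5), ((1.0, 0.0), 0.0), ((0.9, 0.1), 0.18)],
)
def test_gene_diversity_examples(freqs, expected):
    assert gene_diversity(freqs) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "freqs,expected",
    [((0.5, 0.5), 0.375), ((1.0, 0.0), 0.0)],
)
def test_pic_examples(freqs, expected):
    # (0.5, 0.5): 1 - 0.5 - 2 * 0.0625 = 0.375
    assert pic(freqs) == pytest.approx(expected, abs=1e-12)


def test_negative_frequency_rejected():
    with pytest.raises(ValueError):
        gene_diversity((-0.1, 1.1))
    with pytest.raises(ValueError):
        pic((-0.1, 1.1))


@pytest.mark.parametrize(
    "counts,expected_maf,expected_het",
    [
        (GenotypeCounts(3, 2, 1), 4 / 12, 2 / 6),
        (GenotypeCounts(6, 0, 0), 0.0, 0.0),
        (GenotypeCounts(0, 0, 6), 0.0, 0.0),  # orientation invariance
        (GenotypeCounts(0, 5, 0), 0.5, 1.0),
    ],
)
def test_counts_statistics(counts, expected_maf, expected_het):
    assert minor_allele_frequency(counts) == pytest.approx(expected_maf, abs=1e-12)
    assert heterozygosity(counts) == pytest.approx(expected_het, abs=1e-12)


def test_all_missing_locus_rejected():
    with pytest.raises(ValueError):
        minor_allele_frequency(GenotypeCounts(0, 0, 0))


@given(st.floats(min_value=0.0, max_value=1.0))
@settings(deadline=None, max_examples=100)
def test_pic_dominated_by_gene_diversity(p):
    freqs = (p, 1.0 - p)
    gd = gene_diversity(freqs)
    assert pic(freqs) <= gd + 1e-12
    # allele-relabeling invariance and GD == 2pq for biallelic loci
    assert gene_diversity(freqs[::-1]) == pytest.approx(gd, abs=1e-12)
    assert pic(freqs[::-1]) == pytest.approx(pic(freqs), abs=1e-12)
    assert gd == pytest.approx(2 * p * (1 - p), abs=1e-12)


# ---------------------------------------------------------------------------
# matrix-level statistics vs brute-force oracle


def test_locus_stats_match_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(10):
        gm = random_matrix(rng, n=12, m=25, missing_rate=0.1)
        st_tab = locus_stats(gm)
        for j in range(gm.n_markers):
            expect = oracle_locus_stats(gm.calls[:, j].tolist())
            row = st_tab.iloc[j]
            if expect is None:
                assert row["n_called"] == 0
                continue
            for key in ("gd", "pic", "het", "maf"):
                assert row[key] == pytest.approx(expect[key], abs=1e-12), key
            assert row["n_called"] == expect["n_called"]


def test_single_fully_heterozygous_individual():
    gm = make_matrix(np.ones((1, 10), dtype=np.int8))
    st_tab = locus_stats(gm)
    # p = q = 0.5 at every het locus: GD = 0.5, H = 1
    assert np.allclose(st_tab["gd"], 0.5)
    assert np.allclose(st_tab["het"], 1.0)


def test_group_of_homozygous_clones_is_zero():
    gm = make_matrix(np.zeros((4, 8), dtype=np.int8))
    groups = GroupAssignment({i: "g" for i in gm.individuals})
    gs = group_summary(gm, groups)
    assert (gs[["gd", "pic", "het", "maf"]].to_numpy() == 0).all()


def test_group_summary_matches_brute_force():
    rng = np.random.default_rng(7)
    gm = random_matrix(rng, n=8, m=20, missing_rate=0.05)
    groups = GroupAssignment(
        {ind: ("gA" if k < 4 else "gB") for k, ind in enumerate(gm.individuals)}
    )
    gs = group_summary(gm, groups).set_index("group")
    for g, rows in (("gA", range(0, 4)), ("gB", range(4, 8))):
        per_locus = [
            oracle_locus_stats(gm.calls[list(rows), j].tolist())
            for j in range(gm.n_markers)
        ]
        per_locus = [x for x in per_locus if x is not None]
        for key in ("gd", "pic", "het", "maf"):
            expect = sum(x[key] for x in per_locus) / len(per_locus)
            assert gs.loc[g, key] == pytest.approx(expect, abs=1e-12)


def test_group_summary_invariant_under_replication():
    gm = make_matrix([[0, 1, 2], [1, 1, 0]])
    groups = GroupAssignment({i: "g" for i in gm.individuals})
    doubled = make_matrix(
        np.vstack([gm.calls, gm.calls]),
        individuals=["a", "b", "c", "d"],
    )
    groups2 = GroupAssignment({i: "g" for i in doubled.individuals})
    g1 = group_summary(gm, groups).drop(columns=["nh"])
    g2 = group_summary(doubled, groups2).drop(columns=["nh"])
    pd.testing.assert_frame_equal(g1, g2)


# ---------------------------------------------------------------------------
# private alleles


def test_private_allele_definition():
    # allele_b observed only in group S at marker m1; m2 shared
    gm = make_matrix([[1, 1], [0, 1], [0, 0], [0, 1]])
    groups = GroupAssignment(
        {"i1": "S", "i2": "S", "i3": "T", "i4": "T"}
    )
    recs = private_alleles(gm, groups)
    tagged = [(r.marker_id, r.allele, r.group) for r in recs]
    assert ("m1", "G", "S") in tagged
    assert not any(r.marker_id == "m2" for r in recs)


def test_private_alleles_planted_counts(private_fixture):
    gm, groups, planted = private_fixture
    recs = private_alleles(gm, groups)
    by_group = {}
    for r in recs:
        by_group[r.group] = by_group.get(r.group, 0) + 1
    assert by_group == planted


def test_private_alleles_empty_after_merging(private_fixture):
    gm, groups, _ = private_fixture
    merged = GroupAssignment({i: "all" for i in gm.individuals})
    with pytest.raises(ValueError):
        private_alleles(gm, merged)  # <2 groups is rejected outright
    # two groups holding identical copies of the panel -> nothing private
    doubled = make_matrix(
        np.vstack([gm.calls, gm.calls]),
        individuals=[f"c{k}" for k in range(2 * gm.n_individuals)],
        marker_ids=gm.marker_ids,
    )
    two = GroupAssignment(
        {
            ind: ("h1" if k < gm.n_individuals else "h2")
            for k, ind in enumerate(doubled.individuals)
        }
    )
    assert private_alleles(doubled, two) == []


# ---------------------------------------------------------------------------
# correlations


def test_correlation_identity():
    f = pd.DataFrame({"a": [0.1, 0.5, 0.9, 0.3], "b": [0.1, 0.5, 0.9, 0.3]})
    r, p = allele_freq_correlation(f, "a", "b")
    assert r == pytest.approx(1.0)
    assert p < 1e-6


def test_correlation_df_guard():
    f = pd.DataFrame({"a": [0.1, 0.9], "b": [0.9, 0.1]})
    with pytest.raises(ValueError, match="3"):
        allele_freq_correlation(f, "a", "b")


def test_correlation_matches_covariance_oracle():
    rng = np.random.default_rng(3)
    x = rng.uniform(0.05, 0.95, 10)
    y = np.clip(x + rng.normal(0, 0.1, 10), 0, 1)
    f = pd.DataFrame({"a": x, "b": y})
    r, _ = allele_freq_correlation(f, "a", "b")
    assert r == pytest.approx(oracle_pearson(x.tolist(), y.tolist()), abs=1e-12)


def test_zero_variance_flagged():
    f = pd.DataFrame({"a": [0.5, 0.5, 0.5], "b": [0.1, 0.2, 0.3]})
    with pytest.raises(ValueError, match="variance"):
        allele_freq_correlation(f, "a", "b")


def test_correlation_matrix_symmetric_unit_diagonal():
    rng = np.random.default_rng(11)
    gm = random_matrix(rng, n=12, m=30)
    groups = GroupAssignment(
        {ind: f"g{k % 3}" for k, ind in enumerate(gm.individuals)}
    )
    ft = allele_frequency_table(gm, groups)
    r, p = correlation_matrix(ft)
    assert np.allclose(r.to_numpy(), r.to_numpy().T, equal_nan=True)
    assert np.allclose(np.diag(r.to_numpy()), 1.0)
    assert ((p.to_numpy() >= 0) | np.isnan(p.to_numpy())).all()
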