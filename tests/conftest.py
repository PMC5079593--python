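"""Shared fixtures: tiny hand-constructed panels and brute-force oracles.

The oracles recount everything from raw diploid calls, independent of the
library's vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from germdiv.genodata import MISSING, GenotypeMatrix, GroupAssignment, MarkerInfo


def make_matrix(calls, individuals=None, marker_ids=None, alleles=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain nested list of dosages."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    individuals = individuals or [f"i{r+1}" for r in range(n)]
    marker_ids = marker_ids or [f"m{c+1}" for c in range(m)]
    alleles = alleles or [("A", "G")] * m
    markers = [
        MarkerInfo(marker_id=mid, chromosome="1", position_bp=100 * (j + 1),
                   allele_a=a, allele_b=b)
        for j, (mid, (a, b)) in enumerate(zip(marker_ids, alleles))
    ]
    return GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_locus_stats(column):
    """GD/PIC/H/MAF of one marker column by explicit allele counting."""
    called = [c for c in column if c != MISSING]
    if not called:
        return None
    n_a = sum({0: 2, 1: 1, 2: 0}[c] for c in called)
    n_b = sum({0: 0, 1: 1, 2: 2}[c] for c in called)
    tot = n_a + n_b
    p, q = n_a / tot, n_b / tot
    gd = 1 - p * p - q * q
    pic = gd - 2 * p * p * q * q
    het = sum(1 for c in called if c == 1) / len(called)
    return {"gd": gd, "pic": pic, "het": het, "maf": min(p, q), "n_called": len(called)}


def oracle_nei_da(x, y):
    """Per-locus DA sum over loci defined in both profiles."""
    terms = []
    for xa, ya in zip(x, y):
        if math.isnan(xa) or math.isnan(ya):
            continue
        terms.append(1 - (math.sqrt(xa * ya) + math.sqrt((1 - xa) * (1 - ya))))
    return sum(terms) / len(terms)


def oracle_pearson(x, y):
    """Pearson r from the raw covariance formula."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def random_matrix(rng, n=20, m=50, missing_rate=0.0) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    return make_matrix(calls)


# ---------------------------------------------------------------------------
# constructed panels


@pytest.fixture
def qc_fixture():
    """20 individuals x 10 markers: 3 call-rate failures, 2 MAF failures.

    Markers m1-m5 pass (full calls, MAF 0.25); m6-m8 fail call rate (only 17
    of 20 called, rate 0.85); m9-m10 fail MAF (1 minor allele in 40, 0.025).
    """
    n = 20
    calls = np.zeros((n, 10), dtype=np.int8)
    for j in range(5):  # pass: 10 copies of allele_b in 40 => MAF 0.25
        calls[:5, j] = 2
    for j in range(5, 8):  # call-rate failures, MAF kept high among called
        calls[:5, j] = 2
        calls[17:, j] = MISSING
    for j in range(8, 10):  # MAF failures: a single heterozygote
        calls[0, j] = 1
    return make_matrix(calls)


@pytest.fixture
def private_fixture():
    """Three-group panel with exactly 1, 3 and 11 planted private alleles.

    Groups gA (4 ind), gB (4), gC (4).  At a planted marker the owning
    group carries one heterozygote for allele_b while everyone else is
    homozygous allele_a; background markers segregate in all groups.
    """
    n = 12
    planted = {"gA": 1, "gB": 3, "gC": 11}
    owners = ["gA"] * 1 + ["gB"] * 3 + ["gC"] * 11
    m_planted = len(owners)
    m_bg = 10
    calls = np.zeros((n, m_planted + m_bg), dtype=np.int8)
    group_rows = {"gA": range(0, 4), "gB": range(4, 8), "gC": range(8, 12)}
    for j, g in enumerate(owners):
        calls[list(group_rows[g])[0], j] = 1
    for j in range(m_planted, m_planted + m_bg):
        # allele_b present in every group -> nothing private
        calls[0, j] = calls[4, j] = calls[8, j] = 1
    gm = make_matrix(calls)
    mapping = {}
    for g, rows in group_rows.items():
        for r in rows:
            mapping[gm.individuals[r]] = g
    return gm, GroupAssignment(mapping), planted
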