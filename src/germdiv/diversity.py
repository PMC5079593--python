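"""Per-locus and per-group diversity statistics, private alleles, and
between-group allele-frequency correlations.

All statistics are frequency-based: gene diversity GD = 1 - sum p_i^2,
minor allele frequency, observed heterozygosity, and the polymorphism
information content PIC = GD - sum_{i<j} 2 p_i^2 p_j^2.  Group summaries
average the per-locus values over every retained marker of the panel,
including markers monomorphic within the group (which contribute zeros to
GD/PIC/MAF) — this is what keeps single-individual groups' gene diversity
low even when their heterozygosity is high.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeMatrix, GroupAssignment


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one locus: P major homozygotes, Q
    heterozygotes, R minor homozygotes."""

    P: int
    Q: int
    R: int

    def __post_init__(self) -> None:
        if min(self.P, self.Q, self.R) < 0:
            raise ValueError("negative genotype count")

    @property
    def n(self) -> int:
        return self.P + self.Q + self.R


@dataclass(frozen=True)
class PrivateAllele:
    """An allele observed in exactly one group of the panel."""

    marker_id: str
    allele: str
    group: str


def _check_freqs(freqs: Sequence[float]) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("negative allele frequency")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {f.sum()}, not 1")
    return f


def gene_diversity(freqs: Sequence[float]) -> float:
    """GD = 1 - sum p_i^2 (expected heterozygosity)."""
    f = _check_freqs(freqs)
    return float(1.0 - np.sum(f**2))


def pic(freqs: Sequence[float]) -> float:
    """Polymorphism information content; <= gene diversity, max 0.375 biallelic."""
    f = _check_freqs(freqs)
    sq = f**2
    cross = np.outer(sq, sq)
    upper = np.triu(cross, k=1).sum()
    return float(1.0 - sq.sum() - 2.0 * upper)


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """(Q + 2R) / (2(P+Q+R)) folded to [0, 0.5]."""
    if counts.n < 1:
        raise ValueError("no called genotypes at locus")
    raw = (counts.Q + 2 * counts.R) / (2 * counts.n)
    return float(min(raw, 1.0 - raw))


def heterozygosity(counts: GenotypeCounts) -> float:
    """Observed heterozygosity Q / (P+Q+R)."""
    if counts.n < 1:
        raise ValueError("no called genotypes at locus")
    return float(counts.Q / counts.n)


# ---------------------------------------------------------------------------
# matrix-level statistics


def locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker GD, PIC, H, MAF and called count over the whole matrix.

    Markers with zero calls get NaN statistics and n_called = 0.
    """
    called = matrix.called_mask()
    n_called = called.sum(axis=0)
    q = matrix.allele_b_freq()  # NaN where no calls
    p = 1.0 - q
    het = np.where(n_called > 0, (matrix.calls == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    gd = 2.0 * p * q
    pic_v = gd - 2.0 * (p**2) * (q**2)
    maf = np.minimum(p, q)
    return pd.DataFrame(
        {
            "marker_id": matrix.marker_ids,
            "gd": gd,
            "pic": pic_v,
            "het": het,
            "maf": maf,
            "n_called": n_called,
        }
    )


def group_summary(matrix: GenotypeMatrix, groups: GroupAssignment) -> pd.DataFrame:
    """Per-group means of GD/PIC/H/MAF over all retained markers.

    Statistics are computed on the group's sub-matrix; markers monomorphic
    within a group contribute zeros.  Markers entirely missing within the
    group are excluded from that group's mean (their count is reported).
    """
    groups.validate_against(matrix)
    rows = []
    for g in groups.groups():
        sub = matrix.subset(individuals=groups.members(g))
        st = locus_stats(sub)
        contributing = st["n_called"] > 0
        if not contributing.any():
            raise ValueError(f"group {g!r} has no called markers")
        stc = st[contributing]
        rows.append(
            {
                "group": g,
                "nh": sub.n_individuals,
                "gd": stc["gd"].mean(),
                "pic": stc["pic"].mean(),
                "het": stc["het"].mean(),
                "maf": stc["maf"].mean(),
                "n_loci": int(contributing.sum()),
            }
        )
    return pd.DataFrame(rows)


def allele_frequency_table(
    matrix: GenotypeMatrix, groups: GroupAssignment
) -> pd.DataFrame:
    """Per-marker, per-group frequency of allele_a (markers x groups).

    NaN marks a marker with no calls in the group.
    """
    groups.validate_against(matrix)
    data = {}
    for g in groups.groups():
        sub = matrix.subset(individuals=groups.members(g))
        data[g] = sub.allele_a_freq()
    return pd.DataFrame(data, index=matrix.marker_ids)


def private_alleles(
    matrix: GenotypeMatrix, groups: GroupAssignment
) -> list[PrivateAllele]:
    """Alleles whose count is > 0 in exactly one group (non-missing calls).

    Output order is deterministic: marker order, then allele_a before
    allele_b within a marker.
    """
    groups.validate_against(matrix)
    glabels = groups.groups()
    if len(glabels) < 2:
        raise ValueError("private alleles need at least two groups")
    # per-group allele presence: allele_a present iff any call in {0,1},
    # allele_b present iff any call in {1,2}
    present_a = np.zeros((len(glabels), matrix.n_markers), dtype=bool)
    present_b = np.zeros_like(present_a)
    for gi, g in enumerate(glabels):
        rows = [matrix.individuals.index(i) for i in groups.members(g)]
        sub = matrix.calls[rows]
        present_a[gi] = ((sub == 0) | (sub == 1)).any(axis=0)
        present_b[gi] = ((sub == 1) | (sub == 2)).any(axis=0)
    out: list[PrivateAllele] = []
    for j, mk in enumerate(matrix.markers):
        for allele, present in ((mk.allele_a, present_a[:, j]), (mk.allele_b, present_b[:, j])):
            owners = np.flatnonzero(present)
            if len(owners) == 1:
                out.append(PrivateAllele(mk.marker_id, allele, glabels[owners[0]]))
    return out


def allele_freq_correlation(
    freq_table: pd.DataFrame, group_x: str, group_y: str
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two groups' allele_a frequencies.

    Uses the markers with defined frequencies in both groups; requires at
    least three of them.  Zero variance in either vector raises.
    """
    x = freq_table[group_x].to_numpy(dtype=float)
    y = freq_table[group_y].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 shared markers for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in allele frequencies; r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(
    freq_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Square Pearson r matrix across all groups plus parallel p-values.

    Undefined pairs (zero variance / too few markers) are NaN.
    """
    gs = list(freq_table.columns)
    r = pd.DataFrame(np.eye(len(gs)), index=gs, columns=gs)
    p = pd.DataFrame(np.zeros((len(gs), len(gs))), index=gs, columns=gs)
    for i, gx in enumerate(gs):
        for j in range(i + 1, len(gs)):
            gy = gs[j]
            try:
                rij, pij = allele_freq_correlation(freq_table, gx, gy)
            except ValueError:
                rij, pij = np.nan, np.nan
            r.loc[gx, gy] = r.loc[gy, gx] = rij
            p.loc[gx, gy] = p.loc[gy, gx] = pij
    return r, p


def write_private_alleles(records: list[PrivateAllele], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("marker_id\tallele\tgroup\n")
        for r in records:
            fh.write(f"{r.marker_id}\t{r.allele}\t{r.group}\n")
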