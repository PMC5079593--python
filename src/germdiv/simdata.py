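"""Synthetic genotype generator with full truth records.

The differentiation model is Balding-Nichols: each locus draws an ancestral
allele frequency p from a uniform range, and every one of the K populations
draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is p
and whose variance is F*p*(1-p).  Individuals are admixed (Dirichlet-alpha
ancestry proportions) or pure; each of their two allele copies picks an
ancestral origin from Q and then an allele from that population's frequency.
Inbred-line panels duplicate a single drawn allele per locus; F1 hybrids are
deterministic crosses of fully homozygous parents.  All randomness flows
from one master seed through named substreams so each component can be
varied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import json
import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, GroupAssignment, MarkerInfo

_NUCS = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Parameters of one synthetic panel."""

    n_markers: int = 768
    K: int = 2
    F: float = 0.2  # Balding-Nichols differentiation, in (0, 1)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    alpha: float | Literal["pure"] = "pure"
    n_per_population: int | Sequence[int] = 10
    missing_rate: float = 0.0
    mode: Literal["outbred", "inbred_lines", "f1_from_lines"] = "outbred"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ValueError("F must lie strictly in (0, 1)")
        if self.K < 1 or self.n_markers < 1:
            raise ValueError("K and n_markers must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    def pop_sizes(self) -> list[int]:
        if isinstance(self.n_per_population, int):
            return [self.n_per_population] * self.K
        sizes = list(self.n_per_population)
        if len(sizes) != self.K:
            raise ValueError("n_per_population length must equal K")
        return sizes


@dataclass
class SimTruth:
    """Ground truth behind a simulated panel."""

    ancestral_freqs: np.ndarray  # (n_markers,) allele_b frequency
    population_freqs: np.ndarray  # (K, n_markers) allele_b frequency
    Q: np.ndarray  # (n_individuals, K) true ancestry proportions
    individuals: list[str]
    realized_fst: np.ndarray | None = None  # per-marker, populations as units
    pedigree: dict[str, tuple[str, str]] | None = None

    def write(self, out_dir: str | Path, prefix: str = "truth") -> None:
        out = Path(out_dir)
        pd.DataFrame(
            self.Q,
            index=self.individuals,
            columns=[f"pop{k+1}" for k in range(self.Q.shape[1])],
        ).to_csv(out / f"{prefix}_Q.tsv", sep="\t", float_format="%.8g")
        pd.DataFrame(
            self.population_freqs.T,
            columns=[f"pop{k+1}" for k in range(self.population_freqs.shape[0])],
        ).to_csv(out / f"{prefix}_pop_freqs.tsv", sep="\t", float_format="%.8g")
        meta = {
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "pedigree": self.pedigree,
        }
        (out / f"{prefix}.json").write_text(json.dumps(meta) + "\n")


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _make_markers(n_markers: int, rng: np.random.Generator) -> list[MarkerInfo]:
    markers = []
    for j in range(n_markers):
        a, b = sorted(rng.choice(len(_NUCS), size=2, replace=False))
        markers.append(
            MarkerInfo(
                marker_id=f"snp{j+1:05d}",
                chromosome=str(j % 10 + 1),
                position_bp=int(j // 10 + 1) * 1000,
                allele_a=_NUCS[a],
                allele_b=_NUCS[b],
            )
        )
    return markers


def _draw_frequencies(
    config: SimConfig, rng_freq: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.ancestral_freq_range
    anc = rng_freq.uniform(lo, hi, size=config.n_markers)
    f = config.F
    a = anc * (1 - f) / f
    b = (1 - anc) * (1 - f) / f
    pop = rng_freq.beta(
        np.broadcast_to(a, (config.K, config.n_markers)),
        np.broadcast_to(b, (config.K, config.n_markers)),
    )
    return anc, np.clip(pop, 1e-9, 1 - 1e-9)


def _realized_fst(pop_freqs: np.ndarray) -> np.ndarray:
    """Per-marker Fst across populations from truth frequencies
    (variance over mean-heterozygosity form)."""
    if pop_freqs.shape[0] < 2:
        return np.full(pop_freqs.shape[1], np.nan)
    pbar = pop_freqs.mean(axis=0)
    var = pop_freqs.var(axis=0, ddof=1)  # unbiased across-population variance
    with np.errstate(invalid="ignore", divide="ignore"):
        return var / (pbar * (1 - pbar))


def simulate_admixed(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Admixed (or pure-population) diploid outbred panel."""
    streams = _streams(config.seed, ["markers", "freq", "q", "copies", "missing"])
    markers = _make_markers(config.n_markers, streams["markers"])
    anc, pop = _draw_frequencies(config, streams["freq"])
    sizes = config.pop_sizes()
    n = sum(sizes)
    if config.alpha == "pure":
        Q = np.zeros((n, config.K))
        row = 0
        for k, sz in enumerate(sizes):
            Q[row : row + sz, k] = 1.0
            row += sz
    else:
        Q = streams["q"].dirichlet([float(config.alpha)] * config.K, size=n)
    rng = streams["copies"]
    # origin of each of the 2 copies, then the allele from that population
    origins = np.stack(
        [_sample_categorical(Q, rng, config.n_markers) for _ in range(2)], axis=-1
    )  # (n, L, 2)
    pk = pop[origins, np.arange(config.n_markers)[None, :, None]]
    alleles = (rng.random(pk.shape) < pk).astype(np.int8)
    calls = alleles.sum(axis=-1).astype(np.int8)
    individuals = [f"ind{i+1:03d}" for i in range(n)]
    gm = GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)
    if config.missing_rate > 0:
        gm = apply_missingness(gm, config.missing_rate, rng=streams["missing"])
    truth = SimTruth(
        ancestral_freqs=anc,
        population_freqs=pop,
        Q=Q,
        individuals=individuals,
        realized_fst=_realized_fst(pop),
    )
    return gm, truth


def _sample_categorical(
    Q: np.ndarray, rng: np.random.Generator, n_markers: int
) -> np.ndarray:
    """Sample one origin per individual per marker from each row of Q."""
    cum = np.cumsum(Q, axis=1)
    u = rng.random((Q.shape[0], n_markers))
    return (u[:, :, None] > cum[:, None, :]).sum(axis=2)


def population_labels(config: SimConfig) -> GroupAssignment:
    """Group assignment matching the population blocks of a pure panel."""
    sizes = config.pop_sizes()
    mapping = {}
    row = 0
    for k, sz in enumerate(sizes):
        for i in range(sz):
            mapping[f"ind{row + i + 1:03d}"] = f"pop{k+1}"
        row += sz
    return GroupAssignment(mapping=mapping)


def simulate_inbred_panel(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Fully inbred lines: one allele drawn per locus and duplicated."""
    streams = _streams(config.seed, ["markers", "freq", "q", "copies", "missing"])
    markers = _make_markers(config.n_markers, streams["markers"])
    anc, pop = _draw_frequencies(config, streams["freq"])
    sizes = config.pop_sizes()
    n = sum(sizes)
    Q = np.zeros((n, config.K))
    row = 0
    for k, sz in enumerate(sizes):
        Q[row : row + sz, k] = 1.0
        row += sz
    rng = streams["copies"]
    origin = _sample_categorical(Q, rng, config.n_markers)
    pk = pop[origin, np.arange(config.n_markers)[None, :]]
    allele = (rng.random(pk.shape) < pk).astype(np.int8)
    calls = (2 * allele).astype(np.int8)
    individuals = [f"line{i+1:03d}" for i in range(n)]
    gm = GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)
    if config.missing_rate > 0:
        gm = apply_missingness(gm, config.missing_rate, rng=streams["missing"])
    truth = SimTruth(
        ancestral_freqs=anc,
        population_freqs=pop,
        Q=Q,
        individuals=individuals,
        realized_fst=_realized_fst(pop),
    )
    return gm, truth


def cross_hybrids(
    lines: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    names: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Deterministic single-cross F1s from fully homozygous parents.

    F1 dosage = (dosage_p1 + dosage_p2) / 2 per locus; missing in either
    parent propagates to the F1.
    """
    het = np.argwhere(lines.calls == 1)
    if het.size:
        i, j = het[0]
        raise ValueError(
            f"parent {lines.individuals[i]} heterozygous at "
            f"{lines.markers[j].marker_id}; F1 cross requires inbred parents"
        )
    if names is None:
        names = [f"{p1}x{p2}" for p1, p2 in pairs]
    calls = np.full((len(pairs), lines.n_markers), MISSING, dtype=np.int8)
    for r, (p1, p2) in enumerate(pairs):
        c1 = lines.calls[lines.individuals.index(p1)]
        c2 = lines.calls[lines.individuals.index(p2)]
        f1 = ((c1.astype(np.int16) + c2) // 2).astype(np.int8)
        f1[(c1 == MISSING) | (c2 == MISSING)] = MISSING
        calls[r] = f1
    return GenotypeMatrix(individuals=list(names), markers=list(lines.markers), calls=calls)


def apply_missingness(
    matrix: GenotypeMatrix,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Set each call missing independently with probability ``rate`` (MCAR)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return GenotypeMatrix(
            individuals=list(matrix.individuals),
            markers=list(matrix.markers),
            calls=matrix.calls.copy(),
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    drop = rng.random(calls.shape) < rate
    calls[drop] = MISSING
    return GenotypeMatrix(
        individuals=list(matrix.individuals), markers=list(matrix.markers), calls=calls
    )
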