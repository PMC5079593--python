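"""Bayesian admixture inference via a collapsed-parameter Gibbs sampler,
model-order selection with the Evanno second-difference criterion, replicate
label alignment, and membership assignment.

The model is the classic admixture model: individual i has ancestry
proportions q_i over K ancestral populations; each of its two allele copies
at locus l independently draws an origin z ~ Categorical(q_i) and then an
allele from the origin population's frequency p_kl.  The sampler alternates

    z | q, p   (per allele copy, categorical)
    p | z      (Beta conjugate update with prior Beta(lambda, lambda))
    q | z      (Dirichlet conjugate update with prior Dirichlet(alpha))

and records the marginal log-likelihood ln Pr(X | P, Q) each post-burn-in
sweep.  L(K) is mean(trace) - var(trace)/2; deltaK(K) is the absolute
second difference of mean L over K divided by the standard deviation of
L(K) across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment

from .genodata import MISSING, GenotypeMatrix


@njit(cache=True)
def _sweep_counts(alleles, valid, q, p, u, n1, n0, c_ik):
    """Sample the origin of every valid allele copy and accumulate counts.

    ``u`` supplies one pre-drawn uniform per copy so the sampler's RNG
    stream is consumed in a fixed order.  Counts are written in place:
    n1/n0 per (population, locus) for the Beta update, c_ik per
    (individual, population) for the Dirichlet update.
    """
    n, L, _ = alleles.shape
    K = q.shape[1]
    n1[:] = 0.0
    n0[:] = 0.0
    c_ik[:] = 0.0
    for i in range(n):
        for l in range(L):
            for c in range(2):
                if not valid[i, l, c]:
                    continue
                a = alleles[i, l, c]
                total = 0.0
                for k in range(K):
                    em = p[k, l] if a == 1 else 1.0 - p[k, l]
                    total += q[i, k] * em
                target = u[i, l, c] * total
                acc = 0.0
                z = K - 1
                for k in range(K):
                    em = p[k, l] if a == 1 else 1.0 - p[k, l]
                    acc += q[i, k] * em
                    if acc > target:
                        z = k
                        break
                if a == 1:
                    n1[z, l] += 1.0
                else:
                    n0[z, l] += 1.0
                c_ik[i, z] += 1.0


@dataclass
class StructureConfig:
    """Sampler and model-scan settings.

    Publication-scale settings are K 1-10, 10 replicates, 1,000,000 sweeps
    with 500,000 burn-in; the defaults here are desk-scale so a full scan
    finishes in minutes.  ``alpha`` is the symmetric Dirichlet prior on
    ancestry proportions (fixed, keeping the sampler fully conjugate) and
    ``lam`` the Beta prior pseudo-count on allele frequencies.
    """

    k_min: int = 1
    k_max: int = 10
    replicates: int = 10
    sweeps: int = 10_000
    burn_in: int = 5_000
    alpha: float = 1.0
    lam: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.sweeps:
            raise ValueError("burn_in must be < sweeps")
        if self.k_min < 1 or self.replicates < 1:
            raise ValueError("k_min and replicates must be >= 1")

    @classmethod
    def publication_scale(cls, **kw) -> "StructureConfig":
        return cls(sweeps=1_000_000, burn_in=500_000, **kw)


@dataclass
class AncestryResult:
    K: int
    Q: pd.DataFrame  # individuals x K posterior-mean ancestry
    allele_freqs: np.ndarray  # (K, n_markers) posterior-mean frequencies
    lnL_trace: np.ndarray  # per-sweep log-likelihood after burn-in
    L_of_K: float
    converged: bool = True

    def write_q(self, path: str | Path) -> None:
        self.Q.to_csv(path, sep="\t", float_format="%.6g")


def _copies(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Explode dosages into two allele copies per cell.

    Returns (alleles, valid): alleles is (n, L, 2) in {0, 1} counting
    allele_b, valid marks non-missing cells.
    """
    calls = matrix.calls
    n, L = calls.shape
    a = np.zeros((n, L, 2), dtype=np.int8)
    a[..., 0] = (calls >= 1) & (calls != MISSING)
    a[..., 1] = calls == 2
    valid = np.repeat((calls != MISSING)[..., None], 2, axis=2)
    return a, valid


def gibbs_run(
    matrix: GenotypeMatrix,
    K: int,
    config: StructureConfig | None = None,
    seed: int | None = None,
) -> AncestryResult:
    """One MCMC chain of the admixture model at a fixed K."""
    config = config or StructureConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    import warnings

    if K > matrix.n_individuals:
        warnings.warn(f"K={K} exceeds the number of individuals", stacklevel=2)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, L = matrix.n_individuals, matrix.n_markers
    alleles, valid = _copies(matrix)
    alleles_f = alleles.astype(float)
    valid_f = valid.astype(float)

    # initial state
    q = rng.dirichlet([config.alpha] * K, size=n)  # (n, K)
    p = rng.beta(1.0, 1.0, size=(K, L))

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    trace = np.empty(config.sweeps - config.burn_in)
    kept = 0

    n1 = np.zeros((K, L))
    n0 = np.zeros((K, L))
    c_ik = np.zeros((n, K))
    for sweep in range(config.sweeps):
        # --- z | q, p : per copy, prob_k ∝ q_ik * p_kl^a (1-p_kl)^(1-a),
        # sampled and tallied inside the compiled kernel
        u = rng.random((n, L, 2))
        _sweep_counts(alleles, valid, q, p, u, n1, n0, c_ik)

        # --- p | z : Beta(lam + #allele_b, lam + #allele_a) per (k, l)
        p = rng.beta(config.lam + n1, config.lam + n0)
        np.clip(p, 1e-12, 1 - 1e-12, out=p)

        # --- q | z : Dirichlet(alpha + counts) per individual
        g = rng.standard_gamma(config.alpha + c_ik)
        q = g / g.sum(axis=1, keepdims=True)

        if sweep >= config.burn_in:
            q_sum += q
            p_sum += p
            # marginal likelihood of the data given (P, Q)
            m1 = q @ p  # (n, L): per-copy prob of allele_b
            m = np.where(alleles == 1, m1[..., None], (1.0 - m1)[..., None])
            trace[kept] = float(np.sum(np.log(np.clip(m, 1e-300, None)) * valid_f))
            kept += 1

    n_kept = config.sweeps - config.burn_in
    Q = pd.DataFrame(
        q_sum / n_kept,
        index=matrix.individuals,
        columns=[f"q{k+1}" for k in range(K)],
    )
    half = n_kept // 2
    converged = True
    if half >= 2:
        d = abs(estimate_LK(trace[:half]) - estimate_LK(trace[half:]))
        spread = max(np.std(trace), 1.0)
        converged = d <= 5.0 * spread
    return AncestryResult(
        K=K,
        Q=Q,
        allele_freqs=p_sum / n_kept,
        lnL_trace=trace,
        L_of_K=estimate_LK(trace),
        converged=converged,
    )


def estimate_LK(lnL_trace: Sequence[float]) -> float:
    """Model-evidence proxy: mean of the log-likelihood trace minus half its
    (sample) variance."""
    t = np.asarray(lnL_trace, dtype=float)
    if t.size < 1:
        raise ValueError("empty trace")
    var = float(np.var(t, ddof=1)) if t.size > 1 else 0.0
    return float(np.mean(t) - var / 2.0)


def k_scan(
    matrix: GenotypeMatrix,
    config: StructureConfig,
) -> dict[int, list[AncestryResult]]:
    """Run ``replicates`` chains for every K in [k_min, k_max].

    Each (K, replicate) pair gets an independent RNG stream derived from the
    master seed, so adding replicates never perturbs earlier ones.
    """
    out: dict[int, list[AncestryResult]] = {}
    for K in range(config.k_min, config.k_max + 1):
        runs = []
        for rep in range(config.replicates):
            child = np.random.SeedSequence(entropy=config.seed, spawn_key=(K, rep))
            rng_seed = int(child.generate_state(1)[0] % (2**31))
            runs.append(gibbs_run(matrix, K, config, seed=rng_seed))
        out[K] = runs
    return out


def delta_k(L_table: dict[int, Sequence[float]]) -> pd.DataFrame:
    """Evanno table: per K the mean/sd of L(K) across replicates, deltaK at
    interior K, and the argmax flag.

    deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)).
    Requires >= 3 consecutive K values; with sd = 0 the value is undefined
    (NaN) at that K.
    """
    ks = sorted(L_table)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("delta_k needs >= 3 consecutive K values")
    mean_L = {k: float(np.mean(L_table[k])) for k in ks}
    sd_L = {
        k: float(np.std(L_table[k], ddof=1)) if len(L_table[k]) > 1 else np.nan
        for k in ks
    }
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            curv = abs(mean_L[k + 1] - 2 * mean_L[k] + mean_L[k - 1])
            dk = curv / sd_L[k] if sd_L[k] and sd_L[k] > 0 else np.nan
        rows.append(
            {"K": k, "mean_L": mean_L[k], "sd_L": sd_L[k], "deltaK": dk, "is_optimal": False}
        )
    df = pd.DataFrame(rows)
    if df["deltaK"].notna().any():
        df.loc[df["deltaK"].idxmax(), "is_optimal"] = True
    return df


def assign_groups(result: AncestryResult, threshold: float = 0.60) -> pd.Series:
    """Per-individual group label; ``mixed`` unless max Q strictly exceeds
    the threshold."""
    q = result.Q.to_numpy()
    best = q.argmax(axis=1)
    labels = [
        result.Q.columns[b] if q[i, b] > threshold else "mixed"
        for i, b in enumerate(best)
    ]
    return pd.Series(labels, index=result.Q.index, name="group")


def align_labels(results: Sequence[AncestryResult]) -> list[AncestryResult]:
    """Undo label switching across replicate runs of the same K.

    Each replicate's Q columns are permuted to best match the first
    replicate (optimal one-to-one assignment on column correlations);
    deterministic given the inputs.
    """
    if not results:
        return []
    K = results[0].K
    ref = results[0].Q.to_numpy()
    aligned = [results[0]]
    for res in results[1:]:
        if res.K != K or list(res.Q.index) != list(results[0].Q.index):
            raise ValueError("align_labels requires same K and individuals")
        cur = res.Q.to_numpy()
        score = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                if np.std(ref[:, a]) == 0 or np.std(cur[:, b]) == 0:
                    score[a, b] = -np.sum((ref[:, a] - cur[:, b]) ** 2)
                else:
                    score[a, b] = np.corrcoef(ref[:, a], cur[:, b])[0, 1]
        rows, cols = linear_sum_assignment(-score)
        perm = cols[np.argsort(rows)]
        Q = res.Q.iloc[:, perm]
        Q.columns = results[0].Q.columns
        aligned.append(
            AncestryResult(
                K=res.K,
                Q=Q,
                allele_freqs=res.allele_freqs[perm],
                lnL_trace=res.lnL_trace,
                L_of_K=res.L_of_K,
                converged=res.converged,
            )
        )
    return aligned


def write_structure_input(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Classic two-rows-per-individual integer format for cross-checking
    against the original admixture program (missing = -9)."""
    with Path(path).open("w") as fh:
        for i, ind in enumerate(matrix.individuals):
            rows: list[list[int]] = [[], []]
            for c in matrix.calls[i]:
                if c == MISSING:
                    rows[0].append(-9), rows[1].append(-9)
                else:
                    rows[0].append(1 if c >= 1 else 0)
                    rows[1].append(1 if c == 2 else 0)
            for r in rows:
                fh.write(ind + " " + " ".join(map(str, r)) + "\n")
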