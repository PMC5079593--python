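"""Genomic relationship matrix, inbreeding Fst from its diagonal, and
effective population size.

G is the VanRaden method-1 relationship matrix: the dosage matrix is
column-centered by twice the allele frequency (missing cells imputed to the
column mean, i.e. zero after centering) and normalised by sum 2*p*q, so the
mean diagonal equals 1 + F under the model.  The within-population
inbreeding coefficient is then mean(diag(G)) - 1, and effective population
size follows from it: N/(1 + Fst) for a hybrid panel, N/(2*Fst) for the
parents of the hybrids.  A literal ``as_printed`` mode (1/(1+Fst),
1/(2*Fst)) is kept for comparison with legacy formula transcriptions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix

NeMode = Literal["n_scaled", "as_printed"]


@dataclass
class KinshipResult:
    G: pd.DataFrame
    fst: float
    n_individuals: int
    ne_hybrid: float
    ne_parents: float | None
    mode: NeMode
    denominator: float

    def write(self, g_path: str | Path, json_path: str | Path) -> None:
        self.G.to_csv(g_path, sep="\t", float_format="%.10g")
        payload = {
            "fst": self.fst,
            "n": self.n_individuals,
            "ne_hybrid": self.ne_hybrid,
            "ne_parents": self.ne_parents,
            "mode": self.mode,
            "denominator": self.denominator,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def g_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Genomic relationship matrix G = WW' / sum_i 2 p_i q_i.

    W is the dosage matrix centered by 2p per marker, with allele
    frequencies estimated from this same matrix; missing cells are
    mean-imputed (zero after centering), which keeps G positive
    semi-definite.
    """
    q = matrix.allele_b_freq()  # frequency of the dosage-counted allele
    p = 1.0 - q
    denom = float(np.nansum(2.0 * p * q))
    if not denom > 0:
        raise ValueError("all markers monomorphic: zero 2pq denominator")
    X = matrix.calls.astype(float)
    X[matrix.calls == MISSING] = np.nan
    W = X - 2.0 * q[np.newaxis, :]
    W = np.nan_to_num(W, nan=0.0)
    G = (W @ W.T) / denom
    return pd.DataFrame(G, index=matrix.individuals, columns=matrix.individuals)


def fst_from_g(G: pd.DataFrame | np.ndarray) -> float:
    """Within-population inbreeding coefficient: mean(diag(G)) - 1."""
    arr = np.asarray(G, dtype=float)
    if arr.size == 0:
        raise ValueError("empty relationship matrix")
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("G must be square")
    fst = float(np.mean(np.diag(arr)) - 1.0)
    if fst < 0:
        warnings.warn(f"negative inbreeding estimate {fst:.4f}", stacklevel=2)
    return fst


def effective_size(
    fst: float,
    n: int,
    population: Literal["hybrids", "parents"],
    mode: NeMode = "n_scaled",
) -> float:
    """Effective population size from the inbreeding coefficient.

    hybrids: Ne = N/(1+Fst)   (``as_printed``: 1/(1+Fst))
    parents: Ne = N/(2*Fst)   (``as_printed``: 1/(2*Fst))
    """
    if fst <= -1:
        raise ValueError("fst must exceed -1")
    if n < 1:
        raise ValueError("n must be >= 1")
    scale = float(n) if mode == "n_scaled" else 1.0
    if population == "hybrids":
        return scale / (1.0 + fst)
    if population == "parents":
        if fst <= 0:
            raise ValueError("parents Ne undefined for fst <= 0")
        return scale / (2.0 * fst)
    raise ValueError(f"unknown population kind {population!r}")


def kinship_analysis(
    matrix: GenotypeMatrix,
    n: int | None = None,
    mode: NeMode = "n_scaled",
) -> KinshipResult:
    """G matrix, Fst, and both Ne estimates for one panel."""
    G = g_matrix(matrix)
    fst = fst_from_g(G)
    n_eff = n if n is not None else matrix.n_individuals
    ne_h = effective_size(fst, n_eff, "hybrids", mode)
    ne_p = effective_size(fst, n_eff, "parents", mode) if fst > 0 else None
    q = matrix.allele_b_freq()
    denom = float(np.nansum(2.0 * (1 - q) * q))
    return KinshipResult(
        G=G,
        fst=fst,
        n_individuals=n_eff,
        ne_hybrid=ne_h,
        ne_parents=ne_p,
        mode=mode,
        denominator=denom,
    )
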