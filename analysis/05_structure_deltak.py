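#!/usr/bin/env python
"""Admixture structuring of the hybrid panel and Evanno deltaK.

Scans K = 1..7 with 5 replicate chains each (desk-scale MCMC: 2,000 sweeps,
800 burn-in), aligns replicate labels, picks the optimal K by deltaK and
assigns each hybrid to a population when its membership exceeds 60%.
"""

from pathlib import Path

import numpy as np

from germdiv.admixture import (
    StructureConfig,
    align_labels,
    assign_groups,
    delta_k,
    k_scan,
)
from germdiv.genodata import read_genotypes

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "structure"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = read_genotypes(ROOT / "diversity" / "hybrids_qc.tsv")
    cfg = StructureConfig(k_min=1, k_max=7, replicates=5,
                          sweeps=2000, burn_in=800, seed=SEED)
    runs = k_scan(gm, cfg)
    table = {}
    for K, results in runs.items():
        for r_i, res in enumerate(align_labels(results)):
            res.write_q(OUT / f"q_matrix.K{K}.rep{r_i+1}.tsv")
        table[K] = [r.L_of_K for r in results]
    dk = delta_k(table)
    dk.to_csv(OUT / "deltaK.tsv", sep="\t", index=False, float_format="%.4g")
    best = int(dk.loc[dk["is_optimal"], "K"].iloc[0])
    print(dk.to_string(index=False))
    print(f"\noptimal K by deltaK: {best}")

    best_runs = align_labels(runs[best])
    mean_q = best_runs[0].Q.copy()
    mean_q.loc[:, :] = np.mean([r.Q.to_numpy() for r in best_runs], axis=0)
    rep = best_runs[0]
    rep.Q = mean_q
    assignments = assign_groups(rep)
    assignments.to_csv(OUT / "assignments.tsv", sep="\t")
    n_mixed = int((assignments == "mixed").sum())
    print(f"assigned hybrids: {len(assignments) - n_mixed}, mixed: {n_mixed}")


if __name__ == "__main__":
    main()
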