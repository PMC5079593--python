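#!/usr/bin/env python
"""Simulate the two study panels and write them with full truth records.

Panel one: 20 single-cross hybrids from 7 company groups, genotyped at 768
SNPs with 5% missingness.  Hybrids are built as F1 crosses between inbred
lines drawn from each company's ancestral population, so heterozygosity
reflects parental divergence.  Panel two: 27 inbred founder lines at 1,536
SNPs, 340 of which are shared with the hybrid panel.

Outputs under results/panels/.
"""

from dataclasses import replace
from pathlib import Path

from germdiv.genodata import GroupAssignment, write_genotypes, write_groups
from germdiv.simdata import (
    SimConfig,
    cross_hybrids,
    apply_missingness,
    simulate_inbred_panel,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "panels"
SEED = 2024

COMPANY_SIZES = [4, 3, 3, 3, 3, 2, 2]  # hybrids per company, total 20


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    k = len(COMPANY_SIZES)

    # two parental lines per hybrid, drawn from the company's population
    parents_per_pop = [2 * s for s in COMPANY_SIZES]
    line_cfg = SimConfig(n_markers=768, K=k, F=0.25,
                         n_per_population=parents_per_pop, seed=SEED)
    parents, _ = simulate_inbred_panel(line_cfg)
    pairs, names, mapping = [], [], {}
    idx = 0
    for c, size in enumerate(COMPANY_SIZES):
        for h in range(size):
            p1, p2 = parents.individuals[idx], parents.individuals[idx + 1]
            idx += 2
            name = f"hyb_c{c+1}_{h+1}"
            pairs.append((p1, p2))
            names.append(name)
            mapping[name] = f"company{c+1}"
    hybrids = cross_hybrids(parents, pairs, names)
    hybrids = apply_missingness(hybrids, 0.05, seed=SEED + 1)
    write_genotypes(hybrids, OUT / "hybrids_genotypes.tsv")
    write_groups(GroupAssignment(mapping), OUT / "hybrids_groups.tsv")

    # 27 NAM-style founder lines, 3 ancestral populations, 1,536 SNPs
    nam_cfg = SimConfig(n_markers=1536, K=3, F=0.3, n_per_population=9,
                        seed=SEED + 2)
    lines, truth = simulate_inbred_panel(nam_cfg)
    lines.markers = [replace(m, marker_id=f"nam_{m.marker_id}")
                     for m in lines.markers]
    for j in range(340):  # constructed shared subset with the hybrid panel
        lines.markers[j] = hybrids.markers[j]
    write_genotypes(lines, OUT / "lines_genotypes.tsv")
    truth.write(OUT, prefix="lines_truth")

    print(f"hybrid panel: {hybrids.n_individuals} x {hybrids.n_markers}")
    print(f"line panel:   {lines.n_individuals} x {lines.n_markers} "
          f"(340 markers shared with the hybrids)")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
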