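#!/usr/bin/env python
"""Quality control and diversity statistics of the hybrid panel.

Filters markers at call rate >= 90% and MAF >= 5%, then computes per-locus
gene diversity, PIC, heterozygosity and MAF, per-company summaries, private
alleles, and Pearson correlations of company allele frequencies.
"""

from pathlib import Path

from germdiv.diversity import (
    allele_frequency_table,
    correlation_matrix,
    group_summary,
    locus_stats,
    private_alleles,
    write_private_alleles,
)
from germdiv.genodata import qc_filter, read_genotypes, read_groups, write_genotypes

ROOT = Path(__file__).resolve().parents[1] / "results"
PANELS = ROOT / "panels"
OUT = ROOT / "diversity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = read_genotypes(PANELS / "hybrids_genotypes.tsv")
    groups = read_groups(PANELS / "hybrids_groups.tsv")

    filtered, report = qc_filter(gm)
    report.write_tsv(OUT / "qc_report.tsv")
    write_genotypes(filtered, OUT / "hybrids_qc.tsv")
    print(f"QC: {report.markers_passing}/{report.markers_in} markers retained")

    locus_stats(filtered).to_csv(OUT / "locus_stats.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    gs = group_summary(filtered, groups)
    gs.to_csv(OUT / "group_summary.tsv", sep="\t", index=False, float_format="%.4g")
    print("\nper-company diversity:")
    print(gs.to_string(index=False))

    recs = private_alleles(filtered, groups)
    write_private_alleles(recs, OUT / "private_alleles.tsv")
    by_group: dict[str, int] = {}
    for r in recs:
        by_group[r.group] = by_group.get(r.group, 0) + 1
    print(f"\nprivate alleles: {len(recs)} total, by company {by_group}")

    ft = allele_frequency_table(filtered, groups)
    r, p = correlation_matrix(ft)
    r.to_csv(OUT / "correlations_r.tsv", sep="\t", float_format="%.4g")
    p.to_csv(OUT / "correlations_p.tsv", sep="\t", float_format="%.3g")
    import numpy as np

    upper = p.to_numpy()[np.triu_indices(len(p), k=1)]
    stars = int((upper < 0.01).sum())
    print(f"company-pair correlations significant at 1%: {stars} of {len(upper)}")


if __name__ == "__main__":
    main()
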