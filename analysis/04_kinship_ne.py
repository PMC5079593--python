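#!/usr/bin/env python
"""Genomic kinship, within-population inbreeding, and effective size.

Builds the genomic relationship matrix from the QC'd hybrid panel, takes
Fst as mean(diag(G)) - 1, and reports the hybrid effective population size
N/(1+Fst) and the parental estimate N/(2*Fst) with N = 20.
"""

from pathlib import Path

from germdiv.genodata import read_genotypes
from germdiv.kinship import kinship_analysis

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "kinship"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = read_genotypes(ROOT / "diversity" / "hybrids_qc.tsv")
    res = kinship_analysis(gm, n=20)
    res.write(OUT / "G.tsv", OUT / "kinship.json")
    print(f"Fst (mean diagonal of G minus one): {res.fst:.4f}")
    print(f"Ne hybrids  = 20/(1+Fst) = {res.ne_hybrid:.2f}")
    if res.ne_parents is not None:
        print(f"Ne parents  = 20/(2*Fst) = {res.ne_parents:.2f}")


if __name__ == "__main__":
    main()
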