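"""End-to-end orchestration: QC -> diversity -> correlations -> private
alleles -> distances/tree -> kinship/Ne -> admixture/deltaK -> report.

Every stage writes its tabular outputs to the run directory, and stages
that consume an earlier stage's matrix read it back from disk, so the
serialized formats are guaranteed sufficient.  Runs are reproducible: the
same config and master seed give byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import (
    StructureConfig,
    align_labels,
    assign_groups,
    delta_k,
    k_scan,
)
from .diversity import (
    allele_frequency_table,
    correlation_matrix,
    group_summary,
    locus_stats,
    private_alleles,
    write_private_alleles,
)
from .genodata import (
    GenotypeMatrix,
    GroupAssignment,
    intersect_panels,
    qc_filter,
    read_genotypes,
    read_groups,
    write_genotypes,
    write_groups,
)
from .kinship import kinship_analysis
from .neitree import bootstrap_support, distance_matrix, write_newick
from .simdata import SimConfig, population_labels, simulate_admixed

log = logging.getLogger("germdiv")


@dataclass
class PipelineConfig:
    """One self-contained run: either file inputs or a simulate block."""

    out_dir: str = "germdiv_run"
    seed: int = 0
    # file inputs (exactly one of these two input routes must be set)
    genotypes: str | None = None
    genotype_format: str = "individual-major-tsv"
    groups_file: str | None = None
    simulate: SimConfig | None = None
    # stage settings
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    bootstrap_reps: int = 2000
    tree_units: str = "individuals"
    ne_mode: str = "n_scaled"
    ne_n: int | None = None
    structure: StructureConfig | None = field(default_factory=StructureConfig)
    run_structure: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        has_files = self.genotypes is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValueError("config must set exactly one of genotypes / simulate")
        if has_files and self.groups_file is None:
            raise ValueError("file input requires a groups_file")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("simulate") is not None:
            raw["simulate"] = SimConfig(**raw["simulate"])
        if raw.get("structure") is not None:
            raw["structure"] = StructureConfig(**raw["structure"])
        return cls(**raw)

    def config_hash(self) -> str:
        # analytical settings only: the same analysis written elsewhere
        # hashes identically
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    manifest: dict[str, str]  # stage output name -> path
    summary: dict[str, Any]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2) + "\n")
        (out / "summary.json").write_text(
            json.dumps(self.summary, indent=2, default=float) + "\n"
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as e:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, e) from e
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order; see the module docstring."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info("germdiv %s  config %s  seed %d", __version__, config.config_hash(), config.seed)
    manifest: dict[str, str] = {}
    summary: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    # ------ input / simulate
    @_stage("input")
    def load() -> tuple[GenotypeMatrix, GroupAssignment]:
        if config.simulate is not None:
            sim_cfg = config.simulate
            gm, truth = simulate_admixed(sim_cfg)
            groups = population_labels(sim_cfg)
            truth.write(out)
            manifest["truth_Q"] = str(out / "truth_Q.tsv")
        else:
            gm = read_genotypes(config.genotypes, config.genotype_format)
            groups = read_groups(config.groups_file)
        write_genotypes(gm, out / "genotypes_raw.tsv")
        write_groups(groups, out / "groups.tsv")
        manifest["genotypes_raw"] = str(out / "genotypes_raw.tsv")
        manifest["groups"] = str(out / "groups.tsv")
        return gm, groups

    gm, groups = load()

    # groups for simulated panels may use custom labels
    if config.simulate is not None and config.simulate.K == 1:
        groups = GroupAssignment({i: "pop1" for i in gm.individuals})

    # ------ QC
    @_stage("qc")
    def qc() -> GenotypeMatrix:
        filtered, report = qc_filter(gm, config.min_call_rate, config.min_maf)
        report.write_tsv(out / "qc_report.tsv")
        write_genotypes(filtered, out / "genotypes_qc.tsv")
        manifest["qc_report"] = str(out / "qc_report.tsv")
        manifest["genotypes_qc"] = str(out / "genotypes_qc.tsv")
        summary["markers_in"] = report.markers_in
        summary["markers_pass_qc"] = report.markers_passing
        return filtered

    qc()
    # later stages read the QC'd matrix back from disk (format sufficiency)
    gm_qc = read_genotypes(out / "genotypes_qc.tsv")
    groups = read_groups(out / "groups.tsv")

    # ------ diversity
    @_stage("diversity")
    def diversity_stage() -> None:
        locus_stats(gm_qc).to_csv(out / "locus_stats.tsv", sep="\t", index=False, float_format="%.6g")
        gs = group_summary(gm_qc, groups)
        gs.to_csv(out / "group_summary.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["locus_stats"] = str(out / "locus_stats.tsv")
        manifest["group_summary"] = str(out / "group_summary.tsv")
        summary["group_summary"] = gs.set_index("group")[["gd", "pic", "het", "maf"]].round(6).to_dict("index")

    diversity_stage()

    # ------ correlations + private alleles
    @_stage("correlations")
    def correlations() -> None:
        ft = allele_frequency_table(gm_qc, groups)
        r, p = correlation_matrix(ft)
        r.to_csv(out / "correlations_r.tsv", sep="\t", float_format="%.6g")
        p.to_csv(out / "correlations_p.tsv", sep="\t", float_format="%.6g")
        manifest["correlations_r"] = str(out / "correlations_r.tsv")
        manifest["correlations_p"] = str(out / "correlations_p.tsv")

    @_stage("private_alleles")
    def private() -> None:
        if len(groups.groups()) < 2:
            log.info("single group: skipping private alleles")
            return
        recs = private_alleles(gm_qc, groups)
        write_private_alleles(recs, out / "private_alleles.tsv")
        manifest["private_alleles"] = str(out / "private_alleles.tsv")
        summary["n_private_alleles"] = len(recs)

    if len(groups.groups()) >= 2:
        correlations()
    private()

    # ------ distances + tree
    @_stage("tree")
    def tree() -> None:
        d = distance_matrix(gm_qc, units=config.tree_units, groups=groups)
        d.write_tsv(out / "distances.tsv")
        t = bootstrap_support(
            gm_qc,
            units=config.tree_units,
            groups=groups,
            n_reps=config.bootstrap_reps,
            seed=config.seed + 1,
        )
        write_newick(t, out / "tree.nwk")
        (out / "bootstrap.log").write_text(
            f"seed\t{config.seed + 1}\nreplicates\t{config.bootstrap_reps}\n"
        )
        manifest["distances"] = str(out / "distances.tsv")
        manifest["tree"] = str(out / "tree.nwk")
        supports = [nd.support for nd in t.internal_nodes() if nd.support is not None]
        summary["mean_node_support"] = float(np.mean(supports)) if supports else None

    tree()

    # ------ kinship / Ne
    @_stage("kinship")
    def kinship() -> None:
        res = kinship_analysis(gm_qc, n=config.ne_n, mode=config.ne_mode)
        res.write(out / "G.tsv", out / "kinship.json")
        manifest["G"] = str(out / "G.tsv")
        manifest["kinship"] = str(out / "kinship.json")
        summary["fst"] = res.fst
        summary["ne_hybrid"] = res.ne_hybrid
        summary["ne_parents"] = res.ne_parents

    kinship()

    # ------ structure / deltaK
    if config.run_structure and config.structure is not None:
        @_stage("structure")
        def structure() -> None:
            scfg = config.structure
            scfg = StructureConfig(**{**asdict(scfg), "seed": config.seed + 2})
            runs = k_scan(gm_qc, scfg)
            L_table: dict[int, list[float]] = {}
            for K, results in runs.items():
                aligned = align_labels(results)
                for r_i, res in enumerate(aligned):
                    res.write_q(out / f"q_matrix.K{K}.rep{r_i + 1}.tsv")
                L_table[K] = [res.L_of_K for res in results]
            if len(L_table) >= 3 and scfg.replicates >= 2:
                dk = delta_k(L_table)
                dk.to_csv(out / "deltaK.tsv", sep="\t", index=False, float_format="%.6g")
                manifest["deltaK"] = str(out / "deltaK.tsv")
                opt = dk.loc[dk["is_optimal"], "K"]
                best_k = int(opt.iloc[0]) if len(opt) else None
            else:
                best_k = max(L_table, key=lambda k: np.mean(L_table[k]))
            summary["optimal_k"] = best_k
            if best_k is not None:
                best_runs = align_labels(runs[best_k])
                qbar = sum(r.Q.to_numpy() for r in best_runs) / len(best_runs)
                mean_q = best_runs[0].Q.copy()
                mean_q.loc[:, :] = qbar
                best = best_runs[0]
                best_mean = type(best)(
                    K=best.K, Q=mean_q, allele_freqs=best.allele_freqs,
                    lnL_trace=best.lnL_trace, L_of_K=best.L_of_K,
                )
                assign_groups(best_mean).to_csv(out / "assignments.tsv", sep="\t")
                manifest["assignments"] = str(out / "assignments.tsv")

        structure()

    bundle = ReportBundle(manifest=manifest, summary=summary)
    bundle.write(out)
    return bundle


def combined_analysis(
    hybrids: GenotypeMatrix,
    lines: GenotypeMatrix,
    config: PipelineConfig,
    groups: GroupAssignment | None = None,
) -> ReportBundle:
    """Merged-panel analysis: intersect the marker panels, re-run QC on the
    combined matrix, then tree + admixture on the union of individuals."""
    combined = intersect_panels(hybrids, lines)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(combined, out / "genotypes_combined_raw.tsv")
    if groups is None:
        mapping = {i: "hybrids" for i in hybrids.individuals}
        mapping.update({i: "lines" for i in lines.individuals})
        groups = GroupAssignment(mapping)
    write_groups(groups, out / "groups_combined.tsv")
    sub_cfg = PipelineConfig(
        **{
            **{k: v for k, v in asdict(config).items() if k not in (
                "genotypes", "genotype_format", "groups_file", "simulate",
                "structure", "out_dir",
            )},
            "out_dir": str(out),
            "genotypes": str(out / "genotypes_combined_raw.tsv"),
            "groups_file": str(out / "groups_combined.tsv"),
        }
    )
    sub_cfg.structure = config.structure
    sub_cfg.run_structure = config.run_structure
    bundle = run_pipeline(sub_cfg)
    bundle.summary["markers_shared_pre_qc"] = combined.n_markers
    bundle.write(out)
    return bundle
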