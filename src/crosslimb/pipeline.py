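"""End-to-end pipeline orchestration with config, logging and fixed seeds.

Two entry points: :func:`run_interaction_pipeline` chains annotation
transfer -> count aggregation -> species intersection -> interaction DE ->
candidate ranking, either from real input tables or from the synthetic
generator; :func:`run_misexpression_pipeline` chains low-count filtering ->
sex inference -> treatment+sex DE. Both write all intermediate tables plus a
machine-readable JSON report and are byte-reproducible from config + seed.

Upstream read-level processing (trimming, alignment, assembly, clustering,
read counting) is expected provenance of the input count tables and is
recorded in the report as metadata only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import crosslimb
from crosslimb import annotation as ann
from crosslimb import io as cio
from crosslimb import misexpression as mis
from crosslimb.interaction_de import run_interaction_de
from crosslimb.sim_data import SimConfig, PlantedEffect, simulate_assembly, simulate_gene_counts, simulate_misexpression

log = logging.getLogger("crosslimb")


class PipelineError(RuntimeError):
    """Stage failure; the message names the failing stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs: paths, thresholds, seed."""

    outdir: str = "crosslimb_out"
    seed: int = 0
    evalue: float = 1e-5
    alpha: float = 0.05
    min_count: int = 10
    min_samples: int = 2
    sex_cpm_threshold: float = 1.0
    sex_marker: str = "HINTW"
    sim: SimConfig | None = None
    # real-data inputs (unused for synthetic runs)
    chicken_counts: str | None = None
    locus_counts: str | None = None
    clusters: str | None = None
    hits: str | None = None
    samples: str | None = None
    misexpr_counts: str | None = None
    misexpr_samples: str | None = None
    log_level: str = "INFO"
    upstream_metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.evalue <= 0:
            raise ValueError("evalue threshold must be > 0")
        if self.min_count < 0 or self.min_samples < 0:
            raise ValueError("min_count/min_samples must be non-negative")
        if self.sex_cpm_threshold <= 0:
            raise ValueError("sex CPM threshold must be > 0")
        if self.sim is not None:
            self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            planted = [PlantedEffect(**p) for p in sim_raw.pop("planted", [])]
            for key in ("baseline_log2_mean", "lib_size_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            if "misexpr_sexes" in sim_raw and sim_raw["misexpr_sexes"] is not None:
                sim_raw["misexpr_sexes"] = tuple(sim_raw["misexpr_sexes"])
            cfg.sim = SimConfig(planted=planted, **sim_raw)
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        if self.sim is not None:
            raw["sim"]["planted"] = [dataclasses.asdict(p) for p in self.sim.planted]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def run_interaction_pipeline(config: RunConfig) -> dict:
    """annotate -> aggregate -> intersect -> interaction DE -> rank."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim = config.sim.replace(seed=config.seed)
        log.info("simulating two-species gene counts (%d genes)", sim.n_genes)
        emu_genes, chick_counts, samples, truth = simulate_gene_counts(sim)
        locus_counts, cluster_map, hits = simulate_assembly(emu_genes, truth, sim)
        simdir = outdir / "sim"
        simdir.mkdir(exist_ok=True)
        cio.write_counts(chick_counts, simdir / "chicken_gene_counts.tsv", "gene_id")
        cio.write_counts(locus_counts, simdir / "emu_locus_counts.tsv", "locus_id")
        cio.write_cluster_map(cluster_map, simdir / "clusters.tsv")
        cio.write_blast6(hits, simdir / "hits.tsv")
        cio.write_sample_sheet(samples, simdir / "samples.csv")
        truth.genes.to_csv(simdir / "truth_genes.tsv", sep="\t")
        truth.loci.to_csv(simdir / "truth_loci.tsv", sep="\t")
    else:
        needed = ["chicken_counts", "locus_counts", "clusters", "hits", "samples"]
        missing = [k for k in needed if getattr(config, k) is None]
        if missing:
            raise PipelineError(f"stage 'load_inputs' failed: missing inputs {missing}")
        chick_counts = cio.read_counts(config.chicken_counts)
        locus_counts = cio.read_counts(config.locus_counts)
        cluster_map = cio.read_cluster_map(config.clusters)
        hits = cio.read_blast6(config.hits)
        samples = cio.read_sample_sheet(config.samples)

    annotate = _stage("annotate")(_annotate)
    annot, emu_gene_counts = annotate(hits, cluster_map, locus_counts, config.evalue)
    annot.to_frame().to_csv(outdir / "annotation_report.tsv", sep="\t", index=False)
    cio.write_counts(emu_gene_counts, outdir / "emu_gene_counts.tsv", "gene_id")

    intersect = _stage("intersect_species")(ann.intersect_species)
    joined, genes, dropped = intersect(emu_gene_counts, chick_counts)
    cio.write_counts(joined, outdir / "joined_counts.tsv", "gene_id")
    pd.Series(
        {"only_in_emu": len(dropped["only_in_a"]), "only_in_chicken": len(dropped["only_in_b"])}
    ).to_csv(outdir / "drop_log.tsv", sep="\t", header=False)

    de = _stage("de_interaction")(run_interaction_de)
    results, info = de(joined, samples, alpha=config.alpha)
    results.to_csv(outdir / "interaction_results.tsv", sep="\t", index_label="gene_id")
    ranked = results[results["rank"].notna()].sort_values("rank")

    report = {
        "pipeline": "interaction",
        "crosslimb_version": crosslimb.__version__,
        "seed": config.seed,
        "n_loci": int(len(locus_counts)),
        "n_annotated": len(annot.annotated),
        "n_multigene_discarded": len(annot.discarded_multigene),
        "n_unannotated": len(annot.unannotated),
        "n_genes_joined": len(genes),
        "n_genes_tested": info["n_genes_tested"],
        "n_significant": info["n_significant"],
        "d0": info["d0"],
        "s0_2": info["s0_2"],
        "alpha": config.alpha,
        "evalue_threshold": config.evalue,
        "top_ranked_genes": list(ranked.index[:10]),
        "upstream_metadata": config.upstream_metadata,
    }
    _write_report(report, outdir)
    return report


def _annotate(hits, cluster_map, locus_counts, evalue):
    kept = ann.filter_hits(hits, threshold=evalue)
    contig_genes = ann.best_hit_per_contig(kept)
    annot = ann.annotate_loci(cluster_map, contig_genes)
    gene_counts = ann.aggregate_counts(locus_counts, annot)
    return annot, gene_counts


def run_misexpression_pipeline(config: RunConfig) -> dict:
    """filter -> sex inference -> treatment+sex moderated fit."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim = config.sim.replace(seed=config.seed)
        counts, samples, truth = simulate_misexpression(sim)
        simdir = outdir / "sim"
        simdir.mkdir(exist_ok=True)
        cio.write_counts(counts, simdir / "misexpr_counts.tsv", "gene_id")
        cio.write_sample_sheet(samples, simdir / "misexpr_samples.csv")
    else:
        if config.misexpr_counts is None or config.misexpr_samples is None:
            raise PipelineError(
                "stage 'load_inputs' failed: misexpr_counts and misexpr_samples required"
            )
        counts = cio.read_counts(config.misexpr_counts)
        samples = cio.read_sample_sheet(config.misexpr_samples)

    filt = _stage("filter_low_counts")(mis.filter_low_counts)
    filtered = filt(counts, config.min_count, config.min_samples)

    if config.sex_marker in filtered.index or config.sex_marker in counts.index:
        infer = _stage("infer_sex")(mis.infer_sex)
        sex = infer(counts, config.sex_marker, config.sex_cpm_threshold)
        sex_source = "inferred"
    elif "sex" in samples.columns:
        sex = samples.set_index("sample")["sex"]
        sex_source = "sample_sheet"
    else:
        raise PipelineError(
            "stage 'infer_sex' failed: marker gene "
            f"{config.sex_marker!r} absent and no sex column in the sample sheet"
        )
    sex.rename("sex").to_csv(outdir / "inferred_sex.tsv", sep="\t")

    import warnings as _warnings

    fit = _stage("misexpression_fit")(mis.misexpression_fit)
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        results, info = fit(filtered, samples, sex=sex, alpha=config.alpha)
    notes = [str(w.message) for w in caught]
    results.to_csv(outdir / "misexpression_results.tsv", sep="\t", index_label="gene_id")

    top = results.sort_values("rank").head(10)
    report = {
        "pipeline": "misexpression",
        "crosslimb_version": crosslimb.__version__,
        "seed": config.seed,
        "n_genes_input": int(len(counts)),
        "n_genes_after_filter": int(len(filtered)),
        "sex_source": sex_source,
        "sex_calls": sex.to_dict(),
        "design_columns": info["design_columns"],
        "sex_column_dropped": "sex_female" not in info["design_columns"],
        "n_genes_tested": info["n_genes_tested"],
        "n_significant": info["n_significant"],
        "d0": info["d0"],
        "s0_2": info["s0_2"],
        "top_ranked_genes": list(top.index),
        "warnings": notes,
        "upstream_metadata": config.upstream_metadata,
    }
    _write_report(report, outdir)
    return report
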