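"""End-to-end orchestration: simulate/read -> quantify -> differential -> report.

A single :class:`PipelineConfig` drives the run. Outputs land in one
directory: the three quantification matrices, the full differential table,
two published-style top tables (mRNA by log2 m6A fold change; other RNA by
methylation-ratio fold change), a sample clustering tree, a correlation
report, an enrichment table and a JSON manifest. Identical config + seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datatypes import MethylationProfile
from .differential import (
    ClassificationThresholds,
    DifferentialAnalyzer,
    hierarchical_cluster,
    top_table,
)
from .enrichment import fisher_enrichment, top_terms
from .io import (
    read_dataset,
    read_gmt,
    write_dataset,
    write_differential_table,
    write_gmt,
    write_matrix,
)
from .quantify import quantify
from .simulate import ConfigurationError, GroundTruth, SimulationConfig, generate_dataset
from .stats import pearson_correlation

logger = logging.getLogger(__name__)

HYPO_CLASSES = {"Hypo-down", "Hypo-up"}
HYPER_CLASSES = {"Hyper-down", "Hyper-up"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """One run's inputs, thresholds and output destination.

    Exactly one of ``simulation`` (a :class:`SimulationConfig` block) or
    ``inputs`` (paths ``intensities``/``annotation``/``samples``) must be
    present. ``seed`` overrides the simulation block's seed so one flag
    controls all randomness.
    """

    outdir: str = "m6array_out"
    simulation: SimulationConfig | None = None
    inputs: dict | None = None
    gmt_path: str | None = None
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    variant: str = "student"
    fc_basis: str = "quantity"
    min_present: int = 1
    bh: bool = False
    top_n_tables: int = 20
    top_n_terms: int = 10
    n_synthetic_gene_sets: int = 5
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "config must contain exactly one of a simulation block or input paths"
            )
        if self.inputs is not None:
            missing = {"intensities", "annotation", "samples"} - set(self.inputs)
            if missing:
                raise ConfigurationError(f"inputs block missing {sorted(missing)}")
        if self.seed is not None and self.simulation is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        if "thresholds" in data and data["thresholds"] is not None:
            thr = dict(data["thresholds"])
            if "meth_ratio_bounds" in thr:
                thr["meth_ratio_bounds"] = tuple(thr["meth_ratio_bounds"])
            data["thresholds"] = ClassificationThresholds(**thr)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = self.simulation.to_dict()
        out["thresholds"] = dataclasses.asdict(self.thresholds)
        return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    truth: GroundTruth | None = None

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if config.simulation is not None:
        dataset, truth = _stage("simulate")(generate_dataset, config.simulation)
        for p in _stage("simulate")(write_dataset, dataset, outdir / "input").values():
            files.append(str(p.relative_to(outdir)))
        truth.table.to_csv(outdir / "input" / "truth.tsv", sep="\t")
        files.append("input/truth.tsv")
    else:
        dataset = _stage("read")(
            read_dataset,
            config.inputs["intensities"],
            config.inputs["annotation"],
            config.inputs["samples"],
        )

    profile: MethylationProfile = _stage("quantify")(
        quantify, dataset, min_present=config.min_present
    )
    for name, mat in (
        ("meth_level", profile.meth_level),
        ("m6a_quantity", profile.m6a_quantity),
        ("expression", profile.expression),
    ):
        write_matrix(mat, outdir / f"{name}.tsv")
        files.append(f"{name}.tsv")

    analyzer = DifferentialAnalyzer(
        variant=config.variant, fc_basis=config.fc_basis,
        alpha=config.thresholds.alpha, fc_log2_min=config.thresholds.fc_log2_min,
        meth_ratio_bounds=config.thresholds.meth_ratio_bounds, bh=config.bh,
    )
    results = _stage("differential")(analyzer.fit, profile).results_
    write_differential_table(results, outdir / "differential_full.tsv")
    files.append("differential_full.tsv")

    mrna = results[results["rna_type"] == "mRNA"]
    top_mrna = top_table(mrna, config.top_n_tables, key="m6a_fc_asc",
                         regulation_filter=HYPO_CLASSES)
    if len(top_mrna):
        write_differential_table(top_mrna, outdir / "top_hypo_mrna.tsv")
        files.append("top_hypo_mrna.tsv")
    other = results[results["rna_type"] != "mRNA"]
    top_other = top_table(other, config.top_n_tables, key="meth_ratio_asc",
                          regulation_filter=HYPO_CLASSES)
    if len(top_other):
        write_differential_table(top_other, outdir / "top_hypo_other_rna.tsv")
        files.append("top_hypo_other_rna.tsv")

    cluster = _stage("cluster")(hierarchical_cluster, profile.meth_level.T)
    (outdir / "sample_cluster.nwk").write_text(cluster.newick + "\n")
    (outdir / "sample_leaf_order.txt").write_text("\n".join(cluster.leaf_order) + "\n")
    files += ["sample_cluster.nwk", "sample_leaf_order.txt"]

    files.append(_stage("associate")(_stats_report, profile, results, outdir))
    files.extend(_stage("enrich")(_enrichment_report, config, results, truth, outdir))

    manifest = {
        "package": "m6array",
        "version": __version__,
        "config": config.to_jsonable(),
        "files": sorted(files),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d files in %s", len(files) + 1, outdir)
    return outdir


def _stats_report(profile: MethylationProfile, results, outdir: Path) -> str:
    """Per-probe correlation of methylation level with expression, top probes."""
    by_p = results[results["p_m6a"].notna()].sort_values(
        ["p_m6a", "gene_symbol"], kind="mergesort"
    )
    lines = ["probe_id\tgene_symbol\tr\tp\tn"]
    for probe_id in by_p.index[:5]:
        x = profile.meth_level.loc[probe_id].to_numpy(dtype=float)
        y = profile.expression.loc[probe_id].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].var() == 0 or y[ok].var() == 0:
            continue
        res = pearson_correlation(x[ok], np.log2(y[ok]))
        lines.append(
            f"{probe_id}\t{by_p.loc[probe_id, 'gene_symbol']}\t"
            f"{res.r!r}\t{res.p!r}\t{res.n}"
        )
    (outdir / "stats_report.tsv").write_text("\n".join(lines) + "\n")
    return "stats_report.tsv"


def _enrichment_report(config: PipelineConfig, results, truth: GroundTruth | None,
                       outdir: Path) -> list[str]:
    written = ["enrichment.tsv"]
    background = sorted(set(results["gene_symbol"]))
    hits = sorted(set(results.loc[results["regulation"].isin(HYPO_CLASSES), "gene_symbol"]))
    if config.gmt_path is not None:
        gene_sets = read_gmt(config.gmt_path)
    elif truth is not None:
        gene_sets = synthetic_gene_sets(
            truth, results, n_random=config.n_synthetic_gene_sets,
            seed=truth.config.seed + 1,
        )
        write_gmt(gene_sets, outdir / "synthetic_gene_sets.gmt")
        written.append("synthetic_gene_sets.gmt")
    else:
        gene_sets = {}
    if not gene_sets or not hits:
        (outdir / "enrichment.tsv").write_text(
            "term_id\tcategory\tn_hits_in_set\tset_size\tn_hits\tbackground_size\tp\tscore\n"
        )
        return written
    table = fisher_enrichment(hits, background, gene_sets)
    top = top_terms(table, n=config.top_n_terms)
    top.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return written


def synthetic_gene_sets(truth: GroundTruth, results, n_random: int = 5,
                        seed: int = 1) -> dict[str, set[str]]:
    """Gene sets for simulated runs: the planted set plus seeded random sets.

    The planted set collects the gene symbols of probes with a planted
    methylation effect (restricted to measured genes); the random sets are
    size-matched draws from the measured background, so the planted set
    should dominate the enrichment ranking when the pipeline detects the
    planted probes.
    """
    rng = np.random.default_rng(seed)
    measured = results["gene_symbol"]
    planted_probes = [p for p in truth.diff_meth_probes if p in results.index]
    planted = set(measured.loc[planted_probes])
    background = sorted(set(measured))
    size = max(len(planted), 2)
    sets = {"PLANTED_DIFF_METH": planted} if planted else {}
    for i in range(n_random):
        draw = rng.choice(background, size=min(size, len(background)), replace=False)
        sets[f"RANDOM_SET_{i + 1}"] = set(draw)
    return sets
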