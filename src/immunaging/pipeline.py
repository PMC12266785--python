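"""End-to-end orchestration: configuration, stage execution, manifest.

A :class:`PipelineConfig` gathers every stage parameter; ``run_pipeline``
executes the enabled stages in dependency order (simulate -> preprocess
-> linear model -> trajectories -> DE-SWAN -> cell scoring/DE ->
proportions -> repertoire), writes each stage's tables as TSV under the
output directory and records a manifest (parameters, fanned-out seeds,
per-file row counts and checksums).  A rerun with the same config is
bit-identical for the seeded stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agelm, deswan, preprocess, repertoire, singlecell, synthetic, trajectory

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("immunaging")

# fixed per-stage seed offsets fanned out from the single config seed
SEED_OFFSETS = {
    "cohort": 11,
    "cells": 23,
    "clones": 37,
    "score": 41,
}


@dataclass
class PipelineConfig:
    """All stage toggles and parameters of one pipeline run."""

    outdir: str = "immunaging_run"
    seed: int = 0
    stages: tuple = (
        "simulate", "preprocess", "agelm", "trajectory", "deswan",
        "scscore", "scde", "proportions", "repertoire",
    )
    # simulate
    n_samples: int = 120
    age_range: tuple = (1, 99)
    n_flat: int = 60
    n_linear: int = 60
    n_saturating: int = 40
    n_transient: int = 40
    noise_sd: float = 0.5
    batch_offset: float = 1.0
    n_cells: int = 400
    cell_types: tuple = ("CD14_Mono", "CD4_T", "CD8_CTL", "B_naive")
    cells_per_sample: int = 300
    # preprocess
    min_fraction: float = 0.75
    filter_before_correct: bool = True
    # trajectory
    span: float = 0.75
    loess_degree: int = 2
    k: int = 6
    k_range: tuple = (6, 12)
    # deswan
    centers: tuple = tuple(range(10, 91))
    half_width: float = 10.0
    q_cutoffs: tuple = (0.05, 0.01, 0.001)
    # thresholds
    q_cut: float = 0.05
    beta_cut: float = 0.005
    deswan_q_cut: float = 0.01
    deswan_beta_cut: float = 0.5
    lfc_cut: float = 0.25
    # scoring
    n_bins: int = 25
    ctrl_size: int = 50
    # age-group bin edges (name -> (lo, hi))
    age_group_bins: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in synthetic.AGE_GROUP_BINS.items()}
    )

    def __post_init__(self):
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        unknown = set(self.stages) - {
            "simulate", "preprocess", "agelm", "trajectory", "deswan",
            "scscore", "scde", "proportions", "repertoire",
        }
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    # --- serialization round trip ---------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        d["age_group_bins"] = {k: list(v) for k, v in d["age_group_bins"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        tuple_fields = {
            f.name for f in dataclasses.fields(cls)
            if f.type == "tuple" or isinstance(getattr(cls(), f.name, None), tuple)
        }
        for k in list(d):
            if k in tuple_fields and isinstance(d[k], list):
                d[k] = tuple(tuple(v) if isinstance(v, list) else v for v in d[k])
        if "age_group_bins" in d:
            d["age_group_bins"] = {k: tuple(v) for k, v in d["age_group_bins"].items()}
        return cls(**d)


def _default_archetypes(cfg: PipelineConfig, rng: np.random.Generator):
    arch = []
    for _ in range(cfg.n_flat):
        arch.append(synthetic.TrajectoryArchetype("flat", baseline=rng.uniform(1, 6)))
    for _ in range(cfg.n_linear):
        arch.append(
            synthetic.TrajectoryArchetype(
                "linear", baseline=rng.uniform(1, 6),
                slope=rng.choice([-1, 1]) * rng.uniform(0.005, 0.03),
            )
        )
    for _ in range(cfg.n_saturating):
        arch.append(
            synthetic.TrajectoryArchetype(
                "saturating", baseline=rng.uniform(1, 6),
                change_age=rng.uniform(5, 30), half_width=rng.uniform(3, 10),
                amplitude=rng.choice([-1, 1]) * rng.uniform(0.5, 2.0),
            )
        )
    for _ in range(cfg.n_transient):
        arch.append(
            synthetic.TrajectoryArchetype(
                "transient", baseline=rng.uniform(1, 6),
                change_age=rng.uniform(20, 80), half_width=rng.uniform(5, 12),
                amplitude=rng.choice([-1, 1]) * rng.uniform(0.5, 1.5),
            )
        )
    return arch


class _Manifest:
    def __init__(self, outdir: Path, cfg: PipelineConfig):
        self.outdir = outdir
        self.data = {
            "package": "immunaging",
            "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=list)),
            "seeds": {k: cfg.seed + off for k, off in SEED_OFFSETS.items()},
            "files": {},
        }

    def add(self, name: str, path: Path, n_rows: int):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["files"][name] = {
            "path": str(path.relative_to(self.outdir)),
            "rows": int(n_rows),
            "sha256": digest,
        }

    def write(self):
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.data, indent=2, sort_keys=True)
        )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages; returns the output directory.

    Raises if a stage's input stage is disabled (dependencies are named in
    the error).  Every file written is declared in ``manifest.json``.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    man = _Manifest(out, cfg)
    stages = set(cfg.stages)

    def need(stage, dep):
        if dep not in stages:
            raise ValueError(f"stage {stage!r} requires stage {dep!r}")

    def save(name, df: pd.DataFrame, **kw):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", **kw)
        man.add(name, path, len(df))
        return path

    cohort = cells = clones = None
    if "simulate" in stages:
        rng = np.random.default_rng(cfg.seed + SEED_OFFSETS["cohort"])
        arch = _default_archetypes(cfg, rng)
        truth = synthetic.CohortTruth(
            noise_sd=cfg.noise_sd,
            batch_offsets={"batch1": cfg.batch_offset},
            seed=cfg.seed + SEED_OFFSETS["cohort"],
        )
        cohort, truth = synthetic.generate_cohort(
            cfg.n_samples, cfg.age_range, arch, truth
        )
        save("expression", cohort.values, index_label="gene")
        save("samples", cohort.meta, index_label="sample")
        cells = synthetic.generate_single_cell(
            cfg.n_cells, list(cfg.cell_types), seed=cfg.seed + SEED_OFFSETS["cells"]
        )
        save("cell_meta", cells.obs, index_label="cell")
        clones = synthetic.generate_clonotypes(
            synthetic.ClonotypeTruth(
                subtypes=tuple(cfg.cell_types),
                cells_per_sample=cfg.cells_per_sample,
                sharing=np.full((len(cfg.cell_types),) * 2, 0.1)
                + np.eye(len(cfg.cell_types)) * 0.6,
                sample_ages=(10, 30, 50, 70, 85),
                seed=cfg.seed + SEED_OFFSETS["clones"],
            )
        )
        save("clonotypes", clones, index=False)
        log.info("simulate: %d genes x %d samples", len(cohort.genes), cohort.n_samples)

    if "preprocess" in stages:
        need("preprocess", "simulate")
        if cfg.filter_before_correct:
            cohort = preprocess.filter_genes(cohort, cfg.min_fraction)
            corrected = preprocess.combat_adjust(cohort)
        else:
            corrected = preprocess.combat_adjust(cohort)
            corrected = preprocess.filter_genes(corrected, cfg.min_fraction)
            cohort = preprocess.filter_genes(cohort, cfg.min_fraction)
        qc = preprocess.batch_qc(cohort, corrected)
        save("expression_corrected", corrected.values, index_label="gene")
        save("batch_qc", qc.summary(), index_label="batch")
        cohort = corrected

    if "agelm" in stages:
        need("agelm", "preprocess")
        table = agelm.fit_gene_age_model(cohort)
        labels = agelm.classify_degs(table, cfg.q_cut, cfg.beta_cut)
        save(
            "age_model",
            table.join(labels, lsuffix="_sign", rsuffix=""),
            index_label="gene",
        )

    if "trajectory" in stages:
        need("trajectory", "preprocess")
        atlas = trajectory.build_trajectory_atlas(cohort, span=cfg.span, degree=cfg.loess_degree)
        atlas = trajectory.cluster_trajectories(atlas, cfg.k, cfg.k_range)
        save("trajectories", atlas.curves, index_label="gene")
        save("trajectory_clusters", atlas.labels.to_frame(), index_label="gene")
        save("cluster_means", atlas.cluster_means, index_label="cluster")

    if "deswan" in stages:
        need("deswan", "preprocess")
        profile = deswan.deswan_scan(
            cohort, centers=cfg.centers, half_width=cfg.half_width, q_cutoffs=cfg.q_cutoffs
        )
        counts_long = (
            profile.counts.reset_index()
            .melt(id_vars="center", var_name="cutoff", value_name="count")
        )
        save("deswan_counts", counts_long, index=False)
        save("deswan_stats", profile.stats, index=False)
        save("deswan_crests", pd.DataFrame({"crest_age": profile.crests}), index=False)
        tops = deswan.top_degs(profile, cfg.deswan_q_cut, cfg.deswan_beta_cut)
        save("deswan_top_degs", tops, index=False)

    if "scscore" in stages:
        need("scscore", "simulate")
        present = [g for g in singlecell.SASP_GENES if g in cells.var_names]
        gene_set = present if present else list(cells.var_names[:20])
        score = singlecell.score_gene_set(
            cells, gene_set, n_bins=min(cfg.n_bins, cells.n_vars // 4),
            ctrl_size=cfg.ctrl_size, seed=cfg.seed + SEED_OFFSETS["score"],
        )
        save("gene_set_scores", score.scores.rename("score").to_frame(), index_label="cell")

    if "scde" in stages:
        need("scde", "simulate")
        types = cells.obs["cell_type"]
        t0, t1 = list(cfg.cell_types)[:2]
        de = singlecell.rank_sum_de(
            cells, (types == t0).to_numpy(), (types == t1).to_numpy(), lfc_cut=cfg.lfc_cut
        )
        save("sc_de", de, index_label="gene")

    if "proportions" in stages:
        need("proportions", "simulate")
        corr, fracs = singlecell.proportion_age_correlation(cells)
        corr = corr.copy()
        corr["poly_coeffs"] = corr["poly_coeffs"].map(
            lambda t: ";".join(f"{c:.6g}" for c in t)
        )
        save("proportion_age_corr", corr, index_label="cell_type")
        save("proportions", fracs, index_label="sample")

    if "repertoire" in stages:
        need("repertoire", "simulate")
        idx = repertoire.repertoire_by_group(clones)
        save("repertoire_indices", idx, index=False)
        trend = repertoire.fit_age_trend(idx, "gini")
        if len(trend):
            trend = trend.copy()
            trend["poly_coeffs"] = trend["poly_coeffs"].map(
                lambda t: ";".join(f"{c:.6g}" for c in t)
            )
        save("repertoire_age_trend", trend, index=False)

    cfg.to_yaml(out / "config.yaml")
    man.add("config", out / "config.yaml", 1)
    man.write()
    return out
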