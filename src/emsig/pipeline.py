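"""End-to-end pipeline orchestration and run provenance.

Stages run in order — ingest (or simulate) -> reverse scoring -> factor
extraction -> embedding -> SIG surface -> ROI extraction -> profiling ->
regression — writing every stage's outputs under one run directory
together with a manifest (files produced, seeds, versions, warnings). All
randomness flows from the config seeds, so two runs with equal configs
produce identical numerical outputs.

A scale with no admissible cluster count is excluded with a manifest
warning and the pipeline continues; a stage failure is recorded in the
manifest and earlier outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embedding import build_grid, embed_pca, embed_umap
from .factors import compute_factor_scores, pcc_matrix, select_k
from .profiling import correlation_screen, disparity_table, profile_roi
from .regression import build_model_suite, fit_suite, rank_predictors
from .schema import SurveySchema, load_survey, reverse_score, summarize_cohort
from .sig import compute_sig_surface, extract_rois
from .simulate import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

#: Per-scale floors on the within-cluster mean PCC used when none are
#: configured, following the published per-scale thresholds.
DEFAULT_PCC_FLOORS = {"CoVaH": 0.7, "T-DiG": 0.6, "TRUST-Ph": 0.5, "TiPHA": 0.6}


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published analysis."""

    outdir: str = "emsig_run"
    input_path: str | None = None
    schema_path: str | None = None
    synthetic: SyntheticConfig | None = None

    # factor extraction
    sc_min: float = 0.25
    pcc_floor: float | dict = field(default_factory=lambda: dict(DEFAULT_PCC_FLOORS))
    k_min: int = 2
    k_max: int = 8
    use_min_pcc: bool = False
    aggregator: str = "mean"
    factor_labels: dict = field(default_factory=dict)

    # embedding
    embed_method: str = "umap"
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    embed_seed: int = 42
    standardize: bool = True

    # SIG / ROI
    grid_step: float = 0.5
    sigma: float = 1.0
    occupancy_floor: int = 5
    sig_prior: str = "cell"
    cutoff_fraction: float = 0.34
    contour_fractions: tuple = (0.0, 0.17, 0.34, 0.51)
    min_roi_members: int = 10

    # profiling
    screen_cutoff: float = 0.2
    alpha: float = 0.05
    adjust: str = "none"

    #: stop after this stage ("ingest", "factors", "embed", "sig", "profile")
    stop_after: str | None = None

    # regression
    run_regression: bool = True
    split_seed: int = 0
    test_size: float = 0.3
    cv_folds: int = 10
    ranking_seeds: tuple = tuple(range(10))
    rank_model: str = "Random Forest Regressor"

    def floor_for(self, scale_id: str) -> float:
        if isinstance(self.pcc_floor, dict):
            return float(self.pcc_floor.get(scale_id, 0.5))
        return float(self.pcc_floor)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)


@dataclass
class RunManifest:
    """What a run produced: outputs, seeds, versions, warnings, failures."""

    outdir: str
    outputs: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    failure: str | None = None

    def record(self, path: Path) -> None:
        self.outputs.append(str(path.relative_to(self.outdir)))

    def save(self) -> Path:
        path = Path(self.outdir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _write_csv(frame: pd.DataFrame, path: Path, manifest: RunManifest, **kw) -> None:
    frame.to_csv(path, **kw)
    manifest.record(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and return the manifest (also saved to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__ as pkg_version

    manifest = RunManifest(outdir=str(outdir))
    manifest.versions = {"emsig": pkg_version, "numpy": np.__version__}
    manifest.seeds = {
        "embed_seed": config.embed_seed,
        "split_seed": config.split_seed,
        "synthetic_seed": config.synthetic.seed if config.synthetic else None,
    }
    manifest.timestamps["started"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    config.save(outdir / "config_used.yaml")
    manifest.record(outdir / "config_used.yaml")

    try:
        _run_stages(config, outdir, manifest)
    except Exception as exc:  # stage failure: preserve prior outputs
        manifest.failure = f"{type(exc).__name__}: {exc}"
    manifest.timestamps["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save()
    return manifest


def _run_stages(config: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    # ---- ingest ----------------------------------------------------------
    if config.synthetic is not None:
        dataset, truth = generate_dataset(config.synthetic)
        truth_path = outdir / "ground_truth.json"
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "item_partition": truth.item_partition,
                    "factor_ids": truth.factor_ids,
                    "subgroup_sizes": truth.subgroup_labels.value_counts().to_dict(),
                    "driving_factors": truth.driving_factors,
                },
                fh,
                indent=2,
                default=str,
            )
        manifest.record(truth_path)
    elif config.input_path and config.schema_path:
        schema = SurveySchema.from_yaml(config.schema_path)
        dataset, rejected = load_survey(
            config.input_path, schema, on_invalid="drop"
        )
        if len(rejected):
            manifest.warnings.append(f"{len(rejected)} rows rejected at ingestion")
            _write_csv(rejected, outdir / "rejected_rows.csv", manifest, index=False)
    else:
        raise ValueError("config needs either synthetic or input_path + schema_path")

    summary = summarize_cohort(dataset)
    (outdir / "cohort_summary.json").write_text(summary.to_json())
    manifest.record(outdir / "cohort_summary.json")
    (outdir / "cohort_table.txt").write_text(summary.to_text())
    manifest.record(outdir / "cohort_table.txt")
    manifest.stages.append("ingest")
    if config.stop_after == "ingest":
        return

    # ---- factors ---------------------------------------------------------
    dataset = reverse_score(dataset)
    solutions = {}
    for scale in dataset.scales:
        corr = pcc_matrix(dataset, scale.scale_id)
        sol = select_k(
            corr,
            k_range=range(config.k_min, config.k_max + 1),
            sc_min=config.sc_min,
            pcc_floor=config.floor_for(scale.scale_id),
            use_min_pcc=config.use_min_pcc,
            scale_id=scale.scale_id,
            prefix=scale.prefix,
            labels=config.factor_labels.get(scale.scale_id, {}),
        )
        _write_csv(
            pd.DataFrame(corr.values, index=corr.item_ids, columns=corr.item_ids),
            outdir / f"pcc_{scale.scale_id}.csv",
            manifest,
        )
        _write_csv(
            sol.quality_table(), outdir / f"quality_{scale.scale_id}.csv", manifest,
            index=False,
        )
        if sol.chosen_k is None:
            manifest.warnings.append(
                f"no admissible cluster count for scale {scale.scale_id}; "
                "its items are excluded downstream"
            )
        solutions[scale.scale_id] = sol
    partitions = {
        sid: (sol.partition.assignment if sol.partition else None)
        for sid, sol in solutions.items()
    }
    with open(outdir / "partitions.json", "w") as fh:
        json.dump(partitions, fh, indent=2)
    manifest.record(outdir / "partitions.json")
    if all(sol.partition is None for sol in solutions.values()):
        raise ValueError("no scale produced an admissible factor solution")
    scores = compute_factor_scores(dataset, solutions, aggregator=config.aggregator)
    _write_csv(scores, outdir / "factor_scores.csv", manifest)
    manifest.stages.append("factors")
    if config.stop_after == "factors":
        return

    # ---- embedding -------------------------------------------------------
    if config.embed_method == "umap":
        emb = embed_umap(
            scores,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            metric=config.metric,
            seed=config.embed_seed,
            standardize=config.standardize,
        )
    elif config.embed_method == "pca":
        emb = embed_pca(
            scores, seed=config.embed_seed, standardize=config.standardize
        )
    else:
        raise ValueError(f"unknown embed_method {config.embed_method!r}")
    _write_csv(emb.frame(), outdir / "coordinates.csv", manifest)
    grid = build_grid(emb, step=config.grid_step)
    with open(outdir / "grid.json", "w") as fh:
        json.dump(grid.to_dict(), fh, indent=2)
    manifest.record(outdir / "grid.json")
    manifest.stages.append("embed")
    if config.stop_after == "embed":
        return

    # ---- SIG + ROIs ------------------------------------------------------
    surface, cells = compute_sig_surface(
        scores,
        dataset.dose,
        emb,
        grid,
        sigma=config.sigma,
        floor=config.occupancy_floor,
        cutoff_fraction=config.cutoff_fraction,
    )
    sig_dir = outdir / "sig_factors"
    sig_dir.mkdir(exist_ok=True)
    for f, mat in surface.raw.items():
        _write_csv(pd.DataFrame(mat), sig_dir / f"sig_{f}.csv", manifest)
    _write_csv(pd.DataFrame(surface.aggregated), outdir / "sig_aggregated.csv", manifest)
    _write_csv(pd.DataFrame(surface.smoothed), outdir / "sig_smoothed.csv", manifest)
    rois = extract_rois(
        surface.smoothed,
        grid,
        cells,
        dataset.dose,
        cutoff_fraction=config.cutoff_fraction,
        min_members=config.min_roi_members,
    )
    roi_rows = []
    membership_rows = []
    for roi in rois:
        x0, x1, y0, y1 = roi.bounding_box()
        roi_rows.append(
            {
                "roi_id": roi.roi_id,
                "n": roi.n,
                "dose_mean": roi.dose_mean,
                "dose_sd": roi.dose_sd,
                "peak_signal": roi.peak_signal,
                "ix_min": x0,
                "ix_max": x1,
                "iy_min": y0,
                "iy_max": y1,
            }
        )
        membership_rows.extend(
            {"respondent_id": rid, "roi_id": roi.roi_id} for rid in roi.member_ids
        )
    _write_csv(pd.DataFrame(roi_rows), outdir / "roi_table.csv", manifest, index=False)
    _write_csv(
        pd.DataFrame(membership_rows, columns=["respondent_id", "roi_id"]),
        outdir / "roi_membership.csv",
        manifest,
        index=False,
    )
    contours = {str(f): lv for f, lv in surface.contour_levels().items()}
    with open(outdir / "contour_levels.json", "w") as fh:
        json.dump(contours, fh, indent=2)
    manifest.record(outdir / "contour_levels.json")
    manifest.stages.append("sig")
    if config.stop_after == "sig":
        return

    # ---- profiling -------------------------------------------------------
    screen_rows, disparity_rows, profiles = [], [], []
    for roi in rois:
        screen = correlation_screen(roi, scores, dataset.dose, cutoff=config.screen_cutoff)
        screen_rows.extend(dataclasses.asdict(r) for r in screen)
        disp = []
        if len(dataset.demographics.columns):
            disp = disparity_table(
                roi, dataset.demographics, alpha=config.alpha, adjust=config.adjust
            )
            disparity_rows.extend(
                {
                    "roi_id": r.roi_id,
                    "variable": r.variable,
                    "chi2": r.chi2,
                    "df": r.df,
                    "p_value": r.p_value,
                    "stars": r.stars,
                    "significant": r.significant,
                    "testable": r.testable,
                }
                for r in disp
            )
        profiles.append(profile_roi(roi, screen, disp, dataset.demographics))
    _write_csv(
        pd.DataFrame(
            screen_rows,
            columns=["roi_id", "factor_id", "pcc", "flagged", "computable"],
        ),
        outdir / "screen.csv",
        manifest,
        index=False,
    )
    _write_csv(
        pd.DataFrame(
            disparity_rows,
            columns=[
                "roi_id", "variable", "chi2", "df", "p_value", "stars",
                "significant", "testable",
            ],
        ),
        outdir / "disparity.csv",
        manifest,
        index=False,
    )
    with open(outdir / "profiles.json", "w") as fh:
        json.dump(profiles, fh, indent=2)
    manifest.record(outdir / "profiles.json")
    manifest.stages.append("profile")
    if config.stop_after == "profile":
        return

    # ---- regression ------------------------------------------------------
    if config.run_regression:
        report = fit_suite(
            scores,
            dataset.dose,
            split_seed=config.split_seed,
            test_size=config.test_size,
            cv_folds=config.cv_folds,
        )
        _write_csv(report, outdir / "regression_report.csv", manifest, index=False)
        model = build_model_suite(config.split_seed)[config.rank_model]
        imp, shap = rank_predictors(
            model, scores, dataset.dose, seeds=list(config.ranking_seeds)
        )
        with open(outdir / "ranking.json", "w") as fh:
            json.dump(
                {
                    "feature_importance": {
                        "ranking": imp.ranking,
                        "top5_stability": imp.top5_stability,
                    },
                    "shapley": {
                        "ranking": shap.ranking,
                        "top5_stability": shap.top5_stability,
                    },
                    "seeds": list(config.ranking_seeds),
                    "model": config.rank_model,
                },
                fh,
                indent=2,
            )
        manifest.record(outdir / "ranking.json")
        manifest.stages.append("regress")
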