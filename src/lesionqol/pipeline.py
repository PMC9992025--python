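"""Pipeline orchestration: simulate -> score -> map -> connect -> associate -> report.

Stages communicate through plain files in a run directory (NIfTI volumes,
TSV tables, YAML config), so each stage can also be run on its own against
externally produced inputs.  A manifest records the package version, the
config echo and a checksum of every file each stage wrote; re-running a
deterministic stage with identical inputs reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasParcellation
from .connectivity import (
    NodeTimeSeries,
    bandpass_filter,
    connectivity_matrix,
    within_network_connectivity,
)
from .mapping import LESION_TYPES, LesionSet, classify_laterality, overlap_table
from .qlq import score_cohort
from .stats import (
    STAT_RESULT_FIELDS,
    laterality_comparison,
    lesion_hrqol_screen,
    rsfc_hrqol_screen,
    volume_hrqol_correlations,
)
from .synthetic import PlantedEffect, SimulationConfig, generate_cohort

log = logging.getLogger("lesionqol")

ALL_STAGES = ("simulate", "score", "map", "connectivity", "associate", "report")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (usually parsed from YAML)."""

    out_dir: Path
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    planted_effects: list[dict] = field(default_factory=list)
    alpha_lesion: float = 0.001
    alpha_rsfc: float = 0.01
    overlap_measure: str = "overlap_ml"
    bilateral_networks: bool = False
    band_hz: tuple[float, float] = (0.008, 0.09)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
        if self.overlap_measure not in ("overlap_ml", "overlap_fraction"):
            raise ValueError(f"unknown overlap measure {self.overlap_measure!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        for key in ("grid_shape", "voxel_size_mm"):
            if key in sim:
                sim[key] = tuple(sim[key])
        effects = [PlantedEffect(**e) for e in self.planted_effects]
        return SimulationConfig(seed=self.seed, planted_effects=effects, **sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


class Manifest:
    """Per-stage record of outputs, checksums and warnings."""

    def __init__(self, config_echo: dict):
        self.data = {
            "package": "lesionqol",
            "version": __version__,
            "config": config_echo,
            "stages": {},
            "warnings": [],
        }

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in sorted(outputs)},
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def fail(self, stage: str, error: str) -> None:
        self.data["stages"][stage] = {"failed": error}

    def warn(self, message: str) -> None:
        self.data["warnings"].append(message)

    def checksums(self) -> dict:
        return {
            s: rec.get("outputs", {}) for s, rec in self.data["stages"].items()
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------------- stages

def stage_simulate(cfg: RunConfig) -> list[Path]:
    out = cfg.out_dir
    sim = cfg.simulation_config()
    with_ts = "connectivity" in cfg.stages
    cohort = generate_cohort(sim, with_timeseries=with_ts)
    written: list[Path] = []

    atlas_dir = out / "atlas"
    atlas_dir.mkdir(parents=True, exist_ok=True)
    cohort.nodes.save(atlas_dir / "nodes.nii.gz", atlas_dir / "nodes_regions.tsv")
    cohort.tracts.save(atlas_dir / "tracts.nii.gz", atlas_dir / "tracts_regions.tsv")
    written += [atlas_dir / "nodes.nii.gz", atlas_dir / "nodes_regions.tsv",
                atlas_dir / "tracts.nii.gz", atlas_dir / "tracts_regions.tsv"]

    lesion_dir = out / "lesions"
    for ls in cohort.lesions:
        ls.save(lesion_dir, cohort.nodes.affine)
        written += [lesion_dir / f"{ls.subject}_{t}.nii.gz" for t in ls.masks]

    written.append(_write_tsv(cohort.responses, out / "responses.tsv"))
    written.append(_write_tsv(cohort.latent_scores, out / "ground_truth_latent.tsv"))
    written.append(_write_tsv(cohort.ground_truth.sides.to_frame(), out / "ground_truth_sides.tsv"))
    written.append(_write_tsv(cohort.ground_truth.predictors, out / "ground_truth_predictors.tsv"))

    if cohort.timeseries is not None:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(parents=True, exist_ok=True)
        for ts in cohort.timeseries:
            p = ts_dir / f"{ts.subject}_ts.tsv"
            ts.save(p)
            written += [p, Path(str(p) + ".json")]
    return written


def stage_score(cfg: RunConfig) -> list[Path]:
    responses = pd.read_csv(cfg.out_dir / "responses.tsv", sep="\t", index_col=0)
    scores, n_used = score_cohort(responses)
    n_missing = int(scores.isna().sum().sum())
    if n_missing:
        log.warning("%d scale scores missing after the half-rule", n_missing)
    return [
        _write_tsv(scores, cfg.out_dir / "scores.tsv"),
        _write_tsv(n_used, cfg.out_dir / "scores_n_items.tsv"),
    ]


def _load_atlases(cfg: RunConfig) -> tuple[AtlasParcellation, AtlasParcellation]:
    atlas_dir = cfg.out_dir / "atlas"
    nodes = AtlasParcellation.load(atlas_dir / "nodes.nii.gz", atlas_dir / "nodes_regions.tsv")
    tracts = AtlasParcellation.load(atlas_dir / "tracts.nii.gz", atlas_dir / "tracts_regions.tsv")
    return nodes, tracts


def stage_map(cfg: RunConfig, manifest: Manifest | None = None) -> list[Path]:
    nodes, tracts = _load_atlases(cfg)
    lesion_dir = cfg.out_dir / "lesions"
    subjects = sorted({p.name.rsplit("_", 1)[0] for p in lesion_dir.glob("*_*.nii.gz")})
    if not subjects:
        raise FileNotFoundError(f"no lesion masks found under {lesion_dir}")
    lesions, sides = [], {}
    for s in subjects:
        ls, _ = LesionSet.load(lesion_dir, s)
        lesions.append(ls)
        try:
            sides[s] = classify_laterality(ls, nodes.affine)
        except ValueError as exc:
            sides[s] = "unclassified"
            if manifest is not None:
                manifest.warn(str(exc))
    overlaps, totals = overlap_table(lesions, nodes, tracts)
    side_df = pd.Series(sides, name="side").rename_axis("subject").to_frame()
    return [
        _write_tsv(overlaps, cfg.out_dir / "overlaps.tsv", index=False),
        _write_tsv(totals, cfg.out_dir / "lesion_totals.tsv", index=False),
        _write_tsv(side_df, cfg.out_dir / "laterality.tsv"),
    ]


def stage_connectivity(cfg: RunConfig, manifest: Manifest | None = None) -> list[Path]:
    nodes, _ = _load_atlases(cfg)
    ts_dir = cfg.out_dir / "timeseries"
    paths = sorted(ts_dir.glob("*_ts.tsv"))
    if not paths:
        raise FileNotFoundError(f"no time series found under {ts_dir}")
    sim = cfg.simulation_config()
    cm_dir = cfg.out_dir / "connectivity"
    cm_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    wnc_rows = {}
    for p in paths:
        subject = p.name.removesuffix("_ts.tsv")
        ts = NodeTimeSeries.load(p, subject, sim.tr_seconds)
        ts = bandpass_filter(ts, *cfg.band_hz)
        cm = connectivity_matrix(ts)
        if cm.excluded_nodes and manifest is not None:
            manifest.warn(f"{subject}: excluded constant nodes {cm.excluded_nodes}")
        written.append(_write_tsv(cm.to_frame(), cm_dir / f"{subject}_z.tsv"))
        wnc_rows[subject] = within_network_connectivity(
            cm, nodes.regions, bilateral=cfg.bilateral_networks
        )
    wnc = pd.DataFrame.from_dict(wnc_rows, orient="index").rename_axis("subject")
    wnc.columns = [f"node_{c}" for c in wnc.columns]
    written.append(_write_tsv(wnc, cfg.out_dir / "within_network_connectivity.tsv"))
    return written


def stage_associate(cfg: RunConfig) -> list[Path]:
    out = cfg.out_dir
    scores = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0)
    written: list[Path] = []
    assoc = out / "assoc"
    assoc.mkdir(parents=True, exist_ok=True)

    overlaps_path = out / "overlaps.tsv"
    if overlaps_path.exists():
        overlaps = pd.read_csv(overlaps_path, sep="\t")
        screen = lesion_hrqol_screen(overlaps, scores, alpha=cfg.alpha_lesion,
                                     measure=cfg.overlap_measure)
        written.append(_write_tsv(screen.p_values, assoc / "lesion_screen_p.tsv"))
        written.append(_write_tsv(screen.estimates, assoc / "lesion_screen_tau.tsv"))
        sig = pd.DataFrame([vars(h) for h in screen.significant],
                           columns=list(STAT_RESULT_FIELDS))
        written.append(_write_tsv(sig, assoc / "lesion_screen_significant.tsv", index=False))

        totals = pd.read_csv(out / "lesion_totals.tsv", sep="\t")
        vol = pd.DataFrame([vars(r) for r in volume_hrqol_correlations(totals, scores)],
                           columns=list(STAT_RESULT_FIELDS))
        written.append(_write_tsv(vol, assoc / "volume_correlations.tsv", index=False))

        side = pd.read_csv(out / "laterality.tsv", sep="\t", index_col=0)["side"]
        side = side[side.isin(["left", "right"])]
        lat = laterality_comparison(scores, side)
        written.append(_write_tsv(lat, assoc / "laterality_comparison.tsv"))

    wnc_path = out / "within_network_connectivity.tsv"
    if wnc_path.exists():
        wnc = pd.read_csv(wnc_path, sep="\t", index_col=0)
        screen = rsfc_hrqol_screen(wnc, scores, alpha=cfg.alpha_rsfc)
        written.append(_write_tsv(screen.p_values, assoc / "rsfc_screen_p.tsv"))
        written.append(_write_tsv(screen.estimates, assoc / "rsfc_screen_r.tsv"))
        sig = pd.DataFrame([vars(h) for h in screen.significant],
                           columns=list(STAT_RESULT_FIELDS))
        written.append(_write_tsv(sig, assoc / "rsfc_screen_significant.tsv", index=False))
    if not written:
        raise FileNotFoundError("associate stage found neither overlaps nor connectivity")
    return written


def stage_report(cfg: RunConfig) -> list[Path]:
    from .report import render_group_comparison, render_scatter, render_screen_heatmap

    out = cfg.out_dir
    assoc = out / "assoc"
    fig_dir = out / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    lat_path = assoc / "laterality_comparison.tsv"
    if lat_path.exists():
        lat = pd.read_csv(lat_path, sep="\t", index_col=0)
        written.append(render_group_comparison(lat, fig_dir / "laterality_scores.png"))

    for name, alpha in (("lesion_screen", cfg.alpha_lesion), ("rsfc_screen", cfg.alpha_rsfc)):
        p_path = assoc / f"{name}_p.tsv"
        if not p_path.exists():
            continue
        est_name = "tau" if name == "lesion_screen" else "r"
        p = pd.read_csv(p_path, sep="\t", index_col=0)
        est = pd.read_csv(assoc / f"{name}_{est_name}.tsv", sep="\t", index_col=0)
        written.append(
            render_screen_heatmap(p, est, alpha, fig_dir / f"{name}_heatmap.png",
                                  title=name.replace("_", " "))
        )

    sig_path = assoc / "rsfc_screen_significant.tsv"
    wnc_path = out / "within_network_connectivity.tsv"
    if sig_path.exists() and wnc_path.exists():
        sig = pd.read_csv(sig_path, sep="\t")
        if len(sig):
            best = sig.sort_values("p_value").iloc[0]
            wnc = pd.read_csv(wnc_path, sep="\t", index_col=0)
            scores = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0)
            common = wnc.index.intersection(scores.index)
            written.append(
                render_scatter(
                    wnc.loc[common, best["predictor"]],
                    scores.loc[common, best["outcome"]],
                    float(best["estimate"]), float(best["p_value"]),
                    fig_dir / "rsfc_example_scatter.png",
                    ylabel=str(best["outcome"]),
                )
            )
    if not written:
        raise FileNotFoundError("report stage found no association outputs")
    return written


_STAGE_FUNCS = {
    "simulate": lambda cfg, m: stage_simulate(cfg),
    "score": lambda cfg, m: stage_score(cfg),
    "map": lambda cfg, m: stage_map(cfg, m),
    "connectivity": lambda cfg, m: stage_connectivity(cfg, m),
    "associate": lambda cfg, m: stage_associate(cfg),
    "report": lambda cfg, m: stage_report(cfg),
}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_run(cfg: RunConfig) -> None:
    """Fail before any computation if enabled stages lack their inputs."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    need = {
        "score": [cfg.out_dir / "responses.tsv"],
        "map": [cfg.out_dir / "atlas", cfg.out_dir / "lesions"],
        "connectivity": [cfg.out_dir / "atlas", cfg.out_dir / "timeseries"],
    }
    producers_enabled = "simulate" in cfg.stages
    if producers_enabled:
        return
    for stage, paths in need.items():
        if stage in cfg.stages:
            for p in paths:
                if not p.exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} requires {p}, which does not exist "
                        "(enable the simulate stage or provide inputs)"
                    )


def run_pipeline(cfg: RunConfig) -> Manifest:
    """Execute the enabled stages in dependency order and write the manifest.

    A stage failure leaves completed outputs intact, records the failure in
    the manifest and re-raises as :class:`StageFailure`.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    validate_run(cfg)
    def _plain(v):
        if isinstance(v, Path):
            return str(v)
        if isinstance(v, tuple):
            return list(v)
        return v

    echo = {k: _plain(v) for k, v in vars(cfg).items()}
    (cfg.out_dir / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    manifest = Manifest(echo)
    try:
        for stage in ALL_STAGES:
            if stage not in cfg.stages:
                continue
            log.info("running stage %s", stage)
            try:
                outputs = _STAGE_FUNCS[stage](cfg, manifest)
            except Exception as exc:
                manifest.fail(stage, f"{type(exc).__name__}: {exc}")
                raise StageFailure(stage, exc) from exc
            manifest.record(stage, outputs)
    finally:
        manifest.save(cfg.out_dir / "manifest.json")
    return manifest
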