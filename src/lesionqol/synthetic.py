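"""Synthetic glioma cohorts with known ground truth.

Every downstream stage of the pipeline (scoring, overlap mapping,
connectivity, screening) is exercised on cohorts generated here, because no
patient-level dataset is publicly deposited for this kind of study.  The
generator emulates the features the analysis depends on:

* nested lesion geometry — per subject, four binary masks where the
  resection cavity and the contrast-enhancing lesion lie inside the
  T2/FLAIR hyperintensity and the PET-positive volume intersects it;
* left/right tumour lateralization with a configurable right-sided fraction;
* node time series with block-structured network covariance, where the
  network coupling of a node is attenuated linearly in its FLAIR-overlap
  fraction (a factor-model construction, so the covariance is positive
  semi-definite by design);
* item-level questionnaire responses whose latent scale scores decline with
  the overlap of designated regions (planted effects), inverted through the
  scoring transform into legal integer item responses.

Default lesion radii are chosen so that simulated lesion volumes land in
the ranges typical of pretreated high-grade glioma cohorts (FLAIR median
around 50 mL, cavities around 10 mL, enhancing lesions around 5 mL,
PET-positive volumes around 15 mL and absent in roughly half the cohort).

Randomness: one global seed feeds an explicit per-subject, per-stage seed
sequence, so enlarging a cohort never changes the subjects already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasParcellation, build_toy_atlas
from .mapping import LESION_TYPES, LesionSet, overlap_table
from .qlq import QlqScale, load_scale_map

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "GroundTruth",
    "Cohort",
    "build_toy_atlas",
    "simulate_lesions",
    "simulate_sides",
    "simulate_timeseries",
    "simulate_qlq_responses",
    "generate_cohort",
    "suggest_target_region",
]

_STAGE_LESIONS = 0
_STAGE_TIMESERIES = 1
_STAGE_RESPONSES = 2


def _rng(seed: int, subject_index: int, stage: int) -> np.random.Generator:
    """Per-subject, per-stage generator derived from the global seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(subject_index, stage))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class PlantedEffect:
    """A known association planted into the questionnaire responses.

    ``region`` names an atlas region (by region-table name); the predictor
    is that region's overlap fraction with ``lesion_type`` lesions.  The
    special forms ``side:right`` / ``side:left`` make the predictor a 0/1
    tumour-side indicator instead (``lesion_type`` is then ignored).
    ``slope`` is in score points per unit predictor; ``noise_sd`` in score
    points.
    """

    target_scale: str
    region: str
    lesion_type: str = "flair"
    slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.region.startswith("side:") and self.lesion_type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.lesion_type!r}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    The imaging defaults mirror a 3 mm isotropic grid with 100 cortical
    nodes in 7 resting-state networks (50 per hemisphere), 24 white-matter
    tracts per hemisphere plus 5 midline structures, and 300 fMRI volumes at
    TR = 2.2 s.
    """

    n_subjects: int = 121
    grid_shape: tuple[int, int, int] = (50, 60, 50)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_nodes_per_hemisphere: int = 50
    n_networks: int = 7
    n_tracts_per_hemisphere: int = 24
    n_midline_tracts: int = 5
    rho_within: float = 0.6
    rho_between: float = 0.1
    n_timepoints: int = 300
    tr_seconds: float = 2.2
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    fraction_right_sided: float = 56.0 / 121.0
    seed: int = 0

    # lesion geometry: mean ellipsoid radius per type (mm), relative per-axis
    # jitter, and the probability that a lesion type is absent in a subject
    lesion_radii_mm: dict = field(
        default_factory=lambda: {"flair": 23.0, "cavity": 13.0, "t1ce": 11.0, "fet": 15.0}
    )
    lesion_absent_prob: dict = field(
        default_factory=lambda: {"flair": 0.0, "cavity": 0.15, "t1ce": 0.25, "fet": 0.48}
    )
    radius_jitter: float = 0.3

    # connectivity attenuation: network coupling multiplier is
    # max(floor, 1 - strength * flair_overlap_fraction)
    attenuation_strength: float = 1.0
    attenuation_floor: float = 0.0

    # questionnaire generation: latent baseline per scale direction and the
    # latent noise for scales without a planted effect (score points)
    baseline_scores: dict = field(
        default_factory=lambda: {"functional": 85.0, "symptom": 15.0, "global": 70.0}
    )
    baseline_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be three dimensions of at least 4 voxels")
        if self.n_networks > self.n_nodes_per_hemisphere:
            raise ValueError("cannot have more networks than nodes per hemisphere")
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError(
                "need 0 <= rho_between <= rho_within < 1 for a positive "
                "semi-definite block covariance"
            )
        if not 0 <= self.fraction_right_sided <= 1:
            raise ValueError("fraction_right_sided must be in [0, 1]")
        if not 0 <= self.attenuation_floor <= 1:
            raise ValueError("attenuation_floor must be in [0, 1]")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery checks."""

    sides: pd.Series  # subject -> left | right
    predictors: pd.DataFrame  # subject x planted-effect predictor values
    effects: list[PlantedEffect]
    node_attenuation: pd.DataFrame | None = None  # subject x node coupling multiplier


@dataclass
class Cohort:
    """Bundle of everything a full synthetic run produces."""

    config: SimulationConfig
    nodes: AtlasParcellation
    tracts: AtlasParcellation
    lesions: list[LesionSet]
    overlaps: pd.DataFrame
    totals: pd.DataFrame
    responses: pd.DataFrame
    latent_scores: pd.DataFrame
    ground_truth: GroundTruth
    timeseries: list | None = None


def _subject_id(i: int) -> str:
    return f"sub-{i + 1:03d}"


def _world_axes(config: SimulationConfig):
    from .atlas import centered_affine

    aff = centered_affine(config.grid_shape, config.voxel_size_mm)
    axes = []
    for k in range(3):
        idx = np.arange(config.grid_shape[k])
        axes.append(aff[k, k] * idx + aff[k, 3])
    return aff, axes


def _ellipsoid(axes, center, radii) -> np.ndarray:
    if np.any(np.asarray(radii) <= 0):
        return np.zeros([len(a) for a in axes], dtype=np.uint8)
    dx = ((axes[0] - center[0]) / radii[0]) ** 2
    dy = ((axes[1] - center[1]) / radii[1]) ** 2
    dz = ((axes[2] - center[2]) / radii[2]) ** 2
    return (
        (dx[:, None, None] + dy[None, :, None] + dz[None, None, :]) <= 1.0
    ).astype(np.uint8)


def simulate_sides(config: SimulationConfig) -> pd.Series:
    """Tumour side per subject, without building any masks.

    Uses the same per-subject stream (and the same first draw) as
    :func:`simulate_lesions`, so a questionnaire-only cohort with
    side-based planted effects matches the sides a full imaging cohort
    would get under the same seed.
    """
    sides = {}
    for i in range(config.n_subjects):
        rng = _rng(config.seed, i, _STAGE_LESIONS)
        sides[_subject_id(i)] = (
            "right" if rng.uniform() < config.fraction_right_sided else "left"
        )
    return pd.Series(sides, name="side")


def simulate_lesions(
    config: SimulationConfig, atlas: AtlasParcellation
) -> tuple[list[LesionSet], pd.Series]:
    """Draw nested ellipsoid lesions per subject and record the tumour side.

    FLAIR is the outer envelope; cavity and contrast-enhancing lesions are
    concentric and intersected with it (nesting), the PET-positive lesion is
    centred inside it (guaranteed intersection) but may protrude.
    """
    aff, axes = _world_axes(config)
    half_width = config.voxel_size_mm[0] * config.grid_shape[0] / 2.0
    ey = config.voxel_size_mm[1] * config.grid_shape[1]
    ez = config.voxel_size_mm[2] * config.grid_shape[2]

    lesions, sides = [], {}
    for i in range(config.n_subjects):
        rng = _rng(config.seed, i, _STAGE_LESIONS)
        subject = _subject_id(i)
        side = "right" if rng.uniform() < config.fraction_right_sided else "left"
        sides[subject] = side
        sign = 1.0 if side == "right" else -1.0
        center = np.array(
            [
                sign * rng.uniform(0.15, 0.55) * half_width,
                axes[1][0] + rng.uniform(0.35, 0.65) * ey,
                axes[2][0] + rng.uniform(0.35, 0.65) * ez,
            ]
        )

        def radii(mean_r):
            jit = 1.0 + config.radius_jitter * rng.uniform(-1, 1, size=3)
            return mean_r * jit

        present = {
            t: rng.uniform() >= config.lesion_absent_prob.get(t, 0.0)
            for t in LESION_TYPES
        }
        r = {t: radii(config.lesion_radii_mm.get(t, 0.0)) for t in LESION_TYPES}
        fet_shift = rng.uniform(-0.3, 0.3, size=3) * r["flair"]

        flair = (
            _ellipsoid(axes, center, r["flair"]) if present["flair"]
            else np.zeros(config.grid_shape, dtype=np.uint8)
        )
        masks = {"flair": flair}
        for t in ("cavity", "t1ce"):
            m = (
                _ellipsoid(axes, center, r[t]) if present[t]
                else np.zeros(config.grid_shape, dtype=np.uint8)
            )
            masks[t] = (m & flair).astype(np.uint8)  # enforce nesting
        masks["fet"] = (
            _ellipsoid(axes, center + fet_shift, r["fet"]) if present["fet"]
            else np.zeros(config.grid_shape, dtype=np.uint8)
        )
        lesions.append(LesionSet(subject, masks))
    return lesions, pd.Series(sides, name="side")


def _node_flair_fraction(
    nodes: AtlasParcellation, lesions: list[LesionSet]
) -> pd.DataFrame:
    """Subject x node table of FLAIR-overlap fractions (0 where no FLAIR)."""
    max_label = int(nodes.regions.index.max())
    vox = np.bincount(nodes.labels.ravel(), minlength=max_label + 1)
    rows = {}
    for ls in lesions:
        m = ls.masks.get("flair")
        if m is None or not m.any():
            counts = np.zeros(max_label + 1)
        else:
            counts = np.bincount(nodes.labels[m.astype(bool)], minlength=max_label + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(vox > 0, counts / np.maximum(vox, 1), 0.0)
        rows[ls.subject] = frac[nodes.regions.index.to_numpy()]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=nodes.regions.index
    )


def simulate_timeseries(
    config: SimulationConfig,
    atlas: AtlasParcellation,
    lesions: list[LesionSet] | None = None,
):
    """Draw node time series from a lesion-attenuated block factor model.

    Node i's signal is ``sqrt(rho_between) * G + b_i * F_net(i) + e_i * E_i``
    with independent standard-normal factors: a global factor shared by all
    nodes, one factor per (hemisphere, network) pool and a node-specific
    residual.  For intact nodes ``b_i = sqrt(rho_within - rho_between)``, so
    the correlation is ``rho_within`` within a pool and ``rho_between``
    across pools; a node's coupling is multiplied by
    ``max(floor, 1 - strength * flair_fraction)``, so a fully attenuated
    node decays to the between-network level.  Residual variance is set so
    every node has unit variance.
    """
    from .connectivity import NodeTimeSeries

    delta = config.rho_within - config.rho_between
    base_resid = 1.0 - config.rho_between - delta
    if base_resid < 0 or config.rho_between < 0:
        raise ValueError("correlation parameters yield a non-PSD covariance")

    regions = atlas.regions
    pools = {}
    for nid in regions.index:
        pools.setdefault(
            (regions.loc[nid, "hemisphere"], regions.loc[nid, "class_"]), []
        ).append(nid)
    pool_names = list(pools)
    pool_index = {}
    for k, (p, members) in enumerate(pools.items()):
        for nid in members:
            pool_index[nid] = k

    if lesions is not None:
        frac = _node_flair_fraction(atlas, lesions)
    else:
        frac = None

    node_ids = list(regions.index)
    n_nodes = len(node_ids)
    T = config.n_timepoints
    out = []
    n_subj = config.n_subjects if lesions is None else len(lesions)
    for i in range(n_subj):
        subject = lesions[i].subject if lesions is not None else _subject_id(i)
        rng = _rng(config.seed, i, _STAGE_TIMESERIES)
        f = (
            frac.loc[subject].to_numpy(dtype=float)
            if frac is not None
            else np.zeros(n_nodes)
        )
        mult = np.maximum(
            config.attenuation_floor, 1.0 - config.attenuation_strength * f
        )
        b = np.sqrt(delta) * mult
        e = np.sqrt(1.0 - config.rho_between - b**2)
        G = rng.standard_normal(T)
        F = rng.standard_normal((len(pool_names), T))
        E = rng.standard_normal((n_nodes, T))
        pool_rows = np.array([pool_index[nid] for nid in node_ids])
        data = (
            np.sqrt(config.rho_between) * G[None, :]
            + b[:, None] * F[pool_rows]
            + e[:, None] * E
        )
        out.append(NodeTimeSeries(subject, data, node_ids, config.tr_seconds))
    return out


def _effect_predictors(
    config: SimulationConfig,
    overlaps: pd.DataFrame | None,
    sides: pd.Series,
) -> pd.DataFrame:
    """One column per planted effect: the predictor value per subject."""
    cols = {}
    for k, eff in enumerate(config.planted_effects):
        name = f"effect_{k}:{eff.region}:{eff.target_scale}"
        if eff.region.startswith("side:"):
            target_side = eff.region.split(":", 1)[1]
            if target_side not in ("left", "right"):
                raise ValueError(f"unknown side predictor {eff.region!r}")
            cols[name] = (sides == target_side).astype(float)
        else:
            if overlaps is None:
                raise ValueError(
                    f"planted effect on region {eff.region!r} needs an overlap table"
                )
            sel = overlaps[
                (overlaps["region_name"] == eff.region)
                & (overlaps["lesion_type"] == eff.lesion_type)
            ]
            if sel.empty:
                raise ValueError(
                    f"planted predictor region {eff.region!r} (lesion type "
                    f"{eff.lesion_type!r}) not present in the overlap table"
                )
            cols[name] = sel.set_index("subject")["overlap_fraction"]
    return pd.DataFrame(cols, index=sides.index).fillna(0.0)


def simulate_qlq_responses(
    config: SimulationConfig,
    overlaps: pd.DataFrame | None,
    ground_truth: GroundTruth,
    scales: list[QlqScale] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate item responses whose scale scores carry the planted effects.

    Per subject and scale, a latent 0-100 score is drawn as
    ``baseline + sum(slope * predictor) + noise``, clamped, inverted through
    the scoring transform to a raw item mean, and quantized to integer item
    responses whose mean is as close as possible to the target (ties round
    toward worse functioning).  Returns (responses, latent scores).
    """
    if scales is None:
        scales = load_scale_map()
    by_id = {s.scale_id: s for s in scales}
    for eff in config.planted_effects:
        if eff.target_scale not in by_id:
            raise ValueError(f"planted target scale {eff.target_scale!r} is unknown")

    predictors = _effect_predictors(config, overlaps, ground_truth.sides)
    ground_truth.predictors = predictors
    subjects = list(ground_truth.sides.index)

    effects_on: dict[str, list[tuple[int, PlantedEffect]]] = {}
    for k, eff in enumerate(config.planted_effects):
        effects_on.setdefault(eff.target_scale, []).append((k, eff))

    resp_rows, latent_rows = [], []
    for i, subject in enumerate(subjects):
        rng = _rng(config.seed, i, _STAGE_RESPONSES)
        row: dict[str, float] = {}
        latent: dict[str, float] = {}
        for sc in scales:
            base = config.baseline_scores[sc.direction]
            effs = effects_on.get(sc.scale_id, [])
            mu = base
            for k, eff in effs:
                mu += eff.slope * float(predictors.iloc[i, k])
            if effs:
                sd = float(np.sqrt(sum(eff.noise_sd**2 for _, eff in effs)))
            else:
                sd = config.baseline_noise_sd
            s = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            s = float(np.clip(s, 0.0, 100.0))
            latent[sc.scale_id] = s
            # invert the 0-100 transform back to a raw item mean
            if sc.direction == "functional":
                m = 1.0 + sc.r * (1.0 - s / 100.0)
            else:
                m = 1.0 + sc.r * s / 100.0
            k_items = len(sc.items)
            total = int(np.floor(m * k_items + 0.5))  # half rounds toward worse
            total = int(np.clip(total, k_items, k_items * (1 + sc.r)))
            base_v, extra = divmod(total, k_items)
            for j, item in enumerate(sc.items):
                row[f"q{item:02d}"] = base_v + (1 if j < extra else 0)
        resp_rows.append(row)
        latent_rows.append(latent)
    responses = pd.DataFrame(resp_rows, index=pd.Index(subjects, name="subject"))
    responses = responses[sorted(responses.columns)].astype(int)
    latent_df = pd.DataFrame(latent_rows, index=responses.index)
    return responses, latent_df


def suggest_target_region(
    config: SimulationConfig, atlas: AtlasParcellation, hemisphere: str = "right"
) -> str:
    """Region of the given hemisphere nearest the expected lesion centre.

    A convenient choice of planted-effect predictor: lesions on that side
    frequently (and variably) overlap it.
    """
    aff, axes = _world_axes(config)
    half_width = config.voxel_size_mm[0] * config.grid_shape[0] / 2.0
    sign = 1.0 if hemisphere == "right" else -1.0
    expected = np.array(
        [
            sign * 0.35 * half_width,
            axes[1][0] + 0.5 * config.voxel_size_mm[1] * config.grid_shape[1],
            axes[2][0] + 0.5 * config.voxel_size_mm[2] * config.grid_shape[2],
        ]
    )
    best, best_d = None, np.inf
    for label in atlas.regions.index:
        if atlas.regions.loc[label, "hemisphere"] != hemisphere:
            continue
        idx = np.nonzero(atlas.labels == label)
        com = np.array(
            [axes[0][idx[0]].mean(), axes[1][idx[1]].mean(), axes[2][idx[2]].mean()]
        )
        d = float(((com - expected) ** 2).sum())
        if d < best_d:
            best, best_d = atlas.regions.loc[label, "name"], d
    if best is None:
        raise ValueError(f"atlas has no regions in hemisphere {hemisphere!r}")
    return best


def generate_cohort(
    config: SimulationConfig, with_timeseries: bool = False
) -> Cohort:
    """Run the full generator: atlas, lesions, overlaps, responses."""
    nodes, tracts = build_toy_atlas(config)
    lesions, sides = simulate_lesions(config, nodes)
    overlaps, totals = overlap_table(lesions, nodes, tracts)
    gt = GroundTruth(sides=sides, predictors=pd.DataFrame(index=sides.index),
                     effects=list(config.planted_effects))
    responses, latent = simulate_qlq_responses(config, overlaps, gt)
    ts = None
    if with_timeseries:
        ts = simulate_timeseries(config, nodes, lesions)
        frac = _node_flair_fraction(nodes, lesions)
        gt.node_attenuation = np.maximum(
            config.attenuation_floor, 1.0 - config.attenuation_strength * frac
        )
    return Cohort(config, nodes, tracts, lesions, overlaps, totals, responses,
                  latent, gt, ts)
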