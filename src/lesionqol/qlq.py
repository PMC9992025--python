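"""EORTC QLQ-C30 / BN20 scale scoring.

Items are averaged into raw scale scores and linearly rescaled to 0-100
following the EORTC scoring-manual conventions: for functional scales higher
means better functioning, for symptom scales and single items higher means a
worse symptom burden, and the two 7-point global items form the global
health / QoL scale.  A scale is scored when at least half of its items were
answered (exactly half counts), using the mean of the answered items.

The item-to-scale composition ships as a data file
(``data/qlq_scales.tsv``) and can be replaced, so the scoring engine is
agnostic to the manual version.  Item columns follow the convention
``q01``..``q30`` for the core questionnaire and ``q31``..``q50`` for the
brain-tumour module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QlqScale",
    "load_scale_map",
    "item_column",
    "raw_score",
    "scale_score",
    "score_cohort",
    "validate_responses",
]


@dataclass(frozen=True)
class QlqScale:
    """One scale of the questionnaire: member items, direction and range.

    ``r`` is the item range (max minus min legal response): 3 for 4-point
    items, 6 for the 7-point global items.
    """

    scale_id: str
    label: str
    instrument: str
    direction: str  # functional | symptom | global
    r: int
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("functional", "symptom", "global"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.r not in (3, 6):
            raise ValueError(f"item range must be 3 or 6, got {self.r}")
        if self.direction == "global" and self.r != 6:
            raise ValueError("global scales use 7-point items (r = 6)")
        if not self.items:
            raise ValueError(f"scale {self.scale_id!r} has no items")


def item_column(item: int) -> str:
    return f"q{item:02d}"


def load_scale_map(path: str | Path | None = None) -> list[QlqScale]:
    """Load the scale composition table (the packaged default or a custom one)."""
    if path is None:
        with resources.files("lesionqol.data").joinpath("qlq_scales.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    scales = []
    seen: dict[tuple[str, int], str] = {}
    for row in df.itertuples(index=False):
        items = tuple(int(i) for i in str(row.items).split(","))
        for i in items:
            key = (row.instrument, i)
            if key in seen:
                raise ValueError(
                    f"item {i} of instrument {row.instrument} assigned to both "
                    f"{seen[key]!r} and {row.scale_id!r}"
                )
            seen[key] = row.scale_id
        scales.append(
            QlqScale(row.scale_id, row.label, row.instrument, row.direction,
                     int(row.r), items)
        )
    return scales


def validate_responses(responses: pd.DataFrame, scales: list[QlqScale]) -> None:
    """Check every present response against its item's legal range."""
    for sc in scales:
        lo, hi = 1, 1 + sc.r
        for item in sc.items:
            col = item_column(item)
            if col not in responses.columns:
                continue
            vals = responses[col].astype(float)
            bad = vals.notna() & ((vals < lo) | (vals > hi) | (vals != vals.round()))
            if bad.any():
                subj = responses.index[bad][0]
                raise ValueError(
                    f"subject {subj!r}, item {col}: response {vals[bad].iloc[0]!r} "
                    f"outside legal range [{lo}, {hi}]"
                )


def raw_score(values, scale: QlqScale) -> float:
    """Mean of the answered member items, or NaN if fewer than half answered.

    ``values`` is a sequence aligned with ``scale.items`` (NaN = missing).
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != (len(scale.items),):
        raise ValueError(
            f"expected {len(scale.items)} values for scale {scale.scale_id!r}"
        )
    answered = ~np.isnan(vals)
    ok = vals[answered]
    if np.any((ok < 1) | (ok > 1 + scale.r)):
        raise ValueError(f"response outside [1, {1 + scale.r}] for scale {scale.scale_id!r}")
    if answered.sum() < math.ceil(len(scale.items) / 2):
        return float("nan")
    return float(ok.mean())


def scale_score(raw: float, scale: QlqScale) -> float:
    """Linear transform of a raw score to the 0-100 range.

    Functional scales: ``100 * (1 - (raw - 1)/r)`` (higher = better);
    symptom and global scales: ``100 * (raw - 1)/r``.
    """
    if math.isnan(raw):
        return float("nan")
    if not 1 <= raw <= 1 + scale.r:
        raise ValueError(f"raw score {raw} outside [1, {1 + scale.r}]")
    if scale.direction == "functional":
        return 100.0 * (1.0 - (raw - 1.0) / scale.r)
    return 100.0 * (raw - 1.0) / scale.r


def score_cohort(
    responses: pd.DataFrame, scales: list[QlqScale] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score an item-response table (subjects x ``q..`` columns).

    Returns the subject x scale score table and a parallel table with the
    number of items used per scale (0 where the half-rule failed).
    Missing item columns are treated as unanswered for every subject.
    """
    if scales is None:
        scales = load_scale_map()
    if responses.index.duplicated().any():
        dup = responses.index[responses.index.duplicated()][0]
        raise ValueError(f"duplicated subject id {dup!r} in responses")
    validate_responses(responses, scales)
    scores = pd.DataFrame(index=responses.index, dtype=float)
    n_used = pd.DataFrame(index=responses.index, dtype=int)
    for sc in scales:
        cols = [item_column(i) for i in sc.items]
        block = pd.DataFrame(
            {c: (responses[c] if c in responses.columns else np.nan) for c in cols},
            index=responses.index, dtype=float,
        )
        answered = block.notna().sum(axis=1)
        need = math.ceil(len(sc.items) / 2)
        raw = block.mean(axis=1)
        raw[answered < need] = np.nan
        if sc.direction == "functional":
            scores[sc.scale_id] = 100.0 * (1.0 - (raw - 1.0) / sc.r)
        else:
            scores[sc.scale_id] = 100.0 * (raw - 1.0) / sc.r
        n_used[sc.scale_id] = answered.where(answered >= need, 0).astype(int)
    return scores, n_used
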