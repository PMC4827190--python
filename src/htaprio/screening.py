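"""Expert-panel screening of candidate criteria.

Candidate criteria for the priority-setting model are screened on expert
ratings collected on three scales:

* necessity (3 levels) feeds Lawshe's content validity ratio
  ``CVR = (n_essential - N/2) / (N/2)``, compared against the Lawshe
  critical value for the panel size;
* relevance (5 levels) feeds the content validity index, the proportion
  rating the item in the top two relevance levels, with a 0.79 floor;
* importance (5 levels) feeds the importance share (proportion rating
  important or very important), with a 0.75 cut used downstream.

An item is retained when its CVR clears the Lawshe critical value, or,
failing that, when at least half the panel judged it necessary AND its CVI
clears the floor.  Face-validity ratings are carried into the report but do
not gate retention (they informed wording/merging, a human editorial step).
Ties at any threshold pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "NECESSITY_LEVELS",
    "RELEVANCE_LEVELS",
    "IMPORTANCE_LEVELS",
    "LAWSHE_CRITICAL",
    "ExpertRatingSet",
    "ScreeningThresholds",
    "ScreeningResult",
    "compute_cvi",
    "compute_cvr",
    "importance_share",
    "screen_items",
    "cronbach_alpha",
]

NECESSITY_LEVELS = ("not-necessary", "useful-not-necessary", "necessary")
NECESSITY_FAVORABLE = ("necessary",)

RELEVANCE_LEVELS = (
    "completely-irrelevant",
    "irrelevant",
    "relatively-irrelevant",
    "relevant",
    "completely-relevant",
)
RELEVANCE_FAVORABLE = ("relevant", "completely-relevant")

IMPORTANCE_LEVELS = (
    "very-slightly-important",
    "slightly-important",
    "moderately-important",
    "important",
    "very-important",
)
IMPORTANCE_FAVORABLE = ("important", "very-important")

#: Lawshe's one-tailed critical CVR values by panel size (Lawshe 1975).
LAWSHE_CRITICAL: Mapping[int, float] = {
    5: 0.99,
    6: 0.99,
    7: 0.99,
    8: 0.75,
    9: 0.78,
    10: 0.62,
    11: 0.59,
    12: 0.56,
    13: 0.54,
    14: 0.51,
    15: 0.49,
    20: 0.42,
    25: 0.37,
    30: 0.33,
    35: 0.31,
    40: 0.29,
}


def _canon(label: str) -> str:
    return str(label).strip().lower().replace(" ", "-").replace("_", "-")


def _check_ratings(ratings: Sequence[str], levels: tuple[str, ...]) -> list[str]:
    if len(ratings) == 0:
        raise InvalidInputError("at least one expert rating is required")
    canon = [_canon(r) for r in ratings]
    unknown = sorted({r for r in canon if r not in levels})
    if unknown:
        raise InvalidInputError(f"unknown rating label(s) {unknown}; expected {levels}")
    return canon


def compute_cvi(relevance_ratings: Sequence[str]) -> float:
    """Content validity index: share of experts in the top two relevance levels."""
    canon = _check_ratings(relevance_ratings, RELEVANCE_LEVELS)
    return sum(r in RELEVANCE_FAVORABLE for r in canon) / len(canon)


def compute_cvr(necessity_ratings: Sequence[str]) -> float:
    """Lawshe content validity ratio (n_essential - N/2) / (N/2), in [-1, 1]."""
    canon = _check_ratings(necessity_ratings, NECESSITY_LEVELS)
    n = len(canon)
    essential = sum(r == "necessary" for r in canon)
    return (essential - n / 2) / (n / 2)


def importance_share(importance_ratings: Sequence[str]) -> float:
    """Share of experts rating the item important or very important."""
    canon = _check_ratings(importance_ratings, IMPORTANCE_LEVELS)
    return sum(r in IMPORTANCE_FAVORABLE for r in canon) / len(canon)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Retention thresholds; ties at a threshold always pass."""

    cvi_min: float = 0.79
    majority_min: float = 0.50
    importance_min: float = 0.75
    lawshe_table: Mapping[int, float] = field(default_factory=lambda: dict(LAWSHE_CRITICAL))

    def __post_init__(self) -> None:
        for name in ("cvi_min", "majority_min", "importance_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")

    def lawshe_critical(self, panel_size: int) -> float:
        if panel_size not in self.lawshe_table:
            raise ConfigurationError(
                f"no Lawshe critical value configured for a panel of {panel_size}"
            )
        return float(self.lawshe_table[panel_size])


@dataclass(frozen=True)
class ExpertRatingSet:
    """Per-item, per-expert ratings on the four screening scales.

    Each scale is an items x experts DataFrame of canonical labels
    (lowercase, hyphen-separated); ``face_clear`` is boolean.  All scales
    must share the same item index and expert columns.
    """

    necessity: pd.DataFrame
    relevance: pd.DataFrame
    importance: pd.DataFrame
    face_clear: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        frames = {"necessity": self.necessity, "relevance": self.relevance,
                  "importance": self.importance}
        base = self.necessity
        if base.shape[0] < 1 or base.shape[1] < 1:
            raise InvalidInputError("rating set needs >= 1 item and >= 1 expert")
        for name, df in frames.items():
            if list(df.index) != list(base.index) or list(df.columns) != list(base.columns):
                raise InvalidInputError(
                    f"{name} ratings do not share the item/expert layout of necessity"
                )
            if df.isna().any().any():
                raise InvalidInputError(f"{name} ratings contain missing cells")
        levels = {"necessity": NECESSITY_LEVELS, "relevance": RELEVANCE_LEVELS,
                  "importance": IMPORTANCE_LEVELS}
        for name, df in frames.items():
            _check_ratings(df.to_numpy().ravel().tolist(), levels[name])
        if self.face_clear is not None:
            fc = self.face_clear
            if list(fc.index) != list(base.index) or list(fc.columns) != list(base.columns):
                raise InvalidInputError("face_clear does not share the item/expert layout")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.necessity.index)

    @property
    def n_experts(self) -> int:
        return self.necessity.shape[1]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ExpertRatingSet":
        """Build from a long table with columns item_id, expert_id, scale_name,
        rating_label (the CSV interchange layout)."""
        required = {"item_id", "expert_id", "scale_name", "rating_label"}
        missing = required - set(long.columns)
        if missing:
            raise InvalidInputError(f"long rating table is missing columns {sorted(missing)}")
        frames: dict[str, pd.DataFrame] = {}
        for scale, sub in long.groupby("scale_name"):
            wide = sub.pivot(index="item_id", columns="expert_id", values="rating_label")
            frames[_canon(scale)] = wide
        for scale in ("necessity", "relevance", "importance"):
            if scale not in frames:
                raise InvalidInputError(f"long rating table has no '{scale}' ratings")
        face = frames.get("face")
        if face is not None:
            face = face.apply(lambda col: col.map(
                lambda v: _canon(v) in ("clear", "true", "1", "yes")))
        # align every scale on the necessity layout
        base = frames["necessity"]
        aligned = {
            s: frames[s].reindex(index=base.index, columns=base.columns)
            for s in ("necessity", "relevance", "importance")
        }
        return cls(aligned["necessity"], aligned["relevance"], aligned["importance"],
                   face.reindex(index=base.index, columns=base.columns) if face is not None else None)

    def to_long(self) -> pd.DataFrame:
        rows = []
        scales = {"necessity": self.necessity, "relevance": self.relevance,
                  "importance": self.importance}
        if self.face_clear is not None:
            scales["face"] = self.face_clear.map(lambda b: "clear" if b else "not-clear")
        for scale, df in scales.items():
            for item in df.index:
                for expert in df.columns:
                    rows.append((item, expert, scale, df.at[item, expert]))
        return pd.DataFrame(rows, columns=["item_id", "expert_id", "scale_name", "rating_label"])


ROUTE_CVR = "cvr-pass"
ROUTE_MAJORITY_CVI = "majority-plus-cvi"
ROUTE_DROPPED = "dropped"


@dataclass(frozen=True)
class ScreeningResult:
    """Per-item screening statistics and the retention verdict."""

    table: pd.DataFrame  # index item_id; cvi, cvr, necessity_majority, ...

    @property
    def retained_items(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["retained"]])


def screen_items(
    ratings: ExpertRatingSet, thresholds: ScreeningThresholds | None = None
) -> ScreeningResult:
    """Apply the retention rule to every item.

    An item is retained via ``cvr-pass`` when CVR >= the Lawshe critical
    value for the panel size, else via ``majority-plus-cvi`` when at least
    ``majority_min`` of the panel judged it necessary and CVI >= ``cvi_min``;
    otherwise it is dropped.
    """
    thr = thresholds or ScreeningThresholds()
    critical = thr.lawshe_critical(ratings.n_experts)
    rows = []
    for item in ratings.necessity.index:
        necessity = ratings.necessity.loc[item].tolist()
        cvr = compute_cvr(necessity)
        majority = sum(_canon(r) == "necessary" for r in necessity) / len(necessity)
        cvi = compute_cvi(ratings.relevance.loc[item].tolist())
        imp = importance_share(ratings.importance.loc[item].tolist())
        face = (
            float(ratings.face_clear.loc[item].mean())
            if ratings.face_clear is not None
            else np.nan
        )
        if cvr >= critical:
            route = ROUTE_CVR
        elif majority >= thr.majority_min and cvi >= thr.cvi_min:
            route = ROUTE_MAJORITY_CVI
        else:
            route = ROUTE_DROPPED
        rows.append(
            {
                "item_id": item,
                "cvi": cvi,
                "cvr": cvr,
                "necessity_majority": majority,
                "importance_share": imp,
                "face_clear_share": face,
                "lawshe_critical": critical,
                "retained": route != ROUTE_DROPPED,
                "retention_route": route,
            }
        )
    table = pd.DataFrame(rows).set_index("item_id")
    return ScreeningResult(table)


def cronbach_alpha(scores: pd.DataFrame) -> float:
    """Cronbach's alpha for internal consistency.

    ``scores`` is respondents x items, numeric (e.g. importance ratings
    coded 1-5 with experts as respondents).  Uses the standard
    ``alpha = k/(k-1) * (1 - sum(item variances)/variance(total))`` with
    unbiased (ddof=1) variances.
    """
    x = scores.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidInputError("alpha needs >= 2 respondents and >= 2 items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InvalidInputError("total score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_var / total_var)


def importance_to_numeric(importance: pd.DataFrame) -> pd.DataFrame:
    """Map importance labels to 1-5 codes, experts as rows (for alpha)."""
    coded = importance.apply(
        lambda col: col.map(lambda v: IMPORTANCE_LEVELS.index(_canon(v)) + 1)
    )
    return coded.T
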