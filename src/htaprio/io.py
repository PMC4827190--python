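"""File dialects, run configuration, and the priority report.

CSV is comma-separated UTF-8 with a header row (and a leading label column
for matrices), decimal point regardless of locale; every CSV has a JSON
equivalent.  Reports carry full-precision values plus a two-decimal
rendering and enough provenance (input hashes, configuration echo, tool
version) to re-run a ranking byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ahp import (
    SAATY_RANDOM_INDEX,
    ConsistencyReport,
    CriterionWeightVector,
    PairwiseComparisonMatrix,
)
from .errors import InvalidInputError, ParseError
from .rubrics import EvidenceProfile
from .screening import ScreeningResult, ScreeningThresholds, LAWSHE_CRITICAL
from .topsis import DecisionMatrix, TopsisResult

__all__ = [
    "RunConfig",
    "read_pairwise_matrix",
    "write_pairwise_matrix",
    "read_decision_matrix",
    "write_decision_matrix",
    "read_weights",
    "write_weights",
    "read_rating_set",
    "read_evidence_profiles",
    "write_evidence_profiles",
    "write_screening_report",
    "build_priority_report",
    "write_priority_report",
    "read_priority_report",
]


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8", **kw)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return df


def _load_json(path) -> Any:
    try:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse {path}: line {exc.lineno}: {exc.msg}") from exc


def _is_json(path) -> bool:
    return str(path).lower().endswith(".json")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide configuration (flat, JSON-compatible)."""

    criteria: tuple[str, ...] | None = None
    directions: tuple[str, ...] | None = None
    thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    random_index: Mapping[int, float] = field(default_factory=lambda: dict(SAATY_RANDOM_INDEX))
    rounding_digits: int = 2
    output_format: str = "table"
    log_level: str = "INFO"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rounding_digits < 0:
            raise InvalidInputError("rounding_digits must be >= 0")
        if self.output_format not in ("csv", "json", "table"):
            raise InvalidInputError(
                f"output_format must be csv/json/table, got {self.output_format!r}"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = _load_json(path)
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a JSON object")
        thr_kw = {}
        for key in ("cvi_min", "majority_min", "importance_min"):
            if key in raw:
                thr_kw[key] = float(raw.pop(key))
        if "lawshe_table" in raw:
            thr_kw["lawshe_table"] = {int(k): float(v)
                                      for k, v in raw.pop("lawshe_table").items()}
        else:
            thr_kw["lawshe_table"] = dict(LAWSHE_CRITICAL)
        ri = raw.pop("random_index", None)
        kw: dict[str, Any] = {}
        if "criteria" in raw:
            kw["criteria"] = tuple(raw.pop("criteria"))
        if "directions" in raw:
            kw["directions"] = tuple(raw.pop("directions"))
        for key in ("rounding_digits", "output_format", "log_level", "seed"):
            if key in raw:
                kw[key] = raw.pop(key)
        if raw:
            raise InvalidInputError(f"unknown config key(s): {sorted(raw)}")
        return cls(
            thresholds=ScreeningThresholds(**thr_kw),
            random_index={int(k): float(v) for k, v in ri.items()} if ri else dict(SAATY_RANDOM_INDEX),
            **kw,
        )


# --- pairwise matrices -----------------------------------------------------

def read_pairwise_matrix(path, repair_reciprocal: bool = False) -> PairwiseComparisonMatrix:
    """Square CSV with a label header row and leading label column, or JSON
    ``{"labels": [...], "values": [[...]]}``."""
    if _is_json(path):
        raw = _load_json(path)
        labels, values = raw.get("labels"), raw.get("values")
        if labels is None or values is None:
            raise ParseError(f"{path}: expected 'labels' and 'values' keys")
        arr = np.asarray(values, dtype=float)
    else:
        df = _read_csv(path, index_col=0)
        labels = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != labels:
            raise ParseError(f"{path}: row labels must equal column labels")
        arr = df.to_numpy(dtype=float)
    if repair_reciprocal:
        return PairwiseComparisonMatrix.repaired(labels, arr)
    return PairwiseComparisonMatrix(tuple(labels), arr)


def write_pairwise_matrix(matrix: PairwiseComparisonMatrix, path) -> None:
    if _is_json(path):
        Path(path).write_text(json.dumps(
            {"labels": list(matrix.labels), "values": matrix.values.tolist()},
            indent=2) + "\n", encoding="utf-8")
    else:
        matrix.to_dataframe().to_csv(path, encoding="utf-8")


# --- decision matrices -----------------------------------------------------

def read_decision_matrix(path) -> DecisionMatrix:
    if _is_json(path):
        raw = _load_json(path)
        try:
            return DecisionMatrix(
                tuple(raw["alternatives"]), tuple(raw["criteria"]),
                np.asarray(raw["values"], dtype=float))
        except KeyError as exc:
            raise ParseError(f"{path}: missing key {exc}") from exc
    df = _read_csv(path, index_col=0)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ParseError(f"{path}: empty decision matrix")
    try:
        return DecisionMatrix.from_dataframe(df.astype(float))
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric score: {exc}") from exc


def write_decision_matrix(matrix: DecisionMatrix, path) -> None:
    if _is_json(path):
        Path(path).write_text(json.dumps({
            "alternatives": list(matrix.alternatives),
            "criteria": list(matrix.criteria),
            "values": matrix.values.tolist()}, indent=2) + "\n", encoding="utf-8")
    else:
        matrix.to_dataframe().to_csv(path, encoding="utf-8")


# --- weights ---------------------------------------------------------------

def read_weights(path) -> CriterionWeightVector:
    """Two-column CSV (label, weight) or JSON ``{"labels": [...], "weights": [...]}``."""
    if _is_json(path):
        raw = _load_json(path)
        if "labels" not in raw or "weights" not in raw:
            raise ParseError(f"{path}: expected 'labels' and 'weights' keys")
        return CriterionWeightVector(tuple(raw["labels"]),
                                     np.asarray(raw["weights"], dtype=float))
    df = _read_csv(path)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns (label, weight)")
    return CriterionWeightVector(
        tuple(str(v) for v in df.iloc[:, 0]), df.iloc[:, 1].to_numpy(dtype=float))


def write_weights(weights: CriterionWeightVector, path) -> None:
    if _is_json(path):
        Path(path).write_text(json.dumps({
            "labels": list(weights.labels),
            "weights": weights.values.tolist()}, indent=2) + "\n", encoding="utf-8")
    else:
        pd.DataFrame({"criterion": weights.labels, "weight": weights.values}
                     ).to_csv(path, index=False, encoding="utf-8")


# --- ratings and evidence --------------------------------------------------

def read_rating_set(path):
    """Long CSV (item_id, expert_id, scale_name, rating_label) or the JSON
    list-of-records equivalent."""
    from .screening import ExpertRatingSet

    if _is_json(path):
        raw = _load_json(path)
        if not isinstance(raw, list):
            raise ParseError(f"{path}: expected a JSON list of rating records")
        long = pd.DataFrame(raw)
    else:
        long = _read_csv(path)
    if long.empty:
        raise ParseError(f"{path}: no rating records found")
    return ExpertRatingSet.from_long(long)


def read_evidence_profiles(path) -> list[EvidenceProfile]:
    raw = _load_json(path)
    if isinstance(raw, dict):
        raw = [raw]
    if not isinstance(raw, list):
        raise ParseError(f"{path}: expected a JSON list of evidence profiles")
    return [EvidenceProfile.from_dict(d) for d in raw]


def write_evidence_profiles(profiles: Sequence[EvidenceProfile], path) -> None:
    Path(path).write_text(
        json.dumps([p.to_dict() for p in profiles], indent=2) + "\n", encoding="utf-8")


def write_screening_report(result: ScreeningResult, path) -> None:
    result.table.to_csv(path, encoding="utf-8")


# --- priority report -------------------------------------------------------

def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_priority_report(
    result: TopsisResult,
    config: RunConfig | None = None,
    input_paths: Mapping[str, Any] | None = None,
    consistency: ConsistencyReport | None = None,
) -> dict:
    """Assemble the lossless report: inputs, every intermediate matrix at
    full precision, the rounded rendering, and provenance."""
    cfg = config or RunConfig()
    digits = cfg.rounding_digits
    report = {
        "tool": {"name": "htaprio", "version": __version__},
        "inputs": {
            name: {"path": str(p), "sha256": _hash_file(p)}
            for name, p in (input_paths or {}).items()
        },
        "config": {
            "directions": list(result.directions),
            "rounding_digits": digits,
        },
        "alternatives": list(result.decision.alternatives),
        "criteria": list(result.decision.criteria),
        "decision_matrix": result.decision.values.tolist(),
        "weights": result.weights.values.tolist(),
        "normalized": result.normalized.values.tolist(),
        "weighted": result.weighted.values.tolist(),
        "a_plus": result.ideals.a_plus.tolist(),
        "a_minus": result.ideals.a_minus.tolist(),
        "d_plus": result.ranking.d_plus.tolist(),
        "d_minus": result.ranking.d_minus.tolist(),
        "closeness": result.ranking.cl.tolist(),
        "ranks": result.ranking.ranks.tolist(),
        "rounded": result.rounded(digits),
    }
    if consistency is not None:
        report["consistency"] = consistency.to_dict()
    return report


def write_priority_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")


def read_priority_report(path) -> dict:
    return _load_json(path)


def render_priority_table(report: dict) -> str:
    """Human-readable rendering mirroring the published pilot layout."""
    digits = report["config"]["rounding_digits"]
    alts, crits = report["alternatives"], report["criteria"]

    def frame(key):
        return pd.DataFrame(report[key], index=alts, columns=crits).round(digits)

    lines = []
    for title, key in (("Decision matrix", "decision_matrix"),
                       ("Normalized matrix", "normalized"),
                       ("Weighted matrix", "weighted")):
        lines += [title, frame(key).to_string(), ""]
    ideals = pd.DataFrame([report["a_plus"], report["a_minus"]],
                          index=["A+", "A-"], columns=crits).round(digits)
    lines += ["Ideal profiles", ideals.to_string(), ""]
    final = pd.DataFrame({
        "d_plus": report["d_plus"],
        "d_minus": report["d_minus"],
        "closeness": report["closeness"],
        "rank": report["ranks"]}, index=alts)
    final[["d_plus", "d_minus", "closeness"]] = final[
        ["d_plus", "d_minus", "closeness"]].round(digits)
    lines += ["Final priority setting", final.to_string(), ""]
    return "\n".join(lines)
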