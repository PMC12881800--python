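"""Model-vs-intraoperative structure concordance scoring.

Surgeons count the arterial, venous and bronchial branches visible in
the intraoperative video and in the patient's 3-D model; from those
per-case counts this module derives TP/FP/FN (TN is identically zero:
a structure absent from both the model and the field is never
enumerated), scores accuracy = TP/(TP+FP+FN), precision = TP/(TP+FP)
and sensitivity = TP/(TP+FN), and macro-averages across cases.

Counts-only derivation (TP = min, FP/FN = excess on either side) is a
proxy: it recovers every narrated discrepancy in the packaged
30-case table but cannot detect offsetting identity errors, so
explicit TP/FP/FN may be supplied instead. Missing counts ('x') make a
structure non-evaluable for that case; nothing is imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STRUCTURES = ("artery", "vein", "bronchus")

#: sanity bound on per-case branch counts
_MAX_COUNT = 20

CountPair = tuple[int | None, int | None]  # (video, ai); None = missing


@dataclass(frozen=True)
class CaseCounts:
    """Branch counts of one case: (video, model) per structure."""

    case_id: int
    artery: CountPair = (None, None)
    vein: CountPair = (None, None)
    bronchus: CountPair = (None, None)

    def __post_init__(self) -> None:
        for name in STRUCTURES:
            video, ai = getattr(self, name)
            for v in (video, ai):
                if v is not None and not 0 <= v <= _MAX_COUNT:
                    raise ValueError(
                        f"case {self.case_id} {name}: count {v} outside [0, {_MAX_COUNT}]"
                    )

    def pair(self, structure: str) -> CountPair:
        if structure not in STRUCTURES:
            raise KeyError(f"unknown structure {structure!r}; expected one of {STRUCTURES}")
        return getattr(self, structure)

    def evaluable(self, structure: str) -> bool:
        video, ai = self.pair(structure)
        return video is not None and ai is not None


@dataclass(frozen=True)
class ConcordanceCounts:
    """TP/FP/FN of one structure in one case; TN is identically 0."""

    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TN != 0:
            raise ValueError("TN is identically zero in this evaluation")


@dataclass(frozen=True)
class ConcordanceScores:
    """Accuracy / precision / sensitivity; None where the denominator is 0."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None


@dataclass(frozen=True)
class MetricAggregate:
    mean: float
    sd: float
    n_evaluable: int


@dataclass(frozen=True)
class AggregateScores:
    """Macro-averaged metrics of one structure across cases."""

    structure: str
    accuracy: MetricAggregate
    precision: MetricAggregate
    sensitivity: MetricAggregate


def derive_counts(video_count: int, ai_count: int) -> ConcordanceCounts:
    """TP/FP/FN from the two branch counts.

    TP = min(video, ai); an excess model branch is a false positive, an
    excess intraoperative branch a false negative. Both counts must be
    present — missing values make the structure non-evaluable instead.
    """
    if video_count is None or ai_count is None:
        raise ValueError("counts-based derivation requires both counts; missing values are non-evaluable")
    video, ai = int(video_count), int(ai_count)
    if video < 0 or ai < 0:
        raise ValueError("counts must be non-negative")
    tp = min(video, ai)
    return ConcordanceCounts(TP=tp, FP=max(0, ai - video), FN=max(0, video - ai))


def score(c: ConcordanceCounts) -> ConcordanceScores:
    """Accuracy, precision and sensitivity with TN = 0.

    A zero denominator yields None (undefined), which aggregation
    skips.
    """
    total = c.TP + c.TN + c.FP + c.FN

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return ConcordanceScores(
        accuracy=ratio(c.TP + c.TN, total),
        precision=ratio(c.TP, c.TP + c.FP),
        sensitivity=ratio(c.TP, c.TP + c.FN),
    )


def case_scores(case: CaseCounts, structure: str) -> ConcordanceScores | None:
    """Scores of one structure in one case; None if non-evaluable."""
    if not case.evaluable(structure):
        return None
    video, ai = case.pair(structure)
    return score(derive_counts(video, ai))


def aggregate(
    cases: Sequence[CaseCounts], structure: str, sample_sd: bool = True
) -> AggregateScores:
    """Macro-average one structure's metrics over evaluable cases.

    Per-case scores are averaged unweighted; undefined per-case values
    are excluded per metric. sd is the sample (n-1) standard deviation
    by default (population form available via ``sample_sd=False``).
    """
    per_metric: dict[str, list[float]] = {m: [] for m in ("accuracy", "precision", "sensitivity")}
    for case in cases:
        s = case_scores(case, structure)
        if s is None:
            continue
        for metric in per_metric:
            value = getattr(s, metric)
            if value is not None:
                per_metric[metric].append(value)
    if not any(per_metric.values()):
        raise ValueError(f"no evaluable cases for structure {structure!r}")

    ddof = 1 if sample_sd else 0

    def agg(values: list[float]) -> MetricAggregate:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
        return MetricAggregate(mean=float(arr.mean()), sd=sd, n_evaluable=len(arr))

    return AggregateScores(
        structure=structure,
        accuracy=agg(per_metric["accuracy"]),
        precision=agg(per_metric["precision"]),
        sensitivity=agg(per_metric["sensitivity"]),
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_COLUMNS = (
    "case_id",
    "artery_video",
    "artery_ai",
    "vein_video",
    "vein_ai",
    "bronchus_video",
    "bronchus_ai",
)


def _parse_cell(raw: str, lineno: int, column: str) -> int | None:
    token = raw.strip().lower()
    if token == "x":
        return None
    try:
        return int(token)
    except ValueError:
        raise ValueError(
            f"line {lineno}: column {column!r} must be a non-negative integer or 'x', got {raw!r}"
        ) from None


def _rows_to_cases(rows: Iterable[Sequence[str]], first_lineno: int) -> list[CaseCounts]:
    cases = []
    for offset, row in enumerate(rows):
        lineno = first_lineno + offset
        if len(row) != len(_COLUMNS):
            raise ValueError(f"line {lineno}: expected {len(_COLUMNS)} columns, got {len(row)}")
        cells = [_parse_cell(raw, lineno, col) for raw, col in zip(row, _COLUMNS)]
        if cells[0] is None:
            raise ValueError(f"line {lineno}: case_id may not be missing")
        cases.append(
            CaseCounts(
                case_id=cells[0],
                artery=(cells[1], cells[2]),
                vein=(cells[3], cells[4]),
                bronchus=(cells[5], cells[6]),
            )
        )
    return cases


def read_counts_csv(path: str | Path) -> list[CaseCounts]:
    """Read a per-case structure-count table.

    Expected header: case_id, artery_video, artery_ai, vein_video,
    vein_ai, bronchus_video, bronchus_ai; 'x' marks a missing count.
    Malformed rows raise with their line number.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(_COLUMNS):
            raise ValueError(f"{path}: expected header {','.join(_COLUMNS)}")
        return _rows_to_cases(reader, first_lineno=2)


def table2_fixture() -> list[CaseCounts]:
    """The packaged 30-case clinical-evaluation count table."""
    text = resources.files("lungfem.data").joinpath("table2_counts.csv").read_text()
    rows = list(csv.reader(text.strip().splitlines()))
    return _rows_to_cases(rows[1:], first_lineno=2)


def evaluate_cases(cases: Sequence[CaseCounts], sample_sd: bool = True) -> dict:
    """Per-case and aggregate scores as a JSON-ready dict."""
    per_case = []
    for case in cases:
        entry: dict = {"case_id": case.case_id}
        for structure in STRUCTURES:
            s = case_scores(case, structure)
            entry[structure] = (
                None
                if s is None
                else {
                    "accuracy": s.accuracy,
                    "precision": s.precision,
                    "sensitivity": s.sensitivity,
                }
            )
        per_case.append(entry)
    aggregates = {}
    for structure in STRUCTURES:
        a = aggregate(cases, structure, sample_sd=sample_sd)
        aggregates[structure] = {
            metric: {
                "mean": getattr(a, metric).mean,
                "sd": getattr(a, metric).sd,
                "n_evaluable": getattr(a, metric).n_evaluable,
            }
            for metric in ("accuracy", "precision", "sensitivity")
        }
    return {"per_case": per_case, "aggregate": aggregates}
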