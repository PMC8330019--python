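"""MCID-based classification of treatment response and response-matrix encoding.

A patient's response to asthma controller therapy is graded per clinical
metric and per inter-visit interval into three ordered categories —
GOOD (1), MODERATE (2), POOR (3) — using minimal-clinically-important-
difference thresholds:

* FEV1 % predicted: a rise of >= 10 percentage points of predicted is GOOD,
  a fall of >= 10 points is POOR, anything between is MODERATE.
* MEF50 % predicted: the same rule with a 15-point cut.
* FENO (ppb): interpreted on a high/low-baseline branch. When the interval's
  starting FENO exceeds the age-dependent cut (35 ppb for children under 12,
  50 ppb otherwise) the change is judged relatively (+/-20 %); below the cut
  it is judged absolutely (+/-10 ppb). Falls beyond the band are GOOD, rises
  beyond it POOR.
* Asthma control (3-level GINA classification, 0 = controlled,
  1 = partly controlled, 2 = uncontrolled): any improvement is GOOD,
  deterioration POOR, no change MODERATE.

Percent-predicted values are handled as fractions (0.87 = 87 % predicted) and
deltas are absolute differences of those fractions, so "+10 % predicted"
means +0.10.

The three categories always partition the outcome space.  The published
GOOD rule for FENO ("decrease < 20 %" / "increase < 10 ppb") overlaps the
MODERATE band; by default GOOD is therefore the complement of the MODERATE
and POOR regions (decrease beyond the band).  The literal published wording
is available via ``ResponseRuleSet(literal_feno_good=True)`` for sensitivity
analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseCategory",
    "ResponseRuleSet",
    "Interval",
    "CONSECUTIVE_INTERVALS",
    "CUMULATIVE_INTERVALS",
    "ALL_INTERVALS",
    "METRICS",
    "CLUSTERING_FEATURES",
    "VisitRecord",
    "ResponseProfile",
    "CodedMatrix",
    "ClassificationError",
    "classify_lungfunction",
    "classify_feno",
    "classify_control",
    "build_response_profile",
    "encode_matrix",
    "read_visits_csv",
    "profiles_to_frame",
]


class ClassificationError(ValueError):
    """Raised when a response category cannot be computed from the inputs."""


class ResponseCategory(enum.IntEnum):
    """Treatment-response grade with its fixed nominal code."""

    GOOD = 1
    MODERATE = 2
    POOR = 3


@dataclass(frozen=True)
class ResponseRuleSet:
    """Thresholds of the MCID response definitions.

    Lung-function cuts are in predicted-fraction points (0.10 = 10 % of
    predicted); FENO cuts in ppb except ``feno_rel_change`` (fraction).
    """

    fev1_good_delta: float = 0.10
    fev1_poor_delta: float = -0.10
    mef50_good_delta: float = 0.15
    mef50_poor_delta: float = -0.15
    feno_high_cut_child: float = 35.0
    feno_high_cut_adult: float = 50.0
    feno_age_cut: float = 12.0
    feno_rel_change: float = 0.20
    feno_abs_change: float = 10.0
    #: use the published (internally inconsistent) GOOD wording for FENO
    literal_feno_good: bool = False

    def __post_init__(self) -> None:
        if not (self.fev1_good_delta > 0 > self.fev1_poor_delta):
            raise ValueError("FEV1 good cut must be > 0 > poor cut")
        if not (self.mef50_good_delta > 0 > self.mef50_poor_delta):
            raise ValueError("MEF50 good cut must be > 0 > poor cut")
        if min(self.feno_high_cut_child, self.feno_high_cut_adult,
               self.feno_abs_change) <= 0:
            raise ValueError("FENO cuts must be positive")
        if not 0 < self.feno_rel_change < 1:
            raise ValueError("feno_rel_change must lie in (0, 1)")

    def feno_high_cut(self, age_years: float) -> float:
        """Age-dependent high-baseline FENO cut (ppb)."""
        return (self.feno_high_cut_child if age_years < self.feno_age_cut
                else self.feno_high_cut_adult)


@dataclass(frozen=True, order=True)
class Interval:
    """A start/end visit-index pair over which response is assessed."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if (self.start, self.end) not in {(0, 1), (1, 2), (2, 3), (0, 2), (0, 3)}:
            raise ValueError(f"invalid visit interval ({self.start}, {self.end})")

    @property
    def kind(self) -> str:
        return "consecutive" if self.end - self.start == 1 else "cumulative"

    def __str__(self) -> str:  # used in feature names and CSV output
        return f"v{self.start}_v{self.end}"


CONSECUTIVE_INTERVALS = (Interval(0, 1), Interval(1, 2), Interval(2, 3))
CUMULATIVE_INTERVALS = (Interval(0, 2), Interval(0, 3))
ALL_INTERVALS = CONSECUTIVE_INTERVALS + CUMULATIVE_INTERVALS

#: metric order mirrors the published per-interval table layout
METRICS = ("FEV1", "FENO", "CTRL", "MEF50")

#: fixed column order of the coded clustering matrix: interval-major,
#: metric-minor; 4 metrics x 3 consecutive intervals = 12 features
CLUSTERING_FEATURES = tuple(
    f"{metric}_{iv}" for iv in CONSECUTIVE_INTERVALS for metric in METRICS
)


@dataclass
class VisitRecord:
    """Measurements from one clinical visit; ``None`` marks a missing value."""

    patient_id: str
    visit_index: int
    fev1_pp: Optional[float] = None
    mef50_pp: Optional[float] = None
    feno_ppb: Optional[float] = None
    control_level: Optional[int] = None
    ics_dose_tier: Optional[int] = None
    laba: Optional[bool] = None
    ltra: Optional[bool] = None
    saba_used: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.visit_index not in (0, 1, 2, 3):
            raise ValueError(f"visit_index must be 0..3, got {self.visit_index}")
        if self.feno_ppb is not None and self.feno_ppb < 0:
            raise ValueError(f"negative FENO for patient {self.patient_id}")
        if self.control_level is not None and self.control_level not in (0, 1, 2):
            raise ValueError(
                f"control_level must be 0, 1 or 2, got {self.control_level} "
                f"(patient {self.patient_id})"
            )


@dataclass
class ResponseProfile:
    """Per-patient map (metric, interval) -> category; absent key = missing."""

    patient_id: str
    entries: dict  # (metric, Interval) -> ResponseCategory

    def get(self, metric: str, interval: Interval) -> Optional[ResponseCategory]:
        return self.entries.get((metric, interval))


@dataclass
class CodedMatrix:
    """Complete-case patients x 12 consecutive response features, codes 1..3."""

    patient_ids: list
    feature_names: tuple
    values: np.ndarray  # (n_patients, 12) int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("value shape does not match feature names")
        if not np.isin(self.values, (1, 2, 3)).all():
            raise ValueError("coded matrix cells must be in {1, 2, 3}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.patient_ids, name="patient_id"),
                            columns=list(self.feature_names))


# ---------------------------------------------------------------------------
# classification rules


def _check_finite(value: float, what: str, context: str = "") -> None:
    if value is None or not math.isfinite(value):
        raise ClassificationError(f"non-finite {what} {context}".strip())


def classify_lungfunction(delta_pp: float, good_cut: float,
                          poor_cut: float) -> ResponseCategory:
    """Grade a lung-function change (predicted-fraction points).

    GOOD if ``delta_pp >= good_cut``, POOR if ``delta_pp <= poor_cut``,
    MODERATE on the open interval between the cuts.
    """
    _check_finite(delta_pp, "lung-function delta")
    if not good_cut > 0 > poor_cut:
        raise ValueError("good_cut must be > 0 > poor_cut")
    if delta_pp >= good_cut:
        return ResponseCategory.GOOD
    if delta_pp <= poor_cut:
        return ResponseCategory.POOR
    return ResponseCategory.MODERATE


def classify_feno(feno_start: float, feno_end: float, age_years: float,
                  rules: ResponseRuleSet = ResponseRuleSet()) -> ResponseCategory:
    """Grade a FENO change using the high/low-baseline branch rules.

    The branch is selected from the interval's *start* value against the
    age-dependent cut.  High branch: relative change beyond +/-20 % is
    POOR/GOOD.  Low branch: absolute change beyond +/-10 ppb is POOR/GOOD.
    Within-band changes are MODERATE.
    """
    _check_finite(feno_start, "FENO start")
    _check_finite(feno_end, "FENO end")
    if feno_start < 0 or feno_end < 0:
        raise ClassificationError("FENO values must be non-negative")
    high_cut = rules.feno_high_cut(age_years)
    if feno_start > high_cut:
        rel = (feno_end - feno_start) / feno_start
        if rel > rules.feno_rel_change:
            return ResponseCategory.POOR
        if rules.literal_feno_good:
            # published wording: "decrease < 20 %" (overlaps MODERATE)
            if rel < 0:
                return ResponseCategory.GOOD
        elif rel < -rules.feno_rel_change:
            return ResponseCategory.GOOD
        return ResponseCategory.MODERATE
    diff = feno_end - feno_start
    if diff > rules.feno_abs_change:
        return ResponseCategory.POOR
    if rules.literal_feno_good:
        # published wording: "increase < 10 ppb" (overlaps MODERATE)
        if 0 < diff <= rules.feno_abs_change:
            return ResponseCategory.GOOD
    elif diff < -rules.feno_abs_change:
        return ResponseCategory.GOOD
    return ResponseCategory.MODERATE


def classify_control(level_start: int, level_end: int) -> ResponseCategory:
    """Grade a change in the 3-level GINA control classification."""
    for level in (level_start, level_end):
        if level not in (0, 1, 2):
            raise ClassificationError(f"control level must be 0, 1 or 2, got {level}")
    if level_end < level_start:
        return ResponseCategory.GOOD
    if level_end > level_start:
        return ResponseCategory.POOR
    return ResponseCategory.MODERATE


# ---------------------------------------------------------------------------
# profile assembly and matrix encoding


def _classify_interval(metric: str, start: VisitRecord, end: VisitRecord,
                       age_years: float, rules: ResponseRuleSet
                       ) -> Optional[ResponseCategory]:
    if metric == "FEV1":
        if start.fev1_pp is None or end.fev1_pp is None:
            return None
        return classify_lungfunction(end.fev1_pp - start.fev1_pp,
                                     rules.fev1_good_delta, rules.fev1_poor_delta)
    if metric == "MEF50":
        if start.mef50_pp is None or end.mef50_pp is None:
            return None
        return classify_lungfunction(end.mef50_pp - start.mef50_pp,
                                     rules.mef50_good_delta, rules.mef50_poor_delta)
    if metric == "FENO":
        if start.feno_ppb is None or end.feno_ppb is None:
            return None
        return classify_feno(start.feno_ppb, end.feno_ppb, age_years, rules)
    if metric == "CTRL":
        if start.control_level is None or end.control_level is None:
            return None
        return classify_control(start.control_level, end.control_level)
    raise ValueError(f"unknown metric {metric!r}")


def build_response_profile(visits: Sequence[VisitRecord], age_years: float,
                           rules: ResponseRuleSet = ResponseRuleSet()
                           ) -> ResponseProfile:
    """Assemble a patient's (metric, interval) response-category map.

    Every valid interval whose two endpoint visits carry the required
    measurement gets an entry; anything else is left missing.  Cumulative
    intervals depend only on their endpoint visits.
    """
    if not visits:
        raise ValueError("no visits supplied")
    by_index: dict[int, VisitRecord] = {}
    pid = visits[0].patient_id
    for v in visits:
        if v.patient_id != pid:
            raise ValueError("visits mix patient ids")
        if v.visit_index in by_index:
            raise ValueError(f"duplicate visit {v.visit_index} for patient {pid}")
        by_index[v.visit_index] = v
    entries = {}
    for interval in ALL_INTERVALS:
        start, end = by_index.get(interval.start), by_index.get(interval.end)
        if start is None or end is None:
            continue
        for metric in METRICS:
            cat = _classify_interval(metric, start, end, age_years, rules)
            if cat is not None:
                entries[(metric, interval)] = cat
    return ResponseProfile(patient_id=pid, entries=entries)


def encode_matrix(profiles: Iterable[ResponseProfile]
                  ) -> tuple[CodedMatrix, list]:
    """Build the complete-case coded clustering matrix.

    Patients missing any of the 12 consecutive (metric, interval) entries
    are excluded and their ids returned alongside the matrix.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no response profiles supplied")
    keys = [(metric, iv) for iv in CONSECUTIVE_INTERVALS for metric in METRICS]
    rows, ids, excluded = [], [], []
    for prof in profiles:
        cats = [prof.entries.get(k) for k in keys]
        if any(c is None for c in cats):
            excluded.append(prof.patient_id)
            continue
        ids.append(prof.patient_id)
        rows.append([int(c) for c in cats])
    if not rows:
        raise ValueError("no complete-case patients after exclusion")
    matrix = CodedMatrix(patient_ids=ids, feature_names=CLUSTERING_FEATURES,
                         values=np.array(rows, dtype=int))
    return matrix, excluded


# ---------------------------------------------------------------------------
# I/O

VISIT_COLUMNS = ["patient_id", "visit_index", "fev1_pp", "mef50_pp", "feno_ppb",
                 "control_level", "ics_dose_tier", "laba", "ltra", "saba_used"]


def read_visits_csv(path) -> dict[str, list[VisitRecord]]:
    """Read a long-format visits CSV into per-patient visit lists.

    Empty fields are missing values.  Column layout is the one written by
    the synthetic-cohort generator (see ``VISIT_COLUMNS``).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = set(VISIT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"visits file missing columns: {sorted(missing_cols)}")

    def opt(value, cast):
        return None if pd.isna(value) else cast(value)

    visits: dict[str, list[VisitRecord]] = {}
    for row in df.itertuples(index=False):
        rec = VisitRecord(
            patient_id=row.patient_id,
            visit_index=int(row.visit_index),
            fev1_pp=opt(row.fev1_pp, float),
            mef50_pp=opt(row.mef50_pp, float),
            feno_ppb=opt(row.feno_ppb, float),
            control_level=opt(row.control_level, lambda x: int(float(x))),
            ics_dose_tier=opt(row.ics_dose_tier, lambda x: int(float(x))),
            laba=opt(row.laba, lambda x: bool(int(float(x)))),
            ltra=opt(row.ltra, lambda x: bool(int(float(x)))),
            saba_used=opt(row.saba_used, lambda x: bool(int(float(x)))),
        )
        visits.setdefault(rec.patient_id, []).append(rec)
    return visits


def profiles_to_frame(profiles: Iterable[ResponseProfile]) -> pd.DataFrame:
    """Long-format table of all classified entries (one row per entry)."""
    rows = []
    for prof in profiles:
        for (metric, interval), cat in sorted(
                prof.entries.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            rows.append({
                "patient_id": prof.patient_id,
                "metric": metric,
                "interval_start": interval.start,
                "interval_end": interval.end,
                "category": cat.name,
                "code": int(cat),
            })
    return pd.DataFrame(rows, columns=["patient_id", "metric", "interval_start",
                                       "interval_end", "category", "code"])
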