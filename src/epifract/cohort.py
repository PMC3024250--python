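"""Patient-level aggregation, cutpoints, categories, ICC and associations.

A patient contributes up to three tissue cores; the core with the maximum
fractal dimension represents the patient, on the rationale that it is the
core most likely to sample the least differentiated (most aggressive)
malignant tissue. Patients are stratified into low / intermediate / high
morphologic complexity by two data-oriented cutpoints: the upper quartile of
the patient-level scores and the median of the remaining lower
three-quarters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import ContractError, InsufficientDataError, UndefinedEstimateError

logger = logging.getLogger(__name__)

CATEGORIES = ("low", "intermediate", "high")

COVARIATE_LEVELS = {
    "age_group": ("<=55y", ">55y"),
    "size_group": ("<=2cm", ">2cm"),
    "grade": ("1&2", "3"),
    "node_status": ("negative", "positive"),
    "er_status": ("positive", "negative"),
    "her2_status": ("negative", "positive"),
}


@dataclass
class PatientRecord:
    """Per-patient covariates, outcome, and fractal-dimension scores.

    Binary covariates are coded 0 for the reference level and 1 for the
    adverse level (see COVARIATE_LEVELS); ``None`` marks a missing value.
    ``dss_event`` flags death from the cancer under study, ``os_event`` death
    from any cause, both over ``followup_years`` from diagnosis.
    """

    patient_id: str
    core_fds: list[float] = field(default_factory=list)
    age_group: Optional[int] = None
    size_group: Optional[int] = None
    grade: Optional[int] = None
    node_status: Optional[int] = None
    er_status: Optional[int] = None
    her2_status: Optional[int] = None
    followup_years: float = 0.0
    dss_event: int = 0
    os_event: int = 0
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.followup_years < 0:
            raise ContractError("followup_years must be >= 0")
        if self.dss_event and not self.os_event:
            raise ContractError("a disease-specific death is also an overall death")

    @property
    def patient_fd(self) -> Optional[float]:
        return max(self.core_fds) if self.core_fds else None


@dataclass(frozen=True)
class Cutpoints:
    """The two boundaries defining the low / intermediate / high strata."""

    c_low_int: float
    c_int_high: float

    def __post_init__(self) -> None:
        if not self.c_low_int < self.c_int_high:
            raise ContractError("cutpoints must satisfy c_low_int < c_int_high")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    n_patients: int
    n_cores: int


def aggregate_patient(core_fds: Sequence[float]) -> float:
    """Patient-level score: the maximum fractal dimension over the cores."""
    if len(core_fds) == 0:
        raise InsufficientDataError("patient has no evaluable cores")
    return float(max(core_fds))


def select_cutpoints(fds: Sequence[float]) -> Cutpoints:
    """Data-oriented cutpoints: upper quartile, then median of the lower 3/4.

    Quantiles use linear interpolation between order statistics (the common
    "type 7" convention); "lower three-quarters" includes values equal to the
    75th percentile.
    """
    values = np.asarray(fds, dtype=np.float64)
    if values.size < 8:
        raise InsufficientDataError("need at least 8 values to place two cutpoints")
    c_high = float(np.percentile(values, 75.0))
    lower = values[values <= c_high]
    c_low = float(np.median(lower))
    if not c_low < c_high:
        raise InsufficientDataError(
            "degenerate quantiles: cutpoints coincide (values too concentrated)"
        )
    return Cutpoints(c_low, c_high)


def categorize(fd: float, cutpoints: Cutpoints) -> str:
    """low iff fd < c_low_int; high iff fd > c_int_high; else intermediate.

    Both boundaries belong to the intermediate stratum, matching the printed
    convention "< c1", "c1 - c2", "> c2".
    """
    if fd < cutpoints.c_low_int:
        return "low"
    if fd > cutpoints.c_int_high:
        return "high"
    return "intermediate"


def icc_cores(records: Iterable[PatientRecord]) -> ICCResult:
    """One-way random-effects intraclass correlation of core FDs.

    Patients are the groups, cores the replicates; the one-way ANOVA
    decomposition with the unbalanced-group correction
    n0 = (N - sum(n_i^2)/N) / (k - 1) gives
    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW).
    """
    groups = [np.asarray(r.core_fds, dtype=np.float64) for r in records]
    groups = [g for g in groups if g.size > 0]
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("need at least 2 patients with cores")
    sizes = np.array([g.size for g in groups])
    n_total = int(sizes.sum())
    if n_total == k:
        raise UndefinedEstimateError(
            "all patients have a single core; within-patient variance undefined"
        )
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    n0 = (n_total - float(np.sum(sizes**2)) / n_total) / (k - 1)
    if msw == 0.0:
        icc = 1.0 if msb > 0 else 0.0
    else:
        icc = (msb - msw) / (msb + (n0 - 1.0) * msw)
    return ICCResult(float(icc), k, n_total)


def association_table(
    records: Iterable[PatientRecord], covariate: str
) -> tuple[pd.DataFrame, float, float]:
    """Covariate-level x FD-category contingency table with Pearson chi-square.

    The chi-square uses no continuity correction. Returns (table, statistic,
    p-value); the table rows are covariate levels, columns FD categories, and
    a ``column_pct`` attribute carries the within-category percentages.
    """
    if covariate not in COVARIATE_LEVELS:
        raise ContractError(f"unknown covariate {covariate!r}")
    rows = []
    for r in records:
        value = getattr(r, covariate)
        if value is None or r.category is None:
            continue
        rows.append((COVARIATE_LEVELS[covariate][int(value)], r.category))
    if not rows:
        raise InsufficientDataError("no complete observations for the covariate")
    df = pd.DataFrame(rows, columns=[covariate, "category"])
    table = pd.crosstab(df[covariate], df["category"])
    table = table.reindex(columns=[c for c in CATEGORIES if c in table.columns])
    table = table.reindex(index=list(COVARIATE_LEVELS[covariate]), fill_value=0)
    if (table.sum(axis=0) == 0).any() or table.shape[1] < len(CATEGORIES):
        raise InsufficientDataError("an FD category is empty; table is degenerate")
    stat, p, _, expected = chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        logger.warning(
            "association table for %s has expected cell counts < 5", covariate
        )
    table.attrs["column_pct"] = (100.0 * table / table.sum(axis=0)).round(1)
    return table, float(stat), float(p)


# ---------------------------------------------------------------------------
# tabular interchange
# ---------------------------------------------------------------------------

_FRAME_COLUMNS = [
    "patient_id",
    "patient_fd",
    "category",
    "age_group",
    "size_group",
    "grade",
    "node_status",
    "er_status",
    "her2_status",
    "followup_years",
    "dss_event",
    "os_event",
]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records to the cohort table used by the survival module."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "patient_fd": r.patient_fd,
                "category": r.category,
                "age_group": r.age_group,
                "size_group": r.size_group,
                "grade": r.grade,
                "node_status": r.node_status,
                "er_status": r.er_status,
                "her2_status": r.her2_status,
                "followup_years": r.followup_years,
                "dss_event": r.dss_event,
                "os_event": r.os_event,
            }
        )
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Rebuild records from a cohort table (core-level FDs collapse to one)."""
    records = []
    for _, row in df.iterrows():
        fd = row.get("patient_fd")
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            core_fds=[float(fd)] if pd.notna(fd) else [],
            followup_years=float(row["followup_years"]),
            dss_event=int(row["dss_event"]),
            os_event=int(row["os_event"]),
            **{
                name: (None if pd.isna(row[name]) else int(row[name]))
                for name in COVARIATE_LEVELS
            },
        )
        cat = row.get("category")
        rec.category = None if pd.isna(cat) else str(cat)
        records.append(rec)
    return records
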