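"""Blood-smear vacuolization scoring.

Manual smear assessment quantifies lymphocyte vacuolization along two axes:
the percentage of vacuolated lymphocytes among 100 counted, and the number of
vacuoles per vacuolated lymphocyte in at most 20 such cells, each assessed
independently by (nominally three) observers.  A cell counts as "vacuolated"
when it shows at least one vacuole.  Observer percentages are combined by
arithmetic mean; per-cell vacuole counts are pooled across observers and
summarised as median and min-max range, matching the reporting style
"median X % (range a-b)".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import SeverityClass

__all__ = [
    "SmearObservation",
    "VacuolizationScore",
    "score_sample",
    "score_cohort",
    "two_axis_summary",
    "log10_pct_with_floor",
    "observations_from_frame",
]

#: Display floor (in %) replacing 0 on the log10 percentage axis.
LOG_FLOOR_PCT = 0.5


@dataclass
class SmearObservation:
    """One observer's counts on one smear sample."""

    sample_id: str
    observer_id: int
    n_counted: int
    n_vacuolated: int
    vacuole_counts: list[int]

    def __post_init__(self) -> None:
        if not 0 <= self.n_vacuolated <= self.n_counted:
            raise ValueError(
                f"n_vacuolated={self.n_vacuolated} outside 0..{self.n_counted}"
            )
        if len(self.vacuole_counts) > min(20, self.n_vacuolated):
            raise ValueError(
                "vacuole_counts longer than min(20, n_vacuolated)"
            )
        if any(c < 1 for c in self.vacuole_counts):
            raise ValueError("each vacuole count must be >= 1")


@dataclass
class VacuolizationScore:
    """Observer-aggregated two-axis vacuolization score for one sample."""

    sample_id: str
    pct_vacuolated: float
    vacuoles_per_cell_median: float  # NaN when no per-cell counts available
    vacuoles_per_cell_min: float
    vacuoles_per_cell_max: float
    n_observers: int


def score_sample(observations: Sequence[SmearObservation]) -> VacuolizationScore:
    """Aggregate one sample's observer counts into a two-axis score.

    ``pct_vacuolated`` is the mean over observers of ``100 * n_vacuolated /
    n_counted``; vacuole counts are pooled across observers before taking the
    median and range.  All observations must share a sample_id.  A sample
    with vacuolated cells but no per-cell counts yields missing (NaN) per-cell
    statistics with a warning.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    ids = {o.sample_id for o in obs}
    if len(ids) != 1:
        raise ValueError(f"mixed sample_ids in one scoring call: {sorted(ids)}")
    pct = float(np.mean([100.0 * o.n_vacuolated / o.n_counted for o in obs]))
    pooled = [c for o in obs for c in o.vacuole_counts]
    if pooled:
        med, lo, hi = (
            float(np.median(pooled)),
            float(min(pooled)),
            float(max(pooled)),
        )
    else:
        if any(o.n_vacuolated > 0 for o in obs):
            warnings.warn(
                f"sample {obs[0].sample_id}: vacuolated cells counted but no "
                "per-cell vacuole counts; per-cell statistics reported missing",
                stacklevel=2,
            )
        med = lo = hi = float("nan")
    return VacuolizationScore(
        sample_id=obs[0].sample_id,
        pct_vacuolated=pct,
        vacuoles_per_cell_median=med,
        vacuoles_per_cell_min=lo,
        vacuoles_per_cell_max=hi,
        n_observers=len(obs),
    )


def _parse_counts(text: object) -> list[int]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    s = str(text).strip()
    if not s:
        return []
    return [int(tok) for tok in s.split(";") if tok.strip()]


def observations_from_frame(frame: pd.DataFrame) -> list[SmearObservation]:
    """Build :class:`SmearObservation` objects from cohort-table rows.

    Expects the cohort CSV schema (``patient_id, age_years, observer_id,
    n_counted, n_vacuolated, vacuole_counts``); the sample_id is
    ``patient_id@age``.
    """
    out = []
    for _, r in frame.iterrows():
        out.append(
            SmearObservation(
                sample_id=f"{r['patient_id']}@{float(r['age_years']):.6g}",
                observer_id=int(r["observer_id"]),
                n_counted=int(r["n_counted"]),
                n_vacuolated=int(r["n_vacuolated"]),
                vacuole_counts=_parse_counts(r.get("vacuole_counts")),
            )
        )
    return out


def score_cohort(
    cohort: pd.DataFrame, patients: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Score every sample of a cohort table, one row per sample.

    ``cohort`` is the observer-level table (cohort CSV schema).  Metadata
    (``class``/``genotype``) may be embedded as columns or supplied through a
    ``patients`` table with columns ``patient_id, class, genotype``; samples
    whose patient lacks metadata raise an error naming the offending IDs.
    The output keeps the repeated-measures structure (patient_id, age_years)
    needed by the severity model.
    """
    if cohort.empty:
        raise ValueError("empty cohort table")
    cohort = cohort.copy()
    if "class" not in cohort.columns or cohort["class"].isna().any():
        if patients is None:
            missing = sorted(
                cohort.loc[
                    cohort.get("class", pd.Series(np.nan, index=cohort.index))
                    .isna(),
                    "patient_id",
                ].unique()
            )
            raise ValueError(f"samples without metadata: {missing}")
        meta = patients[["patient_id", "class", "genotype"]]
        cohort = cohort.drop(columns=["class", "genotype"], errors="ignore")
        cohort = cohort.merge(meta, on="patient_id", how="left")
        if cohort["class"].isna().any():
            missing = sorted(
                cohort.loc[cohort["class"].isna(), "patient_id"].unique()
            )
            raise ValueError(f"samples without metadata: {missing}")

    rows = []
    for (pid, age), grp in cohort.groupby(["patient_id", "age_years"], sort=True):
        score = score_sample(observations_from_frame(grp))
        rows.append(
            {
                "sample_id": score.sample_id,
                "patient_id": pid,
                "severity_class": SeverityClass.from_label(
                    grp["class"].iloc[0]
                ).value,
                "genotype": grp["genotype"].iloc[0]
                if "genotype" in grp.columns
                else "",
                "age_years": float(age),
                "n_observers": score.n_observers,
                "pct_vacuolated": score.pct_vacuolated,
                "vacuoles_per_cell_median": score.vacuoles_per_cell_median,
                "vacuoles_per_cell_min": score.vacuoles_per_cell_min,
                "vacuoles_per_cell_max": score.vacuoles_per_cell_max,
            }
        )
    return pd.DataFrame(rows)


def log10_pct_with_floor(
    pct: Iterable[float], floor: float = LOG_FLOOR_PCT
) -> tuple[np.ndarray, np.ndarray]:
    """log10 of percentages with zeros floored for display.

    A log axis is undefined at 0 %, so zero values are plotted at ``floor``
    (default 0.5 %) and flagged.  Returns ``(log10_values, floored_flags)``.
    """
    arr = np.asarray(list(pct), dtype=float)
    floored = arr <= 0
    return np.log10(np.where(floored, floor, arr)), floored


def two_axis_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-class centroid and range on the two vacuolization axes.

    Axes: percentage of vacuolated lymphocytes (displayed on log10 with a
    floor for zeros) and median vacuoles per affected lymphocyte (linear).
    Returns one row per severity class with centroids (means over samples),
    min-max ranges, the log10-transformed centroid for plotting, and the
    number of zero-percentage samples that would be floored on the log axis.
    """
    if scores.empty:
        raise ValueError("empty scores table")
    rows = []
    for cls, grp in scores.groupby("severity_class", sort=False):
        pct = grp["pct_vacuolated"].to_numpy(dtype=float)
        vpc = grp["vacuoles_per_cell_median"].to_numpy(dtype=float)
        log_pct, floored = log10_pct_with_floor(pct)
        rows.append(
            {
                "severity_class": cls,
                "n_samples": len(grp),
                "pct_center": float(pct.mean()),
                "pct_min": float(pct.min()),
                "pct_max": float(pct.max()),
                "vpc_center": float(np.nanmean(vpc)) if not np.all(np.isnan(vpc))
                else float("nan"),
                "vpc_min": float(np.nanmin(vpc)) if not np.all(np.isnan(vpc))
                else float("nan"),
                "vpc_max": float(np.nanmax(vpc)) if not np.all(np.isnan(vpc))
                else float("nan"),
                "log10_pct_center": float(log_pct.mean()),
                "n_floored": int(floored.sum()),
            }
        )
    order = {c.value: c.ordinal_rank for c in SeverityClass}
    df = pd.DataFrame(rows)
    return (
        df.sort_values("severity_class", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )
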