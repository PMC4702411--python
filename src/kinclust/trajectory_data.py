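"""Containers and long-format I/O for longitudinal biomarker cohorts.

Input files are delimited text (CSV, or TSV by extension) with a header and
columns ``subject_id,time_days,hcg`` plus an optional per-subject binary
``disease`` column (the gold-standard label).  Reading applies the study
inclusion filter: measurements beyond the follow-up horizon (default 21
days) are dropped, and subjects must retain at least ``min_measurements``
(default 2) to be kept.

hCG concentrations must be strictly positive — the model works on the
natural-log scale, so values at or below 0 (e.g. "undetectable") must be
pre-imputed to the assay detection limit upstream.

Disease labels are carried by the :class:`Cohort` but deliberately absent
from :meth:`Cohort.flat`, the array view that all fitting code consumes:
labels can never leak into estimation, only into diagnostics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Measurement",
    "Trajectory",
    "Cohort",
    "FlatCohort",
    "CohortDataError",
    "read_cohort",
    "write_cohort",
    "cohort_summary",
    "DEFAULT_HORIZON",
]

DEFAULT_HORIZON = 21.0
REQUIRED_COLUMNS = ("subject_id", "time_days", "hcg")
DEDUP_POLICIES = ("first", "mean", "error")


class CohortDataError(ValueError):
    """Invalid or unusable cohort input."""


@dataclass(frozen=True)
class Measurement:
    """One biomarker measurement: time in days since curettage, hCG in IU/L."""

    time: float
    value: float

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise CohortDataError(f"time must be a non-negative real, got {self.time}")
        if not np.isfinite(self.value) or self.value <= 0:
            raise CohortDataError(
                f"hCG must be strictly positive (log scale), got {self.value}"
            )

    @property
    def log_value(self) -> float:
        return math.log(self.value)


@dataclass(frozen=True)
class Trajectory:
    """One subject's measurement series, sorted by strictly increasing time."""

    subject_id: str
    measurements: tuple
    disease_label: Optional[int] = None

    def __post_init__(self):
        ms = tuple(self.measurements)
        object.__setattr__(self, "measurements", ms)
        if len(ms) < 2:
            raise CohortDataError(
                f"subject {self.subject_id!r}: at least 2 measurements required"
            )
        times = [m.time for m in ms]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise CohortDataError(
                f"subject {self.subject_id!r}: measurement times must be "
                "strictly increasing"
            )
        if self.disease_label is not None and self.disease_label not in (0, 1):
            raise CohortDataError(
                f"subject {self.subject_id!r}: disease label must be 0/1"
            )

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.measurements])

    @property
    def log_values(self) -> np.ndarray:
        return np.array([m.log_value for m in self.measurements])


@dataclass(frozen=True)
class FlatCohort:
    """Array view of a cohort for vectorized computation (no labels).

    ``offsets`` is CSR-style: rows of subject i are
    ``t[offsets[i]:offsets[i+1]]``.
    """

    t: np.ndarray
    y: np.ndarray  # log-hCG
    offsets: np.ndarray
    n_per_subject: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.n_per_subject)

    @property
    def n_measurements(self) -> int:
        return len(self.t)

    def rows_of(self, i: int) -> slice:
        return slice(self.offsets[i], self.offsets[i + 1])


@dataclass(frozen=True)
class Cohort:
    trajectories: tuple

    def __post_init__(self):
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        if not self.trajectories:
            raise CohortDataError("no subjects after filtering")
        ids = [t.subject_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise CohortDataError("duplicate subject ids in cohort")

    @property
    def n_subjects(self) -> int:
        return len(self.trajectories)

    @property
    def n_measurements(self) -> int:
        return sum(t.n_measurements for t in self.trajectories)

    @property
    def subject_ids(self) -> list:
        return [t.subject_id for t in self.trajectories]

    @property
    def has_labels(self) -> bool:
        return all(t.disease_label is not None for t in self.trajectories)

    def disease_labels(self) -> np.ndarray:
        """0/1 labels per subject; raises if any subject is unlabeled."""
        if not self.has_labels:
            raise CohortDataError("cohort has subjects without disease labels")
        return np.array([t.disease_label for t in self.trajectories], dtype=int)

    def flat(self) -> FlatCohort:
        n_per = np.array([t.n_measurements for t in self.trajectories], dtype=np.intp)
        offsets = np.concatenate(([0], np.cumsum(n_per)))
        t = np.concatenate([tr.times for tr in self.trajectories])
        y = np.concatenate([tr.log_values for tr in self.trajectories])
        return FlatCohort(t=t, y=y, offsets=offsets, n_per_subject=n_per)

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort(tuple(self.trajectories[i] for i in indices))


def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(
    path,
    horizon: float = DEFAULT_HORIZON,
    min_measurements: int = 2,
    dedup: str = "first",
) -> Cohort:
    """Read a long-format cohort file and apply the inclusion filter.

    Rows with ``time_days`` beyond ``horizon`` are dropped first, then
    subjects with fewer than ``min_measurements`` remaining rows.  Duplicate
    (subject, time) pairs are resolved by ``dedup``: ``"first"`` keeps the
    first row in file order, ``"mean"`` averages on the log scale,
    ``"error"`` refuses the file.
    """
    path = Path(path)
    if dedup not in DEDUP_POLICIES:
        raise ValueError(f"dedup must be one of {DEDUP_POLICIES}, got {dedup!r}")
    try:
        df = pd.read_csv(path, sep=_separator_for(path), dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        raise CohortDataError("no subjects after filtering") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortDataError(f"missing required columns: {missing}")

    bad = df[~np.isfinite(df["hcg"]) | (df["hcg"] <= 0)]
    if len(bad):
        ids = sorted(set(bad["subject_id"].astype(str)))
        raise CohortDataError(
            f"non-positive or non-finite hCG values for subjects {ids}; "
            "pre-impute undetectable values to the assay detection limit"
        )
    if (df["time_days"] < 0).any():
        ids = sorted(set(df.loc[df["time_days"] < 0, "subject_id"].astype(str)))
        raise CohortDataError(f"negative times for subjects {ids}")

    df = df[df["time_days"] <= horizon]

    dup_mask = df.duplicated(subset=["subject_id", "time_days"], keep=False)
    if dup_mask.any():
        if dedup == "error":
            ids = sorted(set(df.loc[dup_mask, "subject_id"].astype(str)))
            raise CohortDataError(
                f"duplicate (subject, time) rows for subjects {ids}; "
                "resolve with dedup='first' or dedup='mean'"
            )
        if dedup == "mean":
            keys = ["subject_id", "time_days"]
            logm = (
                np.log(df["hcg"])
                .groupby([df["subject_id"], df["time_days"]])
                .transform("mean")
            )
            df = df.assign(hcg=np.exp(logm)).drop_duplicates(subset=keys, keep="first")
        else:  # first in file order (pandas keeps original row order)
            df = df.drop_duplicates(subset=["subject_id", "time_days"], keep="first")

    has_disease = "disease" in df.columns
    trajectories = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_days", kind="mergesort")
        if len(grp) < min_measurements:
            continue
        label = None
        if has_disease:
            vals = set(int(v) for v in grp["disease"].dropna())
            if len(vals) > 1:
                raise CohortDataError(f"conflicting disease labels for {sid!r}")
            label = vals.pop() if vals else None
        trajectories.append(
            Trajectory(
                subject_id=str(sid),
                measurements=tuple(
                    Measurement(time=float(r.time_days), value=float(r.hcg))
                    for r in grp.itertuples()
                ),
                disease_label=label,
            )
        )
    if not trajectories:
        raise CohortDataError("no subjects after filtering")
    return Cohort(tuple(trajectories))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to long-format delimited text (round-trippable)."""
    path = Path(path)
    rows = []
    for tr in cohort.trajectories:
        for m in tr.measurements:
            row = {"subject_id": tr.subject_id, "time_days": m.time, "hcg": m.value}
            if tr.disease_label is not None:
                row["disease"] = tr.disease_label
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_separator_for(path), index=False)


def cohort_summary(cohort: Cohort) -> dict:
    """Per-subject measurement-count summary plus prevalence when labeled."""
    counts = np.array([t.n_measurements for t in cohort.trajectories])
    out = {
        "n_subjects": cohort.n_subjects,
        "n_measurements": int(counts.sum()),
        "measurements_per_subject": {
            "median": float(np.median(counts)),
            "min": int(counts.min()),
            "max": int(counts.max()),
        },
    }
    if cohort.has_labels:
        labels = cohort.disease_labels()
        out["n_diseased"] = int(labels.sum())
        out["prevalence_pct"] = float(100.0 * labels.mean())
    return out
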