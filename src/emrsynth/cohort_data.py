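"""Longitudinal treated-cohort data handling.

A treated cohort extracted from an electronic medical record consists of
repeated cognitive-score observations (MMSE-style, 0-30, possibly scored out
of a reduced denominator when not all items could be asked) at times measured
in years relative to the offer of treatment (t = 0), together with one row of
baseline characteristics per subject used to flag eligibility for the pooled
randomized trials.

The in-memory container is :class:`CohortDataset`, a thin pair of pandas
DataFrames (``records`` long format, ``baselines`` one row per subject) plus a
subject-level eligibility map ``eligible``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MAX_SCORE = 30

RECORD_COLUMNS = ["subject_id", "time_years", "numerator", "denominator"]
BASELINE_REQUIRED = ["subject_id"]

#: default inclusion rules: at least 24 of 30 items asked, observation within
#: one year before to three years after the treatment offer (closed bounds)
DEFAULT_MIN_DENOMINATOR = 24
DEFAULT_WINDOW = (-1.0, 3.0)


class InvalidRecordError(ValueError):
    """An outcome record violates the numerator/denominator contract."""


class ConfigError(ValueError):
    """An eligibility-criteria config references an unknown field or op."""


def standardize_score(numerator: int, denominator: int) -> float:
    """Adjusted 0-30 score: numerator / denominator * 30, unrounded.

    Scores recorded out of a reduced denominator (e.g. 24/29 when an item
    could not be asked) are rescaled to the full 30-point range so that all
    observations are comparable.
    """
    if denominator <= 0:
        raise InvalidRecordError(f"denominator must be positive, got {denominator}")
    if numerator < 0 or numerator > denominator:
        raise InvalidRecordError(
            f"numerator {numerator} outside [0, denominator={denominator}]"
        )
    if denominator > MAX_SCORE:
        raise InvalidRecordError(f"denominator {denominator} exceeds {MAX_SCORE}")
    return numerator / denominator * MAX_SCORE


@dataclass
class CohortDataset:
    """Per-subject longitudinal adjusted scores with eligibility flags.

    Attributes
    ----------
    records : DataFrame with columns ``subject_id, time_years, numerator,
        denominator, adjusted_score`` (one row per observation).
    baselines : DataFrame with one row per subject; must cover every subject
        appearing in ``records``.
    eligible : mapping subject_id -> bool (the trial-eligibility indicator
        S_i); may be empty until :func:`flag_eligibility` is applied.
    """

    records: pd.DataFrame
    baselines: pd.DataFrame
    eligible: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if "adjusted_score" not in self.records.columns:
            self.records = self.records.assign(
                adjusted_score=[
                    standardize_score(n, d)
                    for n, d in zip(self.records.numerator, self.records.denominator)
                ]
            )
        record_subjects = set(self.records.subject_id)
        baseline_subjects = set(self.baselines.subject_id)
        orphans = record_subjects - baseline_subjects
        if orphans:
            raise ValueError(
                f"{len(orphans)} record subject(s) missing from baselines, "
                f"e.g. {sorted(orphans)[:3]}"
            )

    @property
    def n_subjects(self) -> int:
        return self.records.subject_id.nunique()

    @property
    def n_records(self) -> int:
        return len(self.records)

    def eligible_array(self) -> np.ndarray:
        """Eligibility flags aligned with ``records`` rows."""
        return self.records.subject_id.map(self.eligible).to_numpy(dtype=bool)


def apply_inclusion_filters(
    dataset: CohortDataset,
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> CohortDataset:
    """Retain records with denominator >= ``min_denominator`` observed inside
    the closed window ``[t_lo, t_hi]`` around treatment offer.

    Subjects keeping at least one record remain in the dataset (a single
    qualifying score suffices for inclusion); their baseline rows and
    eligibility flags are carried over. Idempotent.
    """
    t_lo, t_hi = window
    if not (np.isfinite(t_lo) and np.isfinite(t_hi)) or not t_lo < t_hi:
        raise ValueError(f"invalid window {window}")
    rec = dataset.records
    keep = (
        (rec.denominator >= min_denominator)
        & (rec.time_years >= t_lo)
        & (rec.time_years <= t_hi)
    )
    filtered = rec[keep].reset_index(drop=True)
    if filtered.empty:
        logger.warning("inclusion filters removed every record")
    kept_subjects = set(filtered.subject_id)
    baselines = dataset.baselines[
        dataset.baselines.subject_id.isin(kept_subjects)
    ].reset_index(drop=True)
    eligible = {s: v for s, v in dataset.eligible.items() if s in kept_subjects}
    return CohortDataset(records=filtered, baselines=baselines, eligible=eligible)


# --- eligibility criteria -------------------------------------------------

_OPS = frozenset({"range", "in_set", "equals"})


def _check_predicate(value, op: str, args):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None  # missing
    if op == "range":
        lo, hi = args
        return lo <= value <= hi
    if op == "in_set":
        return value in set(args)
    if op == "equals":
        return value == args
    raise ConfigError(f"unknown op {op!r}")


def flag_eligibility(
    baselines: pd.DataFrame,
    criteria: Sequence[Mapping],
) -> dict:
    """Evaluate trial-eligibility predicates on subject baselines.

    ``criteria`` is a list of ``{"field": ..., "op": "range"|"in_set"|"equals",
    "args": ...}`` mappings; a subject is eligible (S_i = 1) iff every
    predicate holds. A missing required field makes the subject ineligible
    with a logged warning (conservative; keeps the flag total).
    """
    for crit in criteria:
        if crit["op"] not in _OPS:
            raise ConfigError(f"unknown op {crit['op']!r} in criteria")
        if crit["field"] not in baselines.columns:
            raise ConfigError(f"criteria reference unknown field {crit['field']!r}")
    flags: dict = {}
    for _, row in baselines.iterrows():
        verdict = True
        for crit in criteria:
            res = _check_predicate(row[crit["field"]], crit["op"], crit["args"])
            if res is None:
                logger.warning(
                    "subject %s: missing field %r, flagged ineligible",
                    row.subject_id, crit["field"],
                )
                verdict = False
                break
            if not res:
                verdict = False
                break
        flags[row.subject_id] = verdict
    return flags


def load_criteria(path: str | Path) -> list[dict]:
    """Read an eligibility-criteria list from a YAML/JSON file."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if isinstance(spec, dict):
        spec = spec.get("criteria", spec)
    if not isinstance(spec, list):
        raise ConfigError("criteria config must be a list of predicates")
    return spec


def baseline_score_from_records(records: pd.DataFrame) -> pd.Series:
    """Operational baseline score: adjusted score of the record nearest t = 0.

    Ties broken toward the earlier observation for determinism.
    """
    def nearest(group: pd.DataFrame) -> float:
        order = group.assign(_d=group.time_years.abs()).sort_values(
            ["_d", "time_years"], kind="mergesort"
        )
        return float(order.adjusted_score.iloc[0])

    return records.groupby("subject_id", sort=True).apply(nearest, include_groups=False)


# --- CSV round-trip -------------------------------------------------------

def read_cohort_csv(
    records_path: str | Path,
    baselines_path: str | Path | None = None,
) -> CohortDataset:
    """Read a cohort from CSV.

    ``records_path`` must contain the record columns; an optional ``eligible``
    column on the baselines table restores stored flags. When
    ``baselines_path`` is omitted a minimal baselines table (subject ids only)
    is synthesized from the records.
    """
    records = pd.read_csv(records_path)
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"{records_path}: missing columns {missing}")
    if records.subject_id.isna().any():
        bad = records.index[records.subject_id.isna()].tolist()
        raise ValueError(f"{records_path}: missing subject_id in rows {bad[:5]}")
    for col in ("time_years", "numerator", "denominator"):
        if not pd.api.types.is_numeric_dtype(records[col]):
            raise ValueError(f"{records_path}: column {col!r} is not numeric")
    if baselines_path is not None:
        baselines = pd.read_csv(baselines_path)
        if "subject_id" not in baselines.columns:
            raise ValueError(f"{baselines_path}: missing subject_id column")
    else:
        baselines = pd.DataFrame({"subject_id": sorted(records.subject_id.unique())})
    eligible = {}
    if "eligible" in baselines.columns:
        eligible = {
            s: bool(v)
            for s, v in zip(baselines.subject_id, baselines.eligible)
            if not pd.isna(v)
        }
    return CohortDataset(records=records, baselines=baselines, eligible=eligible)


def write_cohort_csv(
    dataset: CohortDataset,
    records_path: str | Path,
    baselines_path: str | Path | None = None,
) -> None:
    """Write a cohort to CSV; inverse of :func:`read_cohort_csv`."""
    dataset.records.to_csv(records_path, index=False)
    if baselines_path is not None:
        baselines = dataset.baselines.copy()
        if dataset.eligible:
            baselines["eligible"] = baselines.subject_id.map(dataset.eligible)
        baselines.to_csv(baselines_path, index=False)
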