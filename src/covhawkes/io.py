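"""Reading, writing and constructing cohorts from tabular event records.

Long-format schema (CSV or XLSX): one row per event with columns

    recipient_id, event_time_days, obs_length_days, <covariate columns...>

Covariates repeat across a recipient's rows; a row with an empty
``event_time_days`` declares a recipient with no events (so zero-event
recipients survive a round trip).

:func:`build_cohort` applies the study's inclusion rules to raw calendar-date
event records: for each person, the earliest overdose preceded by at least
``baseline_days`` observed-overdose-free days anchors the timeline, the index
date falls ``index_offset_days`` later, and only people with at least one
event strictly after the index date are kept.  Event times become days since
the index date and the observation horizon runs to the study end
(administrative censoring).  Every dropped recipient lands in an exclusion
log with a reason.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Cohort, RecipientHistory

__all__ = ["read_cohort", "write_cohort", "build_cohort", "encode_covariates"]

logger = logging.getLogger(__name__)

_REQUIRED = ("recipient_id", "event_time_days", "obs_length_days")


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return "xlsx"
    return "csv"


def write_cohort(cohort: Cohort, path, fmt: str | None = None) -> None:
    """Write a cohort in the long format; rows sorted by recipient id then
    event time, so two writes of the same cohort are identical."""
    rows = []
    for rec in sorted(cohort, key=lambda r: str(r.recipient_id)):
        times = rec.event_times if rec.n_events else np.array([np.nan])
        for t in times:
            row = {
                "recipient_id": rec.recipient_id,
                "event_time_days": t,
                "obs_length_days": rec.obs_length,
            }
            row.update(zip(cohort.covariate_names, rec.covariates))
            rows.append(row)
    df = pd.DataFrame(
        rows, columns=list(_REQUIRED) + list(cohort.covariate_names)
    )
    if _infer_format(path, fmt) == "xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_cohort(path, fmt: str | None = None) -> Cohort:
    """Read a long-format cohort file, validating the schema.

    Duplicate (recipient, time) rows are collapsed with a warning; an event
    at or beyond a recipient's observation length is a validation error
    naming the recipient.
    """
    if _infer_format(path, fmt) == "xlsx":
        df = pd.read_excel(path)
    else:
        # round_trip: the default float parser can be one ulp off, which
        # breaks bit-exact round trips
        df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    cov_names = tuple(c for c in df.columns if c not in _REQUIRED)

    recipients = []
    for rid, grp in df.groupby("recipient_id", sort=True):
        obs = grp["obs_length_days"].to_numpy(dtype=float)
        if not np.all(obs == obs[0]):
            raise ValueError(
                f"recipient {rid!r}: inconsistent obs_length_days "
                f"(rows {grp.index.tolist()})"
            )
        times = grp["event_time_days"].to_numpy(dtype=float)
        times = np.sort(times[~np.isnan(times)])
        uniq = np.unique(times)
        if uniq.size != times.size:
            warnings.warn(
                f"recipient {rid!r}: {times.size - uniq.size} duplicate "
                "event time(s) collapsed",
                stacklevel=2,
            )
            times = uniq
        if times.size and times[-1] >= obs[0]:
            raise ValueError(
                f"recipient {rid!r}: event at t={times[-1]} exceeds "
                f"obs_length {obs[0]}"
            )
        cov = grp.iloc[0][list(cov_names)].to_numpy(dtype=float)
        recipients.append(
            RecipientHistory(
                recipient_id=rid,
                event_times=times,
                covariates=cov,
                obs_length=float(obs[0]),
            )
        )
    return Cohort(tuple(recipients), cov_names)


def encode_covariates(
    df: pd.DataFrame,
) -> tuple[np.ndarray, tuple[str, ...], dict]:
    """Dummy-encode a per-recipient covariate frame.

    Non-numeric columns become indicator columns against the alphabetically
    first level (the reference); numeric columns pass through unchanged.
    Returns (matrix, column names, encoding map).
    """
    cols, names, encoding = [], [], {}
    for c in df.columns:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(str(c))
            continue
        levels = sorted(s.astype(str).unique())
        encoding[str(c)] = {"reference": levels[0], "levels": levels}
        for lev in levels[1:]:
            cols.append((s.astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{c}_{lev}")
    matrix = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return matrix, tuple(names), encoding


def build_cohort(
    raw: pd.DataFrame,
    study_start,
    study_end,
    baseline_days: int = 90,
    index_offset_days: int = 90,
    min_age: int = 18,
    collapse_same_day: bool = True,
    covariate_cols: list[str] | None = None,
) -> tuple[Cohort | None, pd.DataFrame]:
    """Apply the cohort-construction rules to raw calendar-date events.

    Parameters
    ----------
    raw : DataFrame
        One row per recorded event: ``recipient_id``, ``event_date``
        (parseable dates), optional numeric ``age`` (age at index date) and
        covariate columns.
    study_start, study_end : date-like
        Observation window; events outside it are unknown.
    baseline_days : int
        Length of the required observed-event-free run-in before the
        anchoring event.
    index_offset_days : int
        Days between the anchoring event and the index date (time origin).
    min_age : int
        Exclusion threshold applied when an ``age`` column is present.
    collapse_same_day : bool
        Collapse duplicate same-day diagnoses to one event (claims commonly
        repeat codes).

    Returns
    -------
    (cohort, exclusion_log)
        ``cohort`` is None when nobody qualifies.  The log has one row per
        dropped recipient with a ``reason``; included + excluded counts add
        up to the distinct recipients in the raw table.
    """
    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)
    if study_end <= study_start:
        raise ValueError("study_end must be after study_start")
    if len(raw) == 0:
        return None, pd.DataFrame(columns=["recipient_id", "reason"])
    for c in ("recipient_id", "event_date"):
        if c not in raw.columns:
            raise ValueError(f"raw table is missing column {c!r}")
    dates = pd.to_datetime(raw["event_date"], errors="coerce")
    n_bad = int(dates.isna().sum())
    if n_bad:
        raise ValueError(
            f"{n_bad} row(s) have unparseable event_date values"
        )
    raw = raw.assign(_date=dates)
    if covariate_cols is None:
        covariate_cols = [
            c
            for c in raw.columns
            if c not in ("recipient_id", "event_date", "age", "_date")
        ]

    kept_rows: list[dict] = []
    excluded: list[dict] = []
    for rid, grp in raw.groupby("recipient_id", sort=True):
        d = grp["_date"].sort_values()
        d = d[(d >= study_start) & (d <= study_end)]
        if collapse_same_day:
            d = d.drop_duplicates()
        d = d.reset_index(drop=True)
        if d.empty:
            excluded.append(
                {"recipient_id": rid, "reason": "no events in study window"}
            )
            continue
        anchor = None
        for k in range(len(d)):
            if k == 0 or (d[k] - d[k - 1]).days > baseline_days:
                anchor = d[k]
                break
        index_date = anchor + pd.Timedelta(days=index_offset_days)
        post = d[d > index_date]
        if post.empty:
            excluded.append(
                {"recipient_id": rid, "reason": "no overdose after index date"}
            )
            continue
        if "age" in grp.columns:
            age = grp["age"].iloc[0]
            if pd.isna(age):
                excluded.append(
                    {"recipient_id": rid, "reason": "missing demographics"}
                )
                continue
            if float(age) < min_age:
                excluded.append(
                    {"recipient_id": rid, "reason": "under minimum age"}
                )
                continue
        cov_row = grp.iloc[0][covariate_cols]
        if cov_row.isna().any():
            excluded.append(
                {"recipient_id": rid, "reason": "missing demographics"}
            )
            continue
        # censored at the end of the study_end day, so an event on that day
        # still lies inside [0, obs_length)
        obs_length = float((study_end - index_date).days + 1)
        times = np.array([(t - index_date).days for t in post], dtype=float)
        kept_rows.append(
            {
                "recipient_id": rid,
                "times": times,
                "obs_length": obs_length,
                "covariates": cov_row,
            }
        )

    log = pd.DataFrame(excluded, columns=["recipient_id", "reason"])
    if not kept_rows:
        return None, log
    cov_df = pd.DataFrame(
        [r["covariates"] for r in kept_rows],
        index=[r["recipient_id"] for r in kept_rows],
    )
    matrix, names, encoding = encode_covariates(cov_df)
    recipients = tuple(
        RecipientHistory(
            recipient_id=r["recipient_id"],
            event_times=r["times"],
            covariates=matrix[i],
            obs_length=r["obs_length"],
        )
        for i, r in enumerate(kept_rows)
    )
    logger.info(
        "built cohort: %d included, %d excluded", len(recipients), len(log)
    )
    return Cohort(recipients, names, encoding), log
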