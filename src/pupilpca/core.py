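"""Data model, long-format I/O, and preprocessing for phasic pupil traces.

The central container is :class:`Recording`, a validated long-format table
(one row per sample) with canonical columns ``subject``, ``trial``, ``time``
(milliseconds relative to target onset) and ``pupil``, plus any number of
per-trial condition columns.  Preprocessing steps (gap interpolation,
z-scoring, baseline subtraction, epoching) map Recording -> Recording and a
final :func:`to_trial_matrix` builds the complete trials x timepoints matrix
that the reduction stage consumes.

Artifacts are expected to arrive pre-marked as missing samples (``NaN``);
blink detection from raw eye-tracker streams is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pupilpca")

__all__ = [
    "Recording",
    "TrialMatrix",
    "SchemaError",
    "ValidationError",
    "DegenerateDataError",
    "read_long_table",
    "interpolate_gaps",
    "zscore_pupil",
    "baseline_correct",
    "epoch_post_onset",
    "to_trial_matrix",
]

#: canonical roles every Recording carries
ROLES = ("subject", "trial", "time", "pupil")

TIME_TOL = 1e-6  # ms tolerance on grid regularity


class SchemaError(ValueError):
    """A required column is missing or unknown."""


class ValidationError(ValueError):
    """The data violate a Recording/TrialMatrix invariant."""


class DegenerateDataError(ValueError):
    """Input is too degenerate to process (zero spread, too few trials...)."""


@dataclass
class Recording:
    """Long-format pupil samples with per-trial condition metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain columns ``subject``, ``trial``, ``time`` (ms, 0 = target
        onset, negative = baseline period), ``pupil`` (NaN = missing sample)
        and one column per entry of `conditions`.
    conditions : list of str
        Names of per-trial covariates (e.g. ``"Luminance"``); values must be
        constant within each (subject, trial).
    report : pandas.DataFrame
        Accumulated per-trial preprocessing report (interpolated fraction,
        dropped flags).  Carried along, never consulted by the maths.
    """

    data: pd.DataFrame
    conditions: list[str] = field(default_factory=list)
    report: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in (*ROLES, *self.conditions) if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise ValidationError("recording contains no samples")
        if df.duplicated(subset=["subject", "trial", "time"]).any():
            dup = df[df.duplicated(subset=["subject", "trial", "time"])].iloc[0]
            raise ValidationError(
                "duplicate (subject, trial, time) sample: "
                f"({dup['subject']}, {dup['trial']}, {dup['time']})"
            )
        gid, trial_keys = pd.factorize(
            pd.MultiIndex.from_frame(df[["subject", "trial"]]), sort=False)
        t = df["time"].to_numpy(dtype=float)
        if len(df) > 1:
            same = np.diff(gid) == 0
            dt = np.diff(t)[same]
            if dt.size:
                if np.any(dt <= 0):
                    bad = trial_keys[gid[:-1][same][np.argmax(dt <= 0)]]
                    raise ValidationError(f"time not strictly increasing in trial {bad}")
                # per-trial spread of the sampling interval
                grp = gid[:-1][same]
                order = np.argsort(grp, kind="mergesort")
                grp_s, dt_s = grp[order], dt[order]
                bounds = np.flatnonzero(np.diff(grp_s)) + 1
                starts = np.concatenate(([0], bounds))
                spread = (np.maximum.reduceat(dt_s, starts)
                          - np.minimum.reduceat(dt_s, starts))
                if np.any(spread > TIME_TOL):
                    bad = trial_keys[grp_s[starts[np.argmax(spread > TIME_TOL)]]]
                    raise ValidationError(
                        f"uneven sampling interval in trial {bad}: spread "
                        f"{spread.max():g} ms exceeds {TIME_TOL:g} ms")
        for c in self.conditions:
            nuniq = df.groupby(gid, sort=False)[c].nunique(dropna=False)
            if (nuniq > 1).any():
                bad = trial_keys[nuniq.index[np.argmax(nuniq.to_numpy() > 1)]]
                raise ValidationError(f"condition {c!r} varies within trial {bad}")

    # -- conveniences ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()

    @property
    def n_trials(self) -> int:
        return len(self.data.drop_duplicates(["subject", "trial"]))

    def with_data(self, data: pd.DataFrame, report: pd.DataFrame | None = None) -> "Recording":
        return Recording(data=data.reset_index(drop=True),
                         conditions=list(self.conditions),
                         report=self.report if report is None else report)

    def trial_meta(self) -> pd.DataFrame:
        """One row per (subject, trial) with the condition columns."""
        cols = ["subject", "trial", *self.conditions]
        return self.data[cols].drop_duplicates(["subject", "trial"]).reset_index(drop=True)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)


def read_long_table(path, column_map: dict[str, str] | None = None,
                    conditions: list[str] | None = None, sep: str | None = None) -> Recording:
    """Read a delimited long-format trace table into a :class:`Recording`.

    Parameters
    ----------
    path : path-like or file object
        Delimited text (comma or tab) with a header row.
    column_map : dict, optional
        Mapping from canonical role to file column name, e.g.
        ``{"subject": "Subject", "trial": "Trial", "time": "Time",
        "pupil": "Pupil"}``.  Roles missing from the map default to the
        capitalised role name (the worked-example schema).
    conditions : list of str, optional
        File columns to treat as per-trial covariates.  Default: every
        column not mapped to a canonical role.
    """
    column_map = dict(column_map or {})
    import csv
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise ValidationError(f"empty or undelimited input file: {path}") from exc
    if len(df) == 0:
        raise ValidationError(f"input file has a header but no samples: {path}")

    rename: dict[str, str] = {}
    for role in ROLES:
        if role in column_map:
            candidates = [column_map[role]]
        else:  # worked-example capitalised schema, else canonical lowercase
            candidates = [role.capitalize(), role]
        src = next((c for c in candidates if c in df.columns), None)
        if src is None:
            raise SchemaError(
                f"column {candidates[0]!r} (role {role!r}) not found; "
                f"available: {list(df.columns)}"
            )
        rename[src] = role
    df = df.rename(columns=rename)
    if conditions is None:
        conditions = [c for c in df.columns if c not in ROLES]
    else:
        missing = [c for c in conditions if c not in df.columns]
        if missing:
            raise SchemaError(f"condition column(s) not found: {missing}")
    df = df[["subject", "trial", "time", "pupil", *conditions]].copy()
    df["time"] = df["time"].astype(float)
    df["pupil"] = pd.to_numeric(df["pupil"], errors="coerce")
    df = df.sort_values(["subject", "trial", "time"], kind="mergesort").reset_index(drop=True)
    return Recording(data=df, conditions=list(conditions))


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def _interp_trial(pupil: np.ndarray, dt: float, max_gap: float) -> tuple[np.ndarray, int]:
    """Linearly fill interior NaN runs of duration <= max_gap; return filled
    array and the number of interpolated samples."""
    y = pupil.copy()
    isnan = np.isnan(y)
    if not isnan.any():
        return y, 0
    n = len(y)
    filled = 0
    # run-length over the NaN mask
    idx = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):  # [start, stop) is a NaN run
        if start == 0 or stop == n:
            continue  # edge gap: no anchor on one side
        if (stop - start) * dt > max_gap:
            continue
        left, right = y[start - 1], y[stop]
        k = stop - start
        y[start:stop] = left + (right - left) * np.arange(1, k + 1) / (k + 1)
        filled += k
    return y, filled


def interpolate_gaps(rec: Recording, max_gap: float = 500.0) -> Recording:
    """Linearly interpolate short artifact gaps (missing runs) per trial.

    Gaps of total duration <= `max_gap` ms with valid neighbours on both
    sides are filled; longer gaps and gaps touching the trial edges stay
    missing (the matrix stage will then drop the trial).  Non-missing
    samples are never altered.  A per-trial report with the fraction of
    interpolated samples is attached to the returned Recording.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    df = rec.data.copy()
    rows = []
    for (subj, trial), g in df.groupby(["subject", "trial"], sort=False, observed=True):
        t = g["time"].to_numpy(dtype=float)
        dt = float(t[1] - t[0]) if len(t) > 1 else max_gap
        y, filled = _interp_trial(g["pupil"].to_numpy(dtype=float), dt, max_gap)
        df.loc[g.index, "pupil"] = y
        rows.append({"subject": subj, "trial": trial,
                     "interpolated_fraction": filled / len(g),
                     "still_missing": int(np.isnan(y).sum())})
    report = pd.DataFrame(rows)
    n_interp = int((report["interpolated_fraction"] > 0).sum())
    if n_interp:
        logger.info("interpolate_gaps: filled gaps in %d/%d trials", n_interp, len(report))
    return rec.with_data(df, report=report)


def zscore_pupil(rec: Recording, grouping: str = "subject") -> Recording:
    """z-score pupil size within groups (default: per subject, whole session).

    Uses the sample standard deviation (denominator n-1).  Missing samples
    stay missing and do not enter the moments.
    """
    if grouping not in rec.data.columns:
        raise SchemaError(f"unknown grouping column {grouping!r}")
    df = rec.data.copy()
    for key, g in df.groupby(grouping, sort=False, observed=True):
        y = g["pupil"].to_numpy(dtype=float)
        valid = y[~np.isnan(y)]
        if len(valid) < 2 or np.std(valid, ddof=1) == 0:
            raise DegenerateDataError(
                f"group {grouping}={key!r} has zero spread (or <2 samples); cannot z-score"
            )
        df.loc[g.index, "pupil"] = (y - valid.mean()) / np.std(valid, ddof=1)
    return rec.with_data(df)


def baseline_correct(rec: Recording, window: tuple[float, float] = (-250.0, 250.0),
                     stat: str = "mean") -> Recording:
    """Subtract each trial's baseline, the mean pupil size in `window`.

    The default window is the 500 ms centred on target onset, [-250, 250) ms.
    Trials with no valid sample in the window are dropped (and logged).
    `stat` may be ``"mean"`` (default) or ``"median"``.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"baseline window start must precede end, got {window}")
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    df = rec.data.copy()
    dropped = []
    for (subj, trial), g in df.groupby(["subject", "trial"], sort=False, observed=True):
        t = g["time"].to_numpy(dtype=float)
        y = g["pupil"].to_numpy(dtype=float)
        inwin = (t >= lo) & (t < hi) & ~np.isnan(y)
        if not inwin.any():
            dropped.append((subj, trial))
            continue
        base = np.mean(y[inwin]) if stat == "mean" else np.median(y[inwin])
        df.loc[g.index, "pupil"] = y - base
    if dropped:
        logger.warning("baseline_correct: dropped %d trial(s) with empty baseline window: %s",
                       len(dropped), dropped[:5])
        keep = ~df.set_index(["subject", "trial"]).index.isin(dropped)
        df = df[keep]
        if len(df) == 0:
            raise DegenerateDataError("all trials lack baseline samples")
    return rec.with_data(df)


def epoch_post_onset(rec: Recording, t_start: float = 0.0, t_end: float = 4500.0) -> Recording:
    """Keep samples in the half-open interval [t_start, t_end) ms.

    Trials left empty are dropped with a warning; an error is raised when no
    trial survives.
    """
    if not t_start < t_end:
        raise ValueError(f"empty epoch: t_start={t_start} must be < t_end={t_end}")
    df = rec.data
    mask = (df["time"] >= t_start) & (df["time"] < t_end)
    out = df[mask]
    before = df.drop_duplicates(["subject", "trial"])[["subject", "trial"]]
    after = out.drop_duplicates(["subject", "trial"])[["subject", "trial"]]
    n_dropped = len(before) - len(after)
    if len(out) == 0:
        raise DegenerateDataError(
            f"epoch [{t_start}, {t_end}) ms leaves no samples in any trial"
        )
    if n_dropped:
        logger.warning("epoch_post_onset: %d trial(s) had no samples in [%g, %g) and were dropped",
                       n_dropped, t_start, t_end)
    return rec.with_data(out)


@dataclass
class TrialMatrix:
    """Complete trials x ordered-timepoints matrix with aligned metadata.

    ``values[i, j]`` is the pupil size of trial ``row_meta.iloc[i]`` at
    ``col_times[j]`` ms.  No cell is missing; every row shares the grid.
    """

    values: np.ndarray
    row_meta: pd.DataFrame  # columns: subject, trial, conditions...
    col_times: np.ndarray
    n_omitted: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.col_times = np.asarray(self.col_times, dtype=float)
        self.validate()

    def validate(self) -> None:
        v, t = self.values, self.col_times
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise DegenerateDataError(
                f"trial matrix must be at least 2x2, got shape {v.shape}"
            )
        if np.isnan(v).any():
            raise ValidationError("trial matrix contains missing cells")
        if v.shape[1] != len(t) or np.any(np.diff(t) <= 0):
            raise ValidationError("col_times must be strictly increasing and match columns")
        if len(self.row_meta) != v.shape[0]:
            raise ValidationError("row_meta length does not match number of rows")
        sd = v.std(axis=0)
        if np.any(sd == 0):
            j = int(np.argmin(sd))
            raise DegenerateDataError(
                f"zero-variance column at t={t[j]:g} ms; epoch strictly after "
                "target onset (epoch_post_onset) so every timepoint varies"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def to_trial_matrix(rec: Recording) -> TrialMatrix:
    """Pivot an epoched Recording into a complete trials x timepoints matrix.

    Any trial containing a missing sample (or not covering the full common
    grid) is omitted entirely; the count of omitted trials is reported on
    the result.  Raises when fewer than 2 complete trials remain or when
    trials are sampled on inconsistent grids.
    """
    df = rec.data
    times = np.unique(df["time"].to_numpy(dtype=float))
    if len(times) > 1:
        dt = np.diff(times)
        if np.ptp(dt) > TIME_TOL:
            raise ValidationError(
                "trials are sampled on inconsistent time grids (uneven union of timestamps)"
            )
    wide = df.pivot_table(index=["subject", "trial"], columns="time",
                          values="pupil", observed=True, dropna=False, sort=True)
    wide = wide.reindex(columns=times)
    complete = ~wide.isna().any(axis=1)
    n_omitted = int((~complete).sum())
    if n_omitted:
        logger.info("to_trial_matrix: omitted %d/%d incomplete trial(s)", n_omitted, len(wide))
    wide = wide[complete]
    if len(wide) < 2:
        raise DegenerateDataError(
            f"only {len(wide)} complete trial(s) remain after the omission rule; need >= 2"
        )
    meta = rec.trial_meta().set_index(["subject", "trial"])
    row_meta = meta.loc[wide.index].reset_index()
    return TrialMatrix(values=wide.to_numpy(dtype=float),
                       row_meta=row_meta, col_times=times, n_omitted=n_omitted)
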