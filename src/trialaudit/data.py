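"""Trial-structured multichannel dataset model and tidy-CSV interchange.

A :class:`TrialDataset` holds a patient's preprocessed relative HbO-change
signals organised as days -> sessions -> per-condition trial tensors of shape
``(n_trials, n_channels, n_timepoints)``.  Conditions are the two answer
classes ``"yes"`` and ``"no"``; the time axis is seconds relative to stimulus
onset and is shared by every trial.

On disk a dataset is a JSON manifest plus one tidy long-format CSV per
session with header ``condition,trial,channel,time_s,value``.  The manifest
is authoritative for the time axis; CSV time values must agree with it to
1e-9 s.  Trial and channel indices are 0-based and contiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("yes", "no")

CSV_HEADER = ["condition", "trial", "channel", "time_s", "value"]

#: relative tolerance for time-axis uniformity and manifest/CSV agreement
TIME_RTOL = 1e-9


class DatasetValidationError(ValueError):
    """A dataset (or file being read) violates the trial-data contract."""


@dataclass
class SessionRecord:
    """One block of trials: per-condition tensors (trial x channel x time)."""

    session_id: str
    trials_yes: np.ndarray
    trials_no: np.ndarray

    def trials(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        return self.trials_yes if condition == "yes" else self.trials_no

    def n_trials(self, condition: str) -> int:
        return self.trials(condition).shape[0]


@dataclass
class DayRecord:
    """One recording day: an ordered list of sessions."""

    day_id: str
    sessions: list[SessionRecord] = field(default_factory=list)


@dataclass
class TrialDataset:
    """Full recording of one patient.

    Parameters
    ----------
    patient_id
        Free-text label.
    days
        Ordered day records.
    n_channels
        Number of recording channels shared by every trial.
    time_axis
        Seconds relative to stimulus onset, strictly increasing and uniform.
    sampling_rate
        Hz; must be consistent with the spacing of ``time_axis``.
    """

    patient_id: str
    days: list[DayRecord]
    n_channels: int
    time_axis: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)

    @property
    def n_timepoints(self) -> int:
        return self.time_axis.shape[0]

    def iter_sessions(self) -> Iterator[tuple[DayRecord, SessionRecord]]:
        for day in self.days:
            for sess in day.sessions:
                yield day, sess

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Return human-readable descriptions of every contract violation.

        An empty list means the dataset is valid.  Violations name the
        day/session/condition/trial they occur in.
        """
        problems: list[str] = []
        t = self.time_axis
        if self.n_channels <= 0:
            problems.append(f"n_channels must be positive, got {self.n_channels}")
        if t.ndim != 1 or t.size < 1:
            problems.append("time_axis must be a non-empty 1-D vector")
        elif t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                problems.append("time_axis is not strictly increasing")
            else:
                span = abs(t[-1] - t[0])
                if np.any(np.abs(dt - dt[0]) > TIME_RTOL * max(span, 1.0)):
                    problems.append("time_axis spacing is not uniform")
                if self.sampling_rate <= 0:
                    problems.append(f"sampling_rate must be positive, got {self.sampling_rate}")
                elif not math.isclose(dt[0], 1.0 / self.sampling_rate, rel_tol=1e-6):
                    problems.append(
                        f"time_axis spacing {dt[0]:g} s inconsistent with "
                        f"sampling_rate {self.sampling_rate:g} Hz"
                    )
        if not self.days:
            problems.append("dataset has no days")
        day_ids = [d.day_id for d in self.days]
        if len(set(day_ids)) != len(day_ids):
            problems.append("day_ids are not unique")
        for day in self.days:
            if not day.sessions:
                problems.append(f"day {day.day_id!r} has no sessions")
            for sess in day.sessions:
                where = f"day {day.day_id!r} / session {sess.session_id!r}"
                for cond in CONDITIONS:
                    arr = sess.trials(cond)
                    if not isinstance(arr, np.ndarray) or arr.ndim != 3:
                        problems.append(f"{where} / condition {cond!r}: trials are not a 3-D array")
                        continue
                    n_tr, n_ch, n_tp = arr.shape
                    if n_ch != self.n_channels:
                        problems.append(
                            f"{where} / condition {cond!r}: {n_ch} channels, "
                            f"dataset declares {self.n_channels}"
                        )
                    if n_tp != self.n_timepoints:
                        problems.append(
                            f"{where} / condition {cond!r}: {n_tp} timepoints, "
                            f"time_axis has {self.n_timepoints}"
                        )
                    bad = ~np.isfinite(arr)
                    if bad.any():
                        for tr in np.unique(np.nonzero(bad)[0]):
                            problems.append(
                                f"{where} / condition {cond!r} / trial {tr}: non-finite value"
                            )
        return problems

    def check(self) -> "TrialDataset":
        """Raise :class:`DatasetValidationError` if invalid; else return self."""
        problems = self.validate()
        if problems:
            raise DatasetValidationError("; ".join(problems))
        return self


def validate(dataset: TrialDataset) -> list[str]:
    """Functional alias for :meth:`TrialDataset.validate`."""
    return dataset.validate()


# ---------------------------------------------------------------------------
# interchange: JSON manifest + per-session tidy CSV
# ---------------------------------------------------------------------------


def _session_csv_name(day_id: str, session_id: str) -> str:
    safe = lambda s: "".join(ch if (ch.isalnum() or ch in "-_") else "_" for ch in s)
    return f"{safe(day_id)}__{safe(session_id)}.csv"


def write_dataset(dataset: TrialDataset, out_dir: str | Path) -> Path:
    """Write ``manifest.json`` plus one CSV per session; return manifest path.

    The files round-trip: ``read_dataset(write_dataset(ds, d))`` reproduces
    every signal value (floats are written with 17 significant digits).
    """
    dataset.check()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "patient_id": dataset.patient_id,
        "n_channels": int(dataset.n_channels),
        "sampling_rate_hz": float(dataset.sampling_rate),
        "time_axis_s": [float(v) for v in dataset.time_axis],
        "days": [],
    }
    n_tp = dataset.n_timepoints
    for day in dataset.days:
        day_entry = {"day_id": day.day_id, "sessions": []}
        for sess in day.sessions:
            csv_name = _session_csv_name(day.day_id, sess.session_id)
            frames = []
            for cond in CONDITIONS:
                arr = sess.trials(cond)
                n_tr = arr.shape[0]
                if n_tr == 0:
                    continue
                idx = pd.MultiIndex.from_product(
                    [range(n_tr), range(dataset.n_channels), range(n_tp)],
                    names=["trial", "channel", "tp"],
                )
                df = pd.DataFrame({"value": arr.ravel()}, index=idx).reset_index()
                df.insert(0, "condition", cond)
                df["time_s"] = dataset.time_axis[df.pop("tp").to_numpy()]
                frames.append(df[CSV_HEADER])
            table = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=CSV_HEADER)
            )
            table.to_csv(out_dir / csv_name, index=False, float_format="%.17g")
            day_entry["sessions"].append({"session_id": sess.session_id, "csv": csv_name})
        manifest["days"].append(day_entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def _tensor_from_long(
    df: pd.DataFrame,
    condition: str,
    n_channels: int,
    time_axis: np.ndarray,
    where: str,
) -> np.ndarray:
    """Assemble the (trial, channel, time) tensor for one condition."""
    sub = df[df["condition"] == condition]
    n_tp = time_axis.shape[0]
    if sub.empty:
        return np.empty((0, n_channels, n_tp), dtype=float)
    trials = np.sort(sub["trial"].unique())
    if trials[0] != 0 or trials[-1] != len(trials) - 1:
        raise DatasetValidationError(
            f"{where}: condition {condition!r} trial indices not 0-based contiguous: {trials.tolist()}"
        )
    n_tr = len(trials)
    expected = n_tr * n_channels * n_tp
    if len(sub) != expected:
        raise DatasetValidationError(
            f"{where}: condition {condition!r} has {len(sub)} rows, "
            f"expected {expected} ({n_tr} trials x {n_channels} channels x {n_tp} timepoints)"
        )
    ch = sub["channel"].to_numpy()
    if ch.min() < 0 or ch.max() >= n_channels:
        raise DatasetValidationError(
            f"{where}: condition {condition!r} channel index out of range [0, {n_channels})"
        )
    # map time values onto the manifest axis
    span = max(abs(float(time_axis[-1] - time_axis[0])), 1.0)
    tp = np.searchsorted(time_axis, sub["time_s"].to_numpy() - TIME_RTOL * span)
    tp = np.clip(tp, 0, n_tp - 1)
    if np.any(np.abs(time_axis[tp] - sub["time_s"].to_numpy()) > TIME_RTOL * span):
        bad = int(np.argmax(np.abs(time_axis[tp] - sub["time_s"].to_numpy()) > TIME_RTOL * span))
        raise DatasetValidationError(
            f"{where}: condition {condition!r} row {sub.index[bad]}: time_s "
            f"{sub['time_s'].iloc[bad]!r} not on the manifest time axis"
        )
    out = np.full((n_tr, n_channels, n_tp), np.nan)
    out[sub["trial"].to_numpy(), ch, tp] = sub["value"].to_numpy()
    if np.isnan(out).any():
        tr = int(np.nonzero(np.isnan(out))[0][0])
        raise DatasetValidationError(
            f"{where}: condition {condition!r} trial {tr}: duplicate or missing samples"
        )
    return out


def read_dataset(manifest_path: str | Path) -> TrialDataset:
    """Read a manifest + CSV bundle written by :func:`write_dataset`.

    Raises
    ------
    FileNotFoundError
        If the manifest or a referenced CSV is missing.
    DatasetValidationError
        On any schema violation: unknown condition label, ragged trials,
        time values off the manifest axis, or non-finite signal values.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    for key in ("patient_id", "n_channels", "sampling_rate_hz", "time_axis_s", "days"):
        if key not in manifest:
            raise DatasetValidationError(f"manifest missing field {key!r}")
    time_axis = np.asarray(manifest["time_axis_s"], dtype=float)
    n_channels = int(manifest["n_channels"])
    base = manifest_path.parent
    days: list[DayRecord] = []
    for day_entry in manifest["days"]:
        sessions: list[SessionRecord] = []
        for sess_entry in day_entry["sessions"]:
            csv_path = base / sess_entry["csv"]
            if not csv_path.exists():
                raise FileNotFoundError(f"session CSV not found: {csv_path}")
            where = f"day {day_entry['day_id']!r} / session {sess_entry['session_id']!r}"
            df = pd.read_csv(csv_path)
            if list(df.columns) != CSV_HEADER:
                raise DatasetValidationError(
                    f"{where}: CSV header {list(df.columns)} != {CSV_HEADER}"
                )
            unknown = ~df["condition"].isin(CONDITIONS)
            if unknown.any():
                row = int(np.nonzero(unknown.to_numpy())[0][0])
                raise DatasetValidationError(
                    f"{where}: row {row}: unknown condition label "
                    f"{df['condition'].iloc[row]!r} (expected one of {list(CONDITIONS)})"
                )
            if df["value"].isna().any():
                row = int(np.nonzero(df["value"].isna().to_numpy())[0][0])
                raise DatasetValidationError(f"{where}: row {row}: NaN value")
            sessions.append(
                SessionRecord(
                    session_id=str(sess_entry["session_id"]),
                    trials_yes=_tensor_from_long(df, "yes", n_channels, time_axis, where),
                    trials_no=_tensor_from_long(df, "no", n_channels, time_axis, where),
                )
            )
        days.append(DayRecord(day_id=str(day_entry["day_id"]), sessions=sessions))
    ds = TrialDataset(
        patient_id=str(manifest["patient_id"]),
        days=days,
        n_channels=n_channels,
        time_axis=time_axis,
        sampling_rate=float(manifest["sampling_rate_hz"]),
    )
    return ds.check()
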