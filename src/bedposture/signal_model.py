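"""Core data types and file I/O for under-bed load-cell recordings.

A bed instrumented with one vertical-force load cell under each leg produces a
four-channel force trace: LH and RH under the head-end legs (left/right), LF
and RF under the foot-end legs.  Together with the sensor spacing (bed width
``w`` and length ``l``) these forces determine the planar centre of mass of
the occupant-bed system, which is the basis of every downstream feature.

This module owns the validated containers (:class:`BedGeometry`,
:class:`LoadCellRecording`, :class:`PostureLabelSet`), plain-text CSV/JSON
round-tripping, optional tare (empty-bed load) subtraction, and the
majority-vote consensus over multiple raters' posture labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "POSTURES",
    "UNRESOLVED",
    "BedGeometry",
    "LoadCellRecording",
    "PostureLabelSet",
    "read_recording",
    "write_recording",
    "apply_tare",
    "consensus_labels",
    "read_labels",
    "write_labels",
    "load_config",
]

#: The three-class posture alphabet.
POSTURES = ("LEFT", "SUPINE", "RIGHT")

#: Consensus token for windows where no strict plurality exists.
UNRESOLVED = "UNRESOLVED"

RECORDING_COLUMNS = ["time_s", "lh_n", "rh_n", "lf_n", "rf_n"]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass(frozen=True)
class BedGeometry:
    """Sensor spacing of the instrumented bed.

    Parameters
    ----------
    width_m : float
        Lateral distance between the left and right sensors, metres.
    length_m : float
        Longitudinal distance between the head and foot sensors, metres.
    """

    width_m: float
    length_m: float

    def __post_init__(self) -> None:
        if not (self.width_m > 0 and np.isfinite(self.width_m)):
            raise ValidationError(f"width_m must be > 0, got {self.width_m}")
        if not (self.length_m > 0 and np.isfinite(self.length_m)):
            raise ValidationError(f"length_m must be > 0, got {self.length_m}")


@dataclass
class LoadCellRecording:
    """A four-channel vertical-force time series from the bed legs.

    Channels are newtons, sampled uniformly at ``sample_rate`` Hz.  ``tare``
    is the optional per-channel empty-bed load; by default features are
    computed on the raw occupant-bed system without tare subtraction.
    """

    sample_rate: float
    lh: np.ndarray
    rh: np.ndarray
    lf: np.ndarray
    rf: np.ndarray
    geometry: BedGeometry
    start_time: float = 0.0
    tare: np.ndarray | None = None  # shape (4,) in LH, RH, LF, RF order
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lh = np.asarray(self.lh, dtype=float)
        self.rh = np.asarray(self.rh, dtype=float)
        self.lf = np.asarray(self.lf, dtype=float)
        self.rf = np.asarray(self.rf, dtype=float)
        if not (self.sample_rate > 0 and np.isfinite(self.sample_rate)):
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        n = len(self.lh)
        if n < 1:
            raise ValidationError("recording must contain at least one sample")
        for name, ch in zip(("rh", "lf", "rf"), (self.rh, self.lf, self.rf)):
            if len(ch) != n:
                raise ValidationError(
                    f"channel length mismatch: lh has {n} samples, {name} has {len(ch)}"
                )
        for name, ch in zip(("lh", "rh", "lf", "rf"), self.channels()):
            if not np.all(np.isfinite(ch)):
                bad = int(np.flatnonzero(~np.isfinite(ch))[0])
                raise ValidationError(f"non-finite force in channel {name} at sample {bad}")
        if self.tare is not None:
            self.tare = np.asarray(self.tare, dtype=float)
            if self.tare.shape != (4,):
                raise ValidationError("tare must be a 4-vector (LH, RH, LF, RF)")

    def __len__(self) -> int:
        return len(self.lh)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from the recording start."""
        return self.start_time + np.arange(len(self)) / self.sample_rate

    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.lh, self.rh, self.lf, self.rf

    def total_force(self) -> np.ndarray:
        return self.lh + self.rh + self.lf + self.rf


@dataclass
class PostureLabelSet:
    """Per-window posture labels from one or more raters plus their consensus.

    ``rater_labels`` is an (n_windows, n_raters) array of tokens from
    :data:`POSTURES`; ``consensus`` holds the strict-plurality label per
    window, or :data:`UNRESOLVED` when the raters tie three ways.
    """

    window_times: np.ndarray
    rater_labels: np.ndarray
    consensus: np.ndarray

    def __post_init__(self) -> None:
        self.window_times = np.asarray(self.window_times, dtype=float)
        self.rater_labels = np.asarray(self.rater_labels, dtype=object)
        self.consensus = np.asarray(self.consensus, dtype=object)
        if self.rater_labels.ndim != 2 or self.rater_labels.shape[1] < 1:
            raise ValidationError("rater_labels must be (n_windows, n_raters) with >= 1 rater")
        if len(self.window_times) != self.rater_labels.shape[0]:
            raise ValidationError("window_times and rater_labels disagree on window count")
        if len(self.consensus) != self.rater_labels.shape[0]:
            raise ValidationError("consensus and rater_labels disagree on window count")

    @property
    def n_raters(self) -> int:
        return self.rater_labels.shape[1]

    def resolved_mask(self) -> np.ndarray:
        return self.consensus != UNRESOLVED


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, geometry: BedGeometry, sample_rate: float,
                   tare: np.ndarray | None = None) -> LoadCellRecording:
    """Read a recording CSV (header ``time_s,lh_n,rh_n,lf_n,rf_n``).

    Row order is preserved; the time column must be strictly increasing.
    Malformed cells raise a parse error naming the offending data row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    numeric = df[RECORDING_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df[RECORDING_COLUMNS].isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        row = int(np.flatnonzero(numeric.isna().any(axis=1).to_numpy())[0])
        raise ValidationError(
            f"{path}: non-numeric or missing value in data row {row + 1} "
            f"(columns {list(numeric.columns[numeric.iloc[row].isna()])})"
        )
    t = numeric["time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ValidationError(f"{path}: time not strictly increasing at data row {row + 2}")
    return LoadCellRecording(
        sample_rate=sample_rate,
        lh=numeric["lh_n"].to_numpy(),
        rh=numeric["rh_n"].to_numpy(),
        lf=numeric["lf_n"].to_numpy(),
        rf=numeric["rf_n"].to_numpy(),
        geometry=geometry,
        start_time=float(t[0]) if len(t) else 0.0,
        tare=tare,
    )


def write_recording(recording: LoadCellRecording, path: str | Path) -> Path:
    """Write a recording to the CSV interchange format (6 decimal places)."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": recording.times,
        "lh_n": recording.lh,
        "rh_n": recording.rh,
        "lf_n": recording.lf,
        "rf_n": recording.rf,
    })
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def apply_tare(recording: LoadCellRecording) -> LoadCellRecording:
    """Subtract the per-channel empty-bed load from every sample.

    If no tare is attached the recording is returned unchanged with
    ``meta['tare_warning']`` set, and a warning is emitted.
    """
    if recording.tare is None:
        warnings.warn("apply_tare: no tare attached; returning recording unchanged")
        out = replace(recording, meta={**recording.meta, "tare_warning": "tare absent"})
        return out
    t = recording.tare
    return replace(
        recording,
        lh=recording.lh - t[0],
        rh=recording.rh - t[1],
        lf=recording.lf - t[2],
        rf=recording.rf - t[3],
        tare=None,
        meta={**recording.meta, "tared": True},
    )


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def _consensus_one(row: np.ndarray) -> str:
    vals, counts = np.unique(row.astype(str), return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    return str(winners[0]) if len(winners) == 1 else UNRESOLVED


def consensus_labels(rater_labels: np.ndarray,
                     window_times: np.ndarray | None = None) -> PostureLabelSet:
    """Majority-vote ground truth: the most common label per window.

    Each window's consensus is the strict-plurality label across raters;
    windows where the top count is shared (a three-way tie with three raters)
    are marked :data:`UNRESOLVED` and excluded downstream.
    """
    rater_labels = np.asarray(rater_labels, dtype=object)
    if rater_labels.ndim == 1:
        rater_labels = rater_labels[:, None]
    bad = set(np.unique(rater_labels.astype(str))) - set(POSTURES)
    if bad:
        raise ValidationError(f"unknown label tokens {sorted(bad)}; expected one of {POSTURES}")
    consensus = np.array([_consensus_one(row) for row in rater_labels], dtype=object)
    if window_times is None:
        window_times = np.arange(len(consensus), dtype=float)
    return PostureLabelSet(window_times=window_times, rater_labels=rater_labels,
                           consensus=consensus)


def read_labels(path: str | Path) -> PostureLabelSet:
    """Read a labels CSV (``window_start_s,rater_1,rater_2,...``)."""
    df = pd.read_csv(Path(path))
    if "window_start_s" not in df.columns:
        raise ValidationError(f"{path}: missing column window_start_s")
    rater_cols = [c for c in df.columns if c.startswith("rater_")]
    if not rater_cols:
        raise ValidationError(f"{path}: no rater_* columns")
    labels = df[rater_cols].to_numpy(dtype=object)
    return consensus_labels(labels, window_times=df["window_start_s"].to_numpy(float))


def write_labels(labels: PostureLabelSet, path: str | Path) -> Path:
    df = pd.DataFrame(
        labels.rater_labels,
        columns=[f"rater_{i + 1}" for i in range(labels.n_raters)],
    )
    df.insert(0, "window_start_s", labels.window_times)
    df.to_csv(Path(path), index=False)
    return Path(path)


def load_config(path: str | Path) -> dict:
    """Load a geometry/acquisition JSON config.

    Keys: ``width_m``, ``length_m``, ``sample_rate_hz``, optional ``tare_n``
    (4-array, LH RH LF RF).  Returns a dict with a ``geometry`` BedGeometry,
    ``sample_rate`` and optional ``tare``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("width_m", "length_m", "sample_rate_hz"):
        if key not in raw:
            raise ValidationError(f"{path}: config missing key {key!r}")
    out = {
        "geometry": BedGeometry(float(raw["width_m"]), float(raw["length_m"])),
        "sample_rate": float(raw["sample_rate_hz"]),
        "tare": None,
    }
    if raw.get("tare_n") is not None:
        tare = np.asarray(raw["tare_n"], dtype=float)
        if tare.shape != (4,):
            raise ValidationError(f"{path}: tare_n must have 4 entries")
        out["tare"] = tare
    return out
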