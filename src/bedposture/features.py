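"""Centre-of-mass features from load-cell forces.

The planar centre of mass (CoM) of the occupant-bed system follows from the
four leg forces and the sensor spacing::

    CoM_x = (w/2) * (LH + LF - RH - RF) / (LH + LF + RH + RF)
    CoM_y = (l/2) * (LH + RH - LF - RF) / (LH + LF + RH + RF)

Its slow drift encodes posture; its millimetre-scale oscillation encodes
breathing, and the summed head-end forces carry a ballistocardiographic
(cardiac) micro-oscillation.  The respiratory component is isolated with a
zero-phase Chebyshev Type II low-pass, breaths are segmented at derivative
zero crossings, and each breath's displacement direction gives the
respiratory-axis angle

    CoM_resp_ANG = arctan | dCoM_resp_y / dCoM_resp_x |   (degrees, 0..90)

evaluated from the end of an exhalation (t_max) to the end of the following
inhalation (t_min).  The cardiac band is isolated from LH+RH with a
zero-phase equiripple FIR band-pass.  Twelve features are aggregated over a
45 s window advanced by 15 s (2250 samples per window at 50 Hz).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_model import LoadCellRecording, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "FilterSpec",
    "CoMSeries",
    "RespSeries",
    "compute_com",
    "isolate_respiration",
    "detect_breath_extrema",
    "resp_angle",
    "isolate_cardiac",
    "extract_features",
    "write_feature_table",
    "read_feature_table",
]

#: The twelve per-window features, in canonical column order.
FEATURE_NAMES = [
    "meanCoM_x",
    "meanCoM_y",
    "ratio_meanCoM",
    "stdCoM_x",
    "stdCoM_y",
    "ratio_stdCoM",
    "CoM_resp_ANG",
    "stdCoM_resp_ANG",
    "rmsCoM_resp_x",
    "rmsCoM_resp_y",
    "ratio_rmsCoM_resp",
    "rmsPulse",
]


@dataclass(frozen=True)
class FilterSpec:
    """Respiratory and cardiac filter design parameters.

    The respiratory filter is a Chebyshev Type II low-pass (stop-band edge
    ``resp_stop_hz``, stop-band attenuation ``resp_atten_db``, order
    ``resp_order``), applied forward-backward for zero phase.  The cardiac
    filter is a linear-phase equiripple FIR band-pass over
    ``cardiac_band_hz`` with ``cardiac_atten_db`` stop-band attenuation and
    at most ``cardiac_ripple_db`` pass-band ripple, also applied
    forward-backward.  ``rms_norm`` selects how the respiratory rms features
    are normalised: ``"window_p97"`` (divide by the 97th percentile of the
    absolute mean-removed respiratory signal within the window),
    ``"global_p97"`` (same percentile over the whole recording) or ``"none"``.
    """

    resp_stop_hz: float = 1.0
    resp_atten_db: float = 40.0
    resp_order: int = 8
    cardiac_band_hz: tuple[float, float] = (0.8, 2.5)
    cardiac_atten_db: float = 60.0
    cardiac_ripple_db: float = 1.0
    cardiac_transition_hz: float = 0.3
    rms_norm: str = "window_p97"

    def __post_init__(self) -> None:
        if self.rms_norm not in ("window_p97", "global_p97", "none"):
            raise ValidationError(f"unknown rms_norm {self.rms_norm!r}")
        lo, hi = self.cardiac_band_hz
        if not (0 < lo < hi):
            raise ValidationError("cardiac_band_hz must satisfy 0 < low < high")

    # -- designs -----------------------------------------------------------
    def resp_sos(self, sample_rate: float):
        """Second-order sections of the respiratory low-pass."""
        return sps.cheby2(self.resp_order, self.resp_atten_db, self.resp_stop_hz,
                          btype="lowpass", fs=sample_rate, output="sos")

    def cardiac_taps(self, sample_rate: float) -> np.ndarray:
        """Equiripple FIR taps for the cardiac band-pass (odd length)."""
        lo, hi = self.cardiac_band_hz
        tw = self.cardiac_transition_hz
        nyq = sample_rate / 2.0
        if hi + tw >= nyq:
            raise ValidationError("cardiac band too close to Nyquist for transition width")
        delta_s = 10 ** (-self.cardiac_atten_db / 20.0)
        r = 10 ** (self.cardiac_ripple_db / 20.0)
        delta_p = min((r - 1) / (r + 1), 0.005)  # design tighter than the ripple budget
        atten = -20 * math.log10(min(delta_p, delta_s))
        numtaps, _ = sps.kaiserord(atten, tw / nyq)
        numtaps = int(numtaps * 1.2) | 1  # margin; force odd (type I)
        bands = [0.0, lo - tw, lo, hi, hi + tw, nyq]
        taps = sps.remez(numtaps, bands, [0.0, 1.0, 0.0],
                         weight=[delta_p / delta_s, 1.0, delta_p / delta_s],
                         fs=sample_rate, maxiter=100)
        return taps

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        doc = {
            "resp": {"type": "cheby2_lowpass", "stop_hz": self.resp_stop_hz,
                     "atten_db": self.resp_atten_db, "order": self.resp_order},
            "cardiac": {"band_hz": list(self.cardiac_band_hz),
                        "atten_db": self.cardiac_atten_db,
                        "ripple_db": self.cardiac_ripple_db,
                        "transition_hz": self.cardiac_transition_hz},
            "rms_norm": self.rms_norm,
        }
        Path(path).write_text(json.dumps(doc, indent=2))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterSpec":
        raw = json.loads(Path(path).read_text())
        resp = raw.get("resp", {})
        card = raw.get("cardiac", {})
        return cls(
            resp_stop_hz=float(resp.get("stop_hz", 1.0)),
            resp_atten_db=float(resp.get("atten_db", 40.0)),
            resp_order=int(resp.get("order", 8)),
            cardiac_band_hz=tuple(card.get("band_hz", (0.8, 2.5))),
            cardiac_atten_db=float(card.get("atten_db", 60.0)),
            cardiac_ripple_db=float(card.get("ripple_db", 1.0)),
            cardiac_transition_hz=float(card.get("transition_hz", 0.3)),
            rms_norm=raw.get("rms_norm", "window_p97"),
        )


@dataclass
class CoMSeries:
    """Per-sample planar centre of mass of the occupant-bed system."""

    sample_rate: float
    com_x: np.ndarray  # metres, positive toward the left (LH/LF) sensors
    com_y: np.ndarray  # metres, positive toward the head (LH/RH) sensors
    start_time: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.com_x)) / self.sample_rate


@dataclass
class RespSeries:
    """Band-isolated respiratory CoM components with breath landmarks.

    ``t_max`` are times of local maxima (end of exhalation), ``t_min`` times
    of local minima (end of inhalation), both detected on the respiratory
    component with the larger variance (the two components oscillate in
    phase along the respiratory axis).
    """

    sample_rate: float
    com_resp_x: np.ndarray
    com_resp_y: np.ndarray
    t_max: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    start_time: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.com_resp_x)) / self.sample_rate


# ---------------------------------------------------------------------------
# Centre of mass
# ---------------------------------------------------------------------------

def compute_com(recording: LoadCellRecording, min_total_n: float = 1.0) -> CoMSeries:
    """Planar CoM from the four leg forces and the sensor spacing.

    Raises if the summed force drops to ``min_total_n`` or below at any
    sample (empty bed / division blow-up), identifying the sample index.
    """
    lh, rh, lf, rf = recording.channels()
    total = lh + rh + lf + rf
    low = total <= min_total_n
    if np.any(low):
        idx = int(np.flatnonzero(low)[0])
        raise ValidationError(
            f"total force {total[idx]:.3g} N <= {min_total_n} N at sample {idx} (bed empty?)"
        )
    w = recording.geometry.width_m
    length = recording.geometry.length_m
    com_x = (w / 2.0) * (lh + lf - rh - rf) / total
    com_y = (length / 2.0) * (lh + rh - lf - rf) / total
    return CoMSeries(sample_rate=recording.sample_rate, com_x=com_x, com_y=com_y,
                     start_time=recording.start_time)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _filtfilt_sos(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise ValidationError(
            f"signal of {len(x)} samples too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def _filtfilt_fir(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = 3 * len(taps)
    if len(x) <= padlen:
        raise ValidationError(
            f"signal of {len(x)} samples too short for zero-phase FIR filtering "
            f"(needs > {padlen})"
        )
    return sps.filtfilt(taps, [1.0], x, padtype="odd", padlen=padlen)


def isolate_respiration(com: CoMSeries, spec: FilterSpec | None = None,
                        detect_extrema: bool = True) -> RespSeries:
    """Zero-phase Chebyshev-II low-pass of both CoM components.

    Forward-backward application cancels the filter's phase, so breath
    landmark times are preserved.  Both components pass through the identical
    filter.  Optionally detects breath extrema (see
    :func:`detect_breath_extrema`).
    """
    spec = spec or FilterSpec()
    sos = spec.resp_sos(com.sample_rate)
    rx = _filtfilt_sos(sos, np.asarray(com.com_x, dtype=float))
    ry = _filtfilt_sos(sos, np.asarray(com.com_y, dtype=float))
    resp = RespSeries(sample_rate=com.sample_rate, com_resp_x=rx, com_resp_y=ry,
                      start_time=com.start_time)
    if detect_extrema:
        resp.t_max, resp.t_min = detect_breath_extrema(resp)
    return resp


def detect_breath_extrema(resp: RespSeries) -> tuple[np.ndarray, np.ndarray]:
    """Breath landmarks from sign changes of the first difference.

    Maxima (derivative + -> -) mark the end of exhalation, minima
    (derivative - -> +) the end of inhalation.  Detection runs on whichever
    respiratory component has the larger variance; a constant signal yields
    empty landmark lists.
    """
    x = resp.com_resp_x if np.var(resp.com_resp_x) >= np.var(resp.com_resp_y) \
        else resp.com_resp_y
    d = np.diff(x)
    s = np.sign(d)
    # carry the previous non-zero sign across flat runs
    nz = s != 0
    if not nz.any():
        return np.empty(0), np.empty(0)
    idx = np.where(nz, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0.0)
    change = np.flatnonzero((filled[1:] != filled[:-1]) & (filled[1:] != 0) & (filled[:-1] != 0))
    t = resp.times
    max_t = t[change[filled[change] > 0] + 1]
    min_t = t[change[filled[change] < 0] + 1]
    return max_t, min_t


def resp_angle(resp: RespSeries, min_disp_frac: float = 0.25) -> np.ndarray:
    """Per-breath respiratory-axis angle, degrees in [0, 90].

    For each maximum time and the next minimum time the angle is
    ``arctan(|dy/dx|)`` of the respiratory CoM displacement between the two
    landmarks.  Returns an array aligned with :func:`breath_pairs`; skipped
    breaths hold NaN.  A breath is skipped when its displacement vanishes,
    or when its magnitude falls below ``min_disp_frac`` of the 90th
    percentile of all breath displacements — residual in-band sensor noise
    produces spurious tiny "breaths" between real ones whose angles are
    essentially random, so they carry no postural information.
    """
    pairs = breath_pairs(resp)
    if len(pairs) == 0:
        return np.empty(0)
    t = resp.times
    i_max = np.searchsorted(t, pairs[:, 0])
    i_min = np.searchsorted(t, pairs[:, 1])
    dx = resp.com_resp_x[i_min] - resp.com_resp_x[i_max]
    dy = resp.com_resp_y[i_min] - resp.com_resp_y[i_max]
    mag = np.hypot(dx, dy)
    floor = min_disp_frac * np.percentile(mag, 90) if len(mag) else 0.0
    angles = np.degrees(np.arctan2(np.abs(dy), np.abs(dx)))
    angles[(mag == 0) | (mag < floor)] = np.nan
    return angles


def breath_pairs(resp: RespSeries) -> np.ndarray:
    """(t_max, next t_min) pairs, shape (n_breaths, 2)."""
    out = []
    t_min = np.asarray(resp.t_min)
    for tm in np.asarray(resp.t_max):
        following = t_min[t_min > tm]
        if len(following):
            out.append((tm, following[0]))
    if not out:
        return np.empty((0, 2))
    pairs = np.asarray(out)
    # successive maxima may share the next minimum near signal edges; keep first
    _, first = np.unique(pairs[:, 1], return_index=True)
    return pairs[np.sort(first)]


def isolate_cardiac(recording: LoadCellRecording, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase equiripple FIR band-pass of the summed head-end forces.

    The heartbeat shows up as a micro-oscillation (ballistocardiogram) in
    LH+RH; band-passing isolates it from posture drift and respiration.
    Output length equals input length.
    """
    spec = spec or FilterSpec()
    taps = spec.cardiac_taps(recording.sample_rate)
    return _filtfilt_fir(taps, recording.lh + recording.rh)


# ---------------------------------------------------------------------------
# Sliding-window feature extraction
# ---------------------------------------------------------------------------

def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 and np.isfinite(den) else np.nan


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if len(x) else np.nan


def extract_features(recording: LoadCellRecording, window_s: float = 45.0,
                     shift_s: float = 15.0, spec: FilterSpec | None = None) -> pd.DataFrame:
    """The twelve-feature table over a sliding window.

    Filters run once over the whole recording; windows then aggregate.  The
    window is half-open ``[t, t + window_s)`` anchored at the recording
    start, advanced by ``shift_s``; a 45 s window at 50 Hz aggregates 2250
    samples.  Returns a DataFrame with ``window_start_s``, the columns of
    :data:`FEATURE_NAMES`, and a boolean ``flag`` marking rows with any
    missing feature (no breath pair in the window, or a zero ratio
    denominator).
    """
    spec = spec or FilterSpec()
    fs = recording.sample_rate
    wlen = int(round(window_s * fs))
    slen = int(round(shift_s * fs))
    n = len(recording)
    if n < wlen:
        raise ValidationError(
            f"recording of {n} samples shorter than one {window_s} s window ({wlen} samples)"
        )
    com = compute_com(recording)
    resp = isolate_respiration(com, spec)
    pulse = isolate_cardiac(recording, spec)
    pairs = breath_pairs(resp)
    angles = resp_angle(resp)

    if spec.rms_norm == "global_p97":
        gx = np.percentile(np.abs(resp.com_resp_x - resp.com_resp_x.mean()), 97)
        gy = np.percentile(np.abs(resp.com_resp_y - resp.com_resp_y.mean()), 97)

    n_windows = (n - wlen) // slen + 1
    rows = []
    for k in range(n_windows):
        i0, i1 = k * slen, k * slen + wlen
        t0 = recording.start_time + i0 / fs
        t1 = recording.start_time + i1 / fs
        cx, cy = com.com_x[i0:i1], com.com_y[i0:i1]
        row = {
            "window_start_s": t0,
            "meanCoM_x": float(np.mean(cx)),
            "meanCoM_y": float(np.mean(cy)),
            "stdCoM_x": float(np.std(cx)),
            "stdCoM_y": float(np.std(cy)),
        }
        row["ratio_meanCoM"] = _safe_ratio(row["meanCoM_y"], row["meanCoM_x"])
        row["ratio_stdCoM"] = _safe_ratio(row["stdCoM_y"], row["stdCoM_x"])

        if len(pairs):
            in_win = (pairs[:, 0] >= t0) & (pairs[:, 1] < t1) & np.isfinite(angles)
            win_angles = angles[in_win]
        else:
            win_angles = np.empty(0)
        if len(win_angles) >= 1:
            row["CoM_resp_ANG"] = float(np.mean(win_angles))
            row["stdCoM_resp_ANG"] = float(np.std(win_angles)) if len(win_angles) > 1 else 0.0
        else:
            row["CoM_resp_ANG"] = np.nan
            row["stdCoM_resp_ANG"] = np.nan

        rx = resp.com_resp_x[i0:i1] - np.mean(resp.com_resp_x[i0:i1])
        ry = resp.com_resp_y[i0:i1] - np.mean(resp.com_resp_y[i0:i1])
        rms_x, rms_y = _rms(rx), _rms(ry)
        if spec.rms_norm == "window_p97":
            rms_x = _safe_ratio(rms_x, float(np.percentile(np.abs(rx), 97)))
            rms_y = _safe_ratio(rms_y, float(np.percentile(np.abs(ry), 97)))
        elif spec.rms_norm == "global_p97":
            rms_x = _safe_ratio(rms_x, float(gx))
            rms_y = _safe_ratio(rms_y, float(gy))
        row["rmsCoM_resp_x"] = rms_x
        row["rmsCoM_resp_y"] = rms_y
        row["ratio_rmsCoM_resp"] = _safe_ratio(rms_y, rms_x)
        row["rmsPulse"] = _rms(pulse[i0:i1])
        rows.append(row)

    table = pd.DataFrame(rows, columns=["window_start_s"] + FEATURE_NAMES)
    table["flag"] = table[FEATURE_NAMES].isna().any(axis=1)
    table.attrs.update({"window_s": window_s, "shift_s": shift_s, "sample_rate": fs})
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the feature CSV (missing values as empty fields)."""
    cols = ["window_start_s"] + FEATURE_NAMES
    table[cols].to_csv(Path(path), index=False)
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    missing = [c for c in ["window_start_s"] + FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: feature table missing columns {missing}")
    table["flag"] = table[FEATURE_NAMES].isna().any(axis=1)
    return table
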