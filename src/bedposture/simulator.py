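"""Synthetic bed-occupant simulator.

Generates four-channel load-cell recordings with known posture schedules so
the full feature-extraction and classification pipeline can be exercised and
validated without real overnight recordings.  The generative model mirrors
the statistical structure the features assume:

* a posture-dependent static CoM offset (lying on the left shifts weight
  toward the left sensors, and vice versa);
* a respiration-driven CoM oscillation of millimetre amplitude along an
  axis whose angle from the bed's x-axis depends on posture (steep when
  supine, shallow when side-lying);
* a small cardiac force oscillation carried by the head-end sensors
  (balanced against the foot-end sensors so the summed vertical force stays
  equal to body weight);
* additive white Gaussian sensor noise per channel.

Forces are laid out on the four corners by the bilinear distribution that is
the exact right-inverse of the CoM equations, so the simulator's ground
truth is recoverable by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .signal_model import (
    BedGeometry, LoadCellRecording, POSTURES, ValidationError,
)

__all__ = [
    "OccupantProfile",
    "PostureSchedule",
    "forces_from_com",
    "simulate_recording",
    "sample_profile",
    "sample_cohort",
    "random_schedule",
    "simulate_raters",
    "DEFAULT_GEOMETRY",
]

#: A typical single-bed footprint between leg sensors.
DEFAULT_GEOMETRY = BedGeometry(width_m=1.0, length_m=2.0)


@dataclass(frozen=True)
class OccupantProfile:
    """Parameters of one simulated occupant.

    ``static_com_offset`` maps posture to the quasi-static CoM offset
    (x lateral, y longitudinal, metres); ``resp_axis_angle`` maps posture to
    the respiratory-axis angle in degrees (0..90).  ``resp_amp`` is the CoM
    excursion amplitude in metres; ``cardiac_amp`` the peak force of the
    cardiac oscillation on the head-end pair, newtons.
    """

    body_weight: float = 700.0                       # N  (~71 kg)
    static_com_offset: dict = field(default_factory=lambda: {
        "LEFT": (0.07, 0.18), "SUPINE": (0.0, 0.20), "RIGHT": (-0.07, 0.18),
    })
    resp_freq: float = 0.25                          # Hz (15 breaths/min)
    resp_amp: float = 0.0015                         # m
    resp_axis_angle: dict = field(default_factory=lambda: {
        "LEFT": 20.0, "SUPINE": 80.0, "RIGHT": 35.0,
    })
    cardiac_freq: float = 1.17                       # Hz (~70 bpm)
    cardiac_amp: float = 0.5                         # N on LH+RH
    noise_sd: float = 0.5                            # N per channel

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be > 0")
        if self.resp_amp < 0 or self.noise_sd < 0 or self.cardiac_amp < 0:
            raise ValidationError("amplitudes and noise_sd must be >= 0")
        for p, ang in self.resp_axis_angle.items():
            if not 0 <= ang <= 90:
                raise ValidationError(f"resp_axis_angle[{p}]={ang} outside [0, 90]")


@dataclass(frozen=True)
class PostureSchedule:
    """Ordered (posture, duration_s) segments."""

    segments: tuple

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("schedule must contain at least one segment")
        for posture, dur in self.segments:
            if posture not in POSTURES:
                raise ValidationError(f"unknown posture {posture!r}")
            if dur <= 0:
                raise ValidationError("segment durations must be > 0")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    def posture_at(self, sample_times: np.ndarray) -> np.ndarray:
        """Posture token per sample time (last segment covers the tail)."""
        edges = np.cumsum([d for _, d in self.segments])
        idx = np.searchsorted(edges, sample_times, side="right")
        idx = np.clip(idx, 0, len(self.segments) - 1)
        tokens = np.array([p for p, _ in self.segments], dtype=object)
        return tokens[idx]


def forces_from_com(total_weight: float, com: tuple[float, float] | np.ndarray,
                    geometry: BedGeometry) -> tuple[np.ndarray, ...]:
    """Bilinear corner distribution of a weight at a given CoM.

    LH = W(1/2 + x/w)(1/2 + y/l), and symmetrically for the other corners;
    the four forces sum to W and invert the CoM equations exactly.  Accepts
    scalar or array CoM components.
    """
    x = np.asarray(com[0] if not isinstance(com, np.ndarray) else com[..., 0], dtype=float)
    y = np.asarray(com[1] if not isinstance(com, np.ndarray) else com[..., 1], dtype=float)
    w, length = geometry.width_m, geometry.length_m
    if np.any(np.abs(x) > w / 2) or np.any(np.abs(y) > length / 2):
        raise ValidationError("CoM outside the bed footprint")
    ax, ay = x / w, y / length
    lh = total_weight * (0.5 + ax) * (0.5 + ay)
    rh = total_weight * (0.5 - ax) * (0.5 + ay)
    lf = total_weight * (0.5 + ax) * (0.5 - ay)
    rf = total_weight * (0.5 - ax) * (0.5 - ay)
    return lh, rh, lf, rf


def simulate_recording(profile: OccupantProfile, schedule: PostureSchedule,
                       geometry: BedGeometry = DEFAULT_GEOMETRY,
                       sample_rate: float = 50.0,
                       tare: np.ndarray | None = None,
                       seed: int | None = None,
                       transition_fade_s: float = 2.0,
                       window_s: float = 45.0, shift_s: float = 15.0,
                       ) -> tuple[LoadCellRecording, pd.DataFrame]:
    """Simulate one occupant's recording and its per-window ground truth.

    Per sample the target CoM is the current posture's static offset plus
    ``resp_amp * sin(2*pi*f*t)`` along the posture's respiratory axis
    ``(cos(theta), sin(theta))``.  Posture changes cross-fade linearly over
    ``transition_fade_s``.  Forces come from :func:`forces_from_com` on the
    body weight; any tare is split equally across channels; the cardiac
    sinusoid is added to the head-end channels and balanced on the foot-end
    channels (net vertical force conserved); seeded Gaussian noise is added
    per channel.

    Returns the recording and a DataFrame of ``(window_start_s, posture)``
    ground-truth labels, one per analysis window, labelled by majority time.
    """
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration_s * sample_rate))
    if n < 1:
        raise ValidationError("schedule too short for one sample")
    t = np.arange(n) / sample_rate
    postures = schedule.posture_at(t)

    off = np.empty((n, 2))
    theta = np.empty(n)
    for p in POSTURES:
        m = postures == p
        if m.any():
            off[m] = profile.static_com_offset[p]
            theta[m] = np.radians(profile.resp_axis_angle[p])
    fade = int(round(transition_fade_s * sample_rate))
    if fade > 1:
        # moving average of the step trace = linear cross-fade at transitions
        off = uniform_filter1d(off, size=fade, axis=0, mode="nearest")
        theta = uniform_filter1d(theta, size=fade, mode="nearest")

    resp = profile.resp_amp * np.sin(2 * np.pi * profile.resp_freq * t)
    com_x = off[:, 0] + resp * np.cos(theta)
    com_y = off[:, 1] + resp * np.sin(theta)
    lh, rh, lf, rf = forces_from_com(profile.body_weight,
                                     np.stack([com_x, com_y], axis=-1), geometry)

    cardiac = 0.5 * profile.cardiac_amp * np.sin(2 * np.pi * profile.cardiac_freq * t)
    lh, rh = lh + cardiac, rh + cardiac
    lf, rf = lf - cardiac, rf - cardiac

    if tare is not None:
        tare = np.asarray(tare, dtype=float)
        lh, rh, lf, rf = (lh + tare[0], rh + tare[1], lf + tare[2], rf + tare[3])
    if profile.noise_sd > 0:
        noise = rng.normal(0.0, profile.noise_sd, size=(4, n))
        lh, rh, lf, rf = lh + noise[0], rh + noise[1], lf + noise[2], rf + noise[3]

    recording = LoadCellRecording(sample_rate=sample_rate, lh=lh, rh=rh, lf=lf, rf=rf,
                                  geometry=geometry, tare=tare,
                                  meta={"seed": seed, "profile": asdict(profile)})

    wlen, slen = int(round(window_s * sample_rate)), int(round(shift_s * sample_rate))
    starts = np.arange(0, n - wlen + 1, slen)
    labels = []
    for i0 in starts:
        window_post = postures[i0:i0 + wlen]
        vals, counts = np.unique(window_post.astype(str), return_counts=True)
        labels.append(vals[np.argmax(counts)])
    truth = pd.DataFrame({"window_start_s": starts / sample_rate,
                          "posture": np.array(labels, dtype=object)})
    return recording, truth


# ---------------------------------------------------------------------------
# Cohorts and raters
# ---------------------------------------------------------------------------

def sample_profile(rng: np.random.Generator) -> OccupantProfile:
    """Draw one occupant with realistic between-subject variation.

    Side-lying lateral offsets and respiratory-axis angles are drawn from
    ranges that overlap across subjects (a light supine sleeper can place
    the CoM where a heavy side sleeper does), which is what makes
    leave-one-subject-out generalisation genuinely imperfect and per-subject
    calibration useful.
    """
    u = rng.uniform
    left_x, right_x = u(0.02, 0.12), -u(0.02, 0.12)
    return OccupantProfile(
        body_weight=u(450.0, 900.0),
        static_com_offset={
            "LEFT": (left_x, u(0.10, 0.25)),
            "SUPINE": (u(-0.04, 0.04), u(0.10, 0.25)),
            "RIGHT": (right_x, u(0.10, 0.25)),
        },
        resp_freq=u(0.18, 0.32),
        resp_amp=u(0.0010, 0.0025),
        resp_axis_angle={
            "LEFT": u(5.0, 45.0),
            "SUPINE": u(45.0, 80.0),
            "RIGHT": u(5.0, 45.0),
        },
        cardiac_freq=u(0.9, 1.5),
        cardiac_amp=u(0.3, 0.8),
        noise_sd=u(0.3, 1.0),
    )


def sample_cohort(n_subjects: int, seed: int) -> list[OccupantProfile]:
    """Draw a cohort of occupant profiles from a master seed."""
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    return [sample_profile(np.random.default_rng(s)) for s in seeds]


def random_schedule(duration_s: float, rng: np.random.Generator,
                    segment_range_s: tuple[float, float] = (90.0, 300.0)) -> PostureSchedule:
    """A random posture schedule: segments of random posture and duration.

    Consecutive segments always change posture; durations are uniform over
    ``segment_range_s`` and the last segment is stretched to fill
    ``duration_s`` exactly.
    """
    segments = []
    remaining = duration_s
    prev = None
    while remaining > 0:
        choices = [p for p in POSTURES if p != prev]
        posture = choices[rng.integers(len(choices))]
        dur = float(rng.uniform(*segment_range_s))
        if remaining - dur < segment_range_s[0] / 2:
            dur = remaining
        segments.append((posture, dur))
        prev = posture
        remaining -= dur
    return PostureSchedule(tuple(segments))


def simulate_raters(true_labels: np.ndarray, n_raters: int = 3,
                    error_rate: float = 0.05, seed: int | None = None) -> np.ndarray:
    """Simulate independent raters labelling each window.

    Each rater reports the true posture except with probability
    ``error_rate``, in which case one of the other two classes is chosen
    uniformly (emulating occlusion by bedding).  Returns an
    (n_windows, n_raters) array of tokens.
    """
    rng = np.random.default_rng(seed)
    true_labels = np.asarray(true_labels, dtype=object)
    n = len(true_labels)
    out = np.empty((n, n_raters), dtype=object)
    for r in range(n_raters):
        out[:, r] = true_labels
        err = rng.random(n) < error_rate
        for i in np.flatnonzero(err):
            others = [p for p in POSTURES if p != true_labels[i]]
            out[i, r] = others[rng.integers(2)]
    return out


def write_manifest(path: str | Path, profile: OccupantProfile,
                   schedule: PostureSchedule, geometry: BedGeometry,
                   sample_rate: float, seed: int | None) -> Path:
    """Ground-truth JSON manifest for a simulated recording."""
    doc = {
        "profile": asdict(profile),
        "schedule": [list(s) for s in schedule.segments],
        "geometry": {"width_m": geometry.width_m, "length_m": geometry.length_m},
        "sample_rate_hz": sample_rate,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2))
    return Path(path)
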