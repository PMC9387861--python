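"""Uniformly sampled time-series containers and the signal primitives
(zero-phase Butterworth filtering, trapezoidal integration, prominence-based
peak picking, central-difference curvature) that every detector builds on.

All filtering in the package is zero-phase (forward-backward): event *timing*
is the deliverable, and a causal filter would bias every detected time by its
group delay.  The stated cutoff therefore applies per pass; the cascade is
-6 dB at the cutoff.  Signals are odd-reflection padded by roughly three
times the filter's impulse-response length before filtering so that trials
that start and end mid-motion do not ring at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from skate_events.errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "UniformSeries", "IMURecording", "MarkerTrack", "PeakList",
    "butter_filter", "integrate_signal", "find_peaks", "second_derivative",
]

#: Semantic axis names used throughout the detectors.
SEMANTIC_AXES = ("yaw", "roll", "pitch")
CHANNEL_NAMES = ("x", "y", "z")

WRIST_LOCATIONS = ("wrist_left", "wrist_right")
SKI_LOCATIONS = ("ski_left", "ski_right")
MARKER_LOCATIONS = ("pole_tip_left", "pole_tip_right", "ski_left", "ski_right")


@dataclass(frozen=True)
class UniformSeries:
    """One uniformly sampled scalar channel.

    Sample ``k`` has timestamp ``t0 + k / fs``.  Values must be finite and
    the series non-empty; violations raise at construction.
    """

    t0: float
    fs: float
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise InvalidParameterError("values must be a non-empty 1-D sequence")
        if not np.isfinite(vals).all():
            raise InvalidParameterError("values must all be finite")
        if not (self.fs > 0):
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.fs

    def time_at(self, index: int) -> float:
        return self.t0 + index / self.fs

    def index_at(self, time: float) -> int:
        """Nearest sample index for a trial-relative time (clipped in-range)."""
        k = int(round((time - self.t0) * self.fs))
        return min(max(k, 0), self.values.size - 1)

    def shifted(self, dt: float) -> "UniformSeries":
        return replace(self, t0=self.t0 + dt)

    def with_values(self, values: np.ndarray, units: str | None = None,
                    label: str | None = None) -> "UniformSeries":
        return UniformSeries(
            t0=self.t0, fs=self.fs, values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
            units=self.units if units is None else units,
        )


@dataclass(frozen=True)
class IMURecording:
    """Six-channel inertial recording bound to a body/equipment location.

    ``acc`` and ``gyro`` hold the x, y, z channels (m·s⁻² and deg·s⁻¹);
    ``axis_map`` maps the semantic axes {yaw, roll, pitch} onto channel
    names {x, y, z} (a bijection).  All channels share t0, fs and length.
    """

    location: str
    acc: tuple[UniformSeries, UniformSeries, UniformSeries]
    gyro: tuple[UniformSeries, UniformSeries, UniformSeries]
    axis_map: dict = field(default_factory=lambda: {"yaw": "z", "roll": "x", "pitch": "y"})

    def __post_init__(self):
        if self.location not in WRIST_LOCATIONS + SKI_LOCATIONS:
            raise InvalidParameterError(f"unknown IMU location {self.location!r}")
        chans = tuple(self.acc) + tuple(self.gyro)
        ref = chans[0]
        for ch in chans[1:]:
            if not (ch.fs == ref.fs and ch.t0 == ref.t0 and len(ch) == len(ref)):
                raise InvalidParameterError("all six channels must share t0, fs and length")
        if sorted(self.axis_map) != sorted(SEMANTIC_AXES) or \
                sorted(self.axis_map.values()) != sorted(CHANNEL_NAMES):
            raise InvalidParameterError(
                f"axis_map must be a bijection {SEMANTIC_AXES} -> {CHANNEL_NAMES}")

    @property
    def fs(self) -> float:
        return self.acc[0].fs

    @property
    def t0(self) -> float:
        return self.acc[0].t0

    def _chan(self, triplet, axis: str) -> UniformSeries:
        return triplet[CHANNEL_NAMES.index(self.axis_map[axis])]

    def acc_axis(self, axis: str) -> UniformSeries:
        """Acceleration channel for a semantic axis ('yaw', 'roll', 'pitch')."""
        return self._chan(self.acc, axis)

    def gyro_axis(self, axis: str) -> UniformSeries:
        """Angular-rate channel for a semantic axis."""
        return self._chan(self.gyro, axis)

    def is_wrist(self) -> bool:
        return self.location in WRIST_LOCATIONS

    def is_ski(self) -> bool:
        return self.location in SKI_LOCATIONS

    @property
    def side(self) -> str:
        return self.location.rsplit("_", 1)[1]


@dataclass(frozen=True)
class MarkerTrack:
    """Vertical position trajectory of one marker (pole tip or ski)."""

    location: str
    z: UniformSeries

    def __post_init__(self):
        if self.location not in MARKER_LOCATIONS:
            raise InvalidParameterError(f"unknown marker location {self.location!r}")

    @property
    def side(self) -> str:
        return self.location.rsplit("_", 1)[1]

    @property
    def family(self) -> str:
        return "pole" if self.location.startswith("pole_tip") else "ski"


@dataclass(frozen=True)
class PeakList:
    """Strict local extrema of one sign with their topographic prominences."""

    indices: np.ndarray
    prominences: np.ndarray
    sign: Literal["positive", "negative"]

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        prom = np.asarray(self.prominences, dtype=float)
        if idx.size != prom.size:
            raise InvalidParameterError("indices and prominences must have equal length")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise InvalidParameterError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "prominences", prom)

    def __len__(self) -> int:
        return self.indices.size


def butter_filter(x: UniformSeries, order: int, cutoff_hz: float,
                  mode: Literal["lowpass", "highpass"]) -> UniformSeries:
    """Zero-phase Butterworth filter (forward-backward ``filtfilt``).

    Odd-reflection padding of about three impulse-response lengths is applied
    before filtering and trimmed afterwards, so trials that start or end
    mid-motion do not produce edge transients.

    Raises
    ------
    InvalidParameterError
        If ``cutoff_hz`` is not strictly inside (0, fs/2).
    InsufficientDataError
        If the series is shorter than ``3 * order + 1`` samples.
    """
    if mode not in ("lowpass", "highpass"):
        raise InvalidParameterError(f"mode must be lowpass/highpass, got {mode!r}")
    nyq = x.fs / 2.0
    if not (0.0 < cutoff_hz < nyq):
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie strictly inside (0, {nyq}) Hz")
    n = len(x)
    if n < 3 * order + 1:
        raise InsufficientDataError(
            f"series of length {n} too short for order-{order} filtering")
    sos = sps.butter(order, cutoff_hz, btype=mode, fs=x.fs, output="sos")
    # ~3x the impulse-response length (~fs/cutoff samples), capped at n-1.
    padlen = int(min(n - 1, max(3 * order, round(3 * x.fs / cutoff_hz))))
    y = sps.sosfiltfilt(sos, x.values, padtype="odd", padlen=padlen)
    return x.with_values(y)


def integrate_signal(x: UniformSeries) -> UniformSeries:
    """Cumulative trapezoidal integral starting at 0 (rate -> angle).

    Keeps length and sampling; units 'deg·s⁻¹' become 'deg'.
    """
    y = cumulative_trapezoid(x.values, dx=1.0 / x.fs, initial=0.0)
    units = x.units
    if units.endswith("·s⁻¹"):
        units = units[: -len("·s⁻¹")]
    elif units.endswith("/s"):
        units = units[:-2]
    return x.with_values(y, units=units)


def find_peaks(x: UniformSeries, min_prominence: float,
               sign: Literal["positive", "negative"]) -> PeakList:
    """All strict local extrema of the given sign with topographic
    prominence >= ``min_prominence``.

    Negative peaks are found on the negated signal.  Prominence uses the
    standard topographic definition bounded by the signal ends.  Plateaus of
    equal-height samples collapse to the leftmost plateau sample.
    """
    if min_prominence < 0:
        raise InvalidParameterError("min_prominence must be >= 0")
    if sign not in ("positive", "negative"):
        raise InvalidParameterError(f"sign must be positive/negative, got {sign!r}")
    v = x.values if sign == "positive" else -x.values
    idx, props = sps.find_peaks(v, prominence=min_prominence, plateau_size=0)
    # collapse equal-height plateaus to their leftmost sample
    left = props.get("left_edges")
    if left is not None:
        idx = np.asarray(left, dtype=int)
    return PeakList(indices=idx, prominences=props["prominences"], sign=sign)


def second_derivative(x: UniformSeries) -> UniformSeries:
    """Central-difference second derivative, ``(x[k-1] - 2 x[k] + x[k+1]) fs²``.

    Endpoints are replicated from the nearest interior value.  Exact for
    quadratics on the interior.
    """
    if len(x) < 3:
        raise InsufficientDataError("second_derivative needs at least 3 samples")
    v = x.values
    d = np.empty_like(v)
    d[1:-1] = (v[:-2] - 2.0 * v[1:-1] + v[2:]) * x.fs ** 2
    d[0] = d[1]
    d[-1] = d[-2]
    units = "m·s⁻²" if x.units == "m" else (x.units + "·s⁻²" if x.units else "")
    return x.with_values(d, units=units)
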