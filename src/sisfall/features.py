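"""Feature extractors C1-C14 over full-overlap sliding windows.

One acceleration sample is the vector a[k] = (ax, ay, az) in g. Dynamic
features slide a trailing window of Nv samples, a~[k] = a[k-Nv+1..k],
advanced one sample at a time ("full overlap"). Integrals use the
trapezoid rule with limits k-Nv+1 to k. The horizontal plane of a
waist-mounted device is the (x, z) plane: omitting the gravity axis y
suppresses false positives from vigorous vertical ADLs.

Feature catalogue (defaults in parentheses; window lengths follow the
heuristic search outcome: 0.5 s for C10/C11/C14, 1 s otherwise):

=====  =================================================================
C1     sum vector magnitude |a[k]| (per sample)
C2     sum vector magnitude on the horizontal plane (per sample)
C3     max peak-to-peak amplitude: norm of the per-axis window ranges
C4     angle between z-axis and vertical: atan2(sqrt(ax^2+az^2), -ay)
C5     trunk orientation: window std of the tilt angle
C6     horizontal orientation change: dot product of mean (ax, az) over
       the previous and the current adjacent windows
C7     jerk: ||a[k] - a[k-Nv+1]|| / (t[k] - t[k-Nv+1])
C8     std magnitude on the horizontal plane sqrt(sx^2 + sz^2)
C9     std magnitude sqrt(sx^2 + sy^2 + sz^2)
C10    signal magnitude area (1/N) * sum_i trapz(|a_i|) dt
C11    C10 restricted to the horizontal plane
C12    activity signal magnitude area: trapz(|a|) over the sample index
C13    C12 restricted to the horizontal plane
C14    velocity approximation (1/N) * hypot(trapz(ax) dt, trapz(az) dt)
=====  =================================================================

Standard deviations are population (divide by N). Windowed series start
at the first index with a complete window (k = Nv-1; C6 needs two
windows, so k = 2*Nv-1): no partial windows, no padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import AccelTrace

__all__ = [
    "WindowSpec",
    "FeatureSeries",
    "FEATURE_CODES",
    "PER_SAMPLE_FEATURES",
    "HALF_SECOND_FEATURES",
    "default_window",
    "trapezoid_integral",
    "extract",
]

FEATURE_CODES: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 15))
PER_SAMPLE_FEATURES = frozenset({"C1", "C2", "C4"})
HALF_SECOND_FEATURES = frozenset({"C10", "C11", "C14"})


@dataclass(frozen=True)
class WindowSpec:
    """Trailing sliding window: ``nv`` samples, advanced ``stride`` samples."""

    nv: int
    fs: float
    stride: int = 1

    def __post_init__(self) -> None:
        if self.nv < 2:
            raise ValueError("windowed features need nv >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class FeatureSeries:
    """One feature's value per valid time index for one trial.

    ``values[i]`` corresponds to trace index ``valid_from + i * stride``.
    """

    code: str
    values: np.ndarray
    valid_from: int
    window: WindowSpec | None
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.code}: non-finite feature values")

    def __len__(self) -> int:
        return len(self.values)

    def max(self) -> float:
        if len(self.values) == 0:
            raise ValueError(f"{self.code}: empty feature series")
        return float(np.max(self.values))


def default_window(code: str, fs: float) -> WindowSpec | None:
    """The per-feature default window: none for the static features,
    0.5 s for C10/C11/C14, 1 s for the other dynamic features."""
    if code not in FEATURE_CODES:
        raise ValueError(f"unknown feature code {code!r}")
    if code in PER_SAMPLE_FEATURES:
        return None
    seconds = 0.5 if code in HALF_SECOND_FEATURES else 1.0
    return WindowSpec(nv=int(round(seconds * fs)), fs=fs)


def trapezoid_integral(values: np.ndarray, fs: float) -> float:
    """Trapezoid-rule integral with sample spacing 1/fs."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("trapezoid integral needs at least 2 samples")
    dt = 1.0 / fs
    return float(dt * (values.sum() - 0.5 * (values[0] + values[-1])))


# ---------------------------------------------------------------------------
# O(n) rolling primitives (trailing windows of length n, stride 1)

def _rolling_sum(x: np.ndarray, n: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    return c[n:] - c[:-n]


def _rolling_mean(x: np.ndarray, n: int) -> np.ndarray:
    return _rolling_sum(x, n) / n


def _rolling_std(x: np.ndarray, n: int) -> np.ndarray:
    # population form; globally centred first so the cumulative sums stay
    # well conditioned, and variance clipped at 0 against rounding noise
    x = x - x.mean()
    m = _rolling_mean(x, n)
    m2 = _rolling_sum(x * x, n) / n
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def _rolling_trapz(x: np.ndarray, n: int, dx: float) -> np.ndarray:
    s = _rolling_sum(x, n)
    first = x[: len(x) - n + 1]
    last = x[n - 1 :]
    return dx * (s - 0.5 * (first + last))


def _rolling_range(x: np.ndarray, n: int) -> np.ndarray:
    # trailing max/min via ndimage filters; origin shifts the centred
    # window so it ends at the current sample
    origin = (n - 1) // 2
    hi = ndimage.maximum_filter1d(x, size=n, mode="nearest", origin=origin)
    lo = ndimage.minimum_filter1d(x, size=n, mode="nearest", origin=origin)
    return (hi - lo)[n - 1 :]


def _require_length(trace: AccelTrace, nv: int, code: str) -> None:
    if len(trace) < nv:
        raise ValueError(f"{code}: trace of {len(trace)} samples shorter than window nv={nv}")


def _tilt(ax: np.ndarray, az: np.ndarray, ay: np.ndarray) -> np.ndarray:
    return np.arctan2(np.hypot(ax, az), ay)


# ---------------------------------------------------------------------------
# feature computations

def _c1(trace: AccelTrace) -> np.ndarray:
    return trace.magnitude()


def _c2(trace: AccelTrace) -> np.ndarray:
    return np.hypot(trace.ax, trace.az)


def _c3(trace: AccelTrace, nv: int, variant: str = "per-axis") -> np.ndarray:
    if variant == "per-axis":
        # peak-to-peak per axis inside the window, combined as a norm
        rx = _rolling_range(trace.ax, nv)
        ry = _rolling_range(trace.ay, nv)
        rz = _rolling_range(trace.az, nv)
        return np.sqrt(rx**2 + ry**2 + rz**2)
    if variant == "magnitude":
        return _rolling_range(trace.magnitude(), nv)
    raise ValueError(f"unknown C3 variant {variant!r}")


def _c4(trace: AccelTrace) -> np.ndarray:
    # kept as printed: the vertical reference enters with a minus sign,
    # so quiet standing (0, 1, 0) reads pi
    return _tilt(trace.ax, trace.az, -trace.ay)


def _c5(trace: AccelTrace, nv: int) -> np.ndarray:
    return _rolling_std(_tilt(trace.ax, trace.az, trace.ay), nv)


def _c6(trace: AccelTrace, nv: int) -> np.ndarray:
    # adjacent non-overlapping windows [k-2N+1, k-N] and [k-N+1, k]
    mx = _rolling_mean(trace.ax, nv)
    mz = _rolling_mean(trace.az, nv)
    return mx[:-nv] * mx[nv:] + mz[:-nv] * mz[nv:]


def _c7(trace: AccelTrace, nv: int, variant: str = "3-axis") -> np.ndarray:
    m = len(trace) - nv + 1
    dx = trace.ax[nv - 1 :] - trace.ax[:m]
    dz = trace.az[nv - 1 :] - trace.az[:m]
    if variant == "3-axis":
        dy = trace.ay[nv - 1 :] - trace.ay[:m]
        d = np.sqrt(dx**2 + dy**2 + dz**2)
    elif variant == "horizontal":
        d = np.hypot(dx, dz)
    else:
        raise ValueError(f"unknown C7 variant {variant!r}")
    return d / ((nv - 1) / trace.fs)


def _c8(trace: AccelTrace, nv: int) -> np.ndarray:
    return np.hypot(_rolling_std(trace.ax, nv), _rolling_std(trace.az, nv))


def _c9(trace: AccelTrace, nv: int) -> np.ndarray:
    return np.sqrt(
        _rolling_std(trace.ax, nv) ** 2
        + _rolling_std(trace.ay, nv) ** 2
        + _rolling_std(trace.az, nv) ** 2
    )


def _c10(trace: AccelTrace, nv: int) -> np.ndarray:
    dt = 1.0 / trace.fs
    total = (
        _rolling_trapz(np.abs(trace.ax), nv, dt)
        + _rolling_trapz(np.abs(trace.ay), nv, dt)
        + _rolling_trapz(np.abs(trace.az), nv, dt)
    )
    return total / nv


def _c11(trace: AccelTrace, nv: int) -> np.ndarray:
    dt = 1.0 / trace.fs
    total = _rolling_trapz(np.abs(trace.ax), nv, dt) + _rolling_trapz(
        np.abs(trace.az), nv, dt
    )
    return total / nv


def _c12(trace: AccelTrace, nv: int) -> np.ndarray:
    # integrated over the sample index n (dx = 1), units g*samples
    return _rolling_trapz(trace.magnitude(), nv, 1.0)


def _c13(trace: AccelTrace, nv: int) -> np.ndarray:
    return _rolling_trapz(np.hypot(trace.ax, trace.az), nv, 1.0)


def _c14(trace: AccelTrace, nv: int, normalize: bool = True) -> np.ndarray:
    dt = 1.0 / trace.fs
    ix = _rolling_trapz(trace.ax, nv, dt)
    iz = _rolling_trapz(trace.az, nv, dt)
    v = np.hypot(ix, iz)
    return v / nv if normalize else v


def extract(
    trace: AccelTrace,
    code: str,
    window: WindowSpec | None = None,
    *,
    filtered: bool = False,
    c3_variant: str = "per-axis",
    c7_variant: str = "3-axis",
    c14_normalize: bool = True,
) -> FeatureSeries:
    """Compute one feature series for a trace.

    ``window`` overrides the feature's default window; it is ignored for
    the per-sample features C1, C2, C4. ``filtered`` is a provenance flag
    recorded on the output (filtering itself lives in
    :mod:`sisfall.preprocessing`).
    """
    if code not in FEATURE_CODES:
        raise ValueError(f"unknown feature code {code!r}")

    if code in PER_SAMPLE_FEATURES:
        values = {"C1": _c1, "C2": _c2, "C4": _c4}[code](trace)
        return FeatureSeries(code, values, valid_from=0, window=None, filtered=filtered)

    win = window or default_window(code, trace.fs)
    assert win is not None
    nv = win.nv
    _require_length(trace, nv if code != "C6" else 2 * nv, code)

    if code == "C3":
        values = _c3(trace, nv, c3_variant)
    elif code == "C5":
        values = _c5(trace, nv)
    elif code == "C6":
        values = _c6(trace, nv)
    elif code == "C7":
        values = _c7(trace, nv, c7_variant)
    elif code == "C8":
        values = _c8(trace, nv)
    elif code == "C9":
        values = _c9(trace, nv)
    elif code == "C10":
        values = _c10(trace, nv)
    elif code == "C11":
        values = _c11(trace, nv)
    elif code == "C12":
        values = _c12(trace, nv)
    elif code == "C13":
        values = _c13(trace, nv)
    else:  # C14
        values = _c14(trace, nv, c14_normalize)

    valid_from = 2 * nv - 1 if code == "C6" else nv - 1
    if win.stride > 1:
        values = values[:: win.stride]
    return FeatureSeries(code, values, valid_from=valid_from, window=win, filtered=filtered)
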