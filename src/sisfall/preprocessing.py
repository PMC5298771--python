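"""Low-pass preprocessing of acceleration traces.

The preprocessing arm of the pipeline is a 4th-order IIR Butterworth
low-pass at 5 Hz, applied independently to each axis as a single causal
forward pass with zero initial state (as a device powering on would run
it). The raw arm simply bypasses this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import AccelTrace

__all__ = ["FilterSpec", "design_lowpass", "frequency_response", "filter_trace"]


@dataclass(frozen=True)
class FilterSpec:
    order: int = 4
    cutoff_hz: float = 5.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={self.fs / 2} Hz)"
            )


def design_lowpass(spec: FilterSpec) -> np.ndarray:
    """Design the Butterworth low-pass as cascaded second-order sections.

    Second-order sections keep the recursion numerically robust; the
    contract is on the frequency response (unit DC gain, -3 dB at the
    cutoff, monotone roll-off), not the realization.
    """
    return signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs, output="sos")


def frequency_response(
    spec: FilterSpec, freqs_hz: np.ndarray | list[float]
) -> np.ndarray:
    """Magnitude of the designed filter at the given frequencies (Hz)."""
    sos = design_lowpass(spec)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * freqs_hz / spec.fs)
    return np.abs(h)


def filter_trace(trace: AccelTrace, spec: FilterSpec | None = None) -> AccelTrace:
    """Filter each axis causally (single forward pass, zero initial state).

    Length and sampling rate are preserved; the filter's group delay is
    accepted, matching an online embedded detector.
    """
    if spec is None:
        spec = FilterSpec(fs=trace.fs)
    if spec.fs != trace.fs:
        spec = FilterSpec(order=spec.order, cutoff_hz=spec.cutoff_hz, fs=trace.fs)
    if len(trace) <= 3 * spec.order:
        raise ValueError(
            f"trace too short to filter: {len(trace)} samples <= 3*order={3 * spec.order}"
        )
    sos = design_lowpass(spec)
    return AccelTrace(
        fs=trace.fs,
        ax=signal.sosfilt(sos, trace.ax),
        ay=signal.sosfilt(sos, trace.ay),
        az=signal.sosfilt(sos, trace.az),
    )
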