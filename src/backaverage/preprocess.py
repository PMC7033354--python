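"""Band-pass filtering and EMG envelope normalisation.

Software filtering is optional (clinical traces usually arrive
hardware-filtered); the recommended corner presets are

====  ===========  =========================================
key   band (Hz)    use
====  ===========  =========================================
bp    0.01 - 50    slow pre-movement potentials (readiness
                   potential); the 0.01 Hz high-pass keeps
                   deflections that start seconds before onset
myoclonus  1 - 70  sharp pre-myoclonic cortical transients
emg   10 - 250     surface EMG (movement artifact is <20 Hz)
====  ===========  =========================================

A slow monophasic potential of duration ``d`` is roughly half a cycle of
a ``1/(2d)`` Hz oscillation, so a 2-s readiness potential lives near
0.25 Hz and is destroyed by a standard 1 Hz high-pass —
:func:`slow_wave_min_frequency` makes that check explicit.

The mandatory detection front-end is :func:`rectify_rescale`: full-wave
rectification followed by global min-max scaling to [0, 1], so detection
thresholds are unitless fractions of the strongest burst regardless of
amplifier gain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "FILTER_PRESETS",
    "NormalizedEnvelope",
    "bandpass",
    "rectify_rescale",
    "slow_wave_min_frequency",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass corners.

    Parameters
    ----------
    low_hz, high_hz : float
        High-pass and low-pass corner frequencies.
    order : int
        Filter order (per pass; zero-phase application doubles the
        effective order).
    zero_phase : bool
        Apply forward-backward (``sosfiltfilt``) so no group delay is
        introduced into onset timing.  Default True.
    """

    low_hz: float
    high_hz: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_for(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"low-pass corner {self.high_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


#: Recommended corner presets, by scenario.
FILTER_PRESETS: dict[str, FilterSpec] = {
    "bp": FilterSpec(0.01, 50.0),
    "myoclonus": FilterSpec(1.0, 70.0),
    "emg": FilterSpec(10.0, 250.0),
}


@dataclass
class NormalizedEnvelope:
    """Rectified, min-max rescaled EMG trace in [0, 1].

    ``min_raw``/``max_raw`` are the rectified extrema (original units)
    used for the scaling, kept for reporting.
    """

    values: np.ndarray
    fs: float
    min_raw: float
    max_raw: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.values.size


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth band-pass; output has the same length as input.

    Zero-phase (forward-backward) application is the default so that a
    symmetric pulse keeps its peak sample and detected onsets are not
    delayed by the filter.
    """
    x = np.asarray(x, dtype=float).ravel()
    spec.validate_for(fs)
    warmup = 3 * spec.order * fs / spec.low_hz
    if x.size < warmup:
        warnings.warn(
            f"signal ({x.size} samples) is shorter than the filter warm-up "
            f"(~{warmup:.0f} samples for a {spec.low_hz} Hz high-pass); "
            "edge transients may dominate",
            stacklevel=2,
        )
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def rectify_rescale(
    emg: np.ndarray,
    fs: float,
    smooth_s: float = 0.0,
    clip_percentile: float | None = None,
) -> NormalizedEnvelope:
    """Full-wave rectify an EMG trace and min-max rescale it to [0, 1].

    ``values = (|emg| - min|emg|) / (max|emg| - min|emg|)`` using the
    global extrema of the whole trace, so the result is invariant to the
    amplifier gain.  A single huge artifact therefore compresses the
    scale; ``clip_percentile`` (e.g. 99.9) optionally clips the rectified
    trace at that percentile before scaling to blunt this.

    ``smooth_s`` > 0 applies a centred moving average of that duration to
    the rectified trace before scaling (off by default: the detector's
    own quiet-window / refractory rules handle the raggedness of raw
    rectified EMG).

    Raises
    ------
    ValueError
        If the rectified trace is constant (a dead channel or a wrongly
        selected column).
    """
    r = np.abs(np.asarray(emg, dtype=float).ravel())
    if smooth_s > 0:
        w = max(1, int(round(smooth_s * fs)))
        r = np.convolve(r, np.ones(w) / w, mode="same")
    if clip_percentile is not None:
        r = np.minimum(r, np.percentile(r, clip_percentile))
    lo, hi = float(r.min()), float(r.max())
    if hi == lo:
        raise ValueError("flat EMG channel: cannot rescale")
    return NormalizedEnvelope(values=(r - lo) / (hi - lo), fs=fs,
                              min_raw=lo, max_raw=hi)


def slow_wave_min_frequency(duration_s: float) -> float:
    """Fundamental frequency of a monophasic deflection lasting ``duration_s``.

    Models the deflection as half a cycle: ``f = 1 / (2 * duration_s)``.
    A readiness potential building over 2 s is thus a ~0.25 Hz wave, so
    any EEG high-pass corner above the returned value will attenuate it —
    use this to sanity-check a filter choice before averaging.
    """
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    return 1.0 / (2.0 * duration_s)


def check_highpass_for_slow_wave(low_hz: float, duration_s: float = 2.0) -> bool:
    """Warn (and return False) if a high-pass corner would remove a slow
    pre-movement potential of the given duration."""
    f = slow_wave_min_frequency(duration_s)
    if low_hz > f:
        warnings.warn(
            f"high-pass corner {low_hz} Hz exceeds the ~{f} Hz content of a "
            f"{duration_s} s slow potential; the potential would be filtered out",
            stacklevel=2,
        )
        return False
    return True
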