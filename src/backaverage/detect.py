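"""EMG burst-onset detection on the normalised envelope.

A sample ``n`` of the rectified, [0, 1]-rescaled envelope is marked as a
burst onset iff all of:

(a) it is an upward threshold crossing: ``env[n] >= threshold`` and
    (``n == 0`` or ``env[n-1] < threshold``);
(b) both context windows fit inside the record:
    ``n - Wb >= 0`` and ``n + Wa <= N`` with
    ``Wb = round(time_before_s * fs)``, ``Wa = round(time_after_s * fs)``;
(c) the pre-window is quiet: ``mean(env[n-Wb : n]) < amp_before``
    (the crossing sample is excluded);
(d) the post-window is active: ``mean(env[n : n+Wa]) > amp_after``
    (the crossing sample is included; half-open on the right);
(e) refractory: at least ``round(burst_duration_s * fs)`` samples since
    the most recently accepted marker (greedy left-to-right scan).

The marker sits on the crossing sample itself — the burst onset — since
the averaging stage defines time 0 as the onset of the muscle burst.
Candidates whose windows run off either edge are skipped silently.

:func:`detect_bursts_oracle` is a deliberately naive loop-based
re-implementation kept as an independent cross-check for the vectorised
detector; the two must agree exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedEnvelope

logger = logging.getLogger(__name__)

__all__ = ["DetectionParams", "MarkerSet", "detect_bursts", "detect_bursts_oracle"]


def _win(seconds: float, fs: float) -> int:
    """Window length in samples: round(seconds * fs), at least 1."""
    return max(1, int(round(seconds * fs)))


@dataclass(frozen=True)
class DetectionParams:
    """The six burst-detection parameters.

    Parameters
    ----------
    threshold : float in (0, 1]
        Envelope level a sample must reach to be a candidate burst.
    time_before_s, time_after_s : float, seconds
        Lengths of the quiet pre-window and active post-window around
        the crossing.
    amp_before : float in [0, 1]
        The pre-window mean must be *lower* than this.
    amp_after : float in [0, 1]
        The post-window mean must be *higher* than this.
    burst_duration_s : float, seconds
        Refractory period: no new marker within this time of the last
        accepted one, so one burst yields one marker.
    """

    threshold: float = 0.3
    time_before_s: float = 0.5
    time_after_s: float = 0.05
    amp_before: float = 0.1
    amp_after: float = 0.3
    burst_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.time_before_s <= 0 or self.time_after_s <= 0:
            raise ValueError("time_before_s and time_after_s must be positive")
        if self.burst_duration_s < 0:
            raise ValueError("burst_duration_s must be >= 0")
        for name in ("amp_before", "amp_after"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.amp_before >= self.amp_after:
            warnings.warn(
                f"amp_before ({self.amp_before}) >= amp_after ({self.amp_after}): "
                "the quiet/active conditions are inconsistent or vacuous",
                stacklevel=2,
            )


@dataclass
class MarkerSet:
    """Ordered burst-onset sample indices (0-based) with provenance."""

    indices: np.ndarray
    fs: float
    provenance: str = "detected"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).ravel()
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("marker indices must be strictly increasing")
        if self.provenance not in ("detected", "ground_truth", "manual"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n(self) -> int:
        return self.indices.size

    def times(self) -> np.ndarray:
        """Marker times in seconds."""
        return self.indices / self.fs


def detect_bursts(env: NormalizedEnvelope, params: DetectionParams) -> MarkerSet:
    """Scan the envelope left-to-right and mark burst onsets.

    Returns an empty :class:`MarkerSet` (with a warning) when nothing
    qualifies — adjust the parameters and run again.
    """
    x = env.values
    N = x.size
    fs = env.fs
    wb = _win(params.time_before_s, fs)
    wa = _win(params.time_after_s, fs)
    refractory = int(round(params.burst_duration_s * fs))
    if wb + wa > N:
        raise ValueError(
            f"context windows ({wb}+{wa} samples) longer than the recording ({N})"
        )

    # (a) upward crossings
    above = x >= params.threshold
    crossing = above.copy()
    crossing[1:] &= ~above[:-1]
    cand = np.flatnonzero(crossing)
    # (b) windows must fit
    cand = cand[(cand - wb >= 0) & (cand + wa <= N)]
    if cand.size:
        # (c)/(d) window means via a cumulative sum
        csum = np.concatenate(([0.0], np.cumsum(x)))
        pre_mean = (csum[cand] - csum[cand - wb]) / wb
        post_mean = (csum[cand + wa] - csum[cand]) / wa
        cand = cand[(pre_mean < params.amp_before) & (post_mean > params.amp_after)]

    # (e) greedy refractory
    accepted: list[int] = []
    last = None
    for n in cand:
        if last is None or n - last >= refractory:
            accepted.append(int(n))
            last = int(n)

    n_skipped = int(np.sum(crossing)) - cand.size
    logger.info("detected %d markers (%d crossings rejected by windows/amplitude)",
                len(accepted), n_skipped)
    if not accepted:
        warnings.warn("no bursts detected; adjust the parameters and run again",
                      stacklevel=2)
    return MarkerSet(indices=np.array(accepted, dtype=int), fs=fs,
                     provenance="detected")


def detect_bursts_oracle(env: NormalizedEnvelope, params: DetectionParams) -> MarkerSet:
    """Naive reference detector: explicit loops, intended for short inputs.

    Enumerates every sample, tests the crossing/window/amplitude
    conditions with per-sample loops, then applies the refractory rule in
    a second pass.  Must agree exactly with :func:`detect_bursts`.
    """
    x = env.values
    N = x.size
    fs = env.fs
    wb = _win(params.time_before_s, fs)
    wa = _win(params.time_after_s, fs)
    refractory = int(round(params.burst_duration_s * fs))
    if wb + wa > N:
        raise ValueError(
            f"context windows ({wb}+{wa} samples) longer than the recording ({N})"
        )

    candidates = []
    for n in range(N):
        if x[n] < params.threshold:
            continue
        if n > 0 and x[n - 1] >= params.threshold:
            continue
        if n - wb < 0 or n + wa > N:
            continue
        pre = 0.0
        for k in range(n - wb, n):
            pre += x[k]
        if not pre / wb < params.amp_before:
            continue
        post = 0.0
        for k in range(n, n + wa):
            post += x[k]
        if not post / wa > params.amp_after:
            continue
        candidates.append(n)

    accepted: list[int] = []
    for n in candidates:
        if not accepted or n - accepted[-1] >= refractory:
            accepted.append(n)
    return MarkerSet(indices=np.array(accepted, dtype=int), fs=fs,
                     provenance="detected")


def match_markers(
    detected: MarkerSet, truth: MarkerSet, tolerance_s: float = 0.010
) -> tuple[int, int, int]:
    """Greedily match detected markers to ground truth within a tolerance.

    Returns ``(n_matched, n_detected, n_truth)``; precision is
    ``n_matched / n_detected`` and recall ``n_matched / n_truth``.
    """
    tol = tolerance_s * truth.fs
    used = np.zeros(truth.n, dtype=bool)
    matched = 0
    for d in detected.indices:
        diffs = np.abs(truth.indices - d)
        diffs[used] = np.iinfo(np.int64).max
        if diffs.size and diffs.min() <= tol:
            used[int(np.argmin(diffs))] = True
            matched += 1
    return matched, detected.n, truth.n
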