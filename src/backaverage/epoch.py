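"""Marker-locked segmentation, baseline correction, averaging and the
randomised split-half consistency check.

Epochs are cut around each burst-onset marker: a segment of ``window_s``
seconds whose sample ``round(onset_s * fs)`` is the marker itself, so
the time axis runs from ``-onset_s`` to ``window_s - onset_s``
(half-open) with 0 at movement onset.  EEG activity time-locked to the
onset survives the across-epoch average; background activity cancels at
the ~1/sqrt(N) rate.

Baseline correction subtracts, per EEG segment, the mean of the first
``baseline_s`` seconds of that segment, so slow inter-trial drift cannot
masquerade as a pre-movement potential.  Rectified EMG keeps its raw
baseline (its resting level is physiologically meaningful).

The split-half check randomly partitions the epochs into two groups and
averages each independently: a genuine movement-locked potential
reproduces in both halves.  Consistency is traditionally judged by eye;
the Pearson correlation between the two pre-onset averages reported here
is this package's own quantitative stand-in for that judgement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .detect import MarkerSet
from .io import ChannelPair

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentSpec",
    "SegmentSet",
    "AverageResult",
    "SplitHalfResult",
    "segment",
    "baseline_correct",
    "average",
    "split_half",
]


@dataclass(frozen=True)
class SegmentSpec:
    """Epoch geometry.

    Parameters
    ----------
    window_s : float
        Total segment length in seconds.
    onset_s : float
        Offset of time-point 0 (the burst onset) from segment start.
    baseline_s : float
        Length, from segment start, of the baseline-correction interval.
        Must not extend past the onset.

    The defaults (3 s window, onset at 2 s, 0.5 s baseline) span the
    full ~2 s lead time of a slow readiness potential.
    """

    window_s: float = 3.0
    onset_s: float = 2.0
    baseline_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.onset_s < self.window_s:
            raise ValueError(
                f"need 0 < onset_s < window_s, got onset={self.onset_s}, window={self.window_s}"
            )
        if not 0 <= self.baseline_s <= self.onset_s:
            raise ValueError(
                f"baseline_s must lie in [0, onset_s], got {self.baseline_s}"
            )

    def n_samples(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def onset_sample(self, fs: float) -> int:
        return int(round(self.onset_s * fs))


@dataclass
class SegmentSet:
    """Stack of equal-length EEG+EMG epochs time-locked to markers."""

    eeg: np.ndarray  # [n_kept, L]
    emg: np.ndarray  # [n_kept, L]
    kept_markers: MarkerSet
    dropped: int
    fs: float
    spec: SegmentSpec
    baseline_applied: bool = False

    @property
    def n_kept(self) -> int:
        return self.eeg.shape[0]

    @property
    def length(self) -> int:
        return self.eeg.shape[1]


@dataclass
class AverageResult:
    """Per-sample mean traces with a time axis relative to burst onset."""

    eeg_mean: np.ndarray
    emg_mean: np.ndarray
    time_s: np.ndarray
    n: int
    fs: float
    eeg_sem: np.ndarray | None = None

    @property
    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.time_s)))


@dataclass
class SplitHalfResult:
    """Two independent half-averages plus their pre-onset similarity."""

    avg_a: AverageResult
    avg_b: AverageResult
    assignment: np.ndarray  # permutation of segment indices; first ceil(n/2) -> A
    seed: int
    similarity: float


def segment(pair: ChannelPair, markers: MarkerSet, spec: SegmentSpec) -> SegmentSet:
    """Cut marker-locked epochs out of the paired EMG/EEG channels.

    For each marker ``m`` the segment covers samples
    ``[m - round(onset_s*fs), m - round(onset_s*fs) + L)`` of both
    channels, ``L = round(window_s*fs)``.  Markers whose window exceeds
    either record edge are dropped (and counted in ``dropped``).
    """
    fs = pair.fs
    L = spec.n_samples(fs)
    on = spec.onset_sample(fs)
    N = pair.n_samples
    if L > N:
        raise ValueError(f"segment length ({L} samples) exceeds the record ({N})")
    eeg_rows, emg_rows, kept = [], [], []
    for m in markers.indices:
        start = int(m) - on
        if start < 0 or start + L > N:
            continue
        eeg_rows.append(pair.eeg[start:start + L])
        emg_rows.append(pair.emg[start:start + L])
        kept.append(int(m))
    dropped = markers.n - len(kept)
    if not kept:
        raise ValueError("no complete segments: every marker's window crosses a record edge")
    if dropped:
        logger.info("dropped %d of %d markers at record edges", dropped, markers.n)
    return SegmentSet(
        eeg=np.array(eeg_rows), emg=np.array(emg_rows),
        kept_markers=MarkerSet(indices=np.array(kept, dtype=int), fs=fs,
                               provenance=markers.provenance),
        dropped=dropped, fs=fs, spec=spec,
    )


def baseline_correct(segs: SegmentSet, baseline_s: float | None = None) -> SegmentSet:
    """Subtract each EEG segment's own early-baseline mean.

    The baseline interval is the first ``baseline_s`` seconds of the
    segment (default: the value in ``segs.spec``); it must end at or
    before the onset so post-movement activity never leaks into the
    correction.  EMG segments are left untouched.
    """
    if segs.baseline_applied:
        raise ValueError("baseline correction already applied")
    if baseline_s is None:
        baseline_s = segs.spec.baseline_s
    if baseline_s > segs.spec.onset_s:
        raise ValueError(
            f"baseline_s ({baseline_s}) extends past the onset ({segs.spec.onset_s} s); "
            "the baseline would include post-onset activity"
        )
    nb = int(round(baseline_s * segs.fs))
    if nb < 1:
        raise ValueError("baseline interval is empty")
    eeg = segs.eeg - segs.eeg[:, :nb].mean(axis=1, keepdims=True)
    return SegmentSet(
        eeg=eeg, emg=segs.emg, kept_markers=segs.kept_markers,
        dropped=segs.dropped, fs=segs.fs,
        spec=replace(segs.spec, baseline_s=baseline_s),
        baseline_applied=True,
    )


def _make_average(eeg: np.ndarray, emg: np.ndarray, spec: SegmentSpec,
                  fs: float) -> AverageResult:
    L = eeg.shape[1]
    on = spec.onset_sample(fs)
    time_s = (np.arange(L) - on) / fs
    n = eeg.shape[0]
    sem = eeg.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
    return AverageResult(eeg_mean=eeg.mean(axis=0), emg_mean=emg.mean(axis=0),
                         time_s=time_s, n=n, fs=fs, eeg_sem=sem)


def average(segs: SegmentSet) -> AverageResult:
    """Per-sample arithmetic mean of the epoch stack (the back-average)."""
    if segs.n_kept < 1:
        raise ValueError("cannot average zero segments")
    return _make_average(segs.eeg, segs.emg, segs.spec, segs.fs)


def split_half(segs: SegmentSet, seed: int) -> SplitHalfResult:
    """Randomly partition the epochs into two halves and average each.

    The permutation is drawn from ``numpy.random.default_rng(seed)``;
    group A takes the first ``ceil(n/2)`` permuted epochs.  Similarity is
    the Pearson correlation between the two EEG half-averages restricted
    to the pre-onset samples (where a readiness potential lives).
    Deterministic given the seed.
    """
    n = segs.n_kept
    if n < 2:
        raise ValueError(f"split-half needs at least 2 segments, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = (n + 1) // 2  # odd n: group A gets the extra segment
    ia, ib = perm[:half], perm[half:]
    avg_a = _make_average(segs.eeg[ia], segs.emg[ia], segs.spec, segs.fs)
    avg_b = _make_average(segs.eeg[ib], segs.emg[ib], segs.spec, segs.fs)
    on = segs.spec.onset_sample(segs.fs)
    a, b = avg_a.eeg_mean[:on], avg_b.eeg_mean[:on]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        sim = 1.0 if np.allclose(a, b) else 0.0  # degenerate constant halves
    else:
        sim = float(stats.pearsonr(a, b).statistic)
    return SplitHalfResult(avg_a=avg_a, avg_b=avg_b, assignment=perm,
                           seed=seed, similarity=sim)


def split_half_similarities(segs: SegmentSet, n_splits: int, seed: int) -> np.ndarray:
    """Similarity values for ``n_splits`` re-seeded random splits.

    Split ``k`` uses seed ``seed + k``, so the whole family is
    reproducible from the single base seed.
    """
    return np.array([split_half(segs, seed + k).similarity for k in range(n_splits)])


def measure_trough(avg: AverageResult, smooth_s: float = 0.05,
                   t_min: float | None = None, t_max: float = 0.1) -> tuple[float, float]:
    """Amplitude and latency of the pre-movement negative trough.

    The EEG average is smoothed with a centred moving average of
    ``smooth_s`` seconds (default 50 ms) so single-sample noise
    excursions do not masquerade as the trough, then the minimum is
    taken over ``[t_min, t_max]`` (default: whole pre-onset interval
    through +100 ms).  Returns ``(amplitude, latency_s)``.
    """
    y = avg.eeg_mean
    w = max(1, int(round(smooth_s * avg.fs)))
    if w > 1:
        y = np.convolve(y, np.ones(w) / w, mode="same")
    mask = avg.time_s <= t_max
    if t_min is not None:
        mask &= avg.time_s >= t_min
    idx = np.flatnonzero(mask)
    k = idx[np.argmin(y[idx])]
    return float(y[k]), float(avg.time_s[k])
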