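"""Synthetic EEG-EMG recordings with ground-truth burst onsets.

Emulates the two clinical scenarios the back-average is used for:

``mode="bp"``
    Self-paced jerky movements preceded by a readiness potential — a
    slow negative EEG ramp building from ``bp_lead_s`` seconds before
    each EMG burst to ``bp_amp_uv`` at onset, then returning to zero.
``mode="myoclonus"``
    Cortical myoclonus — a brief biphasic EEG transient (one windowed
    cycle of a 15 Hz sine) a few tens of ms before each burst.
``mode="null"``
    Negative control: EEG is background noise only.

The EMG channel is band-limited (20-300 Hz) Gaussian baseline noise with
burst epochs of the same noise raised by ``emg_burst_snr``; each burst
is shaped by a raised-cosine-tapered (Tukey) envelope whose 10 ms onset
ramp gives the sharp EMG rise real bursts show, so the true onset is a
well-defined sample.  The EEG background is Gaussian noise low-passed at
50 Hz, scaled to ``eeg_noise_sd``.

Determinism: all randomness flows from ``numpy.random.default_rng``
(PCG64) generators spawned from a single ``SeedSequence(seed)``; event
placement, EMG, EEG background and the auxiliary channels each get their
own stream, so switching ``mode`` changes *only* the EEG template — the
EMG channel is bit-identical across modes at the same seed.

The written layout mirrors the interchange convention used downstream:
four columns, EMG in column 3 and EEG in column 4 (1-based); columns 1-2
are auxiliary noise channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .detect import MarkerSet
from .io import Recording, write_markers, write_recording

__all__ = ["SynthConfig", "SynthRecording", "generate", "write_synth"]

EMG_COL = 3  #: 1-based column of the EMG channel in generated recordings
EEG_COL = 4  #: 1-based column of the EEG channel


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults encode the recommended recording session for a readiness-
    potential study: at least 1000 Hz sampling, ~40 movements at least
    5 s apart (about twice the ~20 trials needed to see the potential,
    so the set can be split in half), and a potential leading the
    movement by up to 2 s.

    Parameters
    ----------
    fs : float
        Sampling rate, Hz (>= 1000).
    duration_s : float
        Total record length, seconds.
    n_events : int
        Number of movements.
    min_iei_s : float
        Minimum inter-event interval, seconds.
    emg_burst_dur_s : float
        EMG burst length, seconds.
    emg_burst_snr : float
        Burst RMS / baseline RMS.
    eeg_noise_sd : float
        Background EEG standard deviation, microvolts.
    mode : {"bp", "myoclonus", "null"}
        Which EEG template (if any) precedes each burst.
    bp_amp_uv : float
        Readiness-potential amplitude at onset, microvolts (negative).
    bp_lead_s : float
        Readiness-potential lead time before onset, seconds.
    myo_latency_s : float
        Lead of the myoclonic EEG transient before the EMG burst,
        seconds.  The 20 ms default is a generator convenience of the
        right order of magnitude, not a measured physiological constant.
    myo_amp_uv : float
        Transient amplitude, microvolts.
    seed : int
        Master seed for all randomness.
    """

    fs: float = 1000.0
    duration_s: float = 300.0
    n_events: int = 40
    min_iei_s: float = 5.0
    emg_burst_dur_s: float = 0.2
    emg_burst_snr: float = 10.0
    eeg_noise_sd: float = 10.0
    mode: str = "bp"
    bp_amp_uv: float = -8.0
    bp_lead_s: float = 2.0
    myo_latency_s: float = 0.020
    myo_amp_uv: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 1000:
            raise ValueError(f"sampling rate must be >= 1000 Hz, got {self.fs}")
        if self.mode not in ("bp", "myoclonus", "null"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_events < 1:
            raise ValueError("need at least one event")
        if self.n_events * self.min_iei_s >= self.duration_s:
            raise ValueError(
                f"{self.n_events} events at >= {self.min_iei_s} s spacing do not fit "
                f"in {self.duration_s} s; increase duration_s"
            )


@dataclass
class SynthRecording:
    """A generated recording plus its ground truth."""

    recording: Recording
    truth: MarkerSet
    config: SynthConfig


_EDGE_MARGIN_S = 3.0  # events keep this clearance from both record edges


def _place_events(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Event onset samples: uniform given all gaps >= min_iei_s.

    Drawn by the spacing construction: n uniform points in the slack
    interval (usable length minus the n-1 mandatory gaps), sorted, with
    the i-th shifted by i * min_iei_s.  Equivalent in distribution to
    rejection sampling of uniform points conditioned on the minimum gap,
    but O(n) and feasible at any density.
    """
    usable = cfg.duration_s - 2 * _EDGE_MARGIN_S
    slack = usable - (cfg.n_events - 1) * cfg.min_iei_s
    if slack <= 0:
        raise ValueError(
            f"{cfg.n_events} events with {cfg.min_iei_s} s gaps need more than "
            f"{cfg.duration_s} s; increase duration_s"
        )
    pts = np.sort(rng.uniform(0.0, slack, size=cfg.n_events))
    times = _EDGE_MARGIN_S + pts + np.arange(cfg.n_events) * cfg.min_iei_s
    return np.round(times * cfg.fs).astype(int)


def _bandlimited_noise(n: int, fs: float, low: float, high: float,
                       rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


def _bp_template(cfg: SynthConfig) -> tuple[np.ndarray, int]:
    """Slow ramp: 0 at -lead, bp_amp_uv at 0, back to 0 over 0.5 s.

    Returns the template and the offset of the onset sample within it.
    """
    n_lead = int(round(cfg.bp_lead_s * cfg.fs))
    n_ret = int(round(0.5 * cfg.fs))
    ramp = np.linspace(0.0, cfg.bp_amp_uv, n_lead, endpoint=False)
    ret = np.linspace(cfg.bp_amp_uv, 0.0, n_ret)
    return np.concatenate([ramp, ret]), n_lead


def _myo_template(cfg: SynthConfig) -> tuple[np.ndarray, int]:
    """One Hann-windowed cycle of a 15 Hz sine, centred myo_latency_s
    before the onset."""
    f0 = 15.0
    n_cyc = int(round(cfg.fs / f0))
    t = np.arange(n_cyc) / cfg.fs
    wave = cfg.myo_amp_uv * np.sin(2 * np.pi * f0 * t) * np.hanning(n_cyc)
    centre = int(round(cfg.myo_latency_s * cfg.fs))
    # onset sample sits centre samples after the template midpoint
    return wave, n_cyc // 2 + centre


def generate(config: SynthConfig) -> SynthRecording:
    """Generate a synthetic EEG-EMG recording with ground-truth onsets."""
    cfg = config
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    ss = np.random.SeedSequence(cfg.seed)
    rng_events, rng_emg, rng_eeg, rng_aux = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    onsets = _place_events(cfg, rng_events)

    # EMG: band-limited baseline noise; bursts add Tukey-shaped extra gain
    emg = _bandlimited_noise(n, fs, 20.0, 300.0, rng_emg)
    emg /= np.sqrt(np.mean(emg**2))  # unit baseline RMS
    burst_len = int(round(cfg.emg_burst_dur_s * fs))
    ramp_frac = min(1.0, 2 * 0.010 / cfg.emg_burst_dur_s)  # 10 ms cosine ramps
    win = sps.windows.tukey(burst_len, alpha=ramp_frac)
    gain = np.ones(n)
    for m in onsets:
        sl = slice(m, m + burst_len)
        gain[sl] += (cfg.emg_burst_snr - 1.0) * win[: n - m]
    emg *= gain

    # EEG: low-passed background noise at the requested SD
    sos = sps.butter(4, 50.0, btype="lowpass", fs=fs, output="sos")
    eeg = sps.sosfiltfilt(sos, rng_eeg.standard_normal(n))
    eeg *= cfg.eeg_noise_sd / eeg.std()
    if cfg.mode != "null":
        tmpl, t_onset = (_bp_template if cfg.mode == "bp" else _myo_template)(cfg)
        for m in onsets:
            start = m - t_onset
            sl_sig = slice(max(0, start), min(n, start + tmpl.size))
            sl_t = slice(sl_sig.start - start, sl_sig.stop - start)
            eeg[sl_sig] += tmpl[sl_t]

    aux = rng_aux.standard_normal((n, 2))
    data = np.column_stack([aux[:, 0], aux[:, 1], emg, eeg])
    rec = Recording(data=data, fs=fs, source=f"synthetic(mode={cfg.mode}, seed={cfg.seed})")
    truth = MarkerSet(indices=onsets, fs=fs, provenance="ground_truth")
    return SynthRecording(recording=rec, truth=truth, config=cfg)


def write_synth(sr: SynthRecording, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write the recording (interchange text) and truth markers (CSV).

    Returns ``(txt_path, truth_csv_path)``.  The text file loads back
    bit-identically and its EMG/EEG live in columns 3 and 4.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    txt = prefix.with_name(prefix.name + ".txt")
    csv = prefix.with_name(prefix.name + "_truth.csv")
    write_recording(sr.recording, txt)
    write_markers(sr.truth, sr.config.fs, csv)
    return txt, csv
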