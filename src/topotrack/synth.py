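"""Synthetic 32-channel EEG with event-locked responses at known times.

The generator emulates the structure of the tracking recordings: continuous
500 Hz data per subject, one 4 s motion window per trial separated by pure
-noise gaps, spatially correlated 1/f background noise, and additive
event-locked waveforms ("kernels") injected at the topological-event times
of the *target* set only.  Each event type carries a distinct Gabor-like
waveform and a ground-truth latency shift (flip anticipatory at -150 ms,
concave lagged at +150 ms, convex at 0 ms), all mixed through one fixed
bilateral ventral-occipital scalp topography.  Because distractor-set
events drive nothing, the distractor pipeline is a built-in null control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import EVENT_TYPES, detect_session_events
from .trajectory import MotionConfig, TrialTrajectory, generate_session

__all__ = [
    "CHANNELS_32",
    "MASTOIDS",
    "ScalpTopography",
    "EventKernel",
    "SynthConfig",
    "ContinuousRecording",
    "SimulatedDataset",
    "default_topography",
    "default_kernels",
    "make_noise",
    "embed_events",
    "simulate_dataset",
]

# 32-channel extended 10-20 montage with mastoid surrogates (TP9/TP10) for
# offline re-referencing and the O9/O10 inferior-occipital pair.
CHANNELS_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O9", "O1", "Oz", "O2", "O10",
)
MASTOIDS = ("TP9", "TP10")

_OCCIPITAL_WEIGHTS = {
    # bilateral ventral-occipital pattern, strongest over O1/O2
    "O1": 1.0, "O2": 1.0, "Oz": 0.7, "O9": 0.8, "O10": 0.8,
    "P7": 0.45, "P8": 0.45, "P3": 0.25, "P4": 0.25, "Pz": 0.15,
}


@dataclass(frozen=True)
class ScalpTopography:
    """Unit-norm channel weight vector describing a scalp distribution."""

    weights: np.ndarray
    ch_names: tuple[str, ...] = CHANNELS_32

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.ch_names),):
            raise ValueError("one weight per channel required")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        for must in ("O1", "Oz", "O2", "O9", "O10"):
            if must not in self.ch_names:
                raise ValueError(f"montage must include {must}")
        n = np.linalg.norm(w)
        if n == 0:
            raise ValueError("topography must be non-zero")
        object.__setattr__(self, "weights", w / n)


def default_topography() -> ScalpTopography:
    w = np.array([_OCCIPITAL_WEIGHTS.get(ch, 0.0) for ch in CHANNELS_32])
    return ScalpTopography(w)


@dataclass(frozen=True)
class EventKernel:
    """Event-locked waveform for one transition type.

    ``waveform`` is sampled on the symmetric ``tau`` grid (seconds),
    ``latency_shift`` places its centre of energy relative to the event
    (negative = anticipatory).  Peak amplitude is 1 (scaled by snr in µV
    at embedding time).
    """

    event_type: str
    waveform: np.ndarray
    tau: np.ndarray
    latency_shift: float = 0.0


def _gabor(tau: np.ndarray, freq: float, phase: float, sigma: float) -> np.ndarray:
    w = np.exp(-0.5 * (tau / sigma) ** 2) * np.cos(2 * np.pi * freq * tau + phase)
    return w / np.abs(w).max()


def default_kernels(
    sampling_rate: float = 500.0,
    support: float = 0.4,
    sigma: float = 0.1,
) -> dict[str, EventKernel]:
    """Three discriminable Gabor kernels with the ground-truth latency
    asymmetry: flip -150 ms (anticipatory), concave +150 ms, convex 0 ms.

    Frequencies sit in the 3–7 Hz band that dominates transition-locked
    ERPs, so each kernel's autocorrelation stays positive over ±50 ms (the
    interval event-time ESM is averaged over) while pairwise waveform
    correlations stay below 0.5 by construction.
    """
    half = int(round(support * sampling_rate))
    tau = np.arange(-half, half + 1) / sampling_rate
    spec = {
        "flip": (3.0, 0.0, -0.150),
        "concave": (5.0, np.pi / 2, +0.150),
        "convex": (7.0, 0.0, 0.0),
    }
    return {
        et: EventKernel(et, _gabor(tau, f, ph, sigma), tau, shift)
        for et, (f, ph, shift) in spec.items()
    }


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-recording parameters.

    ``snr`` is the ratio of kernel peak amplitude to the per-channel noise
    SD (noise is unit variance, so snr is also the peak in µV);
    ``noise_exponent`` is the 1/f^alpha spectral exponent;
    ``channel_noise_corr`` the pairwise spatial correlation of the noise.
    """

    n_subjects: int = 6
    sampling_rate: float = 500.0
    snr: float = 1.0
    noise_exponent: float = 1.0
    channel_noise_corr: float = 0.2
    inter_trial_gap: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if not 0 <= self.channel_noise_corr < 1:
            raise ValueError("channel_noise_corr must be in [0, 1)")
        if self.n_subjects < 1 or self.sampling_rate <= 0:
            raise ValueError("invalid n_subjects or sampling_rate")


@dataclass
class ContinuousRecording:
    """One subject's continuous multichannel EEG.

    ``data`` is (n_channels, n_samples) in µV; ``trial_onsets`` are the
    motion-onset sample indices of ``trial_ids``; ``trial_n_samples`` is
    the motion-window length in samples.
    """

    subject_id: int
    data: np.ndarray
    sampling_rate: float
    trial_onsets: np.ndarray
    trial_ids: np.ndarray
    trial_n_samples: int
    ch_names: tuple[str, ...] = CHANNELS_32

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def trial_slice(self, trial_id: int) -> slice:
        i = int(np.flatnonzero(self.trial_ids == trial_id)[0])
        on = int(self.trial_onsets[i])
        return slice(on, on + self.trial_n_samples)

    def to_mne(self):
        """Export as an :class:`mne.io.RawArray` (requires mne)."""
        import mne

        info = mne.create_info(list(self.ch_names), self.sampling_rate, "eeg")
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")


def make_noise(
    config: SynthConfig,
    n_samples: int,
    rng: np.random.Generator,
    n_channels: int = len(CHANNELS_32),
) -> np.ndarray:
    """Spatially correlated Gaussian 1/f^alpha noise, unit variance per channel.

    Channels share a common component (pairwise correlation
    ``channel_noise_corr``); the same spectral shaping is applied to every
    channel so the spatial correlation survives the colouring.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rho = config.channel_noise_corr
    shared = rng.standard_normal(n_samples)
    white = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(
        (n_channels, n_samples)
    )
    if config.noise_exponent != 0:
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / config.sampling_rate)
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
        spec = np.fft.rfft(white, axis=1) * gain
        white = np.fft.irfft(spec, n=n_samples, axis=1)
    white -= white.mean(axis=1, keepdims=True)
    white /= white.std(axis=1, keepdims=True)
    return white


@dataclass
class GroundTruth:
    """Bookkeeping of what was embedded where."""

    placements: pd.DataFrame  # trial_id, event_type, time_s, center_sample, truncated
    kernels: dict[str, EventKernel]
    topography: ScalpTopography
    snr: float


def embed_events(
    noise: np.ndarray,
    events: pd.DataFrame,
    kernels: dict[str, EventKernel],
    topography: ScalpTopography,
    snr: float,
    trial_onsets: np.ndarray,
    trial_ids: np.ndarray,
    sampling_rate: float,
    subject_id: int = 0,
    trial_n_samples: int | None = None,
) -> tuple[ContinuousRecording, GroundTruth]:
    """Add ``snr * kernel (x) topography`` at each event's (shifted) time.

    Event times are relative to their trial's motion onset.  Kernels whose
    support crosses a recording edge are truncated with a warning.
    """
    data = np.array(noise, dtype=float)
    n_ch, n_samples = data.shape
    onset_of = {int(t): int(o) for t, o in zip(trial_ids, trial_onsets)}
    rows = []
    for ev in events.itertuples(index=False):
        kern = kernels[ev.event_type]
        center = onset_of[int(ev.trial_id)] + int(
            round((ev.time_s + kern.latency_shift) * sampling_rate)
        )
        half = (len(kern.waveform) - 1) // 2
        lo, hi = center - half, center + half + 1
        klo, khi = 0, len(kern.waveform)
        truncated = False
        if lo < 0:
            klo, lo, truncated = -lo, 0, True
        if hi > n_samples:
            khi, hi, truncated = khi - (hi - n_samples), n_samples, True
        if truncated:
            warnings.warn(
                f"kernel support for event at trial {ev.trial_id}, "
                f"t={ev.time_s:.3f}s crosses the recording edge; truncated",
                stacklevel=2,
            )
        if hi > lo:
            data[:, lo:hi] += snr * np.outer(
                topography.weights, kern.waveform[klo:khi]
            )
        rows.append((int(ev.trial_id), ev.event_type, float(ev.time_s), center, truncated))
    if trial_n_samples is None:
        trial_n_samples = n_samples
    rec = ContinuousRecording(
        subject_id=subject_id,
        data=data,
        sampling_rate=sampling_rate,
        trial_onsets=np.asarray(trial_onsets, dtype=int),
        trial_ids=np.asarray(trial_ids, dtype=int),
        trial_n_samples=int(trial_n_samples),
        ch_names=topography.ch_names,
    )
    truth = GroundTruth(
        placements=pd.DataFrame(
            rows, columns=["trial_id", "event_type", "time_s", "center_sample", "truncated"]
        ),
        kernels=kernels,
        topography=topography,
        snr=snr,
    )
    return rec, truth


@dataclass
class SimulatedDataset:
    """One fully simulated study: shared trials/events, per-subject noise."""

    trials: list[TrialTrajectory]
    target_events: pd.DataFrame
    distractor_events: pd.DataFrame
    recordings: list[ContinuousRecording]
    ground_truth: list[GroundTruth]
    match_conditions: pd.Series  # trial_id -> condition

    @property
    def events(self) -> pd.DataFrame:
        return pd.concat([self.target_events, self.distractor_events], ignore_index=True)


def simulate_dataset(
    motion_config: MotionConfig,
    synth_config: SynthConfig,
    n_trials: int = 300,
    rng: np.random.Generator | int | None = None,
    kernels: dict[str, EventKernel] | None = None,
    topography: ScalpTopography | None = None,
    embed_at: str = "raw",
) -> SimulatedDataset:
    """End-to-end simulation: trajectories -> events -> recordings.

    All subjects share one trial set (and hence one event table), as in
    the original fixed-session design; the noise is drawn independently
    per subject.  Only target-set events drive kernels; the distractor
    event table is returned for null-control analyses.

    ``embed_at="raw"`` (default) places a kernel at *every* non-degenerate
    target transition — the simulated brain responds to each transition it
    perceives, while the returned event tables carry the repeat/boundary
    filters, which are an analysis step, not a property of the brain.
    ``embed_at="filtered"`` restricts kernels to the analysis events.
    """
    if rng is None:
        rng = np.random.default_rng(synth_config.rng_seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if kernels is None:
        kernels = default_kernels(synth_config.sampling_rate)
    if topography is None:
        topography = default_topography()
    if embed_at not in ("raw", "filtered"):
        raise ValueError("embed_at must be 'raw' or 'filtered'")

    trials = generate_session(motion_config, n_trials, rng)
    events = detect_session_events(trials, "both")
    t_events = events[events.set_label == "target"].reset_index(drop=True)
    d_events = events[events.set_label == "distractor"].reset_index(drop=True)
    if embed_at == "raw":
        raw = detect_session_events(trials, "target", debounce=0.0, start_excl=0.0, end_excl=0.0)
        drive_events = raw
    else:
        drive_events = t_events

    fs = synth_config.sampling_rate
    n_trial = int(round(motion_config.duration * fs)) + 1
    n_gap = int(round(synth_config.inter_trial_gap * fs))
    trial_ids = np.array([t.trial_id for t in trials], dtype=int)
    trial_onsets = n_gap + np.arange(n_trials) * (n_trial + n_gap)
    n_samples = int(n_gap + n_trials * (n_trial + n_gap))

    recordings, truths = [], []
    for s in range(synth_config.n_subjects):
        noise = make_noise(synth_config, n_samples, rng)
        rec, truth = embed_events(
            noise,
            drive_events,
            kernels,
            topography,
            synth_config.snr,
            trial_onsets,
            trial_ids,
            fs,
            subject_id=s,
            trial_n_samples=n_trial,
        )
        recordings.append(rec)
        truths.append(truth)
    match = pd.Series(
        {t.trial_id: t.match_condition for t in trials}, name="match_condition"
    )
    return SimulatedDataset(trials, t_events, d_events, recordings, truths, match)
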