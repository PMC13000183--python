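"""Epoching, grand averaging and the PCA channel-weight machinery.

The decoding chain works in "component space": a PCA of the per-type grand
-average transition ERPs (observations = epoch time samples of all three
event types, variables = the 32 channels, covariance PCA on channel
-centred data) yields a weight matrix whose rows are orthonormal scalp
distributions; projecting the continuous signal through one row gives the
component time series everything downstream correlates against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .synth import MASTOIDS, ContinuousRecording
from .topology import EVENT_TYPES

__all__ = [
    "EpochSet",
    "WeightMatrix",
    "SpatialPCA",
    "preprocess",
    "epoch",
    "grand_average",
    "transition_window_contrast",
    "pca_weights",
    "project",
]

OCCIPITAL = ("O1", "Oz", "O2")
ERP_WINDOW = (0.084, 0.128)  # transition-ERP contrast window, seconds


@dataclass
class EpochSet:
    """Event-locked epochs: ``data`` is (n_events, n_channels, n_tau) µV,
    ``times`` the relative-time grid in seconds, ``info`` one row per epoch
    (subject, trial_id, event_type, time_s)."""

    data: np.ndarray
    times: np.ndarray
    info: pd.DataFrame
    ch_names: tuple[str, ...]
    n_dropped: int = 0

    def __len__(self) -> int:
        return self.data.shape[0]

    def select(self, event_type: str) -> "EpochSet":
        mask = (self.info.event_type == event_type).to_numpy()
        return EpochSet(
            self.data[mask], self.times, self.info[mask].reset_index(drop=True),
            self.ch_names, 0,
        )

    def to_mne(self):
        """Export as :class:`mne.EpochsArray` (requires mne)."""
        import mne

        info = mne.create_info(list(self.ch_names), 1.0 / (self.times[1] - self.times[0]), "eeg")
        return mne.EpochsArray(
            self.data * 1e-6, info, tmin=float(self.times[0]), verbose="error"
        )


def preprocess(
    rec: ContinuousRecording,
    highpass: float = 0.5,
    reference: tuple[str, str] = MASTOIDS,
    order: int = 4,
) -> ContinuousRecording:
    """Zero-phase high-pass filter, then re-reference to a channel-pair mean.

    The Butterworth high-pass (default 0.5 Hz, applied forward-backward so
    phase is preserved) removes slow drifts; each channel then has the
    mean of the two reference channels (mastoid surrogates by default)
    subtracted.
    """
    for ch in reference:
        if ch not in rec.ch_names:
            raise ValueError(f"reference channel {ch!r} not in recording")
    data = rec.data
    if highpass and highpass > 0:
        sos = signal.butter(order, highpass, btype="highpass", fs=rec.sampling_rate, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    ref_idx = [rec.ch_names.index(ch) for ch in reference]
    data = data - data[ref_idx].mean(axis=0, keepdims=True)
    return ContinuousRecording(
        subject_id=rec.subject_id,
        data=data,
        sampling_rate=rec.sampling_rate,
        trial_onsets=rec.trial_onsets,
        trial_ids=rec.trial_ids,
        trial_n_samples=rec.trial_n_samples,
        ch_names=rec.ch_names,
    )


def epoch(
    rec: ContinuousRecording,
    events: pd.DataFrame,
    tau_min: float = -0.4,
    tau_max: float = 0.4,
) -> EpochSet:
    """Slice event-locked epochs out of the continuous recording.

    Event times (seconds from their trial's motion onset) are snapped to
    the nearest sample.  Epochs whose window would leave the trial's
    motion span are dropped (counted in ``n_dropped``) — epochs never
    cross trial boundaries.
    """
    fs = rec.sampling_rate
    j0 = int(round(tau_min * fs))
    j1 = int(round(tau_max * fs))
    times = np.arange(j0, j1 + 1) / fs
    onset_of = {int(t): int(o) for t, o in zip(rec.trial_ids, rec.trial_onsets)}

    slices, rows = [], []
    n_dropped = 0
    for ev in events.itertuples(index=False):
        onset = onset_of[int(ev.trial_id)]
        center = onset + int(round(ev.time_s * fs))
        lo, hi = center + j0, center + j1 + 1
        if lo < onset or hi > onset + rec.trial_n_samples:
            n_dropped += 1
            continue
        slices.append(rec.data[:, lo:hi])
        rows.append((rec.subject_id, int(ev.trial_id), ev.event_type, float(ev.time_s)))
    data = (
        np.stack(slices)
        if slices
        else np.empty((0, len(rec.ch_names), len(times)))
    )
    info = pd.DataFrame(rows, columns=["subject", "trial_id", "event_type", "time_s"])
    return EpochSet(data, times, info, rec.ch_names, n_dropped)


def grand_average(epochs: EpochSet, by: str = "event_type") -> dict[str, np.ndarray]:
    """Pooled grand average per group: the plain mean over *all* epochs of
    each group (every event weighs equally — not a mean of per-subject
    means), shape (n_channels, n_tau)."""
    out: dict[str, np.ndarray] = {}
    groups = epochs.info.groupby(by, sort=True).indices
    for key, idx in groups.items():
        out[key] = epochs.data[idx].mean(axis=0)
    return out


def transition_window_contrast(
    epochs: EpochSet,
    channels: tuple[str, ...] = OCCIPITAL,
    window: tuple[float, float] = ERP_WINDOW,
) -> pd.DataFrame:
    """Per-subject, per-type mean amplitude over ``channels`` and ``window``.

    This is the occipital transition-ERP contrast feeding the one-factor
    repeated-measures test; returns a subject x event_type table in µV.
    """
    for ch in channels:
        if ch not in epochs.ch_names:
            raise ValueError(f"channel {ch!r} not present")
    lo, hi = window
    tmask = (epochs.times >= lo) & (epochs.times <= hi)
    if not tmask.any():
        raise ValueError("window outside the epoch time grid")
    cidx = [epochs.ch_names.index(ch) for ch in channels]
    vals = epochs.data[:, cidx][:, :, tmask].mean(axis=(1, 2))
    df = epochs.info[["subject", "event_type"]].copy()
    df["amplitude"] = vals
    return df.groupby(["subject", "event_type"], sort=True)["amplitude"].mean().unstack()


@dataclass
class WeightMatrix:
    """PCA channel weights: ``w`` is (n_components, n_channels) with
    orthonormal rows ordered by descending explained variance."""

    w: np.ndarray
    explained_variance: np.ndarray
    ch_names: tuple[str, ...]
    rank: int = field(default=0)

    def component(self, c: int) -> np.ndarray:
        """Weights of component ``c`` (1-based, as components are named C1..C32)."""
        return self.w[c - 1]


class SpatialPCA(BaseEstimator, TransformerMixin):
    """Covariance PCA over channels of a (samples x channels) matrix.

    ``fit`` centres each channel and extracts orthonormal loading vectors
    (rows of ``weights_``), sign-fixed so every component's largest
    -magnitude loading is positive — eigenvector signs are otherwise
    arbitrary and determinism matters for regression tests.  ``transform``
    applies the plain weighted channel sum *without* re-centring, because
    downstream the weights multiply raw µV signals; the omitted constant
    offset is irrelevant to the windowed-demeaned correlation measure.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "SpatialPCA":
        X = np.asarray(X, dtype=float)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        w = pca.components_
        # deterministic sign: largest-|loading| entry positive per row
        flip = np.sign(w[np.arange(w.shape[0]), np.abs(w).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.weights_ = w * flip[:, None]
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        tol = max(X.shape) * np.finfo(float).eps * (
            self.explained_variance_[0] if len(self.explained_variance_) else 1.0
        )
        self.rank_ = int((self.explained_variance_ > tol).sum())
        if self.rank_ < self.weights_.shape[0]:
            warnings.warn(
                f"rank-deficient input: only {self.rank_} of "
                f"{self.weights_.shape[0]} components carry variance",
                stacklevel=2,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights_.T


def pca_weights(grand_averages: dict[str, np.ndarray], ch_names: tuple[str, ...]) -> WeightMatrix:
    """Channel weights from the per-type grand averages.

    The observation matrix stacks the epoch time samples of all three
    transition types (rows) against channels (columns); the PCA is on the
    channel covariance.
    """
    missing = [e for e in EVENT_TYPES if e not in grand_averages]
    if missing:
        raise ValueError(f"grand averages missing for {missing}")
    X = np.concatenate([grand_averages[e].T for e in EVENT_TYPES], axis=0)
    est = SpatialPCA().fit(X)
    return WeightMatrix(
        w=est.weights_,
        explained_variance=est.explained_variance_,
        ch_names=tuple(ch_names),
        rank=est.rank_,
    )


def project(obj, weights: WeightMatrix, component: int):
    """Project a recording or epoch set onto one PCA component (1-based).

    Returns the component time series (n_samples,) for a recording, or
    (n_events, n_tau) for an :class:`EpochSet`.
    """
    w = weights.component(component)
    if isinstance(obj, ContinuousRecording):
        if tuple(obj.ch_names) != tuple(weights.ch_names):
            raise ValueError("channel order mismatch between recording and weights")
        return w @ obj.data
    if isinstance(obj, EpochSet):
        if tuple(obj.ch_names) != tuple(weights.ch_names):
            raise ValueError("channel order mismatch between epochs and weights")
        return np.einsum("c,ect->et", w, obj.data)
    raise TypeError(f"cannot project object of type {type(obj).__name__}")
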