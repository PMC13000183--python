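"""Event-signature template decoding of the ongoing component signal.

The event-similarity measure (ESM) is a sliding, windowed, mean-subtracted
and SD-normalised cross-correlation: at each time point t the component
signal over [t + tau_min, t + tau_max] is compared (Pearson-style, both
sides demeaned over that window and normalised by their windowed SDs) to
an event signature — the mean component-space ERP of one transition type
computed on training trials only.  Training/test splits reuse the probe
-match condition as a random 5-fold selector.  Locked ESM curves (the ESM
averaged around actual test-set events) are corrected by a permutation
baseline obtained by shuffling event-type labels among training events,
and finally averaged over the five splits and over subjects.

The time-lag analysis crops a fixed 400 ms window out of signatures with
±500 ms support, sliding its centre ("lag") from -300 to +300 ms in 20 ms
steps; each lag column is a full re-run of the correlate/lock/correct
chain with the PCA weights held fixed, so anticipatory versus lagged
encoding shows up as the sign of the lag at which similarity peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .topology import EVENT_TYPES

__all__ = [
    "SplitPlan",
    "make_splits",
    "build_signature",
    "esm_trace",
    "lock_esm",
    "permutation_baseline",
    "corrected_esm",
    "EsmTemplateDecoder",
    "SubjectESM",
    "decode_subject",
    "lag_map_subject",
    "group_corrected",
    "DEFAULT_LAGS",
]

N_CONDITIONS = 5
DEFAULT_LAGS = np.round(np.arange(-0.300, 0.301, 0.020), 3)
_VAR_TOL = 1e-12



def _nanmean(a, axis):
    """nanmean that stays silent on all-NaN cells (they remain NaN)."""
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)

@dataclass(frozen=True)
class SplitPlan:
    """One train/test split: test trials are those probed with match
    condition ``m``, training trials all others."""

    m: int
    train_ids: np.ndarray
    test_ids: np.ndarray


def make_splits(match_conditions) -> list[SplitPlan]:
    """Five complementary split plans from the trial -> condition mapping."""
    mc = pd.Series(match_conditions)
    if mc.isna().any():
        raise ValueError("every trial needs a match-condition label")
    trials = mc.index.to_numpy()
    plans = []
    for m in range(N_CONDITIONS):
        test = trials[mc.to_numpy() == m]
        train = trials[mc.to_numpy() != m]
        plans.append(SplitPlan(m, train, test))
    return plans


def build_signature(train_epochs: np.ndarray) -> np.ndarray:
    """Pooled mean over training events, (n_events, n_tau) -> (n_tau,)."""
    E = np.asarray(train_epochs, dtype=float)
    if E.ndim != 2 or E.shape[0] == 0:
        raise ValueError("need at least one training event epoch")
    return E.mean(axis=0)


def _window_variance(p: np.ndarray, L: int) -> np.ndarray:
    """Sum of squared deviations from the windowed mean, per window start."""
    z = np.concatenate([[0.0], np.cumsum(p)])
    z2 = np.concatenate([[0.0], np.cumsum(p * p)])
    s1 = z[L:] - z[:-L]
    s2 = z2[L:] - z2[:-L]
    return np.maximum(s2 - s1 * s1 / L, 0.0)


def _batch_traces(
    p: np.ndarray, sigs: np.ndarray, j0: int
) -> tuple[np.ndarray, np.ndarray]:
    """ESM traces of many signatures against one signal.

    ``sigs`` is (n_sig, L); the window for trace index t spans samples
    [t + j0, t + j0 + L).  Returns (traces, zero_variance) both
    (n_sig, len(p)); undefined positions (window off the signal) are NaN,
    zero-variance windows are 0 and flagged.
    """
    p = np.asarray(p, dtype=float)
    sigs = np.atleast_2d(np.asarray(sigs, dtype=float))
    n = p.shape[0]
    n_sig, L = sigs.shape
    out = np.full((n_sig, n), np.nan)
    flags = np.zeros((n_sig, n), dtype=bool)
    if n < L:
        return out, flags
    sd = sigs - sigs.mean(axis=1, keepdims=True)
    ssd = (sd * sd).sum(axis=1)
    num = sliding_window_view(p, L) @ sd.T  # (n-L+1, n_sig)
    var = _window_variance(p, L)  # (n-L+1,)
    denom2 = var[:, None] * ssd[None, :]
    bad = denom2 < _VAR_TOL
    r = np.zeros_like(num)
    np.divide(num, np.sqrt(denom2, where=~bad, out=np.ones_like(denom2)), out=r, where=~bad)
    np.clip(r, -1.0, 1.0, out=r)
    # map window-start index t' to trace index t = t' - j0
    t_lo = max(0, -j0)
    t_hi = min(n - 1, n - L - j0)
    if t_hi >= t_lo:
        sl = slice(t_lo + j0, t_hi + j0 + 1)
        out[:, t_lo : t_hi + 1] = r[sl].T
        flags[:, t_lo : t_hi + 1] = bad[sl].T
    return out, flags


def esm_trace(
    p: np.ndarray,
    signature: np.ndarray,
    tau_min: float = -0.4,
    tau_max: float = 0.4,
    sampling_rate: float = 500.0,
    return_flags: bool = False,
):
    """Sliding normalised cross-correlation of a signal with a signature.

    ``esm[t]`` correlates the signature (demeaned over its support) with
    ``p[t + tau_min .. t + tau_max]`` demeaned over the same window and
    normalised by both windowed SDs, so values lie in [-1, 1].  Positions
    where the window leaves the signal are NaN ("missing"); zero-variance
    windows give 0 and are flagged (``return_flags=True``).
    """
    j0 = int(round(tau_min * sampling_rate))
    j1 = int(round(tau_max * sampling_rate))
    signature = np.asarray(signature, dtype=float)
    if signature.shape[0] != j1 - j0 + 1:
        raise ValueError(
            f"signature length {signature.shape[0]} does not match the "
            f"window [{tau_min}, {tau_max}] s at {sampling_rate} Hz "
            f"({j1 - j0 + 1} samples)"
        )
    traces, flags = _batch_traces(p, signature[None], j0)
    return (traces[0], flags[0]) if return_flags else traces[0]


def lock_esm(
    traces: np.ndarray,
    event_samples: np.ndarray,
    tau_w: float = 0.4,
    sampling_rate: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average trace values time-locked to events.

    ``traces`` is (..., n_samples), ``event_samples`` the event positions
    (sample indices into the trace).  Returns ``(locked, counts)`` where
    ``locked`` is (..., 2*W+1) over tau in [-tau_w, +tau_w]; missing (NaN
    or out-of-range) samples are excluded pairwise, with the effective
    event count per tau in ``counts``.
    """
    traces = np.asarray(traces, dtype=float)
    event_samples = np.asarray(event_samples, dtype=int)
    if event_samples.size == 0:
        raise ValueError("no events to lock on")
    W = int(round(tau_w * sampling_rate))
    n = traces.shape[-1]
    idx = event_samples[:, None] + np.arange(-W, W + 1)[None, :]
    valid = (idx >= 0) & (idx < n)
    idx_c = np.clip(idx, 0, n - 1)
    vals = traces[..., idx_c]  # (..., n_ev, 2W+1)
    vals = np.where(valid, vals, np.nan)
    counts = np.isfinite(vals).sum(axis=-2)
    with np.errstate(invalid="ignore"):
        locked = np.nansum(np.nan_to_num(vals), axis=-2) / np.maximum(counts, 1)
    locked = np.where(counts > 0, locked, np.nan)
    return locked, counts


def permutation_baseline(
    train_epochs: np.ndarray,
    train_labels: np.ndarray,
    lock_fn,
    n_perm: int = 50,
    rng: np.random.Generator | int | None = None,
) -> dict[str, np.ndarray]:
    """Mean locked ESM under label shuffling among training events.

    ``train_epochs`` (n_events, L) and ``train_labels`` are the training
    -run component epochs and their true types; labels are permuted
    (counts preserved, event times untouched), per-permutation signatures
    rebuilt, and ``lock_fn(signatures: dict) -> dict[(e, f) -> curve]``
    re-evaluated.  Returns the per-(e, f) mean over permutations.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.asarray(train_labels)
    acc: dict[str, np.ndarray] = {}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        sigs = {e: build_signature(train_epochs[perm == e]) for e in EVENT_TYPES}
        locked = lock_fn(sigs)
        for key, curve in locked.items():
            acc[key] = acc.get(key, 0.0) + curve
    return {k: v / n_perm for k, v in acc.items()}


def corrected_esm(
    locked: np.ndarray, baseline: np.ndarray, subject_axis: int = 0, split_axis: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtract, then unweighted means over splits then subjects.

    ``locked``/``baseline`` are (n_subjects, n_splits, ...); cells a split
    never defined (NaN) are dropped from the averages.  Returns
    ``(group_curve, per_subject_curves)`` — the per-subject curves are what
    group statistics run on.
    """
    delta = np.asarray(locked, dtype=float) - np.asarray(baseline, dtype=float)
    per_subject = _nanmean(delta, axis=split_axis)
    group = _nanmean(per_subject, axis=subject_axis)
    return group, per_subject


class EsmTemplateDecoder(BaseEstimator):
    """sklearn-style wrapper around signature building and ESM tracing.

    ``fit(E, y)`` takes component-space epochs (n_events, n_tau) with event
    -type labels and stores one pooled-mean signature per type in
    ``signatures_``; ``transform(p)`` returns the ESM traces of a continuous
    component signal against every fitted signature, shape
    (n_types, n_samples) in ``classes_`` order.
    """

    def __init__(
        self,
        tau_min: float = -0.4,
        tau_max: float = 0.4,
        sampling_rate: float = 500.0,
    ):
        self.tau_min = tau_min
        self.tau_max = tau_max
        self.sampling_rate = sampling_rate

    def fit(self, X: np.ndarray, y) -> "EsmTemplateDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        j0 = int(round(self.tau_min * self.sampling_rate))
        j1 = int(round(self.tau_max * self.sampling_rate))
        if X.ndim != 2 or X.shape[1] != j1 - j0 + 1:
            raise ValueError("epochs must be (n_events, n_tau) on the decoder's tau grid")
        self.classes_ = np.array(sorted(set(y.tolist())))
        self.signatures_ = {
            e: build_signature(X[y == e]) for e in self.classes_
        }
        return self

    def transform(self, p: np.ndarray) -> np.ndarray:
        j0 = int(round(self.tau_min * self.sampling_rate))
        sigs = np.stack([self.signatures_[e] for e in self.classes_])
        traces, _ = _batch_traces(p, sigs, j0)
        return traces


@dataclass
class SubjectESM:
    """Per-subject ESM products on a common tau grid.

    Arrays are indexed [split m, train type e, test type f, tau]; NaN marks
    split cells without test events (dropped from averages and logged in
    ``n_test_events``).
    """

    subject: int
    taus: np.ndarray
    locked: np.ndarray
    baseline: np.ndarray
    n_test_events: np.ndarray  # (n_splits, n_types) events of type f

    @property
    def corrected(self) -> np.ndarray:
        """Split-averaged corrected curves, (e, f, tau)."""
        return _nanmean(self.locked - self.baseline, axis=0)


def _trial_events(events: pd.DataFrame, sampling_rate: float) -> pd.DataFrame:
    ev = events.copy()
    ev["sample"] = np.round(ev["time_s"].to_numpy() * sampling_rate).astype(int)
    return ev


def decode_subject(
    p_c: np.ndarray,
    events: pd.DataFrame,
    match_conditions,
    trial_onsets: dict[int, int],
    trial_n_samples: int,
    sampling_rate: float = 500.0,
    tau_min: float = -0.4,
    tau_max: float = 0.4,
    tau_w: float = 0.4,
    n_perm: int = 50,
    rng: np.random.Generator | int | None = None,
    subject: int = 0,
) -> SubjectESM:
    """Full within-subject decoding: signatures, ESM, locking, baseline.

    ``p_c`` is the continuous component time series; ``events`` the event
    table (trial_id, event_type, time_s — times relative to motion onset);
    ``trial_onsets`` maps trial_id to its onset sample.  ESM windows never
    cross a trial edge: each trial's trace is computed on its own motion
    span, with positions whose window leaves the span left missing.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fs = sampling_rate
    j0 = int(round(tau_min * fs))
    j1 = int(round(tau_max * fs))
    W = int(round(tau_w * fs))
    taus = np.arange(-W, W + 1) / fs
    n_types = len(EVENT_TYPES)
    type_idx = {e: i for i, e in enumerate(EVENT_TYPES)}

    ev = _trial_events(events, fs)
    # component-space epochs of every event (for signature building)
    abs_center = ev.trial_id.map(trial_onsets).to_numpy() + ev["sample"].to_numpy()
    E = np.stack([p_c[c + j0 : c + j1 + 1] for c in abs_center])
    labels = ev.event_type.to_numpy()

    splits = make_splits(match_conditions)
    n_splits = len(splits)
    locked = np.full((n_splits, n_types, n_types, 2 * W + 1), np.nan)
    baseline = np.full_like(locked, np.nan)
    n_test = np.zeros((n_splits, n_types), dtype=int)

    trial_of = ev.trial_id.to_numpy()
    for mi, plan in enumerate(splits):
        train_mask = np.isin(trial_of, plan.train_ids)
        E_train, y_train = E[train_mask], labels[train_mask]
        if any((y_train == e).sum() == 0 for e in EVENT_TYPES):
            missing = [e for e in EVENT_TYPES if (y_train == e).sum() == 0]
            raise ValueError(
                f"subject {subject}, split m={plan.m}: no training events of "
                f"type(s) {missing}"
            )
        # signatures: real + n_perm label permutations (times untouched)
        sig_sets = [ {e: build_signature(E_train[y_train == e]) for e in EVENT_TYPES} ]
        for _ in range(n_perm):
            perm = rng.permutation(y_train)
            sig_sets.append({e: build_signature(E_train[perm == e]) for e in EVENT_TYPES})
        S = np.stack([s[e] for s in sig_sets for e in EVENT_TYPES])  # ((1+P)*3, L)

        # accumulate locked sums over test trials
        sums = np.zeros((len(sig_sets) * n_types, n_types, 2 * W + 1))
        counts = np.zeros((len(sig_sets) * n_types, n_types, 2 * W + 1), dtype=int)
        for tid in plan.test_ids:
            tmask = trial_of == tid
            if not tmask.any():
                continue
            on = trial_onsets[int(tid)]
            seg = p_c[on : on + trial_n_samples]
            traces, _ = _batch_traces(seg, S, j0)
            for f in EVENT_TYPES:
                fmask = tmask & (labels == f)
                if not fmask.any():
                    continue
                samples = ev["sample"].to_numpy()[fmask]
                lk, ct = lock_esm(traces, samples, tau_w, fs)
                fin = np.isfinite(lk)
                sums[:, type_idx[f]][fin] += (lk * ct)[fin]
                counts[:, type_idx[f]] += ct
        with np.errstate(invalid="ignore"):
            curves = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        curves = curves.reshape(len(sig_sets), n_types, n_types, 2 * W + 1)
        locked[mi] = curves[0]
        baseline[mi] = curves[1:].mean(axis=0) if n_perm else np.nan
        for f in EVENT_TYPES:
            n_test[mi, type_idx[f]] = int(
                ((labels == f) & np.isin(trial_of, plan.test_ids)).sum()
            )
    return SubjectESM(subject, taus, locked, baseline, n_test)


def lag_map_subject(
    p_c: np.ndarray,
    events: pd.DataFrame,
    match_conditions,
    trial_onsets: dict[int, int],
    trial_n_samples: int,
    sampling_rate: float = 500.0,
    lags: np.ndarray = DEFAULT_LAGS,
    window_len: float = 0.4,
    tau_w: float = 0.5,
    n_perm: int = 50,
    rng: np.random.Generator | int | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected lag-ESM map for one subject.

    For each lag tau_bar, the signature (built on ±(tau_w) support) is
    cropped to the ``window_len`` interval centred at tau_bar and the whole
    correlate/lock/correct chain re-runs; permutation label draws are
    shared across lags so baselines are variance-coupled.  Returns
    ``(map, taus)`` with ``map`` indexed [e, f, tau, lag] (NaN where no
    split had test events); restrict via ``pairs`` to save work.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fs = sampling_rate
    half_len = window_len / 2.0
    need = max(abs(lags.min()), abs(lags.max())) + half_len
    sup = int(round(need * fs))
    W = int(round(tau_w * fs))
    Lw = int(round(window_len * fs)) + 1
    taus = np.arange(-W, W + 1) / fs
    n_types = len(EVENT_TYPES)
    type_idx = {e: i for i, e in enumerate(EVENT_TYPES)}
    if pairs is None:
        pairs = [(e, f) for e in EVENT_TYPES for f in EVENT_TYPES]
    e_used = sorted({type_idx[e] for e, _ in pairs})
    f_used = sorted({type_idx[f] for _, f in pairs})

    ev = _trial_events(events, fs)
    abs_center = ev.trial_id.map(trial_onsets).to_numpy() + ev["sample"].to_numpy()
    lo_ok = abs_center - sup >= 0
    hi_ok = abs_center + sup + 1 <= len(p_c)
    ev = ev[lo_ok & hi_ok].reset_index(drop=True)
    abs_center = abs_center[lo_ok & hi_ok]
    E = np.stack([p_c[c - sup : c + sup + 1] for c in abs_center])  # support grid
    labels = ev.event_type.to_numpy()
    trial_of = ev.trial_id.to_numpy()

    lag_j0 = np.round((lags - half_len) * fs).astype(int)  # window start vs event
    crop_lo = lag_j0 + sup  # index into the support grid

    splits = make_splits(match_conditions)
    out = np.full((n_types, n_types, 2 * W + 1, len(lags)), np.nan)
    acc = np.full((len(splits), n_types, n_types, 2 * W + 1, len(lags)), np.nan)
    for mi, plan in enumerate(splits):
        train_mask = np.isin(trial_of, plan.train_ids)
        E_train, y_train = E[train_mask], labels[train_mask]
        label_sets = [y_train] + [rng.permutation(y_train) for _ in range(n_perm)]
        # signatures on full support, per label set and type
        sig_support = np.stack(
            [
                build_signature(E_train[ls == EVENT_TYPES[eidx]])
                for ls in label_sets
                for eidx in e_used
            ]
        )  # (n_sets*n_e, 2*sup+1)
        # crop every lag window: (n_lag, n_sets*n_e, Lw) -> stacked
        crops = np.stack([sig_support[:, c : c + Lw] for c in crop_lo])
        n_rows = crops.shape[0] * crops.shape[1]
        S = crops.reshape(n_rows, Lw)

        sums = np.zeros((n_rows, len(f_used), 2 * W + 1))
        counts = np.zeros((n_rows, len(f_used), 2 * W + 1), dtype=int)
        for tid in plan.test_ids:
            tmask = trial_of == tid
            if not tmask.any():
                continue
            on = trial_onsets[int(tid)]
            seg = p_c[on : on + trial_n_samples]
            # all rows share window length; j0 differs per lag -> compute
            # valid-window correlations once, then place per lag
            if len(seg) < Lw:
                continue
            sd = S - S.mean(axis=1, keepdims=True)
            ssd = (sd * sd).sum(axis=1)
            numv = sliding_window_view(seg, Lw) @ sd.T  # (n', n_rows)
            var = _window_variance(seg, Lw)
            denom2 = var[:, None] * ssd[None, :]
            bad = denom2 < _VAR_TOL
            r = np.zeros_like(numv)
            np.divide(
                numv,
                np.sqrt(denom2, where=~bad, out=np.ones_like(denom2)),
                out=r,
                where=~bad,
            )
            np.clip(r, -1.0, 1.0, out=r)
            n_seg = len(seg)
            for li, jj in enumerate(lag_j0):
                rows = slice(li * crops.shape[1], (li + 1) * crops.shape[1])
                tr = np.full((crops.shape[1], n_seg), np.nan)
                t_lo = max(0, -jj)
                t_hi = min(n_seg - 1, n_seg - Lw - jj)
                if t_hi >= t_lo:
                    tr[:, t_lo : t_hi + 1] = r[t_lo + jj : t_hi + jj + 1, rows].T
                for fi, fidx in enumerate(f_used):
                    fmask = tmask & (labels == EVENT_TYPES[fidx])
                    if not fmask.any():
                        continue
                    samples = ev["sample"].to_numpy()[fmask]
                    lk, ct = lock_esm(tr, samples, tau_w, fs)
                    fin = np.isfinite(lk)
                    sums[rows, fi][fin] += (lk * ct)[fin]
                    counts[rows, fi] += ct
        with np.errstate(invalid="ignore"):
            curves = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        curves = curves.reshape(
            len(lags), len(label_sets), len(e_used), len(f_used), 2 * W + 1
        )
        real = curves[:, 0]
        base = curves[:, 1:].mean(axis=1) if n_perm else 0.0
        delta = real - base  # (n_lag, n_e, n_f, taus)
        for ei, eidx in enumerate(e_used):
            for fi, fidx in enumerate(f_used):
                acc[mi, eidx, fidx] = delta[:, ei, fi].T  # (taus, n_lag)
    out = _nanmean(acc, axis=0)
    return out, taus


def group_corrected(results: list[SubjectESM]) -> tuple[np.ndarray, np.ndarray]:
    """Group-average corrected ESM: mean over splits within subject (done in
    :attr:`SubjectESM.corrected`), then unweighted mean over subjects.
    Returns ``(group (e, f, tau), per_subject (s, e, f, tau))``."""
    per_subject = np.stack([r.corrected for r in results])
    return _nanmean(per_subject, axis=0), per_subject
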