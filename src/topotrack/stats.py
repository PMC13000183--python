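"""Group-level inference on ESM products.

Cluster-based permutation correction for pointwise one-sample t-tests
(sign-flip null, cluster mass statistic), the pointwise one-factor
repeated-measures F across the three ESM traces, correlations between
locked ESM curves and the temporal histogram of co-occurring events, and
the median performance split.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "Cluster",
    "ClusterResult",
    "cluster_permutation_t",
    "pointwise_repeated_F",
    "EventHistogram",
    "event_relative_histogram",
    "esm_histogram_correlation",
    "performance_split",
]


@dataclass(frozen=True)
class Cluster:
    """One supra-threshold cluster: the index span (tuple of slices), its
    mass (sum of t-values) and the permutation-corrected p."""

    span: tuple
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    t_map: np.ndarray
    n_perm: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]


def _t_map(X: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t vs 0 over the subject axis (axis 0);
    zero-variance points give t = 0."""
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _max_cluster_mass(t: np.ndarray, thresh: float) -> float:
    lab, n = ndimage.label(t > thresh)  # 1-D contiguity / 2-D 4-connectivity
    if n == 0:
        return 0.0
    return float(max(ndimage.sum_labels(t, lab, index=range(1, n + 1))))


def cluster_permutation_t(
    X: np.ndarray,
    alpha_primary: float = 0.05,
    n_perm: int | str = 1000,
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """One-sided (positive) cluster-corrected one-sample t-test.

    ``X`` is (n_subjects, *grid) with a 1-D or 2-D grid.  Pointwise t
    values above the one-sided t threshold at ``alpha_primary`` (df = n-1)
    form contiguous clusters (4-connectivity in 2-D) whose mass (sum of t)
    is compared to the null distribution of the maximum mass under random
    per-subject sign flips.  ``n_perm="all"`` enumerates all 2^n flips
    (exact); the corrected p is then the fraction of null maxima >= the
    observed mass, while random permutation uses the standard
    (b + 1) / (m + 1) estimator.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    exhaustive = n_perm == "all"
    if not exhaustive and n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} gives a coarse p resolution", stacklevel=2)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    thresh = float(stats.t.ppf(1 - alpha_primary, df=n - 1))
    t_obs = _t_map(X)
    lab, n_cl = ndimage.label(t_obs > thresh)
    spans = ndimage.find_objects(lab)
    masses = (
        ndimage.sum_labels(t_obs, lab, index=range(1, n_cl + 1)) if n_cl else np.array([])
    )

    if exhaustive:
        signs_iter = (np.array(s) for s in product((1.0, -1.0), repeat=n))
        null = np.array(
            [_max_cluster_mass(_t_map(s[:, None] * X.reshape(n, -1)).reshape(X.shape[1:]), thresh) for s in signs_iter]
        )
        pvals = [(null >= m).mean() for m in masses]
        m_eff = len(null)
    else:
        null = np.empty(int(n_perm))
        flat = X.reshape(n, -1)
        for b in range(int(n_perm)):
            s = rng.choice([-1.0, 1.0], size=n)
            null[b] = _max_cluster_mass(_t_map(s[:, None] * flat).reshape(X.shape[1:]), thresh)
        pvals = [((null >= m).sum() + 1) / (int(n_perm) + 1) for m in masses]
        m_eff = int(n_perm)
    clusters = [
        Cluster(span=s, mass=float(m), p=float(p))
        for s, m, p in zip(spans, masses, pvals)
    ]
    return ClusterResult(clusters, thresh, t_obs, m_eff)


def pointwise_repeated_F(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-factor repeated-measures F at every grid point.

    ``X`` is (n_subjects, n_conditions, n_points).  Classic within-subject
    sums of squares, df = (c-1) and (c-1)(s-1); no sphericity correction
    is applied (p-values are uncorrected).  Returns ``(F, p)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[..., None]
    s, c = X.shape[0], X.shape[1]
    if np.isnan(X).any():
        raise ValueError("missing cells are not supported")
    gm = X.mean(axis=(0, 1))
    cond_m = X.mean(axis=0)
    subj_m = X.mean(axis=1)
    ss_cond = s * ((cond_m - gm) ** 2).sum(axis=0)
    resid = X - cond_m[None, :, :] - subj_m[:, None, :] + gm
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = c - 1, (c - 1) * (s - 1)
    # points with (numerically) no condition variance are F = 0 by
    # convention, guarding the 0/0 ratio on degenerate inputs
    ss_tot = ((X - gm) ** 2).sum(axis=(0, 1))
    null_pts = ss_cond <= 1e-12 * np.maximum(ss_tot, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_err / df2)
    F = np.where(null_pts, 0.0, F)
    F = np.where(np.isnan(F), 0.0, F)
    p = stats.f.sf(F, df1, df2)
    return np.squeeze(F), np.squeeze(p)


@dataclass
class EventHistogram:
    """Counts of events of one type relative to reference events of another,
    binned over [-tau_w, +tau_w]."""

    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def event_relative_histogram(
    events: pd.DataFrame,
    ref_type: str,
    other_type: str,
    tau_w: float = 0.4,
    bin_width: float = 0.02,
) -> EventHistogram:
    """Histogram of ``other_type`` event times relative to each ``ref_type``
    event of the same trial (and set)."""
    edges = np.arange(-tau_w, tau_w + bin_width / 2, bin_width)
    deltas = []
    for _, g in events.groupby("trial_id"):
        ref = g.loc[g.event_type == ref_type, "time_s"].to_numpy()
        oth = g.loc[g.event_type == other_type, "time_s"].to_numpy()
        if len(ref) and len(oth):
            d = (oth[None, :] - ref[:, None]).ravel()
            deltas.append(d[np.abs(d) <= tau_w])
    all_d = np.concatenate(deltas) if deltas else np.empty(0)
    counts, _ = np.histogram(all_d, bins=edges)
    return EventHistogram(counts, edges)


def esm_histogram_correlation(
    locked: np.ndarray,
    taus: np.ndarray,
    hist: EventHistogram,
) -> tuple[float, float]:
    """Pearson correlation between a locked ESM curve and the event
    histogram, the latter linearly interpolated onto the ESM tau grid.
    Constant inputs give (nan, nan)."""
    h = np.interp(taus, hist.bin_centers, hist.counts.astype(float))
    ok = np.isfinite(locked)
    if ok.sum() < 3 or np.ptp(locked[ok]) == 0 or np.ptp(h[ok]) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(locked[ok], h[ok])
    return float(r), float(p)


def performance_split(error_rates: dict[int, float]) -> tuple[list[int], list[int]]:
    """Median split into (high-performance, low-performance) subject groups.

    High performance = low error rate.  Ties straddling the median are
    resolved deterministically by subject-id parity (even ids sort ahead)
    and then by id.
    """
    items = sorted(error_rates.items(), key=lambda kv: (kv[1], kv[0] % 2, kv[0]))
    half = len(items) // 2
    high = [sid for sid, _ in items[:half]]
    low = [sid for sid, _ in items[half:]]
    return high, low
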