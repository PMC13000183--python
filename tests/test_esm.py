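"""Signatures, sliding normalized cross-correlation, locking, baselines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from conftest import pooled_epochs
from topotrack import erp, esm
from topotrack.esm import (
    EsmTemplateDecoder,
    build_signature,
    corrected_esm,
    decode_subject,
    esm_trace,
    lag_map_subject,
    lock_esm,
    make_splits,
    permutation_baseline,
)
from topotrack.topology import EVENT_TYPES


def naive_esm(p, sig, j0):
    """Independent per-t Pearson oracle (plain corrcoef on each window)."""
    L = len(sig)
    out = np.full(len(p), np.nan)
    for t in range(len(p)):
        lo = t + j0
        if lo < 0 or lo + L > len(p):
            continue
        w = p[lo : lo + L]
        if w.std() == 0 or sig.std() == 0:
            out[t] = 0.0
        else:
            out[t] = np.corrcoef(w, sig)[0, 1]
    return out


class TestSplits:
    def test_balanced_300(self):
        mc = pd.Series(np.repeat(np.arange(5), 60), index=np.arange(300))
        plans = make_splits(mc)
        assert len(plans) == 5
        for p in plans:
            assert len(p.test_ids) == 60 and len(p.train_ids) == 240

    def test_one_per_condition(self):
        plans = make_splits(pd.Series([0, 1, 2, 3, 4]))
        for p in plans:
            assert len(p.test_ids) == 1 and len(p.train_ids) == 4

    def test_union_disjoint_random_labels(self, rng):
        labels = rng.integers(0, 5, size=47)
        mc = pd.Series(labels, index=np.arange(47))
        for p in make_splits(mc):
            assert len(np.intersect1d(p.train_ids, p.test_ids)) == 0
            assert len(np.union1d(p.train_ids, p.test_ids)) == 47

    def test_missing_labels_fail(self):
        with pytest.raises(ValueError):
            make_splits(pd.Series([0.0, np.nan, 2.0]))


class TestSignature:
    def test_single_event(self, rng):
        e = rng.standard_normal((1, 401))
        np.testing.assert_array_equal(build_signature(e), e[0])

    def test_pooled_mean_oracle(self, rng):
        E = rng.standard_normal((7, 31))
        acc = np.zeros(31)
        for row in E:
            acc += row
        np.testing.assert_allclose(build_signature(E), acc / 7)

    def test_zero_events_fail(self):
        with pytest.raises(ValueError):
            build_signature(np.empty((0, 401)))


class TestEsmTrace:
    def test_planted_exact_copy_gives_one(self, rng):
        sig = rng.standard_normal(401)
        p = rng.standard_normal(3000)
        t0 = 1200  # window [t0-200, t0+200] holds the signature exactly
        p[t0 - 200 : t0 + 201] = sig
        trace = esm_trace(p, sig)
        assert trace[t0] == pytest.approx(1.0)
        anti = esm_trace(p, -sig)
        assert anti[t0] == pytest.approx(-1.0)

    def test_matches_naive_pearson_oracle(self, rng):
        p = rng.standard_normal(2500)
        sig = rng.standard_normal(401)
        trace = esm_trace(p, sig)
        oracle = naive_esm(p, sig, -200)
        ok = np.isfinite(oracle)
        assert np.array_equal(np.isfinite(trace), ok)
        np.testing.assert_allclose(trace[ok], oracle[ok], atol=1e-10)

    def test_bounded(self, rng):
        trace = esm_trace(rng.standard_normal(4000), rng.standard_normal(401))
        v = trace[np.isfinite(trace)]
        assert (v >= -1).all() and (v <= 1).all()

    def test_shift_equivariance(self, rng):
        p = rng.standard_normal(3000)
        sig = rng.standard_normal(401)
        d = 37
        shifted = np.concatenate([rng.standard_normal(d), p])
        a = esm_trace(p, sig)
        b = esm_trace(shifted, sig)
        ok = np.isfinite(a[: 3000 - d]) & np.isfinite(b[d:3000])
        np.testing.assert_allclose(a[: 3000 - d][ok], b[d:3000][ok], atol=1e-12)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=25, derandomize=True)
    def test_scale_invariance(self, a, b):
        rng = np.random.default_rng(0)
        p = rng.standard_normal(1200)
        sig = rng.standard_normal(401)
        base = esm_trace(p, sig)
        scaled = esm_trace(a * p, b * sig)
        ok = np.isfinite(base)
        np.testing.assert_allclose(base[ok], scaled[ok], atol=1e-10)

    def test_zero_variance_window_flagged(self):
        p = np.zeros(1000)
        sig = np.random.default_rng(3).standard_normal(401)
        trace, flags = esm_trace(p, sig, return_flags=True)
        ok = np.isfinite(trace)
        assert (trace[ok] == 0).all() and flags[ok].all()

    def test_asymmetric_window(self, rng):
        p = rng.standard_normal(1500)
        sig = rng.standard_normal(151)  # [-0.1, +0.2] s at 500 Hz
        trace = esm_trace(p, sig, tau_min=-0.1, tau_max=0.2)
        oracle = naive_esm(p, sig, -50)
        ok = np.isfinite(oracle)
        np.testing.assert_allclose(trace[ok], oracle[ok], atol=1e-10)


class TestLockEsm:
    def test_single_event_is_trace_slice(self, rng):
        trace = rng.standard_normal(3000)
        locked, counts = lock_esm(trace, np.array([1500]), tau_w=0.4)
        np.testing.assert_array_equal(locked, trace[1300:1701])
        assert (counts == 1).all()

    def test_pooled_average_oracle(self, rng):
        trace = rng.standard_normal(3000)
        evs = np.array([700, 1500, 2100])
        locked, counts = lock_esm(trace, evs, tau_w=0.2)
        oracle = np.mean([trace[e - 100 : e + 101] for e in evs], axis=0)
        np.testing.assert_allclose(locked, oracle)
        assert (counts == 3).all()

    def test_missing_samples_excluded_pairwise(self, rng):
        trace = rng.standard_normal(1000)
        trace[:150] = np.nan
        locked, counts = lock_esm(trace, np.array([100, 600]), tau_w=0.2)
        assert counts[0] == 1  # first event's left flank is missing
        np.testing.assert_allclose(locked[0], trace[500])

    def test_no_events_fails(self, rng):
        with pytest.raises(ValueError):
            lock_esm(rng.standard_normal(100), np.array([]))


class TestPermutationBaseline:
    def test_identical_kernels_make_baseline_match(self, rng):
        """If all types share one waveform, label shuffling is a no-op in
        expectation and the baseline converges to the true locked curve."""
        E = np.tile(rng.standard_normal(101), (30, 1))
        E += 0.01 * rng.standard_normal(E.shape)
        labels = np.array((["flip", "concave", "convex"] * 10))
        p = rng.standard_normal(2000)

        def lock_fn(sigs):
            return {
                e: lock_esm(
                    esm_trace(p, sigs[e], -0.1, 0.1), np.array([800, 1300]), 0.1
                )[0]
                for e in EVENT_TYPES
            }

        true_curves = lock_fn({e: build_signature(E[labels == e]) for e in EVENT_TYPES})
        base = permutation_baseline(E, labels, lock_fn, n_perm=40, rng=1)
        for e in EVENT_TYPES:
            assert np.nanmax(np.abs(base[e] - true_curves[e])) < 0.05

    def test_seeded_reproducibility(self, rng):
        E = rng.standard_normal((12, 51))
        labels = np.array((["flip", "concave", "convex"] * 4))
        lock_fn = lambda sigs: {e: sigs[e][:3] for e in EVENT_TYPES}
        a = permutation_baseline(E, labels, lock_fn, n_perm=5, rng=11)
        b = permutation_baseline(E, labels, lock_fn, n_perm=5, rng=11)
        for e in EVENT_TYPES:
            np.testing.assert_array_equal(a[e], b[e])

    def test_oracle_with_materialized_shuffles(self, rng):
        """Baseline equals explicit recomputation from the same label draws."""
        E = rng.standard_normal((9, 21))
        labels = np.array((["flip", "concave", "convex"] * 3))
        lock_fn = lambda sigs: {e: sigs[e] for e in EVENT_TYPES}
        got = permutation_baseline(E, labels, lock_fn, n_perm=7, rng=3)
        r = np.random.default_rng(3)
        acc = {e: np.zeros(21) for e in EVENT_TYPES}
        for _ in range(7):
            perm = r.permutation(labels)
            for e in EVENT_TYPES:
                acc[e] += E[perm == e].mean(axis=0)
        for e in EVENT_TYPES:
            np.testing.assert_allclose(got[e], acc[e] / 7)


class TestCorrectedEsm:
    def test_baseline_equal_locked_gives_zero(self, rng):
        locked = rng.standard_normal((4, 5, 11))
        group, per = corrected_esm(locked, locked)
        assert np.allclose(group, 0) and np.allclose(per, 0)

    def test_single_subject_single_split(self, rng):
        locked = rng.standard_normal((1, 1, 11))
        base = rng.standard_normal((1, 1, 11))
        group, per = corrected_esm(locked, base)
        np.testing.assert_allclose(group, (locked - base)[0, 0])

    def test_aggregation_order_matches_pooled_when_balanced(self, rng):
        locked = rng.standard_normal((6, 5, 11))
        base = rng.standard_normal((6, 5, 11))
        group, _ = corrected_esm(locked, base)
        np.testing.assert_allclose(group, (locked - base).mean(axis=(0, 1)), atol=1e-12)


class TestDecoderEstimator:
    def test_sklearn_api_and_signatures(self, rng):
        X = rng.standard_normal((30, 401))
        y = np.array((["flip", "concave", "convex"] * 10))
        dec = EsmTemplateDecoder()
        assert "tau_min" in dec.get_params()
        dec = clone(dec).fit(X, y)
        assert set(dec.signatures_) == set(EVENT_TYPES)
        np.testing.assert_allclose(
            dec.signatures_["flip"], X[y == "flip"].mean(axis=0)
        )
        traces = dec.transform(rng.standard_normal(1500))
        assert traces.shape == (3, 1500)
        v = traces[np.isfinite(traces)]
        assert (np.abs(v) <= 1).all()


class TestSubjectDecoding:
    @pytest.fixture(scope="class")
    def decoded(self, tiny_dataset):
        ds = tiny_dataset
        pre, pooled = pooled_epochs(ds, erp)
        W = erp.pca_weights(erp.grand_average(pooled), pooled.ch_names)
        rec = pre[0]
        onsets = {int(t): int(o) for t, o in zip(rec.trial_ids, rec.trial_onsets)}
        p_c = erp.project(rec, W, 1)
        res = decode_subject(
            p_c, ds.target_events, ds.match_conditions, onsets,
            rec.trial_n_samples, 500.0, n_perm=4, rng=0,
        )
        return ds, p_c, onsets, rec.trial_n_samples, res

    def test_locked_shapes_and_bounds(self, decoded):
        *_, res = decoded
        assert res.locked.shape == (5, 3, 3, 401)
        v = res.locked[np.isfinite(res.locked)]
        assert (np.abs(v) <= 1 + 1e-9).all()
        assert res.n_test_events.sum() == len(decoded[0].target_events)

    def test_locked_matches_manual_recomputation(self, decoded):
        """Split m=0, e=f=flip locked curve equals an explicit loop over
        test trials using only the public trace/lock primitives."""
        ds, p_c, onsets, n_trial, res = decoded
        ev = ds.target_events.copy()
        ev["sample"] = np.round(ev.time_s * 500).astype(int)
        mc = ds.match_conditions
        train = [t for t in mc.index if mc[t] != 0]
        test = [t for t in mc.index if mc[t] == 0]
        E = np.stack([
            p_c[onsets[int(r.trial_id)] + r.sample - 200:
                onsets[int(r.trial_id)] + r.sample + 201]
            for r in ev.itertuples() if r.trial_id in train and r.event_type == "flip"
        ])
        sig = E.mean(axis=0)
        sums = np.zeros(401)
        counts = np.zeros(401)
        for t in test:
            seg = p_c[onsets[int(t)] : onsets[int(t)] + n_trial]
            tr = esm_trace(seg, sig)
            s_ev = ev[(ev.trial_id == t) & (ev.event_type == "flip")]["sample"].to_numpy()
            if len(s_ev):
                lk, ct = lock_esm(tr, s_ev, 0.4)
                fin = np.isfinite(lk)
                sums[fin] += (lk * ct)[fin]
                counts += ct
        oracle = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        np.testing.assert_allclose(res.locked[0, 0, 0], oracle, atol=1e-12)


class TestLagMap:
    def test_columns_match_single_lag_oracle(self, tiny_dataset):
        """Each lag column equals an independent single-window pipeline run
        (signature epoched on the cropped support, esm_trace, lock)."""
        ds = tiny_dataset
        pre, pooled = pooled_epochs(ds, erp)
        W = erp.pca_weights(erp.grand_average(pooled), pooled.ch_names)
        rec = pre[0]
        onsets = {int(t): int(o) for t, o in zip(rec.trial_ids, rec.trial_onsets)}
        p_c = erp.project(rec, W, 1)
        lags = esm.DEFAULT_LAGS
        m, taus = lag_map_subject(
            p_c, ds.target_events, ds.match_conditions, onsets,
            rec.trial_n_samples, 500.0, n_perm=0, rng=0,
            pairs=[("concave", "concave")],
        )
        ev = ds.target_events.copy()
        ev["sample"] = np.round(ev.time_s * 500).astype(int)
        mc = ds.match_conditions
        for lag in (-0.2, 0.0, 0.14):
            li = int(np.argmin(np.abs(lags - lag)))
            j0 = int(round((lags[li] - 0.2) * 500))
            L = 201
            curves = []
            for mm in range(5):
                train = [t for t in mc.index if mc[t] != mm]
                test = [t for t in mc.index if mc[t] == mm]
                sig = np.stack([
                    p_c[onsets[int(r.trial_id)] + r.sample + j0:
                        onsets[int(r.trial_id)] + r.sample + j0 + L]
                    for r in ev.itertuples()
                    if r.trial_id in train and r.event_type == "concave"
                ]).mean(axis=0)
                sums = np.zeros(501)
                counts = np.zeros(501)
                for t in test:
                    seg = p_c[onsets[int(t)] : onsets[int(t)] + rec.trial_n_samples]
                    tr = esm_trace(seg, sig, lags[li] - 0.2, lags[li] + 0.2)
                    s_ev = ev[(ev.trial_id == t) & (ev.event_type == "concave")][
                        "sample"
                    ].to_numpy()
                    if len(s_ev):
                        lk, ct = lock_esm(tr, s_ev, 0.5)
                        fin = np.isfinite(lk)
                        sums[fin] += (lk * ct)[fin]
                        counts += ct
                curves.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
            oracle = np.nanmean(np.stack(curves), axis=0)
            got = m[1, 1][:, li]
            fin = np.isfinite(oracle)
            np.testing.assert_allclose(got[fin], oracle[fin], atol=1e-12)

    def test_insufficient_support_drops_edge_events(self, tiny_dataset):
        """Events whose ±0.5 s support leaves the recording are excluded
        rather than crashing (none at default layout; assert it runs)."""
        ds = tiny_dataset
        pre, pooled = pooled_epochs(ds, erp)
        W = erp.pca_weights(erp.grand_average(pooled), pooled.ch_names)
        rec = pre[0]
        onsets = {int(t): int(o) for t, o in zip(rec.trial_ids, rec.trial_onsets)}
        m, taus = lag_map_subject(
            erp.project(rec, W, 1), ds.target_events, ds.match_conditions,
            onsets, rec.trial_n_samples, 500.0, n_perm=1, rng=0,
            pairs=[("flip", "flip")],
        )
        assert m.shape == (3, 3, 501, 31)
        assert np.isfinite(m[0, 0]).any()
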