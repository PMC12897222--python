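"""Wavelength selectors: closed forms, oracles, planted-band recovery."""

import numpy as np
import pytest
from scipy.stats import ranksums

from grainspec import (CVPlan, ParameterError, SynthConfig, cars,
                       cars_schedule, chain, generate_spectra, iriv, msc,
                       run_selector, spa, uve, uve_stability)
from grainspec.select import SelectionResult, _iriv_classify, spa_chain


class TestCarsSchedule:
    def test_endpoints_closed_form(self):
        counts = cars_schedule(256, 50)
        assert counts[0] == 256   # r_1 = 1 keeps everything
        assert counts[-1] == 2    # r_N = 2/B keeps two bands

    def test_matches_independent_formula_everywhere(self):
        import math
        B, N = 256, 50
        counts = cars_schedule(B, N)
        k = math.log(B / 2) / (N - 1)
        a = math.exp(k)
        for i in range(1, N + 1):
            expected = math.ceil(round(B * a * math.exp(-k * i), 9))
            assert counts[i - 1] == expected

    def test_monotone_non_increasing(self):
        counts = cars_schedule(100, 30)
        assert np.all(np.diff(counts) <= 0)


class TestCars:
    def test_deterministic_given_seed(self, planted_small):
        m, _ = planted_small
        X = msc(m).X
        a = cars(X, m.labels, n_runs=10, seed=5)
        b = cars(X, m.labels, n_runs=10, seed=5)
        np.testing.assert_array_equal(a.selected, b.selected)
        assert a.trace == b.trace

    def test_recovers_planted_bands(self, planted_small):
        m, truth = planted_small
        X = msc(m).X
        hits = set()
        for seed in range(3):
            r = cars(X, m.labels, n_runs=20, seed=seed)
            hits |= set(r.selected.tolist())
        assert set(truth.informative_band_indices.tolist()) <= hits

    def test_trace_counts_follow_schedule_cap(self, planted_small):
        m, _ = planted_small
        r = cars(m.X, m.labels, n_runs=10, seed=1)
        sched = cars_schedule(m.n_bands, 10)
        for rec in r.trace:
            assert rec["n_vars"] <= sched[rec["run"] - 1]


class TestSpa:
    def test_orthogonal_columns_ordered_by_norm(self):
        # orthogonal columns with distinct norms: projection is a no-op
        norms = np.array([3.0, 5.0, 1.0, 4.0])
        X = np.diag(norms)
        chain_ = spa_chain(X, start=1, length=4)
        assert chain_.tolist() == [1, 3, 0, 2]  # decreasing residual norm

    def test_tie_breaks_to_lowest_index(self):
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
        X = np.column_stack([e1, e2, e1 + e2])
        chain_ = spa_chain(X, start=2, length=2)
        # residual norms of e1 and e2 both 1/sqrt(2): index 0 wins
        assert chain_.tolist() == [2, 0]

    def test_chain_matches_gram_schmidt_oracle(self):
        """Independent oracle: residual via QR projection at every step."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(30, 20))
            start = int(r.integers(0, 20))
            ours = spa_chain(X, start, 8)
            sel = [start]
            for _ in range(7):
                Q, _ = np.linalg.qr(X[:, sel])
                resid = X - Q @ (Q.T @ X)
                norms = np.linalg.norm(resid, axis=0)
                norms[sel] = -1
                sel.append(int(np.argmax(norms)))
            assert ours.tolist() == sel

    def test_selection_invariant_to_duplicated_rows(self, planted_small):
        m, _ = planted_small
        X = m.X[:40]
        y = m.labels[:40]
        r1 = spa(X, y, n_min=2, n_max=5, plan=CVPlan(5, seed=0))
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        r2 = spa(X2, y2, n_min=2, n_max=5, plan=CVPlan(5, seed=0))
        # projection geometry unchanged by duplicating all rows
        np.testing.assert_array_equal(
            spa_chain(X, 0, 5), spa_chain(X2, 0, 5))
        assert r1.n_selected >= 2 and r2.n_selected >= 2


class TestUve:
    def test_planted_bands_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 60))
            y = X[:, 10] + X[:, 50] + r.normal(0, 0.3, 200)
            res = uve(X, y, max_pc=8, seed=seed)
            hits += {10, 50} <= set(res.selected.tolist())
        assert hits >= 9

    def test_null_model_retention_bounded(self):
        q = 0.99
        fracs = []
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            X = r.normal(size=(150, 40))
            y = r.normal(size=150)
            res = uve(X, y, max_pc=5, threshold_quantile=q, seed=seed)
            fracs.append(res.n_selected / 40)
        assert np.mean(fracs) <= 2 * (1 - q)

    def test_stability_matches_brute_force_refits(self, planted_small):
        m, _ = planted_small
        X, y = m.X, m.labels.astype(float)
        plan = CVPlan(n_folds=5, seed=3)
        ours = uve_stability(X, y, max_pc=6, plan=plan)
        from grainspec import fit_pls
        folds = plan.folds(len(y), y)
        a = min(6, X.shape[1], len(y) - max(f.size for f in folds) - 1)
        coefs = []
        for f in folds:
            tr = np.setdiff1d(np.arange(len(y)), f)
            coefs.append(fit_pls(X[tr], y[tr], a).b)
        coefs = np.array(coefs)
        oracle = coefs.mean(axis=0) / coefs.std(axis=0, ddof=1)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_deterministic_given_seed(self, planted_small):
        m, _ = planted_small
        a = uve(m.X, m.labels, seed=4)
        b = uve(m.X, m.labels, seed=4)
        np.testing.assert_array_equal(a.selected, b.selected)


class TestIriv:
    def test_recovers_two_planted_bands_small(self):
        """Noise-only spectra: at B = 8 the scatter model would couple all
        bands to the (proportionally large) class effect, so the planted
        recovery is scored on spectra with white noise alone."""
        wins = 0
        for seed in range(10):
            cfg = SynthConfig(n_healthy=90, n_infested=110, n_bands=8,
                              seed=seed, gain_sd=0, offset_sd=0,
                              baseline_sd=0).with_planted_bands([2, 6], 0.02)
            m, _ = generate_spectra(cfg)
            res = iriv(m.X, m.labels, max_pc=8, m_rows=100,
                       plan=CVPlan(n_folds=5, seed=seed), seed=seed)
            wins += set(res.selected.tolist()) == {2, 6}
        assert wins >= 8

    def test_retained_size_non_increasing_and_terminates(self):
        cfg = SynthConfig(n_healthy=50, n_infested=60, n_bands=10,
                          seed=1).with_planted_bands([3], 0.02)
        m, _ = generate_spectra(cfg)
        res = iriv(m.X, m.labels, max_pc=5, m_rows=60,
                   plan=CVPlan(n_folds=5, seed=1), seed=1)
        sizes = [rec["n_vars"] for rec in res.trace if "n_vars" in rec]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_classification_matches_independent_recomputation(self):
        r = np.random.default_rng(0)
        m_rows, p = 80, 6
        M = r.integers(0, 2, size=(m_rows, p))
        M[M.sum(axis=1) < 2] = 1
        rmse_rows = r.uniform(0.2, 0.6, m_rows)
        dmean, pvals, cats = _iriv_classify(rmse_rows, M, alpha=0.05)
        for j in range(p):
            inc = [rmse_rows[i] for i in range(m_rows) if M[i, j] == 1]
            exc = [rmse_rows[i] for i in range(m_rows) if M[i, j] == 0]
            d = np.mean(exc) - np.mean(inc)
            pv = ranksums(exc, inc).pvalue
            assert dmean[j] == pytest.approx(d, abs=1e-12)
            if d > 0:
                expected = "strong" if pv < 0.05 else "weak"
            else:
                expected = "interfering" if pv < 0.05 else "uninformative"
            assert cats[j] == expected

    def test_deterministic_given_seed(self):
        cfg = SynthConfig(n_healthy=40, n_infested=50, n_bands=8,
                          seed=2).with_planted_bands([4], 0.02)
        m, _ = generate_spectra(cfg)
        kw = dict(max_pc=5, m_rows=60, plan=CVPlan(n_folds=5, seed=2), seed=9)
        a = iriv(m.X, m.labels, **kw)
        b = iriv(m.X, m.labels, **kw)
        np.testing.assert_array_equal(a.selected, b.selected)


class TestChain:
    def test_chained_subset_of_first_stage(self, planted_small):
        m, _ = planted_small
        X = msc(m).X
        first = cars(X, m.labels, n_runs=15, seed=3, grid=m.grid)
        combo = chain(first, spa, X, m.labels, grid=m.grid,
                      n_min=2, n_max=min(6, first.n_selected))
        assert set(combo.selected.tolist()) <= set(first.selected.tolist())
        assert combo.method == "cars_spa"
        assert combo.n_selected <= first.n_selected

    def test_identity_selector_returns_first_stage(self, planted_small):
        m, _ = planted_small
        first = cars(m.X, m.labels, n_runs=10, seed=1)

        def identity(X, y, **kw):
            return SelectionResult(method="identity",
                                   selected=np.arange(X.shape[1]),
                                   selected_nm=np.arange(X.shape[1], dtype=float),
                                   trace=[{}], seed=None, params={})

        combo = chain(first, identity, m.X, m.labels)
        np.testing.assert_array_equal(np.sort(combo.selected),
                                      np.sort(first.selected))

    def test_empty_first_stage_rejected(self, planted_small):
        m, _ = planted_small
        empty = SelectionResult(method="uve", selected=np.array([], dtype=int),
                                selected_nm=np.array([]), trace=[{}],
                                seed=0, params={})
        with pytest.raises(ParameterError):
            chain(empty, spa, m.X, m.labels)

    def test_dispatcher_runs_combinations(self, planted_small):
        m, truth = planted_small
        X = msc(m).X
        res = run_selector("cars_spa", X, m.labels, grid=m.grid, seed=3,
                           n_runs=15, n_min=2, n_max=6)
        assert res.method == "cars_spa"
        assert 2 <= res.n_selected <= 6
        with pytest.raises(ParameterError):
            run_selector("genetic", X, m.labels)
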