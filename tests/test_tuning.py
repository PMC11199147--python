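"""Tuning statistics: OLS and rank oracles, FDR, summaries, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import innerspeech as isp
from innerspeech.rates import PhaseRates
from innerspeech.session import SessionValidationError


def make_phase_rates(config, rates_by_phase, words_per_trial):
    labels = pd.DataFrame(
        {
            "trial_id": np.arange(len(words_per_trial)),
            "word": words_per_trial,
            "cue_modality": "written",
        }
    )
    return PhaseRates(
        rates={p: np.asarray(m, float) for p, m in rates_by_phase.items()},
        labels=labels,
        unit_ids=[f"u{i}" for i in range(next(iter(rates_by_phase.values())).shape[1])],
    )


class TestWordRegression:
    def test_beta_equals_word_mean_minus_iti_mean(self, config):
        """Closed-form check against an independent normal-equations oracle."""
        rng = np.random.default_rng(0)
        words = np.repeat(list(config.words), 4)
        n = len(words)
        iti = rng.normal(5, 1, size=(n, 2))
        internal = rng.normal(9, 2, size=(n, 2))
        phase_rates = make_phase_rates(
            config,
            {"ITI": iti, "cue": internal.copy(), "D1": iti.copy(),
             "internal": internal, "D2": iti.copy(), "speech": internal.copy()},
            words,
        )
        res = isp.fit_word_regression(phase_rates, config)
        j = res.index.index("internal")
        # oracle: normal equations on the one-hot design with fixed offset
        X = np.array([[1.0 if w == v else 0.0 for v in config.words] for w in words])
        for u in range(2):
            y = internal[:, u] - iti[:, u].mean()
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(res.beta[u, j], beta_oracle, atol=1e-10)
            for k, w in enumerate(config.words):
                direct = internal[words == w, u].mean() - iti[:, u].mean()
                assert res.beta[u, j, k] == pytest.approx(direct, abs=1e-10)

    def test_constant_rates_not_tuned(self, config):
        words = np.repeat(list(config.words), 3)
        n = len(words)
        flat = np.full((n, 1), 7.0)
        pr = make_phase_rates(
            config, {p: flat.copy() for p in config.phase_names}, words
        )
        res = isp.fit_word_regression(pr, config)
        assert not res.tuned.any()
        assert (res.p == 1).all()
        assert res.degenerate.all()

    def test_tuned_flag_follows_adjusted_p(self, config):
        """A unit is tuned iff its smallest adjusted p value is below 0.05."""
        rng = np.random.default_rng(1)
        words = np.repeat(list(config.words), 16)
        n = len(words)
        iti = rng.normal(5, 1, size=(n, 2))
        internal = rng.normal(5, 1, size=(n, 2))
        internal[words == "python", 0] += 6.0  # strong single-word effect, unit 0
        pr = make_phase_rates(
            config,
            {p: (internal if p == "internal" else iti).copy() for p in config.phase_names},
            words,
        )
        res = isp.fit_word_regression(pr, config)
        j = res.index.index("internal")
        assert res.tuned[0, j] == (res.p_adj[0, j].min() < 0.05)
        assert res.tuned[0, j]
        assert "python" in res.tuned_words(0, "internal")
        assert (res.p_adj >= res.p - 1e-15).all()

    def test_missing_word_rejected(self, config):
        words = np.repeat(list(config.words[:-1]), 4)
        mat = np.random.default_rng(0).normal(5, 1, (len(words), 1))
        pr = make_phase_rates(config, {p: mat.copy() for p in config.phase_names}, words)
        with pytest.raises(SessionValidationError, match="nifzig"):
            isp.fit_word_regression(pr, config)

    def test_per_bin_matches_per_phase_direction(self, config, smg_session, smg_phase_rates):
        """Per-bin and per-phase beta agree in sign for piecewise-constant units."""
        pop, trials, _, _ = smg_session
        pr, tensor = smg_phase_rates
        per_phase = isp.fit_word_regression(pr, config)
        per_bin = isp.fit_word_regression(pr, config, granularity="per_bin", rate_tensor=tensor)
        sl = config.phase_bin_slices()["internal"]
        j = per_phase.index.index("internal")
        mid_bin = (sl.start + sl.stop) // 2
        strong = np.abs(per_phase.beta[:, j, :]) > 3.0
        agree = np.sign(per_bin.beta[:, mid_bin, :][strong]) == np.sign(
            per_phase.beta[:, j, :][strong]
        )
        assert agree.mean() > 0.9


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(isp.adjust_fdr(np.array([0.03])), [0.03])

    def test_textbook_example(self):
        """BH on (0.01..0.04) -> all 0.04, per min_{j>=i} m p_(j)/j."""
        p = np.array([0.01, 0.02, 0.03, 0.04])
        m = len(p)
        # brute-force step-up oracle
        order = np.argsort(p)
        raw = p[order] * m / np.arange(1, m + 1)
        oracle = np.minimum.accumulate(raw[::-1])[::-1][np.argsort(order)]
        np.testing.assert_allclose(isp.adjust_fdr(p), oracle)
        np.testing.assert_allclose(isp.adjust_fdr(p), 0.04)

    def test_equal_ps_stay_equal(self):
        np.testing.assert_allclose(isp.adjust_fdr(np.full(5, 0.2)), 0.2)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        adj = isp.adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1).all() and (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(SessionValidationError):
            isp.adjust_fdr(np.array([0.5, 1.2]))


class TestKruskalWallis:
    def test_hand_example_matches_rank_formula(self, config):
        """3 words x 3 trials, no ties: H equals the textbook rank-sum formula."""
        cfg = isp.TaskConfig(words=("a", "b", "c"))
        words = np.repeat(["a", "b", "c"], 3)
        vals = np.array([1, 2, 3, 10, 11, 12, 20, 21, 22], float)[:, None]
        pr = make_phase_rates(cfg, {p: vals.copy() for p in cfg.phase_names}, words)
        res = isp.kruskal_wallis_tuning(pr, cfg)
        ranks = stats.rankdata(vals[:, 0])
        n = 9
        h_oracle = 12 / (n * (n + 1)) * sum(
            3 * ranks[words == w].mean() ** 2 for w in "abc"
        ) - 3 * (n + 1)
        assert res.h[0, 0] == pytest.approx(h_oracle)

    def test_constant_unit_not_tuned(self, config):
        words = np.repeat(list(config.words), 3)
        flat = np.full((len(words), 1), 4.0)
        pr = make_phase_rates(config, {p: flat.copy() for p in config.phase_names}, words)
        res = isp.kruskal_wallis_tuning(pr, config)
        assert (res.p == 1).all()
        assert not res.tuned.any()

    def test_null_rejection_rate_near_alpha(self, config):
        """Unadjusted per-unit rejection under the null stays near 5%."""
        rng = np.random.default_rng(3)
        words = np.repeat(list(config.words), 8)
        n = len(words)
        rejections = []
        for _ in range(60):
            mat = rng.normal(5, 1, size=(n, 4))
            pr = make_phase_rates(config, {p: mat for p in ["ITI"]} | {
                p: mat for p in config.phase_names}, words)
            res = isp.kruskal_wallis_tuning(pr, config)
            rejections.append((res.p[:, 0] < 0.05).mean())
        rate = np.mean(rejections)
        se = np.sqrt(0.05 * 0.95 / (60 * 4))
        assert rate < 0.05 + 3 * se


class TestSummariesAndComparisons:
    def test_identical_sessions_have_zero_width_ci(self):
        frac = np.tile([10.0, 50.0], (5, 1))
        out = isp.tuned_fraction_summary(frac, index=["ITI", "internal"])
        np.testing.assert_allclose(out["ci_low"], out["mean_pct_tuned"])
        np.testing.assert_allclose(out["ci_high"], out["mean_pct_tuned"])

    def test_ci_multiplier_is_t_quantile(self):
        """n=10 sessions: CI must use the 97.5th Student-t percentile, 9 d.f."""
        rng = np.random.default_rng(4)
        frac = rng.uniform(20, 60, size=(10, 1))
        out = isp.tuned_fraction_summary(frac)
        sem = frac[:, 0].std(ddof=1) / np.sqrt(10)
        mult = (out["ci_high"][0] - out["mean_pct_tuned"][0]) / sem
        # independent numeric inverse-CDF oracle
        from scipy.optimize import brentq

        t_oracle = brentq(lambda x: stats.t.cdf(x, 9) - 0.975, 0, 10)
        assert mult == pytest.approx(t_oracle, abs=1e-6)
        assert mult == pytest.approx(2.2622, abs=1e-3)

    def test_single_session_ci_undefined(self):
        out = isp.tuned_fraction_summary(np.array([[30.0]]))
        assert np.isnan(out["ci_low"][0]) and np.isnan(out["ci_high"][0])

    def test_identical_phases_give_null_comparison(self):
        frac = pd.DataFrame(
            {p: np.full(6, 25.0) for p in ("ITI", "cue", "D1", "internal", "D2", "speech")}
        )
        out = isp.compare_phase_tuning(frac)
        assert (out["t"] == 0).all() and (out["p"] == 1).all() and (out["cohen_d"] == 0).all()

    def test_paired_t_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        frac = pd.DataFrame(
            {
                "ITI": np.full(8, 10.0),
                "cue": 11.0 + rng.normal(0, 0.01, 8),
                "D1": np.full(8, 10.0),
                "internal": np.full(8, 10.0),
                "D2": np.full(8, 10.0),
                "speech": np.full(8, 10.0),
            }
        )
        out = isp.compare_phase_tuning(frac)
        row = out[out["action_phase"] == "cue"].iloc[0]
        diff = frac["cue"] - frac["ITI"]
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(8))
        assert row["t"] == pytest.approx(t_oracle)
        assert row["df"] == 7
        assert row["cohen_d"] == pytest.approx(diff.mean() / diff.std(ddof=1))
        assert set(zip(out["rest_phase"], out["action_phase"])) == {
            ("ITI", "cue"), ("D1", "internal"), ("D2", "speech")
        }


class TestTuningOverlap:
    def _result(self, config, tuned_words_by_unit, phase="internal"):
        """Build a minimal TuningResult with prescribed tuned word sets."""
        words = list(config.words)
        n_units = len(tuned_words_by_unit)
        shape = (n_units, 1, len(words))
        p_adj = np.ones(shape)
        for i, tw in enumerate(tuned_words_by_unit):
            for w in tw:
                p_adj[i, 0, words.index(w)] = 0.01
        return isp.TuningResult(
            unit_ids=[f"u{i}" for i in range(n_units)],
            words=words,
            granularity="per_phase",
            index=[phase],
            beta=np.zeros(shape), se=np.zeros(shape), t=np.zeros(shape),
            p=p_adj.copy(), p_adj=p_adj,
            tuned=(p_adj < 0.05).any(axis=2),
            degenerate=np.zeros((n_units, 1), bool),
        )

    def test_identical_sets_give_full_overlap(self, config):
        a = self._result(config, [{"python"}, {"spoon"}])
        out = isp.tuning_overlap(a, "internal", a, "internal")
        assert out["pct_also_tuned"] == 100.0
        assert out["pct_preserved_word"] == 100.0

    def test_disjoint_unit_sets_give_zero(self, config):
        a = self._result(config, [{"python"}, set()])
        b = self._result(config, [set(), {"python"}])
        out = isp.tuning_overlap(a, "internal", b, "internal")
        assert out["pct_also_tuned"] == 0.0 and out["pct_preserved_word"] == 0.0

    def test_word_preservation_set_logic(self, config):
        # unit0: {python} vs {python, spoon} -> both statistics
        # unit1: {cowboy} vs {spoon} -> also-tuned only
        a = self._result(config, [{"python"}, {"cowboy"}])
        b = self._result(config, [{"python", "spoon"}, {"spoon"}])
        out = isp.tuning_overlap(a, "internal", b, "internal")
        assert out["pct_also_tuned"] == 100.0
        assert out["pct_preserved_word"] == 50.0

    def test_no_tuned_units_reports_nan(self, config):
        a = self._result(config, [set(), set()])
        b = self._result(config, [{"python"}, set()])
        out = isp.tuning_overlap(a, "internal", b, "internal")
        assert np.isnan(out["pct_also_tuned"])
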