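"""dPCA: nested-loop marginalization oracle, reconstruction, PCA limit, CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

import innerspeech as isp
from innerspeech.dpca import TrialTensor, _marg_matrices
from innerspeech.session import SessionValidationError


def random_tensor(seed, N=5, T=6, C=2, W=3, K=4, scale=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(5, scale, size=(N, T, C, W, K))
    return TrialTensor(
        X,
        [f"u{i}" for i in range(N)],
        np.arange(T) * 0.05,
        [f"m{c}" for c in range(C)],
        [f"w{w}" for w in range(W)],
    )


def nested_loop_marginalize(X):
    """Brute-force oracle: every term by explicit nested-loop averaging."""
    N, T, C, W, K = X.shape
    A = X.mean(axis=4)
    Xbar = np.array([A[n].mean() for n in range(N)])
    cen = A - Xbar[:, None, None, None]

    def avg_keep(keep):
        shape = tuple(dict(t=T, c=C, w=W)[a] for a in keep)
        out = np.zeros((N,) + shape)
        axes = {"t": range(T), "c": range(C), "w": range(W)}
        for n in range(N):
            for idx in itertools.product(*[axes[a] for a in keep]):
                sel = cen[n]
                full = {"t": slice(None), "c": slice(None), "w": slice(None)}
                for a, i in zip(keep, idx):
                    full[a] = i
                out[(n,) + idx] = np.mean(sel[full["t"], full["c"], full["w"]])
        return out

    eff = {}
    for keep in [("t",), ("c",), ("w",), ("t", "c"), ("t", "w"), ("c", "w"), ("t", "c", "w")]:
        total = avg_keep(keep)
        # subtract lower-order effects by inclusion-exclusion
        for r in range(len(keep)):
            for sub in itertools.combinations(keep, r):
                if not sub:
                    continue
                lower = eff[sub]
                expand = lower
                for pos, a in enumerate(keep):
                    if a not in sub:
                        expand = np.expand_dims(expand, axis=1 + pos)
                total = total - expand
        eff[keep] = total
    timing = eff[("t",)]
    cue = eff[("c",)][:, None, :] + eff[("t", "c")]
    word = eff[("w",)][:, None, :] + eff[("t", "w")]
    cue_word = eff[("c", "w")][:, None, :, :] + eff[("t", "c", "w")]
    noise = X - A[..., None]
    return Xbar, timing, cue, word, cue_word, noise


class TestMarginalize:
    def test_matches_nested_loop_oracle_on_integer_tensor(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 10, size=(1, 2, 2, 2, 2)).astype(float)
        tt = TrialTensor(X, ["u0"], np.arange(2) * 0.05, ["m0", "m1"], ["w0", "w1"])
        m = isp.marginalize(tt)
        Xbar, timing, cue, word, cue_word, noise = nested_loop_marginalize(X)
        np.testing.assert_allclose(m.mean, Xbar, atol=1e-12)
        np.testing.assert_allclose(m.timing, timing, atol=1e-12)
        np.testing.assert_allclose(m.cue, cue, atol=1e-12)
        np.testing.assert_allclose(m.word, word, atol=1e-12)
        np.testing.assert_allclose(m.cue_word, cue_word, atol=1e-12)
        np.testing.assert_allclose(m.noise, noise, atol=1e-12)

    def test_matches_oracle_on_random_tensor(self):
        tt = random_tensor(1)
        m = isp.marginalize(tt)
        Xbar, timing, cue, word, cue_word, noise = nested_loop_marginalize(tt.X)
        np.testing.assert_allclose(m.timing, timing, atol=1e-10)
        np.testing.assert_allclose(m.cue_word, cue_word, atol=1e-10)

    def test_reconstruction_identity(self):
        tt = random_tensor(2)
        m = isp.marginalize(tt)
        np.testing.assert_allclose(m.reconstruct(tt.X.shape), tt.X, atol=1e-10)

    def test_timing_only_structure(self):
        """Tensor constant in c, w, k but varying in t: only timing nonzero."""
        T = 8
        base = np.sin(np.arange(T))
        X = np.broadcast_to(base[None, :, None, None, None], (3, T, 2, 4, 5)).copy()
        tt = TrialTensor(X, ["a", "b", "c"], np.arange(T) * 0.05, ["m0", "m1"],
                         [f"w{i}" for i in range(4)])
        m = isp.marginalize(tt)
        assert np.abs(m.timing).max() > 0
        for part in (m.cue, m.word, m.cue_word, m.noise):
            np.testing.assert_allclose(part, 0, atol=1e-12)

    def test_marginalizations_mutually_orthogonal(self):
        """Pairwise inner products vanish on random balanced tensors."""
        for seed in range(5):
            tt = random_tensor(10 + seed)
            m = isp.marginalize(tt)
            parts = m.expanded(tt.X.shape[:4])
            names = list(parts)
            total = sum(float(np.sum(parts[n] ** 2)) for n in names)
            for a, b in itertools.combinations(names, 2):
                assert abs(float(np.sum(parts[a] * parts[b]))) < 1e-8 * total


class TestBuildBalancedTensor:
    def _session(self, config, n_reps=4, seed=0, errors=()):
        pop = isp.sample_population(isp.PopulationSpec(n_units=3, seed=seed), config)
        trials, spikes, _ = isp.simulate_session(
            pop, config, n_reps=n_reps, cue_modalities=("written",), seed=seed + 1
        )
        for tid in errors:
            trials.loc[trials["trial_id"] == tid, "error_kind"] = "wrong_word_vocalized"
        tensor = isp.bin_spike_counts(spikes, trials, config)
        return trials, tensor

    def test_no_errors_equals_raw_stacking(self, config):
        trials, tensor = self._session(config)
        tt = isp.build_balanced_tensor(tensor, trials, config, k_target=4)
        word = config.words[2]
        cell = trials[trials["word"] == word].sort_values("trial_id")
        for k, tid in enumerate(cell["trial_id"]):
            np.testing.assert_array_equal(
                tt.X[:, :, 0, 2, k], tensor.values[tensor.trial_index(tid)]
            )

    def test_error_trial_replaced_by_k_minus_1_mean(self, config):
        trials, tensor = self._session(config, n_reps=8)
        word = config.words[0]
        cell = trials[trials["word"] == word].sort_values("trial_id")
        err_tid = int(cell["trial_id"].iloc[3])
        trials.loc[trials["trial_id"] == err_tid, "error_kind"] = "spoke_during_internal"
        tt = isp.build_balanced_tensor(tensor, trials, config, k_target=8)
        valid_tids = [int(t) for t in cell["trial_id"] if int(t) != err_tid]
        expected = np.mean(
            [tensor.values[tensor.trial_index(t)] for t in valid_tids], axis=0
        )
        np.testing.assert_allclose(tt.X[:, :, 0, 0, 7], expected, atol=1e-12)

    def test_cell_with_no_valid_trials_rejected(self, config):
        trials, tensor = self._session(config, n_reps=2)
        word = config.words[1]
        trials.loc[trials["word"] == word, "error_kind"] = "wrong_word_vocalized"
        with pytest.raises(SessionValidationError, match="zero valid"):
            isp.build_balanced_tensor(tensor, trials, config, k_target=2)


class TestFitDpca:
    def test_lambda_zero_full_data_matches_pca(self):
        """Single full-data target at lambda=0: decoder spans the PCA subspace."""
        tt = random_tensor(3, N=7, T=8, C=2, W=3, K=4)
        Xmat, _ = _marg_matrices(tt, None)
        model = isp.fit_dpca(tt, lam=0.0, q=3, marg_matrices={"full": Xmat})
        # independent PCA oracle via eigendecomposition
        evals, evecs = np.linalg.eigh(Xmat @ Xmat.T)
        order = np.argsort(evals)[::-1]
        U = evecs[:, order[:3]]
        F = model.encoders["full"]
        angles = np.arccos(np.clip(np.linalg.svd(U.T @ F, compute_uv=False), -1, 1))
        assert angles.max() < 1e-6

    def test_zero_marginalization_explains_zero_variance(self):
        tt = random_tensor(4)
        Xmat, Xphis = _marg_matrices(tt, None)
        Xphis["null"] = np.zeros_like(Xmat)
        model = isp.fit_dpca(tt, lam=1e-6, q=2, marg_matrices=Xphis)
        np.testing.assert_allclose(model.component_variance["null"], 0, atol=1e-16)

    def test_penalty_form(self):
        tt = random_tensor(5)
        Xmat, _ = _marg_matrices(tt, None)
        lam = 3e-4
        model = isp.fit_dpca(tt, lam=lam, q=2)
        assert model.mu == pytest.approx((lam * np.linalg.norm(Xmat)) ** 2)

    def test_negative_lambda_rejected(self):
        with pytest.raises(SessionValidationError):
            isp.fit_dpca(random_tensor(6), lam=-1.0)

    def test_heldin_loss_nondecreasing_in_lambda(self):
        tt = random_tensor(7)
        Xmat, Xphis = _marg_matrices(tt, None)

        def loss(lam):
            model = isp.fit_dpca(tt, lam=lam, q=2)
            total = 0.0
            for name in model.marginalizations:
                approx = model.encoders[name] @ (model.decoders[name] @ Xmat)
                total += float(np.sum((Xphis[name] - approx) ** 2))
            return total

        losses = [loss(l) for l in (0.0, 1e-3, 1e-2, 1e-1)]
        assert all(b >= a - 1e-9 for a, b in zip(losses, losses[1:]))


class TestSelectLambda:
    def test_single_candidate_returned(self):
        tt = random_tensor(8)
        lam, table = isp.select_lambda(tt, [1e-4], folds=3, seed=0)
        assert lam == 1e-4 and len(table) == 1

    def test_noiseless_low_rank_prefers_smallest_lambda(self):
        """Without trial noise the unpenalized fit is optimal."""
        rng = np.random.default_rng(9)
        N, T, C, W, K = 6, 8, 2, 3, 4
        base = rng.normal(0, 1, (N, T))
        word_eff = rng.normal(0, 1, (N, 1, 1, W))
        A = base[:, :, None, None] + word_eff  # (N,T,C,W) deterministic
        X = np.repeat(A[..., None], K, axis=4)
        tt = TrialTensor(X, [f"u{i}" for i in range(N)], np.arange(T) * 0.05,
                         ["m0", "m1"], [f"w{i}" for i in range(W)])
        lam, table = isp.select_lambda(tt, [1e-7, 1e-3, 1e-1], folds=5, seed=1)
        assert lam == 1e-7

    def test_empty_grid_rejected(self):
        with pytest.raises(SessionValidationError):
            isp.select_lambda(random_tensor(10), [])

    def test_deterministic_given_seed(self):
        tt = random_tensor(11)
        lam1, t1 = isp.select_lambda(tt, [1e-6, 1e-4], folds=4, seed=5)
        lam2, t2 = isp.select_lambda(tt, [1e-6, 1e-4], folds=4, seed=5)
        assert lam1 == lam2
        pd.testing.assert_frame_equal(t1, t2)


class TestVarianceAndProjections:
    def test_variance_shares_sum_to_one(self):
        tt = random_tensor(12)
        model = isp.fit_dpca(tt, lam=1e-6, q=2)
        ledger, _ = isp.variance_and_projections(model, tt)
        shares = ledger.drop_duplicates("marginalization")["marg_variance_share"]
        assert shares.sum() == pytest.approx(1.0, abs=1e-8)

    def test_word_only_structure_dominates_word_share(self):
        """Generative word gains only: word share beats cue share by far."""
        rng = np.random.default_rng(13)
        N, T, C, W, K = 8, 10, 2, 4, 6
        word_eff = rng.normal(0, 3, (N, 1, 1, W))
        X = 5 + np.repeat((word_eff + np.zeros((N, T, C, W)))[..., None], K, axis=4)
        X = X + rng.normal(0, 0.5, X.shape)  # moderate trial noise
        tt = TrialTensor(X, [f"u{i}" for i in range(N)], np.arange(T) * 0.05,
                         ["m0", "m1"], [f"w{i}" for i in range(W)])
        model = isp.fit_dpca(tt, lam=1e-6, q=2)
        ledger, proj = isp.variance_and_projections(model, tt)
        shares = dict(
            ledger.drop_duplicates("marginalization")[
                ["marginalization", "marg_variance_share"]
            ].itertuples(index=False, name=None)
        )
        assert shares["word"] > 5 * shares["cue"]
        assert shares["word"] > shares["timing"]
        assert proj["word"].shape == (2, T, C, W)

    def test_noise_floor_zeroes_pure_noise_shares(self):
        """Signal shares of a pure-noise tensor are ~0 after floor correction."""
        rng = np.random.default_rng(77)
        X = rng.normal(0, 2, size=(6, 12, 2, 4, 8))
        tt = TrialTensor(X, [f"u{i}" for i in range(6)], np.arange(12) * 0.05,
                         ["m0", "m1"], [f"w{i}" for i in range(4)])
        model = isp.fit_dpca(tt, lam=1e-6, q=1)
        ledger, _ = isp.variance_and_projections(model, tt)
        sig = ledger.drop_duplicates("marginalization").set_index("marginalization")[
            "signal_variance_share"
        ]
        for name in ("timing", "cue", "word", "cue_word"):
            assert sig[name] < 0.02
            assert ledger.set_index("marginalization")["marg_variance_share"][name].max() > 0

    def test_variance_ordering_recovered_across_simulations(self):
        """Sign/order of generative variance recovered in >=95% of runs."""
        hits = 0
        n_sim = 40
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            N, T, C, W, K = 6, 8, 2, 3, 4
            timing_eff = rng.normal(0, 3, (N, T, 1, 1))
            word_eff = rng.normal(0, 1.5, (N, 1, 1, W))
            X = 5 + timing_eff + word_eff + np.zeros((N, T, C, W))
            X = np.repeat(X[..., None], K, axis=4) + rng.normal(0, 0.5, (N, T, C, W, K))
            tt = TrialTensor(X, [f"u{i}" for i in range(N)], np.arange(T) * 0.05,
                             ["m0", "m1"], [f"w{i}" for i in range(W)])
            model = isp.fit_dpca(tt, lam=1e-6, q=1)
            ledger, _ = isp.variance_and_projections(model, tt)
            shares = dict(
                ledger.drop_duplicates("marginalization")[
                    ["marginalization", "marg_variance_share"]
                ].itertuples(index=False, name=None)
            )
            if shares["timing"] > shares["word"] > shares["cue"]:
                hits += 1
        assert hits / n_sim >= 0.95
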