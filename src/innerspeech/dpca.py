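"""Demixed principal component analysis of the trial tensor.

The balanced firing-rate tensor ``X[n, t, c, w, k]`` (neurons x time bins x
cue modalities x words x trials) is decomposed exactly into ANOVA-style
marginalizations

    X = Xbar + X_t + (X_c + X_tc) + (X_w + X_tw) + (X_cw + X_tcw) + eps

where each non-noise term averages to zero over the parameters it
marginalizes out and the noise term is ``eps = X - <X>_k``.  Pure
time-independent task terms are grouped with their time-interaction terms
(timing, cue, word, cue x word), since every component is expected to vary
with time.

For each grouped marginalization ``phi`` an encoder ``F_phi`` and decoder
``D_phi`` are fit by minimizing the ridge-penalized reduced-rank loss

    L_phi = ||X_phi - F_phi D_phi X||^2 + mu ||F_phi D_phi||^2,
    mu = (lambda ||X||)^2

with ``X`` the trial-averaged, mean-centered data matrix and ``||.||`` the
Frobenius norm.  The closed-form solution is the ridge regression of
``X_phi`` on ``X`` followed by rank-q truncation through the SVD of the
fitted values; encoder columns are unit norm with the scale absorbed into
the decoder.  ``lambda`` is selected by tenfold cross-validation that holds
out one trial per (cue, word) cell per fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import RateTensor
from .session import SessionValidationError, TaskConfig

MARGINALIZATION_NAMES = ("timing", "cue", "word", "cue_word")

_AXES = {"t": 1, "c": 2, "w": 3}


@dataclass
class TrialTensor:
    """Balanced firing-rate tensor (n_units, T, C, W, K) with axis labels."""

    X: np.ndarray
    unit_ids: list[str]
    times: np.ndarray  # bin left edges, seconds
    modalities: list[str]
    words: list[str]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.X.shape

    @property
    def k(self) -> int:
        return self.X.shape[4]

    def trial_average(self) -> np.ndarray:
        return self.X.mean(axis=4)


@dataclass
class MarginalizationSet:
    """Exact additive decomposition of a balanced trial tensor."""

    mean: np.ndarray  # (N,)
    timing: np.ndarray  # (N, T)
    cue: np.ndarray  # (N, T, C)
    word: np.ndarray  # (N, T, W)
    cue_word: np.ndarray  # (N, T, C, W)
    noise: np.ndarray  # (N, T, C, W, K)

    def grouped(self) -> dict[str, np.ndarray]:
        return {
            "timing": self.timing,
            "cue": self.cue,
            "word": self.word,
            "cue_word": self.cue_word,
        }

    def expanded(self, shape: tuple[int, ...]) -> dict[str, np.ndarray]:
        """Each grouped term broadcast to the full (N,T,C,W) shape."""
        N, T, C, W = shape[:4]
        return {
            "timing": np.broadcast_to(self.timing[:, :, None, None], (N, T, C, W)),
            "cue": np.broadcast_to(self.cue[:, :, :, None], (N, T, C, W)),
            "word": np.broadcast_to(self.word[:, :, None, :], (N, T, C, W)),
            "cue_word": self.cue_word,
        }

    def reconstruct(self, shape: tuple[int, ...]) -> np.ndarray:
        """mean + all marginalizations + noise, at full (N,T,C,W,K) shape."""
        N, T, C, W, K = shape
        parts = self.expanded(shape)
        total = (
            self.mean[:, None, None, None]
            + parts["timing"]
            + parts["cue"]
            + parts["word"]
            + parts["cue_word"]
        )
        return total[..., None] + self.noise


def build_balanced_tensor(
    rates: RateTensor,
    trials: pd.DataFrame,
    config: TaskConfig,
    k_target: int,
    modalities=None,
) -> TrialTensor:
    """Stack rates into a balanced (N,T,C,W,K) tensor.

    Error trials keep their slot but their entries are replaced by the mean
    firing rate of the cell's remaining valid trials (the k-1 replacement
    rule).  Cells with more than ``k_target`` valid trials are truncated
    deterministically by trial id.
    """
    modalities = list(modalities or sorted(trials["cue_modality"].unique()))
    words = list(config.words)
    n_units = len(rates.unit_ids)
    T = rates.n_bins
    X = np.zeros((n_units, T, len(modalities), len(words), k_target))
    for ci, c in enumerate(modalities):
        for wi, w in enumerate(words):
            cell = trials[(trials["cue_modality"] == c) & (trials["word"] == w)]
            cell = cell.sort_values("trial_id")
            valid = cell[cell["error_kind"] == "none"]["trial_id"].to_list()
            errors = cell[cell["error_kind"] != "none"]["trial_id"].to_list()
            if len(valid) == 0:
                raise SessionValidationError(
                    f"cell ({c!r}, {w!r}) has zero valid trials"
                )
            n_err_used = max(0, k_target - min(len(valid), k_target))
            if len(valid) + n_err_used < k_target:
                raise SessionValidationError(
                    f"cell ({c!r}, {w!r}) has too few trials for k={k_target}"
                )
            use_valid = valid[: min(len(valid), k_target)]
            # slab shape: (units, bins)
            slabs = [rates.values[rates.trial_index(tid)] for tid in use_valid]
            stack = np.stack(slabs, axis=-1)  # (units, bins, k_valid)
            if len(use_valid) < k_target:
                fill = stack.mean(axis=-1, keepdims=True)
                pad = np.repeat(fill, k_target - len(use_valid), axis=-1)
                stack = np.concatenate([stack, pad], axis=-1)
            X[:, :, ci, wi, :] = stack
    return TrialTensor(
        X=X,
        unit_ids=list(rates.unit_ids),
        times=rates.bin_edges[:-1],
        modalities=modalities,
        words=words,
    )


def _effect(centered: np.ndarray, keep: tuple[str, ...]) -> np.ndarray:
    """Pure ANOVA effect of parameter subset ``keep`` via inclusion-exclusion.

    ``centered`` is the grand-mean-removed trial average (N,T,C,W); the
    effect of subset S is sum over subsets T of S of (-1)^{|S|-|T|} times
    the average keeping only T's axes.
    """
    out = None
    for r in range(len(keep) + 1):
        for sub in itertools.combinations(keep, r):
            drop = tuple(_AXES[a] for a in _AXES if a not in sub)
            term = centered.mean(axis=drop, keepdims=True)
            sign = (-1) ** (len(keep) - len(sub))
            out = sign * term if out is None else out + sign * term
    return np.squeeze(
        out, axis=tuple(_AXES[a] for a in _AXES if a not in keep)
    )


def marginalize(tensor: TrialTensor) -> MarginalizationSet:
    """Decompose the tensor into mean/timing/cue/word/interaction/noise."""
    X = tensor.X
    A = X.mean(axis=4)  # (N,T,C,W) trial average
    mean = A.mean(axis=(1, 2, 3))
    centered = A - mean[:, None, None, None]
    timing = _effect(centered, ("t",))
    cue = _effect(centered, ("c",))[:, None, :] + _effect(centered, ("t", "c"))
    word = _effect(centered, ("w",))[:, None, :] + _effect(centered, ("t", "w"))
    cue_word = (
        _effect(centered, ("c", "w"))[:, None, :, :]
        + _effect(centered, ("t", "c", "w"))
    )
    noise = X - A[..., None]
    return MarginalizationSet(
        mean=mean, timing=timing, cue=cue, word=word, cue_word=cue_word, noise=noise
    )


@dataclass
class DPCAModel:
    """Fitted encoder/decoder pairs and explained-variance ledger."""

    marginalizations: list[str]
    encoders: dict[str, np.ndarray]  # F_phi: (N, q)
    decoders: dict[str, np.ndarray]  # D_phi: (q, N)
    lam: float
    mu: float
    component_variance: dict[str, np.ndarray]  # per-component EV of X_phi
    total_marg_variance: dict[str, float]  # ||X_phi||^2 per marginalization

    def project(self, data: np.ndarray, phi: str) -> np.ndarray:
        """Project (N, ...) data onto the decoder axes of marginalization phi."""
        flat = data.reshape(data.shape[0], -1)
        return (self.decoders[phi] @ flat).reshape(
            (self.decoders[phi].shape[0],) + data.shape[1:]
        )


def _marg_matrices(
    tensor: TrialTensor, margs: MarginalizationSet | None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Trial-averaged centered data matrix X and expanded X_phi matrices."""
    if margs is None:
        margs = marginalize(tensor)
    A = tensor.trial_average()
    N = A.shape[0]
    Xmat = (A - margs.mean[:, None, None, None]).reshape(N, -1)
    Xphis = {
        name: part.reshape(N, -1)
        for name, part in margs.expanded(A.shape).items()
    }
    return Xmat, Xphis


def fit_dpca(
    tensor: TrialTensor,
    lam: float = 1e-6,
    q: int = 3,
    margs: MarginalizationSet | None = None,
    marg_matrices: dict[str, np.ndarray] | None = None,
) -> DPCAModel:
    """Fit the regularized encoder/decoder pair for each marginalization.

    ``marg_matrices`` may override the targets (name -> (N, TCW) matrix),
    e.g. a single full-data target, in which case the solution at lambda=0
    coincides with PCA of the data matrix.
    """
    if lam < 0:
        raise SessionValidationError("lambda must be >= 0")
    Xmat, Xphis = _marg_matrices(tensor, margs)
    if marg_matrices is not None:
        Xphis = marg_matrices
    N = Xmat.shape[0]
    mu = (lam * np.linalg.norm(Xmat)) ** 2
    G = Xmat @ Xmat.T
    Greg = G + mu * np.eye(N)
    Ginv = np.linalg.pinv(Greg)
    encoders, decoders, comp_var, tot_var = {}, {}, {}, {}
    for name, Xphi in Xphis.items():
        rank = int(np.linalg.matrix_rank(Xphi)) if Xphi.any() else 0
        q_phi = min(q, max(rank, 1))
        Wls = Xphi @ Xmat.T @ Ginv  # (N, N) ridge solution
        fitted = Wls @ Xmat
        U, s, _ = np.linalg.svd(fitted, full_matrices=False)
        F = U[:, :q_phi]
        D = F.T @ Wls
        encoders[name] = F
        decoders[name] = D
        # per-component explained variance of X_phi
        ev = []
        for i in range(q_phi):
            approx = np.outer(F[:, i], D[i] @ Xmat)
            ev.append(float(np.sum(Xphi**2) - np.sum((Xphi - approx) ** 2)))
        comp_var[name] = np.array(ev)
        tot_var[name] = float(np.sum(Xphi**2))
    return DPCAModel(
        marginalizations=list(Xphis),
        encoders=encoders,
        decoders=decoders,
        lam=lam,
        mu=float(mu),
        component_variance=comp_var,
        total_marg_variance=tot_var,
    )


def select_lambda(
    tensor: TrialTensor,
    lambdas,
    folds: int = 10,
    seed: int = 0,
    q: int = 3,
) -> tuple[float, pd.DataFrame]:
    """Pick lambda by tenfold CV: hold out one trial per (c, w) cell per fold.

    Per fold, the model is fit on the remaining trials' averages and scored
    by the reconstruction error of the held-out trials' marginalizations,
    summed over marginalizations.  Returns (best lambda, per-lambda table).
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise SessionValidationError("lambda grid is empty")
    K = tensor.k
    if K < 2:
        raise SessionValidationError("need >= 2 trials per cell for CV")
    rng = np.random.default_rng(seed)
    N, T, C, W, _ = tensor.shape
    errors = np.zeros((len(lambdas), folds))
    for f in range(folds):
        held = rng.integers(0, K, size=(C, W))
        mask = np.ones((C, W, K), bool)
        for c in range(C):
            for w in range(W):
                mask[c, w, held[c, w]] = False
        Xtrain = np.empty((N, T, C, W, K - 1))
        Xtest = np.empty((N, T, C, W, 1))
        for c in range(C):
            for w in range(W):
                Xtrain[:, :, c, w, :] = tensor.X[:, :, c, w, mask[c, w]]
                Xtest[:, :, c, w, 0] = tensor.X[:, :, c, w, held[c, w]]
        tr = TrialTensor(Xtrain, tensor.unit_ids, tensor.times, tensor.modalities, tensor.words)
        te = TrialTensor(Xtest, tensor.unit_ids, tensor.times, tensor.modalities, tensor.words)
        Xmat_te, Xphi_te = _marg_matrices(te, None)
        margs_tr = marginalize(tr)
        for li, lam in enumerate(lambdas):
            model = fit_dpca(tr, lam=lam, q=q, margs=margs_tr)
            err = 0.0
            for name in model.marginalizations:
                approx = model.encoders[name] @ (model.decoders[name] @ Xmat_te)
                err += float(np.sum((Xphi_te[name] - approx) ** 2))
            errors[li, f] = err
    mean_err = errors.mean(axis=1)
    best = int(np.argmin(mean_err))
    table = pd.DataFrame({"lambda": lambdas, "cv_error": mean_err})
    return float(lambdas[best]), table


def marginalization_noise_floor(tensor: TrialTensor) -> dict[str, float]:
    """Expected leakage of trial noise into each marginalization.

    Averaging K noisy trials leaves residual noise in the trial average that
    the ANOVA decomposition distributes across marginalizations in
    proportion to their degrees of freedom (expected mean squares): with
    pooled within-cell sum of squares ||eps||^2,

        floor_phi = df_phi / (T C W) * ||eps||^2 / (K (K - 1)),

    in the same units as ||X_phi||^2.  df: timing T-1, cue T(C-1),
    word T(W-1), cue x word T(C-1)(W-1).  Subtracting the floor gives an
    (approximately) unbiased estimate of the signal variance in each
    marginalization; it is exact for noise that is homoscedastic across
    cells at each (unit, bin).
    """
    _, T, C, W, K = tensor.shape
    if K < 2:
        return {name: 0.0 for name in MARGINALIZATION_NAMES}
    noise_ss = float(np.sum((tensor.X - tensor.trial_average()[..., None]) ** 2))
    df = {
        "timing": T - 1,
        "cue": T * (C - 1),
        "word": T * (W - 1),
        "cue_word": T * (C - 1) * (W - 1),
    }
    scale = noise_ss / (K * (K - 1)) / (T * C * W)
    return {name: df[name] * scale for name in MARGINALIZATION_NAMES}


def variance_and_projections(
    model: DPCAModel, tensor: TrialTensor, margs: MarginalizationSet | None = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Explained-variance ledger and decoder-axis time courses.

    Variance shares are fractions of the total mean-removed variance
    ``||X - Xbar||^2`` over all tensor entries; under the balanced design
    the marginalization terms (times K) plus noise sum to it exactly.
    ``signal_variance_share`` subtracts the analytic noise floor
    (:func:`marginalization_noise_floor`) from each marginalization, so a
    word-agnostic population reports a word signal share near zero even
    though averaging noise leaks into its raw word marginalization.
    Projections map the trial-averaged data through each decoder axis,
    giving per-condition time courses of shape (q, T, C, W).
    """
    if margs is None:
        margs = marginalize(tensor)
    K = tensor.k
    A = tensor.trial_average()
    total = float(np.sum((tensor.X - margs.mean[:, None, None, None, None]) ** 2))
    floors = marginalization_noise_floor(tensor)
    rows = []
    shares = {}
    for name in model.marginalizations:
        v = K * model.total_marg_variance.get(name, 0.0)
        share = v / total if total > 0 else 0.0
        signal = max(
            0.0,
            K * (model.total_marg_variance.get(name, 0.0) - floors.get(name, 0.0))
            / total
            if total > 0
            else 0.0,
        )
        shares[name] = share
        for i, ev in enumerate(model.component_variance[name]):
            rows.append(
                {
                    "marginalization": name,
                    "component": i + 1,
                    "component_variance": ev,
                    "marg_variance_share": share,
                    "signal_variance_share": signal,
                }
            )
    noise_var = float(np.sum(margs.noise**2))
    rows.append(
        {
            "marginalization": "noise",
            "component": 0,
            "component_variance": noise_var,
            "marg_variance_share": noise_var / total if total > 0 else 0.0,
            "signal_variance_share": float("nan"),
        }
    )
    ledger = pd.DataFrame(rows)
    centered = A - margs.mean[:, None, None, None]
    projections = {
        name: model.project(centered, name) for name in model.marginalizations
    }
    return ledger, projections
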