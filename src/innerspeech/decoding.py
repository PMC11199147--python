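"""Phase-wise word decoding.

Decoder: PCA on the training rows keeping the smallest number of
components whose cumulative variance share strictly exceeds 95%, followed
by linear discriminant analysis with a covariance matrix shared across
words (equal priors).  Performance is estimated by leave-one-out
cross-validation in which the PCA projection and the LDA parameters are
refit from scratch on every fold, so the held-out trial never influences
the model.  Significance is graded against a label-shuffle null: observed
mean accuracy above the null's 97.5th percentile is reported as p < 0.05,
above the 99.5th as p < 0.01.

Also provided: cross-phase generalization (train the fold model on one
phase's rates, test on each phase's rates of the held-out trial) and a
simulated closed-loop online decoder that is retrained after each run on
all data accumulated so far.

When the training-set size is small relative to the feature count the
pooled covariance is shrunk toward its diagonal with an analytically chosen
(Ledoit-Wolf) intensity; ties in the discriminant are broken toward the
lowest class index in word-list order, making every prediction
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import ledoit_wolf_shrinkage

from .rates import PhaseRates
from .session import SessionValidationError, TaskConfig

VAR_THRESHOLD = 0.95


@dataclass
class DecoderModel:
    """Fitted PCA feature projection + shared-covariance LDA."""

    classes: list[str]
    center: np.ndarray  # (n_features,)
    components: np.ndarray  # (n_features, q)
    class_means: np.ndarray  # (K, q)
    cov: np.ndarray  # (q, q) pooled, possibly shrunk
    shrinkage: float
    _coef: np.ndarray = field(repr=False, default=None)  # (K, q)
    _intercept: np.ndarray = field(repr=False, default=None)  # (K,)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.center) @ self.components

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores per class (equal priors)."""
        Z = self.transform(X)
        return Z @ self._coef.T + self._intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        # argmax returns the first maximum: lowest class index wins ties
        idx = np.argmax(scores, axis=1)
        return np.asarray(self.classes, object)[idx]

    def param_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for arr in (self.center, self.components, self.class_means, self.cov):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


@dataclass
class DecodingResult:
    """Leave-one-out decoding outcome for one phase of one session."""

    phase: str
    classes: list[str]
    accuracy: float  # percent
    confusion: np.ndarray  # (K, K) true x predicted counts
    n_trials: int
    n_units: int
    predictions: np.ndarray | None = None


@dataclass
class ShuffleResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    percentile_975: float
    percentile_995: float
    grade: str  # "p<0.01" | "p<0.05" | "ns"


def _class_order(y: np.ndarray, classes) -> list[str]:
    if classes is None:
        seen = []
        for v in y:
            if v not in seen:
                seen.append(v)
        return seen
    return [c for c in classes if c in set(y)]


def train_decoder(
    X: np.ndarray,
    y: np.ndarray,
    classes=None,
    var_threshold: float = VAR_THRESHOLD,
) -> DecoderModel:
    """Fit PCA (+>95% variance components) and shared-covariance LDA.

    ``classes`` fixes the class order used for tie-breaking (pass the task's
    word list); classes absent from ``y`` are dropped.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, object)
    order = _class_order(y, classes)
    if len(order) < 2:
        raise SessionValidationError("need >= 2 classes to train a decoder")
    for c in order:
        if (y == c).sum() < 2:
            raise SessionValidationError(f"class {c!r} has < 2 training trials")

    center = X.mean(axis=0)
    Xc = X - center
    # PCA via SVD of the centered training matrix
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        q = 1
    else:
        cum = np.cumsum(var) / total
        above = np.nonzero(cum > var_threshold)[0]
        q = int(above[0]) + 1 if above.size else len(var)
        # never keep numerically-zero directions
        nz = int((var > 1e-12 * total).sum())
        q = max(1, min(q, nz if nz else 1))
    P = Vt[:q].T
    Z = Xc @ P

    K = len(order)
    n, d = Z.shape
    means = np.vstack([Z[y == c].mean(axis=0) for c in order])
    resid = Z - means[[order.index(c) for c in y]]
    dof = max(n - K, 1)
    cov = (resid.T @ resid) / dof
    alpha = 0.0
    if n <= d + K:
        # small-sample regime: shrink toward the diagonal, analytic intensity
        alpha = float(ledoit_wolf_shrinkage(resid))
        cov = (1 - alpha) * cov + alpha * np.diag(np.diag(cov))
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        # zero or rank-deficient residual covariance (e.g. noiseless toys)
        prec = np.linalg.pinv(cov)
    coef = means @ prec  # (K, d)
    intercept = -0.5 * np.einsum("kd,kd->k", coef, means)
    return DecoderModel(
        classes=order,
        center=center,
        components=P,
        class_means=means,
        cov=cov,
        shrinkage=alpha,
        _coef=coef,
        _intercept=intercept,
    )


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    return M


def loo_cv_decode(
    X: np.ndarray,
    y: np.ndarray,
    classes=None,
    var_threshold: float = VAR_THRESHOLD,
    phase: str = "",
) -> DecodingResult:
    """Leave-one-out CV: refit PCA + LDA on every fold, predict the held trial."""
    X = np.asarray(X, float)
    y = np.asarray(y, object)
    n = len(y)
    order = _class_order(y, classes)
    if n < len(order) + 1:
        raise SessionValidationError("need n trials >= n classes + 1 for LOO")
    preds = np.empty(n, object)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        model = train_decoder(X[mask], y[mask], classes=order, var_threshold=var_threshold)
        preds[i] = model.predict(X[i : i + 1])[0]
    conf = _confusion(y, preds, order)
    acc = 100.0 * np.trace(conf) / n
    return DecodingResult(
        phase=phase,
        classes=order,
        accuracy=acc,
        confusion=conf,
        n_trials=n,
        n_units=X.shape[1],
        predictions=preds,
    )


def decode_phase(
    phase_rates: PhaseRates,
    phase: str,
    classes=None,
    var_threshold: float = VAR_THRESHOLD,
) -> DecodingResult:
    """LOO word decoding from one phase's trial x unit mean rates."""
    X = phase_rates.rates[phase]
    y = phase_rates.labels["word"].to_numpy(object)
    return loo_cv_decode(X, y, classes=classes, var_threshold=var_threshold, phase=phase)


def grade_against_null(observed: float, null: np.ndarray) -> ShuffleResult:
    """Percentile grading of an observed accuracy against a shuffle null."""
    q975, q995 = np.percentile(null, [97.5, 99.5])
    if observed > q995:
        grade = "p<0.01"
    elif observed > q975:
        grade = "p<0.05"
    else:
        grade = "ns"
    return ShuffleResult(
        observed_accuracy=float(observed),
        null_accuracies=np.asarray(null, float),
        percentile_975=float(q975),
        percentile_995=float(q995),
        grade=grade,
    )


def shuffle_significance(
    X: np.ndarray,
    y: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    classes=None,
    var_threshold: float = VAR_THRESHOLD,
    observed: float | None = None,
) -> ShuffleResult:
    """Label-shuffle null for LOO decoding accuracy.

    Each repetition applies a full within-session label permutation
    (class counts preserved) and reruns the entire LOO procedure.
    """
    if n_shuffles < 1:
        raise SessionValidationError("n_shuffles: must be >= 1")
    y = np.asarray(y, object)
    if observed is None:
        observed = loo_cv_decode(X, y, classes=classes, var_threshold=var_threshold).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(y))
        null[s] = loo_cv_decode(
            X, y[perm], classes=classes, var_threshold=var_threshold
        ).accuracy
    return grade_against_null(observed, null)


def cross_phase_decode(
    phase_rates: PhaseRates,
    train_phase: str,
    test_phases=None,
    classes=None,
    var_threshold: float = VAR_THRESHOLD,
) -> dict[str, DecodingResult]:
    """Train on one phase, test on several, sharing leave-one-out folds.

    Per fold the model is fit on the training phase's rows of the training
    trials and evaluated on each test phase's row of the held-out trial, so
    same-trial leakage is impossible by construction and testing on the
    training phase reproduces :func:`loo_cv_decode` exactly.
    """
    test_phases = list(test_phases or phase_rates.phases)
    y = phase_rates.labels["word"].to_numpy(object)
    n = len(y)
    Xtr = phase_rates.rates[train_phase]
    for ph in test_phases:
        if phase_rates.rates[ph].shape[0] != n:
            raise SessionValidationError(f"phase {ph!r} missing trials present elsewhere")
    order = _class_order(y, classes)
    preds = {ph: np.empty(n, object) for ph in test_phases}
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        model = train_decoder(Xtr[mask], y[mask], classes=order, var_threshold=var_threshold)
        for ph in test_phases:
            preds[ph][i] = model.predict(phase_rates.rates[ph][i : i + 1])[0]
    out = {}
    for ph in test_phases:
        conf = _confusion(y, preds[ph], order)
        out[ph] = DecodingResult(
            phase=ph,
            classes=order,
            accuracy=100.0 * np.trace(conf) / n,
            confusion=conf,
            n_trials=n,
            n_units=Xtr.shape[1],
            predictions=preds[ph],
        )
    return out


def cross_phase_matrix(
    phase_rates: PhaseRates, phases=None, classes=None
) -> pd.DataFrame:
    """Full train-phase x test-phase LOO accuracy matrix (percent)."""
    phases = list(phases or phase_rates.phases)
    rows = {}
    for tr in phases:
        res = cross_phase_decode(phase_rates, tr, phases, classes=classes)
        rows[tr] = {ph: res[ph].accuracy for ph in phases}
    return pd.DataFrame(rows).T.loc[phases, phases]


def compare_test_phases(
    per_session: pd.DataFrame, pairs
) -> pd.DataFrame:
    """Paired two-tailed t tests between test phases, BH-FDR corrected.

    ``per_session`` has one row per session and one column per test phase.
    """
    from .tuning import adjust_fdr

    rows = []
    for a, b in pairs:
        va = per_session[a].to_numpy(float)
        vb = per_session[b].to_numpy(float)
        diff = va - vb
        sd = diff.std(ddof=1)
        if sd == 0:
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p = stats.ttest_rel(va, vb)
            d = diff.mean() / sd
        rows.append({"phase_a": a, "phase_b": b, "t": float(t), "df": len(diff) - 1,
                     "p": float(p), "cohen_d": float(d)})
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_fdr(out["p"].to_numpy())
    return out


@dataclass
class OnlineResult:
    """Simulated closed-loop outcome: per-run accuracy and training budget."""

    run_accuracies: list[float]  # percent, one per online run
    trials_per_word_before_run: list[float]  # training reps per word
    train_seconds_per_word_before_run: list[float]
    feedback: list[np.ndarray]  # per run: bool correct/incorrect per trial
    shuffle: list[ShuffleResult] | None = None

    @property
    def overall_accuracy(self) -> float:
        all_fb = np.concatenate(self.feedback)
        return 100.0 * all_fb.mean()


def training_seconds_per_word(n_reps: int, config: TaskConfig) -> float:
    """Seconds of internal-phase training data per word for n repetitions."""
    internal = dict(zip(config.phase_names, config.phase_durations))["internal"]
    return n_reps * internal


def simulate_online(
    initial_X: np.ndarray,
    initial_y: np.ndarray,
    runs: list[tuple[np.ndarray, np.ndarray]],
    config: TaskConfig,
    classes=None,
    n_shuffles: int = 0,
    seed: int = 0,
    var_threshold: float = VAR_THRESHOLD,
) -> OnlineResult:
    """Simulate the closed-loop protocol on internal-phase rates.

    Starts from an initial training block; each run's trials are classified
    once (feedback logged), then the decoder is retrained on the accumulated
    data.  With ``n_shuffles`` > 0, each run is graded against a null built
    by retraining on label-shuffled accumulated data (1,000 repetitions is
    the convention for online runs).
    """
    if any(len(ry) == 0 for _, ry in runs):
        raise SessionValidationError("empty online run")
    X = np.asarray(initial_X, float)
    y = np.asarray(initial_y, object)
    order = _class_order(y, classes)
    rng = np.random.default_rng(seed)
    accs, reps, seconds, feedback, shuffles = [], [], [], [], []
    for run_X, run_y in runs:
        run_X = np.asarray(run_X, float)
        run_y = np.asarray(run_y, object)
        counts = pd.Series(y).value_counts()
        reps_per_word = float(counts.mean())
        reps.append(reps_per_word)
        seconds.append(training_seconds_per_word(reps_per_word, config))
        model = train_decoder(X, y, classes=order, var_threshold=var_threshold)
        pred = model.predict(run_X)
        correct = pred == run_y
        feedback.append(correct)
        accs.append(100.0 * correct.mean())
        if n_shuffles > 0:
            null = np.empty(n_shuffles)
            for s in range(n_shuffles):
                perm = rng.permutation(len(y))
                m = train_decoder(X, y[perm], classes=order, var_threshold=var_threshold)
                null[s] = 100.0 * (m.predict(run_X) == run_y).mean()
            shuffles.append(grade_against_null(accs[-1], null))
        X = np.vstack([X, run_X])
        y = np.concatenate([y, run_y])
    return OnlineResult(
        run_accuracies=accs,
        trials_per_word_before_run=reps,
        train_seconds_per_word_before_run=seconds,
        feedback=feedback,
        shuffle=shuffles if n_shuffles > 0 else None,
    )
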