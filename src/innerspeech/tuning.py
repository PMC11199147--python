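"""Word-tuning statistics for single units.

The primary tuning definition fits, per unit, the indicator regression

    FR = sum_w beta_w * X_w + beta_0

where ``X_w`` is 1 on trials of word ``w`` and ``beta_0`` is the offset
term equal to the unit's average ITI firing rate.  The offset is taken
literally: the ITI mean (over the same trials) is subtracted from the
response and the word indicators are fit without an intercept, so
``beta_w`` is exactly the word mean minus the ITI mean.  Estimating the
offset from pooled ITI observations instead would mix the ITI window's
(low) residual variance into the tested phase's and misstate the standard
errors whenever the two windows differ in length.  A t statistic
(beta / SE, residual d.f. = n - W) with its two-sided p value is computed
per word; p values are Benjamini-Hochberg adjusted per unit across the W
words, and a unit is tuned wherever ``min_w p_adj < 0.05``.

The regression runs either per task phase (on phase-averaged rates) or per
50-ms bin (the per-bin response against the trial's ITI mean).  A
Kruskal-Wallis test across words is provided as the non-parametric
alternative, FDR-adjusted across units within each phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rates import PhaseRates, RateTensor
from .session import SessionValidationError, TaskConfig

ALPHA = 0.05

#: rest-phase -> following action-phase pairs tested by compare_phase_tuning
DEFAULT_PHASE_PAIRS = (("ITI", "cue"), ("D1", "internal"), ("D2", "speech"))


@dataclass
class TuningResult:
    """Per unit x (phase or bin) x word regression tuning statistics."""

    unit_ids: list[str]
    words: list[str]
    granularity: str  # "per_phase" | "per_bin"
    index: list  # phase names or bin indices
    beta: np.ndarray  # (n_units, n_index, W)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    tuned: np.ndarray  # bool (n_units, n_index)
    degenerate: np.ndarray  # bool (n_units, n_index): zero residual variance

    @property
    def tuned_any(self) -> np.ndarray:
        """Per unit: tuned in at least one phase/bin."""
        return self.tuned.any(axis=1)

    def tuned_fraction(self) -> np.ndarray:
        """% of units tuned, per phase/bin."""
        return 100.0 * self.tuned.mean(axis=0)

    def tuned_words(self, unit: int | str, where) -> set[str]:
        """Set of words with adjusted p < alpha for a unit at a phase/bin."""
        i = self.unit_ids.index(unit) if isinstance(unit, str) else unit
        j = self.index.index(where)
        return {w for k, w in enumerate(self.words) if self.p_adj[i, j, k] < ALPHA}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, uid in enumerate(self.unit_ids):
            for j, idx in enumerate(self.index):
                for k, w in enumerate(self.words):
                    rows.append(
                        {
                            "unit_id": uid,
                            ("phase" if self.granularity == "per_phase" else "bin"): idx,
                            "word": w,
                            "beta": self.beta[i, j, k],
                            "se": self.se[i, j, k],
                            "t": self.t[i, j, k],
                            "p": self.p[i, j, k],
                            "p_adj": self.p_adj[i, j, k],
                            "tuned": bool(self.tuned[i, j]),
                        }
                    )
        return pd.DataFrame(rows)


def adjust_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise SessionValidationError("p values must lie in [0, 1]")
    flat = p.ravel()
    adj = multipletests(flat, method="fdr_bh")[1]
    return adj.reshape(p.shape)


def _design(labels: pd.DataFrame, words: list[str]) -> np.ndarray:
    """One-hot word indicator design (n trials x W), no intercept column.

    The offset beta_0 is handled by subtracting the unit's average ITI rate
    from the response before the fit.
    """
    n = len(labels)
    X = np.zeros((n, len(words)))
    word_idx = {w: k for k, w in enumerate(words)}
    for i, w in enumerate(labels["word"]):
        X[i, word_idx[w]] = 1.0
    return X


def _ols_tuning(
    X: np.ndarray, Y: np.ndarray, var_offset: np.ndarray | None = None
) -> tuple[np.ndarray, ...]:
    """Vectorized OLS over columns of Y (one column per unit/bin series).

    ``var_offset`` is the per-column sampling variance of the subtracted
    ITI-mean offset; the coefficient beta_w = (word mean - ITI mean)
    inherits it, so it is added to the squared standard error.
    Returns (beta, se, t, p, degenerate) for the W word coefficients.
    """
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    H = XtX_inv @ X.T
    B = H @ Y  # (k, m)
    resid = Y - X @ B
    dof = n - k
    rss = (resid**2).sum(axis=0)
    s2 = rss / dof
    degenerate = s2 <= 1e-12 * max(1.0, float(np.abs(Y).max()) ** 2)
    diag = np.diag(XtX_inv)[:, None]
    var = s2[None, :] * diag
    if var_offset is not None:
        var = var + var_offset[None, :]
    se = np.sqrt(np.clip(var, 0, None))
    beta = B
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    # zero residual variance: no evidence convention, p = 1
    p[:, degenerate] = 1.0
    t[:, degenerate] = 0.0
    return beta, se, t, p, degenerate


def _check_word_balance(labels: pd.DataFrame, words: list[str]) -> None:
    counts = labels["word"].value_counts()
    missing = [w for w in words if counts.get(w, 0) < 2]
    if missing:
        raise SessionValidationError(
            f"need >=2 trials per word; deficient words: {missing}"
        )


def fit_word_regression(
    phase_rates: PhaseRates,
    config: TaskConfig,
    granularity: str = "per_phase",
    rate_tensor: RateTensor | None = None,
) -> TuningResult:
    """Indicator regression against ITI baseline, per phase or per 50-ms bin.

    ``per_phase`` uses the phase-averaged rates; ``per_bin`` additionally
    needs the (smoothed) ``rate_tensor`` and regresses each bin's rate on
    the word indicators with the trial's ITI mean as reference rows.
    """
    words = list(config.words)
    labels = phase_rates.labels
    _check_word_balance(labels, words)
    X = _design(labels, words)
    n = len(labels)
    unit_ids = phase_rates.unit_ids
    iti = phase_rates.rates["ITI"]  # (n, units) reference observations

    if granularity == "per_phase":
        index: list = [p for p in config.phase_names]
        blocks = [phase_rates.rates[p] for p in index]
    elif granularity == "per_bin":
        if rate_tensor is None:
            raise SessionValidationError("per_bin granularity needs rate_tensor")
        index = list(range(rate_tensor.n_bins))
        blocks = [rate_tensor.values[:, :, b] for b in index]
    else:
        raise SessionValidationError(f"unknown granularity {granularity!r}")

    W = len(words)
    shape = (len(unit_ids), len(index), W)
    beta = np.zeros(shape)
    se = np.zeros(shape)
    tstat = np.zeros(shape)
    p = np.ones(shape)
    degen = np.zeros((len(unit_ids), len(index)), bool)
    iti_mean = iti.mean(axis=0)  # fixed offset beta_0 per unit
    var_offset = iti.var(axis=0, ddof=1) / n  # sampling variance of beta_0
    for j, resp in enumerate(blocks):
        Y = resp - iti_mean[None, :]  # (n, units)
        b, s, t, pv, dg = _ols_tuning(X, Y, var_offset)
        beta[:, j, :] = b.T
        se[:, j, :] = s.T
        tstat[:, j, :] = t.T
        p[:, j, :] = pv.T
        degen[:, j] = dg
    # FDR family: per unit, per phase/bin, across its W word p values
    p_adj = np.ones_like(p)
    for i in range(len(unit_ids)):
        for j in range(len(index)):
            p_adj[i, j] = adjust_fdr(p[i, j])
    tuned = (p_adj < ALPHA).any(axis=2)
    return TuningResult(
        unit_ids=list(unit_ids),
        words=words,
        granularity=granularity,
        index=index,
        beta=beta,
        se=se,
        t=tstat,
        p=p,
        p_adj=p_adj,
        tuned=tuned,
        degenerate=degen,
    )


@dataclass
class KruskalResult:
    """Per unit x phase Kruskal-Wallis word-tuning statistics."""

    unit_ids: list[str]
    phases: list[str]
    h: np.ndarray  # (n_units, n_phases)
    p: np.ndarray
    p_adj: np.ndarray
    tuned: np.ndarray

    def tuned_fraction(self) -> np.ndarray:
        return 100.0 * self.tuned.mean(axis=0)


def kruskal_wallis_tuning(
    phase_rates: PhaseRates, config: TaskConfig
) -> KruskalResult:
    """Kruskal-Wallis test of rate differences between words, per unit x phase.

    Tie-corrected H with the chi-square approximation; all-constant units
    get p = 1 by convention.  FDR adjustment is applied across units within
    each phase.
    """
    words = list(config.words)
    labels = phase_rates.labels
    _check_word_balance(labels, words)
    groups_idx = [np.nonzero((labels["word"] == w).to_numpy())[0] for w in words]
    phases = list(phase_rates.phases)
    n_units = len(phase_rates.unit_ids)
    h = np.zeros((n_units, len(phases)))
    p = np.ones((n_units, len(phases)))
    for j, phase in enumerate(phases):
        mat = phase_rates.rates[phase]
        for i in range(n_units):
            samples = [mat[idx, i] for idx in groups_idx]
            pooled = np.concatenate(samples)
            if np.allclose(pooled, pooled[0]):
                h[i, j], p[i, j] = 0.0, 1.0
                continue
            res = stats.kruskal(*samples)
            h[i, j], p[i, j] = res.statistic, res.pvalue
    p_adj = np.ones_like(p)
    for j in range(len(phases)):
        p_adj[:, j] = adjust_fdr(p[:, j])
    return KruskalResult(
        unit_ids=list(phase_rates.unit_ids),
        phases=phases,
        h=h,
        p=p,
        p_adj=p_adj,
        tuned=p_adj < ALPHA,
    )


def tuned_fraction_summary(fractions: np.ndarray, index=None) -> pd.DataFrame:
    """Mean tuned % across sessions with the Student-t 95% CI of the mean.

    ``fractions`` is (n_sessions, n_index) in percent.  The CI multiplier is
    the 97.5th percentile of Student t with n-1 degrees of freedom; with a
    single session the CI is undefined and reported as NaN.
    """
    fractions = np.atleast_2d(np.asarray(fractions, float))
    n = fractions.shape[0]
    mean = fractions.mean(axis=0)
    if n >= 2:
        sem = fractions.std(axis=0, ddof=1) / np.sqrt(n)
        mult = stats.t.ppf(0.975, n - 1)
        lo, hi = mean - mult * sem, mean + mult * sem
    else:
        lo = hi = np.full_like(mean, np.nan)
    out = pd.DataFrame(
        {
            "mean_pct_tuned": mean,
            "ci_low": lo,
            "ci_high": hi,
            "n_sessions": n,
        }
    )
    if index is not None:
        out.index = list(index)
    return out


def compare_phase_tuning(
    fractions: pd.DataFrame, pairs=DEFAULT_PHASE_PAIRS
) -> pd.DataFrame:
    """Paired two-tailed t tests of per-session values between phase pairs.

    ``fractions`` has one row per session and one column per phase.  Reports
    t, d.f. = n-1, p, paired Cohen's d (mean difference / SD of
    differences), and BH-FDR adjusted p across the tested pairs.
    """
    rows = []
    for rest, action in pairs:
        a = fractions[action].to_numpy(float)
        r = fractions[rest].to_numpy(float)
        if len(a) != len(r):
            raise SessionValidationError("phase vectors differ in length")
        diff = a - r
        n = len(diff)
        sd = diff.std(ddof=1)
        if sd == 0:
            tstat, pval, d = (0.0, 1.0, 0.0)
        else:
            tstat, pval = stats.ttest_rel(a, r)
            d = diff.mean() / sd
        rows.append(
            {
                "rest_phase": rest,
                "action_phase": action,
                "t": float(tstat),
                "df": n - 1,
                "p": float(pval),
                "cohen_d": float(d),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_fdr(out["p"].to_numpy())
    return out


def tuning_overlap(
    result_a: TuningResult,
    phase_a: str,
    result_b: TuningResult,
    phase_b: str,
) -> dict:
    """Overlap of tuned units between two phases (or two results).

    Returns the % of units tuned in A that are also tuned in B, and the %
    of units tuned in A that share at least one identical tuned word in B
    (preserved tuning).  Undefined (NaN) when no unit is tuned in A.
    """
    if result_a.unit_ids != result_b.unit_ids:
        raise SessionValidationError("unit rosters differ between results")
    ja = result_a.index.index(phase_a)
    jb = result_b.index.index(phase_b)
    tuned_a = np.nonzero(result_a.tuned[:, ja])[0]
    n_a = len(tuned_a)
    if n_a == 0:
        return {
            "n_tuned_a": 0,
            "pct_also_tuned": float("nan"),
            "pct_preserved_word": float("nan"),
        }
    also = 0
    preserved = 0
    for i in tuned_a:
        if result_b.tuned[i, jb]:
            also += 1
            wa = result_a.tuned_words(int(i), phase_a)
            wb = result_b.tuned_words(int(i), phase_b)
            if wa & wb:
                preserved += 1
    return {
        "n_tuned_a": n_a,
        "pct_also_tuned": 100.0 * also / n_a,
        "pct_preserved_word": 100.0 * preserved / n_a,
    }
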