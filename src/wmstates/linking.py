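"""Brain-behavior linking: GLMs relating decoding strength to performance.

All models are fit per subject (summary-statistics approach); group inference
on the per-subject weights is done with one-sample t tests and JZS Bayes
factors from :mod:`wmstates.inference`.  Conventions:

* RT models: ordinary least squares on the natural log of RT in ms, correct
  responded trials only.
* Accuracy models: logistic regression, all responded trials; on perfect
  separation the fit falls back to an L2-penalized fit (penalty 1e-6) with a
  warning.
* Decoding-score regressors are centered within block before entering any
  model, isolating across-trial fluctuations from sustained block-level
  differences.
* Missing responses (deadline) are excluded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from . import inference


@dataclass
class RegressionResult:
    """Per-subject weights for one model family."""

    weights: pd.DataFrame       # rows: subjects; columns: regressors
    model: str                  # 'linear_logRT' | 'logistic_accuracy' | ...
    n_per_subject: pd.Series

    def group_stats(self, column: str, tail: str = "two"):
        """Group-level t / p / d and BF10 for one regressor's weights."""
        w = self.weights[column].to_numpy()
        t, p, d = inference.summarize_t(w, tail=tail)
        bf = inference.jzs_bayes_factor(w, tail=tail)
        return {"t": t, "p": p, "d": d, "bf10": bf.bf10, "bf01": bf.bf01,
                "n": len(w)}


def normalize_within_block(scores, blocks) -> np.ndarray:
    """Subtract the block mean from each score (all trials included)."""
    scores = np.asarray(scores, dtype=float)
    blocks = np.asarray(blocks)
    out = np.empty_like(scores)
    for b in np.unique(blocks):
        m = blocks == b
        out[m] = scores[m] - scores[m].mean()
    return out


# --------------------------------------------------------------------------
# Model-fitting primitives
# --------------------------------------------------------------------------

def _check_design(X: pd.DataFrame):
    sd = X.std(axis=0)
    dead = sd[sd < 1e-12].index.tolist()
    if dead:
        raise ValueError(f"degenerate (constant) regressors: {dead}")
    cn = np.linalg.cond(((X - X.mean()) / X.std(ddof=0)).to_numpy())
    if cn > 1e4:
        warnings.warn(f"ill-conditioned design (condition number {cn:.3g})")


def _fit_logrt(trials: pd.DataFrame, X: pd.DataFrame) -> pd.Series:
    """OLS of ln RT(ms) on X, correct responded trials only."""
    ok = trials["rt_ms"].notna() & (trials["accuracy"] == 1) & X.notna().all(axis=1)
    _check_design(X.loc[ok])
    y = np.log(trials.loc[ok, "rt_ms"].to_numpy())
    res = sm.OLS(y, sm.add_constant(X.loc[ok])).fit()
    return res.params.drop("const")


def _fit_accuracy(trials: pd.DataFrame, X: pd.DataFrame) -> pd.Series:
    """Logistic regression of accuracy on X, all responded trials."""
    ok = trials["rt_ms"].notna() & X.notna().all(axis=1)
    _check_design(X.loc[ok])
    y = trials.loc[ok, "accuracy"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # escalate separation warnings
            res = sm.Logit(y, sm.add_constant(X.loc[ok])).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e3:
            raise np.linalg.LinAlgError("diverged")
        return res.params.drop("const")
    except Exception:
        warnings.warn("logistic fit failed (separation?); ridge fallback, penalty 1e-6")
        clf = LogisticRegression(penalty="l2", C=1.0 / 1e-6, solver="lbfgs",
                                 max_iter=2000)
        clf.fit(X.loc[ok].to_numpy(), y)
        return pd.Series(clf.coef_[0], index=X.columns)


def _per_subject(trials: pd.DataFrame, build_X, model: str,
                 extra: dict | None = None) -> RegressionResult:
    """Fit one model family for every subject in the table."""
    fitter = _fit_logrt if model == "linear_logRT" else _fit_accuracy
    rows, ns = {}, {}
    for subj, sub in trials.groupby("subject"):
        X = build_X(sub, **(extra or {}))
        rows[subj] = fitter(sub, X)
        ns[subj] = int(sub["rt_ms"].notna().sum())
    return RegressionResult(pd.DataFrame(rows).T, model, pd.Series(ns))


# --------------------------------------------------------------------------
# Trial-wise and block-wise decoding -> performance models
# --------------------------------------------------------------------------

def fit_trialwise_model(perf: pd.DataFrame, scores_cued, scores_uncued
                        ) -> dict[str, RegressionResult]:
    """Trial-wise decoding strength as a predictor of log-RT and accuracy.

    ``scores_*`` are per-trial spatiotemporal decoding indices aligned with
    ``perf`` rows (may span several subjects); they are centered within block
    before entering the models.  Covariates: block number and trial within
    block.  Returns {'linear_logRT': ..., 'logistic_accuracy': ...}.
    """
    perf = perf.copy()
    perf["_sc"] = np.asarray(scores_cued, dtype=float)
    perf["_su"] = np.asarray(scores_uncued, dtype=float)

    def build_X(sub):
        return pd.DataFrame({
            "score_cued": normalize_within_block(sub["_sc"], sub["block"]),
            "score_uncued": normalize_within_block(sub["_su"], sub["block"]),
            "block": sub["block"].to_numpy(dtype=float),
            "trial_in_block": sub["trial_in_block"].to_numpy(dtype=float),
        }, index=sub.index)

    return {m: _per_subject(perf, build_X, m)
            for m in ("linear_logRT", "logistic_accuracy")}


def blockwise_regressors(sub: pd.DataFrame, scores_cued, scores_uncued):
    """Leave-one-out block-average decoding strength of the test trial's item.

    For each test trial with cued item X: (i) the mean cued-item score over
    the *other* trials of the block on which X was cued, and (ii) the mean
    uncued-item score over the block's trials on which X was uncued.  Trials
    whose leave-one-out set is empty get NaN (dropped with a count warning).
    """
    sc = np.asarray(scores_cued, dtype=float)
    su = np.asarray(scores_uncued, dtype=float)
    n = len(sub)
    r_cued = np.full(n, np.nan)
    r_uncued = np.full(n, np.nan)
    pos = {idx: i for i, idx in enumerate(sub.index)}
    for _, blk in sub.groupby("block"):
        i_blk = np.array([pos[i] for i in blk.index])
        cues = blk["cue"].to_numpy()
        for j, i_test in enumerate(i_blk):
            same = cues == cues[j]
            loo = same.copy()
            loo[j] = False
            if loo.any():
                r_cued[i_test] = sc[i_blk[loo]].mean()
            if (~same).any():
                r_uncued[i_test] = su[i_blk[~same]].mean()
    return r_cued, r_uncued


def fit_blockwise_model(perf: pd.DataFrame, scores_cued, scores_uncued
                        ) -> dict[str, RegressionResult]:
    """Block-wise (leave-one-trial-out) decoding strength -> performance."""
    perf = perf.copy()
    perf["_sc"] = np.asarray(scores_cued, dtype=float)
    perf["_su"] = np.asarray(scores_uncued, dtype=float)

    dropped = 0

    def build_X(sub):
        nonlocal dropped
        r_cued, r_uncued = blockwise_regressors(sub, sub["_sc"], sub["_su"])
        bad = ~(np.isfinite(r_cued) & np.isfinite(r_uncued))
        dropped += int(bad.sum())
        X = pd.DataFrame({
            "block_cued": r_cued,
            "block_uncued": r_uncued,
            "block": sub["block"].to_numpy(dtype=float),
            "trial_in_block": sub["trial_in_block"].to_numpy(dtype=float),
        }, index=sub.index)
        return X

    out = {}
    for m in ("linear_logRT", "logistic_accuracy"):
        out[m] = _per_subject(perf, build_X, m)
    if dropped:
        warnings.warn(f"{dropped} trials had an empty leave-one-out set and were dropped")
    return out


# --------------------------------------------------------------------------
# Noise-matched cross-item control
# --------------------------------------------------------------------------

def noise_match(perf: pd.DataFrame, cross_scores, regular_scores,
                n_iter: int = 1000, seed=None):
    """Match the cross-item decoder to the regular uncued decoder in mean/SD.

    Both score vectors are mean-centered and scaled by the SD of the
    cross-item vector; Gaussian noise with
    SD = sqrt(max(0, Var(regular_scaled) - Var(cross_scaled))) is added to the
    scaled cross vector, the trial-wise model is refit, and weights are
    averaged over ``n_iter`` injections.  If the regular decoder has the
    *smaller* variance (degenerate case) the cross vector is rescaled instead,
    with a prominent warning.

    Returns (matched_example, {'linear_logRT': DataFrame, 'logistic_accuracy':
    DataFrame}) where the DataFrames hold iteration-averaged per-subject
    weights for the matched cross-item regressor.
    """
    cross = np.asarray(cross_scores, dtype=float)
    reg = np.asarray(regular_scores, dtype=float)
    if cross.shape != reg.shape:
        raise ValueError("score vectors must have equal length")
    if cross.std() < 1e-12 or reg.std() < 1e-12:
        raise ValueError("constant score vector")
    rng = np.random.default_rng(seed)

    sd_cross = cross.std()
    cross_s = (cross - cross.mean()) / sd_cross
    reg_s = (reg - reg.mean()) / sd_cross
    var_gap = reg_s.var() - cross_s.var()
    rescale = None
    if var_gap < 0:
        warnings.warn(
            "DEGENERATE NOISE MATCH: regular decoder has smaller variance than "
            "the cross-item decoder; matching by rescaling instead of noise "
            "addition")
        rescale = reg_s.std() / cross_s.std()
        noise_sd = 0.0
    else:
        noise_sd = float(np.sqrt(var_gap))

    acc_w = {"linear_logRT": [], "logistic_accuracy": []}
    example = None
    for _ in range(n_iter):
        matched = cross_s * rescale if rescale is not None else \
            cross_s + rng.normal(0.0, noise_sd, size=cross_s.shape)
        if example is None:
            example = matched
        fits = fit_trialwise_model(perf, matched, reg_s)
        for m in acc_w:
            acc_w[m].append(fits[m].weights)
    avg = {m: sum(ws) / n_iter for m, ws in acc_w.items()}
    return example, avg


# --------------------------------------------------------------------------
# Psychometric and priority-shift models
# --------------------------------------------------------------------------

def psychometric_fit(perf: pd.DataFrame, reference: str = "cued") -> pd.DataFrame:
    """Probit-link binomial GLM of P(clockwise) on the signed target distance.

    ``reference`` selects the distance to the cued or the uncued item.
    Returns a per-subject DataFrame with fitted 'slope' (per deg) and 'pse'
    (point of subjective equality, deg).
    """
    col = {"cued": "signed_delta", "uncued": "signed_delta_uncued"}[reference]
    rows = {}
    for subj, sub in perf.groupby("subject"):
        ok = sub["rt_ms"].notna()
        y = (sub.loc[ok, "choice"] == "CW").to_numpy(dtype=float)
        x = sub.loc[ok, col].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate responses: all one category")
        if x.min() >= 0 or x.max() <= 0:
            raise ValueError("signed distances must span both signs")
        X = sm.add_constant(x)
        res = sm.GLM(y, X, family=sm.families.Binomial(
            link=sm.families.links.Probit())).fit()
        b0, b1 = res.params
        rows[subj] = {"slope": b1, "pse": -b0 / b1 if abs(b1) > 1e-12 else np.nan}
    return pd.DataFrame(rows).T


def priority_shift_model(perf: pd.DataFrame) -> dict[str, RegressionResult]:
    """Time-dependent vs shift-dependent degradation within blocks.

    Regresses accuracy (logistic) and log-RT (linear) on the trial number
    within the block and the cue-sequence index.  Group tests are one-tailed
    in the degradation direction (negative accuracy weights, positive RT
    weights), via :meth:`RegressionResult.group_stats`.
    """

    def build_X(sub):
        X = pd.DataFrame({
            "trial_in_block": sub["trial_in_block"].to_numpy(dtype=float),
            "cue_sequence": sub["cue_sequence"].to_numpy(dtype=float),
        }, index=sub.index)
        r = np.corrcoef(X["trial_in_block"], X["cue_sequence"])[0, 1]
        if abs(r) > 0.999:
            warnings.warn("trial_in_block and cue_sequence are collinear")
        return X

    return {m: _per_subject(perf, build_X, m)
            for m in ("linear_logRT", "logistic_accuracy")}


def cardinal_bias_model(perf: pd.DataFrame, by_cue_sequence: bool = True,
                        max_sequence: int = 4):
    """Accuracy as a function of the cued item's cardinal distance.

    When ``by_cue_sequence`` the model is fit separately for cue sequences
    1..4 (trials from later sequences ignored; empty subject x sequence cells
    dropped with a warning).  Returns {sequence: RegressionResult}; with
    ``by_cue_sequence=False`` a single RegressionResult.
    """

    def build_X(sub):
        return pd.DataFrame(
            {"cardinal_distance": sub["cardinal_distance"].to_numpy(dtype=float)},
            index=sub.index)

    if not by_cue_sequence:
        return _per_subject(perf, build_X, "logistic_accuracy")

    out = {}
    for q in range(1, max_sequence + 1):
        sub = perf[perf["cue_sequence"] == q]
        counts = sub.groupby("subject").size()
        keep = counts[counts >= 16].index
        if len(keep) < perf["subject"].nunique():
            warnings.warn(
                f"cue sequence {q}: dropping "
                f"{perf['subject'].nunique() - len(keep)} subjects with sparse cells")
        out[q] = _per_subject(sub[sub["subject"].isin(keep)], build_X,
                              "logistic_accuracy")
    return out
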