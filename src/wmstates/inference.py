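"""Group-level statistics: cluster-based permutation tests over time,
one-sample t summaries with effect sizes, and JZS (Cauchy-prior) Bayes factors.

The cluster test corrects for multiple comparisons across timepoints in the
standard nonparametric way: pointwise one-sample t statistics against zero,
contiguous supra-threshold runs scored by their summed t (cluster mass), and a
null distribution of maximum cluster masses built from random subject-wise
sign flips.  The Bayes factors are the default JZS one-sample test: marginal
likelihood under a Cauchy prior (scale sqrt(2)/2) on the standardized effect,
integrated numerically; one-tailed variants truncate the prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats


@dataclass
class ClusterResult:
    clusters: list                  # (start_idx, end_idx_inclusive, mass, corrected_p)
    threshold_p: float
    n_perm: int
    t_series: np.ndarray
    times: np.ndarray | None = None

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c[3] <= alpha]


@dataclass
class BayesResult:
    bf10: float
    prior_scale: float
    tail: str

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


# --------------------------------------------------------------------------
# Frequentist summaries
# --------------------------------------------------------------------------

def summarize_t(values, tail: str = "two", mu0: float = 0.0):
    """One-sample t test with Cohen's d.

    ``tail``: 'two', 'greater' or 'less'.  Returns (t, p, d) where
    d = (mean - mu0) / SD.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input")
    t = (x.mean() - mu0) / (sd / np.sqrt(len(x)))
    df = len(x) - 1
    if tail == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    return float(t), float(p), float((x.mean() - mu0) / sd)


# --------------------------------------------------------------------------
# Cluster-based permutation testing
# --------------------------------------------------------------------------

def _t_series(x: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t against 0; x is subjects x timepoints."""
    n = x.shape[0]
    m = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, m / se, 0.0)
    return t


def _clusters_from_t(t: np.ndarray, crit: float):
    """Signed supra-threshold runs: list of (start, stop_inclusive, mass)."""
    supra = np.abs(t) > crit
    out = []
    i = 0
    n = len(t)
    while i < n:
        if supra[i]:
            s = np.sign(t[i])
            j = i
            while j + 1 < n and supra[j + 1] and np.sign(t[j + 1]) == s:
                j += 1
            out.append((i, j, float(t[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def cluster_permutation_test(subject_series, n_perm: int = 10000,
                             alpha: float = 0.05, cluster_alpha: float = 0.05,
                             seed=None, times=None) -> ClusterResult:
    """One-sample cluster permutation test across time.

    ``subject_series``: subjects x timepoints.  Cluster-forming threshold is
    the two-tailed pointwise |t| criterion at ``cluster_alpha``; clusters are
    scored by summed t and corrected against the permutation distribution of
    the maximum absolute cluster mass under random subject sign flips.
    Corrected p values use the add-one permutation convention, so they lie in
    (0, 1].
    """
    x = np.asarray(subject_series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5:
        raise ValueError("need subjects x timepoints with at least 5 subjects")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives unstable p values")
    n_sub, n_t = x.shape
    crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, n_sub - 1)

    t_obs = _t_series(x)
    clusters = _clusters_from_t(t_obs, crit)

    rng = np.random.default_rng(seed)
    max_mass = np.zeros(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_sub)
        t_perm = _t_series(x * flips[:, None])
        cl = _clusters_from_t(t_perm, crit)
        if cl:
            max_mass[p] = max(abs(c[2]) for c in cl)

    out = []
    for (i, j, mass) in clusters:
        p_corr = (1 + np.sum(max_mass >= abs(mass))) / (n_perm + 1)
        out.append((i, j, mass, float(p_corr)))
    return ClusterResult(out, cluster_alpha, n_perm, t_obs,
                         None if times is None else np.asarray(times))


# --------------------------------------------------------------------------
# JZS Bayes factors
# --------------------------------------------------------------------------

DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0


def jzs_bf_from_t(t: float, n: int, tail: str = "two",
                  prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS Bayes factor (BF10) for a one-sample t statistic.

    Marginal likelihood of t under H1 integrates the noncentral-t likelihood
    over a Cauchy prior on the standardized effect delta (noncentrality
    delta * sqrt(n)); H0 is the central t.  One-tailed versions ('greater' /
    'less') use the prior truncated to the corresponding half line.
    """
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(
            delta, scale=prior_scale)

    if tail == "two":
        num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    elif tail == "greater":
        num, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        num *= 2.0
    elif tail == "less":
        num, _ = integrate.quad(integrand, -np.inf, 0.0, limit=200)
        num *= 2.0
    else:
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    den = stats.t.pdf(t, df)
    return float(num / den)


def jzs_bayes_factor(values, mu0: float = 0.0, tail: str = "two",
                     prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesResult:
    """Bayesian one-sample t test (JZS default prior) on per-subject values."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if x.std(ddof=1) == 0:
        raise ValueError("zero-variance input")
    t, _, _ = summarize_t(x, tail="two", mu0=mu0)
    return BayesResult(jzs_bf_from_t(t, len(x), tail, prior_scale),
                       prior_scale, tail)


def sequential_bf(values, mu0: float = 0.0, tail: str = "two",
                  prior_scale: float = DEFAULT_PRIOR_SCALE) -> np.ndarray:
    """BF10 trajectory over the first k subjects, k = 3 ... n."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    return np.array([
        jzs_bayes_factor(x[:k], mu0, tail, prior_scale).bf10
        for k in range(3, len(x) + 1)
    ])
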