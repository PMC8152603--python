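"""Drift-diffusion model: simulation, first-passage likelihood, regression fit.

The decision model is the two-boundary Wiener diffusion: evidence x(t) starts
at z*a (relative start point z in (0,1), fixed at 0.5 here), drifts at rate v
with unit diffusion coefficient, and a response is emitted when x hits 0
(counterclockwise) or a (clockwise); observed RT = decision time + non-decision
time t0.

The regression fit links a per-trial neural regressor (block-centered decoding
strength) to either the drift rate or the non-decision time through a
single-level Bayesian model sampled by random-walk Metropolis: 5000 draws per
chain with the first 1000 discarded as burn-in, weakly-informative priors
(a ~ N(1.5, 1) truncated > 0.3; t0 ~ N(0.4, 0.3^2) truncated > 0.05 s; drift
terms and the coupling slope ~ N(0, 5^2)).  Evidence for a coupling is read
off the posterior as the fraction of mass on one side of zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class DDMParams:
    """Parameters of a single diffusion process (sigma fixed at 1)."""

    a: float            # boundary separation
    v: float            # drift rate (evidence units / s)
    t0_s: float         # non-decision time (s)
    z: float = 0.5      # relative start point

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("boundary separation must be positive")
        if self.t0_s < 0:
            raise ValueError("non-decision time must be non-negative")
        if not (0.0 < self.z < 1.0):
            raise ValueError("relative start point must lie in (0, 1)")


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def simulate_paths(a: float, v, z: float, n: int, rng: np.random.Generator,
                   dt_s: float = 0.0005, max_t_s: float = 20.0):
    """Euler-Maruyama first-passage sampling for n trials.

    ``v`` may be a scalar or per-trial array.  Returns (decision_time_s,
    hit_upper).  Paths not absorbed within ``max_t_s`` are resampled (counted
    with a warning); with sane parameters this never triggers.

    Discrete-time crossing tests miss excursions between steps, which inflates
    first-passage times by an O(sqrt(dt)) boundary widening; the standard
    continuity correction (Broadie-Glasserman-Kou) shrinks each boundary by
    0.5826 * sigma * sqrt(dt) to cancel the leading-order bias.
    """
    v = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
    dt_sqrt = np.sqrt(dt_s)
    bgk = 0.5826 * dt_sqrt        # continuity correction, sigma = 1
    hi, lo = a - bgk, bgk
    max_steps = int(np.ceil(max_t_s / dt_s))
    dec_t = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    pending = np.arange(n)
    n_resampled = 0
    while pending.size:
        x = np.full(pending.size, z * a)
        alive = np.ones(pending.size, dtype=bool)
        for step in range(1, max_steps + 1):
            idx = np.nonzero(alive)[0]
            if idx.size == 0:
                break
            x[idx] += v[pending[idx]] * dt_s + dt_sqrt * rng.standard_normal(idx.size)
            hit_up = x[idx] >= hi
            hit_lo = x[idx] <= lo
            done = hit_up | hit_lo
            if done.any():
                d = idx[done]
                dec_t[pending[d]] = step * dt_s
                upper[pending[d]] = hit_up[done]
                alive[d] = False
        still = np.nonzero(alive)[0]
        n_resampled += still.size
        pending = pending[still]
    if n_resampled:
        warnings.warn(f"{n_resampled} paths not absorbed within {max_t_s}s; resampled")
    return dec_t, upper


def simulate_ddm(params: DDMParams, n: int, seed=None, dt_s: float = 0.0005):
    """Simulate n trials; returns (rt_s, hit_upper)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dec_t, upper = simulate_paths(params.a, params.v, params.z, n, rng, dt_s)
    return dec_t + params.t0_s, upper


def absorption_probability_upper(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    a, v, w = params.a, params.v, params.z * params.a
    if abs(v) < 1e-12:
        return w / a
    return float(np.expm1(-2.0 * v * w) / np.expm1(-2.0 * v * a))


# --------------------------------------------------------------------------
# Wiener first-passage density (small-time / large-time series)
# --------------------------------------------------------------------------

def _fpt_lower_std(t, w, k_small: int = 7, k_large: int = 7):
    """Standard (a=1, v=0) lower-boundary first-passage density at scaled time t.

    Automatic switching between the small-time and large-time series at the
    point where they need equally many terms; both are truncated at a fixed
    term count that keeps the error far below 1e-10 over t in [1e-3, 20] for
    the switch rule used (small-time for t < 0.35).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    ts = t[pos]
    small = ts < 0.35
    if small.any():
        tt = ts[small]
        ks = np.arange(-k_small, k_small + 1)
        nodes = w + 2.0 * ks[:, None]
        out_pos_small = (nodes * np.exp(-nodes ** 2 / (2.0 * tt))).sum(axis=0)
        out_pos_small /= _SQRT_2PI * tt ** 1.5
    if (~small).any():
        tt = ts[~small]
        ks = np.arange(1, k_large + 1)
        out_pos_large = np.pi * (
            ks[:, None] * np.exp(-(ks[:, None] ** 2) * np.pi ** 2 * tt / 2.0)
            * np.sin(ks[:, None] * np.pi * w)
        ).sum(axis=0)
    res = np.empty_like(ts)
    if small.any():
        res[small] = out_pos_small
    if (~small).any():
        res[~small] = out_pos_large
    out[pos] = np.maximum(res, 0.0)
    return out


def wiener_density(t_s, params: DDMParams, boundary: str):
    """First-passage density of the Wiener process at the given boundary.

    ``boundary`` is 'upper' (clockwise) or 'lower'.  Density is 0 for
    t_s <= t0_s.  Stable for decision times between about 1 ms and 20 s.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t = np.asarray(t_s, dtype=float) - params.t0_s
    a, v, w = params.a, params.v, params.z
    if boundary == "upper":
        v, w = -v, 1.0 - w
    tau = np.where(t > 0, t, np.nan) / a ** 2
    dens = (1.0 / a ** 2) * np.exp(-v * a * w - v ** 2 * np.where(t > 0, t, 0.0) / 2.0)
    dens = dens * _fpt_lower_std(np.nan_to_num(tau, nan=0.0), w)
    return np.where(t > 0, dens, 0.0)


def wiener_log_density(t_dec, a, v, w, eps: float = 1e-300):
    """Vectorized log first-passage density at the *lower* boundary.

    ``t_dec`` is the decision time (already t0-subtracted), ``v``/``w`` may be
    per-trial arrays.  Used by the likelihood; responses at the upper boundary
    are handled by the caller through the (v, w) -> (-v, 1-w) reflection.
    """
    t_dec = np.asarray(t_dec, dtype=float)
    tau = t_dec / a ** 2
    f = _fpt_lower_std(tau, w) if np.isscalar(w) else _fpt_lower_std_vec(tau, w)
    logf = np.log(np.maximum(f, eps)) - 2.0 * np.log(a)
    return logf - v * a * w - v ** 2 * t_dec / 2.0


def _fpt_lower_std_vec(t, w, k_small: int = 7, k_large: int = 7):
    """As _fpt_lower_std but with per-element start point w (array)."""
    t = np.asarray(t, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), t.shape)
    out = np.zeros_like(t)
    pos = t > 0
    ts, ws = t[pos], w[pos]
    small = ts < 0.35
    res = np.empty_like(ts)
    if small.any():
        tt, ww = ts[small], ws[small]
        ks = np.arange(-k_small, k_small + 1)
        nodes = ww + 2.0 * ks[:, None]
        res[small] = (nodes * np.exp(-nodes ** 2 / (2.0 * tt))).sum(axis=0) / (
            _SQRT_2PI * tt ** 1.5)
    if (~small).any():
        tt, ww = ts[~small], ws[~small]
        ks = np.arange(1, k_large + 1)
        res[~small] = np.pi * (
            ks[:, None] * np.exp(-(ks[:, None] ** 2) * np.pi ** 2 * tt / 2.0)
            * np.sin(ks[:, None] * np.pi * ww)
        ).sum(axis=0)
    out[pos] = np.maximum(res, 0.0)
    return out


# --------------------------------------------------------------------------
# Bayesian regression DDM (random-walk Metropolis)
# --------------------------------------------------------------------------

PARAM_NAMES = ("a", "t0_s", "v_intercept", "v_slope", "beta")


@dataclass
class RegressionDDMFit:
    """Posterior draws of the regression diffusion model for one subject."""

    samples: pd.DataFrame       # retained draws, columns PARAM_NAMES
    target_param: str           # 'drift' or 'ndt'
    acceptance_rate: float
    n_samples: int = 5000
    n_burn: int = 1000


def _log_prior(theta) -> float:
    a, t0, v0, v1, beta = theta
    if a <= 0.3 or t0 <= 0.05:
        return -np.inf
    lp = -0.5 * ((a - 1.5) / 1.0) ** 2
    lp += -0.5 * ((t0 - 0.4) / 0.3) ** 2
    lp += -0.5 * (v0 / 5.0) ** 2 - 0.5 * (v1 / 5.0) ** 2 - 0.5 * (beta / 5.0) ** 2
    return lp


def _make_loglik(rt_s, upper, dv, side, scores, target_param):
    """Build the vectorized log-likelihood over trials."""

    def loglik(theta):
        a, t0, v0, v1, beta = theta
        drift_mag = v0 + v1 * dv
        if target_param == "drift":
            drift_mag = drift_mag + beta * scores
            t0_trial = t0
        else:
            t0_trial = t0 + beta * scores
        v = side * drift_mag
        t_dec = rt_s - t0_trial
        if np.any(t_dec <= 1e-4):
            return -np.inf
        # reflection: density of the observed response boundary; z = 0.5 is
        # reflection-symmetric so only the drift sign flips
        v_eff = np.where(upper, -v, v)
        ll = wiener_log_density(t_dec, a, v_eff, 0.5)
        return float(ll.sum())

    return loglik


def fit_regression_ddm(behavior: pd.DataFrame, regressor, target_param: str,
                       seed=None, n_samples: int = 5000, n_burn: int = 1000,
                       progress: bool = False) -> RegressionDDMFit:
    """Fit the regression DDM to one subject's responded trials.

    ``behavior`` must provide rt_ms, choice ('CW'/'CCW'), dv_cued and
    signed_delta; ``regressor`` is the per-trial (block-centered) decoding
    strength.  ``target_param`` selects whether the regressor modulates the
    drift rate ('drift') or the non-decision time ('ndt').  Returns the
    retained posterior draws (n_samples - n_burn rows).
    """
    if target_param not in ("drift", "ndt"):
        raise ValueError("target_param must be 'drift' or 'ndt'")
    scores = np.asarray(regressor, dtype=float)
    ok = behavior["rt_ms"].notna().to_numpy() & np.isfinite(scores)
    beh = behavior.loc[ok]
    scores = scores[ok]
    if len(beh) < 200:
        raise ValueError("need at least 200 responded trials for a stable fit")

    rt_s = beh["rt_ms"].to_numpy() / 1000.0
    upper = (beh["choice"].to_numpy() == "CW")
    dv = beh["dv_cued"].to_numpy()
    side = np.sign(beh["signed_delta"].to_numpy())
    loglik = _make_loglik(rt_s, upper, dv, side, scores, target_param)

    rng = np.random.default_rng(seed)
    theta = np.array([1.5, max(0.06, 0.8 * rt_s.min()), 0.3, 0.02, 0.0])
    scale = np.array([0.05, 0.01, 0.08, 0.004, 0.05])
    lp = _log_prior(theta) + loglik(theta)

    # Adaptive random-walk Metropolis: diagonal scale tuning in the first half
    # of burn-in, then a covariance-matched multivariate proposal (2.38^2/d)
    # learned from the second half.  Adaptation stops at the end of burn-in so
    # the retained chain is Markov.
    draws = np.empty((n_samples, 5))
    accepted = 0
    adapt_every = 50
    acc_window = 0
    half_burn = n_burn // 2
    prop_chol = None
    for i in range(n_samples):
        if prop_chol is None:
            prop = theta + scale * rng.standard_normal(5)
        else:
            prop = theta + prop_chol @ rng.standard_normal(5)
        lp_prop = _log_prior(prop)
        if np.isfinite(lp_prop):
            lp_prop += loglik(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
            acc_window += 1
        draws[i] = theta
        if i < n_burn and (i + 1) % adapt_every == 0:
            rate = acc_window / adapt_every
            scale *= np.exp(np.clip(rate - 0.28, -0.7, 0.7) * 2.0)
            acc_window = 0
        if i + 1 == n_burn:
            cov = np.cov(draws[half_burn:n_burn].T)
            cov = cov + 1e-10 * np.eye(5) + 1e-4 * np.diag(scale ** 2)
            prop_chol = np.linalg.cholesky((2.38 ** 2 / 5.0) * cov)
            accepted = 0
    rate = accepted / (n_samples - n_burn)
    if not (0.1 <= rate <= 0.6):
        warnings.warn(f"Metropolis acceptance rate {rate:.2f} outside [0.1, 0.6]")
    kept = pd.DataFrame(draws[n_burn:], columns=list(PARAM_NAMES))
    return RegressionDDMFit(kept, target_param, rate, n_samples, n_burn)


def posterior_direction_mass(samples, direction: str = "positive") -> float:
    """Fraction of posterior draws with the stated sign."""
    s = np.asarray(samples, dtype=float)
    if s.size < 100:
        raise ValueError("need at least 100 retained draws")
    if direction == "positive":
        return float(np.mean(s > 0))
    if direction == "negative":
        return float(np.mean(s < 0))
    raise ValueError("direction must be 'positive' or 'negative'")


def gelman_rubin(chains) -> float:
    """Split-free Gelman-Rubin R-hat over a list of 1-D chains."""
    chains = [np.asarray(c, dtype=float) for c in chains]
    m = len(chains)
    n = min(len(c) for c in chains)
    if m < 2:
        raise ValueError("need at least 2 chains")
    x = np.stack([c[:n] for c in chains])
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))
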