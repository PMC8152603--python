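"""Synthetic task design, EEG epochs, and diffusion-coupled behavior.

Emulates a blocked two-item orientation working-memory task with auditory
retro-cues: on each block two orientations are memorized; on each trial a cue
designates one of them ("cued" item) as the decision boundary for a clockwise /
counterclockwise judgement of a probe grating, while the other ("uncued") item
is retained for later trials.

The EEG generator plants the statistical structure the downstream decoding
analyses assume:

* an *active* code for the cued item — sustained from shortly after the cue to
  the end of the epoch, magnified by a target-evoked transient;
* a *latent* code for the uncued item — expressed only in a target-evoked
  transient (100-500 ms post-target), not in delay activity;
* a target-orientation code and a ramping decision-variable code after target
  onset;
* trial-wise lognormal encoding-gain fluctuations per item; and
* spatially correlated, temporally autocorrelated Gaussian sensor noise.

Behavior is sampled from a two-boundary diffusion process whose drift rate (or
non-decision time, depending on the coupling mode) is modulated by the same
trial-wise encoding gain that scales the planted neural code, so that
decoding -> behavior regressions have a known ground truth.

Orientation convention: 0 deg = vertical; all orientations are 180 deg
periodic. The convention is irrelevant to every computation by symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ddm as _ddm

# --------------------------------------------------------------------------
# Orientation grids and angular helpers
# --------------------------------------------------------------------------

GRID_STEP_DEG = 11.25
N_ORIENTATIONS = 16
ITEM_GRID_START_DEG = 2.8125
TARGET_GRID_START_DEG = 8.4375

#: Decision-variable support implied by the two grids (8 evenly spaced levels).
DV_LEVELS_DEG = np.arange(5.625, 90.0, GRID_STEP_DEG)


@dataclass(frozen=True)
class OrientationGrid:
    """16 orientations in [0, 180) deg, evenly spaced at 11.25 deg."""

    values: np.ndarray
    step: float = GRID_STEP_DEG

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_ORIENTATIONS,):
            raise ValueError("an orientation grid has exactly 16 values")
        if not np.allclose(np.diff(v), self.step):
            raise ValueError("grid spacing must be uniform at 11.25 deg")
        object.__setattr__(self, "values", v)

    def index_of(self, theta) -> np.ndarray:
        """Map orientations (deg) to their grid indices; raises if off-grid."""
        theta = np.asarray(theta, dtype=float)
        idx = np.rint((theta - self.values[0]) / self.step).astype(int) % N_ORIENTATIONS
        if not np.allclose(self.values[idx], theta % 180.0, atol=1e-9):
            raise ValueError("orientation not on this grid")
        return idx


def build_orientation_grids() -> tuple[OrientationGrid, OrientationGrid]:
    """Return the (memory-item, target) orientation grids.

    Items are drawn from 2.8125-171.5625 deg and targets from
    8.4375-177.1875 deg, both at 11.25 deg spacing.  The 5.625 deg offset
    between the two grids guarantees that the item-target angular distance can
    never be 0 or 90 deg, and makes the decision variable live on the 8-level
    grid 5.625 ... 84.375 deg.
    """
    item = OrientationGrid(ITEM_GRID_START_DEG + GRID_STEP_DEG * np.arange(N_ORIENTATIONS))
    target = OrientationGrid(TARGET_GRID_START_DEG + GRID_STEP_DEG * np.arange(N_ORIENTATIONS))
    return item, target


def signed_angle_180(a, b):
    """Signed orientation difference a - b folded into (-90, 90] deg."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.where(d > 90.0, d - 180.0, d)


def acute_distance(a, b):
    """Acute (unsigned) angular distance between two orientations, in [0, 90]."""
    return np.abs(signed_angle_180(a, b))


def decision_variable(theta_item, theta_target):
    """Acute angular distance (deg) between a memory item and the target.

    Both arguments must be orientations in [0, 180).  On the printed stimulus
    grids the result lies on the 8-level support {5.625, ..., 84.375} deg.
    """
    ti = np.asarray(theta_item, dtype=float)
    tt = np.asarray(theta_target, dtype=float)
    if np.any((ti < 0) | (ti >= 180)) or np.any((tt < 0) | (tt >= 180)):
        raise ValueError("orientations must lie in [0, 180) deg")
    return acute_distance(ti, tt)


def cardinal_distance(theta):
    """Angular distance (deg, in [0, 45]) to the nearest cardinal axis.

    The cardinal axes are the vertical (0 deg) and horizontal (90 deg)
    orientations; distance is computed under 180 deg periodicity.
    """
    theta = np.asarray(theta, dtype=float)
    return np.minimum(acute_distance(theta, 0.0), acute_distance(theta, 90.0))


def sample_item_pair(grid: OrientationGrid, rng: np.random.Generator):
    """Draw two distinct grid orientations that are neither identical nor
    exactly orthogonal (rejection sampling; 16 x 14 ordered pairs admissible).
    """
    while True:
        a, b = rng.choice(grid.values, size=2, replace=True)
        d = acute_distance(a, b)
        if 1e-9 < d < 90.0 - 1e-9:
            return float(a), float(b)


# --------------------------------------------------------------------------
# Intertrial-interval sampler
# --------------------------------------------------------------------------

def _truncexp_mean(rate: float, lo: float, hi: float) -> float:
    span = hi - lo
    x = rate * span
    # mean of Exp(rate) truncated to [0, span], shifted by lo
    return lo + 1.0 / rate - span * np.exp(-x) / (1.0 - np.exp(-x))


def solve_iti_rate(mean_ms: float, lo_ms: float = 400.0, hi_ms: float = 900.0) -> float:
    """Rate (1/ms) of an exponential truncated to [lo, hi] with the given mean.

    Solved by bisection to 1e-9 ms.  Achievable means lie strictly between
    lo and the midpoint (lo+hi)/2; anything else raises.
    """
    mid = 0.5 * (lo_ms + hi_ms)
    if not (lo_ms < mean_ms < mid):
        raise ValueError(
            f"truncated-exponential mean must lie in ({lo_ms}, {mid}) ms, got {mean_ms}"
        )
    r_lo, r_hi = 1e-12, 1.0  # 1/ms; mean is decreasing in rate
    while _truncexp_mean(r_hi, lo_ms, hi_ms) > mean_ms:
        r_hi *= 2.0
    for _ in range(200):
        r = 0.5 * (r_lo + r_hi)
        m = _truncexp_mean(r, lo_ms, hi_ms)
        if m > mean_ms:
            r_lo = r
        else:
            r_hi = r
        if abs(m - mean_ms) < 1e-9:
            break
    return r


def sample_iti(n: int, rng: np.random.Generator, mean_ms: float = 550.0,
               lo_ms: float = 400.0, hi_ms: float = 900.0) -> np.ndarray:
    """Sample intertrial intervals (ms) from the truncated exponential."""
    rate = solve_iti_rate(mean_ms, lo_ms, hi_ms)
    span = hi_ms - lo_ms
    u = rng.uniform(size=n)
    # inverse CDF of Exp(rate) truncated to [0, span]
    return lo_ms - np.log1p(-u * (1.0 - np.exp(-rate * span))) / rate


# --------------------------------------------------------------------------
# Session / trial-table generation
# --------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Task-design parameters for one recording session."""

    n_blocks: int = 128
    trials_per_block: int = 16
    p_switch: float = 0.5          # P(cue differs from previous trial); first cue fair coin
    iti_mean_ms: float = 550.0
    iti_min_ms: float = 400.0
    iti_max_ms: float = 900.0


def generate_session(config: SessionConfig | None = None, seed=None,
                     subject: int = 0) -> pd.DataFrame:
    """Generate the design columns of a session trial table.

    Per block, one item pair is drawn (never identical or orthogonal) and held
    fixed; the cue is drawn per trial as a Markov chain with switch probability
    ``config.p_switch``.  Returns one row per trial with columns:

    subject, block, trial_in_block, cue ('A'/'B'), theta_cued, theta_uncued,
    theta_target, dv_cued, dv_uncued, signed_delta (target relative to cued
    item, deg in (-90, 90]), signed_delta_uncued, is_switch (NaN on the first
    trial of a block), cue_sequence (1-based count of priority phases),
    cardinal_distance (of the cued item), iti_ms.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(seed)
    item_grid, target_grid = build_orientation_grids()

    # Balanced coverage: item A cycles through shuffled copies of the grid so
    # every orientation recurs as a memory item; the partner is drawn by
    # rejection.  Keeps the relative-orientation bins of the leave-one-block-
    # out decoder populated at desk-scale block counts.
    n_rep = int(np.ceil(config.n_blocks / N_ORIENTATIONS))
    theta_a_seq = np.concatenate(
        [rng.permutation(item_grid.values) for _ in range(n_rep)])[: config.n_blocks]

    rows = []
    for block in range(1, config.n_blocks + 1):
        theta_a = float(theta_a_seq[block - 1])
        while True:
            theta_b = float(rng.choice(item_grid.values))
            d = acute_distance(theta_a, theta_b)
            if 1e-9 < d < 90.0 - 1e-9:
                break
        cue_prev = None
        cue_seq = 0
        for t in range(1, config.trials_per_block + 1):
            if cue_prev is None:
                cue = "A" if rng.uniform() < 0.5 else "B"
                is_switch = np.nan
                cue_seq = 1
            else:
                switch = rng.uniform() < config.p_switch
                cue = ({"A": "B", "B": "A"}[cue_prev]) if switch else cue_prev
                is_switch = float(switch)
                cue_seq += int(switch)
            cue_prev = cue
            theta_cued = theta_a if cue == "A" else theta_b
            theta_uncued = theta_b if cue == "A" else theta_a
            theta_target = float(rng.choice(target_grid.values))
            rows.append(
                dict(
                    subject=subject,
                    block=block,
                    trial_in_block=t,
                    cue=cue,
                    theta_cued=theta_cued,
                    theta_uncued=theta_uncued,
                    theta_target=theta_target,
                    dv_cued=float(decision_variable(theta_cued, theta_target)),
                    dv_uncued=float(decision_variable(theta_uncued, theta_target)),
                    signed_delta=float(signed_angle_180(theta_target, theta_cued)),
                    signed_delta_uncued=float(signed_angle_180(theta_target, theta_uncued)),
                    is_switch=is_switch,
                    cue_sequence=cue_seq,
                    cardinal_distance=float(cardinal_distance(theta_cued)),
                )
            )
    table = pd.DataFrame(rows)
    table["iti_ms"] = sample_iti(len(table), rng, config.iti_mean_ms,
                                 config.iti_min_ms, config.iti_max_ms)
    return table


def cue_sequence_from_cues(cues) -> np.ndarray:
    """1-based run index of a cue sequence, e.g. A,A,B,B,B,A -> 1,1,2,2,2,3."""
    cues = np.asarray(cues)
    if len(cues) == 0:
        return np.array([], dtype=int)
    return 1 + np.concatenate([[0], np.cumsum(cues[1:] != cues[:-1])])


# --------------------------------------------------------------------------
# Epochs container and the generative EEG model
# --------------------------------------------------------------------------

#: Posterior channel subset used by the decoding analyses of the source study.
POSTERIOR_17 = ["P7", "P5", "P3", "P1", "P2", "P4", "P6", "P8",
                "PO7", "PO5", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2"]

CUE_ONSET_MS = 0.0
CUE_DURATION_MS = 100.0
DELAY_MS = 700.0
TARGET_ONSET_MS = CUE_DURATION_MS + DELAY_MS   # 800 ms post-cue
EPOCH_START_MS = -200.0
EPOCH_END_MS = TARGET_ONSET_MS + 1800.0        # 2600 ms post-cue
SAMPLE_STEP_MS = 4.0                            # 250 Hz
BASELINE_WINDOW_MS = (-200.0, -50.0)


@dataclass
class EpochsArray:
    """Trials x channels x samples voltage container (arbitrary units)."""

    data: np.ndarray
    time_ms: np.ndarray
    channel_labels: list[str]
    target_onset_ms: float = TARGET_ONSET_MS
    sampling_rate_hz: float = 250.0

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels must match data axis 1")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("time_ms must match data axis 2")
        steps = np.diff(self.time_ms)
        if not np.allclose(steps, steps[0]):
            raise ValueError("sampling must be uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, lo_ms: float, hi_ms: float, half_open: bool = False):
        if half_open:
            return (self.time_ms >= lo_ms) & (self.time_ms < hi_ms)
        return (self.time_ms >= lo_ms) & (self.time_ms <= hi_ms)

    def pick(self, channels: list[str]) -> "EpochsArray":
        idx = [self.channel_labels.index(c) for c in channels]
        return EpochsArray(self.data[:, idx, :], self.time_ms, list(channels),
                          self.target_onset_ms, self.sampling_rate_hz)


def default_time_axis() -> np.ndarray:
    return np.arange(EPOCH_START_MS, EPOCH_END_MS + SAMPLE_STEP_MS / 2, SAMPLE_STEP_MS)


def _random_spd(n: int, rng: np.random.Generator, cond: float = 50.0) -> np.ndarray:
    """Random SPD matrix with condition number <= cond and unit mean variance."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    eigs = np.exp(rng.uniform(0.0, np.log(cond), size=n))
    cov = (q * eigs) @ q.T
    cov = 0.5 * (cov + cov.T)
    return cov / np.mean(np.diag(cov))


def _raised_cosine(time_ms: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Unit-peak raised-cosine bump supported on [lo, hi] ms."""
    env = np.zeros_like(time_ms)
    m = (time_ms >= lo) & (time_ms <= hi)
    env[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (time_ms[m] - lo) / (hi - lo)))
    return env


def _smooth_step(time_ms: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """0 before lo, 1 after hi, half-cosine ramp in between."""
    env = np.zeros_like(time_ms)
    env[time_ms >= hi] = 1.0
    m = (time_ms >= lo) & (time_ms < hi)
    env[m] = 0.5 * (1.0 - np.cos(np.pi * (time_ms[m] - lo) / (hi - lo)))
    return env


@dataclass
class GenerativeModel:
    """Forward model mapping the trial table to multichannel epochs.

    Each planted component is (spatial pattern) x (temporal envelope) x
    (per-trial amplitude).  Orientation patterns are ``tuning_map @ (cos 2th,
    sin 2th)``; with orthonormal tuning-map columns every orientation pattern
    has unit norm, so the amplitudes below are in noise-SD units.

    Component windows (ms relative to cue onset; target at +800):

    * active (cued item): sustained from 200 ms post-cue to epoch end, with a
      target-evoked magnification bump 900-1300 ms so the code has temporal
      structure inside the spatiotemporal decoding window; expressed in the
      *active* tuning map;
    * latent (uncued item): transient bump 900-1300 ms (100-500 ms
      post-target) only, expressed in its own *latent* tuning map (independent
      of the active format unless ``shared_item_format``);
    * lingering reactivation (uncued item, switch trials only): transient bump
      in the *active* tuning map at the uncued orientation, with its own gain
      -- the previously acted-upon item's decision code that has not yet been
      cleared.  This is the component the cross-item decoder reads out, and
      the one that carries behavioral interference;
    * target orientation: transient bump from 870 ms (70 ms post-target), in
      an independent target map (evoked visual response, distinct from the
      memory codes so that target-evoked activity does not masquerade as
      memory decoding);
    * decision variable: linear ramp from 1050 ms (250 ms post-target),
      amplitude proportional to the centered decision variable.
    """

    n_channels: int = 20
    n_eye_channels: int = 2
    amp_active: float = 0.8
    amp_latent: float = 0.7
    amp_linger: float = 0.25
    amp_target: float = 1.0
    amp_dv: float = 0.7
    active_magnification: float = 1.0   # bump multiplier on the active code
    shared_item_format: bool = False    # latent code reuses the active map
    gain_sigma_log: float = 0.3         # lognormal, median 1
    linger_sigma_log: float = 1.2       # heavy-tailed linger gain, mean 1
    ar1: float = 0.8
    noise_scale: float = 1.0
    noise_cond: float = 50.0
    coupling_mode: str = "matched_filter"  # {matched_filter, head_start, none}
    tuning_map: np.ndarray | None = None       # channels x 2, orthonormal cols
    tuning_map_uncued: np.ndarray | None = None
    tuning_map_target: np.ndarray | None = None
    dv_pattern: np.ndarray | None = None       # channels, unit norm
    noise_cov: np.ndarray | None = None        # channels x channels SPD

    def materialize(self, rng: np.random.Generator) -> "GenerativeModel":
        """Fill in any unset random structure (tuning maps, noise covariance)."""
        c = self.n_channels
        out = replace(self)
        if out.tuning_map is None:
            out.tuning_map = np.linalg.qr(rng.standard_normal((c, 2)))[0]
        if out.tuning_map_uncued is None:
            out.tuning_map_uncued = (out.tuning_map if out.shared_item_format
                                     else np.linalg.qr(rng.standard_normal((c, 2)))[0])
        if out.tuning_map_target is None:
            out.tuning_map_target = np.linalg.qr(rng.standard_normal((c, 2)))[0]
        if out.dv_pattern is None:
            v = rng.standard_normal(c)
            out.dv_pattern = v / np.linalg.norm(v)
        if out.noise_cov is None:
            out.noise_cov = self.noise_scale ** 2 * _random_spd(c, rng, self.noise_cond)
        if not (0.0 <= out.ar1 < 1.0):
            raise ValueError("ar1 must lie in [0, 1)")
        np.linalg.cholesky(out.noise_cov)  # raises if not SPD
        return out


def orientation_pattern(tuning_map: np.ndarray, theta_deg) -> np.ndarray:
    """Channel pattern(s) for orientation(s): tuning_map @ (cos 2th, sin 2th)."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float)) * 2.0
    feats = np.stack([np.cos(th), np.sin(th)], axis=-1)
    return feats @ tuning_map.T


def sample_gains(n_trials: int, rng: np.random.Generator,
                 sigma_log: float = 0.3,
                 linger_sigma_log: float = 1.2) -> pd.DataFrame:
    """Per-trial lognormal encoding gains.

    ``gain_cued`` / ``gain_uncued`` scale the active and latent item codes
    (median 1).  ``gain_linger`` scales the lingering active-format
    reactivation of the uncued item on switch trials (the
    interference-carrying component); it is heavy-tailed (mean 1, SD ~ 1.7 at
    the default log-SD) so that interference is dominated by trial-to-trial
    fluctuation rather than by a constant switch-trial offset.
    """
    return pd.DataFrame({
        "gain_cued": np.exp(rng.normal(0.0, sigma_log, size=n_trials)),
        "gain_uncued": np.exp(rng.normal(0.0, sigma_log, size=n_trials)),
        "gain_linger": np.exp(rng.normal(-linger_sigma_log ** 2 / 2.0,
                                         linger_sigma_log, size=n_trials)),
    })


def simulate_epochs(trials: pd.DataFrame, model: GenerativeModel, seed=None,
                    gains: pd.DataFrame | None = None) -> EpochsArray:
    """Simulate multichannel epochs with the planted active/latent codes.

    Noise is multivariate Gaussian with the model's spatial covariance and an
    AR(1) process over samples (stationary marginal covariance equal to
    ``noise_cov``).  Eye channels, when requested, carry independent white
    noise and no task signal (confound-control fixture).  Bit-for-bit
    reproducible for a fixed (trials, model, gains, seed).
    """
    rng = np.random.default_rng(seed)
    model = model.materialize(rng)
    time_ms = default_time_axis()
    n_trials, n_t = len(trials), len(time_ms)
    c = model.n_channels

    if gains is None:
        gains = sample_gains(n_trials, rng, model.gain_sigma_log,
                             model.linger_sigma_log)
    g_cued = gains["gain_cued"].to_numpy()
    g_uncued = gains["gain_uncued"].to_numpy()
    if np.any(g_cued <= 0) or np.any(g_uncued <= 0):
        raise ValueError("encoding gains must be positive")

    t_on = TARGET_ONSET_MS
    env_active = _smooth_step(time_ms, 200.0, 300.0) * (
        1.0 + model.active_magnification * _raised_cosine(time_ms, t_on + 100, t_on + 500))
    env_latent = _raised_cosine(time_ms, t_on + 100, t_on + 500)
    env_target = _raised_cosine(time_ms, t_on + 70, t_on + 570)
    env_dv = np.clip((time_ms - (t_on + 250.0)) / 750.0, 0.0, 1.0)

    g_linger = gains["gain_linger"].to_numpy() if "gain_linger" in gains else \
        np.ones(n_trials)
    is_switch = np.nan_to_num(trials["is_switch"].to_numpy(dtype=float), nan=0.0)

    pat_cued = orientation_pattern(model.tuning_map, trials["theta_cued"])
    pat_uncued = orientation_pattern(model.tuning_map_uncued, trials["theta_uncued"])
    pat_linger = orientation_pattern(model.tuning_map, trials["theta_uncued"])
    pat_target = orientation_pattern(model.tuning_map_target, trials["theta_target"])
    dv_amp = (trials["dv_cued"].to_numpy() - 45.0) / 45.0   # centered, ~[-0.9, 0.9]

    signal = (
        model.amp_active * (g_cued[:, None] * pat_cued)[:, :, None] * env_active
        + model.amp_latent * (g_uncued[:, None] * pat_uncued)[:, :, None] * env_latent
        + model.amp_linger * ((is_switch * g_linger)[:, None] * pat_linger)[:, :, None] * env_latent
        + model.amp_target * pat_target[:, :, None] * env_target
        + model.amp_dv * (dv_amp[:, None] * model.dv_pattern)[:, :, None] * env_dv
    )

    chol = np.linalg.cholesky(model.noise_cov)
    noise = np.empty((n_trials, c, n_t))
    white = rng.standard_normal((n_trials, n_t, c))
    innov = np.einsum("ij,ntj->nti", chol, white)  # spatially correlated
    noise[:, :, 0] = innov[:, 0, :]
    phi, scale = model.ar1, np.sqrt(1.0 - model.ar1 ** 2)
    for k in range(1, n_t):
        noise[:, :, k] = phi * noise[:, :, k - 1] + scale * innov[:, k, :]

    data = signal + noise
    labels = [f"CH{i + 1:02d}" for i in range(c)]
    if model.n_eye_channels:
        eye = rng.standard_normal((n_trials, model.n_eye_channels, n_t))
        data = np.concatenate([data, eye], axis=1)
        labels += [f"EOG{i + 1}" for i in range(model.n_eye_channels)]
    return EpochsArray(data, time_ms, labels)


def eeg_channels(epochs: EpochsArray) -> list[str]:
    """Channel labels excluding eye channels."""
    return [c for c in epochs.channel_labels if not c.startswith("EOG")]


def eye_channels(epochs: EpochsArray) -> list[str]:
    return [c for c in epochs.channel_labels if c.startswith("EOG")]


# --------------------------------------------------------------------------
# Diffusion-coupled behavior
# --------------------------------------------------------------------------

RESPONSE_DEADLINE_MS = 4000.0


@dataclass
class DDMGenParams:
    """Generating diffusion parameters for the synthetic observer.

    Defaults place the observer near the empirical operating point of the
    task (about 80% correct, mean RT around 600 ms): with drift magnitude
    v0 + v1*dv over the 8-level decision-variable support and boundary a,
    accuracy at a symmetric start point is 1/(1+exp(-a*v)).
    """

    a: float = 1.2                  # boundary separation (evidence units)
    t0_s: float = 0.30              # non-decision time (s)
    v0: float = 0.2                 # drift intercept (1/s)
    v1: float = 0.025               # drift slope per degree of |delta|
    gamma: float = 1.0              # gain -> drift coupling (matched filter)
    delta: float = 0.05             # gain -> t0 coupling, s (head start)
    switch_cost_s: float = 0.08     # added t0 on priority-switch trials
    interference_t0_s: float = 0.06  # lingering-gain -> t0 on switch trials
    fatigue: float = 0.01           # per-trial-in-block drift decrement
    cardinal_coef: float = 0.2      # drift penalty per unit cardinal_distance/45

    def __post_init__(self):
        if self.a <= 0 or self.t0_s <= 0:
            raise ValueError("a and t0_s must be positive")


def simulate_behavior(trials: pd.DataFrame, gains: pd.DataFrame,
                      ddm: DDMGenParams, mode: str = "matched_filter",
                      seed=None, dt_s: float = 0.0005) -> pd.DataFrame:
    """Fill rt_ms / choice / accuracy by simulating the diffusion process.

    Per trial the drift magnitude is ``(v0 + v1*dv_cued)`` scaled by fatigue,
    cardinal bias, and (matched_filter mode) the cued-item gain; the
    non-decision time collects the switch cost, the lingering-reactivation
    interference on switch trials, and (head_start mode) the cued-item gain.
    The drift sign follows the signed target-item distance; the upper boundary
    codes a clockwise response.  RTs beyond the 4000 ms response deadline are
    recorded as missing.
    """
    if mode not in ("matched_filter", "head_start", "none"):
        raise ValueError(f"unknown coupling mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    g_cued = gains["gain_cued"].to_numpy()
    g_uncued = gains["gain_uncued"].to_numpy()
    g_linger = gains["gain_linger"].to_numpy() if "gain_linger" in gains else \
        np.ones(n)

    v_mag = (ddm.v0 + ddm.v1 * out["dv_cued"].to_numpy())
    v_mag = v_mag * (1.0 - ddm.fatigue * (out["trial_in_block"].to_numpy() - 1))
    v_mag = v_mag * (1.0 - ddm.cardinal_coef * out["cardinal_distance"].to_numpy() / 45.0)
    if mode == "matched_filter":
        v_mag = v_mag * (1.0 + ddm.gamma * (g_cued - 1.0))
    sign = np.sign(out["signed_delta"].to_numpy())
    v = sign * v_mag

    is_switch = np.nan_to_num(out["is_switch"].to_numpy(), nan=0.0)
    t0 = np.full(n, ddm.t0_s)
    t0 = t0 + ddm.switch_cost_s * is_switch
    t0 = t0 + ddm.interference_t0_s * (g_linger - 1.0) * is_switch
    if mode == "head_start":
        t0 = t0 - ddm.delta * (g_cued - 1.0)
    if np.any(t0 <= 0):
        raise ValueError("non-decision time driven below zero; reduce couplings")

    dt_trial, upper = _ddm.simulate_paths(ddm.a, v, 0.5, n, rng, dt_s=dt_s)
    rt_ms = (dt_trial + t0) * 1000.0
    missed = rt_ms > RESPONSE_DEADLINE_MS
    choice = np.where(upper, "CW", "CCW")
    correct = (upper == (sign > 0)).astype(float)

    out["rt_ms"] = np.where(missed, np.nan, rt_ms)
    out["choice"] = np.where(missed, None, choice)
    out["accuracy"] = np.where(missed, np.nan, correct)
    out["gain_cued"] = g_cued
    out["gain_uncued"] = g_uncued
    out["gain_linger"] = g_linger
    if missed.any():
        warnings.warn(f"{int(missed.sum())} trials exceeded the response deadline")
    return out


# --------------------------------------------------------------------------
# Convenience: one subject / one experiment
# --------------------------------------------------------------------------

def simulate_subject(session: SessionConfig | None = None,
                     model: GenerativeModel | None = None,
                     ddm_params: DDMGenParams | None = None,
                     seed=None, subject: int = 0):
    """Simulate one subject end to end.

    Returns ``(trials, epochs)`` where trials includes behavior and the
    generating per-trial gains.  All randomness derives from ``seed``.
    """
    session = session or SessionConfig()
    model = model or GenerativeModel()
    ddm_params = ddm_params or DDMGenParams()
    ss = np.random.SeedSequence(seed)
    s_design, s_model, s_gain, s_eeg, s_beh = ss.spawn(5)
    trials = generate_session(session, s_design, subject=subject)
    rng_g = np.random.default_rng(s_gain)
    model_m = model.materialize(np.random.default_rng(s_model))
    gains = sample_gains(len(trials), rng_g, model_m.gain_sigma_log,
                         model_m.linger_sigma_log)
    epochs = simulate_epochs(trials, model_m, seed=s_eeg, gains=gains)
    trials = simulate_behavior(trials, gains, ddm_params, model_m.coupling_mode,
                               seed=s_beh)
    return trials, epochs
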