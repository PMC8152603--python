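"""Mahalanobis tuning-curve decoders for multichannel EEG epochs.

The decoding approach reconstructs a population tuning curve per test trial:
training trials are binned by their orientation *relative* to the test trial's
label, bin-averaged, and the Mahalanobis distance (under a Ledoit-Wolf
shrinkage noise covariance estimated from the training fold's residuals) from
the test pattern to each of the 16 bin means is computed.  Distances are
mean-centered and sign-reversed, so positive values mean pattern similarity.
The curve is collapsed to a scalar decoding index either by the cosine vector
mean (circular orientation labels; angle doubling handles the 180-deg
periodicity) or by the sign-reversed linear slope of similarity against
absolute label distance (the linear decision-variable labels).

Cross-validation is leave-one-block-out throughout.  Two decoder geometries
are provided: time-resolved (one index per trial and 4 ms sample) and
spatiotemporal (channels x time features from a 100-400 ms post-target
window, mean-removed per trial and channel, downsampled x10; one index per
trial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.ndimage import gaussian_filter1d
from sklearn.covariance import LedoitWolf

from .synthetic import (
    BASELINE_WINDOW_MS,
    EpochsArray,
    GRID_STEP_DEG,
    N_ORIENTATIONS,
    TARGET_ONSET_MS,
    signed_angle_180,
)

#: Relative-orientation bin centers, deg: -78.75, -67.5, ..., 0, ..., +90.
REL_BIN_CENTERS_DEG = np.arange(-78.75, 90.0 + GRID_STEP_DEG / 2, GRID_STEP_DEG)
#: Cosine readout weights on the (angle-doubled) relative-orientation bins.
COSINE_WEIGHTS = np.cos(2.0 * np.deg2rad(REL_BIN_CENTERS_DEG))

SMOOTHING_SD_MS = 24.0
SPATIOTEMPORAL_WINDOW_MS = (100.0, 400.0)   # post-target, half-open
DOWNSAMPLE_FACTOR = 10
RESIDUAL_WINDOW_MS = (0.0, 1800.0)          # post-cue, for noise covariance


@dataclass
class TuningCurve:
    """16-bin pattern-similarity profile (mean-centered, sign-reversed)."""

    bins: np.ndarray
    similarity: np.ndarray


@dataclass
class DecodingSeries:
    """Per-trial decoding indices, time-resolved or one scalar per trial."""

    values: np.ndarray          # trials x timepoints, or trials
    readout: str                # 'cosine' | 'slope'
    item: str                   # 'cued' | 'uncued' | 'target' | 'dv' | 'cross_item'
    time_ms: np.ndarray | None = None
    mean_timecourse: np.ndarray | None = None   # smoothed trial mean (time-resolved)


@dataclass
class CovarianceEstimate:
    matrix: np.ndarray
    shrinkage_intensity: float


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------

def baseline_correct(epochs: EpochsArray,
                     window_ms: tuple = BASELINE_WINDOW_MS) -> EpochsArray:
    """Subtract the mean pre-cue voltage (per trial and channel)."""
    m = epochs.time_mask(*window_ms)
    if not m.any():
        raise ValueError("baseline window outside the epoch")
    base = epochs.data[:, :, m].mean(axis=2, keepdims=True)
    return EpochsArray(epochs.data - base, epochs.time_ms, epochs.channel_labels,
                       epochs.target_onset_ms, epochs.sampling_rate_hz)


def _group_demean(x: np.ndarray, labels: np.ndarray, warn_singleton: bool = True):
    """Subtract the per-label mean from each row."""
    out = np.empty_like(x)
    for lab in np.unique(labels):
        m = labels == lab
        if warn_singleton and m.sum() < 2:
            warnings.warn(f"label {lab!r} has a single trial; its residual is zero")
        out[m] = x[m] - x[m].mean(axis=0)
    return out


def compute_noise_residuals(epochs: EpochsArray, labels,
                            window_ms: tuple = RESIDUAL_WINDOW_MS) -> np.ndarray:
    """Trials x channels residuals for noise-covariance estimation.

    Each trial's voltage has the mean of same-orientation trials subtracted,
    then residuals are averaged over the (cue-locked) window.  Demeaning and
    window-averaging commute, so the window average is taken first.
    """
    labels = np.asarray(labels)
    m = epochs.time_mask(*window_ms)
    avg = epochs.data[:, :, m].mean(axis=2)
    return _group_demean(avg, labels)


def shrinkage_covariance(residuals: np.ndarray) -> CovarianceEstimate:
    """Ledoit-Wolf shrinkage covariance (toward the scaled identity).

    Degenerate case: if the residuals are identically zero (e.g. noiseless
    fixtures where every orientation has a single training trial) the
    covariance is the zero matrix; the estimator then falls back to the
    identity, reducing Mahalanobis to Euclidean distance, with a warning.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual rows")
    lw = LedoitWolf().fit(residuals)
    cov = lw.covariance_
    if np.trace(cov) <= 0.0:
        warnings.warn("zero residual covariance; falling back to the identity "
                      "(Euclidean distances)")
        return CovarianceEstimate(np.eye(residuals.shape[1]), 1.0)
    return CovarianceEstimate(cov, float(lw.shrinkage_))


def tuning_curve(test_pattern: np.ndarray, train_means: np.ndarray,
                 cov: CovarianceEstimate) -> TuningCurve:
    """Mean-centered, sign-reversed Mahalanobis distances to the 16 bin means.

    ``train_means`` rows must be ordered by relative-orientation bin
    (REL_BIN_CENTERS_DEG).
    """
    d = train_means - test_pattern[None, :]
    c, low = cho_factor(cov.matrix)
    dist = np.sqrt(np.einsum("bc,bc->b", d, cho_solve((c, low), d.T).T))
    sim = -(dist - dist.mean())
    return TuningCurve(REL_BIN_CENTERS_DEG.copy(), sim)


def cosine_vector_mean(curve) -> float:
    """Scalar decoding index: mean over bins of cos(2*delta) * similarity."""
    sim = curve.similarity if isinstance(curve, TuningCurve) else np.asarray(curve)
    if sim.shape[-1] != N_ORIENTATIONS:
        raise ValueError("expected 16 relative-orientation bins")
    return float(np.mean(COSINE_WEIGHTS * sim, axis=-1))


def slope_readout(similarity, distances) -> float:
    """Sign-reversed OLS slope of similarity against bin distance.

    Similarity that decays with label distance yields a positive index.
    """
    sim = np.asarray(similarity, dtype=float)
    x = np.asarray(distances, dtype=float)
    if sim.shape[-1] < 2:
        raise ValueError("need at least 2 bins for a slope")
    xc = x - x.mean()
    return float(-(sim * xc).sum(axis=-1) / (xc ** 2).sum())


# --------------------------------------------------------------------------
# Shared cross-validation machinery
# --------------------------------------------------------------------------

def _grid_indices(labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Map circular orientation labels onto their 16-point grid indices.

    The grid offset is inferred from the labels themselves; labels need not
    cover all 16 orientations (empty *training* bins are caught downstream).
    """
    offset = float(np.min(labels) % GRID_STEP_DEG)
    pos = (labels - offset) % 180.0
    idx = np.rint(pos / GRID_STEP_DEG).astype(int) % N_ORIENTATIONS
    if not np.allclose(idx * GRID_STEP_DEG, pos, atol=1e-6):
        raise ValueError("orientation labels are not on an 11.25-deg grid")
    return idx, offset


#: Offsets mapping relative-bin position to REL_BIN_CENTERS_DEG order.
#  For test grid-index i, the training orientation at grid index
#  (i + k) mod 16 sits at relative angle fold(k * 11.25) in (-90, 90].
_REL_ORDER = np.argsort(np.where(np.arange(N_ORIENTATIONS) * GRID_STEP_DEG > 90.0,
                                 np.arange(N_ORIENTATIONS) * GRID_STEP_DEG - 180.0,
                                 np.arange(N_ORIENTATIONS) * GRID_STEP_DEG))


def _relative_similarity(dist_to_orients: np.ndarray, test_idx: np.ndarray):
    """Re-index per-orientation distances into relative-orientation bins.

    ``dist_to_orients``: n_test x 16 [x T] distances to the absolute
    orientation means.  Returns similarities n_test x 16 [x T] ordered by
    REL_BIN_CENTERS_DEG.
    """
    k = np.arange(N_ORIENTATIONS)
    gather = (test_idx[:, None] + k[None, :]) % N_ORIENTATIONS   # n_test x 16
    if dist_to_orients.ndim == 3:
        gather = np.broadcast_to(gather[:, :, None], dist_to_orients.shape)
    rel = np.take_along_axis(dist_to_orients, gather, axis=1)
    rel = rel[:, _REL_ORDER]
    return -(rel - rel.mean(axis=1, keepdims=True))


def _whitened_distances(wm_means: np.ndarray, wx_test: np.ndarray) -> np.ndarray:
    """Euclidean distances in whitened space.

    wm_means: bins x C [x T]; wx_test: n_test x C [x T].
    Returns n_test x bins [x T].
    """
    if wm_means.ndim == 2:
        diff = wx_test[:, None, :] - wm_means[None, :, :]
        return np.sqrt(np.einsum("ibc,ibc->ib", diff, diff))
    g = np.einsum("ict,bct->ibt", wx_test, wm_means)
    m2 = np.einsum("bct,bct->bt", wm_means, wm_means)
    x2 = np.einsum("ict,ict->it", wx_test, wx_test)
    sq = x2[:, None, :] + m2[None, :, :] - 2.0 * g
    return np.sqrt(np.maximum(sq, 0.0))


def _orientation_means(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Per-orientation mean patterns; data: trials x C [x T] -> 16 x C [x T]."""
    out = np.zeros((N_ORIENTATIONS,) + data.shape[1:])
    counts = np.bincount(idx, minlength=N_ORIENTATIONS)
    if np.any(counts == 0):
        raise ValueError(
            "a relative-orientation bin is empty in the training data; "
            "use balanced designs covering the full grid")
    np.add.at(out, idx, data)
    return out / counts.reshape((-1,) + (1,) * (data.ndim - 1))


# --------------------------------------------------------------------------
# Time-resolved decoding
# --------------------------------------------------------------------------

def smooth_timecourse(x: np.ndarray, sd_ms: float = SMOOTHING_SD_MS,
                      step_ms: float = 4.0) -> np.ndarray:
    """Gaussian temporal smoothing (reflection padding) along the last axis."""
    return gaussian_filter1d(x, sigma=sd_ms / step_ms, axis=-1, mode="reflect")


def decode_time_resolved(epochs: EpochsArray, labels, blocks,
                         readout: str = "cosine", item: str = "cued",
                         baseline: bool = True,
                         channels: list[str] | None = None) -> DecodingSeries:
    """Leave-one-block-out tuning-curve decoding at every 4 ms sample.

    ``labels`` are circular orientations on the 16-point grid (cosine readout)
    or decision-variable levels on the 8-level linear grid (slope readout).
    One shrinkage noise covariance is estimated per training fold from
    residuals averaged over 0-1800 ms post-cue.  Returns per-trial time series
    plus the Gaussian-smoothed (SD 24 ms) mean time course.
    """
    labels = np.asarray(labels, dtype=float)
    blocks = np.asarray(blocks)
    if len(np.unique(blocks)) < 2:
        raise ValueError("leave-one-block-out cross-validation needs >= 2 blocks")
    if channels is not None:
        epochs = epochs.pick(channels)
    if baseline:
        epochs = baseline_correct(epochs)
    data = epochs.data
    n_trials, _, n_t = data.shape
    values = np.full((n_trials, n_t), np.nan)

    circular = readout == "cosine"
    if circular:
        idx, _ = _grid_indices(labels)
        n_bins = N_ORIENTATIONS
    else:
        levels = np.unique(labels)
        idx = np.searchsorted(levels, labels)
        n_bins = len(levels)

    # fold bin means via per-block partial sums (train = total - held-out)
    uniq_blocks = np.unique(blocks)
    blk_pos = {b: i for i, b in enumerate(uniq_blocks)}
    bin_sums = np.zeros((len(uniq_blocks), n_bins) + data.shape[1:])
    bin_counts = np.zeros((len(uniq_blocks), n_bins), dtype=int)
    for t in range(n_trials):
        bin_sums[blk_pos[blocks[t]], idx[t]] += data[t]
        bin_counts[blk_pos[blocks[t]], idx[t]] += 1
    tot_sums = bin_sums.sum(axis=0)
    tot_counts = bin_counts.sum(axis=0)

    resid_mask = epochs.time_mask(*RESIDUAL_WINDOW_MS)
    win_avg = data[:, :, resid_mask].mean(axis=2)   # trials x C, for noise cov

    for b in uniq_blocks:
        test = blocks == b
        train = ~test
        counts = tot_counts - bin_counts[blk_pos[b]]
        if np.any(counts == 0):
            raise ValueError(
                "a training bin is empty under leave-one-block-out; "
                "use balanced designs covering the full label grid")
        resid = _group_demean(win_avg[train], labels[train], warn_singleton=False)
        cov = shrinkage_covariance(resid)
        chol = np.linalg.cholesky(cov.matrix)
        w = solve_triangular(chol, np.eye(chol.shape[0]), lower=True)
        means = (tot_sums - bin_sums[blk_pos[b]]) / counts[:, None, None]
        wm = np.einsum("dc,bct->bdt", w, means)
        wx = np.einsum("dc,ict->idt", w, data[test])
        dist = _whitened_distances(wm, wx)          # n_test x bins x T
        if circular:
            sim = _relative_similarity(dist, idx[test])
            values[test] = np.einsum("b,ibt->it", COSINE_WEIGHTS, sim) / N_ORIENTATIONS
        else:
            sim = -(dist - dist.mean(axis=1, keepdims=True))
            values[test] = _slope_series(sim, levels, labels[test])

    mean_tc = smooth_timecourse(values.mean(axis=0))
    return DecodingSeries(values, readout, item, epochs.time_ms, mean_tc)


def _level_means(data: np.ndarray, idx: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((n_levels,) + data.shape[1:])
    counts = np.bincount(idx, minlength=n_levels)
    if np.any(counts == 0):
        raise ValueError("a decision-variable level is empty in the training data")
    np.add.at(out, idx, data)
    return out / counts.reshape((-1,) + (1,) * (data.ndim - 1))


def _slope_series(sim: np.ndarray, levels: np.ndarray, test_labels: np.ndarray):
    """Sign-reversed OLS slope against |level - test label| per trial [x T]."""
    x = np.abs(levels[None, :] - test_labels[:, None])       # n_test x L
    xc = x - x.mean(axis=1, keepdims=True)
    denom = (xc ** 2).sum(axis=1)
    if sim.ndim == 3:
        return -np.einsum("il,ilt->it", xc, sim) / denom[:, None]
    return -(xc * sim).sum(axis=1) / denom


# --------------------------------------------------------------------------
# Spatiotemporal (single-trial) decoding
# --------------------------------------------------------------------------

def spatiotemporal_features(epochs: EpochsArray,
                            window_ms: tuple = SPATIOTEMPORAL_WINDOW_MS,
                            downsample: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Trials x (channels * reduced samples) feature matrix.

    Restricts to the half-open post-target window, removes each trial's
    per-channel mean across the window, block-averages ``downsample``
    consecutive samples (dropping any incomplete trailing block), and
    concatenates channels x reduced samples.
    """
    lo = epochs.target_onset_ms + window_ms[0]
    hi = epochs.target_onset_ms + window_ms[1]
    m = epochs.time_mask(lo, hi, half_open=True)
    n_samp = int(m.sum())
    if n_samp < downsample:
        raise ValueError("window shorter than one downsampling block")
    x = epochs.data[:, :, m]
    x = x - x.mean(axis=2, keepdims=True)
    n_blocks = n_samp // downsample
    x = x[:, :, : n_blocks * downsample]
    x = x.reshape(x.shape[0], x.shape[1], n_blocks, downsample).mean(axis=3)
    return x.reshape(x.shape[0], -1)


def _decode_spatiotemporal_features(feats, train_labels, test_labels, blocks,
                                    readout, item) -> DecodingSeries:
    """LOBO Mahalanobis decoding on a precomputed feature matrix.

    ``train_labels`` sort the training bins; ``test_labels`` locate each test
    trial on the label space (they differ only for the cross-item decoder).
    """
    train_labels = np.asarray(train_labels, dtype=float)
    test_labels = np.asarray(test_labels, dtype=float)
    blocks = np.asarray(blocks)
    if len(np.unique(blocks)) < 2:
        raise ValueError("leave-one-block-out cross-validation needs >= 2 blocks")
    n = feats.shape[0]
    values = np.full(n, np.nan)

    circular = readout == "cosine"
    if circular:
        tr_idx, _ = _grid_indices(train_labels)
        te_idx, _ = _grid_indices(test_labels)
    else:
        levels = np.unique(train_labels)
        tr_idx = np.searchsorted(levels, train_labels)

    for b in np.unique(blocks):
        test = blocks == b
        train = ~test
        resid = _group_demean(feats[train], train_labels[train], warn_singleton=False)
        cov = shrinkage_covariance(resid)
        chol = np.linalg.cholesky(cov.matrix)
        w = solve_triangular(chol, np.eye(chol.shape[0]), lower=True)
        means = _orientation_means(feats[train], tr_idx[train]) if circular else \
            _level_means(feats[train], tr_idx[train], len(levels))
        dist = _whitened_distances(means @ w.T, feats[test] @ w.T)
        if circular:
            sim = _relative_similarity(dist, te_idx[test])
            values[test] = sim @ COSINE_WEIGHTS / N_ORIENTATIONS
        else:
            sim = -(dist - dist.mean(axis=1, keepdims=True))
            values[test] = _slope_series(sim, levels, test_labels[test])
    return DecodingSeries(values, readout, item)


def decode_spatiotemporal(epochs: EpochsArray, labels, blocks,
                          readout: str = "cosine", item: str = "cued",
                          window_ms: tuple = SPATIOTEMPORAL_WINDOW_MS,
                          baseline: bool = True,
                          channels: list[str] | None = None) -> DecodingSeries:
    """Single-trial decoding from channels x time features (one index/trial)."""
    if channels is not None:
        epochs = epochs.pick(channels)
    if baseline:
        epochs = baseline_correct(epochs)
    feats = spatiotemporal_features(epochs, window_ms)
    return _decode_spatiotemporal_features(feats, labels, labels, blocks,
                                           readout, item)


def decode_cross_item(epochs: EpochsArray, cued_labels, uncued_labels, blocks,
                      window_ms: tuple = SPATIOTEMPORAL_WINDOW_MS,
                      baseline: bool = True,
                      channels: list[str] | None = None) -> DecodingSeries:
    """Train on cued-item labels, evaluate each test trial at its uncued label.

    Measures the extent to which the uncued item is expressed in the cued
    item's (functionally active) representational format.  Spatiotemporal
    geometry, cosine readout.
    """
    if channels is not None:
        epochs = epochs.pick(channels)
    if baseline:
        epochs = baseline_correct(epochs)
    feats = spatiotemporal_features(epochs, window_ms)
    return _decode_spatiotemporal_features(feats, cued_labels, uncued_labels,
                                           blocks, "cosine", "cross_item")


# --------------------------------------------------------------------------
# Eye-movement confound control
# --------------------------------------------------------------------------

def regress_out_eye(eeg_series: DecodingSeries,
                    eye_series: DecodingSeries) -> DecodingSeries:
    """Residualize an EEG decoding time course on the eye-channel time course.

    OLS with intercept across timepoints of the subject-mean time courses; the
    intercept is kept so the residual retains the original mean level.
    """
    y = np.asarray(eeg_series.mean_timecourse, dtype=float)
    x = np.asarray(eye_series.mean_timecourse, dtype=float)
    if y.shape != x.shape:
        raise ValueError("EEG and eye decoding time courses must be aligned")
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    if denom < 1e-14 * len(x):
        warnings.warn("eye decoding series is constant; returning original series")
        resid = y.copy()
    else:
        slope = (xc * (y - y.mean())).sum() / denom
        resid = y - slope * xc
    return DecodingSeries(eeg_series.values, eeg_series.readout, eeg_series.item,
                          eeg_series.time_ms, resid)
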