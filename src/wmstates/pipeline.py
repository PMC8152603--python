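"""End-to-end orchestration: simulate -> decode -> link -> stats -> ddm.

The pipeline runs a whole synthetic experiment (n subjects), writes every
stage's outputs under an output directory, and records a manifest with the
configuration, derived seeds, and SHA-256 checksums of all written files, so
that identical configurations produce identical manifests.

Seed scheme: every stochastic stage draws its seed deterministically from the
master seed via ``numpy.random.SeedSequence(master, spawn_key=(STAGE, index))``
with a fixed stage numbering, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ddm as ddm_mod
from . import decoding, inference, io, linking, synthetic

logger = logging.getLogger("wmstates")

STAGE_IDS = {"design": 0, "model": 1, "gains": 2, "eeg": 3, "behavior": 4,
             "stats": 5, "ddm": 6}


def stage_seed(master: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the master seed."""
    return np.random.SeedSequence(master, spawn_key=(STAGE_IDS[stage], index))


@dataclass
class PipelineConfig:
    """Fully serializable configuration of a pipeline run."""

    seed: int = 0
    n_subjects: int = 10
    n_blocks: int = 32
    trials_per_block: int = 16
    p_switch: float = 0.5
    iti_mean_ms: float = 550.0
    coupling_mode: str = "matched_filter"
    n_channels: int = 20
    cluster_n_perm: int = 1000
    run_ddm: bool = True
    ddm_n_samples: int = 5000
    ddm_n_burn: int = 1000
    out_dir: str = "wmstates_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.read_yaml(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_stage(config: PipelineConfig, subject: int):
    session = synthetic.SessionConfig(
        n_blocks=config.n_blocks, trials_per_block=config.trials_per_block,
        p_switch=config.p_switch, iti_mean_ms=config.iti_mean_ms)
    model = synthetic.GenerativeModel(n_channels=config.n_channels,
                                      coupling_mode=config.coupling_mode)
    params = synthetic.DDMGenParams()
    trials = synthetic.generate_session(
        session, stage_seed(config.seed, "design", subject), subject=subject)
    model = model.materialize(
        np.random.default_rng(stage_seed(config.seed, "model", subject)))
    gains = synthetic.sample_gains(
        len(trials), np.random.default_rng(stage_seed(config.seed, "gains", subject)),
        model.gain_sigma_log, model.linger_sigma_log)
    epochs = synthetic.simulate_epochs(
        trials, model, seed=stage_seed(config.seed, "eeg", subject), gains=gains)
    trials = synthetic.simulate_behavior(
        trials, gains, params, model.coupling_mode,
        seed=stage_seed(config.seed, "behavior", subject))
    return trials, epochs


def decode_stage(trials: pd.DataFrame, epochs: synthetic.EpochsArray):
    """Time-resolved (cued/uncued) and spatiotemporal (cued/uncued/cross)."""
    chans = synthetic.eeg_channels(epochs)
    blocks = trials["block"].to_numpy()
    out = {}
    out["tr_cued"] = decoding.decode_time_resolved(
        epochs, trials["theta_cued"], blocks, "cosine", "cued", channels=chans)
    out["tr_uncued"] = decoding.decode_time_resolved(
        epochs, trials["theta_uncued"], blocks, "cosine", "uncued", channels=chans)
    out["st_cued"] = decoding.decode_spatiotemporal(
        epochs, trials["theta_cued"], blocks, "cosine", "cued", channels=chans)
    out["st_uncued"] = decoding.decode_spatiotemporal(
        epochs, trials["theta_uncued"], blocks, "cosine", "uncued", channels=chans)
    out["st_cross"] = decoding.decode_cross_item(
        epochs, trials["theta_cued"], trials["theta_uncued"], blocks,
        channels=chans)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / ".failed"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        manifest = _run_pipeline_inner(config, out_dir)
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise
    return manifest


def _run_pipeline_inner(config: PipelineConfig, out_dir: Path) -> dict:
    # out_dir is not part of the scientific configuration: identical configs
    # in different directories must yield identical checksums
    cfg_dict = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    io.write_yaml(out_dir / "config.yaml", cfg_dict)

    all_trials, tr_cued_tc, tr_uncued_tc = [], [], []
    st_scores = []
    for s in range(config.n_subjects):
        logger.info("subject %d: simulate + decode", s)
        trials, epochs = simulate_stage(config, s)
        io.write_trials_csv(out_dir / f"trials_s{s:02d}.csv", trials)
        io.write_epochs_h5(out_dir / f"epochs_s{s:02d}.h5", epochs)
        dec = decode_stage(trials, epochs)
        tr_cued_tc.append(dec["tr_cued"].mean_timecourse)
        tr_uncued_tc.append(dec["tr_uncued"].mean_timecourse)
        scores = pd.DataFrame({
            "subject": s,
            "st_cued": dec["st_cued"].values,
            "st_uncued": dec["st_uncued"].values,
            "st_cross": dec["st_cross"].values,
        })
        st_scores.append(scores)
        all_trials.append(trials)

    trials = pd.concat(all_trials, ignore_index=True)
    scores = pd.concat(st_scores, ignore_index=True)
    io.write_trials_csv(out_dir / "scores.csv", scores)

    tr_cued = np.vstack(tr_cued_tc)
    tr_uncued = np.vstack(tr_uncued_tc)

    # --- linking ---
    logger.info("linking stage")
    link = linking.fit_trialwise_model(trials, scores["st_cued"],
                                       scores["st_uncued"])
    weights = link["linear_logRT"].weights.add_prefix("logRT_").join(
        link["logistic_accuracy"].weights.add_prefix("acc_"))
    weights.to_csv(out_dir / "trialwise_weights.csv")

    # --- stats ---
    logger.info("stats stage")
    time_axis = synthetic.default_time_axis()
    delay = (time_axis >= 200.0) & (time_axis <= synthetic.TARGET_ONSET_MS)
    cl_cued = inference.cluster_permutation_test(
        tr_cued, n_perm=config.cluster_n_perm,
        seed=stage_seed(config.seed, "stats", 0), times=time_axis)
    cl_uncued = inference.cluster_permutation_test(
        tr_uncued, n_perm=config.cluster_n_perm,
        seed=stage_seed(config.seed, "stats", 1), times=time_axis)

    def _cluster_json(cl):
        return [
            {"start_ms": float(time_axis[i]), "end_ms": float(time_axis[j]),
             "mass": m, "corrected_p": p}
            for (i, j, m, p) in cl.clusters
        ]

    def _delay_sig(cl):
        return any(p <= 0.05 and time_axis[i] < synthetic.TARGET_ONSET_MS
                   for (i, j, m, p) in cl.clusters)

    stats_out = {
        "cued_clusters": _cluster_json(cl_cued),
        "uncued_clusters": _cluster_json(cl_uncued),
        "cued_delay_cluster_present": bool(_delay_sig(cl_cued)),
        "uncued_delay_cluster_present": bool(_delay_sig(cl_uncued)),
        "trialwise_logRT_cued": link["linear_logRT"].group_stats(
            "score_cued", tail="less"),
        "trialwise_logRT_uncued": link["linear_logRT"].group_stats(
            "score_uncued", tail="greater"),
        "trialwise_acc_cued": link["logistic_accuracy"].group_stats(
            "score_cued", tail="greater"),
        "trialwise_acc_uncued": link["logistic_accuracy"].group_stats(
            "score_uncued", tail="less"),
        "mean_delay_decoding_cued": float(tr_cued[:, delay].mean()),
        "mean_delay_decoding_uncued": float(tr_uncued[:, delay].mean()),
    }
    (out_dir / "stats.json").write_text(json.dumps(stats_out, indent=2))

    # --- ddm ---
    ddm_out = {}
    if config.run_ddm:
        logger.info("ddm stage")
        masses = {"drift": [], "ndt": []}
        for s in range(config.n_subjects):
            sub = trials[trials["subject"] == s].reset_index(drop=True)
            sc = scores.loc[scores["subject"] == s, "st_cued"].to_numpy()
            sc = linking.normalize_within_block(sc, sub["block"])
            for target in ("drift", "ndt"):
                fit = ddm_mod.fit_regression_ddm(
                    sub, sc, target,
                    seed=stage_seed(config.seed, "ddm", s * 2 + (target == "ndt")),
                    n_samples=config.ddm_n_samples, n_burn=config.ddm_n_burn)
                direction = "positive" if target == "drift" else "negative"
                masses[target].append(
                    ddm_mod.posterior_direction_mass(fit.samples["beta"], direction))
        ddm_out = {
            "drift_beta_mass_positive": masses["drift"],
            "ndt_beta_mass_negative": masses["ndt"],
            "drift_beta_mass_positive_median": float(np.median(masses["drift"])),
            "ndt_beta_mass_negative_median": float(np.median(masses["ndt"])),
        }
        (out_dir / "ddm.json").write_text(json.dumps(ddm_out, indent=2))

    files = sorted(p for p in out_dir.iterdir() if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "summary": {k: stats_out[k] for k in
                    ("cued_delay_cluster_present", "uncued_delay_cluster_present",
                     "mean_delay_decoding_cued", "mean_delay_decoding_uncued")},
        "ddm": {k: v for k, v in ddm_out.items() if k.endswith("median")},
        "checksums": {p.name: _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


REPORT_SECTIONS = ("Decoding time courses", "Trial-wise regression weights",
                   "Bayes factors", "DDM posterior summaries", "Run provenance")


def make_report(out_dir) -> str:
    """Render a deterministic markdown report from a completed run directory."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    lines = ["# wmstates run report", ""]

    lines += [f"## {REPORT_SECTIONS[0]}", ""]
    stats_path = out_dir / "stats.json"
    if stats_path.exists():
        stats = json.loads(stats_path.read_text())
        lines += [
            f"- cued delay-period cluster present: "
            f"{stats['cued_delay_cluster_present']}",
            f"- uncued delay-period cluster present: "
            f"{stats['uncued_delay_cluster_present']}",
            f"- mean delay decoding (cued): "
            f"{stats['mean_delay_decoding_cued']:.5f}",
            f"- mean delay decoding (uncued): "
            f"{stats['mean_delay_decoding_uncued']:.5f}", ""]
    else:
        stats = None
        lines += ["*unavailable*", ""]

    lines += [f"## {REPORT_SECTIONS[1]}", ""]
    if stats is not None:
        for key in ("trialwise_logRT_cued", "trialwise_logRT_uncued",
                    "trialwise_acc_cued", "trialwise_acc_uncued"):
            g = stats[key]
            lines.append(
                f"- {key}: t({g['n'] - 1}) = {g['t']:.3f}, p = {g['p']:.4f}, "
                f"d = {g['d']:.3f}")
        lines.append("")
    else:
        lines += ["*unavailable*", ""]

    lines += [f"## {REPORT_SECTIONS[2]}", ""]
    if stats is not None:
        for key in ("trialwise_logRT_cued", "trialwise_logRT_uncued"):
            g = stats[key]
            lines.append(f"- {key}: BF10 = {g['bf10']:.3f} (BF01 = {g['bf01']:.3f})")
        lines.append("")
    else:
        lines += ["*unavailable*", ""]

    lines += [f"## {REPORT_SECTIONS[3]}", ""]
    ddm_path = out_dir / "ddm.json"
    if ddm_path.exists():
        dd = json.loads(ddm_path.read_text())
        lines += [
            f"- median posterior mass for positive drift slope: "
            f"{dd['drift_beta_mass_positive_median']:.3f}",
            f"- median posterior mass for negative non-decision-time slope: "
            f"{dd['ndt_beta_mass_negative_median']:.3f}", ""]
    else:
        lines += ["*unavailable*", ""]

    lines += [f"## {REPORT_SECTIONS[4]}", ""]
    lines.append(f"- seed: {manifest['config']['seed']}")
    lines.append(f"- subjects: {manifest['config']['n_subjects']}, "
                 f"blocks: {manifest['config']['n_blocks']}")
    for name, digest in sorted(manifest["checksums"].items()):
        lines.append(f"- `{name}`: `{digest[:16]}`")
    lines.append("")
    report = "\n".join(lines)
    (out_dir / "report.md").write_text(report)
    return report
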