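"""Shared fixtures: small single-subject sets and the demo-scale experiment.

Expensive fixtures are session-scoped so the structure-recovery tests and the
acceptance suite share one simulated experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wmstates import decoding as dec
from wmstates import linking
from wmstates import synthetic as syn

DEMO_N_SUBJECTS = 10
DEMO_N_BLOCKS = 32
DEMO_SEED = 400


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """One 32-block subject.

    32 blocks guarantee every orientation appears twice as a block item, so
    item-label decoding bins stay populated under leave-one-block-out.
    """
    trials, epochs = syn.simulate_subject(syn.SessionConfig(n_blocks=32), seed=77)
    return trials, epochs


def full_grid_two_block_design() -> pd.DataFrame:
    """Two identical 16-trial blocks whose cued labels span the full grid.

    Not a realistic session (cued orientation changes every trial) but a
    coverage-complete fixture for label-decoding tests on tiny data.
    """
    item, target = syn.build_orientation_grids()
    rng = np.random.default_rng(2)
    base = pd.DataFrame({
        "block": 1,
        "trial_in_block": np.arange(1, 17),
        "cue": "A",
        "theta_cued": item.values,
        "theta_uncued": np.roll(item.values, 3),
        "theta_target": rng.permutation(target.values),
        "is_switch": 0.0,
        "cue_sequence": 1,
    })
    base["dv_cued"] = syn.decision_variable(base["theta_cued"],
                                            base["theta_target"])
    second = base.copy()
    second["block"] = 2
    return pd.concat([base, second], ignore_index=True)


def _decode_subject(trials: pd.DataFrame, epochs: syn.EpochsArray) -> dict:
    chans = syn.eeg_channels(epochs)
    blocks = trials["block"].to_numpy()
    out = {}
    out["tr_cued"] = dec.decode_time_resolved(
        epochs, trials["theta_cued"], blocks, channels=chans)
    out["tr_uncued"] = dec.decode_time_resolved(
        epochs, trials["theta_uncued"], blocks, channels=chans)
    out["st_cued"] = dec.decode_spatiotemporal(
        epochs, trials["theta_cued"], blocks, channels=chans).values
    out["st_uncued"] = dec.decode_spatiotemporal(
        epochs, trials["theta_uncued"], blocks, channels=chans).values
    out["st_cross"] = dec.decode_cross_item(
        epochs, trials["theta_cued"], trials["theta_uncued"], blocks,
        channels=chans).values
    return out


@pytest.fixture(scope="session")
def demo_experiment():
    """Demo-scale experiment: 10 subjects x 32 blocks, matched-filter coupling.

    Returns (perf, decodings) where perf concatenates all subjects' trial
    tables and decodings holds per-trial spatiotemporal scores plus the
    per-subject time-resolved mean time courses.
    """
    behs, st_c, st_u, st_x, tr_c, tr_u = [], [], [], [], [], []
    for s in range(DEMO_N_SUBJECTS):
        trials, epochs = syn.simulate_subject(
            syn.SessionConfig(n_blocks=DEMO_N_BLOCKS), seed=DEMO_SEED + s,
            subject=s)
        d = _decode_subject(trials, epochs)
        behs.append(trials)
        st_c.append(d["st_cued"])
        st_u.append(d["st_uncued"])
        st_x.append(d["st_cross"])
        tr_c.append(d["tr_cued"].mean_timecourse)
        tr_u.append(d["tr_uncued"].mean_timecourse)
    perf = pd.concat(behs, ignore_index=True)
    decodings = {
        "st_cued": np.concatenate(st_c),
        "st_uncued": np.concatenate(st_u),
        "st_cross": np.concatenate(st_x),
        "tr_cued": np.vstack(tr_c),
        "tr_uncued": np.vstack(tr_u),
        "time_ms": syn.default_time_axis(),
    }
    return perf, decodings


@pytest.fixture(scope="session")
def head_start_experiment():
    """10 subjects x 32 blocks with the gain -> non-decision-time coupling."""
    model = syn.GenerativeModel(coupling_mode="head_start")
    behs, scores = [], []
    for s in range(DEMO_N_SUBJECTS):
        trials, epochs = syn.simulate_subject(
            syn.SessionConfig(n_blocks=DEMO_N_BLOCKS), model=model,
            seed=4000 + s, subject=s)
        chans = syn.eeg_channels(epochs)
        st = dec.decode_spatiotemporal(epochs, trials["theta_cued"],
                                       trials["block"].to_numpy(), channels=chans)
        behs.append(trials.assign(subject=s))
        scores.append(linking.normalize_within_block(st.values, trials["block"]))
    return pd.concat(behs, ignore_index=True), np.concatenate(scores)
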