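"""File formats: HDF5 epoch container, CSV trial tables, YAML configs.

The epoch container stores datasets ``/data`` (trials x channels x samples),
``/time_ms`` and ``/channels``, with root attributes ``sampling_rate_hz`` and
``target_onset_ms``.  Trial tables are plain CSV with the documented column
names; times are in ms.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import EpochsArray


def write_epochs_h5(path, epochs: EpochsArray) -> None:
    # track_times=False keeps files byte-identical across identical runs
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("time_ms", data=epochs.time_ms, track_times=False)
        f.create_dataset("channels", track_times=False,
                         data=np.array(epochs.channel_labels, dtype="S"))
        f.attrs["sampling_rate_hz"] = epochs.sampling_rate_hz
        f.attrs["target_onset_ms"] = epochs.target_onset_ms


def read_epochs_h5(path) -> EpochsArray:
    with h5py.File(path, "r") as f:
        return EpochsArray(
            data=f["data"][()],
            time_ms=f["time_ms"][()],
            channel_labels=[c.decode() for c in f["channels"][()]],
            target_onset_ms=float(f.attrs["target_onset_ms"]),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
        )


def write_trials_csv(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
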