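"""Spike-table and weight-snapshot I/O.

Spikes travel as columnar event tables (``time_ms``, ``neuron_id``, ``phase``,
``trial``), weight snapshots as sparse triplets (``pre``, ``post``,
``weight``).  Both are written either as TSV (human-readable, test fixtures)
or HDF5 (large runs).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SPIKE_COLUMNS = ["time_ms", "neuron_id", "phase", "trial"]


def write_spikes_tsv(spikes: pd.DataFrame, path) -> None:
    spikes.to_csv(path, sep="\t", index=False, columns=SPIKE_COLUMNS)


def read_spikes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"neuron_id": np.int32, "trial": np.int32})
    return df[SPIKE_COLUMNS]


def write_spikes_hdf5(spikes: pd.DataFrame, path, group: str = "spikes") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("time_ms", data=spikes["time_ms"].to_numpy())
        g.create_dataset("neuron_id", data=spikes["neuron_id"].to_numpy(np.int32))
        g.create_dataset(
            "phase", data=spikes["phase"].astype(str).to_numpy(dtype="S16")
        )
        g.create_dataset("trial", data=spikes["trial"].to_numpy(np.int32))


def read_spikes_hdf5(path, group: str = "spikes") -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        g = f[group]
        return pd.DataFrame(
            {
                "time_ms": g["time_ms"][:],
                "neuron_id": g["neuron_id"][:],
                "phase": [s.decode() for s in g["phase"][:]],
                "trial": g["trial"][:],
            }
        )


def write_weights_tsv(ee: pd.DataFrame, path) -> None:
    ee.to_csv(path, sep="\t", index=False, columns=["pre", "post", "weight"])


def read_weights_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pre": np.int32, "post": np.int32})


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
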