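"""Serialization of learned systems: HDF5 for matrices, CSV for curves."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .plasticity import EnvironmentSequence

__all__ = ["save_learned_system", "load_learned_system"]


def save_learned_system(
    path, W: np.ndarray, seq: EnvironmentSequence, params: dict
) -> None:
    """Write the weight matrix with its environment sequence and the map
    parameters needed to reproduce it."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=W, compression="gzip")
        f.create_dataset("slots", data=seq.slots, compression="gzip")
        f.create_dataset("active", data=seq.active, compression="gzip")
        g = f.create_group("params")
        for key, val in params.items():
            g.attrs[key] = val
        for key in ("N", "M", "s", "n", "seed"):
            f.attrs[key] = getattr(seq, key)


def load_learned_system(path):
    """Inverse of :func:`save_learned_system`.

    Returns ``(W, seq, params)``; the sequence is rebuilt from its seed and
    verified against the stored slot/mask arrays.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        W = f["weights"][()]
        slots = f["slots"][()]
        active = f["active"][()]
        meta = dict(f.attrs)
        params = dict(f["params"].attrs)
    seq = EnvironmentSequence(
        N=int(meta["N"]), M=int(meta["M"]), s=float(meta["s"]),
        n=int(meta["n"]), seed=int(meta["seed"]),
    )
    if not (np.array_equal(seq.slots, slots) and np.array_equal(seq.active, active)):
        raise ValueError(f"{path}: stored environments do not match their seed")
    return W, seq, params
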