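"""Output writing: self-describing field containers and summary tables.

Field arrays go to HDF5 with named axes (y, z, time), units attributes and
the fully resolved configuration embedded as JSON for provenance; scalar
summaries append one row per run to a delimited text table.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "write_steady_fields",
    "write_transient",
    "write_checkpoint",
    "load_checkpoint",
    "append_summary_row",
]


def _provenance(cfg_dict: dict) -> str:
    try:
        ver = version("ductld")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    return json.dumps({"config": cfg_dict, "ductld_version": ver})


def write_steady_fields(path, result, cfg_dict: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["provenance"] = _provenance(cfg_dict)
        f.create_dataset("y", data=result.y).attrs["units"] = "h*"
        f.create_dataset("z", data=result.z).attrs["units"] = "h*"
        for name in ("u", "S", "Pe", "beta"):
            d = f.create_dataset(name, data=getattr(result, name))
            d.attrs["axes"] = "y,z"
        f.create_dataset("residuals", data=np.asarray(result.residuals))


def write_transient(path, record, final: dict, cfg_dict: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["provenance"] = _provenance(cfg_dict)
        g = f.create_group("series")
        for name in ("t", "S_mean", "S_max", "u_mean"):
            g.create_dataset(name, data=getattr(record, name))
        gf = f.create_group("final")
        gf.create_dataset("y", data=final["y"])
        gf.create_dataset("z", data=final["z"])
        gf.create_dataset("u", data=final["u"])
        gf.create_dataset("S", data=final["S"])
        if "S_half_avg" in final:
            gf.create_dataset("S_half_avg", data=final["S_half_avg"])
            gf.create_dataset("u_half_avg", data=final["u_half_avg"])
        if record.snapshots:
            gs = f.create_group("snapshots")
            for step, S, u in record.snapshots:
                sub = gs.create_group(f"step_{step:07d}")
                sub.create_dataset("S", data=S)
                sub.create_dataset("u", data=u)


def write_checkpoint(path, checkpoint, cfg_dict: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["provenance"] = _provenance(cfg_dict)
        f.attrs["step"] = checkpoint.step
        f.create_dataset("u", data=checkpoint.u)
        f.create_dataset("X0", data=checkpoint.X0)
        f.create_dataset("X1", data=checkpoint.X1)


def load_checkpoint(path):
    from .oscillatory import Checkpoint

    with h5py.File(path, "r") as f:
        return Checkpoint(
            step=int(f.attrs["step"]),
            u=f["u"][()],
            X0=f["X0"][()],
            X1=f["X1"][()],
        )


def append_summary_row(path, row: dict) -> None:
    """Append one summary row (header written once) to a TSV table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([row])
    df.to_csv(path, sep="\t", mode="a", header=not path.exists(), index=False)
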