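"""File round-tripping: parameter files, trace tables, trajectories, maps.

Formats are plain text throughout:

* parameter sets: flat ``key: value`` YAML, one key per model parameter;
* bud traces: long-format TSV with header ``explant_id  label  day  bud
  length_mm  excluded`` (``bud`` is ``top`` or ``bottom``);
* trajectories: TSV with columns ``t E F N M`` plus a JSON sidecar holding
  params, seed, scheme, dt and the clamp count;
* grid maps: one TSV matrix per payload channel (rows = v0 index, columns =
  mu index) plus a JSON sidecar with the axes, masks and provenance.

Numeric serialization uses full repr precision so write -> read is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ExplantState, ModelParameters
from .paramspace import GridMap
from .simulate import Trajectory
from .traces import BudTrace

__all__ = [
    "save_params",
    "load_params",
    "save_traces",
    "load_traces",
    "save_trajectory",
    "load_trajectory",
    "save_gridmap",
    "load_gridmap",
]


def save_params(params: ModelParameters, path) -> None:
    Path(path).write_text(
        yaml.safe_dump({k: float(v) for k, v in params.to_dict().items()}, sort_keys=True)
    )


def load_params(path) -> ModelParameters:
    data = yaml.safe_load(Path(path).read_text())
    return ModelParameters.from_dict(data)


def save_traces(traces: list[BudTrace], path) -> None:
    rows = []
    for t in traces:
        for bud, lengths in (("top", t.top), ("bottom", t.bottom)):
            for day, length in zip(t.times, lengths):
                rows.append(
                    {
                        "explant_id": t.explant_id,
                        "label": t.label,
                        "day": repr(float(day)),
                        "bud": bud,
                        "length_mm": repr(float(length)),
                        "excluded": int(t.excluded),
                        "source": t.source,
                    }
                )
    pd.DataFrame.from_records(rows).to_csv(path, sep="\t", index=False)


def load_traces(path) -> list[BudTrace]:
    df = pd.read_csv(path, sep="\t", dtype={"explant_id": str, "label": str},
                     float_precision="round_trip")
    df["day"] = df["day"].astype(float)
    df["length_mm"] = df["length_mm"].astype(float)
    traces = []
    for (explant_id, label), group in df.groupby(["explant_id", "label"], sort=True):
        top = group[group["bud"] == "top"].sort_values("day")
        bottom = group[group["bud"] == "bottom"].sort_values("day")
        if len(top) != len(bottom):
            raise ValueError(f"explant {explant_id}: top/bottom lengths differ")
        traces.append(
            BudTrace(
                explant_id=str(explant_id),
                label=str(label),
                times=top["day"].to_numpy(dtype=float),
                top=top["length_mm"].to_numpy(dtype=float),
                bottom=bottom["length_mm"].to_numpy(dtype=float),
                source=str(top["source"].iloc[0]) if "source" in top else "experimental",
                excluded=bool(top["excluded"].iloc[0]) if "excluded" in top else False,
            )
        )
    return traces


def save_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    df = traj.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=None)
    sidecar = {
        "params": traj.params.to_dict(),
        "scheme": traj.scheme,
        "seed": traj.seed,
        "dt": traj.dt,
        "clamp_count": traj.clamp_count,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Trajectory(
        times=df["t"].to_numpy(),
        values=df[["E", "F", "N", "M"]].to_numpy(),
        params=ModelParameters.from_dict(meta["params"]),
        scheme=meta["scheme"],
        seed=meta["seed"],
        dt=meta["dt"],
        clamp_count=meta["clamp_count"],
    )


def save_gridmap(gmap: GridMap, prefix) -> None:
    """Write ``<prefix>.<channel>.tsv`` per channel and ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, arr in gmap.cells.items():
        np.savetxt(prefix.parent / f"{prefix.name}.{name}.tsv", arr, delimiter="\t")
    sidecar = {
        "payload": gmap.payload,
        "v0_values": [repr(float(v)) for v in gmap.v0_values],
        "mu_values": [repr(float(v)) for v in gmap.mu_values],
        "channels": sorted(gmap.cells),
        "boundary_mask": None
        if gmap.boundary_mask is None
        else gmap.boundary_mask.astype(int).tolist(),
        "failure_mask": gmap.failure_mask.astype(int).tolist(),
        "provenance": gmap.provenance,
    }
    (prefix.parent / f"{prefix.name}.json").write_text(json.dumps(sidecar, indent=1))


def load_gridmap(prefix) -> GridMap:
    prefix = Path(prefix)
    sidecar = json.loads((prefix.parent / f"{prefix.name}.json").read_text())
    cells = {}
    for name in sidecar["channels"]:
        arr = np.loadtxt(prefix.parent / f"{prefix.name}.{name}.tsv", delimiter="\t", ndmin=2)
        if name in ("class_id", "n_stable"):
            arr = arr.astype(int)
        cells[name] = arr
    return GridMap(
        v0_values=np.array([float(v) for v in sidecar["v0_values"]]),
        mu_values=np.array([float(v) for v in sidecar["mu_values"]]),
        payload=sidecar["payload"],
        cells=cells,
        boundary_mask=None
        if sidecar["boundary_mask"] is None
        else np.array(sidecar["boundary_mask"], dtype=bool),
        failure_mask=np.array(sidecar["failure_mask"], dtype=bool),
        provenance=sidecar["provenance"],
    )
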