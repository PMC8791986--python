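"""Plain-text persistence: TSV tables with JSON sidecars.

Traces are TSV with ``time_s`` plus one value column; deflection fields
are TSV with ``time_s`` then ``fx_i``/``fy_i`` per pillar, with grid
geometry and the cell mask in a JSON sidecar; indentation curves are TSV
(``indentation_nm``, ``force_nN``) with probe metadata in a sidecar;
parameter sets round-trip as JSON with the exact dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DeflectionField, ForceTrace
from .fokker_planck import FPParams
from .hertz import IndentationCurve
from .kvm import KVMParams

__all__ = [
    "write_trace", "read_trace", "write_field", "read_field",
    "write_curve", "read_curve", "write_params", "read_params",
    "write_matrix", "read_matrix",
]


def write_trace(trace: ForceTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, sep="\t", index=False)


def read_trace(path, kind: str = "global") -> ForceTrace:
    df = pd.read_csv(path, sep="\t")
    return ForceTrace(times=df["time_s"].to_numpy(),
                      values=df.iloc[:, 1].to_numpy(), kind=kind)


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_field(field: DeflectionField, path) -> None:
    data = {"time_s": field.times}
    which = "forces" if field.forces is not None else "deflections"
    arr = getattr(field, which)
    if arr is None:
        raise ValueError("field holds neither forces nor deflections")
    for i in range(field.n_pillars):
        data[f"fx_{i}"] = arr[:, i, 0]
        data[f"fy_{i}"] = arr[:, i, 1]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    sidecar = {
        "grid_shape": list(field.grid_shape),
        "positions_um": field.positions.tolist(),
        "cell_mask": field.cell_mask.astype(int).tolist(),
        "channel": which,
    }
    _sidecar(path).write_text(json.dumps(sidecar))


def read_field(path) -> DeflectionField:
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(_sidecar(path).read_text())
    n = len(meta["cell_mask"])
    arr = np.stack(
        [np.column_stack([df[f"fx_{i}"], df[f"fy_{i}"]]) for i in range(n)],
        axis=1)
    kwargs = {meta["channel"]: arr}
    return DeflectionField(
        times=df["time_s"].to_numpy(),
        positions=np.asarray(meta["positions_um"], dtype=float),
        grid_shape=tuple(meta["grid_shape"]),
        cell_mask=np.asarray(meta["cell_mask"], dtype=bool), **kwargs)


def write_curve(curve: IndentationCurve, path) -> None:
    pd.DataFrame({"indentation_nm": curve.indentation,
                  "force_nN": curve.force}).to_csv(path, sep="\t", index=False)
    _sidecar(path).write_text(json.dumps({
        "probe_radius_um": curve.probe_radius_um,
        "poisson_nu": curve.poisson_nu,
        "cantilever_k": curve.cantilever_k,
    }))


def read_curve(path) -> IndentationCurve:
    df = pd.read_csv(path, sep="\t")
    side = _sidecar(path)
    kwargs = json.loads(side.read_text()) if side.exists() else {}
    return IndentationCurve(indentation=df["indentation_nm"].to_numpy(),
                            force=df["force_nN"].to_numpy(), **kwargs)


_PARAM_TYPES = {"kvm": KVMParams, "fp": FPParams}


def write_params(params, path) -> None:
    kind = "kvm" if isinstance(params, KVMParams) else "fp"
    payload = {"type": kind, **dataclasses.asdict(params)}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path):
    payload = json.loads(Path(path).read_text())
    cls = _PARAM_TYPES[payload.pop("type")]
    return cls(**payload)


def write_matrix(matrix, path, col_prefix: str = "c") -> None:
    matrix = np.asarray(matrix, dtype=float)
    cols = [f"{col_prefix}{j}" for j in range(matrix.shape[1])]
    pd.DataFrame(matrix, columns=cols).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)
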