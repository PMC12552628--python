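"""Reading and writing stacks, fields and manifests.

Real-valued frame stacks travel as multi-page TIFF; complex stacks and
fields as HDF5 with separate ``real``/``imag`` datasets.  Every stack is
accompanied by a JSON sidecar recording mode, seed and simulation
parameters so a reconstruction can be re-run from disk alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .optics import ComplexField
from .simulate import FrameStack

__all__ = [
    "save_stack",
    "load_stack",
    "save_field",
    "load_field",
    "save_measurement_matrix",
    "load_measurement_matrix",
    "write_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def save_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack (TIFF for real data, HDF5 for complex) + sidecar."""
    path = Path(path)
    if stack.mode == "incoherent":
        tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("real", data=stack.frames.real)
            f.create_dataset("imag", data=stack.frames.imag)
    write_json(
        _sidecar(path),
        {"mode": stack.mode, "seed": stack.seed, "meta": stack.meta},
    )


def load_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    side = _sidecar(path)
    info = json.loads(side.read_text()) if side.exists() else {}
    mode = info.get("mode")
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = np.asarray(tifffile.imread(path), dtype=float)
        mode = mode or "incoherent"
    else:
        with h5py.File(path, "r") as f:
            frames = f["real"][()] + 1j * f["imag"][()]
        mode = mode or "coherent"
    return FrameStack(
        frames=frames, mode=mode, seed=info.get("seed"), meta=info.get("meta", {})
    )


def save_measurement_matrix(A, path: str | Path) -> None:
    """Write a MeasurementMatrix to HDF5 (columns + row-to-frequency map)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("columns_real", data=A.columns.real)
        f.create_dataset("columns_imag", data=A.columns.imag)
        f.create_dataset("k_index", data=A.k_index)
        if A.mean_frame is not None:
            f.create_dataset("mean_frame", data=A.mean_frame)
        f.attrs["grid_shape"] = A.grid_shape
        f.attrs["mode"] = A.mode
        if A.lowpass_frac is not None:
            f.attrs["lowpass_frac"] = A.lowpass_frac


def load_measurement_matrix(path: str | Path):
    from .matrixops import MeasurementMatrix

    with h5py.File(path, "r") as f:
        cols = f["columns_real"][()] + 1j * f["columns_imag"][()]
        return MeasurementMatrix(
            columns=cols,
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            mode=str(f.attrs["mode"]),
            mean_frame=f["mean_frame"][()] if "mean_frame" in f else None,
            lowpass_frac=float(f.attrs["lowpass_frac"])
            if "lowpass_frac" in f.attrs
            else None,
        )


def save_field(field: ComplexField, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=field.field.real)
        f.create_dataset("imag", data=field.field.imag)
        f.attrs["pitch_um"] = field.pitch_um
        f.attrs["plane"] = field.plane


def load_field(path: str | Path) -> ComplexField:
    with h5py.File(path, "r") as f:
        arr = f["real"][()] + 1j * f["imag"][()]
        return ComplexField(
            field=arr,
            pitch_um=float(f.attrs.get("pitch_um", 1.0)),
            plane=str(f.attrs.get("plane", "scatt")),
        )
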