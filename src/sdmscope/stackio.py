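"""OME-TIFF image stack reader/writer.

Stacks are written with a declared TZYX axis order; modality, timestamps
and settings travel in a JSON sidecar next to the TIFF.  A plain 2D TIFF
read back is promoted to T=1, Z=1 with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .synthetic_scope import ImageStack, Modality


class StackReadError(RuntimeError):
    pass


def save_spectra_grid(spectra, path: str | Path, step_um: float,
                      timestamp_s: float = 0.0) -> Path:
    """Write a rectangular grid of spectra to an HDF5 container."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    axis = spectra[0][0].freq_axis_GHz
    counts = np.stack([np.stack([s.counts for s in row]) for row in spectra])
    with h5py.File(path, "w") as fh:
        fh.create_dataset("freq_axis_GHz", data=axis)
        fh.create_dataset("counts", data=counts)
        fh.attrs["dwell_s"] = spectra[0][0].dwell_s
        fh.attrs["step_um"] = step_um
        fh.attrs["timestamp_s"] = timestamp_s
    return path


def load_spectra_grid(path: str | Path):
    """Read an HDF5 spectra container -> (grid of Spectrum, step_um, t)."""
    import h5py

    from .synthetic_scope import Spectrum

    with h5py.File(path, "r") as fh:
        axis = fh["freq_axis_GHz"][...]
        counts = fh["counts"][...]
        dwell = float(fh.attrs.get("dwell_s", 0.1))
        step = float(fh.attrs.get("step_um", 1.0))
        ts = float(fh.attrs.get("timestamp_s", 0.0))
    grid = [[Spectrum(freq_axis_GHz=axis, counts=counts[i, j], dwell_s=dwell,
                      pixel_index=(i, j))
             for j in range(counts.shape[1])] for i in range(counts.shape[0])]
    return grid, step, ts


def save_dataset(examples, manifest: dict, out_dir: str | Path) -> Path:
    """Write a labeled dataset as OME-TIFF tensors plus a JSON manifest."""
    from .synthetic_scope import ImageStack, Modality

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for ex, entry in zip(examples, manifest["entries"]):
        name = f"example_{ex.cell_id:04d}.ome.tif"
        stack = ImageStack(
            data=ex.tensor,
            timestamps_s=np.arange(ex.tensor.shape[0], dtype=np.float64),
            modality=Modality(manifest.get("modality", "FLUOR")),
            position=ex.cell_id)
        write_stack(stack, out / name)
        entry = dict(entry)
        entry["path"] = name
        entries.append(entry)
    manifest = dict(manifest)
    manifest["entries"] = entries
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_dataset(in_dir: str | Path):
    """Read back a dataset written by :func:`save_dataset`."""
    from .synthetic_scope import LabeledExample

    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    examples = []
    for entry in manifest["entries"]:
        stack = read_stack(in_dir / entry["path"])
        tto = entry.get("t0_offset_s")
        examples.append(LabeledExample(
            tensor=stack.data, label=int(entry["label"]),
            cell_id=int(entry["id"]),
            time_to_onset_s=float("nan") if tto is None else float(tto)))
    return examples, manifest


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data, ome=True, photometric="minisblack",
                     metadata={"axes": "TZYX"})
    sidecar = {
        "axes": "TZYX",
        "shape": list(stack.data.shape),
        "modality": stack.modality.value,
        "position": stack.position,
        "timestamps_s": [float(t) for t in stack.timestamps_s],
        "settings": stack.settings,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            axes = series.axes
            data = series.asarray()
    except Exception as exc:  # corrupt or not a TIFF
        raise StackReadError(f"cannot read image stack from {path}: {exc}") from exc

    sidecar_shape = None
    sc = path.with_suffix(path.suffix + ".json")
    if sc.exists():
        try:
            sidecar_shape = json.loads(sc.read_text()).get("shape")
        except (json.JSONDecodeError, OSError):
            sidecar_shape = None
    if sidecar_shape is not None and int(np.prod(sidecar_shape)) == data.size:
        # the writer's sidecar is authoritative: restores squeezed axes
        data = data.reshape(sidecar_shape)
        axes = "TZYX"
    elif data.ndim == 2:
        warnings.warn(f"{path}: plain 2D TIFF promoted to T=1, Z=1 stack")
        data = data[None, None]
        axes = "TZYX"
    elif data.ndim == 4 and axes in ("TZYX", "QQYX", "ZTYX"):
        if axes == "ZTYX":
            data = np.swapaxes(data, 0, 1)
    elif data.ndim == 3 and axes.endswith("YX"):
        # single leading axis: treat as Z
        data = data[None]
        axes = "TZYX"
    else:
        raise StackReadError(
            f"{path}: unsupported or missing axis metadata (axes={axes!r})")

    sidecar_path = path.with_suffix(path.suffix + ".json")
    modality = Modality.FLUOR
    position = 0
    timestamps = np.arange(data.shape[0], dtype=np.float64)
    settings: dict = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        modality = Modality(meta.get("modality", "FLUOR"))
        position = int(meta.get("position", 0))
        ts = meta.get("timestamps_s")
        if ts is not None and len(ts) == data.shape[0]:
            timestamps = np.asarray(ts, dtype=np.float64)
        settings = meta.get("settings", {})
    return ImageStack(data=np.clip(np.asarray(data, dtype=np.float32), 0, None),
                      timestamps_s=timestamps, modality=modality,
                      position=position, settings=settings)
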