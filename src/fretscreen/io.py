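"""On-disk formats: multi-page TIFF stacks with JSON metadata sidecars.

A dual-channel stack is stored as one grayscale 16-bit multi-page TIFF with
pages interleaved donor-first (page 2i = donor frame i, page 2i+1 = acceptor
frame i) next to a ``.json`` sidecar holding the acquisition metadata
(axis kind, frame interval or z plan, pixel size, seed).  CSV outputs are
comma-separated, UTF-8, '.' decimal; times in seconds, positions in pixels
unless suffixed ``_um``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stacks import ChannelStack

__all__ = ["write_stack", "read_stack", "write_template", "read_template", "write_csv"]

_REQUIRED = ("axis", "pixel_size_um")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(
    path: str | Path,
    stack: ChannelStack,
    seed: int | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write a stack as interleaved 16-bit TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n, h, w = stack.shape
    pages = np.empty((2 * n, h, w), dtype=np.uint16)
    pages[0::2] = np.clip(np.round(stack.donor), 0, 65535).astype(np.uint16)
    pages[1::2] = np.clip(np.round(stack.acceptor), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "axis": stack.axis,
        "n_frames": n,
        "pixel_size_um": stack.pixel_size_um,
        "exposure_ms": stack.exposure_ms,
        "channels": list(stack.channels),
        "page_order": "donor_first",
        "seed": seed,
    }
    if stack.axis == "time":
        meta["frame_interval_s"] = stack.frame_interval_s
    else:
        meta["z_values_um"] = [float(z) for z in stack.z_values_um]
    if extra_meta:
        meta.update(extra_meta)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ChannelStack:
    """Read a stack written by :func:`write_stack`; pixel data unmodified.

    Raises on odd page counts and on missing required sidecar fields,
    naming the field.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in _REQUIRED:
        if key not in meta:
            raise KeyError(f"sidecar {sidecar} is missing required field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 2 != 0:
        raise ValueError(f"{path}: odd page count {pages.shape[0]}; expected interleaved channels")
    donor, acceptor = pages[0::2], pages[1::2]
    axis = meta["axis"]
    if axis == "time":
        if "frame_interval_s" not in meta:
            raise KeyError(f"sidecar {sidecar} is missing required field 'frame_interval_s'")
        stack = ChannelStack(
            donor, acceptor, axis="time",
            pixel_size_um=meta["pixel_size_um"],
            exposure_ms=meta.get("exposure_ms", 80.0),
            frame_interval_s=meta["frame_interval_s"],
        )
    else:
        if "z_values_um" not in meta:
            raise KeyError(f"sidecar {sidecar} is missing required field 'z_values_um'")
        stack = ChannelStack(
            donor, acceptor, axis="z",
            pixel_size_um=meta["pixel_size_um"],
            exposure_ms=meta.get("exposure_ms", 80.0),
            z_values_um=np.asarray(meta["z_values_um"], dtype=float),
        )
    stack.meta = meta
    return stack


def write_template(path: str | Path, patch: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(patch, dtype=np.float32))
    return path


def read_template(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic CSV output (fixed float formatting, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.8g")
    return path
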