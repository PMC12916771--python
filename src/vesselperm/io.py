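"""Reading and writing calibrated TIFF/OME-TIFF stacks.

Calibration (pixel size, frame interval) is carried in OME metadata when
writing. When reading a plain multi-page TIFF that lacks it, values must be
supplied explicitly or through a JSON/YAML sidecar file named
``<stack>.calib.json`` / ``<stack>.calib.yaml`` next to the stack.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .stack import FrameStack

__all__ = ["read_stack", "write_stack", "max_project", "CalibrationError"]


class CalibrationError(ValueError):
    """Raised when a stack has no usable pixel size / frame interval."""


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as OME-TIFF (axes TCYX or TZCYX) with calibration metadata."""
    path = Path(path)
    if stack.has_z:
        # OME canonical order TZCYX
        data = np.moveaxis(stack.pixels, 2, 1)
        axes = "TZCYX"
    else:
        data = stack.pixels
        axes = "TCYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeX": stack.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size,
        "PhysicalSizeYUnit": "µm",
        "TimeIncrement": stack.frame_interval,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.z_step is not None:
        metadata["PhysicalSizeZ"] = stack.z_step
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, data.astype(np.float32), ome=True, metadata=metadata)


def _sidecar_calibration(path: Path) -> dict:
    for suffix, loader in ((".calib.json", json.load), (".calib.yaml", yaml.safe_load)):
        sidecar = path.with_suffix(path.suffix + suffix) if False else Path(
            str(path) + suffix
        )
        if sidecar.exists():
            with open(sidecar) as fh:
                return loader(fh) or {}
    return {}


def _ome_calibration(tif: tifffile.TiffFile) -> dict:
    out: dict = {}
    if not tif.is_ome or tif.ome_metadata is None:
        return out
    xml = tif.ome_metadata
    m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', xml)
    if m:
        out["pixel_size"] = float(m.group(1))
    m = re.search(r'TimeIncrement="([\d.eE+-]+)"', xml)
    if m:
        out["frame_interval"] = float(m.group(1))
    m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', xml)
    if m:
        out["z_step"] = float(m.group(1))
    out["channel_names"] = re.findall(r'<Channel[^>]*Name="([^"]+)"', xml)
    return out


def read_stack(
    path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    z_step: float | None = None,
    channel_names: list[str] | None = None,
) -> FrameStack:
    """Read a TIFF/OME-TIFF stack into a :class:`FrameStack`.

    Explicit arguments override OME metadata, which overrides a sidecar
    calibration file. Missing pixel size or frame interval is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        meta = _ome_calibration(tif)

    meta = {**_sidecar_calibration(path), **{k: v for k, v in meta.items() if v}}
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    frame_interval = (
        frame_interval if frame_interval is not None else meta.get("frame_interval")
    )
    z_step = z_step if z_step is not None else meta.get("z_step")
    channel_names = channel_names or meta.get("channel_names") or None

    if pixel_size is None or frame_interval is None:
        raise CalibrationError(
            f"{path.name}: pixel size / frame interval not in metadata or sidecar; "
            "pass them explicitly"
        )

    data = _to_tc_order(data, axes)
    return FrameStack(
        pixels=data,
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
        z_step=z_step,
        channel_names=list(channel_names) if channel_names else [],
    )


def _to_tc_order(data: np.ndarray, axes: str) -> np.ndarray:
    """Rearrange a tifffile series into (T, C, [Z,] Y, X)."""
    axes = axes.replace("S", "C")  # treat samples as channels
    if axes in ("YX", "QQ", ""):
        return data[None, None]
    if "Q" in axes:  # unidentified leading axes: collapse into time
        data = data.reshape((-1,) + data.shape[-2:])
        axes = "TYX"
    if set(axes) - set("TZCYX"):
        raise ValueError(f"unsupported axes {axes!r}")
    # insert missing singleton axes
    for ax in "TZC":
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in ("T", "C", "Z", "Y", "X")]
    data = np.transpose(data, order)
    if data.shape[2] == 1:  # drop singleton z
        data = data[:, :, 0]
    return data


def max_project(stack: FrameStack) -> FrameStack:
    """Maximum-intensity projection over z; time and channels preserved."""
    if not stack.has_z:
        raise ValueError("stack has no z axis to project")
    projected = stack.pixels.max(axis=2)
    return FrameStack(
        pixels=projected,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        z_step=None,
        channel_names=list(stack.channel_names),
        origin_time=stack.origin_time,
    )
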