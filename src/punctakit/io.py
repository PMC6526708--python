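"""Reading and writing movies, masks and tables.

Movies travel as single-channel multi-page TIFF (one page per frame, 16-bit
unsigned on write) with the two calibration constants in a YAML sidecar named
``<stem>.yaml`` next to the stack; explicit calibration overrides the
sidecar.  OME-TIFF physical pixel sizes are honored when present.  Masks are
written as 8-bit 0/255 stacks; tables as CSV with units in the header names.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .movie import Movie


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.suffix == "" else path.with_suffix(".yaml")


def write_movie(movie: Movie, path: str | Path, dtype=np.uint16) -> Path:
    """Write a movie as multi-page TIFF + YAML calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = movie.frames
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        frames = np.clip(np.round(frames), info.min, info.max).astype(dtype)
    else:
        frames = frames.astype(dtype)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        yaml.safe_dump(
            {
                "pixel_size_um": float(movie.pixel_size_um),
                "frame_interval_s": float(movie.frame_interval_s),
                "channel": movie.channel,
            },
            sort_keys=True,
        )
    )
    return path


def _ome_calibration(tif: tifffile.TiffFile) -> dict:
    """Pull pixel size / frame interval from OME metadata when present."""
    out: dict = {}
    try:
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                size = px.get("PhysicalSizeX")
                if size is not None:
                    out["pixel_size_um"] = float(size)
                dt = px.get("TimeIncrement")
                if dt is not None:
                    out["frame_interval_s"] = float(dt)
    except Exception:
        pass
    return out


def read_movie(
    path: str | Path,
    pixel_size_um: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
    channel: Optional[str] = None,
) -> Movie:
    """Read a single-channel TIFF stack with calibration resolution.

    Calibration priority: explicit arguments > YAML sidecar > OME metadata.
    Missing calibration after all three is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = _ome_calibration(tif)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path} is not a single-channel T×H×W stack (shape {frames.shape})"
        )
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(yaml.safe_load(sidecar.read_text()) or {})
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    if frame_interval_s is not None:
        meta["frame_interval_s"] = frame_interval_s
    if channel is not None:
        meta["channel"] = channel
    if "pixel_size_um" not in meta or "frame_interval_s" not in meta:
        raise ValueError(
            f"no calibration for {path}: supply pixel_size_um/frame_interval_s "
            "explicitly or via sidecar/OME metadata"
        )
    return Movie(
        frames.astype(float),
        float(meta["pixel_size_um"]),
        float(meta["frame_interval_s"]),
        channel=str(meta.get("channel", "unnamed")),
    )


def write_masks(masks: np.ndarray, path: str | Path) -> Path:
    """Write a boolean T×H×W mask stack as 8-bit 0/255 multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(masks, bool) * np.uint8(255)), photometric="minisblack")
    return path


def read_masks(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack > 0
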