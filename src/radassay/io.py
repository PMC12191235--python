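"""Image containers and file I/O.

A :class:`FrameStack` is one field of view at one timepoint: a dict of named
2-D channel images (``red`` = mApple, ``green`` = GC150, ``blue`` = DAPI)
plus acquisition metadata. Timelapse experiments are lists of FrameStacks.

On disk a timelapse is a single multi-page TIFF, one page per channel per
timepoint, each page carrying a JSON description tag with its channel name,
timepoint and field-of-view id, so the stack round-trips without side files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = ["FrameStack", "write_timelapse", "read_timelapse"]


@dataclass
class FrameStack:
    """Multi-channel image(s) of one field of view at one timepoint.

    Parameters
    ----------
    channels
        Mapping from channel name (``red``/``green``/``blue``) to a 2-D
        intensity array (arbitrary units, non-negative).
    timepoint_h
        Hours post-irradiation.
    fov
        Field-of-view identifier.
    pixel_size_um
        Physical pixel size in micrometres per pixel, if known.
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    timepoint_h: float = 0.0
    fov: str = "fov0"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(img).shape for name, img in self.channels.items()}
        if shapes:
            first = next(iter(shapes.values()))
            if len(first) != 2:
                raise ValueError(f"channel images must be 2-D, got shape {first}")
            for name, shape in shapes.items():
                if shape != first:
                    raise ValueError(
                        f"channel {name!r} shape {shape} differs from {first}"
                    )
        for name, img in self.channels.items():
            arr = np.asarray(img)
            if not np.isfinite(arr).all():
                raise ValueError(f"channel {name!r} contains non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        if not self.channels:
            return (0, 0)
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(
                f"channel {channel!r} not present; have {sorted(self.channels)}"
            ) from None


def write_timelapse(path: str | Path, frames: list[FrameStack]) -> Path:
    """Write frames as a multi-page TIFF, one page per channel per timepoint."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for frame in frames:
            for name, img in frame.channels.items():
                meta = {
                    "channel": name,
                    "timepoint_h": frame.timepoint_h,
                    "fov": frame.fov,
                    "pixel_size_um": frame.pixel_size_um,
                }
                tif.write(
                    np.asarray(img, dtype=np.float32),
                    description=json.dumps(meta),
                    contiguous=False,
                )
    return path


def read_timelapse(
    path: str | Path, channel_map: Mapping[str, str] | None = None
) -> list[FrameStack]:
    """Read a timelapse TIFF back into FrameStacks, grouped by timepoint.

    ``channel_map`` optionally renames on-disk channel names (for TIFFs from
    external microscopes whose tags use vendor channel labels).
    """
    pages: list[tuple[dict, np.ndarray]] = []
    with tifffile.TiffFile(Path(path)) as tif:
        for i, page in enumerate(tif.pages):
            desc = page.description or "{}"
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = {}
            meta.setdefault("channel", f"ch{i}")
            meta.setdefault("timepoint_h", 0.0)
            meta.setdefault("fov", "fov0")
            pages.append((meta, page.asarray()))

    frames: dict[tuple[str, float], FrameStack] = {}
    for meta, img in pages:
        name = meta["channel"]
        if channel_map is not None:
            name = channel_map.get(name, name)
        key = (meta["fov"], float(meta["timepoint_h"]))
        if key not in frames:
            frames[key] = FrameStack(
                channels={},
                timepoint_h=float(meta["timepoint_h"]),
                fov=meta["fov"],
                pixel_size_um=meta.get("pixel_size_um"),
            )
        frames[key].channels[name] = img
    return [frames[k] for k in sorted(frames, key=lambda k: (k[0], k[1]))]
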