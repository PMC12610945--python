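"""Multi-channel scene container and TIFF round-trip.

A :class:`Scene` holds the named 2-D fluorescence channels of one imaged
well (one field of view), together with optional label masks and the study
labels needed downstream (well, condition, timepoint).  Scenes are written
as multi-page TIFFs (one page per channel) with a JSON sidecar carrying the
channel names and metadata; label masks go to separate 16-bit TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Scene", "write_scene", "read_scene"]


@dataclass
class Scene:
    """Named 2-D intensity channels of one well, plus optional label masks.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D float array in arbitrary
        fluorescence units.  All channels must share one shape.
    masks
        Optional label images (``uint16``-compatible; 0 = background)
        sharing the channel shape, e.g. ``"nuclei"`` or ``"cytoplasm"``.
    pixel_size_um
        Physical pixel size in micrometres per pixel, if known.
    """

    channels: dict[str, np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size_um: float | None = None
    well_id: str = ""
    condition: str = ""
    timepoint_days: int | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a Scene needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        shapes |= {np.asarray(a).shape for a in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels/masks disagree on shape: {shapes}")
        if any(np.asarray(a).ndim != 2 for a in self.channels.values()):
            raise ValueError("channels must be 2-D arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"scene has no channel {name!r}; available: {sorted(self.channels)}"
            ) from None


def write_scene(scene: Scene, path: str | Path) -> Path:
    """Write a scene as a multi-page TIFF plus a JSON sidecar.

    Channel order in the TIFF follows the sidecar's ``channel_names`` list.
    Masks are written next to it as ``<stem>.mask-<name>.tif`` (uint16).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(scene.channels)
    stack = np.stack([np.asarray(scene.channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(path, stack)
    for mname, mask in scene.masks.items():
        tifffile.imwrite(
            path.with_name(f"{path.stem}.mask-{mname}.tif"),
            np.asarray(mask, dtype=np.uint16),
        )
    sidecar = {
        "channel_names": names,
        "mask_names": list(scene.masks),
        "pixel_size_um": scene.pixel_size_um,
        "well_id": scene.well_id,
        "condition": scene.condition,
        "timepoint_days": scene.timepoint_days,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_scene(path: str | Path) -> Scene:
    """Read a scene written by :func:`write_scene`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {n: stack[i] for i, n in enumerate(meta["channel_names"])}
    masks = {}
    for mname in meta.get("mask_names", []):
        masks[mname] = tifffile.imread(path.with_name(f"{path.stem}.mask-{mname}.tif"))
    return Scene(
        channels=channels,
        masks=masks,
        pixel_size_um=meta.get("pixel_size_um"),
        well_id=meta.get("well_id", ""),
        condition=meta.get("condition", ""),
        timepoint_days=meta.get("timepoint_days"),
    )
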