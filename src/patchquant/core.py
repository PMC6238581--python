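"""Core container for time-lapse Z-stacks and their TIFF round trip.

A :class:`MovieStack` holds a ``(T, Z, Y, X)`` float array together with the
acquisition metadata the downstream analysis needs (frame interval in seconds,
Z spacing in micrometers).  Calibration images are single-time-point stacks
(``T == 1``).  On disk the pages are T-major/Z-minor multi-page TIFF with the
axis order and metadata recorded in the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import DimensionError

__all__ = ["MovieStack"]


@dataclass
class MovieStack:
    """A ``(T, Z, Y, X)`` intensity array with acquisition metadata.

    Parameters
    ----------
    data : ndarray
        Four-dimensional intensity array in ADU (camera digital units).
    frame_interval : float
        Time between frames, seconds.
    z_spacing : float
        Distance between Z-sections, micrometers.
    meta : dict
        Free-form provenance (crop box, correction parameters, ...).
    """

    data: np.ndarray
    frame_interval: float = 1.0
    z_spacing: float = 0.6
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionError(
                f"MovieStack data must be (T, Z, Y, X); got shape {self.data.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def sum_projection(self) -> np.ndarray:
        """Per-pixel sum over Z: ``(T, Y, X)``.

        Sum (not max) projection keeps intensities proportional to total
        fluorophore content, which every quantitative step relies on.
        """
        return self.data.sum(axis=1)

    def with_data(self, data: np.ndarray, **meta) -> "MovieStack":
        """Copy of this stack with new pixel data and updated metadata."""
        new_meta = {**self.meta, **meta}
        return replace(self, data=np.asarray(data), meta=new_meta)

    # -- disk round trip ------------------------------------------------
    def to_tiff(self, path) -> None:
        """Write as multi-page TIFF, pages ordered T-major then Z."""
        t, z, y, x = self.data.shape
        desc = json.dumps(
            {
                "axes": "TZYX",
                "n_frames": t,
                "n_z": z,
                "frame_interval_s": self.frame_interval,
                "z_spacing_um": self.z_spacing,
                "meta": _jsonable(self.meta),
            }
        )
        tifffile.imwrite(
            path,
            self.data.reshape(t * z, y, x).astype(np.float32),
            description=desc,
            metadata=None,
        )

    @classmethod
    def from_tiff(cls, path) -> "MovieStack":
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
        info = json.loads(desc)
        t, z = info["n_frames"], info["n_z"]
        data = pages.reshape(t, z, *pages.shape[-2:]).astype(np.float64)
        return cls(
            data=data,
            frame_interval=info["frame_interval_s"],
            z_spacing=info["z_spacing_um"],
            meta=info.get("meta", {}),
        )


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
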