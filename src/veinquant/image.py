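"""Core containers: multi-channel vein images and cell-label maps.

A :class:`VeinImage` is a 2-channel pixel grid — channel 0 carries the general
wall stain (calcofluor-white-like), channel 1 the plasma-membrane marker
(AtSWEET11–GFP-like) — together with the physical pixel size.  A
:class:`CellMap` is an integer label map (0 = background) plus a table
assigning each label a cell type: XY (xylem), SE (sieve element), CC
(companion cell), PP (phloem parenchyma), BS (bundle sheath) or OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import EmptyInputError

#: Recognised cell types.
CELL_TYPES = ("XY", "SE", "CC", "PP", "BS", "OTHER")

#: Cell types counted as phloem tissue.
PHLOEM_TYPES = ("SE", "CC", "PP")

#: Cell types whose combined area defines the vascular-bundle (vein) size.
VASCULAR_TYPES = ("XY", "SE", "CC", "PP")

WALL_CHANNEL = 0
MARKER_CHANNEL = 1


@dataclass
class VeinImage:
    """2-channel image of a vein cross-section.

    Parameters
    ----------
    channels : ndarray, shape (2, H, W)
        Channel 0 = wall stain, channel 1 = membrane marker.  Stored as
        float64 internally; intensities are arbitrary units >= 0.
    pixel_size : float
        Physical pixel edge length in micrometres.
    """

    channels: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != 2:
            raise EmptyInputError(
                f"expected channel array of shape (2, H, W), got {self.channels.shape}"
            )
        if self.pixel_size <= 0:
            raise EmptyInputError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def wall(self) -> np.ndarray:
        return self.channels[WALL_CHANNEL]

    @property
    def marker(self) -> np.ndarray:
        return self.channels[MARKER_CHANNEL]

    def copy(self) -> "VeinImage":
        return VeinImage(self.channels.copy(), self.pixel_size, dict(self.meta))

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write as 2-channel OME-TIFF (uint16, values clipped and rounded)."""
        data = np.clip(np.rint(self.channels), 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            data,
            ome=True,
            datetime=False,
            metadata={
                "axes": "CYX",
                "PhysicalSizeX": self.pixel_size,
                "PhysicalSizeY": self.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
            },
        )

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None) -> "VeinImage":
        """Read a 2-channel TIFF / OME-TIFF; pixel size from OME metadata
        unless given explicitly."""
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            if pixel_size is None:
                try:
                    import xml.etree.ElementTree as ET

                    root = ET.fromstring(tif.ome_metadata)
                    ns = {"ome": root.tag.split("}")[0].strip("{")}
                    px = root.find(".//ome:Pixels", ns)
                    pixel_size = float(px.attrib["PhysicalSizeX"])
                except Exception as exc:  # pragma: no cover - malformed metadata
                    raise EmptyInputError(
                        f"{path}: pixel size not given and not readable from metadata"
                    ) from exc
        if data.ndim != 3 or data.shape[0] != 2:
            raise EmptyInputError(f"{path}: expected 2-channel image, got {data.shape}")
        return cls(data.astype(np.float64), pixel_size)


@dataclass
class CellMap:
    """Integer cell-label map with per-cell type annotations.

    ``labels`` is a 2D integer grid; 0 means background.  ``types`` maps each
    nonzero label to one of :data:`CELL_TYPES`.
    """

    labels: np.ndarray
    pixel_size: float
    types: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise EmptyInputError("label map must be 2-D")
        if self.pixel_size <= 0:
            raise EmptyInputError("pixel_size must be positive")
        self.types = dict(self.types)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.types)
        if missing:
            raise EmptyInputError(f"labels missing from type table: {sorted(missing)}")
        bad = {t for t in self.types.values() if t not in CELL_TYPES}
        if bad:
            raise EmptyInputError(f"unknown cell types: {sorted(bad)}")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def cells_of_type(self, *types: str) -> list[int]:
        return [c for c in self.cell_ids if self.types[c] in types]

    def mask(self, cell: int) -> np.ndarray:
        return self.labels == cell

    def centroid(self, cell: int) -> np.ndarray:
        """(row, col) centroid of a cell, in pixels."""
        rr, cc = np.nonzero(self.labels == cell)
        if rr.size == 0:
            raise EmptyInputError(f"cell {cell} not present in label map")
        return np.array([rr.mean(), cc.mean()])

    # ------------------------------------------------------------------ I/O
    def save(self, label_path: str | Path, types_path: str | Path) -> None:
        tifffile.imwrite(str(label_path), self.labels.astype(np.uint16))
        pd.DataFrame(
            {"label": list(self.types), "type": list(self.types.values())}
        ).to_csv(types_path, index=False)

    @classmethod
    def load(
        cls, label_path: str | Path, types_path: str | Path, pixel_size: float
    ) -> "CellMap":
        labels = tifffile.imread(str(label_path)).astype(np.int64)
        table = pd.read_csv(types_path)
        for col in ("label", "type"):
            if col not in table.columns:
                raise EmptyInputError(f"{types_path}: missing column '{col}'")
        types = dict(zip(table["label"].astype(int), table["type"].astype(str)))
        return cls(labels, pixel_size, types)
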