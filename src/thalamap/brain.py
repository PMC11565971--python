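"""Annotated experimental brain: serial coronal sections plus annotations.

The container mirrors what the annotation workflow produces: ordered
coronal sections at a known thickness and pixel pitch, a fiducial set, a
per-section bounding-box series, and a cell table.  Section images are
optional — every downstream computation except intensity scoring works
from the annotation tables alone.

Brain-space coordinates follow the package convention: ``(ap, dv, ml)``
in μm with ``ap = section_index * section_thickness_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .registration import BoundingBoxSeries, FiducialSet

CELL_COLUMNS = ("section_index", "ml_um", "dv_um", "raw_intensity")


@dataclass
class AnnotatedBrain:
    """Ordered coronal sections with fiducial, box, and cell annotations.

    ``cells`` is a DataFrame with at least ``section_index``, ``ml_um``,
    ``dv_um`` and ``raw_intensity`` columns; each cell's AP position is
    implied by its section.
    """

    brain_id: str
    section_thickness_um: float
    pixel_um: float
    fiducials: FiducialSet
    boxes: BoundingBoxSeries
    cells: pd.DataFrame
    images: dict[int, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        if self.section_thickness_um <= 0 or self.pixel_um <= 0:
            raise ValueError("section thickness and pixel pitch must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_points(self) -> np.ndarray:
        """Cell coordinates as (n, 3) ``(ap, dv, ml)`` μm points."""
        ap = self.cells["section_index"].to_numpy(dtype=float) * self.section_thickness_um
        return np.column_stack(
            [ap, self.cells["dv_um"].to_numpy(dtype=float), self.cells["ml_um"].to_numpy(dtype=float)]
        )

    # ------------------------------------------------------------------
    # I/O: per-section TIFF + CSV annotation tables + JSON metadata
    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.fiducials.to_frame().to_csv(d / "fiducials.csv", index=False)
        self.boxes.to_frame().to_csv(d / "boxes.csv", index=False)
        self.cells.to_csv(d / "cells.csv", index=False)
        (d / "brain.json").write_text(
            json.dumps(
                {
                    "brain_id": self.brain_id,
                    "section_thickness_um": self.section_thickness_um,
                    "pixel_um": self.pixel_um,
                    "meta": self.meta,
                },
                indent=2,
            )
        )
        for idx, img in self.images.items():
            tifffile.imwrite(d / f"section_{idx:04d}.tif", img)
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "AnnotatedBrain":
        d = Path(directory)
        payload = json.loads((d / "brain.json").read_text())
        images = {}
        for p in sorted(d.glob("section_*.tif")):
            images[int(p.stem.split("_")[1])] = tifffile.imread(p)
        return cls(
            brain_id=payload["brain_id"],
            section_thickness_um=payload["section_thickness_um"],
            pixel_um=payload["pixel_um"],
            fiducials=FiducialSet.from_frame(pd.read_csv(d / "fiducials.csv")),
            boxes=BoundingBoxSeries.from_frame(pd.read_csv(d / "boxes.csv")),
            cells=pd.read_csv(d / "cells.csv"),
            images=images,
            meta=payload.get("meta", {}),
        )
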