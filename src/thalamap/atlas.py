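"""Reference atlas container: a 3D region-label volume plus a region table.

Coordinate conventions used throughout the package:

* Points are ``(ap, dv, ml)`` triples in micrometres (μm).
* AP increases posteriorly; DV increases ventrally.
* ML is signed, with the midline at ``ml = 0``.
* Voxel index ``(i, j, k)`` maps to ``ap = i * voxel_um``,
  ``dv = j * voxel_um`` and ``ml = (k - (n_ml - 1) / 2) * voxel_um``,
  so the midline falls on the centre of the ML axis.

The atlas carries its own programmatically defined fiducial landmarks and
per-plane bounding boxes so it can serve as the *source* of the
registration chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .registration import BoundingBoxSeries, FiducialSet

OUTSIDE_REGION = 0  # label value reserved for "not in any region"


@dataclass
class AtlasVolume:
    """A 3D label grid at fixed voxel pitch with a region lookup table.

    Parameters
    ----------
    labels
        ``uint16`` array of shape ``(n_ap, n_dv, n_ml)``; 0 means outside
        any region.
    voxel_um
        Isotropic voxel pitch in μm (10 μm for the published atlases).
    regions
        DataFrame with columns ``region_id`` and ``name``.
    fiducials, boxes
        The atlas-side registration landmarks, defined programmatically.
    """

    labels: np.ndarray
    voxel_um: float
    regions: pd.DataFrame
    fiducials: FiducialSet | None = None
    boxes: BoundingBoxSeries | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D array")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def ml_center_index(self) -> float:
        return (self.shape[2] - 1) / 2.0

    def um_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each ``(ap, dv, ml)`` μm point.

        Ties are broken toward the lower index (lexicographic on the
        voxel grid) via round-half-down, keeping assignment deterministic.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.empty_like(pts)
        idx[:, 0] = pts[:, 0] / self.voxel_um
        idx[:, 1] = pts[:, 1] / self.voxel_um
        idx[:, 2] = pts[:, 2] / self.voxel_um + self.ml_center_index
        # round half down: ceil(x - 0.5)
        return np.ceil(idx - 0.5).astype(np.int64)

    def voxel_to_um(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        pts = np.empty_like(idx)
        pts[:, 0] = idx[:, 0] * self.voxel_um
        pts[:, 1] = idx[:, 1] * self.voxel_um
        pts[:, 2] = (idx[:, 2] - self.ml_center_index) * self.voxel_um
        return pts

    def region_at(self, points: np.ndarray) -> np.ndarray:
        """Region id of the nearest voxel for each point.

        Points whose nearest voxel lies outside the volume bounds are
        labelled ``OUTSIDE_REGION`` (0).
        """
        idx = self.um_to_voxel(points)
        n = np.asarray(self.shape)
        inside = np.all((idx >= 0) & (idx < n), axis=1)
        out = np.full(len(idx), OUTSIDE_REGION, dtype=np.int64)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def region_name(self, region_id: int) -> str:
        if region_id == OUTSIDE_REGION:
            return "outside"
        row = self.regions.loc[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row["name"].iloc[0])

    # ------------------------------------------------------------------
    # I/O: TIFF label stack + JSON sidecar
    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / "labels.tif", self.labels.astype(np.uint16))
        payload = {
            "voxel_um": self.voxel_um,
            "regions": self.regions.to_dict(orient="records"),
            "fiducials": self.fiducials.to_dict() if self.fiducials else None,
            "meta": self.meta,
        }
        (d / "atlas.json").write_text(json.dumps(payload, indent=2))
        if self.boxes is not None:
            self.boxes.to_frame().to_csv(d / "boxes.csv", index=False)
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "AtlasVolume":
        d = Path(directory)
        labels = tifffile.imread(d / "labels.tif")
        payload = json.loads((d / "atlas.json").read_text())
        fids = (
            FiducialSet.from_dict(payload["fiducials"])
            if payload.get("fiducials")
            else None
        )
        boxes = None
        if (d / "boxes.csv").exists():
            boxes = BoundingBoxSeries.from_frame(pd.read_csv(d / "boxes.csv"))
        return cls(
            labels=labels,
            voxel_um=payload["voxel_um"],
            regions=pd.DataFrame(payload["regions"]),
            fiducials=fids,
            boxes=boxes,
            meta=payload.get("meta", {}),
        )
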