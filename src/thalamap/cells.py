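"""Scoring, filtering and localization of labeled neurons.

After registration, each annotated neuron is scored for label intensity
(mean of the brightest 20% of pixels in a 25 μm circular ROI), intensity
is min–max normalized per brain, dim cells (normalized intensity <= 5%)
are excluded as likely off-target label, and each remaining cell is
assigned to the atlas region of its nearest 10 μm voxel.  Summaries are
per-region percentages (per brain, then mean ± SEM across brains) and 3D
densities on a 100 μm grid: the per-bin percentage of each brain's cells,
averaged across brains without weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import OUTSIDE_REGION, AtlasVolume

logger = logging.getLogger(__name__)

INTENSITY_EXCLUSION = 0.05
ROI_DIAMETER_UM = 25.0
TOP_FRACTION = 0.20
DENSITY_BIN_UM = 100.0


# ----------------------------------------------------------------------
# Image-level operations
# ----------------------------------------------------------------------
def lower_quartile_mean(image: np.ndarray) -> float:
    """Default background estimator: mean of the dimmest quartile of pixels.

    Scale-equivariant (doubling the image doubles the estimate), which is
    what global level balancing needs.
    """
    flat = np.asarray(image, dtype=float).ravel()
    q = np.quantile(flat, 0.25)
    return float(flat[flat <= q].mean())


def level_balance_sections(
    stack: dict[int, np.ndarray],
    background_fn=lower_quartile_mean,
) -> dict[int, np.ndarray]:
    """Scale each section so background levels match across the stack.

    Each section is multiplied by a single global factor bringing its
    estimated mean background intensity to the stack-wide mean of those
    estimates; no local (sub-section) adjustment is ever made, so
    relative intensities within a section are preserved.
    """
    if not stack:
        raise ValueError("empty section stack")
    backgrounds = {idx: background_fn(img) for idx, img in stack.items()}
    for idx, b in backgrounds.items():
        if b <= 0:
            raise ValueError(f"section {idx} has non-positive background estimate {b}")
    target = float(np.mean(list(backgrounds.values())))
    return {
        idx: np.asarray(img, dtype=float) * (target / backgrounds[idx])
        for idx, img in stack.items()
    }


def cell_intensity(
    image: np.ndarray,
    center_px: tuple[float, float],
    pixel_um: float,
    roi_diameter_um: float = ROI_DIAMETER_UM,
    top_fraction: float = TOP_FRACTION,
) -> float:
    """Mean of the brightest pixels in a circular ROI at an annotation.

    The ROI is ``roi_diameter_um`` wide, centred at ``center_px`` (row,
    col); the score is the mean of the brightest
    ``ceil(top_fraction * n_roi_pixels)`` pixels.  ROIs extending past
    the image edge are clipped to the pixels that exist.
    """
    img = np.asarray(image, dtype=float)
    r_px = roi_diameter_um / 2.0 / pixel_um
    r0, c0 = center_px
    rows = np.arange(max(0, int(np.floor(r0 - r_px))), min(img.shape[0], int(np.ceil(r0 + r_px)) + 1))
    cols = np.arange(max(0, int(np.floor(c0 - r_px))), min(img.shape[1], int(np.ceil(c0 + r_px)) + 1))
    if rows.size == 0 or cols.size == 0:
        raise ValueError("ROI lies entirely outside the image")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= r_px**2
    values = img[rr[mask], cc[mask]]
    if values.size == 0:
        raise ValueError("empty ROI (diameter smaller than one pixel?)")
    k = int(np.ceil(top_fraction * values.size))
    top = np.partition(values, values.size - k)[values.size - k :]
    return float(top.mean())


# ----------------------------------------------------------------------
# Cell-table operations
# ----------------------------------------------------------------------
def filter_cells(
    cells: pd.DataFrame,
    threshold: float = INTENSITY_EXCLUSION,
) -> tuple[pd.DataFrame, dict]:
    """Normalize intensities per brain and drop dim cells.

    ``raw_intensity`` is min–max normalized to [0, 1] within the table
    (one brain); cells with normalized intensity <= ``threshold`` are
    excluded.  If all intensities are equal the normalized value is 1 for
    every cell and all are retained.

    Returns the retained table (with a ``normalized_intensity`` column)
    and a small report of the counts.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    raw = cells["raw_intensity"].to_numpy(dtype=float)
    lo, hi = raw.min(), raw.max()
    norm = np.ones_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    out = cells.copy()
    out["normalized_intensity"] = norm
    keep = norm > threshold
    report = {
        "n_input": int(len(cells)),
        "n_excluded": int(np.sum(~keep)),
        "n_retained": int(np.sum(keep)),
        "threshold": threshold,
    }
    logger.info("filter_cells: excluded %d / %d cells (<= %.0f%% normalized intensity)",
                report["n_excluded"], report["n_input"], 100 * threshold)
    return out[keep], report  # original index preserved for traceability


def assign_regions(cells_atlas: pd.DataFrame, atlas: AtlasVolume) -> pd.DataFrame:
    """Label each cell with the atlas region of its nearest voxel.

    Expects ``ap_um``, ``dv_um``, ``ml_um`` columns of registered atlas
    coordinates.  Cells whose nearest voxel falls outside the volume (or
    in unlabeled space) get region id 0 and name ``"outside"``.
    """
    pts = cells_atlas[["ap_um", "dv_um", "ml_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("cell coordinates contain non-finite values")
    out = cells_atlas.copy()
    region_ids = atlas.region_at(pts)
    names = {int(r["region_id"]): str(r["name"]) for _, r in atlas.regions.iterrows()}
    names[OUTSIDE_REGION] = "outside"
    out["region_id"] = region_ids
    out["region_name"] = [names.get(int(r), "outside") for r in region_ids]
    n_out = int(np.sum(region_ids == OUTSIDE_REGION))
    if n_out:
        logger.info("assign_regions: %d cells outside labeled volume", n_out)
    return out


def region_distribution(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-region percentage of cells, per brain and averaged across brains.

    Expects ``brain_id`` and ``region_name`` columns.  Per brain, the
    count in each region is divided by that brain's total cell count;
    rows are regions, with per-brain percentage columns plus cross-brain
    ``mean_pct`` and ``sem_pct``.
    """
    if len(cells) == 0:
        raise ValueError("no cells to summarize")
    counts = cells.groupby(["region_name", "brain_id"]).size().unstack(fill_value=0)
    pct = counts / counts.sum(axis=0) * 100.0
    out = pct.copy()
    out["mean_pct"] = pct.mean(axis=1)
    n = pct.shape[1]
    out["sem_pct"] = pct.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return out.sort_values("mean_pct", ascending=False)


def pool_small_regions(distribution: pd.DataFrame, min_mean_pct: float = 1.0) -> pd.DataFrame:
    """Pool regions averaging below ``min_mean_pct`` into an "other" row.

    Mirrors the presentation rule for the thalamic nuclei breakdown:
    nuclei with an average of at least 1% of labeled cells are listed,
    the remainder combined as "other".
    """
    brain_cols = [c for c in distribution.columns if c not in ("mean_pct", "sem_pct")]
    small = distribution["mean_pct"] < min_mean_pct
    kept = distribution[~small].copy()
    if small.any():
        pooled = distribution.loc[small, brain_cols].sum(axis=0)
        row = pooled.to_dict()
        row["mean_pct"] = pooled.mean()
        n = len(brain_cols)
        row["sem_pct"] = pooled.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        kept.loc["other"] = row
    return kept


@dataclass
class DensityGrid:
    """Binned 3D cell densities in atlas space.

    ``per_brain`` holds, per brain, the percentage of that brain's cells
    in each bin (sums to 100); ``mean`` is the unweighted cross-brain
    average.  Bin edges are anchored at ``origin`` so they coincide
    across brains.
    """

    bin_um: float
    origin: np.ndarray
    index_offset: np.ndarray  # lowest (ap, dv, ml) bin index in the arrays
    per_brain: dict[str, np.ndarray]
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = []
        for d in range(3):
            idx = self.index_offset[d] + np.arange(self.mean.shape[d])
            axes.append(self.origin[d] + (idx + 0.5) * self.bin_um)
        return tuple(axes)  # type: ignore[return-value]

    def nonzero_frame(self) -> pd.DataFrame:
        ap_c, dv_c, ml_c = self.bin_centers()
        ii = np.nonzero(self.mean)
        return pd.DataFrame(
            {
                "ap_um": ap_c[ii[0]],
                "dv_um": dv_c[ii[1]],
                "ml_um": ml_c[ii[2]],
                "mean_pct": self.mean[ii],
            }
        )

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        np.savez(
            stem.with_suffix(".npz"),
            mean=self.mean,
            origin=self.origin,
            index_offset=self.index_offset,
            bin_um=np.array(self.bin_um),
            **{f"brain__{k}": v for k, v in self.per_brain.items()},
        )
        self.nonzero_frame().to_csv(stem.with_suffix(".csv"), index=False)


def density_grid(
    cells_by_brain: dict[str, np.ndarray],
    bin_um: float = DENSITY_BIN_UM,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DensityGrid:
    """Cross-brain mean of per-brain binned cell percentages.

    ``cells_by_brain`` maps brain id → (n, 3) registered ``(ap, dv, ml)``
    μm coordinates.  Bins are ``bin_um`` cubes with edges at integer
    multiples of ``bin_um`` from ``origin`` (the atlas volume origin), so
    bin edges are identical for every brain; each brain contributes the
    percentage of its own cells per bin, and brains are averaged without
    weighting by cell count.
    """
    if not cells_by_brain:
        raise ValueError("no brains supplied")
    origin_arr = np.asarray(origin, dtype=float)
    all_idx = {
        bid: np.floor((np.atleast_2d(pts) - origin_arr) / bin_um).astype(int)
        for bid, pts in cells_by_brain.items()
    }
    stacked = np.vstack(list(all_idx.values()))
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    shape = tuple(hi - lo + 1)
    per_brain = {}
    for bid, idx in all_idx.items():
        grid = np.zeros(shape)
        rel = idx - lo
        np.add.at(grid, (rel[:, 0], rel[:, 1], rel[:, 2]), 1.0)
        per_brain[bid] = grid / len(idx) * 100.0
    mean = np.mean(list(per_brain.values()), axis=0)
    return DensityGrid(
        bin_um=bin_um,
        origin=origin_arr,
        index_offset=lo,
        per_brain=per_brain,
        mean=mean,
    )
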