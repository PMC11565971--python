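"""Fiducial/bounding-box affine registration of serial sections to an atlas.

The registration maps an atlas volume onto an experimental brain through a
fixed sequence of affine steps, each fitted from manually annotated
landmarks rather than image intensities:

1. a best-fit affine over four midline fiducials (corpus callosum anterior
   and posterior, anterior commissure posterior, dentate gyrus anterior);
2. an A-P shear against signed ML, fitted from two lateral left/right
   landmark pairs, compensating left/right asymmetry of coronal sections;
3. a translation anchoring both volumes at the subcommissural organ (SCO)
   fiducial, which becomes the coordinate origin for the scaling steps;
4. an A-P scale matching the length that contains 99% of the bounding-box
   volume anterior of the SCO;
5. an M-L scale and 6. a D-V scale matching the average box width and
   height within ±1 mm of the SCO;
and finally a per-slice (ML, DV) translation compensating residual drift
in serial-section alignment, computed from the dorsomedial corner of each
annotated box versus the corner of the transformed registration volume in
that slice plane.

Cell coordinates travel the other way: the inverse of the per-slice step
for the cell's own section, then the inverse of the global chain.

All coordinates are ``(ap, dv, ml)`` in μm (see :mod:`thalamap.atlas` for
the axis conventions).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIDLINE_NAMES = (
    "cc_anterior",
    "cc_posterior",
    "ac_posterior",
    "dg_anterior",
    "sco",
)
#: the four fiducials entering the step-1 fit (all midline points but SCO)
STEP1_NAMES = MIDLINE_NAMES[:4]
LATERAL_NAMES = ("stria_terminalis", "lgn_posterior")


# ----------------------------------------------------------------------
# Landmark containers
# ----------------------------------------------------------------------
@dataclass
class FiducialSet:
    """Five midline fiducials plus two left/right lateral landmark pairs.

    ``midline`` maps each name in :data:`MIDLINE_NAMES` to an
    ``(ap, dv, ml)`` μm point; ``lateral_pairs`` maps each name in
    :data:`LATERAL_NAMES` to a ``{"left": point, "right": point}`` dict.
    Midline points must sit within ``midline_tol_um`` of ``ml = 0``.
    """

    midline: dict[str, np.ndarray]
    lateral_pairs: dict[str, dict[str, np.ndarray]]
    midline_tol_um: float = 50.0

    def __post_init__(self) -> None:
        missing = [n for n in MIDLINE_NAMES if n not in self.midline]
        if missing:
            raise ValueError(f"missing midline fiducials: {missing}")
        self.midline = {
            k: np.asarray(v, dtype=float) for k, v in self.midline.items()
        }
        for name, pt in self.midline.items():
            if pt.shape != (3,):
                raise ValueError(f"fiducial {name!r} must be an (ap, dv, ml) triple")
            if abs(pt[2]) > self.midline_tol_um:
                raise ValueError(
                    f"midline fiducial {name!r} is {pt[2]:.1f} μm off the "
                    f"midline (tolerance {self.midline_tol_um} μm)"
                )
        for name in LATERAL_NAMES:
            pair = self.lateral_pairs.get(name)
            if pair is None or "left" not in pair or "right" not in pair:
                raise ValueError(f"lateral pair {name!r} must have both sides")
        self.lateral_pairs = {
            k: {s: np.asarray(p, dtype=float) for s, p in v.items()}
            for k, v in self.lateral_pairs.items()
        }

    @property
    def sco(self) -> np.ndarray:
        return self.midline["sco"]

    def step1_points(self) -> np.ndarray:
        """The four non-SCO midline points, in canonical order, as (4, 3)."""
        return np.stack([self.midline[n] for n in STEP1_NAMES])

    def transformed(self, matrix: np.ndarray) -> "FiducialSet":
        """Apply a homogeneous 4x4 affine to every landmark."""
        return FiducialSet(
            midline={k: apply_affine(matrix, v) for k, v in self.midline.items()},
            lateral_pairs={
                k: {s: apply_affine(matrix, p) for s, p in v.items()}
                for k, v in self.lateral_pairs.items()
            },
            midline_tol_um=np.inf,  # transformed sets may leave the midline
        )

    def to_dict(self) -> dict:
        return {
            "midline": {k: list(v) for k, v in self.midline.items()},
            "lateral_pairs": {
                k: {s: list(p) for s, p in v.items()}
                for k, v in self.lateral_pairs.items()
            },
            "midline_tol_um": self.midline_tol_um
            if np.isfinite(self.midline_tol_um)
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiducialSet":
        tol = d.get("midline_tol_um")
        return cls(
            midline={k: np.asarray(v) for k, v in d["midline"].items()},
            lateral_pairs={
                k: {s: np.asarray(p) for s, p in v.items()}
                for k, v in d["lateral_pairs"].items()
            },
            midline_tol_um=np.inf if tol is None else tol,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, pt in self.midline.items():
            rows.append(dict(name=name, side="mid", ap_um=pt[0], dv_um=pt[1], ml_um=pt[2]))
        for name, pair in self.lateral_pairs.items():
            for side, pt in pair.items():
                rows.append(dict(name=name, side=side, ap_um=pt[0], dv_um=pt[1], ml_um=pt[2]))
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, midline_tol_um: float = 50.0) -> "FiducialSet":
        midline = {}
        pairs: dict[str, dict[str, np.ndarray]] = {}
        for _, r in df.iterrows():
            pt = np.array([r["ap_um"], r["dv_um"], r["ml_um"]], dtype=float)
            if r["side"] == "mid":
                midline[r["name"]] = pt
            else:
                pairs.setdefault(r["name"], {})[r["side"]] = pt
        return cls(midline=midline, lateral_pairs=pairs, midline_tol_um=midline_tol_um)


@dataclass
class BoundingBoxSeries:
    """Per-section thalamic bounding boxes defining the registration volume.

    Backed by a DataFrame with columns ``section_index``, ``ap_um``,
    ``medial_um``, ``lateral_um``, ``dorsal_um``, ``ventral_um``.  The
    stacked boxes (each extruded over one section thickness) form the 3D
    registration volume.
    """

    frame: pd.DataFrame
    thickness_um: float

    REQUIRED = ("section_index", "ap_um", "medial_um", "lateral_um", "dorsal_um", "ventral_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"bounding-box table missing columns: {missing}")
        f = self.frame.sort_values("ap_um").reset_index(drop=True)
        if not (f["lateral_um"] > f["medial_um"]).all():
            raise ValueError("each box needs lateral_um > medial_um")
        if not (f["ventral_um"] > f["dorsal_um"]).all():
            raise ValueError("each box needs ventral_um > dorsal_um")
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ap(self) -> np.ndarray:
        return self.frame["ap_um"].to_numpy(dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return (self.frame["lateral_um"] - self.frame["medial_um"]).to_numpy(dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return (self.frame["ventral_um"] - self.frame["dorsal_um"]).to_numpy(dtype=float)

    def translated(self, d_ap: float = 0.0, d_dv: float = 0.0, d_ml: float = 0.0) -> "BoundingBoxSeries":
        f = self.frame.copy()
        f["ap_um"] += d_ap
        f["medial_um"] += d_ml
        f["lateral_um"] += d_ml
        f["dorsal_um"] += d_dv
        f["ventral_um"] += d_dv
        return BoundingBoxSeries(f, self.thickness_um)

    def interp_bounds(self, ap_um: float) -> dict[str, float] | None:
        """Linearly interpolate box bounds at an AP position.

        Returns ``None`` outside the AP range of the series.
        """
        ap = self.ap
        if ap_um < ap.min() - self.thickness_um / 2 or ap_um > ap.max() + self.thickness_um / 2:
            return None
        out = {}
        for col in ("medial_um", "lateral_um", "dorsal_um", "ventral_um"):
            out[col] = float(
                np.interp(ap_um, ap, self.frame[col].to_numpy(dtype=float))
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        f = self.frame.copy()
        f["thickness_um"] = self.thickness_um
        return f

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BoundingBoxSeries":
        thickness = float(df["thickness_um"].iloc[0]) if "thickness_um" in df else 40.0
        return cls(df.drop(columns=["thickness_um"], errors="ignore"), thickness)


# ----------------------------------------------------------------------
# Homogeneous-affine helpers
# ----------------------------------------------------------------------
def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous affine to (ap, dv, ml) points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ matrix[:3, :3].T + matrix[:3, 3]
    return out[0] if single else out


def translation_matrix(t: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    m[:3, 3] = np.asarray(t, dtype=float)
    return m


def scale_matrix(ap: float = 1.0, dv: float = 1.0, ml: float = 1.0) -> np.ndarray:
    return np.diag([ap, dv, ml, 1.0])


def shear_matrix(s: float) -> np.ndarray:
    """A-P shear against signed ML: ``ap' = ap + s * ml``."""
    m = np.eye(4)
    m[0, 2] = s
    return m


# ----------------------------------------------------------------------
# Step fits
# ----------------------------------------------------------------------
@dataclass
class AffineStep:
    """One fitted step: its 4x4 matrix plus a small fit report."""

    name: str
    matrix: np.ndarray
    params: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None

    @property
    def max_residual(self) -> float:
        if self.residuals is None or self.residuals.size == 0:
            return 0.0
        return float(np.max(np.abs(self.residuals)))


def fit_midline_affine(
    source_fids: FiducialSet,
    target_fids: FiducialSet,
    axes_mode: str = "ap_dv",
) -> AffineStep:
    """Step 1: least-squares affine over the four non-SCO midline fiducials.

    The midline fiducials vary along AP and DV only, so the default fit is
    a planar affine in the midsagittal (AP, DV) plane with ML untouched
    (``axes_mode="ap_dv"``).  ``axes_mode="ap_ml"`` instead fits the
    (AP, ML) plane, leaving DV untouched.

    With four point pairs and six planar parameters the system is
    overdetermined; residuals of the least-squares solve are reported on
    the step.
    """
    if axes_mode not in ("ap_dv", "ap_ml"):
        raise ValueError(f"unknown axes_mode {axes_mode!r}")
    axes = (0, 1) if axes_mode == "ap_dv" else (0, 2)

    src = source_fids.step1_points()[:, axes]
    tgt = target_fids.step1_points()[:, axes]

    centered = src - src.mean(axis=0)
    a0, a1 = axes
    matrix = np.eye(4)
    if np.ptp(src[:, 1]) < 1e-9 * max(np.ptp(src[:, 0]), 1.0):
        # the fiducials carry no spread along the second axis (midline
        # points in "ap_ml" mode): fall back to a 1D affine on the first
        # axis, identity on the second
        design = np.column_stack([src[:, 0], np.ones(len(src))])
        coef1, *_ = np.linalg.lstsq(design, tgt[:, 0], rcond=None)
        matrix[a0, a0] = coef1[0]
        matrix[a0, 3] = coef1[1]
        residuals = (design @ coef1 - tgt[:, 0])[:, None]
        coef = np.array([[coef1[0], 0.0], [0.0, 1.0], [coef1[1], 0.0]])
    else:
        # a planar affine needs rank-2 source spread
        svals = np.linalg.svd(centered, compute_uv=False)
        if svals[-1] < 1e-6 * max(svals[0], 1.0):
            raise ValueError(
                "degenerate (collinear) step-1 fiducials: "
                + ", ".join(STEP1_NAMES)
            )
        design = np.hstack([src, np.ones((len(src), 1))])
        coef, *_ = np.linalg.lstsq(design, tgt, rcond=None)  # (3, 2)
        matrix[a0, a0] = coef[0, 0]
        matrix[a0, a1] = coef[1, 0]
        matrix[a0, 3] = coef[2, 0]
        matrix[a1, a0] = coef[0, 1]
        matrix[a1, a1] = coef[1, 1]
        matrix[a1, 3] = coef[2, 1]
        residuals = design @ coef - tgt
    return AffineStep(
        "midline_affine",
        matrix,
        params={"axes_mode": axes_mode, "coef": coef.tolist()},
        residuals=residuals,
    )


def fit_shear(
    lateral_pairs_source: dict[str, dict[str, np.ndarray]],
    lateral_pairs_target: dict[str, dict[str, np.ndarray]],
) -> AffineStep:
    """Step 2: A-P shear aligning left/right AP asymmetry of lateral pairs.

    For each pair the left-minus-right AP offset after shearing is
    ``a + s * dml`` with ``dml`` the left-minus-right ML separation; ``s``
    is the least-squares solution over both pairs jointly, so if the two
    pairs disagree the solution averages them.
    """
    num = 0.0
    den = 0.0
    resid = []
    for name in lateral_pairs_source:
        ls, rs = lateral_pairs_source[name]["left"], lateral_pairs_source[name]["right"]
        lt, rt = lateral_pairs_target[name]["left"], lateral_pairs_target[name]["right"]
        dml = ls[2] - rs[2]
        if abs(dml) < 1e-9:
            raise ValueError(
                f"coincident left/right ML for lateral pair {name!r}; shear unidentifiable"
            )
        a_src = ls[0] - rs[0]
        a_tgt = lt[0] - rt[0]
        num += dml * (a_tgt - a_src)
        den += dml * dml
        resid.append((name, a_src, a_tgt, dml))
    s = num / den
    residuals = np.array([a_src + s * dml - a_tgt for (_, a_src, a_tgt, dml) in resid])
    return AffineStep("ap_shear", shear_matrix(s), params={"s": float(s)}, residuals=residuals)


def anchor_at_sco(
    chain_so_far: np.ndarray,
    source_sco: np.ndarray,
    target_sco: np.ndarray,
) -> tuple[AffineStep, np.ndarray]:
    """Step 3: translate so the transformed source SCO sits at the origin.

    Returns the anchoring step and the target SCO (kept aside so target
    boxes can be expressed in the same SCO-centred frame, and restored as
    the final translation of the composed chain).
    """
    source_sco = np.asarray(source_sco, dtype=float)
    target_sco = np.asarray(target_sco, dtype=float)
    if source_sco.shape != (3,) or target_sco.shape != (3,):
        raise ValueError("SCO fiducials must be (ap, dv, ml) points")
    sco_now = apply_affine(chain_so_far, source_sco)
    step = AffineStep("sco_anchor", translation_matrix(-sco_now), params={"t": (-sco_now).tolist()})
    return step, target_sco


def _anterior_segments(boxes: BoundingBoxSeries) -> list[tuple[float, float, float]]:
    """Piecewise-constant area segments ``(x0, x1, area)`` anterior of the SCO.

    Each box contributes its cross-sectional area over one section
    thickness centred on its AP position; overlapping extents are split
    at midpoints between neighbouring boxes, and everything is clipped
    to AP <= 0 (SCO-anchored coordinates).
    """
    ap = boxes.ap
    areas = boxes.widths * boxes.heights
    half = boxes.thickness_um / 2
    segments = []
    for i in range(len(ap)):
        lo = ap[i] - half
        hi = ap[i] + half
        if i > 0:
            lo = max(lo, (ap[i - 1] + ap[i]) / 2)
        if i < len(ap) - 1:
            hi = min(hi, (ap[i] + ap[i + 1]) / 2)
        hi = min(hi, 0.0)
        if hi > lo:
            segments.append((float(lo), float(hi), float(areas[i])))
    return segments


def anterior_quantile_length(boxes: BoundingBoxSeries, volume_fraction: float) -> float:
    """AP distance from the anterior pole containing a volume fraction.

    The cumulative bounding-box volume between the anterior pole and the
    SCO is piecewise linear in AP; the quantile position is solved
    exactly by linear interpolation within the containing segment.
    """
    segments = _anterior_segments(boxes)
    total = sum((x1 - x0) * a for x0, x1, a in segments)
    if not segments or total <= 0:
        raise ValueError("no bounding-box volume anterior of the SCO")
    target = volume_fraction * total
    pole = segments[0][0]
    cum = 0.0
    for x0, x1, a in segments:
        seg = (x1 - x0) * a
        if cum + seg >= target:
            return x0 + (target - cum) / a - pole
        cum += seg
    return segments[-1][1] - pole


def fit_ap_scale(
    source_boxes: BoundingBoxSeries,
    target_boxes: BoundingBoxSeries,
    volume_fraction: float = 0.99,
) -> AffineStep:
    """Step 4: A-P scale from the anterior volume-quantile length.

    Both series must already be in SCO-anchored coordinates (SCO AP = 0;
    anterior of the SCO is negative AP).  For each series ``L`` is the AP
    distance from the anterior pole at which the cumulative bounding-box
    volume reaches ``volume_fraction`` of the total volume between the
    pole and the SCO.  The scale is ``L_target / L_source``.
    """
    ls = anterior_quantile_length(source_boxes, volume_fraction)
    lt = anterior_quantile_length(target_boxes, volume_fraction)
    scale = lt / ls
    return AffineStep(
        "ap_scale",
        scale_matrix(ap=scale),
        params={"scale": float(scale), "L_source_um": ls, "L_target_um": lt,
                "volume_fraction": volume_fraction},
    )


def fit_ml_dv_scales(
    source_boxes: BoundingBoxSeries,
    target_boxes: BoundingBoxSeries,
    window_mm: float = 1.0,
) -> tuple[AffineStep, AffineStep]:
    """Steps 5–6: ML and DV scales from mean box width/height near the SCO.

    Uses boxes within ``window_mm`` anterior and posterior of the SCO
    (coordinates must be SCO-anchored).  The ML scale is the ratio of mean
    target to mean source box width over that window; the DV scale uses
    heights.
    """
    w = window_mm * 1000.0

    def window_mean(boxes: BoundingBoxSeries, values: np.ndarray, label: str) -> float:
        sel = np.abs(boxes.ap) <= w
        if not np.any(sel):
            raise ValueError(
                f"no {label} bounding boxes within ±{window_mm} mm of the SCO"
            )
        return float(values[sel].mean())

    ml_scale = window_mean(target_boxes, target_boxes.widths, "target") / window_mean(
        source_boxes, source_boxes.widths, "source"
    )
    dv_scale = window_mean(target_boxes, target_boxes.heights, "target") / window_mean(
        source_boxes, source_boxes.heights, "source"
    )
    return (
        AffineStep("ml_scale", scale_matrix(ml=ml_scale), params={"scale": float(ml_scale)}),
        AffineStep("dv_scale", scale_matrix(dv=dv_scale), params={"scale": float(dv_scale)}),
    )


def transform_boxes(boxes: BoundingBoxSeries, matrix: np.ndarray) -> BoundingBoxSeries:
    """Carry a bounding-box series through an affine of the chain family.

    Chain matrices never mix DV or ML into each other, and the only ML→AP
    coupling is the shear, which vanishes on the midline.  Each box is
    therefore transformed by mapping its AP at the midline (ML = 0, box
    DV centre), its DV bounds at the midline, and its ML bounds through
    the ML row.  Bounds are re-sorted in case of negative scales.
    """
    rows = []
    for _, r in boxes.frame.iterrows():
        dv_c = (r["dorsal_um"] + r["ventral_um"]) / 2
        ap_new = apply_affine(matrix, np.array([r["ap_um"], dv_c, 0.0]))[0]
        d_new = apply_affine(matrix, np.array([r["ap_um"], r["dorsal_um"], 0.0]))[1]
        v_new = apply_affine(matrix, np.array([r["ap_um"], r["ventral_um"], 0.0]))[1]
        m_new = apply_affine(matrix, np.array([r["ap_um"], dv_c, r["medial_um"]]))[2]
        l_new = apply_affine(matrix, np.array([r["ap_um"], dv_c, r["lateral_um"]]))[2]
        rows.append(
            dict(
                section_index=r["section_index"],
                ap_um=ap_new,
                medial_um=min(m_new, l_new),
                lateral_um=max(m_new, l_new),
                dorsal_um=min(d_new, v_new),
                ventral_um=max(d_new, v_new),
            )
        )
    ap_ratio = abs(matrix[0, 0]) if matrix[0, 0] != 0 else 1.0
    return BoundingBoxSeries(pd.DataFrame(rows), boxes.thickness_um * ap_ratio)


# ----------------------------------------------------------------------
# The composed chain
# ----------------------------------------------------------------------
@dataclass
class AffineChain:
    """The fitted atlas→brain mapping: six global steps + per-slice drift.

    ``steps`` holds the six global steps in fit order (midline affine,
    shear, SCO anchor, AP scale, ML scale, DV scale); ``restore_t`` is the
    final translation that moves the SCO-centred result onto the brain's
    SCO.  ``per_slice`` maps each brain section index to an (ML, DV)
    drift-correction translation applied after the global chain.
    """

    steps: list[AffineStep]
    restore_t: np.ndarray
    per_slice: dict[int, np.ndarray]
    section_thickness_um: float
    fit_report: dict = field(default_factory=dict)

    SCHEMA_VERSION = 1

    @property
    def global_matrix(self) -> np.ndarray:
        m = translation_matrix(self.restore_t)
        for step in reversed(self.steps):
            m = m @ step.matrix
        return m

    @property
    def effective_params(self) -> dict[str, float]:
        """Scale/shear/translation of the *composed* global map.

        Individual fitted steps can redistribute parameters among
        themselves (the four-point step-1 fit absorbs any AP/DV scaling
        present in the data, leaving later scale steps near 1), so
        recovered parameters are meaningful only on the composition:
        ``ap_scale = g00``, ``dv_scale = g11``, ``ml_scale = g22``,
        ``shear = g02 / g00``, translation = last column.
        """
        g = self.global_matrix
        return {
            "ap_scale": float(g[0, 0]),
            "dv_scale": float(g[1, 1]),
            "ml_scale": float(g[2, 2]),
            "shear": float(g[0, 2] / g[0, 0]),
            "t_ap": float(g[0, 3]),
            "t_dv": float(g[1, 3]),
            "t_ml": float(g[2, 3]),
        }

    def _slice_correction(self, section_index: int) -> np.ndarray:
        """(ml, dv) correction for a section; nearest annotated fallback."""
        if section_index in self.per_slice:
            return self.per_slice[section_index]
        if not self.per_slice:
            return np.zeros(2)
        keys = np.array(sorted(self.per_slice))
        nearest = int(keys[np.argmin(np.abs(keys - section_index))])
        return self.per_slice[nearest]

    def section_of(self, ap_um: np.ndarray) -> np.ndarray:
        return np.round(np.asarray(ap_um, dtype=float) / self.section_thickness_um).astype(int)

    def forward(self, points: np.ndarray, with_per_slice: bool = True) -> np.ndarray:
        """Map atlas μm points into brain coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = apply_affine(self.global_matrix, pts)
        out = np.atleast_2d(out)
        if with_per_slice and self.per_slice:
            sections = self.section_of(out[:, 0])
            for i, sec in enumerate(sections):
                dml, ddv = self._slice_correction(int(sec))
                out[i, 1] += ddv
                out[i, 2] += dml
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self, points: np.ndarray, section_index: np.ndarray | int | None = None) -> np.ndarray:
        """Map brain coordinates back into atlas space.

        ``section_index`` selects the per-slice correction to undo; if
        omitted it is inferred from each point's AP position.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        if self.per_slice:
            if section_index is None:
                sections = self.section_of(pts[:, 0])
            else:
                sections = np.broadcast_to(np.asarray(section_index, dtype=int), (len(pts),))
            for i, sec in enumerate(sections):
                dml, ddv = self._slice_correction(int(sec))
                pts[i, 1] -= ddv
                pts[i, 2] -= dml
        inv = np.linalg.inv(self.global_matrix)
        out = apply_affine(inv, pts)
        out = np.atleast_2d(out)
        return out[0] if np.asarray(points).ndim == 1 else out

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "steps": [
                {"name": s.name, "matrix": s.matrix.tolist(), "params": s.params}
                for s in self.steps
            ],
            "restore_t": self.restore_t.tolist(),
            "per_slice": {str(k): v.tolist() for k, v in self.per_slice.items()},
            "section_thickness_um": self.section_thickness_um,
            "fit_report": self.fit_report,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineChain":
        return cls(
            steps=[
                AffineStep(s["name"], np.asarray(s["matrix"]), params=s.get("params", {}))
                for s in d["steps"]
            ],
            restore_t=np.asarray(d["restore_t"], dtype=float),
            per_slice={int(k): np.asarray(v, dtype=float) for k, v in d["per_slice"].items()},
            section_thickness_um=d["section_thickness_um"],
            fit_report=d.get("fit_report", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AffineChain":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_per_slice_drift(
    chain: AffineChain,
    source_boxes: BoundingBoxSeries,
    brain_boxes: BoundingBoxSeries,
) -> dict[int, np.ndarray]:
    """Per-section (ML, DV) drift from dorsomedial box-corner mismatch.

    The atlas box series is carried through the fitted global chain; for
    each annotated brain section the transformed series is interpolated at
    that section's AP plane, and the translation moving the transformed
    volume's dorsomedial corner (medial, dorsal) onto the annotated box's
    corner is recorded.  Sections whose plane misses the transformed
    volume get a zero correction and a logged warning.
    """
    transformed = transform_boxes(source_boxes, chain.global_matrix)
    out: dict[int, np.ndarray] = {}
    for _, r in brain_boxes.frame.iterrows():
        sec = int(r["section_index"])
        bounds = transformed.interp_bounds(float(r["ap_um"]))
        if bounds is None:
            warnings.warn(
                f"section {sec} (AP {r['ap_um']:.0f} μm) lies outside the "
                "transformed registration volume; zero drift correction used",
                stacklevel=2,
            )
            out[sec] = np.zeros(2)
            continue
        dml = r["medial_um"] - bounds["medial_um"]
        ddv = r["dorsal_um"] - bounds["dorsal_um"]
        out[sec] = np.array([dml, ddv])
    return out


def register_brain(
    brain,
    atlas,
    axes_mode: str = "ap_dv",
    volume_fraction: float = 0.99,
    window_mm: float = 1.0,
) -> AffineChain:
    """Fit the full atlas→brain chain: the six global steps then drift.

    ``brain`` must carry a :class:`FiducialSet` and
    :class:`BoundingBoxSeries`; ``atlas`` carries its programmatic
    equivalents.  A per-step fit report (residuals, fitted parameters) is
    attached to the returned chain.
    """
    src_fids: FiducialSet = atlas.fiducials
    tgt_fids: FiducialSet = brain.fiducials
    if src_fids is None or brain.boxes is None or atlas.boxes is None:
        raise ValueError("both atlas and brain need fiducials and bounding boxes")

    step1 = fit_midline_affine(src_fids, tgt_fids, axes_mode=axes_mode)
    src_after1 = src_fids.transformed(step1.matrix)
    step2 = fit_shear(src_after1.lateral_pairs, tgt_fids.lateral_pairs)
    m12 = step2.matrix @ step1.matrix
    step3, target_sco = anchor_at_sco(m12, src_fids.sco, tgt_fids.sco)
    m123 = step3.matrix @ m12

    src_boxes_anchored = transform_boxes(atlas.boxes, m123)
    tgt_boxes_anchored = brain.boxes.translated(
        d_ap=-target_sco[0], d_dv=-target_sco[1], d_ml=-target_sco[2]
    )
    step4 = fit_ap_scale(src_boxes_anchored, tgt_boxes_anchored, volume_fraction)
    step5, step6 = fit_ml_dv_scales(
        transform_boxes(src_boxes_anchored, step4.matrix), tgt_boxes_anchored, window_mm
    )

    chain = AffineChain(
        steps=[step1, step2, step3, step4, step5, step6],
        restore_t=target_sco,
        per_slice={},
        section_thickness_um=brain.section_thickness_um,
        fit_report={
            "step1_max_residual_um": step1.max_residual,
            "step2_max_residual_um": step2.max_residual,
            "shear_s": step2.params["s"],
            "ap_scale": step4.params["scale"],
            "ml_scale": step5.params["scale"],
            "dv_scale": step6.params["scale"],
            "axes_mode": axes_mode,
        },
    )
    chain.per_slice = fit_per_slice_drift(chain, atlas.boxes, brain.boxes)
    drifts = np.array(list(chain.per_slice.values())) if chain.per_slice else np.zeros((0, 2))
    chain.fit_report["per_slice_max_um"] = float(np.abs(drifts).max()) if drifts.size else 0.0
    return chain


def map_to_atlas(
    chain: AffineChain,
    points: np.ndarray,
    section_index: np.ndarray | None = None,
) -> np.ndarray:
    """Map annotated brain coordinates into atlas μm space.

    This is the inverse of the fitted chain: the per-slice correction for
    each point's own section is undone first, then the inverted global
    chain is applied.
    """
    return chain.inverse(points, section_index=section_index)
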