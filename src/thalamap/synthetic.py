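"""Synthetic study generator: every pipeline input, with known ground truth.

The generators emulate the study's data classes so the full analysis can
be exercised and validated offline:

* a mini label atlas (ellipsoidal stand-in regions with thalamic-nucleus
  style names, programmatic fiducials and bounding boxes);
* experimental brains derived from the atlas under a known affine chain
  (translation, A-P shear, per-axis scales) with optional per-slice
  alignment jitter, sectioned at 40 μm;
* multi-site photometry in which SNr and DCN traces are autocorrelated
  event trains and the thalamus trace is a known linear mixture
  ``A*snr + B*dcn + C`` plus Gaussian noise, wrapped in shared bleaching
  and background artifacts that the isosbestic correction must remove;
* lever-position and wheel-velocity traces containing exactly the
  requested events.

Every generator is deterministic given its seed.  Ground truth is
returned alongside each artifact so downstream stages can be tested for
exact or statistical recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasVolume
from .brain import AnnotatedBrain
from .photometry import PhotometryBundle
from .registration import (
    AffineChain,
    AffineStep,
    BoundingBoxSeries,
    FiducialSet,
    LATERAL_NAMES,
    scale_matrix,
    shear_matrix,
    transform_boxes,
    translation_matrix,
)

SECTION_THICKNESS_UM = 40.0
CELL_PIXEL_UM = 0.454  # acquisition pixel pitch of the cell-counting images
REGION_NAME_POOL = ("VM", "VAL", "VPM", "PO", "MD", "ZI", "CL", "PF", "VPL", "LD")

# fractional (ap, dv) positions of the midline fiducials; ml = 0
_MIDLINE_LAYOUT = {
    "cc_anterior": (0.08, 0.18),
    "cc_posterior": (0.42, 0.12),
    "ac_posterior": (0.28, 0.55),
    "dg_anterior": (0.50, 0.30),
    "sco": (0.62, 0.40),
}
# fractional (ap, dv, |ml|) positions of the lateral pairs
_LATERAL_LAYOUT = {
    "stria_terminalis": (0.55, 0.32, 0.62),
    "lgn_posterior": (0.72, 0.50, 0.72),
}
# bounding boxes span this fractional AP range of the atlas
_BOX_AP_RANGE = (0.20, 0.92)


# ----------------------------------------------------------------------
# Mini atlas
# ----------------------------------------------------------------------
def gen_mini_atlas(
    n_regions: int = 6,
    shape: tuple[int, int, int] = (600, 100, 101),
    voxel_um: float = 10.0,
    seed: int = 0,
    section_thickness_um: float = SECTION_THICKNESS_UM,
) -> AtlasVolume:
    """Generate a mini label atlas with landmarks and bounding boxes.

    Regions are disjoint axis-aligned ellipsoids strung along the AP
    extent of the registration volume, labeled 1..n with stand-in
    thalamic-nucleus names.  Fiducial coordinates are snapped to the
    voxel grid (μm = voxel index × ``voxel_um``); bounding boxes are laid
    out every ``section_thickness_um`` with smoothly varying width and
    height so the anterior volume profile is non-trivial.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"invalid atlas shape {shape}; need three positive extents")
    rng = np.random.default_rng(seed)
    n_ap, n_dv, n_ml = shape
    ap_ext = (n_ap - 1) * voxel_um
    dv_ext = (n_dv - 1) * voxel_um
    ml_half = (n_ml - 1) / 2 * voxel_um

    def snap(x: float) -> float:
        return round(x / voxel_um) * voxel_um

    midline = {
        name: np.array([snap(fa * ap_ext), snap(fd * dv_ext), 0.0])
        for name, (fa, fd) in _MIDLINE_LAYOUT.items()
    }
    lateral = {}
    for name, (fa, fd, fm) in _LATERAL_LAYOUT.items():
        ap, dv, ml = snap(fa * ap_ext), snap(fd * dv_ext), snap(fm * ml_half)
        lateral[name] = {
            "left": np.array([ap, dv, -ml]),
            "right": np.array([ap, dv, ml]),
        }
    fiducials = FiducialSet(midline=midline, lateral_pairs=lateral)

    # bounding boxes on the section grid, smooth non-uniform profile
    ap_lo, ap_hi = (_BOX_AP_RANGE[0] * ap_ext, _BOX_AP_RANGE[1] * ap_ext)
    box_aps = np.arange(
        np.ceil(ap_lo / section_thickness_um) * section_thickness_um,
        ap_hi + 1e-9,
        section_thickness_um,
    )
    u = (box_aps - box_aps[0]) / (box_aps[-1] - box_aps[0])
    lateral_b = (0.35 + 0.30 * np.sin(np.pi * u)) * ml_half
    dorsal_b = (0.25 - 0.06 * np.sin(np.pi * u)) * dv_ext
    ventral_b = (0.70 + 0.08 * np.sin(np.pi * u)) * dv_ext
    boxes = BoundingBoxSeries(
        pd.DataFrame(
            {
                "section_index": np.round(box_aps / section_thickness_um).astype(int),
                "ap_um": box_aps,
                "medial_um": 0.0,
                "lateral_um": lateral_b,
                "dorsal_um": dorsal_b,
                "ventral_um": ventral_b,
            }
        ),
        thickness_um=section_thickness_um,
    )

    # ellipsoidal regions in disjoint AP slots inside the box volume
    labels = np.zeros(shape, dtype=np.uint16)
    ap_grid = np.arange(n_ap)[:, None, None] * voxel_um
    dv_grid = np.arange(n_dv)[None, :, None] * voxel_um
    ml_grid = (np.arange(n_ml)[None, None, :] - (n_ml - 1) / 2) * voxel_um
    slot = (ap_hi - ap_lo) / n_regions
    regions = []
    for i in range(n_regions):
        ap_c = ap_lo + (i + 0.5) * slot + rng.uniform(-0.05, 0.05) * slot
        b = boxes.interp_bounds(ap_c)
        ml_c = 0.45 * b["lateral_um"] + rng.uniform(-0.05, 0.05) * b["lateral_um"]
        dv_c = 0.5 * (b["dorsal_um"] + b["ventral_um"]) + rng.uniform(-0.05, 0.05) * (
            b["ventral_um"] - b["dorsal_um"]
        )
        r_ap = 0.45 * slot
        r_ml = 0.32 * b["lateral_um"]
        r_dv = 0.30 * (b["ventral_um"] - b["dorsal_um"])
        inside = (
            ((ap_grid - ap_c) / r_ap) ** 2
            + ((dv_grid - dv_c) / r_dv) ** 2
            + ((ml_grid - ml_c) / r_ml) ** 2
        ) <= 1.0
        labels[inside] = i + 1
        name = REGION_NAME_POOL[i % len(REGION_NAME_POOL)]
        if i >= len(REGION_NAME_POOL):
            name = f"{name}{i // len(REGION_NAME_POOL) + 1}"
        regions.append({"region_id": i + 1, "name": name})

    return AtlasVolume(
        labels=labels,
        voxel_um=voxel_um,
        regions=pd.DataFrame(regions),
        fiducials=fiducials,
        boxes=boxes,
        meta={"seed": seed, "section_thickness_um": section_thickness_um},
    )


# ----------------------------------------------------------------------
# Synthetic brains
# ----------------------------------------------------------------------
@dataclass
class ChainParams:
    """Ground-truth parameters of the atlas→brain map for a synthetic brain."""

    t_ap: float = 0.0
    t_dv: float = 0.0
    t_ml: float = 0.0
    shear: float = 0.0
    ap_scale: float = 1.0
    dv_scale: float = 1.0
    ml_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ap_scale, self.dv_scale, self.ml_scale) <= 0:
            raise ValueError("non-invertible chain: scales must be positive")


@dataclass
class SynthBrainTruth:
    """Ground truth for one synthetic brain: the physical map and cells.

    ``chain`` is the true atlas→brain chain *without* per-slice terms
    (annotation jitter is recorded separately in ``jitter_per_slice``,
    keyed by section index, bounded by three times the generator's
    ``jitter_sd``).
    """

    chain: AffineChain
    params: ChainParams
    cell_atlas_coords: np.ndarray
    cell_true_regions: np.ndarray
    jitter_per_slice: dict[int, np.ndarray]


def _truth_chain(params: ChainParams, atlas: AtlasVolume) -> AffineChain:
    """Build the family-form chain realizing the requested parameters."""
    m1 = translation_matrix([params.t_ap, params.t_dv, 0.0])
    sh = shear_matrix(params.shear)
    sco_src = atlas.fiducials.sco
    sco2 = (sh @ m1)[:3, :3] @ sco_src + (sh @ m1)[:3, 3]
    anchor = translation_matrix(-sco2)
    scales = scale_matrix(ap=params.ap_scale, dv=params.dv_scale, ml=params.ml_scale)
    restore = sco2 + np.array([0.0, 0.0, params.t_ml])
    steps = [
        AffineStep("midline_affine", m1),
        AffineStep("ap_shear", sh, params={"s": params.shear}),
        AffineStep("sco_anchor", anchor),
        AffineStep("ap_scale", scale_matrix(ap=params.ap_scale)),
        AffineStep("ml_scale", scale_matrix(ml=params.ml_scale)),
        AffineStep("dv_scale", scale_matrix(dv=params.dv_scale)),
    ]
    # the composed scale step is applied once; build chain from the parts
    chain = AffineChain(
        steps=steps,
        restore_t=restore,
        per_slice={},
        section_thickness_um=float(atlas.meta.get("section_thickness_um", SECTION_THICKNESS_UM)),
    )
    # consistency: composed matrix equals restore·S·anchor·shear·m1
    expected = translation_matrix(restore) @ scales @ anchor @ sh @ m1
    assert np.allclose(chain.global_matrix, expected)
    return chain


def _default_intensities(rng: np.random.Generator, n: int, dim_fraction: float) -> np.ndarray:
    """Graded label intensities: a bright lognormal bulk plus a dim tail."""
    bright = 1000.0 * rng.lognormal(mean=0.0, sigma=0.4, size=n)
    n_dim = int(round(dim_fraction * n))
    dim_idx = rng.choice(n, size=n_dim, replace=False)
    bright[dim_idx] = rng.uniform(1.0, 30.0, size=n_dim)
    return bright


def gen_brain_from_atlas(
    atlas: AtlasVolume,
    chain_params: ChainParams | None = None,
    n_cells: int = 500,
    intensity_dist=None,
    jitter_sd: float = 0.0,
    seed: int = 0,
    region_weights: dict[int, float] | None = None,
    dim_fraction: float = 0.1,
    brain_id: str = "brain",
    pixel_um: float = CELL_PIXEL_UM,
) -> tuple[AnnotatedBrain, SynthBrainTruth]:
    """Derive an annotated experimental brain from the atlas.

    The atlas is carried through the known chain; fiducials, per-section
    bounding boxes and cells are then re-annotated in brain coordinates
    with optional per-slice (ML, DV) jitter emulating serial-alignment
    drift (normal with SD ``jitter_sd``, clipped at 3 SD; the same
    offset corrupts every annotation on a section).  Cells are placed
    uniformly inside atlas regions, sampled according to
    ``region_weights`` (uniform over regions by default); each cell's AP
    is snapped to its section plane, and the recorded ground truth is the
    exact atlas coordinate of the snapped point, guaranteed to lie in the
    intended region.
    """
    params = chain_params or ChainParams()
    rng = np.random.default_rng(seed)
    chain = _truth_chain(params, atlas)
    g = chain.global_matrix
    g_inv = np.linalg.inv(g)
    th = chain.section_thickness_um

    # brain-side bounding boxes: transformed volume sliced on the section grid
    t_boxes = transform_boxes(atlas.boxes, g)
    sec_lo = int(np.ceil((t_boxes.ap.min()) / th - 0.5))
    sec_hi = int(np.floor((t_boxes.ap.max()) / th + 0.5))
    jitter: dict[int, np.ndarray] = {}
    rows = []
    for sec in range(sec_lo, sec_hi + 1):
        ap_b = sec * th
        bounds = t_boxes.interp_bounds(ap_b)
        if bounds is None:
            continue
        j = np.clip(rng.normal(0.0, jitter_sd, size=2), -3 * jitter_sd, 3 * jitter_sd) \
            if jitter_sd > 0 else np.zeros(2)
        jitter[sec] = j  # (ml, dv)
        rows.append(
            dict(
                section_index=sec,
                ap_um=ap_b,
                medial_um=bounds["medial_um"] + j[0],
                lateral_um=bounds["lateral_um"] + j[0],
                dorsal_um=bounds["dorsal_um"] + j[1],
                ventral_um=bounds["ventral_um"] + j[1],
            )
        )
    brain_boxes = BoundingBoxSeries(pd.DataFrame(rows), thickness_um=th)

    def nearest_jitter(sec: int) -> np.ndarray:
        if sec in jitter:
            return jitter[sec]
        if not jitter:
            return np.zeros(2)
        keys = np.array(sorted(jitter))
        return jitter[int(keys[np.argmin(np.abs(keys - sec))])]

    # fiducials: true map + the jitter of each landmark's section
    def annotate_point(p_atlas: np.ndarray) -> np.ndarray:
        q = g[:3, :3] @ p_atlas + g[:3, 3]
        j = nearest_jitter(int(round(q[0] / th)))
        return q + np.array([0.0, j[1], j[0]])

    fids = FiducialSet(
        midline={k: annotate_point(v) for k, v in atlas.fiducials.midline.items()},
        lateral_pairs={
            k: {s: annotate_point(p) for s, p in v.items()}
            for k, v in atlas.fiducials.lateral_pairs.items()
        },
        midline_tol_um=np.inf,
    )

    # cells: uniform within regions, AP snapped to the containing section
    region_ids = atlas.regions["region_id"].to_numpy()
    if region_weights is None:
        weights = np.ones(len(region_ids)) / len(region_ids)
    else:
        weights = np.array([region_weights.get(int(r), 0.0) for r in region_ids], dtype=float)
        weights = weights / weights.sum()
    voxel_lists = {
        int(r): np.argwhere(atlas.labels == r) for r in region_ids
    }
    for r, v in voxel_lists.items():
        if len(v) == 0:
            raise ValueError(f"atlas region {r} has no voxels")

    coords_true = np.empty((n_cells, 3))
    regions_true = np.empty(n_cells, dtype=int)
    cell_rows = []
    for i in range(n_cells):
        r = int(rng.choice(region_ids, p=weights))
        for _attempt in range(200):
            vox = voxel_lists[r][rng.integers(len(voxel_lists[r]))]
            p = atlas.voxel_to_um(vox)[0] + rng.uniform(-0.5, 0.5, 3) * atlas.voxel_um
            q = g[:3, :3] @ p + g[:3, 3]
            sec = int(round(q[0] / th))
            q_snap = np.array([sec * th, q[1], q[2]])
            p_true = g_inv[:3, :3] @ q_snap + g_inv[:3, 3]
            if atlas.region_at(p_true)[0] == r:
                break
        else:
            raise RuntimeError(f"could not place a cell in region {r}")
        j = nearest_jitter(sec)
        coords_true[i] = p_true
        regions_true[i] = r
        cell_rows.append(
            dict(section_index=sec, ml_um=q_snap[2] + j[0], dv_um=q_snap[1] + j[1])
        )

    cells = pd.DataFrame(cell_rows, columns=["section_index", "ml_um", "dv_um"])
    if intensity_dist is None:
        cells["raw_intensity"] = _default_intensities(rng, n_cells, dim_fraction)
    else:
        cells["raw_intensity"] = intensity_dist(rng, n_cells)

    brain = AnnotatedBrain(
        brain_id=brain_id,
        section_thickness_um=th,
        pixel_um=pixel_um,
        fiducials=fids,
        boxes=brain_boxes,
        cells=cells,
        meta={"seed": seed, "jitter_sd": jitter_sd},
    )
    truth = SynthBrainTruth(
        chain=chain,
        params=params,
        cell_atlas_coords=coords_true,
        cell_true_regions=regions_true,
        jitter_per_slice=jitter,
    )
    return brain, truth


# ----------------------------------------------------------------------
# Photometry
# ----------------------------------------------------------------------
@dataclass
class SynthSignalTruth:
    """Ground truth for a synthetic multi-site recording.

    ``A``, ``B``, ``C`` are the mixing coefficients of the thalamus trace
    (``thal = A*snr + B*dcn + C + noise``); ``noise_sd`` is the SD of the
    additive Gaussian noise in trace units; ``bleach_tau`` the shared
    photobleaching time constant in seconds (``None`` disables bleach).
    ``event_times`` is filled by the generator with the Ca²⁺ event times
    of each source region.
    """

    A: float = 0.5
    B: float = 0.3
    C: float = 0.1
    noise_sd: float = 0.05
    bleach_tau: float | None = 600.0
    event_rate_hz: float = 0.2
    kernel_tau_s: float = 1.0
    motion_amp: float = 0.02
    seed: int = 0
    event_times: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bleach_tau is not None and self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive (or None to disable)")
        for region, times in self.event_times.items():
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"event_times for {region} must be strictly increasing")


def _event_trace(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rate_hz: float,
    kernel_tau_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson event train convolved with an exponential-decay kernel.

    The ~1 s decay gives the traces the autocorrelation that makes the
    time-shift shuffle null meaningfully weaker than the observed fit.
    """
    times = []
    t = rng.exponential(1.0 / rate_hz)
    while t < n / fs:
        times.append(t)
        t += rng.exponential(1.0 / rate_hz)
    times = np.asarray(times)
    train = np.zeros(n)
    idx = np.floor(times * fs).astype(int)
    amps = rng.lognormal(0.0, 0.3, size=len(idx))
    np.add.at(train, idx, amps)
    k = np.exp(-np.arange(0, 5 * kernel_tau_s, 1 / fs) / kernel_tau_s)
    trace = np.convolve(train, k)[:n]
    return trace, times


def gen_photometry(
    duration_s: float,
    fs: float,
    truth: SynthSignalTruth,
    session_id: str = "session",
    day_index: int = 1,
    f470_base: float = 100.0,
    f410_base: float = 80.0,
    background_level: float = 10.0,
) -> PhotometryBundle:
    """Generate a synchronized three-site recording with known mixture.

    SNr and DCN ideal traces are autocorrelated event trains; the ideal
    thalamus trace is exactly ``A*snr + B*dcn + C`` plus Gaussian noise
    of SD ``truth.noise_sd``.  Raw 470 nm channels carry the ideal trace
    on a fluorescence baseline, multiplied by a shared exponential bleach
    and offset by the background level; 410 nm channels share the bleach
    and motion artifacts but not the Ca²⁺ transients.  ``truth`` is
    updated in place with the drawn event times, and the bundle's
    ``truth`` dict carries the ideal (artifact-free) traces.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    ideal: dict[str, np.ndarray] = {}
    truth.event_times = {}
    for region in ("snr", "dcn"):
        trace, times = _event_trace(rng, n, fs, truth.event_rate_hz, truth.kernel_tau_s)
        ideal[region] = trace
        truth.event_times[region] = times
    noise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else np.zeros(n)
    ideal["thalamus"] = truth.A * ideal["snr"] + truth.B * ideal["dcn"] + truth.C + noise

    bleach = np.exp(-t / truth.bleach_tau) if truth.bleach_tau is not None else np.ones(n)
    if truth.motion_amp > 0:
        raw = rng.normal(0.0, 1.0, n)
        k = np.exp(-np.arange(0, 2.0, 1 / fs) / 0.5)
        motion = truth.motion_amp * np.convolve(raw, k / np.sqrt((k**2).sum()))[:n]
    else:
        motion = np.zeros(n)

    signals = {}
    for region in ("snr", "dcn", "thalamus"):
        f470 = f470_base * (1.0 + ideal[region] + motion) * bleach + background_level
        f410 = f410_base * (1.0 + motion) * bleach + background_level
        signals[region] = {"470": f470, "410": f410}
    background = np.full(n, background_level)

    return PhotometryBundle(
        signals=signals,
        background=background,
        fs=fs,
        session_id=session_id,
        day_index=day_index,
        truth={"ideal": ideal, "params": {"A": truth.A, "B": truth.B, "C": truth.C,
                                          "noise_sd": truth.noise_sd}},
    )


# ----------------------------------------------------------------------
# Behavior
# ----------------------------------------------------------------------
def gen_behavior(
    kind: str,
    events: list[tuple[float, float]],
    fs: float,
    duration_s: float,
    rise_s: float = 0.15,
    hold_s: float = 0.10,
    fall_s: float = 0.25,
) -> np.ndarray:
    """A lever-position (mm) or wheel-velocity trace with known events.

    Each event ``(time_s, amplitude)`` produces a linear-rise /
    hold / linear-fall excursion starting exactly at ``time_s``.  Lever
    amplitudes must fit the 8 mm travel of the manipulandum.  Events
    whose extents overlap are rejected: the generator's event list is the
    detector's ground truth, and overlapping excursions would make it
    ambiguous.
    """
    if kind not in ("lever", "wheel"):
        raise ValueError(f"unknown behavior kind {kind!r}")
    n = int(round(duration_s * fs))
    trace = np.zeros(n)
    span = rise_s + hold_s + fall_s
    prev_end = -np.inf
    for time_s, amp in sorted(events):
        if kind == "lever" and not (0.0 < amp <= 8.0):
            raise ValueError(f"lever amplitude {amp} mm outside the 0–8 mm travel")
        if time_s < prev_end:
            raise ValueError(f"event at {time_s:.3f} s overlaps the previous event")
        prev_end = time_s + span
        i0 = int(round(time_s * fs))
        for k in range(i0, min(i0 + int(round(span * fs)) + 1, n)):
            dt = (k - i0) / fs
            if dt < rise_s:
                v = amp * dt / rise_s
            elif dt < rise_s + hold_s:
                v = amp
            else:
                v = max(amp * (1.0 - (dt - rise_s - hold_s) / fall_s), 0.0)
            trace[k] = max(trace[k], v)
    return trace
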