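"""Perpendicular cross-section extraction and airway/artery diameter measurement.

A cross-section is resampled from the CT volume on a plane perpendicular to
the (smoothed) branch centreline tangent, which removes the parallax error of
axial reslices through oblique airways. Diameters are measured by casting
rays from the centre: along each ray the lumen/wall and wall/parenchyma edges
are placed at full-width-half-maximum crossings, an ellipse is fitted to each
edge-point set, and the equivalent-area diameter ``2 * sqrt(area / pi)`` is
reported — the automated analogue of manual area-based ellipse annotation.

Quality control mirrors clinical practice: a branch is excluded when no inner
lumen is resolvable (mucus plugging, sub-voxel calibre), when no adjacent
artery is identifiable, or when the patch is too noisy for a reliable fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from aaquant.phantom import PhantomVolume, HU_PARENCHYMA
from aaquant.tree_model import AirwayTree, Branch, GenerationLabels, label_tree

logger = logging.getLogger(__name__)

QC_OK = "ok"
QC_NO_LUMEN = "excluded_no_lumen"
QC_NO_ARTERY = "excluded_no_artery"
QC_NOISE = "excluded_noise"


class BoundaryError(ValueError):
    """Cross-section plane leaves the volume."""


class GeometryError(ValueError):
    """Degenerate centreline tangent."""


class MeasurementExclusion(Exception):
    """A measurement failed a quality-control rule (carries the qc status)."""

    def __init__(self, status: str, detail: str = ""):
        super().__init__(f"{status}: {detail}" if detail else status)
        self.status = status
        self.detail = detail


@dataclass
class MeasureConfig:
    """Tunable measurement parameters (YAML namespace ``measure.*``)."""

    n_rays: int = 64
    position: float = 0.5               # arclength fraction along each branch
    patch_factor: float = 3.0           # patch side as multiple of outer diameter
    patch_oversampling: float = 2.0     # in-plane grid finer than voxels by this
    smoothing_window: int = 5           # centreline moving-average width (points)
    min_valid_ray_frac: float = 0.6
    contrast_factor: float = 3.0        # lumen/wall contrast >= this x noise sd
    min_lumen_voxels: float = 2.0       # lumen must span >= this many voxels
    max_residual_frac: float = 0.15     # ellipse RMS residual / radius
    max_noise_sd_hu: float = 150.0      # above this a failed fit counts as noise
    artery_search_factor: float = 3.0   # search radius x expected outer radius
    artery_threshold_hu: Optional[float] = None  # None: background/peak midpoint
    artery_area_bounds: Tuple[float, float] = (0.2, 5.0)  # x expected artery area
    default_outer_diameter_mm: float = 4.0  # when no ground truth is available
    boundary_tolerance_frac: float = 0.02   # patch samples allowed out of volume


@dataclass
class CrossSection:
    """A 2-D patch resampled perpendicular to the centreline."""

    patch: np.ndarray               # (n, n) intensities
    spacing_mm: float               # in-plane, isotropic
    centre_mm: np.ndarray           # world position of the patch centre
    axis_u: np.ndarray              # in-plane unit vectors (world)
    axis_v: np.ndarray
    normal: np.ndarray              # centreline tangent (unit)
    branch_id: str = ""
    arclength_fraction: float = 0.5
    volume: Optional[PhantomVolume] = None

    @property
    def centre_px(self) -> float:
        return (self.patch.shape[0] - 1) / 2.0


def _smoothed_tangent(centreline: np.ndarray, fraction: float,
                      window: int) -> np.ndarray:
    """Unit tangent at an arclength fraction, from a moving-average smoothed
    polyline and centred differences."""
    pts = centreline
    if len(pts) >= window > 1:
        kernel = np.ones(window) / window
        sm = np.column_stack([
            np.convolve(np.pad(pts[:, k], window // 2, mode="edge"),
                        kernel, mode="valid")
            for k in range(3)
        ])
        # keep endpoints anchored so the position lookup stays aligned
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.all(seg == 0):
        raise GeometryError("centreline points all coincide")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = fraction * cum[-1]
    i = int(np.clip(np.searchsorted(cum, target, side="right") - 1, 0, len(seg) - 1))
    lo, hi = max(i - 1, 0), min(i + 2, len(pts) - 1)
    tangent = pts[hi] - pts[lo]
    n = np.linalg.norm(tangent)
    if n == 0:
        raise GeometryError("degenerate tangent (repeated centreline points)")
    return tangent / n


def _plane_axes(normal: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _expected_radii(branch: Branch, config: MeasureConfig) -> Tuple[float, float]:
    """(outer airway radius, artery radius) to size the patch and searches."""
    r_out = (branch.outer_radius_mm if branch.outer_radius_mm is not None
             else config.default_outer_diameter_mm / 2)
    r_art = branch.artery_radius_mm if branch.artery_radius_mm is not None else r_out
    return r_out, r_art


def extract_cross_section(volume: PhantomVolume, branch: Branch,
                          position: float = 0.5,
                          config: Optional[MeasureConfig] = None) -> CrossSection:
    """Resample a patch perpendicular to the centreline at ``position``.

    The patch is centred on the exact (continuous) centreline point, sampled
    by trilinear interpolation on an isotropic in-plane grid finer than the
    voxel spacing, with side length ``patch_factor`` times the expected outer
    diameter (wide enough to include the paired artery).
    """
    config = config or MeasureConfig()
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must be an arclength fraction in [0, 1]")
    centre = branch.point_at(position)
    normal = _smoothed_tangent(branch.centreline, position, config.smoothing_window)
    u, v = _plane_axes(normal)

    r_out, r_art = _expected_radii(branch, config)
    half = max(config.patch_factor * r_out, r_out + 3.0 * r_art, 3.0)
    spacing = float(volume.spacing_mm.min()) / config.patch_oversampling
    n = int(2 * math.ceil(half / spacing)) + 1
    offs = (np.arange(n) - (n - 1) / 2) * spacing
    grid = (centre[None, None, :]
            + offs[:, None, None] * u[None, None, :]
            + offs[None, :, None] * v[None, None, :])
    idx = volume.world_to_voxel(grid.reshape(-1, 3)).T

    shape = np.array(volume.data.shape)
    outside = np.any((idx < -0.5) | (idx > (shape[:, None] - 0.5)), axis=0)
    if outside.mean() > config.boundary_tolerance_frac:
        raise BoundaryError(
            f"branch {branch.branch_id}: {outside.mean():.0%} of the patch "
            f"falls outside the volume"
        )
    patch = ndimage.map_coordinates(volume.data, idx, order=1,
                                    mode="constant", cval=HU_PARENCHYMA)
    return CrossSection(
        patch=patch.reshape(n, n).astype(float),
        spacing_mm=spacing, centre_mm=centre,
        axis_u=u, axis_v=v, normal=normal,
        branch_id=branch.branch_id, arclength_fraction=position,
        volume=volume,
    )


# ---------------------------------------------------------------------------
# airway measurement
# ---------------------------------------------------------------------------

def _sample_rays(cs: CrossSection, n_rays: int, r_max_mm: float,
                 step_mm: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear profiles along rays from the patch centre.

    Returns (radii_mm, angles, profiles[n_rays, n_steps])."""
    radii = np.arange(0.0, r_max_mm, step_mm)
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    c = cs.centre_px
    px = c + np.cos(angles)[:, None] * radii[None, :] / cs.spacing_mm
    py = c + np.sin(angles)[:, None] * radii[None, :] / cs.spacing_mm
    prof = ndimage.map_coordinates(cs.patch, [px.ravel(), py.ravel()],
                                   order=1, mode="nearest")
    return radii, angles, prof.reshape(n_rays, len(radii))


def estimate_patch_noise_sd(patch: np.ndarray) -> float:
    """Robust noise estimate from horizontal first differences (edges are a
    small minority of pixels, so the median absolute difference is driven by
    noise, not structure)."""
    d = np.diff(patch, axis=1)
    return float(1.4826 * np.median(np.abs(d)) / math.sqrt(2.0))


def _cross_up(radii: np.ndarray, prof: np.ndarray, i0: int, i1: int,
              level: float) -> Optional[float]:
    """First sub-sample upward crossing of `level` in prof[i0:i1]."""
    for i in range(i0, min(i1, len(prof) - 1)):
        if prof[i] < level <= prof[i + 1]:
            t = (level - prof[i]) / (prof[i + 1] - prof[i])
            return float(radii[i] + t * (radii[i + 1] - radii[i]))
    return None


def _cross_down(radii: np.ndarray, prof: np.ndarray, i0: int,
                level: float) -> Optional[float]:
    for i in range(i0, len(prof) - 1):
        if prof[i] >= level > prof[i + 1]:
            t = (prof[i] - level) / (prof[i] - prof[i + 1])
            return float(radii[i] + t * (radii[i + 1] - radii[i]))
    return None


def _fit_ellipse_diameter(points_xy: np.ndarray) -> Tuple[float, float]:
    """(equivalent-area diameter, RMS residual) of an ellipse fit, with a
    circle fallback for degenerate point sets."""
    model = None
    if len(points_xy) >= 5:
        try:
            m = skmeasure.EllipseModel.from_estimate(points_xy)
            if m:
                model = m
        except Exception:
            model = None
    if model is not None:
        a, b = (float(x) for x in model.axis_lengths)
        if a > 0 and b > 0:
            resid = float(np.sqrt(np.mean(model.residuals(points_xy) ** 2)))
            return 2.0 * math.sqrt(a * b), resid
    r = np.linalg.norm(points_xy - points_xy.mean(axis=0), axis=1)
    return 2.0 * float(r.mean()), float(r.std())


def measure_airway(cs: CrossSection,
                   config: Optional[MeasureConfig] = None
                   ) -> Tuple[float, float, Dict]:
    """Measure inner and outer airway diameters (mm) on a cross-section.

    Raises :class:`MeasurementExclusion` with status ``excluded_no_lumen``
    when too few rays resolve a lumen/wall edge, or ``excluded_noise`` when
    the patch is noise-dominated or the edge sets do not fit an ellipse.
    """
    config = config or MeasureConfig()
    patch = cs.patch
    noise_sd = estimate_patch_noise_sd(patch)
    background = float(np.median(patch))

    r_max = (cs.patch.shape[0] - 1) / 2 * cs.spacing_mm
    step = cs.spacing_mm / 2
    radii, angles, prof = _sample_rays(cs, config.n_rays, r_max, step)

    n_centre = max(2, int(0.25 / step))     # first ~0.25 mm = lumen plateau
    contrast_min = config.contrast_factor * max(noise_sd, 1.0)
    inner_pts, outer_pts = [], []
    for k in range(config.n_rays):
        p = ndimage.gaussian_filter1d(prof[k], sigma=1.0)
        lumen_level = float(p[:n_centre].mean())
        # the wall is the FIRST local maximum with lumen contrast along the
        # ray; a global argmax would lock onto the brighter paired artery
        i_peak = None
        for i in range(1, len(p) - 1):
            if (p[i] >= p[i - 1] and p[i] >= p[i + 1]
                    and p[i] - lumen_level >= contrast_min):
                i_peak = i
                break
        if i_peak is None:
            continue
        wall_level = float(p[i_peak])
        half_in = (lumen_level + wall_level) / 2
        r_in = _cross_up(radii, p, 0, i_peak + 1, half_in)
        if r_in is None:
            continue
        half_out = (wall_level + background) / 2
        r_out = _cross_down(radii, p, i_peak, half_out)
        if r_out is None or r_out <= r_in:
            continue
        inner_pts.append((r_in * math.cos(angles[k]), r_in * math.sin(angles[k])))
        outer_pts.append((r_out * math.cos(angles[k]), r_out * math.sin(angles[k])))

    # robust trim: drop rays whose edge radius is far from the ring median
    # (a touching neighbour or the paired artery can drag single rays out)
    def _trim(pts: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
        if len(pts) < 8:
            return pts
        r = np.linalg.norm(np.asarray(pts), axis=1)
        med = float(np.median(r))
        keep = np.abs(r - med) <= max(0.35 * med, 0.3)
        return [p for p, k in zip(pts, keep) if k]

    inner_pts = _trim(inner_pts)
    outer_pts = _trim(outer_pts)

    valid_frac = len(inner_pts) / config.n_rays
    diag = {"valid_ray_frac": valid_frac, "noise_sd_hu": noise_sd,
            "background_hu": background}
    if valid_frac < config.min_valid_ray_frac:
        if noise_sd > config.max_noise_sd_hu:
            raise MeasurementExclusion(QC_NOISE,
                                       f"noise sd {noise_sd:.0f} HU, "
                                       f"{valid_frac:.0%} valid rays")
        raise MeasurementExclusion(QC_NO_LUMEN,
                                   f"only {valid_frac:.0%} of rays found a "
                                   f"lumen/wall edge")

    inner_d, inner_res = _fit_ellipse_diameter(np.asarray(inner_pts))
    outer_d, outer_res = _fit_ellipse_diameter(np.asarray(outer_pts))
    diag.update(inner_residual_mm=inner_res, outer_residual_mm=outer_res)
    max_res = config.max_residual_frac * max(outer_d / 2, cs.spacing_mm)
    if inner_res > max_res or outer_res > max_res:
        raise MeasurementExclusion(
            QC_NOISE, f"ellipse residual {max(inner_res, outer_res):.2f} mm "
                      f"exceeds {max_res:.2f} mm")
    min_lumen = config.min_lumen_voxels * (
        cs.spacing_mm * config.patch_oversampling)
    if inner_d < min_lumen:
        raise MeasurementExclusion(
            QC_NO_LUMEN, f"lumen {inner_d:.2f} mm below the "
                         f"{min_lumen:.2f} mm resolvability limit")
    if outer_d <= inner_d:
        raise MeasurementExclusion(QC_NOISE, "outer fit collapsed onto lumen")
    return inner_d, outer_d, diag


# ---------------------------------------------------------------------------
# artery measurement
# ---------------------------------------------------------------------------

def measure_artery(cs: CrossSection, config: Optional[MeasureConfig] = None,
                   expected_outer_radius_mm: Optional[float] = None,
                   expected_artery_radius_mm: Optional[float] = None,
                   airway_outer_radius_mm: Optional[float] = None
                   ) -> Tuple[float, Dict]:
    """Measure the paired artery diameter (mm) on a cross-section.

    The artery is the brightest above-threshold connected component whose
    centroid lies within the search radius of the airway centre; nearest
    centroid wins ties (logged). Raises :class:`MeasurementExclusion`
    (``excluded_no_artery``) when no plausible component exists.
    """
    config = config or MeasureConfig()
    patch = ndimage.gaussian_filter(cs.patch, sigma=0.7)
    if config.artery_threshold_hu is not None:
        threshold = config.artery_threshold_hu
    else:
        # full-width-half-maximum convention: the vessel boundary sits at the
        # midpoint between the parenchyma background and the bright plateau
        background = float(np.median(patch))
        threshold = 0.5 * (background + float(patch.max()))
    mask = patch > threshold
    if airway_outer_radius_mm is not None:
        # blank the airway's own footprint: its wall ring is above the
        # vessel threshold and must not masquerade as the artery
        n = patch.shape[0]
        yy, xx = np.mgrid[0:n, 0:n]
        rr = np.hypot(yy - cs.centre_px, xx - cs.centre_px) * cs.spacing_mm
        mask &= rr > 1.1 * airway_outer_radius_mm

    r_out = expected_outer_radius_mm or config.default_outer_diameter_mm / 2
    search_mm = config.artery_search_factor * r_out
    r_art = expected_artery_radius_mm or r_out
    area_px = math.pi * r_art ** 2 / cs.spacing_mm ** 2
    lo, hi = (b * area_px for b in config.artery_area_bounds)

    labels = skmeasure.label(mask)
    c = cs.centre_px
    candidates = []
    for region in skmeasure.regionprops(labels):
        if not lo <= region.area <= hi:
            continue
        dy, dx = region.centroid[0] - c, region.centroid[1] - c
        dist_mm = math.hypot(dy, dx) * cs.spacing_mm
        # components at/inside the airway's own footprint are its wall, not
        # an adjacent vessel
        if dist_mm > search_mm or dist_mm < 0.8 * r_out:
            continue
        candidates.append((dist_mm, region))
    if not candidates:
        raise MeasurementExclusion(
            QC_NO_ARTERY, "no identifiable adjacent artery within "
                          f"{search_mm:.1f} mm")
    candidates.sort(key=lambda t: t[0])
    if len(candidates) > 1:
        logger.info("branch %s: %d artery candidates, tie broken toward the "
                    "nearest (%.1f mm)", cs.branch_id, len(candidates),
                    candidates[0][0])
    dist_mm, region = candidates[0]
    coords = (region.coords - region.coords.mean(axis=0)) * cs.spacing_mm
    # boundary pixels of the component, in mm relative to its centroid
    boundary = skmeasure.find_contours(labels == region.label, 0.5)
    if boundary:
        pts = (np.vstack(boundary) - region.centroid) * cs.spacing_mm
        d, resid = _fit_ellipse_diameter(pts)
    else:
        d = 2.0 * math.sqrt(region.area / math.pi) * cs.spacing_mm
        resid = float("nan")
    diag = {"artery_distance_mm": dist_mm, "artery_residual_mm": resid,
            "artery_candidates": len(candidates),
            "artery_area_px": int(region.area)}
    return d, diag


# ---------------------------------------------------------------------------
# batch measurement
# ---------------------------------------------------------------------------

@dataclass
class AAMeasurement:
    """One airway-artery measurement attempt for one branch."""

    subject_id: str
    branch_id: str
    lobe: str
    generation: int
    segmental_generation: Optional[int]
    volume_state: str
    qc_status: str = QC_OK
    inner_diameter_mm: float = float("nan")
    outer_diameter_mm: float = float("nan")
    wall_thickness_mm: float = float("nan")
    artery_diameter_mm: float = float("nan")
    diagnostics: Dict = field(default_factory=dict)

    def as_row(self) -> Dict:
        row = asdict(self)
        diag = row.pop("diagnostics")
        row["valid_ray_frac"] = diag.get("valid_ray_frac", float("nan"))
        row["ellipse_residual_mm"] = diag.get("outer_residual_mm", float("nan"))
        row["artery_distance_mm"] = diag.get("artery_distance_mm", float("nan"))
        return row


def measure_branch(volume: PhantomVolume, branch: Branch,
                   labels: GenerationLabels, subject_id: str,
                   volume_state: str,
                   config: Optional[MeasureConfig] = None) -> AAMeasurement:
    """Attempt one AA measurement at the configured arclength position."""
    config = config or MeasureConfig()
    m = AAMeasurement(
        subject_id=subject_id,
        branch_id=branch.branch_id,
        lobe=branch.lobe,
        generation=labels.generation[branch.branch_id],
        segmental_generation=labels.segmental_generation.get(branch.branch_id),
        volume_state=volume_state,
    )
    r_out, r_art = _expected_radii(branch, config)
    try:
        cs = extract_cross_section(volume, branch, config.position, config)
        inner, outer, diag = measure_airway(cs, config)
        artery, adiag = measure_artery(cs, config,
                                       expected_outer_radius_mm=r_out,
                                       expected_artery_radius_mm=r_art,
                                       airway_outer_radius_mm=outer / 2)
        m.inner_diameter_mm = inner
        m.outer_diameter_mm = outer
        m.wall_thickness_mm = outer - inner
        m.artery_diameter_mm = artery
        m.diagnostics = {**diag, **adiag}
    except MeasurementExclusion as exc:
        m.qc_status = exc.status
        m.diagnostics = {"detail": exc.detail}
    except (BoundaryError, GeometryError) as exc:
        m.qc_status = QC_NOISE
        m.diagnostics = {"detail": f"unmeasurable geometry: {exc}"}
    return m


def measure_tree(volume: PhantomVolume, tree: AirwayTree,
                 labels: Optional[GenerationLabels] = None,
                 subject_id: str = "", volume_state: str = "inspiration",
                 config: Optional[MeasureConfig] = None) -> List[AAMeasurement]:
    """One measurement attempt per branch; never aborts the batch.

    Deterministic given volume, tree and config (measurement has no random
    state). Every branch gets a row; failures are recorded as qc exclusions.
    """
    labels = labels if labels is not None else label_tree(tree)
    return [
        measure_branch(volume, b, labels, subject_id, volume_state, config)
        for b in tree
    ]


def measurements_to_frame(measurements: List[AAMeasurement]) -> pd.DataFrame:
    df = pd.DataFrame([m.as_row() for m in measurements])
    if not df.empty:
        df["segmental_generation"] = df["segmental_generation"].astype("Float64")
    return df
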