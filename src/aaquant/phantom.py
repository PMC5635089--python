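"""Synthetic two-cohort chest-CT phantoms with known airway-artery ground truth.

Builds branching airway trees (trachea to ~8 segmental generations) whose
per-branch inner/outer airway and paired-artery diameters follow a configurable
disease model, and rasterizes them into CT-like intensity volumes:

* CF-like cohort: outer-airway/artery ratio and wall-thickness/artery ratio
  increase with segmental generation (bronchiectasis + wall thickening that
  worsen towards the periphery).
* Control cohort: ratios constant across generations.
* Paired inspiration/expiration volumes per subject: expiration multiplies
  airway (not artery) diameters by a fixed factor < 1, so airway calibre and
  the number of resolvable peripheral airway-artery pairs both drop.

The phantom stands in for patient CTs: tube intensities are flat plateaus at
nominal HU levels with Gaussian noise, so it exercises geometry, partial
volume and resolution limits, not scanner texture.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from aaquant.tree_model import AirwayTree, Branch, label_tree

# nominal intensity plateaus (HU)
HU_AIR = -1000.0
HU_WALL = -50.0
HU_BLOOD = 50.0
HU_PARENCHYMA = -850.0


class PhantomGenerationError(ValueError):
    """Raised when parameters produce an impossible geometry (e.g. inner <= 0)."""


@dataclass
class CohortParams:
    """Simulation parameters for one cohort.

    Ratio model, per branch at segmental generation ``g`` (g = 1 at the
    segmental bronchus; central airways use g = 1):

        AoutA(g) = base_AoutA + per_generation_slope_AoutA * (g - 1)
        AWTA(g)  = 2 * wall_fraction * base_AoutA
                   + per_generation_slope_AWTA * (g - 1)

    then ``outer = artery * AoutA`` and ``inner = artery * (AoutA - AWTA)``,
    with a subject-level normal shift on base_AoutA and lognormal
    branch-level jitter on both ratios. Arteries follow a geometric
    calibre taper with airway generation and are unaffected by lung volume;
    expiration multiplies airway diameters by ``volume_scale_expiration``.
    """

    n_subjects: int = 11
    disease_status: str = "CF"
    base_AoutA: float = 1.05
    per_generation_slope_AoutA: float = 0.03
    per_generation_slope_AWTA: float = 0.02
    wall_fraction: float = 0.17
    artery_d0_mm: float = 12.0          # artery diameter at generation 0
    artery_decay: float = 0.75          # per-generation geometric taper
    artery_profile_mm: Optional[Sequence[float]] = None  # explicit override
    volume_scale_expiration: float = 0.8
    noise_sd_HU: float = 25.0
    voxel_spacing_mm: float = 0.5
    rng_seed: int = 0
    # tree structure
    max_seg_gen: int = 8                # deepest segmental generation grown
    full_bifurcation_seg_gen: int = 2   # full binary splitting down to here
    n_segmental_per_lobe: int = 2
    # variability
    subject_sd: float = 0.05            # sd of subject shift on base_AoutA
    jitter_sigma: float = 0.1           # lognormal sigma on branch ratios

    def __post_init__(self) -> None:
        if self.per_generation_slope_AoutA < 0 or self.per_generation_slope_AWTA < 0:
            raise ValueError("per-generation slopes must be >= 0")
        if not 0 < self.volume_scale_expiration < 1:
            raise ValueError("volume_scale_expiration must be in (0, 1)")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be > 0")

    def artery_diameter(self, generation: int) -> float:
        if self.artery_profile_mm is not None:
            i = min(generation, len(self.artery_profile_mm) - 1)
            return float(self.artery_profile_mm[i])
        return self.artery_d0_mm * self.artery_decay ** generation


def control_params(**overrides) -> CohortParams:
    """Default control cohort: constant ratios across generations."""
    base = dict(
        n_subjects=12,
        disease_status="control",
        base_AoutA=1.0,
        per_generation_slope_AoutA=0.0,
        per_generation_slope_AWTA=0.0,
        wall_fraction=0.15,
        max_seg_gen=6,
    )
    base.update(overrides)
    return CohortParams(**base)


def cf_params(**overrides) -> CohortParams:
    """Default CF-like cohort: ratios widen with segmental generation.

    The artery taper is slightly slower than in controls (0.78 vs 0.75 per
    generation): bronchiectatic airway-artery pairs remain absolutely larger
    towards the periphery, so they stay above the CT resolution floor for
    two to three generations longer — the mechanism behind the excess of
    visible peripheral AA-pairs in CF.
    """
    return CohortParams(**{"n_subjects": 11, "disease_status": "CF",
                           "artery_decay": 0.78, **overrides})


@dataclass
class SubjectRecord:
    """One simulated CT acquisition (one subject in one volume state)."""

    subject_id: str
    disease_status: str
    age_years: float
    height_cm: float
    gender: str
    volume_state: str = "inspiration"

    def __post_init__(self) -> None:
        if self.volume_state not in ("inspiration", "expiration"):
            raise ValueError(f"unknown volume_state {self.volume_state!r}")
        if not 6.0 <= self.age_years <= 16.0:
            raise ValueError("age outside the simulated paediatric range (6-16 y)")


@dataclass
class PhantomVolume:
    """CT-like intensity grid with world geometry metadata."""

    data: np.ndarray                    # (nx, ny, nz) float32, HU
    spacing_mm: np.ndarray              # (3,)
    origin_mm: np.ndarray               # world position of voxel (0,0,0)
    tree: Optional[AirwayTree] = None

    def __post_init__(self) -> None:
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world-mm points (0-based)."""
        return (np.asarray(points_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def save_nifti(self, path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(self.spacing_mm))
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path) -> "PhantomVolume":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float32),
            spacing_mm=np.abs(np.diag(aff)[:3]),
            origin_mm=aff[:3, 3],
        )

    @classmethod
    def load(cls, path) -> "PhantomVolume":
        """Load a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
        name = str(path)
        if name.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.ReadImage(name)
            return cls(
                data=sitk.GetArrayFromImage(img).T.astype(np.float32),
                spacing_mm=np.asarray(img.GetSpacing()),
                origin_mm=np.asarray(img.GetOrigin()),
            )
        return cls.load_nifti(path)


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _rotate_about(direction: np.ndarray, angle_deg: float,
                  azimuth_deg: float) -> np.ndarray:
    """Unit vector at `angle` from `direction`, azimuth around it."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    a = np.radians(angle_deg)
    phi = np.radians(azimuth_deg)
    out = np.cos(a) * d + np.sin(a) * (np.cos(phi) * u + np.sin(phi) * v)
    return out / np.linalg.norm(out)


# central skeleton: id, parent, lobe, angle from parent dir, azimuth, length mm
# The trachea grows towards -z (craniocaudal); upper-lobe bronchi turn back
# upwards via large branch angles. Lengths are generous relative to calibre
# so neighbouring tubes stay separated at the measurement plane.
_CENTRAL_SKELETON = [
    ("Rmain", "trachea", "central", 38, 0, 22.0),
    ("Lmain", "trachea", "central", 42, 180, 26.0),
    ("RULb", "Rmain", "RUL", 80, -60, 16.0),
    ("BronInt", "Rmain", "central", 12, 120, 18.0),
    ("RMLb", "BronInt", "RML", 55, -140, 15.0),
    ("RLLb", "BronInt", "RLL", 12, 40, 15.0),
    ("LULb", "Lmain", "LUL", 65, 60, 16.0),
    ("LLLb", "Lmain", "LLL", 12, -90, 15.0),
    ("LINGb", "LULb", "LING", 50, 160, 13.0),
]

# where each lobe's segmental bronchi attach; lower lobes insert one extra
# division, so upper-lobe segments start at generation 3 and lower-lobe ones
# at generation 4-5, mimicking the real depth asymmetry between lobes
_LOBE_ENTRY = {
    "RUL": ("RULb", False),   # segmental children of RULb -> generation 3
    "LUL": ("LULb", False),
    "LING": ("LINGb", False),
    "RML": ("RMLb", False),   # generation 4
    "RLL": ("RLLb", True),    # extra division: segments at generations 4 and 5
    "LLL": ("LLLb", True),
}


def _branch_length(params: CohortParams, generation: int) -> float:
    """Branch length ~3.2x the local artery (and hence airway) calibre, so
    sibling tubes clear each other by mid-branch."""
    return float(np.clip(4.0 * params.artery_diameter(generation), 3.0, 28.0))


class _TreeBuilder:
    def __init__(self, params: CohortParams, subject: SubjectRecord,
                 rng: np.random.Generator):
        self.p = params
        self.subject = subject
        self.rng = rng
        self.branches: List[Branch] = []
        self.gen: Dict[str, int] = {}
        self.dir: Dict[str, np.ndarray] = {}
        self.subject_shift = rng.normal(0.0, params.subject_sd)
        self.airway_scale = (params.volume_scale_expiration
                            if subject.volume_state == "expiration" else 1.0)

    def radii(self, generation: int, seg_gen: Optional[int]) -> Tuple[float, float, float]:
        """(inner_r, outer_r, artery_r) in mm for one branch."""
        p = self.p
        g = 1 if seg_gen is None else seg_gen
        artery_d = p.artery_diameter(generation)
        aouta = (p.base_AoutA + self.subject_shift
                 + p.per_generation_slope_AoutA * (g - 1))
        awta = (2.0 * p.wall_fraction * p.base_AoutA
                + p.per_generation_slope_AWTA * (g - 1))
        aouta *= float(np.exp(self.rng.normal(0.0, p.jitter_sigma)))
        awta *= float(np.exp(self.rng.normal(0.0, p.jitter_sigma)))
        outer_d = artery_d * aouta * self.airway_scale
        inner_d = artery_d * (aouta - awta) * self.airway_scale
        if inner_d <= 0:
            raise PhantomGenerationError(
                f"parameters give non-positive inner diameter at generation "
                f"{generation} (AoutA={aouta:.3f}, AWTA={awta:.3f})"
            )
        return inner_d / 2, outer_d / 2, artery_d / 2

    def add(self, branch_id: str, parent_id: Optional[str], start: np.ndarray,
            direction: np.ndarray, length: float, lobe: str,
            generation: int, seg_gen: Optional[int],
            is_segmental: bool = False) -> np.ndarray:
        end = start + direction * length
        inner_r, outer_r, artery_r = self.radii(generation, seg_gen)
        self.branches.append(Branch(
            branch_id=branch_id,
            parent_id=parent_id,
            centreline=np.vstack([start, (start + end) / 2, end]),
            lobe=lobe,
            is_segmental_bronchus=is_segmental,
            inner_radius_mm=inner_r,
            outer_radius_mm=outer_r,
            artery_radius_mm=artery_r,
        ))
        self.gen[branch_id] = generation
        self.dir[branch_id] = direction
        return end

    def grow_subtree(self, parent_id: str, start: np.ndarray,
                     direction: np.ndarray, lobe: str, generation: int,
                     seg_gen: int) -> None:
        """Grow a segment subtree keeping every internal node bifurcating.

        Full binary splitting down to ``full_bifurcation_seg_gen``; past that,
        each node spawns a continuing "main" daughter and a terminating side
        twig, which bounds branch count while still reaching
        ``max_seg_gen`` segmental generations.
        """
        p = self.p
        if seg_gen > p.max_seg_gen:
            return
        full = seg_gen <= p.full_bifurcation_seg_gen
        base_phi = self.rng.uniform(0, 360)
        for k in range(2):
            bid = f"{parent_id}.{k}"
            if full:
                angle = self.rng.uniform(35, 50)
            else:
                # continuing main daughter runs nearly straight; the
                # terminating twig swings wide out of its way
                angle = self.rng.uniform(5, 15) if k == 0 else self.rng.uniform(40, 55)
            phi = base_phi + 180 * k + self.rng.uniform(-20, 20)
            d = _rotate_about(direction, angle, phi)
            end = self.add(bid, parent_id, start, d,
                           _branch_length(p, generation), lobe, generation,
                           seg_gen)
            if full or k == 0:
                self.grow_subtree(bid, end, d, lobe, generation + 1, seg_gen + 1)

    def add_segmental(self, bid: str, attach: str, start: np.ndarray,
                      direction: np.ndarray, lobe: str, generation: int) -> None:
        phi = self.rng.uniform(0, 360)
        d = _rotate_about(direction, self.rng.uniform(30, 45), phi)
        end = self.add(bid, attach, start, d,
                       _branch_length(self.p, generation), lobe,
                       generation, 1, is_segmental=True)
        self.grow_subtree(bid, end, d, lobe, generation + 1, 2)

    def build(self) -> AirwayTree:
        top = np.array([0.0, 0.0, 20.0])
        down = np.array([0.0, 0.0, -1.0])
        carina = self.add("trachea", None, top, down, 20.0, "central", 0, None)
        ends = {"trachea": carina}
        for bid, parent, lobe, angle, azim, length in _CENTRAL_SKELETON:
            d = _rotate_about(self.dir[parent], angle, azim)
            ends[bid] = self.add(bid, parent, ends[parent], d, length, lobe,
                                 self.gen[parent] + 1, None)
        for lobe, (entry, extra_division) in _LOBE_ENTRY.items():
            start, direction = ends[entry], self.dir[entry]
            gen_child = self.gen[entry] + 1
            if extra_division:
                # lobar bronchus -> {segment 1, basal division}; basal
                # division -> {segment 2, segment 3} one generation deeper
                self.add_segmental(f"{lobe}_S1", entry, start, direction,
                                   lobe, gen_child)
                div = f"{entry}_div"
                d = _rotate_about(direction, 15, self.rng.uniform(0, 360))
                div_end = self.add(div, entry, start, d,
                                   _branch_length(self.p, gen_child), lobe,
                                   gen_child, None)
                for s in (2, 3):
                    self.add_segmental(f"{lobe}_S{s}", div, div_end, d,
                                       lobe, gen_child + 1)
            else:
                for s in range(self.p.n_segmental_per_lobe):
                    self.add_segmental(f"{lobe}_S{s + 1}", entry, start,
                                       direction, lobe, gen_child)
        return AirwayTree(self.branches)


def generate_tree(params: CohortParams, subject: SubjectRecord,
                  rng: np.random.Generator) -> AirwayTree:
    """Generate one subject's airway tree with ground-truth radii.

    Deterministic given the rng state; calling twice with identically seeded
    generators and subjects differing only in ``volume_state`` yields the same
    geometry with airway (not artery) radii scaled by
    ``params.volume_scale_expiration`` in expiration.
    """
    return _TreeBuilder(params, subject, rng).build()


def apply_volume_state(tree: AirwayTree, scale: float) -> AirwayTree:
    """Return a copy with airway diameters scaled (artery untouched).

    Models the calibre drop from inspiration to expiration breath-hold.
    """
    scaled = [replace(
        b,
        centreline=b.centreline.copy(),
        inner_radius_mm=None if b.inner_radius_mm is None else b.inner_radius_mm * scale,
        outer_radius_mm=None if b.outer_radius_mm is None else b.outer_radius_mm * scale,
    ) for b in tree]
    return AirwayTree(scaled)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def artery_offset_direction(branch: Branch,
                            parent_dir: Optional[np.ndarray] = None) -> np.ndarray:
    """Deterministic lateral unit vector for a branch's paired artery.

    Perpendicular to the branch axis. When the parent direction is known the
    artery runs along the binormal of the bifurcation plane — the side of
    the branch facing away from its siblings — which keeps artery tubes out
    of neighbouring airways; the sign and the root fallback azimuth come
    from a CRC of the branch id, so rasterization needs no random state.
    """
    d = branch.centreline[-1] - branch.centreline[0]
    d = d / np.linalg.norm(d)
    crc = zlib.crc32(branch.branch_id.encode())
    if parent_dir is not None:
        b = np.cross(d, parent_dir)
        n = np.linalg.norm(b)
        if n > 1e-3:
            b = b / n
            return b if crc % 2 == 0 else -b
    return _rotate_about(d, 90.0, float(crc % 360))


def artery_centre_offset_mm(branch: Branch) -> float:
    """Centre-to-centre airway-artery distance: outer radius + 1.5 x artery
    radius, leaving a half-artery-radius parenchyma gap so the artery is
    adjacent but never fused with the airway wall."""
    return branch.outer_radius_mm + 1.5 * branch.artery_radius_mm


def _paint_tube(data: np.ndarray, spacing: np.ndarray, origin: np.ndarray,
                p0: np.ndarray, p1: np.ndarray, radius: float,
                hu: float) -> None:
    """Composite one cylinder segment into the volume.

    Coverage is 1 inside, 0 outside, and estimated by 2x2x2 supersampled
    averaging in the one-voxel shell around the surface (partial volume).
    """
    h = float(spacing.min())
    lo = np.minimum(p0, p1) - radius - h
    hi = np.maximum(p0, p1) + radius + h
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1,
                    np.array(data.shape))
    if np.any(i1 <= i0):
        return
    idx = np.mgrid[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]].astype(float)
    pts = np.stack([idx[k] * spacing[k] + origin[k] for k in range(3)], axis=-1)

    def seg_dist(q: np.ndarray) -> np.ndarray:
        v = p1 - p0
        t = np.clip(((q - p0) @ v) / (v @ v), 0.0, 1.0)
        return np.linalg.norm(q - (p0 + t[..., None] * v), axis=-1)

    d = seg_dist(pts)
    cover = (d <= radius - 0.5 * h).astype(np.float32)
    shell = np.abs(d - radius) < h
    if shell.any():
        q = pts[shell]
        sub = np.zeros(len(q), dtype=np.float32)
        for off in np.array([[sx, sy, sz] for sx in (-0.25, 0.25)
                             for sy in (-0.25, 0.25) for sz in (-0.25, 0.25)]):
            sub += seg_dist(q + off * spacing) <= radius
        cover[shell] = sub / 8.0
    sl = tuple(slice(i0[k], i1[k]) for k in range(3))
    data[sl] = data[sl] * (1 - cover) + hu * cover


def rasterize(tree: AirwayTree, spacing_mm: float | Sequence[float] = 0.5,
              noise_sd_HU: float = 25.0,
              rng: Optional[np.random.Generator] = None,
              margin_mm: float = 8.0,
              plugged_branch_ids: Sequence[str] = (),
              suppress_artery_ids: Sequence[str] = (),
              hu_air: float = HU_AIR, hu_wall: float = HU_WALL,
              hu_blood: float = HU_BLOOD,
              hu_parenchyma: float = HU_PARENCHYMA) -> PhantomVolume:
    """Rasterize a tree (airway walls, lumina, paired arteries) into a volume.

    Draw order is walls, then arteries, then lumina, so a lumen is never
    occluded by a neighbouring structure. ``plugged_branch_ids`` skip the
    lumen (mucus plugging); ``suppress_artery_ids`` skip the artery
    (e.g. atelectasis), both for exclusion-rule testing.
    """
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    for b in tree:
        if b.outer_radius_mm is None or b.artery_radius_mm is None:
            raise ValueError(f"branch {b.branch_id} lacks ground-truth radii")

    pts = []
    for b in tree:
        reach = artery_centre_offset_mm(b) + b.artery_radius_mm
        pts.append(b.centreline - reach)
        pts.append(b.centreline + reach)
    allpts = np.vstack(pts)
    origin = allpts.min(axis=0) - margin_mm
    extent = allpts.max(axis=0) + margin_mm - origin
    shape = tuple(np.ceil(extent / spacing).astype(int) + 1)
    data = np.full(shape, hu_parenchyma, dtype=np.float32)

    plugged, no_artery = set(plugged_branch_ids), set(suppress_artery_ids)

    def paint_polyline(line: np.ndarray, radius: float, hu: float) -> None:
        for i in range(len(line) - 1):
            _paint_tube(data, spacing, origin, line[i], line[i + 1], radius, hu)

    parent_dirs = {}
    for b in tree:
        if b.parent_id is not None:
            pc = tree[b.parent_id].centreline
            v = pc[-1] - pc[0]
            parent_dirs[b.branch_id] = v / np.linalg.norm(v)

    for b in tree:
        paint_polyline(b.centreline, b.outer_radius_mm, hu_wall)
    for b in tree:
        if b.branch_id in no_artery:
            continue
        off = artery_offset_direction(b, parent_dirs.get(b.branch_id)) \
            * artery_centre_offset_mm(b)
        paint_polyline(b.centreline + off, b.artery_radius_mm, hu_blood)
    for b in tree:
        hu = hu_wall if b.branch_id in plugged else hu_air
        paint_polyline(b.centreline, b.inner_radius_mm, hu)

    if noise_sd_HU > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        data += rng.normal(0.0, noise_sd_HU, size=data.shape).astype(np.float32)
    return PhantomVolume(data=data, spacing_mm=spacing, origin_mm=origin, tree=tree)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """One simulated study: subjects, paired trees, optional volumes, truth."""

    subjects: List[SubjectRecord]
    trees: Dict[Tuple[str, str], AirwayTree] = field(default_factory=dict)
    volumes: Dict[Tuple[str, str], PhantomVolume] = field(default_factory=dict)
    ground_truth: Optional[pd.DataFrame] = None


def _simulate_subject_covariates(rng: np.random.Generator) -> Tuple[float, float, str]:
    age = float(rng.uniform(6.0, 16.0))
    height = float(np.clip(6.2 * age + 80 + rng.normal(0, 6), 105, 185))
    gender = "M" if rng.random() < 0.5 else "F"
    return age, height, gender


def ground_truth_table(tree: AirwayTree, subject: SubjectRecord) -> pd.DataFrame:
    """Per-branch ground-truth diameters in the measurement CSV schema."""
    labels = label_tree(tree)
    rows = []
    for b in tree:
        sg = labels.segmental_generation.get(b.branch_id)
        rows.append({
            "subject_id": subject.subject_id,
            "disease_status": subject.disease_status,
            "volume_state": subject.volume_state,
            "age_years": subject.age_years,
            "height_cm": subject.height_cm,
            "gender": subject.gender,
            "branch_id": b.branch_id,
            "lobe": b.lobe,
            "generation": labels.generation[b.branch_id],
            "segmental_generation": np.nan if sg is None else sg,
            "is_peripheral": labels.is_peripheral[b.branch_id],
            "inner_diameter_mm": 2 * b.inner_radius_mm,
            "outer_diameter_mm": 2 * b.outer_radius_mm,
            "wall_thickness_mm": 2 * (b.outer_radius_mm - b.inner_radius_mm),
            "artery_diameter_mm": 2 * b.artery_radius_mm,
            "qc_status": "ok",
        })
    return pd.DataFrame(rows)


def generate_cohort(params_cf: Optional[CohortParams] = None,
                    params_control: Optional[CohortParams] = None,
                    n_per_cohort: Optional[int] = None,
                    rng_seed: int = 0,
                    rasterize_volumes: bool = False) -> CohortData:
    """Simulate both cohorts, one inspiration + one expiration CT each.

    Fully reproducible from ``rng_seed``; per-subject seeds are derived with
    numpy's seed-spawning so the pair of volume states of a subject share
    their tree geometry and branch jitter exactly.
    """
    params_cf = params_cf if params_cf is not None else cf_params()
    params_control = params_control if params_control is not None else control_params()
    root = np.random.SeedSequence(rng_seed)
    out = CohortData(subjects=[])
    truth_frames = []
    for params, prefix in ((params_cf, "CF"), (params_control, "CTRL")):
        n = n_per_cohort if n_per_cohort is not None else params.n_subjects
        if n < 2:
            raise ValueError("need >= 2 subjects per cohort")
        for i in range(n):
            ss = root.spawn(1)[0]
            cov_rng = np.random.default_rng(ss.spawn(1)[0])
            age, height, gender = _simulate_subject_covariates(cov_rng)
            tree_seed = ss.spawn(1)[0]
            for state in ("inspiration", "expiration"):
                subject = SubjectRecord(
                    subject_id=f"{prefix}{i + 1:02d}",
                    disease_status=params.disease_status,
                    age_years=age, height_cm=height, gender=gender,
                    volume_state=state,
                )
                tree = generate_tree(params, subject,
                                     np.random.default_rng(tree_seed))
                out.subjects.append(subject)
                out.trees[(subject.subject_id, state)] = tree
                truth_frames.append(ground_truth_table(tree, subject))
                if rasterize_volumes:
                    vol_rng = np.random.default_rng(ss.spawn(1)[0])
                    out.volumes[(subject.subject_id, state)] = rasterize(
                        tree, spacing_mm=params.voxel_spacing_mm,
                        noise_sd_HU=params.noise_sd_HU, rng=vol_rng,
                    )
    out.ground_truth = pd.concat(truth_frames, ignore_index=True)
    return out
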