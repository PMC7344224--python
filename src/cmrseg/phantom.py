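"""Synthetic multi-slice short-axis CMR phantom with exact ground truth.

Each subject is a stack of 2D slices containing three structures built from
analytic geometry: the LV blood pool is a disk whose radius tapers linearly
from base to apex, the myocardium an annulus of fixed thickness around it,
and the RV blood pool a crescent formed by a disk that overlaps the
epicardial border and is clipped both by the epicardial disk and by a tilted
planar cut on its free wall. The tilt of that cut makes the anatomy chiral:
a mirrored heart is not a rotation of an unmirrored one, so orientation
(flip) variation is a genuine axis of domain shift and not an alias of pose.

End-systole contracts both cavities radially by a factor c while preserving
myocardial cross-sectional area per slice (incompressible-wall
approximation, thickening inward), so myocardial mass is approximately
frame-independent.

Because every structure boundary is a circular arc or chord, per-slice areas
— disk, annulus, circle-circle lens, circular segment — have closed forms,
giving exact analytic volumes against which voxel-counted volumes and the
whole clinical-parameter pipeline can be checked. Intensities are class
means (blood bright, myocardium intermediate, background dark, as in bSSFP
cine) with optional gamma shift and additive Gaussian noise; the label maps
are the exact generating masks, so noise never touches the ground truth.

Two stock "domains" emulate the cross-site situation: domain A (the training
distribution) has one fixed scanner geometry — 1.8 mm in-plane, 8 mm slices,
upright pose, consistent contrast — while domain B draws pixel spacing from
0.78-2.3 mm, slice thickness from 5-10 mm, pose from +/-45 degrees, mirrored
orientation with probability 0.5, wider heart-size and contrast ranges, and
more variable noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .types import BG, LV, MYO, RV, LabelMap, SubjectStudy, ValidationError, VolumeImage


# --------------------------------------------------------------------------
# closed-form areas
# --------------------------------------------------------------------------

def circle_lens_area(r1: float, r2: float, d: float) -> float:
    """Area of the intersection of two disks with radii r1, r2, centres d apart."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = (d * d + r1 * r1 - r2 * r2) / (2 * d * r1)
    a2 = (d * d + r2 * r2 - r1 * r1) / (2 * d * r2)
    tri = 0.5 * math.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2)
                              * (d - r1 + r2) * (d + r1 + r2)))
    return (r1 * r1 * math.acos(np.clip(a1, -1, 1))
            + r2 * r2 * math.acos(np.clip(a2, -1, 1)) - tri)


def circle_segment_area(r: float, h: float) -> float:
    """Area of the circular segment cut off by a chord at distance h from centre
    (the part farther than h). Zero when h >= r; the full disk when h <= -r."""
    if h >= r:
        return 0.0
    if h <= -r:
        return math.pi * r * r
    return r * r * math.acos(np.clip(h / r, -1, 1)) - h * math.sqrt(r * r - h * h)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry, contrast and sampling parameters of one synthetic subject.

    Lengths in mm, angles in degrees. Per-slice radii scale with a linear
    base-to-apex taper; the RV disk radius, its centre distance and its cut
    all scale with the same factor so slice geometry stays similar.
    """

    n_slices: int = 10
    in_plane_shape: Tuple[int, int] = (100, 100)
    spacing: Tuple[float, float, float] = (8.0, 1.8, 1.8)

    r_base_mm: float = 20.0          # LV endocardial radius at the basal slice (ED)
    taper_apex: float = 0.4          # radius factor at the apical slice
    myo_thickness_mm: float = 7.0    # ED wall thickness
    rv_radius_frac: float = 1.0      # RV disk radius as a fraction of r_base
    rv_penetration_frac: float = 0.75  # overlap depth into the epicardial disk, of r_rv
    rv_cut_frac: float = 0.5         # free-wall cut distance from RV centre, of r_rv
    rv_cut_tilt_deg: float = 35.0    # cut tilt vs the LV->RV axis (chirality source)
    contraction: float = 0.75        # ED->ES radial cavity contraction c

    pose_deg: float = 0.0            # direction of the RV from the LV centre
    mirrored: bool = False           # mirrored orientation (flips chirality)
    center_offset_mm: Tuple[float, float] = (0.0, 0.0)  # (dy, dx) of heart centre

    blood_mean: float = 1.0
    myo_mean: float = 0.45
    bg_mean: float = 0.15
    noise_sd: float = 0.06
    gamma_shift: float = 1.0         # contrast shift applied to clean intensities
    confusers_enabled: bool = True   # unlabeled background tissue (chest wall,
    # liver-like and random blobs) whose intensities overlap the heart's;
    # placed in the heart's body frame, so they rotate with pose and mirror
    # with orientation — context the network can only exploit via shape priors

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if not (self.r_base_mm > self.myo_thickness_mm > 0):
            raise ValidationError("need r_base_mm > myo_thickness_mm > 0")
        if not 0 < self.contraction <= 1:
            raise ValidationError("contraction must be in (0, 1]")
        if not 0 < self.taper_apex <= 1:
            raise ValidationError("taper_apex must be in (0, 1]")
        if not 0 < self.rv_penetration_frac < 2:
            raise ValidationError("rv_penetration_frac must be in (0, 2)")
        means = (self.blood_mean, self.myo_mean, self.bg_mean)
        if len(set(means)) != 3:
            raise ValidationError("class intensity means must be distinct")
        self._validate_geometry()

    # frame geometry -------------------------------------------------------
    def _radii(self, frame: str) -> Tuple[float, float, float, float, float]:
        """Base-slice (r_in, r_out, r_rv, d, h_cut) for 'ED' or 'ES'."""
        r_in = self.r_base_mm
        r_out = r_in + self.myo_thickness_mm
        r_rv = self.rv_radius_frac * self.r_base_mm
        if frame == "ES":
            c = self.contraction
            r_in_es = c * r_in
            # annulus area preserved: r_out^2 - r_in^2 is frame-invariant
            r_out = math.sqrt(r_out * r_out - r_in * r_in + r_in_es * r_in_es)
            r_in = r_in_es
            r_rv = c * r_rv
        pen = self.rv_penetration_frac * r_rv
        d = r_out + r_rv - pen
        h = self.rv_cut_frac * r_rv
        return r_in, r_out, r_rv, d, h

    def _validate_geometry(self) -> None:
        for frame in ("ED", "ES"):
            r_in, r_out, r_rv, d, h = self._radii(frame)
            if d <= r_out:
                raise ValidationError(
                    f"{frame}: RV centre lies inside the epicardial disk "
                    f"(d={d:.1f} <= r_out={r_out:.1f}); reduce rv_penetration_frac")
            if d >= r_out + r_rv:
                raise ValidationError(f"{frame}: RV crescent detached from the heart")
            # the free-wall cut must not reach the septal lens, else the
            # closed-form area below would be wrong
            tilt = math.radians(self.rv_cut_tilt_deg)
            lens_reach = -d * math.cos(tilt) + r_out
            if lens_reach > h:
                raise ValidationError(
                    f"{frame}: free-wall cut intersects the septal overlap "
                    f"(reach {lens_reach:.1f} > cut {h:.1f}); lower rv_cut_tilt_deg "
                    "or raise rv_cut_frac")
            if h >= r_rv:
                raise ValidationError(f"{frame}: cut misses the RV disk entirely")

    def taper(self, z: int) -> float:
        if self.n_slices == 1:
            return 1.0
        return 1.0 + (self.taper_apex - 1.0) * z / (self.n_slices - 1)

    def slice_areas(self, frame: str, z: int) -> Dict[str, float]:
        """Closed-form per-structure areas (mm^2) of slice z (z=0 is basal)."""
        s = self.taper(z)
        r_in, r_out, r_rv, d, h = (v * s for v in self._radii(frame))
        a_lv = math.pi * r_in * r_in
        a_myo = math.pi * (r_out * r_out - r_in * r_in)
        a_rv = (math.pi * r_rv * r_rv
                - circle_segment_area(r_rv, h)
                - circle_lens_area(r_rv, r_out, d))
        return {"LV": a_lv, "MYO": a_myo, "RV": a_rv}

    def analytic_volumes(self, frame: str) -> Dict[str, float]:
        """Exact structure volumes in mL for one frame."""
        sz = self.spacing[0]
        totals = {"LV": 0.0, "MYO": 0.0, "RV": 0.0}
        for z in range(self.n_slices):
            for k, a in self.slice_areas(frame, z).items():
                totals[k] += a * sz / 1000.0
        return totals


@dataclass
class PhantomTruth:
    """Analytic volumes (mL) per frame and structure, plus the generating config."""

    ed_volumes_ml: Dict[str, float]
    es_volumes_ml: Dict[str, float]
    config: PhantomConfig = field(repr=False)

    @property
    def lv_mass_g(self) -> float:
        """Myocardial ED volume times the 1.05 g/mL tissue density."""
        return self.ed_volumes_ml["MYO"] * 1.05


# --------------------------------------------------------------------------
# voxelization
# --------------------------------------------------------------------------

def _slice_masks(config: PhantomConfig, frame: str, z: int):
    ny, nx = config.in_plane_shape
    _, sy, sx = config.spacing
    cy = (ny - 1) / 2.0 * sy + config.center_offset_mm[0]
    cx = (nx - 1) / 2.0 * sx + config.center_offset_mm[1]
    yy = (np.arange(ny, dtype=np.float64) * sy - cy)[:, None]
    xx = (np.arange(nx, dtype=np.float64) * sx - cx)[None, :]
    rr2 = yy * yy + xx * xx

    s = config.taper(z)
    r_in, r_out, r_rv, d, h = (v * s for v in config._radii(frame))
    theta = math.radians(config.pose_deg)
    # mirroring reflects the whole configuration about the x-axis (y -> -y),
    # which flips the sign of the cut tilt relative to the LV->RV axis and
    # therefore the anatomy's chirality
    chir = -1.0 if config.mirrored else 1.0
    # RV centre along the pose direction (image-plane y grows downward)
    uy, ux = chir * math.sin(theta), math.cos(theta)
    rvy, rvx = d * uy, d * ux
    lv = rr2 <= r_in * r_in
    myo = (rr2 <= r_out * r_out) & ~lv
    drv2 = (yy - rvy) ** 2 + (xx - rvx) ** 2
    # free-wall cut normal: LV->RV direction rotated by the tilt
    beta = theta + math.radians(config.rv_cut_tilt_deg)
    nyv, nxv = chir * math.sin(beta), math.cos(beta)
    proj = (yy - rvy) * nyv + (xx - rvx) * nxv
    rv = (drv2 <= r_rv * r_rv) & (rr2 > r_out * r_out) & (proj <= h)
    return lv, myo, rv


def _draw_confusers(config: PhantomConfig, rng: np.random.Generator):
    """Sample per-subject background-tissue parameters in the heart's body
    frame (distances in mm from the heart centre, angles relative to the
    LV->RV axis). Shared by ED and ES; never labelled."""
    r_in, r_out, r_rv, d, _ = config._radii("ED")
    confusers = []
    # chest-wall-like bright band beyond the RV free wall
    confusers.append({
        "kind": "band",
        "r0": d + r_rv + rng.uniform(3.0, 8.0),
        "width": rng.uniform(6.0, 12.0),
        "half_angle": math.radians(rng.uniform(40.0, 70.0)),
        "angle": math.radians(rng.uniform(-15.0, 15.0)),
        "intensity": rng.uniform(0.55, 0.9),
    })
    # liver-like large blob on the opposite side
    ang = math.pi + math.radians(rng.uniform(-40.0, 40.0))
    confusers.append({
        "kind": "blob",
        "dist": r_out + rng.uniform(8.0, 25.0),
        "angle": ang,
        "ry": rng.uniform(12.0, 25.0),
        "rx": rng.uniform(18.0, 35.0),
        "intensity": rng.uniform(0.35, 0.6),
    })
    # a few smaller tissue blobs anywhere around the heart
    for _ in range(int(rng.integers(2, 5))):
        confusers.append({
            "kind": "blob",
            "dist": r_out + rng.uniform(5.0, 45.0),
            "angle": rng.uniform(0.0, 2 * math.pi),
            "ry": rng.uniform(4.0, 12.0),
            "rx": rng.uniform(4.0, 12.0),
            "intensity": rng.uniform(0.3, 1.0),
        })
    return confusers


def _confuser_field(config: PhantomConfig, confusers) -> np.ndarray:
    """Rasterize the background tissue intensities for one in-plane grid."""
    ny, nx = config.in_plane_shape
    _, sy, sx = config.spacing
    cy = (ny - 1) / 2.0 * sy + config.center_offset_mm[0]
    cx = (nx - 1) / 2.0 * sx + config.center_offset_mm[1]
    yy = (np.arange(ny, dtype=np.float64) * sy - cy)[:, None]
    xx = (np.arange(nx, dtype=np.float64) * sx - cx)[None, :]
    theta = math.radians(config.pose_deg)
    chir = -1.0 if config.mirrored else 1.0
    field = np.zeros((ny, nx), dtype=np.float32)
    for c in confusers:
        a = theta + c["angle"]
        uy, ux = chir * math.sin(a), math.cos(a)
        if c["kind"] == "band":
            rr = np.sqrt(yy * yy + xx * xx)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = np.clip((yy * uy + xx * ux) / np.maximum(rr, 1e-9), -1, 1)
            mask = (rr >= c["r0"]) & (rr <= c["r0"] + c["width"]) \
                & (np.arccos(cosang) <= c["half_angle"])
        else:
            by, bx = c["dist"] * uy, c["dist"] * ux
            mask = ((yy - by) / c["ry"]) ** 2 + ((xx - bx) / c["rx"]) ** 2 <= 1.0
        field[mask] = np.maximum(field[mask], np.float32(c["intensity"]))
    return field


def _render_frame(config: PhantomConfig, frame: str,
                  rng: Optional[np.random.Generator],
                  confusers=None):
    ny, nx = config.in_plane_shape
    labels = np.zeros((config.n_slices, ny, nx), dtype=np.uint8)
    for z in range(config.n_slices):
        lv, myo, rv = _slice_masks(config, frame, z)
        labels[z][lv] = LV
        labels[z][myo] = MYO
        labels[z][rv] = RV
    means = np.array([config.bg_mean, config.blood_mean,
                      config.myo_mean, config.blood_mean], dtype=np.float32)
    clean = means[labels]
    if confusers:
        field = _confuser_field(config, confusers)
        clean = np.where(labels == BG, np.maximum(clean, field[np.newaxis]), clean)
    if config.gamma_shift != 1.0:
        lo, hi = float(clean.min()), float(clean.max())
        if hi > lo:
            clean = ((clean - lo) / (hi - lo)) ** np.float32(config.gamma_shift) \
                * (hi - lo) + lo
    if rng is not None and config.noise_sd > 0:
        clean = clean + rng.normal(0.0, config.noise_sd,
                                   size=clean.shape).astype(np.float32)
    return clean.astype(np.float32), labels


def generate_study(config: PhantomConfig, seed: int = 0,
                   subject_id: str = "phantom") -> Tuple[SubjectStudy, PhantomTruth]:
    """Render one subject: ED and ES frames with exact label maps and truth.

    The seed drives only the additive noise; geometry (and therefore the
    label maps and analytic volumes) is fully determined by the config.
    """
    rng = np.random.default_rng(seed)
    confusers = _draw_confusers(config, rng) if config.confusers_enabled else None
    ed_vox, ed_lab = _render_frame(config, "ED", rng, confusers)
    es_vox, es_lab = _render_frame(config, "ES", rng, confusers)
    study = SubjectStudy(
        subject_id=subject_id,
        ed_image=VolumeImage(ed_vox, config.spacing),
        es_image=VolumeImage(es_vox, config.spacing),
        ed_label=LabelMap(ed_lab, config.spacing),
        es_label=LabelMap(es_lab, config.spacing),
    )
    truth = PhantomTruth(
        ed_volumes_ml=config.analytic_volumes("ED"),
        es_volumes_ml=config.analytic_volumes("ES"),
        config=config,
    )
    return study, truth


def make_partial_labels(study: SubjectStudy) -> SubjectStudy:
    """Reduce a fully-labelled study to the partial-annotation pattern of an
    LV-focused clinical cohort: LV in ED and ES, myocardium in ED only, no RV.
    Unavailable structures are blanked to background in the stored masks and
    recorded in the availability flags."""
    ed = study.ed_label.labels.copy()
    es = study.es_label.labels.copy()
    ed[ed == RV] = BG
    es[(es == RV) | (es == MYO)] = BG
    return SubjectStudy(
        subject_id=study.subject_id,
        ed_image=study.ed_image, es_image=study.es_image,
        ed_label=LabelMap(ed, study.ed_label.spacing),
        es_label=LabelMap(es, study.es_label.spacing),
        label_availability={("ED", LV): True, ("ED", MYO): True,
                            ("ES", LV): True},
    )


# --------------------------------------------------------------------------
# domains
# --------------------------------------------------------------------------

@dataclass
class DomainSpec:
    """Sampling distributions for PhantomConfig fields, one per acquisition
    'site'. Ranges are (lo, hi) uniform unless noted."""

    name: str
    inplane_spacing: Tuple[float, float] = (1.8, 1.8)       # fixed when lo == hi
    slice_thickness: Tuple[float, float] = (8.0, 8.0)
    fov_mm: float = 180.0
    n_slices: Tuple[int, int] = (10, 10)
    r_base: Tuple[float, float] = (18.5, 21.5)
    myo_thickness: Tuple[float, float] = (6.0, 8.0)
    contraction: Tuple[float, float] = (0.70, 0.80)
    pose_deg: Tuple[float, float] = (0.0, 0.0)
    mirror_probability: float = 0.0
    center_offset_sd_mm: float = 2.0
    noise_sd: Tuple[float, float] = (0.05, 0.07)
    gamma_shift: Tuple[float, float] = (1.0, 1.0)
    partial_labels: bool = False


def domain_a() -> DomainSpec:
    """The single-scanner training distribution: fixed 1.8 mm / 8 mm grid,
    upright pose, consistent contrast, modest anatomical variation."""
    return DomainSpec(name="A")


def domain_b() -> DomainSpec:
    """The shifted multi-site test distribution: pixel spacing 0.78-2.3 mm,
    slice thickness 5-10 mm, pose +/-45 deg, mirrored orientation half the
    time, wider heart-size/contrast/noise ranges."""
    return DomainSpec(
        name="B",
        inplane_spacing=(0.78, 2.3),
        slice_thickness=(5.0, 10.0),
        n_slices=(8, 12),
        r_base=(13.0, 26.0),
        myo_thickness=(5.0, 8.5),
        contraction=(0.65, 0.85),
        pose_deg=(-45.0, 45.0),
        mirror_probability=0.5,
        center_offset_sd_mm=4.0,
        noise_sd=(0.04, 0.10),
        gamma_shift=(0.7, 1.4),
    )


def domain_pathology() -> DomainSpec:
    """Hypertrophy-like variant: markedly thickened walls, smaller cavity."""
    spec = domain_b()
    return replace(spec, name="pathology", r_base=(14.0, 18.0),
                   myo_thickness=(11.0, 14.0))


_DOMAINS = {"A": domain_a, "B": domain_b, "pathology": domain_pathology}


def get_domain(name: str) -> DomainSpec:
    try:
        return _DOMAINS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown domain {name!r}; choose from {sorted(_DOMAINS)}") from None


def sample_config(spec: DomainSpec, rng: np.random.Generator) -> PhantomConfig:
    """Draw one subject's PhantomConfig from a domain's distributions."""
    def u(rg):
        lo, hi = rg
        return float(lo) if lo == hi else float(rng.uniform(lo, hi))

    sp = u(spec.inplane_spacing)
    sz = u(spec.slice_thickness)
    npx = int(round(spec.fov_mm / sp))
    npx += npx % 2  # even grid
    n_slices = int(rng.integers(spec.n_slices[0], spec.n_slices[1] + 1))
    r_base = u(spec.r_base)
    t = min(u(spec.myo_thickness), 0.8 * r_base)  # keep r_base > t
    return PhantomConfig(
        n_slices=n_slices,
        in_plane_shape=(npx, npx),
        spacing=(sz, sp, sp),
        r_base_mm=r_base,
        myo_thickness_mm=t,
        contraction=u(spec.contraction),
        pose_deg=u(spec.pose_deg),
        mirrored=bool(rng.random() < spec.mirror_probability),
        center_offset_mm=(float(rng.normal(0, spec.center_offset_sd_mm)),
                          float(rng.normal(0, spec.center_offset_sd_mm))),
        noise_sd=u(spec.noise_sd),
        gamma_shift=u(spec.gamma_shift),
    )


def generate_domain(spec, n_subjects: int, seed: int = 0
                    ) -> List[Tuple[SubjectStudy, PhantomTruth]]:
    """Generate a reproducible cohort from a domain spec (or its name)."""
    if isinstance(spec, str):
        spec = get_domain(spec)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        config = sample_config(spec, rng)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        study, truth = generate_study(config, seed=noise_seed,
                                      subject_id=f"{spec.name}{i:03d}")
        if spec.partial_labels:
            study = make_partial_labels(study)
        out.append((study, truth))
    return out
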