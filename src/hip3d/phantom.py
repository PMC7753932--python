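"""Synthetic hip-joint phantom with exact labels and analytic morphometry.

The phantom emulates a T1 VIBE-like hip MRI at 0.8 mm isotropic
resolution: a femur built from a head sphere plus neck cylinder (bright
marrow with a dark cortical shell), an acetabular cup modelled as a
partial spherical shell concentric with the head (configurable opening
orientation, angular extent and rim deficiency), a fluid joint space,
a smooth multiplicative bias field and additive Gaussian noise.  Labels
and the femoral head center are noise-free ground truth; every
morphometric parameter has a closed-form or deterministically-integrated
analytic value, so the whole measurement pipeline can be validated
end-to-end.  The contrast is a stand-in, not a model of MRI physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry, morphometry
from .io_formats import LabelMap, VolumeImage
from .morphometry import HeadSphere, MorphometryReport


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic hip (mm / degrees)."""

    head_radius_mm: float = 24.0
    head_center_mm: np.ndarray | None = None  # default: volume center
    neck_axis: np.ndarray | None = None       # default: cup opening axis
    neck_radius_mm: float = 11.0
    neck_length_mm: float = 30.0
    joint_space_mm: float = 3.0
    cup_thickness_mm: float = 5.0
    cup_inclination_deg: float = 54.0
    cup_anteversion_deg: float = 17.0
    cup_half_angle_deg: float = 90.0
    rim_deficiency_deg: float = 0.0
    rim_deficiency_center_deg: float = 0.0    # azimuth 0 = anterior
    cortical_thickness_mm: float = 1.5
    intensities: tuple[float, float, float] = (40.0, 100.0, 15.0)  # soft, marrow, cortical
    noise_sd: float = 0.0
    bias_field_amplitude: float = 0.0
    voxel_size_mm: float = 0.8
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    seed: int = 0

    def __post_init__(self):
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if self.head_center_mm is None:
            self.head_center_mm = (np.asarray(self.volume_shape) - 1) / 2.0 * self.voxel_size_mm
        self.head_center_mm = np.asarray(self.head_center_mm, dtype=float).reshape(3)
        if self.neck_axis is None:
            self.neck_axis = self.opening_axis
        self.neck_axis = np.asarray(self.neck_axis, dtype=float).reshape(3)
        self.neck_axis = self.neck_axis / np.linalg.norm(self.neck_axis)
        self.validate()

    @property
    def opening_axis(self) -> np.ndarray:
        return geometry.cup_opening_axis(self.cup_inclination_deg, self.cup_anteversion_deg)

    @property
    def cup_inner_radius_mm(self) -> float:
        return self.head_radius_mm + self.joint_space_mm

    @property
    def cup_outer_radius_mm(self) -> float:
        return self.cup_inner_radius_mm + self.cup_thickness_mm

    def validate(self) -> None:
        for name in ("head_radius_mm", "neck_radius_mm", "neck_length_mm",
                     "joint_space_mm", "cup_thickness_mm", "voxel_size_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.cup_half_angle_deg <= 150):
            raise ValueError("cup_half_angle_deg must be in (0, 150]")
        if not (0 <= self.rim_deficiency_deg < 360):
            raise ValueError("rim_deficiency_deg must be in [0, 360)")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sd and bias_field_amplitude must be non-negative")
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape must be at least (8, 8, 8)")
        extent = np.asarray(self.volume_shape) * self.voxel_size_mm
        c = self.head_center_mm
        r_out = self.cup_outer_radius_mm
        if np.any(c - r_out < 0) or np.any(c + r_out > extent):
            raise ValueError("acetabular cup exceeds volume bounds; enlarge volume_shape "
                             "or move head_center_mm")
        tip = c + self.neck_axis * self.neck_length_mm
        if np.any(tip - self.neck_radius_mm < 0) or np.any(tip + self.neck_radius_mm > extent):
            raise ValueError("femoral neck exceeds volume bounds; enlarge volume_shape "
                             "or shorten neck_length_mm")


@dataclass
class PhantomSample:
    volume: VolumeImage
    labels: LabelMap
    fhc_mm: np.ndarray
    truth: MorphometryReport
    spec: PhantomSpec
    patient_id: str = "p0"
    sample_id: str = "s0"


def _femur_masks(spec: PhantomSpec, pts: np.ndarray):
    """(femur solid, marrow core) membership of world points (..., 3)."""
    c = spec.head_center_mm
    w = spec.neck_axis
    ct = spec.cortical_thickness_mm
    d = pts - c
    dist = np.linalg.norm(d, axis=-1)
    axial = d @ w
    radial = np.linalg.norm(d - axial[..., None] * w, axis=-1)
    sphere = dist <= spec.head_radius_mm
    cyl = (axial >= 0) & (axial <= spec.neck_length_mm) & (radial <= spec.neck_radius_mm)
    solid = sphere | cyl
    sphere_in = dist <= spec.head_radius_mm - ct
    cyl_in = (axial >= ct) & (axial <= spec.neck_length_mm - ct) & \
        (radial <= spec.neck_radius_mm - ct)
    return solid, sphere_in | cyl_in


def _cup_masks(spec: PhantomSpec, pts: np.ndarray):
    """(cup shell, cup cortical lining) membership of world points."""
    c = spec.head_center_mm
    n = spec.opening_axis
    ct = spec.cortical_thickness_mm
    d = pts - c
    dist = np.linalg.norm(d, axis=-1)
    r_in, r_out = spec.cup_inner_radius_mm, spec.cup_outer_radius_mm
    radial_ok = (dist >= r_in) & (dist <= r_out)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = d / np.maximum(dist, 1e-12)[..., None]
    sector = geometry.in_cup_sector(u.reshape(-1, 3), n, spec.cup_half_angle_deg,
                                    spec.rim_deficiency_deg,
                                    spec.rim_deficiency_center_deg).reshape(dist.shape)
    shell = radial_ok & sector & (dist > 1e-9)
    near_faces = (dist <= r_in + ct) | (dist >= r_out - ct)
    rim_margin_deg = np.degrees(ct / r_in)
    cosp = -(u @ n)
    near_rim = cosp <= np.cos(np.deg2rad(max(spec.cup_half_angle_deg - rim_margin_deg, 0.0)))
    cortical = shell & (near_faces | near_rim)
    return shell, cortical


def generate_phantom(spec: PhantomSpec, patient_id: str = "p0", sample_id: str = "s0"
                     ) -> PhantomSample:
    """Rasterize one phantom: labels by voxel-center membership, then image.

    Deterministic given (spec, spec.seed); the label map never depends on
    noise or bias settings.
    """
    spec.validate()
    shape = spec.volume_shape
    sp = spec.voxel_size_mm
    idx = np.indices(shape, dtype=np.float32)
    pts = np.stack([idx[0] * sp, idx[1] * sp, idx[2] * sp], axis=-1)

    femur, marrow_f = _femur_masks(spec, pts)
    cup, cortical_c = _cup_masks(spec, pts)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[cup] = 2
    labels[femur] = 1  # femur wins any (non-physical) overlap

    soft, marrow, cortical = spec.intensities
    img = np.full(shape, soft, dtype=np.float32)
    img[femur] = cortical
    img[marrow_f & femur] = marrow
    img[cup & ~femur] = marrow
    img[cortical_c & ~femur] = cortical

    rng = np.random.default_rng(spec.seed)
    if spec.bias_field_amplitude > 0:
        ax = [np.linspace(-1.0, 1.0, s, dtype=np.float32) for s in shape]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        coef = rng.uniform(-1.0, 1.0, size=9)
        poly = (coef[0] * gx + coef[1] * gy + coef[2] * gz
                + coef[3] * gx * gy + coef[4] * gx * gz + coef[5] * gy * gz
                + coef[6] * gx**2 + coef[7] * gy**2 + coef[8] * gz**2)
        peak = np.abs(poly).max()
        if peak > 0:
            img = img * (1.0 + spec.bias_field_amplitude * poly / peak)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    spacing = np.full(3, sp)
    return PhantomSample(
        volume=VolumeImage(values=img.astype(np.float32), spacing_mm=spacing),
        labels=LabelMap(values=labels, spacing_mm=spacing),
        fhc_mm=spec.head_center_mm.copy(),
        truth=analytic_truth(spec),
        spec=spec,
        patient_id=patient_id,
        sample_id=sample_id,
    )


def analytic_truth(spec: PhantomSpec, n_dirs: int = 100_000, n_rim: int = 720
                   ) -> MorphometryReport:
    """Closed-form / deterministically integrated morphometry of a spec.

    Total coverage is the exact spherical-cap fraction times the kept
    azimuth fraction; anterior/posterior coverage integrate the same
    membership over a dense direction lattice; LCE and extrusion index
    are evaluated on the analytic rim circle (inner cup radius) with the
    same projection definitions as the measurement module.
    """
    theta = np.deg2rad(spec.cup_half_angle_deg)
    keep = 1.0 - spec.rim_deficiency_deg / 360.0
    total = 100.0 * (1.0 - np.cos(theta)) / 2.0 * keep

    n = spec.opening_axis
    dirs = geometry.fibonacci_sphere(n_dirs)
    member = geometry.in_cup_sector(dirs, n, spec.cup_half_angle_deg,
                                    spec.rim_deficiency_deg,
                                    spec.rim_deficiency_center_deg)
    ant = dirs[:, 1] > 0
    post = dirs[:, 1] < 0
    anterior = 100.0 * member[ant].mean()
    posterior = 100.0 * member[post].mean()

    e1, e2 = geometry.cup_basis(n)
    az = np.linspace(-180.0, 180.0, n_rim, endpoint=False)
    if spec.rim_deficiency_deg > 0:
        off = geometry.wrap_deg(az - spec.rim_deficiency_center_deg)
        az = az[np.abs(off) > spec.rim_deficiency_deg / 2.0]
    phi = np.deg2rad(az)
    r_in = spec.cup_inner_radius_mm
    rim = (spec.head_center_mm
           + r_in * (-np.cos(theta) * n)[None, :]
           + r_in * np.sin(theta) * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    head = HeadSphere(center_mm=spec.head_center_mm, radius_mm=spec.head_radius_mm)
    return MorphometryReport(
        inclination_deg=spec.cup_inclination_deg,
        anteversion_deg=spec.cup_anteversion_deg,
        lce_deg=morphometry.lce_angle(head, rim),
        extrusion_index_pct=morphometry.extrusion_index(head, rim),
        total_cov_pct=float(total),
        anterior_cov_pct=float(anterior),
        posterior_cov_pct=float(posterior),
        head=head,
    )


#: Parameter ranges for a desk-scale study population (uniform draws).
DEFAULT_SPEC_RANGES: dict[str, tuple[float, float]] = {
    "head_radius_mm": (20.0, 26.0),
    "cup_inclination_deg": (44.0, 63.0),
    "cup_anteversion_deg": (7.0, 30.0),
    "cup_half_angle_deg": (65.0, 95.0),
}


def sample_spec(rng: np.random.Generator, spec_ranges: dict | None = None,
                base: PhantomSpec | None = None, center_jitter_mm: float = 4.0
                ) -> PhantomSpec:
    """Draw one spec uniformly from ``spec_ranges`` around ``base``."""
    ranges = DEFAULT_SPEC_RANGES if spec_ranges is None else spec_ranges
    base = base if base is not None else PhantomSpec()
    kwargs = {}
    for name, rng_pair in ranges.items():
        lo, hi = rng_pair
        if hi < lo:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        kwargs[name] = float(rng.uniform(lo, hi))
    center = (np.asarray(base.volume_shape) - 1) / 2.0 * base.voxel_size_mm
    if center_jitter_mm > 0:
        center = center + rng.uniform(-center_jitter_mm, center_jitter_mm, size=3)
    kwargs["head_center_mm"] = center
    kwargs["neck_axis"] = None  # re-derive from the drawn cup angles
    kwargs["seed"] = int(rng.integers(0, 2**31 - 1))
    return replace(base, **kwargs)


def make_dataset(n: int, spec_ranges: dict | None = None, seed: int = 0,
                 base: PhantomSpec | None = None, bilateral_fraction: float = 0.2,
                 center_jitter_mm: float = 4.0) -> list[PhantomSample]:
    """Generate ``n`` phantoms with patient ids (some patients bilateral).

    Specs are drawn uniformly from ``spec_ranges``; a ``bilateral_fraction``
    of hips share a patient with the preceding hip, mimicking bilateral
    exams for the patient-grouped cross-validation design.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    bilateral = rng.random(n) < bilateral_fraction
    bilateral[0] = False
    samples = []
    patient = -1
    for i in range(n):
        if not bilateral[i]:
            patient += 1
        spec = sample_spec(rng, spec_ranges, base, center_jitter_mm)
        samples.append(generate_phantom(spec, patient_id=f"p{patient:03d}",
                                        sample_id=f"s{i:03d}"))
    return samples
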