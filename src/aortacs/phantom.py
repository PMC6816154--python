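"""Digital abdominal-aortic-aneurysm phantoms with analytic ground truth.

The phantom is a straight, axially aligned aorta (the abdominal aorta is
largely immobilised against the spine, so a straight tube is an adequate
geometric model) carrying a fusiform bulge.  Each axial cross-section is a
set of concentric rings: flowing (signal-suppressed) lumen, intraluminal
thrombus (ILT), and vessel wall, surrounded by background tissue, a psoas
muscle cylinder and a spine cylinder.  Geometry is prescribed by continuous
radial profiles, so every morphometric quantity of interest (maximal outer
diameter, lumen / ILT areas, ILT-to-muscle signal ratio) is known in closed
form and recorded in a truth record — the raster is never re-measured to
populate it.

Tissue contrast emulates T1-weighted black-blood imaging: lumen dark,
iso-intense ILT at muscle level, "bright" (fresh) ILT clearly above the
1.2 x muscle threshold used for thrombus typing.  Contrast is prescribed,
not simulated; there is no pulse-sequence physics here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "RadialProfile",
    "PhantomSpec",
    "DigitalPhantom",
    "SenseMaps",
    "KSpaceAcquisition",
    "LABELS",
    "build_phantom",
    "coil_sensitivities",
    "simulate_acquisition",
    "default_spec",
]

# Integer label codes for the tissue classes; every voxel gets exactly one.
LABELS = {
    "background": 0,
    "lumen": 1,
    "ilt_iso": 2,
    "ilt_bright": 3,
    "wall": 4,
    "muscle": 5,
    "spine": 6,
    "air": 7,
}

DEFAULT_INTENSITIES = {
    "background": 0.2,
    "lumen": 0.3,
    "ilt_iso": 1.0,
    "ilt_bright": 1.5,
    "wall": 0.9,
    "muscle": 1.0,
    "spine": 0.7,
    "air": 0.02,
}

# Bright-sector fraction used when the spec does not set one explicitly.
BRIGHT_FRACTION_BY_TYPE = {1: 1.0, 2: 0.5, 3: 0.0, 4: 0.0}


@dataclass(frozen=True)
class RadialProfile:
    """Serializable radial profile r(z) in mm, z measured from volume centre.

    kind "constant": value
    kind "gaussian_bulge": base + amplitude * exp(-z^2 / (2 sigma^2))
    """

    kind: str
    params: Mapping[str, float]

    def __call__(self, z_mm: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z_mm, dtype=float)
        p = self.params
        if self.kind == "constant":
            out = np.full_like(z, float(p["value"]))
        elif self.kind == "gaussian_bulge":
            out = p["base"] + p["amplitude"] * np.exp(-(z**2) / (2.0 * p["sigma"] ** 2))
        else:
            raise ValueError(f"unknown profile kind: {self.kind!r}")
        return float(out) if np.isscalar(z_mm) else out

    @staticmethod
    def constant(value: float) -> "RadialProfile":
        return RadialProfile("constant", {"value": float(value)})

    @staticmethod
    def gaussian_bulge(base: float, amplitude: float, sigma: float) -> "RadialProfile":
        return RadialProfile(
            "gaussian_bulge",
            {"base": float(base), "amplitude": float(amplitude), "sigma": float(sigma)},
        )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}

    @staticmethod
    def from_dict(d: Mapping) -> "RadialProfile":
        return RadialProfile(d["kind"], dict(d["params"]))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic AAA phantom.

    Lengths are mm, intensities arbitrary units.  ``ilt_type`` follows the
    black-blood ILT classification: 1 dominantly bright, 2 mixed bright /
    iso-intense, 3 all iso-intense, 4 no thrombus (``ilt_thickness_profile``
    must then be identically zero).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 24)
    voxel_size: float = 1.3
    lumen_radius_profile: RadialProfile = field(
        default_factory=lambda: RadialProfile.gaussian_bulge(10.0, 4.0, 8.0)
    )
    ilt_thickness_profile: RadialProfile = field(
        default_factory=lambda: RadialProfile.gaussian_bulge(0.0, 6.0, 8.0)
    )
    wall_thickness: float = 2.0
    ilt_type: int = 2
    tissue_intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    bright_fraction: float | None = None
    noise_sd: float = 0.02
    seed: int = 0
    # geometry of the reference structures (offsets from the aorta axis, mm)
    muscle_offset: tuple[float, float] = (42.0, 0.0)
    muscle_radius: float = 12.0
    spine_offset: tuple[float, float] = (0.0, -44.0)
    spine_radius: float = 14.0
    body_fraction: float = 0.92  # body ellipse semi-axes as a fraction of half-FOV
    supersample: int = 2

    def __post_init__(self) -> None:
        self.tissue_intensities = {**DEFAULT_INTENSITIES, **self.tissue_intensities}
        if self.ilt_type not in (1, 2, 3, 4):
            raise ValueError("ilt_type must be one of 1, 2, 3, 4")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if any(v < 0 for v in self.tissue_intensities.values()):
            raise ValueError("tissue intensities must be non-negative")

    @property
    def effective_bright_fraction(self) -> float:
        if self.bright_fraction is not None:
            return float(self.bright_fraction)
        return BRIGHT_FRACTION_BY_TYPE[self.ilt_type]

    def axial_positions_mm(self) -> np.ndarray:
        """Slice-centre z coordinates, centred on the volume."""
        nz = self.grid_shape[2]
        return (np.arange(nz) - (nz - 1) / 2.0) * self.voxel_size

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lumen_radius_profile"] = self.lumen_radius_profile.to_dict()
        d["ilt_thickness_profile"] = self.ilt_thickness_profile.to_dict()
        d["grid_shape"] = list(self.grid_shape)
        d["muscle_offset"] = list(self.muscle_offset)
        d["spine_offset"] = list(self.spine_offset)
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "PhantomSpec":
        d = dict(d)
        d["lumen_radius_profile"] = RadialProfile.from_dict(d["lumen_radius_profile"])
        d["ilt_thickness_profile"] = RadialProfile.from_dict(d["ilt_thickness_profile"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["muscle_offset"] = tuple(d["muscle_offset"])
        d["spine_offset"] = tuple(d["spine_offset"])
        return PhantomSpec(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def load(path) -> "PhantomSpec":
        with open(path) as fh:
            return PhantomSpec.from_dict(json.load(fh))


@dataclass
class TruthRecord:
    """Analytic ground truth, in the units used for reporting (cm, cm^2)."""

    max_outer_diameter: float
    slice_of_max: int
    lumen_area_at_max: float
    ilt_wall_area_at_max: float
    ilt_muscle_ratio: float
    ilt_type: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DigitalPhantom:
    intensity: np.ndarray  # (nx, ny, nz), float
    labels: np.ndarray  # (nx, ny, nz), int
    truth: TruthRecord
    voxel_size: float
    spec: PhantomSpec

    @property
    def center_xy(self) -> tuple[float, float]:
        """Aorta axis position in voxel index units (x, y)."""
        nx, ny, _ = self.intensity.shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0)


@dataclass
class SenseMaps:
    """Complex coil sensitivity maps, root-sum-of-squares = 1 on support."""

    maps: np.ndarray  # (n_coils, nx, ny, nz) complex
    support: np.ndarray  # (nx, ny, nz) bool

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


@dataclass
class KSpaceAcquisition:
    """Per-coil k-space data y_n; unsampled entries are exactly zero."""

    data: np.ndarray  # (n_coils, nx, ny, nz) complex
    mask: "object"  # SamplingMask (kept loose to avoid a module cycle)

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]


def _cross_section_labels(
    spec: PhantomSpec,
    xx_mm: np.ndarray,
    yy_mm: np.ndarray,
    z_mm: float,
    body_semi_mm: tuple[float, float] | None = None,
) -> np.ndarray:
    """Label one axial plane at continuous coordinates (mm from the axis)."""
    r_l = float(spec.lumen_radius_profile(z_mm))
    t = float(spec.ilt_thickness_profile(z_mm)) if spec.ilt_type != 4 else 0.0
    w = spec.wall_thickness
    rr = np.hypot(xx_mm, yy_mm)
    lab = np.full(rr.shape, LABELS["background"], dtype=np.int8)
    lab[rr <= r_l + t + w] = LABELS["wall"]
    if t > 0:
        inside_ilt = rr <= r_l + t
        bf = spec.effective_bright_fraction
        if bf >= 1.0:
            lab[inside_ilt] = LABELS["ilt_bright"]
        elif bf <= 0.0:
            lab[inside_ilt] = LABELS["ilt_iso"]
        else:
            # contiguous angular sector of the annulus is bright
            theta = np.arctan2(yy_mm, xx_mm)  # [-pi, pi)
            bright = inside_ilt & (theta >= -np.pi) & (theta < -np.pi + 2 * np.pi * bf)
            lab[inside_ilt] = LABELS["ilt_iso"]
            lab[bright] = LABELS["ilt_bright"]
    lab[rr <= r_l] = LABELS["lumen"]
    # reference structures (muscle, spine) only where not already vessel
    for name, off, rad in (
        ("muscle", spec.muscle_offset, spec.muscle_radius),
        ("spine", spec.spine_offset, spec.spine_radius),
    ):
        d = np.hypot(xx_mm - off[0], yy_mm - off[1])
        lab[(d <= rad) & (lab == LABELS["background"])] = LABELS[name]
    if body_semi_mm is not None:
        outside = (xx_mm / body_semi_mm[0]) ** 2 + (yy_mm / body_semi_mm[1]) ** 2 > 1.0
        lab[outside & (lab == LABELS["background"])] = LABELS["air"]
    return lab


def build_phantom(spec: PhantomSpec) -> DigitalPhantom:
    """Rasterise a phantom and populate its analytic truth record.

    Intensity uses partial-volume anti-aliasing: each voxel's intensity is
    the mean over a ``supersample``^2 sub-grid in-plane, while the label is
    the voxel-centre class.  The truth record is evaluated from the
    continuous profiles at the slice centres, never from the raster.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    z_mm = spec.axial_positions_mm()

    r_outer = (
        np.asarray(spec.lumen_radius_profile(z_mm))
        + (np.asarray(spec.ilt_thickness_profile(z_mm)) if spec.ilt_type != 4 else 0.0)
        + spec.wall_thickness
    )
    r_lumen = np.asarray(spec.lumen_radius_profile(z_mm))
    if np.any(r_lumen <= 0):
        raise ValueError("lumen_radius_profile must be positive everywhere")
    # grid containment: outer radius + 3-voxel margin must fit in-plane
    half_extent = (min(nx, ny) / 2.0 - 3.0) * vs
    if np.any(r_outer > half_extent):
        bad = int(np.argmax(r_outer > half_extent))
        raise ValueError(
            f"phantom geometry exceeds grid at axial slice {bad}: outer radius "
            f"{r_outer[bad]:.1f} mm > available {half_extent:.1f} mm"
        )

    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x_mm = (np.arange(nx) - cx) * vs
    y_mm = (np.arange(ny) - cy) * vs
    xx, yy = np.meshgrid(x_mm, y_mm, indexing="ij")

    intens_of = np.zeros(max(LABELS.values()) + 1)
    for name, code in LABELS.items():
        intens_of[code] = spec.tissue_intensities[name]

    s = max(1, int(spec.supersample))
    if s > 1:
        # in-plane sub-voxel offsets, symmetric about the voxel centre
        offs = (np.arange(s) - (s - 1) / 2.0) / s * vs
    body_semi = (spec.body_fraction * nx / 2.0 * vs, spec.body_fraction * ny / 2.0 * vs)
    labels = np.empty((nx, ny, nz), dtype=np.int8)
    intensity = np.empty((nx, ny, nz), dtype=np.float64)
    for k in range(nz):
        lab = _cross_section_labels(spec, xx, yy, z_mm[k], body_semi)
        labels[:, :, k] = lab
        if s == 1:
            intensity[:, :, k] = intens_of[lab]
        else:
            acc = np.zeros((nx, ny))
            for dx in offs:
                for dy in offs:
                    sub = _cross_section_labels(spec, xx + dx, yy + dy, z_mm[k], body_semi)
                    acc += intens_of[sub]
            intensity[:, :, k] = acc / (s * s)

    k_star = int(np.argmax(r_outer))
    rl, t = float(r_lumen[k_star]), (
        float(spec.ilt_thickness_profile(z_mm[k_star])) if spec.ilt_type != 4 else 0.0
    )
    ro = float(r_outer[k_star])
    bf = spec.effective_bright_fraction
    ti = spec.tissue_intensities
    if spec.ilt_type == 4 or t == 0.0:
        ilt_mean = 0.0
        ratio = 0.0
    else:
        ilt_mean = bf * ti["ilt_bright"] + (1.0 - bf) * ti["ilt_iso"]
        ratio = ilt_mean / ti["muscle"]
    truth = TruthRecord(
        max_outer_diameter=2.0 * ro / 10.0,  # mm -> cm
        slice_of_max=k_star,
        lumen_area_at_max=np.pi * rl**2 / 100.0,  # mm^2 -> cm^2
        ilt_wall_area_at_max=np.pi * (ro**2 - rl**2) / 100.0,
        ilt_muscle_ratio=ratio,
        ilt_type=spec.ilt_type,
    )
    return DigitalPhantom(intensity=intensity, labels=labels, truth=truth, voxel_size=vs, spec=spec)


def coil_sensitivities(
    grid_shape: tuple[int, int, int],
    n_coils: int,
    smoothness_scale: float = 0.5,
    seed: int = 0,
    support: np.ndarray | None = None,
) -> SenseMaps:
    """Smooth random complex coil maps, RSS-normalised to 1 on the support.

    Each coil is a Gaussian bump at a random location near the volume
    boundary (mimicking surface coil elements) with a smooth random linear
    phase; only smoothness and normalisation matter downstream.
    ``smoothness_scale`` sets the bump width as a fraction of the grid.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny, nz = grid_shape
    if support is None:
        support = np.ones(grid_shape, dtype=bool)
    if n_coils == 1:
        maps = np.ones((1, nx, ny, nz), dtype=np.complex128)
        maps[0, ~support] = 0.0
        return SenseMaps(maps=maps, support=support)

    rng = np.random.default_rng(seed)
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz), indexing="ij"
    )
    maps = np.empty((n_coils, nx, ny, nz), dtype=np.complex128)
    for n in range(n_coils):
        # bump centre on a ring outside the object, evenly spread + jitter
        # bump scale is kept large relative to the calibration-region
        # resolution: body-coil elements vary slowly across a thin imaging
        # slab, and the estimator can only recover what the fully sampled
        # centre resolves
        ang = 2 * np.pi * (n + rng.uniform(-0.2, 0.2)) / n_coils
        cx, cy = 1.5 * np.cos(ang), 1.5 * np.sin(ang)
        cz = rng.uniform(-0.2, 0.2)
        width = smoothness_scale * rng.uniform(2.2, 3.0)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + 0.1 * (z - cz) ** 2) / (2 * width**2))
        phase = (
            rng.uniform(-np.pi, np.pi)
            + rng.uniform(-0.6, 0.6) * x
            + rng.uniform(-0.6, 0.6) * y
            + rng.uniform(-0.1, 0.1) * z
        )
        maps[n] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    rss = np.where(rss > 0, rss, 1.0)
    maps /= rss  # RSS = 1 everywhere (support and beyond)
    maps[:, ~support] = 0.0
    return SenseMaps(maps=maps, support=support)


def simulate_acquisition(
    phantom: DigitalPhantom | np.ndarray,
    maps: SenseMaps,
    mask,
    noise_sd: float | None = None,
    seed: int = 0,
) -> KSpaceAcquisition:
    """Forward-simulate multi-coil k-space: y_n = M F(CSM_n * x) + noise.

    F is the orthonormal 3D DFT; M restricts to the sampled phase-encode
    locations (the mask plane spans the last two axes, the readout axis is
    fully sampled).  Complex Gaussian noise with E|n|^2 = noise_sd^2 is added
    on the sampled locations only; unsampled entries are exactly zero.
    """
    x = phantom.intensity if isinstance(phantom, DigitalPhantom) else np.asarray(phantom)
    if noise_sd is None:
        noise_sd = phantom.spec.noise_sd if isinstance(phantom, DigitalPhantom) else 0.0
    if maps.maps.shape[1:] != x.shape:
        raise ValueError(f"coil map shape {maps.maps.shape[1:]} != image shape {x.shape}")
    m2d = np.asarray(mask.grid, dtype=bool)
    if m2d.shape != x.shape[1:]:
        raise ValueError(f"mask shape {m2d.shape} != phase-encode plane {x.shape[1:]}")
    rng = np.random.default_rng(seed)
    n_coils = maps.n_coils
    data = np.empty((n_coils,) + x.shape, dtype=np.complex128)
    for n in range(n_coils):
        k = np.fft.fftn(np.fft.ifftshift(maps.maps[n] * x), norm="ortho")
        k = np.fft.fftshift(k)
        if noise_sd > 0:
            noise = rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
            k = k + noise * (noise_sd / np.sqrt(2.0))
        k[:, ~m2d] = 0.0
        data[n] = k
    return KSpaceAcquisition(data=data, mask=mask)


def default_spec(
    max_diameter_cm: float = 4.0,
    ilt_type: int = 2,
    noise_sd: float = 0.02,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (96, 96, 24),
    ilt_fraction: float = 0.35,
    bulge_sigma_mm: float = 8.0,
) -> PhantomSpec:
    """Convenience constructor: fusiform AAA with a target maximal diameter.

    The outer radius at the bulge apex is split into lumen, ILT (a fraction
    ``ilt_fraction`` of the apex radius, zero for type 4) and a 2 mm wall,
    with a 1 cm-radius undilated aorta away from the bulge.
    """
    r_apex = max_diameter_cm * 10.0 / 2.0
    wall = 2.0
    t_apex = 0.0 if ilt_type == 4 else ilt_fraction * r_apex
    r_lumen_apex = r_apex - wall - t_apex
    base = min(10.0, r_lumen_apex)
    return PhantomSpec(
        grid_shape=grid_shape,
        lumen_radius_profile=RadialProfile.gaussian_bulge(
            base, r_lumen_apex - base, bulge_sigma_mm
        ),
        ilt_thickness_profile=(
            RadialProfile.constant(0.0)
            if ilt_type == 4
            else RadialProfile.gaussian_bulge(0.0, t_apex, bulge_sigma_mm)
        ),
        wall_thickness=wall,
        ilt_type=ilt_type,
        noise_sd=noise_sd,
        seed=seed,
    )
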