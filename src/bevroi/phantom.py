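"""Synthetic digital skull phantom.

A CT-like Hounsfield-unit volume emulating a gelatin-filled skull shell
with an embedded 2 mm metal ball bearing (BB) at isocenter: an ellipsoidal
high-HU shell (~400 HU) with seeded asymmetric surface undulations, a
soft-tissue interior (~36 HU), air-filled sinus-like cavities in the
anterior interior, and a scattering of small bony landmark nodules so that
every beam's-eye view contains registrable structure.  The phantom is the
digital stand-in for a printed-and-filled physical skull; it is generated,
not scanned, so it is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CTVolume",
    "PhantomSpec",
    "generate_skull_phantom",
    "remove_bb_region",
    "sample_fill_hu",
]

AIR_HU = -1000.0


@dataclass
class CTVolume:
    """3D scalar grid in Hounsfield units with room-frame bookkeeping.

    ``values`` is indexed ``[i, j, k]`` along the room axes (x: lateral,
    y: longitudinal, z: vertical) at couch angle zero.  ``origin`` is the
    room position (mm) of the center of voxel (0, 0, 0); ``isocenter`` is
    a room point (mm) that must lie inside the volume bounds.
    """

    values: np.ndarray
    spacing: np.ndarray  # (3,) mm, strictly positive
    origin: np.ndarray  # (3,) mm
    isocenter: np.ndarray  # (3,) mm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.isocenter = np.asarray(self.isocenter, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("CTVolume.values must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive on every axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.values.shape) - 0.5) * self.spacing
        if np.any(self.isocenter < lo) or np.any(self.isocenter > hi):
            raise ValueError("isocenter lies outside the volume bounds")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_of_point(self, point_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index of a room point."""
        idx = np.rint((np.asarray(point_mm, float) - self.origin) / self.spacing)
        return idx.astype(int)

    def point_of_voxel(self, index) -> np.ndarray:
        """Room position (mm) of a voxel center."""
        return self.origin + np.asarray(index, float) * self.spacing

    def copy(self) -> "CTVolume":
        return replace(self, values=self.values.copy(), metadata=dict(self.metadata))


@dataclass
class PhantomSpec:
    """Parameters of the synthetic skull.

    Lengths in mm, intensities in HU.  ``outer_semi_axes`` are the
    (x, y, z) semi-axes of the outer skull ellipsoid; the inner table sits
    ``shell_thickness`` below it.  ``sinus_size_range`` is the full extent
    of the air cavities.  ``landmark_count`` bony nodules are scattered in
    the interior, clear of the BB removal neighborhood, to guarantee
    registrable texture for any gantry/couch combination.
    """

    outer_semi_axes: tuple[float, float, float] = (72.0, 92.0, 78.0)
    shell_thickness: float = 6.0
    skull_hu: float = 400.0
    fill_hu: float = 36.1
    bb_diameter: float = 2.0
    # metal-surrogate: with the linear HU->attenuation ramp, 20000 HU gives
    # ~21x water attenuation, approaching a steel BB at MV energies, so the
    # fiducial dominates any disk-matched convolution response
    bb_hu: float = 20000.0
    sinus_count: int = 3
    sinus_size_range: tuple[float, float] = (8.0, 20.0)
    landmark_count: int = 24
    # mastoid-like clusters of small air cells in the posterior-lateral
    # interior; the dominant fine texture of lateral skull projections
    air_cell_clusters: int = 2
    air_cells_per_cluster: int = 40
    voxel_spacing: float | tuple[float, float, float] = 0.625
    noise_sigma_hu: float = 0.0
    seed: int = 0

    @property
    def spacing(self) -> np.ndarray:
        s = self.voxel_spacing
        if np.isscalar(s):
            return np.full(3, float(s))
        return np.asarray(s, dtype=float).reshape(3)

    def validate(self) -> None:
        sp = self.spacing
        if not np.all(sp > 0):
            raise ValueError("voxel spacing must be strictly positive on every axis")
        if self.shell_thickness >= min(self.outer_semi_axes):
            raise ValueError(
                "invariant violated: shell thickness must be smaller than the "
                "smallest outer semi-axis"
            )
        if self.bb_diameter < 2.0 * sp.min():
            raise ValueError(
                "invariant violated: bb diameter must be at least twice the "
                "smallest voxel spacing"
            )


def _direction_bumps(
    rng: np.random.Generator,
    n_terms: int,
    amp: tuple[float, float],
    freq_range: tuple[int, int] = (1, 5),
):
    """Seeded smooth angular modulation f(azimuth, polar) -> fraction.

    A short random cosine series over the two direction angles; amplitudes
    small enough that the shell stays closed.
    """
    terms = []
    for _ in range(n_terms):
        a = rng.uniform(*amp)
        m = rng.integers(*freq_range)
        n = rng.integers(1, max(2, freq_range[1] // 2))
        pa = rng.uniform(0, 2 * np.pi)
        pb = rng.uniform(0, 2 * np.pi)
        terms.append((a, int(m), int(n), pa, pb))

    def f(az: np.ndarray, pol: np.ndarray) -> np.ndarray:
        out = np.zeros_like(az)
        for a, m, n, pa, pb in terms:
            out += a * np.cos(m * az + pa) * np.cos(n * pol + pb)
        return out

    return f


def generate_skull_phantom(spec: PhantomSpec) -> CTVolume:
    """Build the synthetic skull volume.

    Deterministic for a fixed ``spec.seed``.  The BB is centered exactly at
    isocenter (the volume center).  Surface undulations are asymmetric so
    no beam's-eye view is rotationally degenerate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing
    semi = np.asarray(spec.outer_semi_axes, dtype=float)

    bump_outer = _direction_bumps(rng, 5, (0.005, 0.02))
    bump_thick = _direction_bumps(rng, 4, (0.003, 0.012))
    # higher-frequency thickness ripple: sutures/ridges of the cranial vault
    ripple = _direction_bumps(rng, 8, (0.002, 0.006), freq_range=(4, 11))

    margin = 6.0
    half_extent = semi * 1.03 + margin
    n = (np.ceil(2 * half_extent / sp) // 2 * 2 + 1).astype(int)  # odd => exact center
    center_idx = n // 2

    ax = [(np.arange(n[i]) - center_idx[i]) * sp[i] for i in range(3)]
    x = ax[0][:, None, None].astype(np.float32)
    y = ax[1][None, :, None].astype(np.float32)
    z = ax[2][None, None, :].astype(np.float32)

    r = np.sqrt(x * x + y * y + z * z, dtype=np.float32)
    az = np.arctan2(y, x).astype(np.float32) + np.zeros_like(r)
    with np.errstate(invalid="ignore"):
        pol = np.arccos(np.clip(np.divide(z, np.maximum(r, 1e-6)), -1, 1))
    pol = pol.astype(np.float32) + np.zeros_like(r)

    mod_out = (1.0 + bump_outer(az, pol)).astype(np.float32)
    # direction-modulated shell thickness, kept strictly positive; the
    # ripple term adds suture/ridge-scale variation
    thick = spec.shell_thickness * np.clip(
        1.0 + 20.0 * bump_thick(az, pol) + 30.0 * ripple(az, pol), 0.30, 2.0
    ).astype(np.float32)
    # normalized ellipsoidal radii; boundary where rho == modulation
    rho_out = np.sqrt(
        (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2,
        dtype=np.float32,
    )
    # inner boundary: shrink the radius by the thickness, converting mm to
    # normalized units with the mean semi-axis
    mean_semi = float(semi.mean())
    rho_in = rho_out * (mean_semi / (mean_semi - thick))

    values = np.full(n, AIR_HU, dtype=np.float32)
    interior = rho_in < mod_out
    shell = (rho_out < mod_out) & ~interior
    values[interior] = spec.fill_hu
    values[shell] = spec.skull_hu

    inner_semi = semi - spec.shell_thickness

    # sinus-like air cavities in the anterior (+y) interior, clear of the BB
    lo_s, hi_s = spec.sinus_size_range
    for _ in range(spec.sinus_count):
        size = rng.uniform(lo_s, hi_s)
        cs = np.array(
            [
                rng.uniform(-0.35, 0.35) * inner_semi[0],
                rng.uniform(0.35, 0.65) * inner_semi[1],
                rng.uniform(-0.30, 0.20) * inner_semi[2],
            ]
        )
        axes = size / 2.0 * rng.uniform(0.7, 1.3, size=3)
        d2 = (
            ((x - cs[0]) / axes[0]) ** 2
            + ((y - cs[1]) / axes[1]) ** 2
            + ((z - cs[2]) / axes[2]) ** 2
        )
        values[(d2 < 1.0) & interior] = AIR_HU

    # mastoid-like air-cell clusters, posterior-lateral, mirrored
    for side in [-1.0, 1.0][: max(0, int(spec.air_cell_clusters))]:
        cc = np.array(
            [
                side * rng.uniform(0.60, 0.80) * inner_semi[0],
                -rng.uniform(0.30, 0.55) * inner_semi[1],
                -rng.uniform(0.05, 0.35) * inner_semi[2],
            ]
        )
        for _ in range(spec.air_cells_per_cluster):
            pos = cc + rng.normal(0.0, 0.16 * inner_semi.min(), size=3)
            rad = rng.uniform(1.5, 4.0)
            d2 = ((x - pos[0]) ** 2 + (y - pos[1]) ** 2 + (z - pos[2]) ** 2) / rad**2
            values[(d2 < 1.0) & interior] = AIR_HU

    # bony landmark nodules at 60-90% of the inner radius, any direction
    for _ in range(spec.landmark_count):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        f = rng.uniform(0.60, 0.90)
        cn = f * inner_semi * u
        rad = rng.uniform(3.0, 8.0)
        d2 = ((x - cn[0]) ** 2 + (y - cn[1]) ** 2 + (z - cn[2]) ** 2) / rad**2
        values[(d2 < 1.0) & interior] = spec.skull_hu

    if spec.noise_sigma_hu > 0:
        values += rng.normal(0.0, spec.noise_sigma_hu, size=values.shape).astype(
            np.float32
        )

    # BB last so nothing overwrites it
    bb_r = spec.bb_diameter / 2.0
    d2 = x * x + y * y + z * z
    values[d2 <= bb_r**2 + 1e-6] = spec.bb_hu

    origin = -center_idx * sp
    return CTVolume(
        values=values,
        spacing=sp,
        origin=origin,
        isocenter=np.zeros(3),
        metadata={
            "bb_diameter_mm": spec.bb_diameter,
            "bb_hu": spec.bb_hu,
            "fill_hu": spec.fill_hu,
            "skull_hu": spec.skull_hu,
            "outer_semi_axes_mm": tuple(spec.outer_semi_axes),
            "seed": spec.seed,
        },
    )


def skull_volume_cm3(spec: PhantomSpec) -> float:
    """Nominal skull volume (outer ellipsoid, cm^3) used for clinical scaling."""
    a, b, c = spec.outer_semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


def remove_bb_region(
    volume: CTVolume,
    neighborhood: tuple[int, int, int] = (60, 60, 40),
    fill_hu: float = 36.1,
) -> CTVolume:
    """Replace a voxel-aligned box around the BB center with soft-tissue HU.

    Performed before reference DRR generation so the fiducial does not bias
    anatomy registration.  The box is centered on the voxel nearest the
    isocenter and clipped (with a warning) if it does not fit.
    """
    ext = np.asarray(neighborhood, dtype=int)
    if ext.shape != (3,) or np.any(ext <= 0):
        raise ValueError("neighborhood extent must be three positive integers")
    center = volume.voxel_of_point(volume.isocenter)
    lo = center - ext // 2
    hi = lo + ext
    shape = np.array(volume.shape)
    if np.any(lo < 0) or np.any(hi > shape):
        warnings.warn(
            "BB removal neighborhood clipped to the volume bounds", stacklevel=2
        )
        lo = np.clip(lo, 0, shape)
        hi = np.clip(hi, 0, shape)
    out = volume.copy()
    out.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = fill_hu
    out.metadata["bb_removed"] = True
    return out


def sample_fill_hu(
    volume: CTVolume,
    region_center: tuple[int, int, int],
    extent: tuple[int, int, int] = (20, 20, 20),
) -> tuple[float, float]:
    """Mean and SD of HU over a voxel box that must avoid the BB."""
    ext = np.asarray(extent, dtype=int)
    if np.any(ext <= 0):
        raise ValueError("extent must be positive")
    c = np.asarray(region_center, dtype=int)
    lo = c - ext // 2
    hi = lo + ext
    shape = np.array(volume.shape)
    if np.any(lo < 0) or np.any(hi > shape):
        raise ValueError("sampling region extends outside the volume")
    bb_d = float(volume.metadata.get("bb_diameter_mm", 2.0))
    bb_center = volume.voxel_of_point(volume.isocenter)
    # closest point of the box to the BB center, in mm
    nearest = np.clip(bb_center, lo, hi - 1)
    dist_mm = np.linalg.norm((nearest - bb_center) * volume.spacing)
    if not volume.metadata.get("bb_removed", False) and dist_mm <= bb_d / 2.0:
        raise ValueError(
            f"sampling region overlaps the BB sphere (closest approach "
            f"{dist_mm:.2f} mm, BB radius {bb_d / 2.0:.2f} mm)"
        )
    block = volume.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(
        np.float64
    )
    return float(np.mean(block)), float(np.std(block))
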