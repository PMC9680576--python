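"""Couch corrections from BEV displacements and motion-trace simulation.

A displacement (dx, dy) detected in the beam's-eye view at gantry theta /
couch phi (plan scale) maps to room/couch-axis corrections via

    [dLat]   [cos phi  -sin phi  0] [dx cos theta]
    [dLng] = [sin phi   cos phi  0] [dy          ]
    [dVrt]   [0         0        1] [dx sin theta]

which preserves the displacement norm and is exactly the projection of
the 3D couch offset onto the plane perpendicular to the beam, expressed
on the couch axes.  Delivery simulation is open-loop: a known motion
trace displaces the phantom, a synthetic EPID image is computed at every
imaging point, and the couch correction detected from BB tracking or
anatomy registration is compared against the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .apertures import Aperture, ImagingPlan
from .phantom import CTVolume
from .projection import BeamGeometry, DRRImage, compute_drr, _rz
from .registration import (
    DetectionError,
    aperture_pixel_window,
    detect_bb,
    preprocess,
    register_crop,
)

__all__ = [
    "CouchShift",
    "MotionTrace",
    "DeliveryRecord",
    "DeliveryConfig",
    "ErrorSummary",
    "derive_couch_shift",
    "couch_to_room",
    "make_motion_trace",
    "simulate_epid_image",
    "simulate_delivery",
    "evaluate_errors",
]


@dataclass(frozen=True)
class CouchShift:
    """Lateral/longitudinal/vertical correction triple (mm, couch axes)."""

    lat_mm: float
    lng_mm: float
    vrt_mm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.lat_mm, self.lng_mm, self.vrt_mm])

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array()))


def derive_couch_shift(d, theta_deg: float, phi_deg: float) -> CouchShift:
    """Map a BEV displacement (dx, dy) in mm to couch-axis corrections.

    ``theta_deg``/``phi_deg`` are the plan-scale gantry and couch angles.
    The transform preserves the norm: |(dLat, dLng, dVrt)| = |(dx, dy)|.
    """
    dx, dy = float(d[0]), float(d[1])
    t = np.deg2rad(theta_deg)
    p = np.deg2rad(phi_deg)
    vx = dx * np.cos(t)
    vz = dx * np.sin(t)
    return CouchShift(
        lat_mm=np.cos(p) * vx - np.sin(p) * dy,
        lng_mm=np.sin(p) * vx + np.cos(p) * dy,
        vrt_mm=vz,
    )


def couch_to_room(offset_couch_mm, couch_deg: float) -> np.ndarray:
    """Room-frame vector of a couch-axis offset at plan couch angle."""
    phi_iec = (360.0 - couch_deg) % 360.0
    return _rz(phi_iec) @ np.asarray(offset_couch_mm, dtype=float)


@dataclass
class MotionTrace:
    """Per-control-point true phantom offset (mm, couch axes)."""

    kind: str  # 'linear-drift' | 'sudden-shift' | 'none'
    magnitude_mm: float
    offsets: np.ndarray  # (N, 3)
    onset: int | None = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 3:
            raise ValueError("offsets must have shape (N, 3)")


def make_motion_trace(
    kind: str,
    magnitude_mm: float,
    control_points: list[BeamGeometry],
    onset: int | None = None,
) -> MotionTrace:
    """Build a motion trace over the imaging control points.

    linear-drift: magnitude * i/(N-1) on every axis (zero at the first
    point, full magnitude at the last).  sudden-shift: a step of the full
    magnitude at the onset index, by default halfway through the first
    (axial) arc.  none: all zero.
    """
    n = len(control_points)
    if n == 0:
        raise ValueError("control-point list is empty")
    if not np.isfinite(magnitude_mm):
        raise ValueError("magnitude must be finite")
    offsets = np.zeros((n, 3))
    if kind == "linear-drift":
        ramp = np.arange(n) / max(n - 1, 1)
        offsets[:] = magnitude_mm * ramp[:, None]
    elif kind == "sudden-shift":
        if onset is None:
            couch0 = control_points[0].couch_deg
            n_first = 0
            for cp in control_points:
                if cp.couch_deg != couch0:
                    break
                n_first += 1
            onset = n_first // 2
        offsets[onset:] = magnitude_mm
    elif kind != "none":
        raise ValueError(f"unknown trace kind: {kind!r}")
    return MotionTrace(kind=kind, magnitude_mm=magnitude_mm, offsets=offsets, onset=onset)


def simulate_epid_image(
    volume: CTVolume,
    geometry: BeamGeometry,
    offset_couch_mm,
    aperture: Aperture,
    detector_px: tuple[int, int] = (512, 512),
    noise_photons: float | None = None,
    mu_water: float | None = None,
    seed: int = 0,
) -> DRRImage:
    """Synthetic EPID acquisition: DRR of the rigidly displaced phantom,
    cropped to the aperture.

    ``noise_photons`` enables Poisson-like noise at the given mean photon
    count for unit transmission (deterministic per seed).  Unlike the
    reference DRRs, the simulated EPID sees the BB (pass the un-removed
    volume).
    """
    from .projection import DEFAULT_MU_WATER

    t_room = couch_to_room(offset_couch_mm, geometry.couch_deg)
    drr = compute_drr(
        volume,
        geometry,
        detector_px,
        mu_water=DEFAULT_MU_WATER if mu_water is None else mu_water,
        volume_offset_mm=t_room,
    )
    r0, r1, c0, c1 = aperture_pixel_window(drr, aperture)
    if r1 - r0 < 2 or c1 - c0 < 2:
        raise ValueError("aperture lies outside the detector")
    pixels = drr.pixels[r0:r1, c0:c1]
    if noise_photons is not None:
        rng = np.random.default_rng(seed)
        pixels = rng.poisson(np.clip(pixels, 0, None) * noise_photons) / noise_photons
    return DRRImage(
        pixels=pixels,
        pitch_mm=drr.pitch_mm,
        principal_point=(drr.principal_point[0] - r0, drr.principal_point[1] - c0),
        geometry=geometry,
        metadata={"crop_origin": (r0, c0), "offset_couch_mm": tuple(map(float, offset_couch_mm))},
    )


@dataclass
class DeliveryRecord:
    index: int
    geometry: BeamGeometry
    bev_mm: np.ndarray  # detected (dx, dy)
    shift: CouchShift
    ok: bool = True
    note: str = ""


@dataclass
class DeliveryConfig:
    detector_px: tuple[int, int] = (512, 512)
    mu_water: float | None = None
    bound_mm: float = 3.0
    bins: int = 50
    bb_field_mm: float = 25.0  # 2.5 x 2.5 cm^2 jaw field for BB tracking
    noise_photons: float | None = None
    seed: int = 0


def simulate_delivery(
    volume: CTVolume,
    plan: ImagingPlan,
    trace: MotionTrace,
    method: str,
    config: DeliveryConfig | None = None,
    reference_volume: CTVolume | None = None,
) -> list[DeliveryRecord]:
    """Open-loop delivery simulation over all imaging control points.

    ``method`` 'bb' tracks the fiducial through a small jaw field;
    'anatomy' registers the aperture-cropped EPID image to the BB-free
    reference DRR.  ``reference_volume`` (BB removed) is required for the
    anatomy method.  Per-point failures are flagged, the run continues.
    """
    if config is None:
        config = DeliveryConfig()
    if len(plan.entries) != len(trace.offsets):
        raise ValueError("plan and trace cover different control-point counts")
    if method not in ("bb", "anatomy"):
        raise ValueError("method must be 'bb' or 'anatomy'")
    if method == "anatomy" and reference_volume is None:
        raise ValueError("anatomy method needs the BB-removed reference volume")

    bb_d = float(volume.metadata.get("bb_diameter_mm", 2.0))
    records: list[DeliveryRecord] = []
    ref_cache: dict = {}
    for i, entry in enumerate(plan.entries):
        geo = entry.geometry
        aperture = (
            Aperture(0.0, 0.0, config.bb_field_mm, config.bb_field_mm)
            if method == "bb"
            else entry.aperture
        )
        try:
            epid = simulate_epid_image(
                volume,
                geo,
                trace.offsets[i],
                aperture,
                detector_px=config.detector_px,
                noise_photons=config.noise_photons,
                mu_water=config.mu_water,
                seed=config.seed + i,
            )
            if method == "bb":
                d = detect_bb(
                    epid.pixels,
                    bb_d,
                    epid.pitch_mm,
                    principal_point=epid.principal_point,
                )
            else:
                key = (geo.gantry_deg, geo.couch_deg, geo.sid_mm)
                if key not in ref_cache:
                    from .projection import DEFAULT_MU_WATER

                    from scipy import ndimage as _ndi

                    ref = compute_drr(
                        reference_volume,
                        geo,
                        config.detector_px,
                        mu_water=config.mu_water or DEFAULT_MU_WATER,
                    )
                    ref_pre = preprocess(ref.pixels)
                    ref_cache[key] = (
                        ref,
                        ref_pre,
                        _ndi.spline_filter(ref_pre, order=3),
                    )
                ref, ref_pre, ref_pref = ref_cache[key]
                r0, c0 = epid.metadata["crop_origin"]
                res = register_crop(
                    ref_pre,
                    preprocess(epid.pixels),
                    (r0, c0),
                    epid.pitch_mm,
                    bound_mm=config.bound_mm,
                    bins=config.bins,
                    ref_prefiltered=ref_pref,
                )
                if not res.converged:
                    raise DetectionError("registration did not converge")
                d = res.shift_mm
            shift = derive_couch_shift(d, geo.gantry_deg, geo.couch_deg)
            records.append(DeliveryRecord(i, geo, np.asarray(d), shift))
        except (DetectionError, ValueError) as exc:
            records.append(
                DeliveryRecord(
                    i,
                    geo,
                    np.full(2, np.nan),
                    CouchShift(np.nan, np.nan, np.nan),
                    ok=False,
                    note=str(exc),
                )
            )
    return records


@dataclass
class ErrorSummary:
    """Anatomy-vs-BB positioning error statistics over a delivery."""

    err2d_mm: np.ndarray
    err3d_mm: np.ndarray
    median_3d_mm: float
    mean_3d_mm: float
    median_2d_mm: float
    frac_2d_lt_1mm: float
    percentiles_3d_mm: dict = field(default_factory=dict)
    n_points: int = 0
    n_flagged: int = 0


def evaluate_errors(
    anatomy: list[DeliveryRecord], bb: list[DeliveryRecord]
) -> ErrorSummary:
    """Per-point 2D (BEV) and 3D (couch-axis) discrepancies between
    anatomy-derived and BB-derived corrections; flagged points are
    excluded and counted."""
    if len(anatomy) != len(bb):
        raise ValueError("record lists have different lengths")
    err2d, err3d = [], []
    flagged = 0
    for a, b in zip(anatomy, bb):
        if not (a.ok and b.ok):
            flagged += 1
            continue
        err2d.append(np.linalg.norm(a.bev_mm - b.bev_mm))
        err3d.append(np.linalg.norm(a.shift.as_array() - b.shift.as_array()))
    e2 = np.asarray(err2d)
    e3 = np.asarray(err3d)
    if e3.size == 0:
        raise ValueError("no valid control points to compare")
    return ErrorSummary(
        err2d_mm=e2,
        err3d_mm=e3,
        median_3d_mm=float(np.median(e3)),
        mean_3d_mm=float(np.mean(e3)),
        median_2d_mm=float(np.median(e2)),
        frac_2d_lt_1mm=float(np.mean(e2 < 1.0)),
        percentiles_3d_mm={
            p: float(np.percentile(e3, p)) for p in (5, 25, 75, 95)
        },
        n_points=int(e3.size),
        n_flagged=flagged,
    )
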