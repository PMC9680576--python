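"""Arc geometry and digitally reconstructed radiographs (DRRs).

Geometry follows a fixed room frame: x lateral, y longitudinal (gun-target
axis), z vertical, isocenter at the origin.  The gantry rotates about y;
at gantry 0 the source sits above the supine patient and the beam points
down.  The couch rotates the patient about z.  Plan (Eclipse-scale) couch
angles are converted internally via couch_IEC = (360 - couch) mod 360.

The gantry rotation sense and the beam's-eye-view (BEV) axes are chosen so
that the couch-correction transform in :mod:`bevroi.motion` is an exact
projection operator:

    source(theta) = SAD * (-sin t, 0, cos t)
    u_bev(theta)  = (cos t, 0, sin t)        # BEV x at the isocenter plane
    v_bev         = (0, 1, 0)                # BEV y

DRR pixel intensity is exp(-path), with the radiological path computed by
Siddon's parametric voxel traversal (exact per-voxel chord lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .phantom import CTVolume

__all__ = [
    "BeamGeometry",
    "ArcSpec",
    "DRRImage",
    "control_points_from_arcs",
    "three_arc_geometry",
    "hu_to_attenuation",
    "compute_drr",
    "project_point",
]

#: effective water attenuation (1/mm) in the 2.5 MV imaging-beam regime
DEFAULT_MU_WATER = 0.00505


def _rz(alpha_deg: float) -> np.ndarray:
    a = np.deg2rad(alpha_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class BeamGeometry:
    """One imaging control point.

    Angles are stored on the plan (Eclipse) scale in [0, 360).  ``sid_mm``
    is 1500 when the EPID sits 50 cm below isocenter and 1800 at 80 cm.
    """

    gantry_deg: float
    couch_deg: float = 0.0
    sad_mm: float = 1000.0
    sid_mm: float = 1500.0
    panel_pitch_mm: float = 0.336

    def __post_init__(self):
        if not (self.sid_mm > self.sad_mm > 0):
            raise ValueError("require SID > SAD > 0")
        object.__setattr__(self, "gantry_deg", float(self.gantry_deg) % 360.0)
        object.__setattr__(self, "couch_deg", float(self.couch_deg) % 360.0)

    @property
    def couch_iec_deg(self) -> float:
        return (360.0 - self.couch_deg) % 360.0

    @property
    def iso_pitch_mm(self) -> float:
        """Detector pixel pitch rescaled to the isocenter plane."""
        return self.panel_pitch_mm * self.sad_mm / self.sid_mm

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(source, u, v, beam direction) in the room frame, mm / unit."""
        t = np.deg2rad(self.gantry_deg)
        source = self.sad_mm * np.array([-np.sin(t), 0.0, np.cos(t)])
        u = np.array([np.cos(t), 0.0, np.sin(t)])
        v = np.array([0.0, 1.0, 0.0])
        b = -source / self.sad_mm
        return source, u, v, b


@dataclass(frozen=True)
class ArcSpec:
    """One imaging arc: couch angle, gantry span and rotation direction.

    ``direction`` 'CW' enumerates increasing gantry angle (mod 360), 'CCW'
    decreasing.  A near-full arc (span within one spacing of 360 degrees)
    is treated as closed: the stop point, which nearly coincides with the
    start, is not duplicated.
    """

    couch_deg: float
    gantry_start_deg: float
    gantry_stop_deg: float
    direction: str = "CW"
    spacing_deg: float = 5.0
    epid_offset_cm: float | None = None  # default 50 at couch 0, else 80

    def __post_init__(self):
        if self.spacing_deg <= 0:
            raise ValueError("control-point spacing must be positive")
        if self.direction not in ("CW", "CCW"):
            raise ValueError("direction must be 'CW' or 'CCW'")

    def gantry_angles(self) -> np.ndarray:
        start = self.gantry_start_deg % 360.0
        stop = self.gantry_stop_deg % 360.0
        sign = 1.0 if self.direction == "CW" else -1.0
        span = (sign * (stop - start)) % 360.0
        if span == 0.0:
            span = 360.0
        steps = int(np.floor(span / self.spacing_deg + 1e-9))
        angles = (start + sign * self.spacing_deg * np.arange(steps + 1)) % 360.0
        closed = span >= 360.0 - self.spacing_deg
        if not closed and abs((sign * (stop - angles[-1])) % 360.0) > 1e-9:
            angles = np.append(angles, stop)
        return angles


def three_arc_geometry(spacing_deg: float = 5.0) -> list[ArcSpec]:
    """The study's three-arc geometry: one full axial arc and two partial
    arcs with the couch at +/-45 degrees (plan scale)."""
    return [
        ArcSpec(0.0, 180.1, 179.9, "CW", spacing_deg),
        ArcSpec(45.0, 179.9, 355.0, "CCW", spacing_deg),
        ArcSpec(315.0, 180.1, 5.0, "CW", spacing_deg),
    ]


def control_points_from_arcs(
    arcs: list[ArcSpec],
    sad_mm: float = 1000.0,
    panel_pitch_mm: float = 0.336,
) -> list[BeamGeometry]:
    """Concatenated, ordered control points for a list of arcs.

    The EPID vertical offset defaults to 50 cm for the axial (couch 0) arc
    and 80 cm otherwise (collision avoidance), i.e. SID 1500/1800 mm.
    """
    if not arcs:
        raise ValueError("arcs must be non-empty")
    points: list[BeamGeometry] = []
    for arc in arcs:
        offset = arc.epid_offset_cm
        if offset is None:
            offset = 50.0 if (arc.couch_deg % 360.0) == 0.0 else 80.0
        sid = sad_mm + 10.0 * offset
        for g in arc.gantry_angles():
            points.append(
                BeamGeometry(
                    gantry_deg=g,
                    couch_deg=arc.couch_deg,
                    sad_mm=sad_mm,
                    sid_mm=sid,
                    panel_pitch_mm=panel_pitch_mm,
                )
            )
    return points


def hu_to_attenuation(hu, mu_water: float = DEFAULT_MU_WATER):
    """Linear attenuation (1/mm): mu_water * (1 + HU/1000), clamped at 0."""
    return np.maximum(mu_water * (1.0 + np.asarray(hu, dtype=np.float32) / 1000.0), 0.0)


@dataclass
class DRRImage:
    """A BEV projection image.

    ``pixels`` holds intensities exp(-radiological path) indexed
    [row, col]; rows run along BEV y, columns along BEV x.  ``pitch_mm``
    is the pixel pitch at the isocenter plane; the principal point (where
    the central axis hits the detector) is at ``(cy, cx)`` pixel
    coordinates.
    """

    pixels: np.ndarray
    pitch_mm: float
    principal_point: tuple[float, float]  # (cy, cx)
    geometry: BeamGeometry
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def bev_x_mm(self, col) -> np.ndarray:
        return (np.asarray(col, float) - self.principal_point[1]) * self.pitch_mm

    def bev_y_mm(self, row) -> np.ndarray:
        return (np.asarray(row, float) - self.principal_point[0]) * self.pitch_mm

    def col_of_x(self, x_mm) -> np.ndarray:
        return np.asarray(x_mm, float) / self.pitch_mm + self.principal_point[1]

    def row_of_y(self, y_mm) -> np.ndarray:
        return np.asarray(y_mm, float) / self.pitch_mm + self.principal_point[0]


@njit(cache=True)
def _siddon_paths(mu, sx, sy, sz, ox, oy, oz, src, det00, ustep, vstep, H, W):
    """Radiological path integrals, one ray per detector pixel.

    ``mu`` is the attenuation grid (1/mm); ``(ox, oy, oz)`` the position of
    the low corner (face of voxel (0,0,0)); ``det00`` the position of pixel
    (0, 0); ``ustep``/``vstep`` the per-pixel column/row offsets.  All
    coordinates are in the volume frame, mm.  Exact per-voxel chord
    lengths (Siddon / Amanatides-Woo traversal).
    """
    nx, ny, nz = mu.shape
    out = np.zeros((H, W), dtype=np.float64)
    bx0, by0, bz0 = ox, oy, oz
    bx1 = ox + nx * sx
    by1 = oy + ny * sy
    bz1 = oz + nz * sz
    for r in range(H):
        for c in range(W):
            px = det00[0] + c * ustep[0] + r * vstep[0]
            py = det00[1] + c * ustep[1] + r * vstep[1]
            pz = det00[2] + c * ustep[2] + r * vstep[2]
            dx = px - src[0]
            dy = py - src[1]
            dz = pz - src[2]
            length = np.sqrt(dx * dx + dy * dy + dz * dz)
            # slab clipping in normalized ray parameter t in [0, 1]
            t0 = 0.0
            t1 = 1.0
            ok = True
            for axis in range(3):
                if axis == 0:
                    d, s0, b0, b1 = dx, src[0], bx0, bx1
                elif axis == 1:
                    d, s0, b0, b1 = dy, src[1], by0, by1
                else:
                    d, s0, b0, b1 = dz, src[2], bz0, bz1
                if abs(d) < 1e-12:
                    if s0 < b0 or s0 > b1:
                        ok = False
                        break
                else:
                    ta = (b0 - s0) / d
                    tb = (b1 - s0) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if not ok or t0 >= t1:
                continue
            # entry voxel
            eps = 1e-9
            te = t0 + eps
            ix = int(np.floor((src[0] + te * dx - ox) / sx))
            iy = int(np.floor((src[1] + te * dy - oy) / sy))
            iz = int(np.floor((src[2] + te * dz - oz) / sz))
            if ix < 0:
                ix = 0
            if iy < 0:
                iy = 0
            if iz < 0:
                iz = 0
            if ix > nx - 1:
                ix = nx - 1
            if iy > ny - 1:
                iy = ny - 1
            if iz > nz - 1:
                iz = nz - 1
            # parametric step sizes and next-crossing values per axis
            big = 1e30
            if dx > 0:
                step_x, tdx = 1, sx / dx
                tnx = ((ox + (ix + 1) * sx) - src[0]) / dx
            elif dx < 0:
                step_x, tdx = -1, -sx / dx
                tnx = ((ox + ix * sx) - src[0]) / dx
            else:
                step_x, tdx, tnx = 0, big, big
            if dy > 0:
                step_y, tdy = 1, sy / dy
                tny = ((oy + (iy + 1) * sy) - src[1]) / dy
            elif dy < 0:
                step_y, tdy = -1, -sy / dy
                tny = ((oy + iy * sy) - src[1]) / dy
            else:
                step_y, tdy, tny = 0, big, big
            if dz > 0:
                step_z, tdz = 1, sz / dz
                tnz = ((oz + (iz + 1) * sz) - src[2]) / dz
            elif dz < 0:
                step_z, tdz = -1, -sz / dz
                tnz = ((oz + iz * sz) - src[2]) / dz
            else:
                step_z, tdz, tnz = 0, big, big
            acc = 0.0
            tcur = t0
            while tcur < t1 - 1e-12:
                tnext = tnx
                if tny < tnext:
                    tnext = tny
                if tnz < tnext:
                    tnext = tnz
                if tnext > t1:
                    tnext = t1
                seg = (tnext - tcur) * length
                if seg > 0:
                    acc += mu[ix, iy, iz] * seg
                tcur = tnext
                if tnext == tnx and tnx <= tny and tnx <= tnz:
                    ix += step_x
                    tnx += tdx
                    if ix < 0 or ix >= nx:
                        break
                elif tnext == tny and tny <= tnz:
                    iy += step_y
                    tny += tdy
                    if iy < 0 or iy >= ny:
                        break
                elif tnext == tnz:
                    iz += step_z
                    tnz += tdz
                    if iz < 0 or iz >= nz:
                        break
            out[r, c] = acc
    return out


def compute_drr(
    volume: CTVolume,
    geometry: BeamGeometry,
    detector_px: tuple[int, int] = (512, 512),
    mu_water: float = DEFAULT_MU_WATER,
    volume_offset_mm=None,
) -> DRRImage:
    """Siddon DRR of ``volume`` for one control point.

    ``volume_offset_mm`` rigidly translates the patient in the room frame
    (couch-motion simulation); rays are transformed into the patient frame
    instead of resampling the volume.  Rays that miss the volume give
    intensity 1.
    """
    H, W = int(detector_px[0]), int(detector_px[1])
    src_r, u_r, v_r, b_r = geometry.axes()
    det_center = src_r + geometry.sid_mm * b_r
    pitch = geometry.panel_pitch_mm
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0

    # room -> patient: undo couch rotation and couch translation
    rz = _rz(-geometry.couch_iec_deg)
    t_off = np.zeros(3) if volume_offset_mm is None else np.asarray(volume_offset_mm, float)

    def to_patient(p):
        return rz @ (p - t_off)

    src_p = to_patient(src_r) + volume.isocenter
    det_c_p = to_patient(det_center) + volume.isocenter
    u_p = rz @ u_r
    v_p = rz @ v_r
    det00 = det_c_p - cx * pitch * u_p - cy * pitch * v_p

    mu = hu_to_attenuation(volume.values, mu_water).astype(np.float32)
    sp = volume.spacing
    corner = volume.origin - 0.5 * sp  # low face of voxel (0,0,0)
    paths = _siddon_paths(
        mu,
        sp[0],
        sp[1],
        sp[2],
        corner[0],
        corner[1],
        corner[2],
        src_p.astype(np.float64),
        det00.astype(np.float64),
        (pitch * u_p).astype(np.float64),
        (pitch * v_p).astype(np.float64),
        H,
        W,
    )
    pixels = np.exp(-paths)
    return DRRImage(
        pixels=pixels,
        pitch_mm=geometry.iso_pitch_mm,
        principal_point=(cy, cx),
        geometry=geometry,
        metadata={"mu_water": mu_water},
    )


def project_point(geometry: BeamGeometry, point_room_mm) -> np.ndarray:
    """Perspective projection of a room point onto the BEV, rescaled to the
    isocenter plane (mm).  The isocenter projects to (0, 0)."""
    p = np.asarray(point_room_mm, dtype=float)
    src, u, v, b = geometry.axes()
    rel = p - src
    depth = rel @ b
    if depth <= 0:
        raise ValueError("point lies at or behind the source")
    scale = geometry.sad_mm / depth
    q = src + rel * scale  # on the isocenter plane
    return np.array([q @ u, q @ v])


def bev_displacement_of_offset(geometry: BeamGeometry, offset_room_mm) -> np.ndarray:
    """First-order BEV displacement of a small rigid room-frame offset:
    the component of the offset perpendicular to the beam axis."""
    t = np.asarray(offset_room_mm, dtype=float)
    _, u, v, _ = geometry.axes()
    return np.array([t @ u, t @ v])
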