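"""Random aperture search and threshold-map aperture extraction.

For each beam's-eye view, rectangular MLC-style apertures are sampled at
random positions and sizes (0.375-37.5 cm^2), scored by how well an
MI registration recovers known grid shifts applied to the anatomy, and
the top 10% overlaid into a per-pixel topographic count map.  The imaging
aperture for a control point is the bounding rectangle of a superlevel
set of that map (e.g. the 60% threshold), optionally rescaled to a new
anatomy by the cube root of the skull volume ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .projection import BeamGeometry, DRRImage
from .registration import (
    aperture_pixel_window,
    preprocess,
    register_crop,
)

__all__ = [
    "Aperture",
    "ApertureStats",
    "TopographicMap",
    "ImagingPlan",
    "PlanEntry",
    "SearchConfig",
    "shift_grid",
    "sample_apertures",
    "ApertureEvaluator",
    "evaluate_aperture",
    "select_top",
    "build_topographic_map",
    "extract_threshold_aperture",
    "scale_aperture",
    "classify_aperture",
    "build_imaging_plan",
    "open_field_aperture",
]


@dataclass(frozen=True)
class Aperture:
    """Axis-aligned BEV rectangle at the isocenter plane (mm, relative to
    the principal point)."""

    cx_mm: float
    cy_mm: float
    width_mm: float
    height_mm: float

    def __post_init__(self):
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("aperture width and height must be positive")

    @property
    def area_cm2(self) -> float:
        return self.width_mm * self.height_mm / 100.0

    def scaled(self, s: float) -> "Aperture":
        return Aperture(
            self.cx_mm * s, self.cy_mm * s, self.width_mm * s, self.height_mm * s
        )


@dataclass
class ApertureStats:
    """Registration-error statistics of one aperture over a shift grid."""

    mean_error_mm: np.ndarray  # signed, per axis (dx, dy)
    sd_error_mm: float  # pooled SD of signed errors
    range_mm: float  # 95th - 5th percentile of |error| over the grid
    score_mm: float  # ranking scalar: mean(|error|) + SD
    area_cm2: float
    valid: bool = True


@dataclass
class TopographicMap:
    """Per-pixel count of covering top apertures, aligned to the DRR grid."""

    counts: np.ndarray
    pitch_mm: float
    principal_point: tuple[float, float]
    n_apertures: int


@dataclass
class PlanEntry:
    geometry: BeamGeometry
    aperture: Aperture
    threshold: str  # '50'..'90' or 'open'


@dataclass
class ImagingPlan:
    entries: list[PlanEntry]
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "entries": [
                {
                    "gantry_deg": e.geometry.gantry_deg,
                    "couch_deg": e.geometry.couch_deg,
                    "sad_mm": e.geometry.sad_mm,
                    "sid_mm": e.geometry.sid_mm,
                    "panel_pitch_mm": e.geometry.panel_pitch_mm,
                    "threshold": e.threshold,
                    "aperture": {
                        "cx_mm": round(e.aperture.cx_mm, 6),
                        "cy_mm": round(e.aperture.cy_mm, 6),
                        "w_mm": round(e.aperture.width_mm, 6),
                        "h_mm": round(e.aperture.height_mm, 6),
                    },
                }
                for e in self.entries
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ImagingPlan":
        payload = json.loads(text)
        entries = [
            PlanEntry(
                geometry=BeamGeometry(
                    gantry_deg=e["gantry_deg"],
                    couch_deg=e["couch_deg"],
                    sad_mm=e["sad_mm"],
                    sid_mm=e["sid_mm"],
                    panel_pitch_mm=e["panel_pitch_mm"],
                ),
                aperture=Aperture(
                    e["aperture"]["cx_mm"],
                    e["aperture"]["cy_mm"],
                    e["aperture"]["w_mm"],
                    e["aperture"]["h_mm"],
                ),
                threshold=e["threshold"],
            )
            for e in payload["entries"]
        ]
        return cls(entries=entries, provenance=payload.get("provenance", {}))


@dataclass
class SearchConfig:
    """Aperture-search knobs for one BEV."""

    n_apertures: int = 3000
    area_range_cm2: tuple[float, float] = (0.375, 37.5)
    aspect_range: tuple[float, float] = (1.0 / 3.0, 3.0)
    fraction: float = 0.10
    field_mm: float = 220.0  # open imaging field edge at the isocenter plane
    grid_half_width_mm: float = 2.0
    grid_n: int = 10  # grid_n x grid_n shift grid for scoring
    bound_mm: float = 3.0
    bins: int = 50
    seed: int = 0
    rank_refine: bool = False  # fast parabolic sub-pixel during ranking


def shift_grid(half_width_mm: float, n: int) -> np.ndarray:
    """(m, 2) grid of (dx, dy) shifts, excluding the exact zero shift."""
    axis = np.linspace(-half_width_mm, half_width_mm, n)
    g = np.array([(dx, dy) for dy in axis for dx in axis])
    return g[~np.all(np.isclose(g, 0.0), axis=1)]


def open_field_aperture(config_or_field=220.0) -> Aperture:
    f = (
        config_or_field.field_mm
        if isinstance(config_or_field, SearchConfig)
        else float(config_or_field)
    )
    return Aperture(0.0, 0.0, f, f)


def sample_apertures(
    n: int,
    drr: DRRImage,
    area_range_cm2: tuple[float, float] = (0.375, 37.5),
    seed: int = 0,
    field_mm: float = 220.0,
    aspect_range: tuple[float, float] = (1.0 / 3.0, 3.0),
) -> list[Aperture]:
    """Sample ``n`` rectangles: log-uniform area, uniform aspect ratio,
    center uniform over positions keeping the rectangle inside the open
    field.  Deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = area_range_cm2
    field = min(field_mm, (min(drr.shape) - 1) * drr.pitch_mm)
    if np.sqrt(hi * 100.0) > field:
        raise ValueError("area range infeasible for the field size")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        area_mm2 = 100.0 * np.exp(rng.uniform(np.log(lo), np.log(hi)))
        # restrict the aspect draw so both extents fit inside the field
        a_lo = max(aspect_range[0], area_mm2 / field**2)
        a_hi = min(aspect_range[1], field**2 / area_mm2)
        asp = rng.uniform(a_lo, a_hi)
        w = float(np.sqrt(area_mm2 * asp))
        h = float(np.sqrt(area_mm2 / asp))
        cx = float(rng.uniform(-(field - w) / 2.0, (field - w) / 2.0))
        cy = float(rng.uniform(-(field - h) / 2.0, (field - h) / 2.0))
        out.append(Aperture(cx, cy, w, h))
    return out


class ApertureEvaluator:
    """Scores apertures on one BEV against a fixed grid of applied shifts.

    The DRR is preprocessed once; each grid shift produces one spline-
    shifted copy of the whole preprocessed image, shared by every aperture
    (one fixed grid per BEV).  ``refine=False`` ranks with the fast
    integer+parabolic registration; ``refine=True`` runs the full
    continuous refinement.
    """

    def __init__(
        self,
        drr: DRRImage,
        grid_mm: np.ndarray,
        bound_mm: float = 3.0,
        bins: int = 50,
        refine: bool = False,
        max_samples: int = 2500,
    ):
        self.drr = drr
        self.grid_mm = np.asarray(grid_mm, dtype=float)
        self.bound_mm = bound_mm
        self.bins = bins
        self.refine = refine
        self.max_samples = max_samples
        self.fixed = preprocess(drr.pixels)
        self._fixed_pref = (
            ndimage.spline_filter(self.fixed, order=3) if refine else None
        )
        self.shifted = [
            ndimage.shift(
                self.fixed,
                (dy / drr.pitch_mm, dx / drr.pitch_mm),
                order=3,
                mode="nearest",
            )
            for dx, dy in self.grid_mm
        ]

    def evaluate(self, aperture: Aperture) -> ApertureStats:
        r0, r1, c0, c1 = aperture_pixel_window(self.drr, aperture)
        errors = []
        valid = True
        if (r1 - r0) < 4 or (c1 - c0) < 4:
            valid = False
        else:
            for (dx, dy), shifted in zip(self.grid_mm, self.shifted):
                res = register_crop(
                    self.fixed,
                    shifted[r0:r1, c0:c1],
                    (r0, c0),
                    self.drr.pitch_mm,
                    bound_mm=self.bound_mm,
                    bins=self.bins,
                    refine=self.refine,
                    max_samples=self.max_samples,
                    ref_prefiltered=self._fixed_pref,
                )
                if not res.converged:
                    valid = False
                    break
                errors.append(res.shift_mm - np.array([dx, dy]))
        if not valid:
            return ApertureStats(
                mean_error_mm=np.full(2, np.nan),
                sd_error_mm=np.inf,
                range_mm=np.inf,
                score_mm=np.inf,
                area_cm2=aperture.area_cm2,
                valid=False,
            )
        e = np.asarray(errors)
        abs_pooled = np.abs(e).ravel()
        signed_pooled = e.ravel()
        rng_mm = float(
            np.percentile(abs_pooled, 95) - np.percentile(abs_pooled, 5)
        )
        return ApertureStats(
            mean_error_mm=e.mean(axis=0),
            sd_error_mm=float(signed_pooled.std()),
            range_mm=rng_mm,
            score_mm=float(abs_pooled.mean() + signed_pooled.std()),
            area_cm2=aperture.area_cm2,
        )


def evaluate_aperture(
    drr: DRRImage,
    aperture: Aperture,
    grid_mm: np.ndarray,
    refine: bool = True,
    **kwargs,
) -> ApertureStats:
    """Score one aperture (convenience wrapper over ApertureEvaluator)."""
    return ApertureEvaluator(drr, grid_mm, refine=refine, **kwargs).evaluate(aperture)


def select_top(
    scored: list[tuple[Aperture, ApertureStats]], fraction: float = 0.10
) -> list[tuple[Aperture, ApertureStats]]:
    """The floor(n * fraction) lowest-score apertures; ties broken by
    smaller area, then sampling order."""
    if not scored:
        raise ValueError("no scored apertures")
    if all(not s.valid for _, s in scored):
        raise ValueError("all apertures invalid: nothing to select")
    k = max(1, int(np.floor(len(scored) * fraction)))
    order = sorted(
        range(len(scored)),
        key=lambda i: (scored[i][1].score_mm, scored[i][1].area_cm2, i),
    )
    return [scored[i] for i in order[:k]]


def build_topographic_map(
    selected: list[Aperture] | list[tuple[Aperture, ApertureStats]],
    drr: DRRImage,
) -> TopographicMap:
    """Overlay-and-sum of binary aperture masks on the DRR pixel grid."""
    if not selected:
        raise ValueError("selected apertures must be non-empty")
    apertures = [a[0] if isinstance(a, tuple) else a for a in selected]
    counts = np.zeros(drr.shape, dtype=np.int32)
    for ap in apertures:
        r0, r1, c0, c1 = aperture_pixel_window(drr, ap)
        counts[r0:r1, c0:c1] += 1
    return TopographicMap(
        counts=counts,
        pitch_mm=drr.pitch_mm,
        principal_point=drr.principal_point,
        n_apertures=len(apertures),
    )


def extract_threshold_aperture(tmap: TopographicMap, level_pct: float) -> Aperture:
    """Bounding rectangle (BEV mm) of the largest connected component of
    pixels with count >= level% of the map maximum."""
    if not (0 < level_pct <= 100):
        raise ValueError("threshold level must be in (0, 100]")
    mx = tmap.counts.max()
    if mx <= 0:
        raise ValueError("topographic map has no coverage")
    mask = tmap.counts >= (level_pct / 100.0) * mx
    if not mask.any():
        raise ValueError("empty superlevel set at this threshold")
    labels = measure.label(mask)
    regions = measure.regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = best.bbox
    cy0, cx0 = tmap.principal_point
    x0 = (c0 - cx0) * tmap.pitch_mm
    x1 = (c1 - 1 - cx0) * tmap.pitch_mm
    y0 = (r0 - cy0) * tmap.pitch_mm
    y1 = (r1 - 1 - cy0) * tmap.pitch_mm
    return Aperture(
        (x0 + x1) / 2.0,
        (y0 + y1) / 2.0,
        max(x1 - x0, tmap.pitch_mm),
        max(y1 - y0, tmap.pitch_mm),
    )


def scale_aperture(
    aperture: Aperture, reference_volume_cm3: float, target_volume_cm3: float
) -> Aperture:
    """Cube-root volumetric scaling of size and position to a new anatomy."""
    if reference_volume_cm3 <= 0 or target_volume_cm3 <= 0:
        raise ValueError("volumes must be positive")
    s = (target_volume_cm3 / reference_volume_cm3) ** (1.0 / 3.0)
    return aperture.scaled(s)


def classify_aperture(
    stats: ApertureStats,
    good_range_mm: float = 0.1,
    good_mean_mm: float = 0.1,
    bad_range_mm: float = 1.0,
    min_area_cm2: float = 4.0,
) -> str:
    """'good' | 'bad' | 'neither' per the error-range / mean-error rules;
    apertures below the minimum area are never labeled."""
    if stats.area_cm2 < min_area_cm2:
        return "neither"
    if not stats.valid:
        return "bad"  # unregistrable content: unbounded errors
    if stats.range_mm < good_range_mm and np.all(
        np.abs(stats.mean_error_mm) < good_mean_mm
    ):
        return "good"
    if stats.range_mm > bad_range_mm:
        return "bad"
    return "neither"


def build_imaging_plan(
    control_points: list[BeamGeometry],
    volume,
    threshold: str,
    config: SearchConfig,
    detector_px: tuple[int, int] = (512, 512),
    mu_water: float | None = None,
    progress=None,
) -> ImagingPlan:
    """Full per-control-point pipeline: DRR -> sample -> score -> top 10%
    -> topographic map -> threshold aperture.  ``threshold`` is a level
    ('50'...'90') or 'open'.  A control point whose search produces no
    valid aperture falls back to the open field (logged in provenance)."""
    from . import projection

    mu = projection.DEFAULT_MU_WATER if mu_water is None else mu_water
    entries: list[PlanEntry] = []
    fallbacks = []
    grid = shift_grid(config.grid_half_width_mm, config.grid_n)
    for i, geo in enumerate(control_points):
        drr = projection.compute_drr(volume, geo, detector_px, mu_water=mu)
        if threshold == "open":
            ap = open_field_aperture(min(config.field_mm, (min(drr.shape) - 1) * drr.pitch_mm))
            entries.append(PlanEntry(geo, ap, "open"))
        else:
            apertures = sample_apertures(
                config.n_apertures,
                drr,
                config.area_range_cm2,
                seed=config.seed + i,
                field_mm=config.field_mm,
                aspect_range=config.aspect_range,
            )
            ev = ApertureEvaluator(
                drr,
                grid,
                bound_mm=config.bound_mm,
                bins=config.bins,
                refine=config.rank_refine,
            )
            scored = [(a, ev.evaluate(a)) for a in apertures]
            try:
                top = select_top(scored, config.fraction)
                tmap = build_topographic_map(top, drr)
                ap = extract_threshold_aperture(tmap, float(threshold))
                entries.append(PlanEntry(geo, ap, threshold))
            except ValueError:
                fallbacks.append(i)
                ap = open_field_aperture(
                    min(config.field_mm, (min(drr.shape) - 1) * drr.pitch_mm)
                )
                entries.append(PlanEntry(geo, ap, "open"))
        if progress is not None:
            progress(i, len(control_points))
    return ImagingPlan(
        entries=entries,
        provenance={
            "seed": config.seed,
            "n_apertures": config.n_apertures,
            "fraction": config.fraction,
            "threshold": threshold,
            "grid_half_width_mm": config.grid_half_width_mm,
            "grid_n": config.grid_n,
            "open_field_fallbacks": fallbacks,
        },
    )
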