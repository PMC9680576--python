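"""Aperture information metrics.

Two scalar features characterize what an aperture sees: (1) the variance
of a magnitude-weighted gradient-direction polar histogram (8 bins of 45
degrees), normalized by the total weight -- low when edge orientations
are spread over many directions, high (or infinite, for featureless
crops) when gradients are unidirectional or absent; and (2) the mean MI
drop-off of the shift surface with respect to its central element --
large when misalignment in any direction destroys mutual information,
i.e. when the aperture can localize shifts in every direction.
Good apertures cluster at low normalized polar variance and high MI mean
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apertures import (
    ApertureEvaluator,
    classify_aperture,
    sample_apertures,
    shift_grid,
)
from .registration import MISurface, aperture_pixel_window, mi_shift_surface

__all__ = [
    "PolarHistogram",
    "ApertureFeatures",
    "gradient_polar_histogram",
    "polar_variance",
    "mi_mean_difference",
    "feature_scatter",
    "plot_feature_scatter",
]


@dataclass
class PolarHistogram:
    """Eight 45-degree direction bins of gradient magnitude weight."""

    counts: np.ndarray  # (8,)
    total_weight: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float).reshape(8)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")


@dataclass
class ApertureFeatures:
    gantry_deg: float
    couch_deg: float
    area_cm2: float
    polar_var_norm: float
    mi_mean_diff: float
    label: str


def gradient_polar_histogram(image: np.ndarray, aperture=None, drr=None) -> PolarHistogram:
    """Magnitude-weighted polar histogram of central-difference gradient
    directions inside an aperture crop (bin 0 = [0, 45) degrees).

    ``image`` may be the crop itself, or a full DRR pixel array combined
    with ``aperture`` and ``drr`` for windowing.
    """
    img = np.asarray(image, dtype=float)
    if aperture is not None:
        if drr is None:
            raise ValueError("windowing by aperture requires the DRR")
        r0, r1, c0, c1 = aperture_pixel_window(drr, aperture)
        img = img[r0:r1, c0:c1]
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError("aperture crop must be at least 8x8 pixels")
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.degrees(np.arctan2(gy, gx)), 360.0)
    bins = np.minimum((ang // 45.0).astype(int), 7)
    nz = mag > 0
    counts = np.bincount(bins[nz].ravel(), weights=mag[nz].ravel(), minlength=8)
    return PolarHistogram(counts=counts, total_weight=float(mag[nz].sum()))


def polar_variance(hist: PolarHistogram) -> float:
    """Population variance of the 8 bin weights normalized by their sum;
    +inf for an all-zero histogram (no directional information)."""
    s = hist.counts.sum()
    if s <= 0:
        return float("inf")
    return float(np.var(hist.counts) / s)


def mi_mean_difference(surface: MISurface) -> float:
    """Mean of (central MI - element MI) over all non-central grid
    elements; invariant to adding a constant to the surface."""
    v = surface.values
    n = v.shape[0] // 2
    mask = np.ones_like(v, dtype=bool)
    mask[n, n] = False
    return float(np.mean(v[n, n] - v[mask]))


def feature_scatter(
    drrs,
    n_good: int = 30,
    n_bad: int = 30,
    budget: int = 200,
    seed: int = 0,
    area_range_cm2: tuple[float, float] = (4.0, 36.0),
    grid_half_width_mm: float = 2.0,
    grid_n: int = 4,
    bound_mm: float = 3.0,
    surface_step_mm: float = 0.4,
) -> pd.DataFrame:
    """Good/bad aperture feature table across a set of BEVs.

    Per BEV, random apertures (>= 4 cm^2) are scored with the refined
    registration and classified until the good/bad quotas are met or the
    sampling budget is exhausted (a shortfall yields a partial table).
    Deterministic per seed.
    """
    grid = shift_grid(grid_half_width_mm, grid_n)
    rows = []
    for k, drr in enumerate(drrs):
        ev = ApertureEvaluator(
            drr, grid, bound_mm=bound_mm, refine=True, max_samples=6000
        )
        pool = sample_apertures(
            budget,
            drr,
            area_range_cm2,
            seed=seed + 1000 * k,
            field_mm=min(220.0, (min(drr.shape) - 1) * drr.pitch_mm),
        )
        got = {"good": 0, "bad": 0}
        for ap in pool:
            if got["good"] >= n_good and got["bad"] >= n_bad:
                break
            stats = ev.evaluate(ap)
            label = classify_aperture(stats)
            if label == "neither":
                continue
            if got[label] >= (n_good if label == "good" else n_bad):
                continue
            got[label] += 1
            try:
                surf = mi_shift_surface(
                    drr, ap, half_width_mm=grid_half_width_mm, step_mm=surface_step_mm
                )
                mi_diff = mi_mean_difference(surf)
            except ValueError:
                mi_diff = np.nan
            hist = gradient_polar_histogram(ev.fixed, ap, drr)
            rows.append(
                {
                    "gantry": drr.geometry.gantry_deg,
                    "couch": drr.geometry.couch_deg,
                    "area_cm2": ap.area_cm2,
                    "polar_var_norm": polar_variance(hist),
                    "polar_total_weight": hist.total_weight,
                    "mi_mean_diff": mi_diff,
                    "label": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gantry",
            "couch",
            "area_cm2",
            "polar_var_norm",
            "polar_total_weight",
            "mi_mean_diff",
            "label",
        ],
    )


def plot_feature_scatter(table: pd.DataFrame, path=None):
    """Scatter of normalized polar variance vs MI mean difference, marker
    size proportional to aperture area, good/bad color-coded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, color in (("good", "k"), ("bad", "r")):
        sub = table[table["label"] == label]
        ax.scatter(
            sub["mi_mean_diff"],
            sub["polar_var_norm"].clip(upper=10),
            s=10 + 3 * sub["area_cm2"],
            facecolors="none",
            edgecolors=color,
            label=label,
        )
    ax.set_xlabel("MI mean difference (nats)")
    ax.set_ylabel("normalized polar variance")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
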