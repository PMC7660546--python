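"""Erythrocyte morphology from cell images.

Segmentation follows the classic stained-smear recipe: Gaussian blur,
rolling-ball background subtraction, contrast normalisation, minimum-
method histogram thresholding, then morphological clean-up. Particles
are measured for area, perimeter, circularity C = 4*pi*A/P^2 and
solidity; a filter chain (area window, minimum circularity, minimum
solidity) removes debris, clumps and cut cells before the two-group
circularity comparison.

The perimeter uses the Crofton multi-direction estimator: naive
pixel-edge counting overestimates the perimeter of rasterised smooth
shapes and would bias C well below 1 even for circles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import filters, measure, morphology, restoration


class ShapeError(ValueError):
    pass


def segment_mask(
    image: np.ndarray,
    blur_sigma: float = 1.0,
    rolling_radius: float = 7.0,
    threshold_method: str = "minimum",
    saturated: float = 0.1,
    binary_passthrough: bool = True,
) -> np.ndarray:
    """Segment dark cells on a light background into a binary mask.

    A boolean input is returned unchanged when ``binary_passthrough``
    (the image is already a mask). Otherwise: invert, Gaussian blur,
    rolling-ball background subtraction, percentile contrast stretch
    (``saturated`` percent clipped), minimum-method threshold, binary
    opening/closing and hole filling.
    """
    if image.ndim != 2:
        raise ShapeError("expected a 2-D single-channel image")
    if image.dtype == bool:
        if binary_passthrough:
            return image.copy()
        raise ShapeError("binary input but passthrough disabled")
    img = image.astype(float)
    img = img.max() - img  # bright objects for background subtraction
    if blur_sigma > 0:
        img = filters.gaussian(img, sigma=blur_sigma, preserve_range=True)
    if rolling_radius > 0:
        img = img - restoration.rolling_ball(img, radius=rolling_radius)
    lo, hi = np.percentile(img, [saturated / 2, 100 - saturated / 2])
    if hi <= lo:
        raise ShapeError(
            "flat image after background subtraction; set a manual threshold"
        )
    img = np.clip((img - lo) / (hi - lo), 0, 1)
    if threshold_method != "minimum":
        raise ShapeError(f"unsupported threshold method {threshold_method!r}")
    try:
        thr = filters.threshold_minimum(img)
    except RuntimeError as err:  # unimodal histogram: no valley
        raise ShapeError(
            "minimum-method threshold found no histogram valley; "
            "set a manual threshold"
        ) from err
    mask = img > thr
    footprint = morphology.disk(1)
    mask = morphology.opening(mask, footprint)
    mask = morphology.closing(mask, footprint)
    mask = ndi.binary_fill_holes(mask)
    return mask


def measure_particles(mask: np.ndarray, pixel_size: float) -> pd.DataFrame:
    """Per-particle area, perimeter, circularity and solidity.

    Connected components use 8-connectivity; particles touching the
    image border are dropped. Area is in um^2, perimeter in um
    (Crofton 4-direction estimator), circularity and solidity unitless.
    """
    if pixel_size <= 0:
        raise ShapeError("pixel_size must be positive")
    if mask.dtype != bool:
        mask = mask.astype(bool)
    labels = measure.label(mask, connectivity=2)
    rows = []
    h, w = mask.shape
    for rp in measure.regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        if touches:
            continue
        area = rp.area * pixel_size**2
        perim = rp.perimeter_crofton * pixel_size
        if perim <= 0:
            continue
        circ = 4 * np.pi * area / perim**2
        rows.append(
            {
                "particle_id": rp.label,
                "area": area,
                "perimeter": perim,
                "circularity": circ,
                "solidity": rp.solidity,
            }
        )
    return pd.DataFrame(
        rows, columns=["particle_id", "area", "perimeter", "circularity", "solidity"]
    )


def measure_labeled(
    label_image: np.ndarray,
    pixel_size: float,
    class_of: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Like :func:`measure_particles` but on a pre-labelled image, with an
    optional particle-id -> class map joined in (handy for ground truth)."""
    if pixel_size <= 0:
        raise ShapeError("pixel_size must be positive")
    rows = []
    h, w = label_image.shape
    for rp in measure.regionprops(label_image):
        minr, minc, maxr, maxc = rp.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            continue
        area = rp.area * pixel_size**2
        perim = rp.perimeter_crofton * pixel_size
        if perim <= 0:
            continue
        rows.append(
            {
                "particle_id": rp.label,
                "area": area,
                "perimeter": perim,
                "circularity": 4 * np.pi * area / perim**2,
                "solidity": rp.solidity,
                "cell_class": (class_of or {}).get(rp.label),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["particle_id", "area", "perimeter", "circularity", "solidity", "cell_class"],
    )


def filter_particles(
    measurements: pd.DataFrame,
    area_range: tuple[float, float] = (70.0, 150.0),
    min_circularity: float = 0.80,
    min_solidity: float = 0.93,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the particle filter chain.

    A particle is retained iff its area lies in ``area_range`` (um^2,
    inclusive) and circularity and solidity reach their minima. Returns
    the table with a ``retained`` column plus per-rule removal counts
    (a particle can fail several rules at once).
    """
    lo, hi = area_range
    if not lo < hi:
        raise ShapeError("area_range must satisfy min < max")
    df = measurements.copy()
    bad_area = (df["area"] < lo) | (df["area"] > hi)
    bad_circ = df["circularity"] < min_circularity
    bad_sol = df["solidity"] < min_solidity
    df["retained"] = ~(bad_area | bad_circ | bad_sol)
    removed = {
        "area": int(bad_area.sum()),
        "circularity": int(bad_circ.sum()),
        "solidity": int(bad_sol.sum()),
    }
    return df, removed


def compare_circularity(group_a, group_b) -> dict:
    """Two-sample rank test (Mann-Whitney U) on circularity.

    Accepts arrays of circularity values or measurement tables (their
    ``circularity`` column, retained rows only if a ``retained`` column
    is present). Returns statistic, two-sided p and per-group n.
    """

    def vals(g):
        if isinstance(g, pd.DataFrame):
            if "retained" in g.columns:
                g = g[g["retained"]]
            return g["circularity"].to_numpy(dtype=float)
        return np.asarray(g, dtype=float)

    a, b = vals(group_a), vals(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ShapeError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    if u == len(a) * len(b) / 2:  # no rank separation at all
        p = 1.0
    return {"statistic": float(u), "p": float(p), "n_a": len(a), "n_b": len(b)}
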