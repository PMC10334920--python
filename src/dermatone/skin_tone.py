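"""Individual typology angle (ITA) skin-tone categorization.

Skin tone is quantified in CIELAB space by the individual typology angle

    ITA = atan((L* - 50) / b*) * 180 / pi   [degrees]

computed from aggregated skin pixels and mapped to one of six categories
(very light ... dark) by a configurable range table. Lighter skin has high
L* (lightness) and moderate b* (yellow-blue chroma), giving large positive
angles; dark skin falls below -30 degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import color as _color

#: Six-class convention (Del Bino): upper-inclusive, half-open intervals.
#: Each entry is (lower_exclusive, upper_inclusive) in degrees.
DEFAULT_ITA_RANGES: dict[str, tuple[float, float]] = {
    "very_light": (55.0, 90.0),
    "light": (41.0, 55.0),
    "intermediate": (28.0, 41.0),
    "tan": (10.0, 28.0),
    "brown": (-30.0, 10.0),
    "dark": (-90.0, -30.0),
}

CATEGORIES = tuple(DEFAULT_ITA_RANGES)


@dataclass(frozen=True)
class SkinToneRecord:
    """Per-image tone summary: CIELAB aggregates, ITA and category."""

    image_id: str
    L_star: float
    b_star: float
    ita_degrees: float
    category: str


def load_ranges(path) -> dict[str, tuple[float, float]]:
    """Read an ITA range table from a JSON file ({category: [low, high]})."""
    with open(path) as fh:
        raw = json.load(fh)
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an sRGB image in [0, 1] to CIELAB (D65, 2 deg observer).

    Parameters
    ----------
    image : (H, W, 3) float array
        sRGB intensities in [0, 1].

    Returns
    -------
    (H, W, 3) array of (L*, a*, b*).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("RGB values must lie in [0, 1]")
    return _color.rgb2lab(image)


def ita_from_lab(L_star: float, b_star: float) -> float:
    """ITA in degrees from a single (L*, b*) pair.

    b* = 0 maps to +/-90 deg by the sign of (L* - 50); (50, 0) maps to 0.
    """
    if b_star == 0.0:
        if L_star == 50.0:
            return 0.0
        return math.copysign(90.0, L_star - 50.0)
    return math.degrees(math.atan2(L_star - 50.0, b_star))


def compute_ita(lab_pixels: np.ndarray, skin_mask: np.ndarray | None = None) -> float:
    """Aggregate ITA over skin pixels: one angle from median L* and median b*.

    Parameters
    ----------
    lab_pixels : (..., 3) array
        CIELAB pixels (any leading shape).
    skin_mask : boolean array, optional
        Restricts the aggregation to skin pixels (e.g. excluding the lesion).
        Whole-image aggregation is used when omitted.
    """
    lab = np.asarray(lab_pixels, dtype=float).reshape(-1, 3)
    if skin_mask is not None:
        mask = np.asarray(skin_mask, dtype=bool).reshape(-1)
        if mask.shape[0] != lab.shape[0]:
            raise ValueError("mask size does not match pixel count")
        lab = lab[mask]
    if lab.shape[0] == 0:
        raise ValueError("no skin pixels to aggregate (empty mask)")
    L_med = float(np.median(lab[:, 0]))
    b_med = float(np.median(lab[:, 2]))
    return ita_from_lab(L_med, b_med)


def classify_skin_tone(
    ita_degrees: float,
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_ITA_RANGES,
) -> str:
    """Map an ITA angle to its tone category.

    Intervals are half-open and upper-inclusive: 28 deg is ``tan``,
    28 + eps is ``intermediate``. The top category includes its upper bound.
    """
    if not -90.0 <= ita_degrees <= 90.0:
        raise ValueError(f"ITA must be in [-90, 90], got {ita_degrees}")
    for cat, (lo, hi) in ranges.items():
        if lo < ita_degrees <= hi:
            return cat
    # bottom of the lowest interval (-90 exactly)
    bottom = min(ranges, key=lambda k: ranges[k][0])
    if ita_degrees == ranges[bottom][0]:
        return bottom
    raise ValueError(f"ITA {ita_degrees} not covered by the range table")


def tone_record(
    image_id: str,
    image: np.ndarray,
    skin_mask: np.ndarray | None = None,
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_ITA_RANGES,
) -> SkinToneRecord:
    """Full per-image pipeline: sRGB -> Lab -> aggregate ITA -> category."""
    lab = rgb_to_lab(image)
    flat = lab.reshape(-1, 3)
    mask = None if skin_mask is None else np.asarray(skin_mask, bool).reshape(-1)
    sel = flat if mask is None else flat[mask]
    if sel.shape[0] == 0:
        raise ValueError("empty skin mask")
    L_med = float(np.median(sel[:, 0]))
    b_med = float(np.median(sel[:, 2]))
    ita = ita_from_lab(L_med, b_med)
    return SkinToneRecord(image_id, L_med, b_med, ita, classify_skin_tone(ita, ranges))


def tone_distribution(categories: Sequence[str]) -> pd.DataFrame:
    """Counts and one-decimal percentages per tone category.

    Parameters
    ----------
    categories : sequence of category strings, one per image (no missing).

    Returns
    -------
    DataFrame indexed by category with columns ``count`` and ``percent``
    (percent rounded to one decimal, counts summing to the input size).
    """
    cats = list(categories)
    if len(cats) == 0:
        raise ValueError("no images to summarize")
    for c in cats:
        if c is None or (isinstance(c, float) and np.isnan(c)):
            raise ValueError("uncategorized image in manifest")
    counts = pd.Series(cats).value_counts()
    order = [c for c in CATEGORIES if c in counts.index]
    order += [c for c in counts.index if c not in order]
    counts = counts.reindex(order)
    pct = (100.0 * counts / len(cats)).round(1)
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})
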