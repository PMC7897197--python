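"""Regional T1 statistics and the simulated two-rater measurement design.

The study design measures each structure in the left and right hemisphere
(the intra-rater repeat) and by two independent observers (the inter-rater
repeat).  Here the "largest possible ROI" is the entire labeled region;
observer variability is injected by perturbing the label map (erosion plus
a small random translation per region), which emulates independently drawn
ROIs of slightly different extent and position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import RegionSpec
from .fitting import T1Map

__all__ = [
    "RoiMeasurement",
    "extract_roi_stats",
    "simulate_rater",
    "pool_measurements",
    "measurements_to_frame",
]

log = logging.getLogger(__name__)

#: Column index separating the left from the right hemisphere on the grid.
MIDLINE_COL = 110


@dataclass(frozen=True)
class RoiMeasurement:
    """Mean/SD of converged T1 over one region, side and rater."""

    subject_id: str
    region: str
    side: str  # left | right | na
    rater: str  # r1 | r2
    mean_t1_ms: float
    sd_t1_ms: float
    n_pixels: int


def _side_masks(label_mask: np.ndarray, region: RegionSpec) -> dict[str, np.ndarray]:
    sides = {e.side for e in region.ellipses}
    if sides == {"na"}:
        return {"na": label_mask}
    cols = np.arange(label_mask.shape[1])[None, :]
    out = {}
    if "left" in sides:
        out["left"] = label_mask & (cols < MIDLINE_COL)
    if "right" in sides:
        out["right"] = label_mask & (cols >= MIDLINE_COL)
    return out


def extract_roi_stats(
    t1_map: T1Map | np.ndarray,
    label_map: np.ndarray,
    regions: tuple[RegionSpec, ...],
    subject_id: str,
    rater: str = "r1",
    sides: str = "all",
) -> list[RoiMeasurement]:
    """Per-region mean and SD of T1 over converged labeled pixels.

    ``t1_map`` may be a fitted :class:`T1Map` (its converged mask is
    honored) or a plain T1 image such as the ground-truth map.  Regions or
    sides with no converged pixel are omitted with a logged warning.
    ``sides`` restricts extraction to ``"left"``/``"right"``/``"na"`` or
    keeps every available side (``"all"``).
    """
    if isinstance(t1_map, T1Map):
        values, ok = t1_map.values, t1_map.mask
    else:
        values = np.asarray(t1_map, dtype=float)
        ok = np.isfinite(values) & (values > 0)
    if values.shape != label_map.shape:
        raise ValueError("T1 map and label map shapes differ")
    out: list[RoiMeasurement] = []
    for region in regions:
        region_mask = label_map == region.label
        for side, mask in _side_masks(region_mask, region).items():
            if sides != "all" and side != sides:
                continue
            sel = mask & ok
            n = int(sel.sum())
            if n == 0:
                log.warning(
                    "region %s side %s: no converged pixels, omitted",
                    region.name, side,
                )
                continue
            vals = values[sel]
            out.append(
                RoiMeasurement(
                    subject_id=subject_id, region=region.name, side=side,
                    rater=rater, mean_t1_ms=float(vals.mean()),
                    sd_t1_ms=float(vals.std(ddof=1)) if n > 1 else 0.0,
                    n_pixels=n,
                )
            )
    return out


def simulate_rater(
    label_map: np.ndarray,
    jitter_px: int = 1,
    erosion_px: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Perturbed label map emulating an independently drawn set of ROIs.

    Each region mask is eroded ``erosion_px`` times (4-connected structuring
    element) and translated by a random integer offset with components in
    [-jitter_px, jitter_px], clipped so the mask stays inside the image.
    Deterministic for a seeded ``rng``.  A region that vanishes after
    erosion is a configuration error.
    """
    if jitter_px < 0 or erosion_px < 0:
        raise ValueError("jitter_px and erosion_px must be >= 0")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = np.zeros_like(label_map)
    for label in np.unique(label_map):
        if label == 0:
            continue
        mask = label_map == label
        if erosion_px:
            mask = ndimage.binary_erosion(mask, iterations=erosion_px)
        if not mask.any():
            raise ValueError(f"label {label} vanished after erosion")
        dr, dc = (
            (0, 0) if jitter_px == 0
            else tuple(gen.integers(-jitter_px, jitter_px + 1, size=2))
        )
        rows, cols = np.nonzero(mask)
        dr = int(np.clip(dr, -rows.min(), label_map.shape[0] - 1 - rows.max()))
        dc = int(np.clip(dc, -cols.min(), label_map.shape[1] - 1 - cols.max()))
        out[rows + dr, cols + dc] = label
    return out


def measurements_to_frame(measurements: list[RoiMeasurement]) -> pd.DataFrame:
    """Measurements as a tidy DataFrame with the RoiMeasurement columns."""
    return pd.DataFrame([m.__dict__ for m in measurements])


def pool_measurements(
    measurements: pd.DataFrame,
    ages: pd.DataFrame,
    age_min: float = 5.0,
    age_max: float = 18.0,
) -> pd.Series:
    """Per-region pooled mean T1 over subjects aged [age_min, age_max].

    Averaging is hierarchical — sides within rater, raters within subject,
    then the arithmetic mean across subjects — so the result is invariant
    to how a subject's records are split across sides and raters.
    ``ages`` joins on ``subject_id`` and must carry ``age_years``.
    """
    df = measurements.merge(
        ages[["subject_id", "age_years"]].drop_duplicates(), on="subject_id"
    )
    df = df[(df.age_years >= age_min) & (df.age_years <= age_max)]
    if df.empty:
        raise ValueError("no subjects in the requested age window")
    per_rater = df.groupby(
        ["region", "subject_id", "rater"], as_index=False
    ).mean_t1_ms.mean()
    per_subject = per_rater.groupby(
        ["region", "subject_id"], as_index=False
    ).mean_t1_ms.mean()
    return per_subject.groupby("region").mean_t1_ms.mean()
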