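"""Scalar assay metrics: tumour volume, lung burden, gel contraction,
cell roundness and Grubbs outlier screening.

These are the bookkeeping quantities of a syngeneic metastasis study:

* tumour volume from calliper width/length, ``0.5236 * ((w + l)/2)**3`` mm³;
* percentage lung tumour burden, ``100 * tumour area / lung area``, from a
  pair of binary section masks, plus nodule counting with a minimum-area
  rule (default 1000 µm² per nodule);
* percentage gel contraction from before/after gel-area masks;
* cell roundness as the isoperimetric quotient ``4*pi*A / P**2`` (1 for a
  perfect disc), a surrogate for proprietary high-content "roundness"
  readouts;
* the two-sided single-outlier Grubbs test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton, regionprops

from .errors import ParameterError

__all__ = [
    "TumourMeasurement",
    "SectionMasks",
    "BurdenReport",
    "OutlierReport",
    "tumour_volume",
    "quantify_burden",
    "gel_contraction",
    "cell_roundness",
    "grubbs_outliers",
]

#: ellipsoid prefactor of the calliper volume formula (≈ π/6)
VOLUME_CONSTANT = 0.5236


@dataclass(frozen=True)
class TumourMeasurement:
    """Calliper width and length of a tumour, in mm."""

    width_mm: float
    length_mm: float

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.length_mm <= 0:
            raise ParameterError("width_mm and length_mm must be positive")


@dataclass(frozen=True)
class SectionMasks:
    """Binary lung and tumour masks of one coronal section.

    Tumour pixels outside the lung are clipped to the lung (the violation
    count is kept in ``n_clipped_px``).
    """

    lung_mask: np.ndarray
    tumour_mask: np.ndarray
    pixel_size_um: float
    n_clipped_px: int = 0

    def __post_init__(self) -> None:
        lung = np.asarray(self.lung_mask, dtype=bool)
        tumour = np.asarray(self.tumour_mask, dtype=bool)
        if lung.shape != tumour.shape:
            raise ParameterError("lung and tumour masks must share a shape")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        clipped = int((tumour & ~lung).sum())
        object.__setattr__(self, "lung_mask", lung)
        object.__setattr__(self, "tumour_mask", tumour & lung)
        object.__setattr__(self, "n_clipped_px", clipped)


@dataclass(frozen=True)
class BurdenReport:
    pct_tumour_area: float
    nodule_count: int
    nodule_areas_um2: tuple[float, ...]
    min_area_um2: float

    def __post_init__(self) -> None:
        if self.nodule_count != len(self.nodule_areas_um2):
            raise ParameterError("nodule_count must match nodule_areas_um2")


@dataclass(frozen=True)
class OutlierReport:
    g_statistic: float
    g_critical: float
    alpha: float
    outlier_index: Optional[int]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def tumour_volume(m: TumourMeasurement) -> float:
    """Calliper tumour volume in mm³: 0.5236 × ((width + length)/2)³."""
    mean_diam = (m.width_mm + m.length_mm) / 2.0
    return VOLUME_CONSTANT * mean_diam**3


def quantify_burden(
    masks: SectionMasks,
    min_area_um2: float = 1000.0,
    include_subthreshold_in_pct: bool = True,
) -> BurdenReport:
    """Percentage tumour burden and filtered nodule count of a section.

    Burden is ``100 × tumour pixels / lung pixels``.  Nodules are
    8-connected components of the tumour mask; only components of at least
    ``min_area_um2`` enter the nodule count.  By default sub-threshold
    components still contribute to the percentage area (the two metrics are
    defined independently); set ``include_subthreshold_in_pct=False`` to
    drop them from the area as well.
    """
    if min_area_um2 <= 0:
        raise ParameterError("min_area_um2 must be positive")
    lung_px = int(masks.lung_mask.sum())
    if lung_px == 0:
        raise ParameterError("invalid section: empty lung mask")
    px_area = masks.pixel_size_um**2

    labels = cc_label(masks.tumour_mask, connectivity=2)
    areas = np.array(
        [r.area * px_area for r in regionprops(labels)], dtype=float
    )
    kept = np.sort(areas[areas >= min_area_um2])

    if include_subthreshold_in_pct:
        tumour_px = int(masks.tumour_mask.sum())
    else:
        tumour_px = int(round(kept.sum() / px_area))
    return BurdenReport(
        pct_tumour_area=100.0 * tumour_px / lung_px,
        nodule_count=len(kept),
        nodule_areas_um2=tuple(float(a) for a in kept),
        min_area_um2=min_area_um2,
    )


def gel_contraction(initial_mask: np.ndarray, final_mask: np.ndarray) -> float:
    """Percentage contraction of a gel: 100 × (1 − final area / initial area).

    Negative values (gel expansion) are reported as-is, not clamped.
    """
    a0 = int(np.asarray(initial_mask, dtype=bool).sum())
    a1 = int(np.asarray(final_mask, dtype=bool).sum())
    if a0 == 0:
        raise ParameterError("empty initial gel mask")
    return 100.0 * (1.0 - a1 / a0)


def cell_roundness(mask: np.ndarray) -> float:
    """Isoperimetric roundness 4πA/P² of a single-component mask, in [0, 1].

    The perimeter is the Crofton estimate of the boundary length, which is
    asymptotically unbiased for smooth shapes (a naive staircase count would
    systematically deflate the score).  1 is a perfect disc; thin elongated
    shapes approach 0.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ParameterError("empty cell mask")
    n_comp = cc_label(m, connectivity=2).max()
    if n_comp != 1:
        raise ParameterError(f"cell mask must be a single component, got {n_comp}")
    area = float(m.sum())
    perim = float(perimeter_crofton(m, directions=4))
    if perim == 0:
        return 1.0
    return float(np.clip(4.0 * math.pi * area / perim**2, 0.0, 1.0))


def grubbs_outliers(values: Sequence[float], alpha: float = 0.05) -> OutlierReport:
    """Two-sided single-outlier Grubbs test.

    G = max_i |x_i − mean| / sd (sd with n−1 denominator);
    G_crit = ((n−1)/√n) · √(t² / (n−2+t²)) with t the upper α/(2n) quantile
    of Student's t on n−2 degrees of freedom.  At most one point — the most
    extreme — is flagged per call, mirroring the once-per-dataset screen of
    common statistics packages.  G is invariant to affine rescaling of the
    data.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ParameterError("Grubbs test needs at least 3 values")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ParameterError("Grubbs test undefined for zero-variance sample")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = float((n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t)))
    return OutlierReport(
        g_statistic=g,
        g_critical=g_crit,
        alpha=alpha,
        outlier_index=idx if g > g_crit else None,
    )
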