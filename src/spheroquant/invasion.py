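"""Spheroid invasion quantification.

Workflow: maximum-intensity projection of a confocal z-stack of DAPI-stained
nuclei, intensity-threshold binarisation, identification of the spheroid
body, marker-based watershed separation of invading nuclei, centroid
extraction, and the mean-square-displacement (MSD) invasion score

    MSD = (1/N) * sum_k d_k**2        [µm²]

where ``d_k`` is the Euclidean distance from invading cell *k* to the
spheroid centroid and ``N`` the number of invading cells.  This MSD is a
snapshot score over cells, not the time-lagged MSD of diffusion analysis.

Coordinate convention: images are indexed ``(row, col)`` with the origin at
the top-left pixel; physical positions are reported as ``(x, y)`` in µm with
``x = (col + 0.5) * pixel_size`` and ``y = (row + 0.5) * pixel_size``
(pixel-centre convention).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .errors import ParameterError, SegmentationError, ThresholdError

__all__ = [
    "PixelImage",
    "ZStack",
    "SegmentationParams",
    "SpheroidSegmentation",
    "InvasionResult",
    "max_project",
    "segment_invasion",
    "compute_msd",
    "invasion_timecourse",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelImage:
    """A single calibrated grayscale image plane.

    Parameters
    ----------
    intensities
        2-D array of non-negative pixel intensities.
    pixel_size_um
        Physical size of one pixel edge in µm (isotropic).
    """

    intensities: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2 or arr.size == 0:
            raise ParameterError("intensities must be a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class ZStack:
    """An ordered stack of identically calibrated image planes."""

    planes: tuple[PixelImage, ...]

    def __post_init__(self) -> None:
        planes = tuple(self.planes)
        if not planes:
            raise ParameterError("a z-stack needs at least one plane")
        shape = planes[0].shape
        px = planes[0].pixel_size_um
        for p in planes[1:]:
            if p.shape != shape or p.pixel_size_um != px:
                raise ParameterError(
                    "all planes must share one shape and calibration"
                )
        object.__setattr__(self, "planes", planes)

    @property
    def pixel_size_um(self) -> float:
        return self.planes[0].pixel_size_um

    def as_array(self) -> np.ndarray:
        """Planes stacked into a (n_planes, rows, cols) array."""
        return np.stack([p.intensities for p in self.planes])


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the invasion segmentation.

    ``threshold_method`` is ``"otsu"`` or a fixed numeric intensity.
    ``spheroid_rule`` selects the spheroid among foreground components:
    ``"largest"`` (default) or ``"center"`` (component containing the image
    centre).  Cell regions outside ``[min_cell_area_um2, max_cell_area_um2]``
    are rejected as debris/doublets.  ``watershed_min_distance_um`` is the
    minimum Euclidean separation between watershed seed maxima (default
    6 µm, one typical nucleus radius); it must sit below the centre
    separation of the closest nucleus pair to be split.
    ``smooth_sigma_um`` is the sd of a Gaussian denoising blur applied
    before thresholding (0 disables it); without it, single noise pixels can
    sever the dim intensity bridge between contacting nuclei.
    ``separate_touching=False`` skips the watershed and treats each
    connected component as one cell — the naive baseline that undercounts
    contacting nuclei.  With
    ``exclude_touching_spheroid`` (default) regions adjacent to the spheroid
    mask are not counted as invading cells.  ``distance_reference`` chooses
    whether d_k is measured to the spheroid centroid (default) or to the
    nearest spheroid edge pixel.
    """

    threshold_method: Union[str, float] = "otsu"
    min_cell_area_um2: float = 20.0
    max_cell_area_um2: float = 400.0
    spheroid_rule: str = "largest"
    watershed_min_distance_um: float = 6.0
    smooth_sigma_um: float = 1.0
    separate_touching: bool = True
    exclude_touching_spheroid: bool = True
    distance_reference: str = "centroid"

    def __post_init__(self) -> None:
        if self.min_cell_area_um2 >= self.max_cell_area_um2:
            raise ParameterError("min_cell_area_um2 must be < max_cell_area_um2")
        if self.min_cell_area_um2 <= 0 or self.watershed_min_distance_um <= 0:
            raise ParameterError("areas and watershed distance must be positive")
        if self.spheroid_rule not in ("largest", "center"):
            raise ParameterError(f"unknown spheroid_rule {self.spheroid_rule!r}")
        if self.distance_reference not in ("centroid", "edge"):
            raise ParameterError(
                f"unknown distance_reference {self.distance_reference!r}"
            )
        if isinstance(self.threshold_method, str) and self.threshold_method != "otsu":
            raise ParameterError(
                "threshold_method must be 'otsu' or a numeric value"
            )


@dataclass(frozen=True)
class SpheroidSegmentation:
    """Spheroid mask/centroid plus invading-cell centroids, in µm."""

    spheroid_mask: np.ndarray
    spheroid_centroid_um: tuple[float, float]
    cell_centroids_um: tuple[tuple[float, float], ...]
    pixel_size_um: float
    distance_reference: str = "centroid"


@dataclass(frozen=True)
class InvasionResult:
    """Per-cell distances d_k, cell count N and the MSD score (µm²).

    ``msd_um2`` is ``None`` when no invading cell was found: with N = 0 the
    score is undefined, not zero.
    """

    distances_um: tuple[float, ...]
    n_cells: int
    msd_um2: Optional[float]

    def __post_init__(self) -> None:
        if self.n_cells != len(self.distances_um):
            raise ParameterError("n_cells must equal len(distances_um)")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def max_project(stack: ZStack) -> PixelImage:
    """Maximum-intensity projection along z; calibration is preserved."""
    arr = stack.as_array()
    return PixelImage(arr.max(axis=0), stack.pixel_size_um)


def _pixel_to_um(row: float, col: float, px: float) -> tuple[float, float]:
    return ((col + 0.5) * px, (row + 0.5) * px)


def segment_invasion(
    image: PixelImage, params: SegmentationParams | None = None
) -> SpheroidSegmentation:
    """Segment the spheroid body and the individual invading nuclei.

    The projected image is binarised with an intensity threshold; the
    spheroid is chosen by ``params.spheroid_rule``; the remaining foreground
    is split into nuclei by marker-based watershed on the Euclidean distance
    transform, so that contacting nuclei are separated.  Accepted regions are
    reported as one centroid each, in µm.
    """
    params = params or SegmentationParams()
    img = np.asarray(image.intensities, dtype=float)
    px = image.pixel_size_um
    if params.smooth_sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma=params.smooth_sigma_um / px)

    if params.threshold_method == "otsu":
        if np.ptp(img) == 0:
            raise ThresholdError("flat image: no intensity threshold exists")
        thr = threshold_otsu(img)
    else:
        thr = float(params.threshold_method)
    binary = img > thr
    if not binary.any() or binary.all():
        raise ThresholdError(
            f"threshold {thr:.4g} leaves no foreground/background split"
        )

    labels = cc_label(binary, connectivity=2)
    props = regionprops(labels)
    if params.spheroid_rule == "largest":
        spheroid_prop = max(props, key=lambda r: r.area)
    else:  # "center"
        centre = (img.shape[0] // 2, img.shape[1] // 2)
        lab = labels[centre]
        if lab == 0:
            raise SegmentationError(
                "no foreground component contains the image centre"
            )
        spheroid_prop = next(r for r in props if r.label == lab)
    spheroid_mask = labels == spheroid_prop.label
    sp_r, sp_c = spheroid_prop.centroid
    spheroid_centroid = _pixel_to_um(sp_r, sp_c, px)

    rest = binary & ~spheroid_mask
    cell_centroids: list[tuple[float, float]] = []
    if rest.any() and not params.separate_touching:
        regions = cc_label(rest, connectivity=2)
    elif rest.any():
        edt = ndi.distance_transform_edt(rest)
        min_dist_px = params.watershed_min_distance_um / px
        # candidate maxima (a disc footprint keeps suppression Euclidean,
        # not chessboard), then greedy thinning by exact Euclidean distance:
        # plateau ties of the integer-grid distance transform collapse to
        # one seed, while genuine twin cores just over the minimum
        # separation survive at any orientation
        fp = disk(max(1, int(math.floor(min_dist_px / math.sqrt(2)))))
        peaks = peak_local_max(
            edt, footprint=fp, labels=cc_label(rest, connectivity=2)
        )
        order = np.argsort(edt[tuple(peaks.T)])[::-1]
        kept: list[np.ndarray] = []
        for i in order:
            cand = peaks[i].astype(float)
            if all(np.linalg.norm(cand - k) >= min_dist_px for k in kept):
                kept.append(cand)
        peak_mask = np.zeros(rest.shape, dtype=bool)
        for k in kept:
            peak_mask[int(k[0]), int(k[1])] = True
        markers, _ = ndi.label(peak_mask)
        regions = watershed(-edt, markers, mask=rest)

    if rest.any():
        near_spheroid = (
            ndi.binary_dilation(spheroid_mask)
            if params.exclude_touching_spheroid
            else None
        )
        for region in regionprops(regions):
            area_um2 = region.area * px * px
            if not params.min_cell_area_um2 <= area_um2 <= params.max_cell_area_um2:
                continue
            if near_spheroid is not None:
                rr, cc = region.coords.T
                if near_spheroid[rr, cc].any():
                    continue
            r, c = region.centroid
            cell_centroids.append(_pixel_to_um(r, c, px))

    return SpheroidSegmentation(
        spheroid_mask=spheroid_mask,
        spheroid_centroid_um=spheroid_centroid,
        cell_centroids_um=tuple(cell_centroids),
        pixel_size_um=px,
        distance_reference=params.distance_reference,
    )


def compute_msd(seg: SpheroidSegmentation) -> InvasionResult:
    """MSD invasion score from a segmentation.

    d_k is the Euclidean distance (µm) from cell k to the spheroid centroid
    (or, with ``distance_reference="edge"``, to the nearest spheroid pixel);
    MSD = mean of the squared d_k.  With no cells the score is reported
    absent (``msd_um2 = None``), signalling "no invasion measurable".
    """
    if not seg.cell_centroids_um:
        return InvasionResult(distances_um=(), n_cells=0, msd_um2=None)

    cells = np.asarray(seg.cell_centroids_um, dtype=float)
    if seg.distance_reference == "edge":
        rr, cc = np.nonzero(seg.spheroid_mask)
        edge_xy = np.column_stack(
            ((cc + 0.5) * seg.pixel_size_um, (rr + 0.5) * seg.pixel_size_um)
        )
        d = np.min(
            np.linalg.norm(cells[:, None, :] - edge_xy[None, :, :], axis=2),
            axis=1,
        )
    else:
        centre = np.asarray(seg.spheroid_centroid_um, dtype=float)
        d = np.linalg.norm(cells - centre, axis=1)
    msd = float(np.mean(d**2))
    return InvasionResult(
        distances_um=tuple(float(v) for v in d),
        n_cells=len(d),
        msd_um2=msd,
    )


def invasion_timecourse(
    results: Mapping[object, Union[InvasionResult, Sequence[InvasionResult]]]
    | Sequence[tuple[object, Union[InvasionResult, Sequence[InvasionResult]]]],
) -> pd.DataFrame:
    """Tabulate MSD over labelled time points.

    ``results`` maps a time label (e.g. "24 h") to one ``InvasionResult`` or
    to a sequence of replicate results.  One row per label reports the number
    of replicate spheroids, the mean cell count, and the mean MSD with its
    s.e.m. across replicates (NaN with a single replicate).  Replicates with
    an absent MSD (N = 0) are excluded from the MSD mean.
    """
    if isinstance(results, Mapping):
        items = list(results.items())
    else:
        items = list(results)
        labels = [k for k, _ in items]
        if len(set(labels)) != len(labels):
            raise ParameterError("duplicate time labels in timecourse input")
    if not items:
        raise ParameterError("timecourse needs at least one labelled result")

    rows = []
    for label_, res in items:
        reps: list[InvasionResult] = (
            [res] if isinstance(res, InvasionResult) else list(res)
        )
        if not reps:
            raise ParameterError(f"time point {label_!r} has no replicates")
        msds = np.array([r.msd_um2 for r in reps if r.msd_um2 is not None])
        n_rep = len(msds)
        mean_msd = float(msds.mean()) if n_rep else math.nan
        sem = (
            float(msds.std(ddof=1) / math.sqrt(n_rep)) if n_rep > 1 else math.nan
        )
        rows.append(
            {
                "time": label_,
                "n_spheroids": len(reps),
                "mean_n_cells": float(np.mean([r.n_cells for r in reps])),
                "mean_msd_um2": mean_msd,
                "sem_msd_um2": sem,
            }
        )
    return pd.DataFrame(rows)
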