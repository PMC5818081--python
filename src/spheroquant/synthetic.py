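"""Ground-truthed synthetic inputs for every quantification stage.

The generators emulate, with known ground truth, the raw material of the
quantification pipeline:

* a DAPI-like confocal z-stack of a collagen-embedded spheroid with N
  invading nuclei at controlled distances (including deliberately contacting
  pairs that merge under naive thresholding);
* biased-random-walk migration tracks sampled at fixed intervals (defaults:
  24 steps of 20 min, i.e. an 8 h observation);
* a coronal lung-section mask pair with tumour nodules of requested areas;
* before/after gel-area masks with a prescribed contraction fraction.

All randomness in a call flows from a single ``numpy`` Generator seeded by
the ``seed`` field, so identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import tifffile

from .chemotaxis import Track, TrackSet, write_tracks
from .errors import ParameterError
from .invasion import PixelImage, ZStack

__all__ = [
    "InvasionSimParams",
    "GroundTruthInvasion",
    "TrackSimParams",
    "LungSimParams",
    "generate_spheroid_stack",
    "generate_tracks",
    "generate_lung_section",
    "generate_gel_masks",
    "write_stack",
    "write_ground_truth",
]

#: rendered intensity of spheroid body and nucleus peaks (arbitrary units)
_SIGNAL = 1.0
#: additive background level, so noise can fluctuate both ways before clipping
_BACKGROUND = 0.1
#: scale factor from arbitrary units to the 16-bit output range
_UINT16_SCALE = 40000.0


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvasionSimParams:
    """Geometry and imaging parameters of a synthetic invasion stack.

    The spheroid is a bright disc at the image centre; ``n_cells`` nuclei are
    placed at distances drawn from ``distance_distribution`` — ``("uniform",
    r_min, r_max)`` or ``("fixed", r)`` µm from the spheroid centroid, always
    outside the spheroid body.  ``n_contacting_pairs`` of those nuclei are
    planted as pairs with centre separation 1.5 × nucleus radius: close
    enough to merge under plain thresholding, so watershed separation is
    exercised.  Nuclei are isotropic Gaussian blobs (σ = nucleus radius / 2,
    truncated at 3σ), each assigned to one random plane of the stack; the
    spheroid appears in every plane.  ``background_noise_sd`` is the Gaussian
    background noise sd relative to the unit signal (default 0.1, SNR ≈ 10).
    """

    image_size_px: tuple[int, int] = (640, 640)
    pixel_size_um: float = 1.0
    spheroid_radius_um: float = 100.0
    n_cells: int = 50
    distance_distribution: tuple = ("uniform", 130.0, 280.0)
    nucleus_radius_um: float = 6.0
    n_contacting_pairs: int = 0
    background_noise_sd: float = 0.1
    n_planes: int = 3
    seed: int = 0
    min_separation_um: Optional[float] = None  # default: 4 × nucleus radius

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ParameterError("image_size_px must be positive")
        if self.pixel_size_um <= 0 or self.spheroid_radius_um <= 0:
            raise ParameterError("pixel size and spheroid radius must be positive")
        if self.nucleus_radius_um <= 0:
            raise ParameterError("nucleus_radius_um must be positive")
        if self.n_cells < 0 or self.n_planes < 1:
            raise ParameterError("n_cells >= 0 and n_planes >= 1 required")
        if self.background_noise_sd < 0:
            raise ParameterError("background_noise_sd must be non-negative")
        if not 0 <= 2 * self.n_contacting_pairs <= self.n_cells:
            raise ParameterError("need n_contacting_pairs <= n_cells / 2")

        half_extent = min(h, w) * self.pixel_size_um / 2.0
        if self.spheroid_radius_um >= half_extent:
            raise ParameterError("spheroid does not fit inside the image")
        r_lo, r_hi = self._distance_range()
        if r_lo <= self.spheroid_radius_um:
            raise ParameterError(
                "minimum cell distance must exceed the spheroid radius"
            )
        margin = 3.0 * self.nucleus_radius_um / 2.0  # blob truncation radius
        if self.n_cells > 0 and r_hi + margin >= half_extent:
            raise ParameterError("sampled cells would fall outside the image")

    def _distance_range(self) -> tuple[float, float]:
        kind = self.distance_distribution[0]
        if kind == "uniform":
            _, lo, hi = self.distance_distribution
            if not 0 < lo <= hi:
                raise ParameterError("uniform range needs 0 < r_min <= r_max")
            return float(lo), float(hi)
        if kind == "fixed":
            _, r = self.distance_distribution
            if r <= 0:
                raise ParameterError("fixed distance must be positive")
            return float(r), float(r)
        raise ParameterError(
            f"unknown distance distribution {kind!r} (use 'uniform' or 'fixed')"
        )

    @property
    def effective_min_separation_um(self) -> float:
        if self.min_separation_um is not None:
            return self.min_separation_um
        return 4.0 * self.nucleus_radius_um


@dataclass(frozen=True)
class GroundTruthInvasion:
    """Exact planted geometry backing an invasion simulation.

    ``msd_um2`` is the mean of the squared planted distances; ``None`` when
    no cells were planted (the score is undefined at N = 0).
    """

    spheroid_centroid_um: tuple[float, float]
    cell_centroids_um: tuple[tuple[float, float], ...]
    distances_um: tuple[float, ...]
    msd_um2: Optional[float]

    def __post_init__(self) -> None:
        if len(self.cell_centroids_um) != len(self.distances_um):
            raise ParameterError("centroid and distance lists must agree")


@dataclass(frozen=True)
class TrackSimParams:
    """Biased-random-walk track simulation.

    Each step adds ``drift_um_per_step`` plus isotropic Gaussian noise of sd
    ``step_sd_um`` per axis; positions are stamped 0, interval, 2×interval …
    The defaults (24 steps × 20 min) reproduce an 8 h observation window.
    """

    n_tracks: int = 60
    n_steps: int = 24
    interval_min: float = 20.0
    drift_um_per_step: tuple[float, float] = (0.0, 0.0)
    step_sd_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1 or self.n_steps < 1:
            raise ParameterError("n_tracks and n_steps must be positive")
        if self.interval_min <= 0:
            raise ParameterError("interval_min must be positive")
        if self.step_sd_um < 0:
            raise ParameterError("step_sd_um must be non-negative")

    @property
    def duration_min(self) -> float:
        return self.n_steps * self.interval_min


@dataclass(frozen=True)
class LungSimParams:
    """A lung section as an ellipse, with disjoint disc nodules inside it."""

    section_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    lung_semiaxes_um: tuple[float, float] = (220.0, 180.0)
    nodule_areas_um2: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.section_size_px
        a, b = self.lung_semiaxes_um
        if h <= 0 or w <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("section size and pixel size must be positive")
        if a <= 0 or b <= 0:
            raise ParameterError("lung semiaxes must be positive")
        if any(x <= 0 for x in self.nodule_areas_um2):
            raise ParameterError("nodule areas must be positive")
        if (
            2 * a >= w * self.pixel_size_um
            or 2 * b >= h * self.pixel_size_um
        ):
            raise ParameterError("lung ellipse does not fit in the section")
        object.__setattr__(
            self, "nodule_areas_um2", tuple(float(x) for x in self.nodule_areas_um2)
        )


# ---------------------------------------------------------------------------
# Invasion stack generator
# ---------------------------------------------------------------------------

def _pixel_centre_grids(shape: tuple[int, int], px: float):
    rows = (np.arange(shape[0]) + 0.5) * px
    cols = (np.arange(shape[1]) + 0.5) * px
    return rows[:, None], cols[None, :]  # y, x broadcast grids


def _sample_positions(params: InvasionSimParams, rng: np.random.Generator):
    """Sample nucleus centres: singles plus contacting pairs.

    Singles and pair anchors keep at least ``effective_min_separation_um``
    from every other anchor/single; pair partners sit at 1.5 × nucleus radius
    from their anchor.  Rejection sampling; infeasibly dense requests raise.
    """
    h, w = params.image_size_px
    px = params.pixel_size_um
    centre = np.array([w * px / 2.0, h * px / 2.0])  # (x, y)
    r_lo, r_hi = params._distance_range()
    blob_margin = 3.0 * params.nucleus_radius_um / 2.0
    half_extent = min(h, w) * px / 2.0
    pair_sep = 1.5 * params.nucleus_radius_um
    min_sep = params.effective_min_separation_um

    n_pairs = params.n_contacting_pairs
    n_single = params.n_cells - 2 * n_pairs

    placed: list[np.ndarray] = []  # anchor positions guarding separation
    positions: list[np.ndarray] = []

    def sample_anchor() -> np.ndarray:
        for _ in range(20000):
            if r_lo == r_hi:
                r = r_lo
            else:
                r = rng.uniform(r_lo, r_hi)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            pos = centre + r * np.array([math.cos(theta), math.sin(theta)])
            if np.linalg.norm(pos - centre) + blob_margin >= half_extent:
                continue
            if all(np.linalg.norm(pos - q) >= min_sep for q in placed):
                return pos
        raise ParameterError(
            "could not place all cells with the requested separation; "
            "reduce n_cells or min_separation_um"
        )

    for _ in range(n_pairs):
        for _ in range(20000):
            anchor = sample_anchor()
            phi = rng.uniform(0.0, 2.0 * math.pi)
            partner = anchor + pair_sep * np.array([math.cos(phi), math.sin(phi)])
            ok = (
                np.linalg.norm(partner - centre) > params.spheroid_radius_um + blob_margin
                and np.abs(partner - centre).max() + blob_margin < half_extent
                and all(np.linalg.norm(partner - q) >= min_sep for q in placed)
            )
            if ok:
                break
        else:  # pragma: no cover - pathological geometry
            raise ParameterError("could not place a contacting pair")
        placed.append(anchor)
        positions.extend([anchor, partner])

    for _ in range(n_single):
        pos = sample_anchor()
        placed.append(pos)
        positions.append(pos)

    return centre, positions


def _render_blob(plane: np.ndarray, x_um: float, y_um: float,
                 sigma_um: float, px: float) -> None:
    """Add a Gaussian nucleus blob (peak _SIGNAL, truncated at 3σ) in place."""
    trunc = 3.0 * sigma_um
    r0 = max(0, int((y_um - trunc) / px) - 1)
    r1 = min(plane.shape[0], int((y_um + trunc) / px) + 2)
    c0 = max(0, int((x_um - trunc) / px) - 1)
    c1 = min(plane.shape[1], int((x_um + trunc) / px) + 2)
    yy = (np.arange(r0, r1) + 0.5) * px - y_um
    xx = (np.arange(c0, c1) + 0.5) * px - x_um
    d2 = yy[:, None] ** 2 + xx[None, :] ** 2
    blob = _SIGNAL * np.exp(-d2 / (2.0 * sigma_um**2))
    blob[d2 > trunc**2] = 0.0
    # fluorescence is additive: overlapping nuclei sum, so contacting pairs
    # form one bright bridged blob under thresholding
    plane[r0:r1, c0:c1] += blob


def generate_spheroid_stack(
    params: InvasionSimParams,
) -> tuple[ZStack, GroundTruthInvasion]:
    """Render a synthetic invasion z-stack and its exact ground truth.

    Returns a 16-bit-range stack (spheroid disc in every plane, each nucleus
    blob in one random plane, additive Gaussian background noise) plus the
    planted spheroid centroid, nucleus centroids, centre distances and their
    mean square — the quantities the invasion pipeline must recover.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    px = params.pixel_size_um
    sigma = params.nucleus_radius_um / 2.0

    centre, positions = _sample_positions(params, rng)

    yg, xg = _pixel_centre_grids((h, w), px)
    spheroid = (
        (xg - centre[0]) ** 2 + (yg - centre[1]) ** 2
        <= params.spheroid_radius_um**2
    )

    planes = np.zeros((params.n_planes, h, w), dtype=float)
    planes[:, spheroid] = _SIGNAL
    # one random plane per nucleus; members of a contacting pair share a
    # plane (they sit at the same depth), so their bridge survives projection
    n_paired = 2 * params.n_contacting_pairs
    pair_planes = rng.integers(0, params.n_planes, size=params.n_contacting_pairs)
    single_planes = rng.integers(0, params.n_planes, size=len(positions) - n_paired)
    plane_of = np.concatenate([np.repeat(pair_planes, 2), single_planes]).astype(int)
    for (x, y), p in zip(positions, plane_of):
        _render_blob(planes[p], float(x), float(y), sigma, px)

    planes += _BACKGROUND
    if params.background_noise_sd > 0:
        planes += rng.normal(0.0, params.background_noise_sd, planes.shape)
    out = np.clip(planes * _UINT16_SCALE, 0, 65535).astype(np.uint16)

    stack = ZStack(tuple(PixelImage(out[i], px) for i in range(params.n_planes)))
    dists = tuple(float(np.linalg.norm(p - centre)) for p in positions)
    msd = float(np.mean(np.square(dists))) if dists else None
    truth = GroundTruthInvasion(
        spheroid_centroid_um=(float(centre[0]), float(centre[1])),
        cell_centroids_um=tuple((float(p[0]), float(p[1])) for p in positions),
        distances_um=dists,
        msd_um2=msd,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Track generator
# ---------------------------------------------------------------------------

def generate_tracks(params: TrackSimParams) -> tuple[TrackSet, dict]:
    """Simulate biased-random-walk tracks.

    Each track starts at the origin and accumulates i.i.d. Gaussian steps of
    per-axis sd ``step_sd_um`` plus the drift vector.  The ground-truth
    summary records the drift, step sd and the expected net displacement
    (drift × n_steps).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    drift = np.asarray(params.drift_um_per_step, dtype=float)
    steps = drift + rng.normal(
        0.0, params.step_sd_um, size=(params.n_tracks, params.n_steps, 2)
    )
    pos = np.concatenate(
        [np.zeros((params.n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    t = np.arange(params.n_steps + 1) * params.interval_min
    tracks = tuple(
        Track(track_id=i, t_min=t, x_um=pos[i, :, 0], y_um=pos[i, :, 1])
        for i in range(params.n_tracks)
    )
    truth = {
        "drift_um_per_step": tuple(float(v) for v in drift),
        "step_sd_um": params.step_sd_um,
        "n_steps": params.n_steps,
        "interval_min": params.interval_min,
        "expected_net_um": tuple(float(v) for v in drift * params.n_steps),
    }
    return TrackSet(tracks=tracks), truth


# ---------------------------------------------------------------------------
# Lung-section generator
# ---------------------------------------------------------------------------

def generate_lung_section(
    params: LungSimParams,
) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Binary lung/tumour masks with disc nodules of the requested areas.

    Nodules are disjoint discs placed uniformly at random fully inside the
    lung ellipse; the returned ground truth is the requested area list
    (rendered pixel areas agree to rasterisation accuracy).  Deterministic
    for a fixed seed; infeasible packings raise a parameter error.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.section_size_px
    px = params.pixel_size_um
    a, b = params.lung_semiaxes_um  # x and y semiaxes
    cx, cy = w * px / 2.0, h * px / 2.0

    yg, xg = _pixel_centre_grids((h, w), px)
    lung = ((xg - cx) / a) ** 2 + ((yg - cy) / b) ** 2 <= 1.0

    tumour = np.zeros((h, w), dtype=bool)
    radii = [math.sqrt(area / math.pi) for area in params.nodule_areas_um2]
    # place large nodules first: better packing odds
    order = np.argsort(radii)[::-1]
    centres: list[tuple[np.ndarray, float]] = []
    for idx in order:
        r = radii[idx]
        for _ in range(20000):
            x = rng.uniform(cx - a, cx + a)
            y = rng.uniform(cy - b, cy + b)
            # disc fully inside the ellipse: shrink both semiaxes by r
            if a <= r or b <= r:
                raise ParameterError("nodule larger than the lung ellipse")
            if ((x - cx) / (a - r)) ** 2 + ((y - cy) / (b - r)) ** 2 > 1.0:
                continue
            if all(
                math.hypot(x - qx, y - qy) > r + qr + 2 * px
                for (qx, qy), qr in centres
            ):
                break
        else:
            raise ParameterError(
                "could not place all nodules disjointly inside the lung"
            )
        centres.append(((x, y), r))
        tumour |= (xg - x) ** 2 + (yg - y) ** 2 <= r**2

    return lung, tumour, params.nodule_areas_um2


# ---------------------------------------------------------------------------
# Gel-mask generator
# ---------------------------------------------------------------------------

def generate_gel_masks(
    initial_area_px: int, contraction_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Before/after gel masks: discs whose areas differ by the given fraction.

    The final disc area is ``initial × (1 − fraction)`` up to rasterisation;
    fraction 0 returns two identical masks, fraction 1 an empty final mask.
    """
    if initial_area_px <= 0:
        raise ParameterError("initial_area_px must be positive")
    if not 0.0 <= contraction_fraction <= 1.0:
        raise ParameterError("contraction_fraction must lie in [0, 1]")
    r0 = math.sqrt(initial_area_px / math.pi)
    size = int(math.ceil(2 * r0)) + 5
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy + 0.5 - c) ** 2 + (xx + 0.5 - c) ** 2
    initial = d2 <= r0**2
    r1 = r0 * math.sqrt(1.0 - contraction_fraction)
    final = d2 <= r1**2
    return initial, final


# ---------------------------------------------------------------------------
# Writers (ground truth as JSON sidecars, images as 16-bit TIFF)
# ---------------------------------------------------------------------------

def write_stack(stack: ZStack, path: Union[str, Path]) -> None:
    """Write a z-stack as a multi-page 16-bit grayscale TIFF."""
    arr = stack.as_array().astype(np.uint16)
    tifffile.imwrite(
        path,
        arr,
        photometric="minisblack",
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata=None,
    )


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255)."""
    tifffile.imwrite(
        path, (np.asarray(mask, bool) * 255).astype(np.uint8), metadata=None
    )


def write_ground_truth(truth: object, path: Union[str, Path]) -> None:
    """Write a ground-truth record (dataclass or dict) as a JSON sidecar."""
    payload = asdict(truth) if hasattr(truth, "__dataclass_fields__") else truth
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
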