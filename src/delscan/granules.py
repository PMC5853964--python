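"""Starch-granule size distributions from micrographs, and swelling power.

The measurement mirrors a standard ImageJ workflow: set the scale, make the
image binary, apply a watershed to separate touching granules, then run
particle analysis twice — once over all particles of at least 0.785 µm²
(every granule above 1 µm diameter, A- plus B-type) and once over the
0.785–78.5 µm² window (granules of 1–10 µm diameter, the small class that
contains the B-type granules).  The per-image percentage of small granules
and the per-sample mean over images summarize the size distribution: wheat
endosperm starch is normally bimodal (large lenticular A-granules plus many
small B-granules), and loss of B-granules collapses it to a unimodal,
large-granule-only distribution.

Area cutoffs are the circle areas of the diameter limits:
pi * (1/2)^2 = 0.785 µm² and pi * (10/2)^2 = 78.5 µm² (printed precision);
both bounds are inclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)


def diameter_to_area(diameter_um: float, digits: int = 3) -> float:
    """Area (µm²) of a circle of the given diameter, rounded to ``digits``
    significant figures — the convention used for the 0.785/78.5 cutoffs."""
    area = math.pi * (diameter_um / 2.0) ** 2
    if area == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(area)))
    return round(area, digits - 1 - exponent)


SMALL_MIN_AREA = diameter_to_area(1.0)  # 0.785 µm²
SMALL_MAX_AREA = diameter_to_area(10.0)  # 78.5 µm²


@dataclass
class Micrograph:
    """A grayscale image with its spatial calibration (µm per pixel)."""

    pixels: np.ndarray
    scale: float  # µm per pixel
    image_id: str = "image"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite intensities")


@dataclass
class ParticleSet:
    """Per-particle areas (µm²) measured on one image."""

    image_id: str
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.areas <= 0).any():
            raise ValueError("particle areas must be positive")

    @property
    def label_count(self) -> int:
        return int(self.areas.size)


@dataclass
class GranuleStats:
    pct_small: float  # % of granules >=1 µm that are 1-10 µm in diameter
    mean_small_area: float  # µm², over the small class
    mean_large_area: float  # µm², over granules > 10 µm diameter
    n_images: int
    per_image_pct_small: list


@dataclass
class SwellingMeasurement:
    """Dry starch weight and the weight of the swollen pellet (starch plus
    retained water) after heating in excess water; both in mg."""

    dry_weight: float
    swollen_pellet_weight: float

    def __post_init__(self) -> None:
        if self.dry_weight <= 0 or self.swollen_pellet_weight <= 0:
            raise ValueError("weights must be positive")
        if self.swollen_pellet_weight < self.dry_weight:
            raise ValueError("swollen pellet cannot weigh less than dry starch")


def binarize(img: Micrograph, threshold: float | None = None, invert: bool = False) -> np.ndarray:
    """Foreground mask of granule pixels.

    Granules are assumed darker than the background (iodine-stained starch in
    bright field); set ``invert`` for bright-on-dark images.  The default
    threshold is Otsu's global automatic threshold; a fixed threshold may be
    supplied instead.
    """
    pixels = img.pixels.astype(float)
    if invert:
        pixels = pixels.max() - pixels
    if pixels.max() == pixels.min():
        logger.info("binarize: blank image %s, empty mask", img.image_id)
        return np.zeros(pixels.shape, dtype=bool)
    thr = float(threshold_otsu(pixels)) if threshold is None else float(threshold)
    return pixels < thr


def split_touching(mask: np.ndarray, min_distance_px: int = 4, smooth_sigma: float = 1.0) -> np.ndarray:
    """Separate touching convex particles with a distance-transform watershed.

    Markers are local maxima of the (lightly smoothed) Euclidean distance
    transform; the watershed of the negative distance map then assigns every
    foreground pixel to exactly one label.  ``min_distance_px`` sets the
    minimum marker separation; smoothing suppresses spurious maxima from
    boundary pixelation.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(distance, sigma=smooth_sigma)
    coords = peak_local_max(
        smoothed, min_distance=min_distance_px, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:  # tiny specks with no interior maximum
        labeled, _ = ndi.label(mask)
        return labeled.astype(np.int32)
    return watershed(-smoothed, markers, mask=mask).astype(np.int32)


def measure_particles(
    labels: np.ndarray, scale: float, image_id: str = "image", exclude_border: bool = True
) -> ParticleSet:
    """Particle areas in µm²: pixel count x scale².

    Particles touching the image border are excluded by default — partial
    granules bias areas low.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    labels = np.asarray(labels)
    if labels.max() == 0:
        return ParticleSet(image_id=image_id, areas=np.empty(0))
    keep = np.ones(labels.max() + 1, dtype=bool)
    keep[0] = False
    if exclude_border:
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        keep[np.unique(border)] = False
        keep[0] = False
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    areas = counts[keep & (counts > 0)] * scale * scale
    return ParticleSet(image_id=image_id, areas=areas)


def granule_stats(
    particles: Sequence[ParticleSet],
    small_min_area: float = SMALL_MIN_AREA,
    small_max_area: float = SMALL_MAX_AREA,
) -> GranuleStats:
    """Two-pass particle statistics over one or more images.

    Per image: pct_small = 100 x (number of particles with area in
    [small_min_area, small_max_area]) / (number of particles with area >=
    small_min_area); bounds inclusive.  The sample value is the unweighted
    mean over images; images with no qualifying particle are excluded from
    the mean (with a notice).  Class mean areas pool particles across images.
    """
    if not particles:
        raise ValueError("at least one image required")
    per_image = []
    all_small, all_large = [], []
    for ps in particles:
        qualifying = ps.areas[ps.areas >= small_min_area]  # pass 1: all granules >= 1 µm
        small = qualifying[qualifying <= small_max_area]  # pass 2: 1-10 µm window
        if qualifying.size == 0:
            logger.info("granule_stats: image %s has no qualifying particle", ps.image_id)
            continue
        per_image.append(100.0 * small.size / qualifying.size)
        all_small.append(small)
        all_large.append(qualifying[qualifying > small_max_area])
    if not per_image:
        raise ValueError("no image with qualifying particles")
    small_areas = np.concatenate(all_small) if all_small else np.empty(0)
    large_areas = np.concatenate(all_large) if all_large else np.empty(0)
    return GranuleStats(
        pct_small=float(np.mean(per_image)),
        mean_small_area=float(small_areas.mean()) if small_areas.size else float("nan"),
        mean_large_area=float(large_areas.mean()) if large_areas.size else float("nan"),
        n_images=len(per_image),
        per_image_pct_small=per_image,
    )


def analyze_micrograph(img: Micrograph, invert: bool = False, exclude_border: bool = True) -> ParticleSet:
    """binarize -> watershed -> measure, on one image."""
    mask = binarize(img, invert=invert)
    labels = split_touching(mask)
    return measure_particles(labels, img.scale, image_id=img.image_id, exclude_border=exclude_border)


def swelling_power(m: SwellingMeasurement) -> float:
    """Swollen pellet weight divided by dry starch weight (dimensionless)."""
    return m.swollen_pellet_weight / m.dry_weight
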