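"""Morphology and intensity features from multichannel cell-image crops.

Re-implements the subset of instrument-software features the senescence
analysis consumes. The exact definitions used by commercial packages are
proprietary; the constructions here are documented approximations chosen for
the same qualitative behaviour — high circularity and shape ratio for round
single cells, low for doublets and aggregates:

* ``width``/``height`` — bounding-box extents of the mask along the image
  axes, in µm, so that diameter D = (width + height) / 2 matches the
  field's width/height phrasing literally.
* ``aspect_ratio`` — minor/major axis ratio of the intensity-weighted
  best-fit ellipse (second central moments), in (0, 1].
* ``circularity`` — mean radial distance of the 8-connected boundary pixels
  from the mask centroid divided by the standard deviation of that distance;
  capped at :data:`CIRCULARITY_CAP` (a perfect disk has vanishing spread).
* ``shape_ratio`` — minimum thickness over length: twice the minimum
  distance-to-background over the mask skeleton, divided by the extent along
  the major axis. Clipped to (0, 1].

Pixels are 0-based, row-major; masks are boolean grids aligned to the crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .errors import AlignmentError, ConfigError, SegmentationEmptyError

#: circularity cap. Near-perfect disks have vanishing boundary-radius spread,
#: so the raw ratio blows up and is dominated by pixelation noise; every value
#: at or above the cap means "as round as measurable".
CIRCULARITY_CAP = 30.0


@dataclass
class CellImage:
    """Multichannel pixel grid for one event.

    ``channels`` maps channel/role name to a 2-D non-negative array; all
    channels share dimensions. ``calibration`` is µm per pixel (> 0);
    ``origin`` the crop's (row, col) offset in the source image.
    """

    channels: dict[str, np.ndarray]
    calibration: float = 1.0
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("CellImage needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ConfigError(f"channel shapes differ: {shapes}")
        if not np.isfinite(self.calibration) or self.calibration <= 0:
            raise ConfigError("calibration must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class CellMask:
    """Boolean foreground grid for one segmented cell."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise SegmentationEmptyError("mask has no foreground pixels")

    def boundary(self) -> np.ndarray:
        """Pixels of the 8-connected outline (mask minus full 3×3 erosion)."""
        eroded = ndimage.binary_erosion(self.mask, structure=np.ones((3, 3)))
        return self.mask & ~eroded

    def touches_border(self) -> bool:
        m = self.mask
        return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())


@dataclass
class FeatureVector:
    area: float  # µm²
    perimeter: float  # µm
    width: float  # µm
    height: float  # µm
    diameter: float  # µm, identically (width + height) / 2
    aspect_ratio: float
    circularity: float
    shape_ratio: float
    channel_means: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {
            "area": self.area,
            "perimeter": self.perimeter,
            "width": self.width,
            "height": self.height,
            "diameter": self.diameter,
            "aspect_ratio": self.aspect_ratio,
            "circularity": self.circularity,
            "shape_ratio": self.shape_ratio,
        }
        row.update(self.channel_means)
        return row


def segment_cell(
    image: CellImage,
    channel: str = "bf",
    method: str = "otsu",
    params: dict | None = None,
) -> CellMask:
    """Threshold one channel and keep the largest connected component.

    ``method='otsu'`` thresholds automatically; ``method='fixed'`` uses
    ``params['threshold']``. Holes are filled before component selection.
    An all-background result raises :class:`SegmentationEmptyError` rather
    than returning an empty mask silently.
    """
    if channel not in image.channels:
        raise ConfigError(f"channel {channel!r} not present in image")
    arr = np.asarray(image.channels[channel], dtype=float)
    if method == "otsu":
        try:
            thr = filters.threshold_otsu(arr)
        except ValueError as exc:  # constant image
            raise SegmentationEmptyError("uniform image: no foreground") from exc
    elif method == "fixed":
        if not params or "threshold" not in params:
            raise ConfigError("fixed segmentation needs params['threshold']")
        thr = float(params["threshold"])
    else:
        raise ConfigError(f"unknown segmentation method {method!r}")
    fg = arr > thr
    if not fg.any():
        raise SegmentationEmptyError("no pixels above threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationEmptyError("no connected foreground component")
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))) + 1
    return CellMask(labels == largest)


def _weighted_axis_ratio(mask: np.ndarray, weights: np.ndarray) -> float:
    coords = np.argwhere(mask).astype(float)
    w = weights[mask].astype(float)
    if w.sum() <= 0:
        w = np.ones(len(coords))
    mean = np.average(coords, axis=0, weights=w)
    centered = coords - mean
    cov = (centered.T * w) @ centered / w.sum()
    # moment ellipse: add the 1/12 variance of a unit pixel
    cov += np.eye(2) / 12.0
    evals = np.linalg.eigvalsh(cov)
    if evals[-1] <= 0:
        return 1.0
    return float(np.sqrt(max(evals[0], 0.0) / evals[-1]))


def _major_axis_vector(mask: np.ndarray) -> np.ndarray:
    coords = np.argwhere(mask).astype(float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    return evecs[:, -1]


def measure_features(image: CellImage, mask: CellMask) -> FeatureVector:
    """Compute the morphology/intensity feature vector for one masked cell."""
    m = mask.mask
    if m.shape != image.shape:
        raise AlignmentError(f"mask shape {m.shape} != image shape {image.shape}")
    cal = image.calibration

    rows, cols = np.nonzero(m)
    height = (rows.max() - rows.min() + 1) * cal
    width = (cols.max() - cols.min() + 1) * cal
    diameter = (width + height) / 2.0
    area = m.sum() * cal * cal
    perimeter = float(measure.perimeter(m)) * cal

    intensity = image.channels.get("bf")
    weights = intensity if intensity is not None else np.ones_like(m, dtype=float)
    aspect_ratio = min(max(_weighted_axis_ratio(m, np.asarray(weights, float)), 1e-6), 1.0)

    boundary = mask.boundary()
    bc = np.argwhere(boundary).astype(float)
    centroid = np.argwhere(m).mean(axis=0)
    dists = np.linalg.norm(bc - centroid, axis=1)
    spread = dists.std()
    if spread <= 0 or dists.mean() / spread > CIRCULARITY_CAP:
        circularity = CIRCULARITY_CAP
    else:
        circularity = float(dists.mean() / spread)

    # Smooth single-pixel boundary raggedness before skeletonizing: spurs from
    # ragged edges would otherwise drive the min-thickness to ~1 px, while a
    # genuine aggregate neck is much wider than the smoothing radius.
    footprint = morphology.disk(2)
    smooth = morphology.opening(morphology.closing(m, footprint), footprint)
    if not smooth.any():
        smooth = m
    skel = morphology.skeletonize(smooth)
    edt = ndimage.distance_transform_edt(smooth)
    if skel.any():
        thickness = 2.0 * float(edt[skel].min()) * cal
    else:  # tiny masks can skeletonize to nothing; fall back to max inradius
        thickness = 2.0 * float(edt.max()) * cal
    axis = _major_axis_vector(m)
    proj = np.argwhere(m).astype(float) @ axis
    length = (proj.max() - proj.min() + 1.0) * cal
    shape_ratio = float(np.clip(thickness / length, 1e-6, 1.0))

    means = {
        name: float(np.asarray(ch, float)[m].mean()) for name, ch in image.channels.items()
    }
    return FeatureVector(
        area=float(area),
        perimeter=perimeter,
        width=float(width),
        height=float(height),
        diameter=float(diameter),
        aspect_ratio=float(aspect_ratio),
        circularity=float(circularity),
        shape_ratio=shape_ratio,
        channel_means=means,
    )
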