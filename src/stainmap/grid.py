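"""Registration, analysis-square grids, and overlap-based labeling.

A paired IHC section is registered to its H&E section by a rigid
transform (translation + rotation); pathologist-style annotations (cancer
regions carrying a Gleason score, and negative/artifact regions) are
transferred between frames through that transform; a virtual grid of
analysis squares (1,000 x 1,000 px by default, 0.25 mm^2 at 0.5 um/px) is
laid over the slide; and each square is labeled cancer/benign or excluded
from its fractional overlap with the annotation masks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, rescale, warp

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "AnnotationRegion",
    "AnalysisSquare",
    "GLEASON_VOCABULARY",
    "estimate_rigid",
    "transfer_annotations",
    "apply_transform_to_image",
    "generate_grid",
    "label_squares",
    "square_area_mm2",
]

#: Gleason scores appearing in the cohort, plus an explicit escape hatch.
GLEASON_VOCABULARY = ("3 + 3", "3 + 4", "4 + 3", "4 + 4", "4 + 5", "5 + 4", "other")


class RegistrationError(RuntimeError):
    """Registration cannot be computed (e.g. constant image)."""


@dataclass(frozen=True)
class RigidTransform:
    """Rigid misalignment of the moving (IHC) frame relative to the fixed
    (H&E) frame.

    A fixed-frame point ``p`` maps to the moving-frame point
    ``T(p) = R(theta) (p - c) + c + t`` where ``c`` is the rotation center
    (image center by convention), ``t = (tx, ty)`` in pixels (x = column,
    y = row) and ``theta`` is in degrees, counter-clockwise. Resampling the
    moving image through ``T`` (see :func:`apply_transform_to_image`)
    realigns it to the fixed frame.
    """

    tx: float
    ty: float
    theta: float
    center: tuple[float, float] = (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix of the point map ``p -> T(p)``."""
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        cx, cy = self.center
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
        post = np.array([[1, 0, cx + self.tx], [0, 1, cy + self.ty], [0, 0, 1]], dtype=float)
        return post @ rot @ pre

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(N, 2)`` array of (x, y) points through the transform."""
        pts = np.asarray(points, dtype=float)
        homo = np.column_stack([pts, np.ones(len(pts))])
        return (homo @ self.matrix().T)[:, :2]

    def inverse(self) -> "RigidTransform":
        """The inverse rigid transform (same rotation center)."""
        th = math.radians(-self.theta)
        c, s = math.cos(th), math.sin(th)
        # T^-1(p) = R(-theta)(p - c - t) + c
        tx, ty = self.tx, self.ty
        inv_tx = -(c * tx - s * ty)
        inv_ty = -(s * tx + c * ty)
        return RigidTransform(inv_tx, inv_ty, -self.theta, self.center)


def apply_transform_to_image(moving: np.ndarray, transform: RigidTransform,
                             cval: float = 255.0, order: int = 1) -> np.ndarray:
    """Resample ``moving`` through ``transform`` into the fixed frame.

    The output at fixed-frame pixel ``p`` samples ``moving`` at ``T(p)``.
    Works on 2-D or ``(H, W, 3)`` rasters; out-of-frame pixels get ``cval``
    (white glass by default). Output is float.
    """
    tf = AffineTransform(matrix=transform.matrix())
    return warp(np.asarray(moving, dtype=float), tf, order=order,
                cval=cval, preserve_range=True, mode="constant")


@dataclass(frozen=True)
class AnnotationRegion:
    """A slide-level annotation polygon in H&E-frame pixel coordinates."""

    geometry: Polygon
    kind: str  # "cancer" | "negative"
    gleason: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cancer", "negative"):
            raise ValueError(f"annotation kind must be 'cancer' or 'negative', got {self.kind!r}")
        if not self.geometry.is_valid:
            raise ValueError("annotation polygon is invalid (self-intersecting?)")
        if self.kind == "cancer":
            if self.gleason is None:
                raise ValueError("cancer annotations require a Gleason score")
            if self.gleason not in GLEASON_VOCABULARY:
                raise ValueError(f"unknown Gleason score {self.gleason!r}")
        elif self.gleason is not None:
            raise ValueError("negative annotations must not carry a Gleason score")


@dataclass
class AnalysisSquare:
    """One grid cell: 0-based, half-open pixel bounds ``(x0, y0, x1, y1)``."""

    row: int
    col: int
    bounds: tuple[int, int, int, int]
    label: str | None = None          # "cancer" | "benign" once labeled
    gleason: str | None = None
    cancer_overlap: float = 0.0
    negative_overlap: float = 0.0
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def square_id(self) -> str:
        return f"r{self.row}c{self.col}"

    @property
    def side_px(self) -> int:
        return self.bounds[2] - self.bounds[0]

    def crop(self, image: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.bounds
        if x0 < 0 or y0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
            raise IndexError(f"square {self.square_id} bounds {self.bounds} exceed "
                             f"image shape {image.shape[:2]}")
        return image[y0:y1, x0:x1]


def square_area_mm2(square_px: int = 1000, um_per_px: float = 0.5) -> float:
    """Physical area of one analysis square in mm^2."""
    side_mm = square_px * um_per_px / 1000.0
    return side_mm * side_mm


def generate_grid(image_width: int, image_height: int, square_px: int = 1000) -> list[AnalysisSquare]:
    """Tile the image with non-overlapping squares from the origin.

    Partial squares at the right/bottom edges are dropped. Returns an
    empty list (with a warning) if the image is smaller than one square.
    """
    if square_px <= 0:
        raise ValueError("square_px must be positive")
    n_cols = image_width // square_px
    n_rows = image_height // square_px
    if n_cols == 0 or n_rows == 0:
        logger.warning("image %dx%d smaller than one %d-px analysis square; empty grid",
                       image_width, image_height, square_px)
        return []
    return [
        AnalysisSquare(row=r, col=c,
                       bounds=(c * square_px, r * square_px,
                               (c + 1) * square_px, (r + 1) * square_px))
        for r in range(n_rows) for c in range(n_cols)
    ]


def _luminance(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr @ np.array([0.2126, 0.7152, 0.0722])
    return arr


def _translation_at_angle(fixed: np.ndarray, moving: np.ndarray, theta: float,
                          center: tuple[float, float]) -> tuple[float, float, float]:
    """Best translation (and registration error) after derotating by theta."""
    derot = apply_transform_to_image(moving, RigidTransform(0.0, 0.0, theta, center),
                                     cval=float(fixed.mean()))
    shift, error, _ = phase_cross_correlation(fixed, derot, upsample_factor=10,
                                              normalization=None)
    # phase_cross_correlation returns the (row, col) shift that moves
    # `derot` onto `fixed`; our tx/ty are the displacement of the moving
    # content, i.e. the negated shift in (x, y) order.
    return -shift[1], -shift[0], float(error)


def estimate_rigid(fixed: np.ndarray, moving: np.ndarray,
                   theta_range: tuple[float, float] = (-5.0, 5.0),
                   theta_step: float = 0.5,
                   refine_step: float = 0.05,
                   downsample: int = 4) -> RigidTransform:
    """Estimate the rigid misalignment of ``moving`` relative to ``fixed``.

    Exhaustive rotation sweep with FFT-based translation search at each
    angle, run coarse-to-fine: a coarse sweep on downsampled luminance
    images followed by a fine sweep around the best angle at full
    resolution. Set ``theta_step <= 0`` to disable the rotation search
    (pure translation).
    """
    fixed_l = _luminance(fixed)
    moving_l = _luminance(moving)
    if fixed_l.shape != moving_l.shape:
        raise RegistrationError("fixed and moving images must have identical shapes")
    if np.ptp(fixed_l) == 0 or np.ptp(moving_l) == 0:
        raise RegistrationError("cannot register constant (featureless) images")

    center = ((fixed_l.shape[1] - 1) / 2.0, (fixed_l.shape[0] - 1) / 2.0)

    if theta_step <= 0:
        angles = [0.0]
    else:
        lo, hi = theta_range
        angles = list(np.arange(lo, hi + theta_step / 2, theta_step))

    def _downsampled(factor: int):
        if factor <= 1:
            return fixed_l, moving_l, center
        scale = 1.0 / factor
        f = rescale(fixed_l, scale, anti_aliasing=True)
        m = rescale(moving_l, scale, anti_aliasing=True)
        return f, m, ((f.shape[1] - 1) / 2.0, (f.shape[0] - 1) / 2.0)

    fixed_small, moving_small, small_center = _downsampled(downsample)
    best_theta, best_err = 0.0, np.inf
    for theta in angles:
        _, _, err = _translation_at_angle(fixed_small, moving_small, theta, small_center)
        if err < best_err:
            best_theta, best_err = theta, err

    if theta_step > 0 and refine_step > 0:
        # refine the rotation at half resolution; translation is re-estimated
        # at full resolution below, so only the angle matters here
        fixed_mid, moving_mid, mid_center = _downsampled(max(1, downsample // 2))
        fine = np.arange(best_theta - theta_step, best_theta + theta_step + refine_step / 2,
                         refine_step)
        best_err = np.inf
        for theta in fine:
            _, _, err = _translation_at_angle(fixed_mid, moving_mid, float(theta), mid_center)
            if err < best_err:
                best_theta, best_err = float(theta), err

    tx, ty, _ = _translation_at_angle(fixed_l, moving_l, best_theta, center)
    return RigidTransform(tx=tx, ty=ty, theta=best_theta, center=center)


def transfer_annotations(regions: Sequence[AnnotationRegion],
                         transform: RigidTransform) -> list[AnnotationRegion]:
    """Map annotation geometry through a rigid transform, preserving labels."""
    matrix = transform.matrix()
    # shapely affine_transform takes [a, b, d, e, xoff, yoff]
    coeffs = [matrix[0, 0], matrix[0, 1], matrix[1, 0], matrix[1, 1],
              matrix[0, 2], matrix[1, 2]]
    return [replace(r, geometry=affinity.affine_transform(r.geometry, coeffs))
            for r in regions]


def rasterize_regions(regions: Sequence[AnnotationRegion],
                      shape: tuple[int, int]) -> np.ndarray:
    """Label raster of regions (0 = background, i+1 = regions[i]).

    Later regions overwrite earlier ones where polygons overlap.
    """
    out = np.zeros(shape, dtype=np.int32)
    for i, region in enumerate(regions):
        coords = np.asarray(region.geometry.exterior.coords)
        # half-pixel shift: a pixel belongs to the region iff its center
        # lies inside the polygon, so a box [0,100)x[0,75) covers exactly
        # 100 x 75 pixels
        ys, xs = draw_polygon(coords[:, 1] - 0.5, coords[:, 0] - 0.5, shape=shape)
        out[ys, xs] = i + 1
    return out


def _per_square_fraction(mask: np.ndarray, square: AnalysisSquare) -> float:
    x0, y0, x1, y1 = square.bounds
    sub = mask[y0:y1, x0:x1]
    return float(sub.mean()) if sub.size else 0.0


_GRADE_ORDER = {gs: i for i, gs in enumerate(GLEASON_VOCABULARY)}


def label_squares(grid: Iterable[AnalysisSquare],
                  cancer_regions: Sequence[AnnotationRegion],
                  negative_regions: Sequence[AnnotationRegion],
                  image_shape: tuple[int, int],
                  cancer_thresh: float = 0.75,
                  negative_thresh: float = 0.75) -> list[AnalysisSquare]:
    """Label every square cancer/benign and flag negative-overlap exclusions.

    A square is labeled cancer when the fraction of its area inside the
    union of cancer regions is at least ``cancer_thresh`` (it inherits the
    Gleason score of the region contributing the largest overlap; ties go
    to the higher grade). A square is excluded (reason
    ``"negative-overlap"``) when its overlap with the union of negative
    regions is at least ``negative_thresh``; exclusion takes precedence
    over labeling. Overlaps are computed on full-resolution rasterized
    masks.
    """
    if not (0 < cancer_thresh <= 1 and 0 < negative_thresh <= 1):
        raise ValueError("overlap thresholds must lie in (0, 1]")
    shape = tuple(image_shape)

    region_masks = [rasterize_regions([r], shape).astype(bool) for r in cancer_regions]
    cancer_union = np.zeros(shape, dtype=bool)
    for m in region_masks:
        cancer_union |= m
    negative_union = np.zeros(shape, dtype=bool)
    for r in negative_regions:
        negative_union |= rasterize_regions([r], shape).astype(bool)

    labeled = []
    for square in grid:
        sq = replace(square) if isinstance(square, AnalysisSquare) else square
        sq.cancer_overlap = _per_square_fraction(cancer_union, sq)
        sq.negative_overlap = _per_square_fraction(negative_union, sq)
        if sq.negative_overlap >= negative_thresh:
            sq.excluded = True
            sq.exclusion_reason = "negative-overlap"
            sq.label = None
            sq.gleason = None
            logger.info("square %s excluded: negative overlap %.3f", sq.square_id,
                        sq.negative_overlap)
        elif sq.cancer_overlap >= cancer_thresh:
            sq.label = "cancer"
            overlaps = [(_per_square_fraction(m, sq), _GRADE_ORDER.get(r.gleason, -1), r.gleason)
                        for m, r in zip(region_masks, cancer_regions)]
            overlaps.sort(key=lambda t: (t[0], t[1]))
            best = overlaps[-1]
            ties = [o for o in overlaps if o[0] == best[0]]
            if len(ties) > 1:
                logger.info("square %s: Gleason tie at overlap %.3f resolved to %r",
                            sq.square_id, best[0], best[2])
            sq.gleason = best[2]
        else:
            sq.label = "benign"
            sq.gleason = None
        labeled.append(sq)
    return labeled
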