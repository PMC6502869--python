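"""Colorimetric quantification of brightfield histology tiles.

Three algorithms operate on 8-bit RGB tiles:

* **Positive Pixel Count (PPC)** — the fraction of pixels falling inside a
  configured hue/saturation/brightness box, used on H&E tiles to estimate
  the area occupied by nuclei, cytoplasm and stroma.
* **Color Deconvolution (CD)** — per-pixel unmixing of stain optical
  densities into Fast Red (AMACR), DAB (HMWCK+p63) and hematoxylin
  concentrations via the Beer–Lambert law, used on IHC tiles.
* **Co-expression (CE)** — the fraction of pixels positive for exactly one
  of the two chromogens (red XOR brown), which discounts double-stained
  debris such as corpora amylacea.

Optical density is defined channel-wise as ``OD_c = -log10(I_c / I0)`` with
white reference ``I0`` (default 255), so OD is linear in stain amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "StainVector",
    "StainMatrix",
    "HSBRange",
    "PPCConfig",
    "CDConfig",
    "FAST_RED",
    "DAB",
    "HEMATOXYLIN",
    "DEFAULT_STAIN_MATRIX",
    "STAIN_ORDER",
    "rgb_to_od",
    "od_to_rgb",
    "sample_stain_vector",
    "deconvolve",
    "forward_mix",
    "rgb_to_hsb",
    "positive_pixel_percent",
    "cd_quantify",
    "ce_quantify",
]

#: Stain channel order used everywhere concentrations appear as triples.
STAIN_ORDER: tuple[str, str, str] = ("red", "brown", "blue")


class ColorimetryError(ValueError):
    """Invalid colorimetry configuration or input."""


@dataclass(frozen=True)
class StainVector:
    """A stain's RGB optical-density signature (unitless OD per channel)."""

    name: str
    od: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.od, dtype=float)
        if arr.shape != (3,):
            raise ColorimetryError(f"stain vector must have 3 components, got {arr.shape}")
        if np.any(arr < 0):
            raise ColorimetryError(f"stain vector {self.name!r} has negative OD components")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.od, dtype=float)

    @property
    def unit(self) -> np.ndarray:
        """The vector scaled to unit Euclidean length."""
        arr = self.array
        norm = np.linalg.norm(arr)
        if norm == 0:
            raise ColorimetryError(f"stain vector {self.name!r} is all-zero; "
                                   "cannot normalize")
        return arr / norm


# Stain OD vectors measured on singly-stained control slides.
FAST_RED = StainVector("red", (0.283, 0.949, 0.757))
DAB = StainVector("brown", (0.461, 0.826, 1.0))
HEMATOXYLIN = StainVector("blue", (0.21, 0.276, 0.176))


@dataclass(frozen=True)
class StainMatrix:
    """Three stain vectors, their unit-norm basis and its inverse.

    Rows of ``normalized_basis`` are the unit stain vectors in
    :data:`STAIN_ORDER`; a pixel with concentrations ``c`` (OD units along
    each basis direction) has optical density ``od = c @ normalized_basis``,
    and deconvolution applies ``inverse`` from the right.
    """

    vectors: tuple[StainVector, StainVector, StainVector]
    normalized_basis: np.ndarray = field(init=False, repr=False, compare=False)
    inverse: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.vectors) != 3:
            raise ColorimetryError("StainMatrix requires exactly three stain vectors")
        basis = np.vstack([v.unit for v in self.vectors])
        cond = np.linalg.cond(basis)
        if not np.isfinite(cond) or cond > 1e8:
            raise ColorimetryError(f"stain basis is singular or near-singular (cond={cond:.3g})")
        inverse = np.linalg.inv(basis)
        if not np.allclose(basis @ inverse, np.eye(3), atol=1e-10):
            raise ColorimetryError("stain basis inversion failed the identity check")
        object.__setattr__(self, "normalized_basis", basis)
        object.__setattr__(self, "inverse", inverse)

    @property
    def names(self) -> tuple[str, str, str]:
        return tuple(v.name for v in self.vectors)  # type: ignore[return-value]

    def index(self, stain: str) -> int:
        try:
            return self.names.index(stain)
        except ValueError as exc:
            raise ColorimetryError(f"unknown stain {stain!r}; matrix has {self.names}") from exc


DEFAULT_STAIN_MATRIX = StainMatrix((FAST_RED, DAB, HEMATOXYLIN))


def rgb_to_od(pixel_rgb: np.ndarray | Sequence[float], i0: float = 255.0) -> np.ndarray:
    """Convert RGB intensities to optical density, ``-log10(max(I,1)/i0)``.

    Accepts a single triple or an ``(..., 3)`` raster. Intensities are
    clamped below at 1 so fully dark pixels map to a finite OD.
    """
    if i0 <= 0:
        raise ColorimetryError(f"white reference i0 must be positive, got {i0}")
    intensities = np.asarray(pixel_rgb, dtype=float)
    return -np.log10(np.maximum(intensities, 1.0) / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od` (float output in ``[0, i0]``, not quantized)."""
    if i0 <= 0:
        raise ColorimetryError(f"white reference i0 must be positive, got {i0}")
    return i0 * np.power(10.0, -np.asarray(od, dtype=float))


def forward_mix(concentrations: np.ndarray, matrix: StainMatrix = DEFAULT_STAIN_MATRIX,
                i0: float = 255.0) -> np.ndarray:
    """Render stain concentrations to RGB intensities (Beer–Lambert forward
    model): ``I_c = i0 * 10^-(sum_s conc_s * basis_{s,c})``. Float output."""
    conc = np.asarray(concentrations, dtype=float)
    od = conc @ matrix.normalized_basis
    return od_to_rgb(od, i0=i0)


def sample_stain_vector(pixels: np.ndarray, i0: float = 255.0, name: str = "sampled") -> StainVector:
    """Estimate a stain vector as the mean RGB OD of pixels from a
    singly-stained control region."""
    arr = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if arr.shape[0] == 0:
        raise ColorimetryError("cannot sample a stain vector from an empty pixel set")
    mean_od = rgb_to_od(arr, i0=i0).mean(axis=0)
    return StainVector(name, tuple(mean_od))


def deconvolve(od: np.ndarray, matrix: StainMatrix = DEFAULT_STAIN_MATRIX) -> np.ndarray:
    """Unmix optical densities into per-stain concentrations.

    ``od`` may be a triple or an ``(..., 3)`` raster. Negative unmixed
    concentrations (out-of-gamut colors) are clipped to zero.
    """
    od_arr = np.asarray(od, dtype=float)
    conc = od_arr @ matrix.inverse
    return np.clip(conc, 0.0, None)


def rgb_to_hsb(pixel_rgb: np.ndarray | Sequence[float]) -> np.ndarray:
    """Convert 8-bit RGB to (hue degrees in [0,360), saturation, brightness).

    Standard HSV convention; achromatic pixels get hue 0.
    """
    arr = np.asarray(pixel_rgb, dtype=float)
    hsv = rgb2hsv(arr.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
    hsv[:, 0] *= 360.0
    return hsv.reshape(arr.shape)


@dataclass(frozen=True)
class HSBRange:
    """An axis-aligned box in HSB space; the hue interval is modular.

    ``hue_lo > hue_hi`` denotes an interval wrapping through 0/360.
    Bounds are inclusive.
    """

    hue_lo: float
    hue_hi: float
    sat_lo: float
    sat_hi: float
    bri_lo: float
    bri_hi: float

    def __post_init__(self) -> None:
        for h in (self.hue_lo, self.hue_hi):
            if not (0.0 <= h < 360.0):
                raise ColorimetryError(f"hue bounds must lie in [0, 360), got {h}")
        for lo, hi, what in ((self.sat_lo, self.sat_hi, "saturation"),
                             (self.bri_lo, self.bri_hi, "brightness")):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ColorimetryError(f"{what} bounds must satisfy 0 <= lo <= hi <= 1")

    def _hue_mask(self, hue: np.ndarray) -> np.ndarray:
        if self.hue_lo <= self.hue_hi:
            return (hue >= self.hue_lo) & (hue <= self.hue_hi)
        return (hue >= self.hue_lo) | (hue <= self.hue_hi)

    def contains(self, hsb: np.ndarray) -> np.ndarray:
        """Boolean mask for an ``(..., 3)`` HSB array."""
        arr = np.asarray(hsb, dtype=float)
        h, s, b = arr[..., 0], arr[..., 1], arr[..., 2]
        return (self._hue_mask(h)
                & (s >= self.sat_lo) & (s <= self.sat_hi)
                & (b >= self.bri_lo) & (b <= self.bri_hi))

    def hue_arcs(self) -> list[tuple[float, float]]:
        """The hue interval as non-wrapping arcs on [0, 360)."""
        if self.hue_lo <= self.hue_hi:
            return [(self.hue_lo, self.hue_hi)]
        return [(self.hue_lo, 360.0), (0.0, self.hue_hi)]

    def intersects(self, other: "HSBRange") -> bool:
        """Closed-box intersection test (hue handled modularly)."""
        def overlap(a_lo: float, a_hi: float, b_lo: float, b_hi: float) -> bool:
            return a_lo <= b_hi and b_lo <= a_hi

        hue_hit = any(overlap(*a, *b) for a in self.hue_arcs() for b in other.hue_arcs())
        return (hue_hit
                and overlap(self.sat_lo, self.sat_hi, other.sat_lo, other.sat_hi)
                and overlap(self.bri_lo, self.bri_hi, other.bri_lo, other.bri_hi))


PPC_COMPARTMENTS: tuple[str, str, str] = ("nuclei", "cytoplasm", "stroma")


@dataclass(frozen=True)
class PPCConfig:
    """Per-compartment HSB ranges for one H&E staining batch.

    The three ranges must be pairwise disjoint so that compartment
    percentages sum to at most 100.
    """

    ranges: Mapping[str, HSBRange]
    batch_id: str = "batch1"

    def __post_init__(self) -> None:
        missing = set(PPC_COMPARTMENTS) - set(self.ranges)
        if missing:
            raise ColorimetryError(f"PPC config missing compartments: {sorted(missing)}")
        names = list(self.ranges)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.ranges[a].intersects(self.ranges[b]):
                    raise ColorimetryError(
                        f"PPC ranges for {a!r} and {b!r} overlap in HSB space")


@dataclass(frozen=True)
class CDConfig:
    """Stain matrix plus per-stain positivity thresholds (OD units)."""

    stain_matrix: StainMatrix = DEFAULT_STAIN_MATRIX
    positivity_threshold: Mapping[str, float] = field(
        default_factory=lambda: {"red": 0.15, "brown": 0.15})
    i0: float = 255.0

    def __post_init__(self) -> None:
        for stain, thr in self.positivity_threshold.items():
            self.stain_matrix.index(stain)
            if thr <= 0:
                raise ColorimetryError(f"positivity threshold for {stain!r} must be > 0")


def positive_pixel_percent(tile: np.ndarray, hsb_range: HSBRange) -> float:
    """Percentage of tile pixels inside the HSB box."""
    arr = np.asarray(tile)
    if arr.size == 0:
        raise ColorimetryError("empty tile")
    mask = hsb_range.contains(rgb_to_hsb(arr))
    return 100.0 * float(mask.mean())


def _stain_concentration(tile: np.ndarray, config: CDConfig, stain: str) -> np.ndarray:
    od = rgb_to_od(np.asarray(tile, dtype=float), i0=config.i0)
    conc = deconvolve(od, config.stain_matrix)
    return conc[..., config.stain_matrix.index(stain)]


def cd_quantify(tile: np.ndarray, config: CDConfig, stain: str) -> tuple[float, float, float]:
    """Quantify one chromogen: ``(%Pos, mean OD over positive pixels,
    OD x %Pos)``.

    A pixel is positive when its unmixed concentration for ``stain``
    exceeds the configured threshold; the mean OD is taken over positive
    pixels only (0 when there are none).
    """
    if stain not in config.positivity_threshold:
        raise ColorimetryError(f"no positivity threshold configured for stain {stain!r}")
    conc = _stain_concentration(tile, config, stain)
    pos = conc > config.positivity_threshold[stain]
    pct_pos = 100.0 * float(pos.mean())
    mean_od = float(conc[pos].mean()) if pos.any() else 0.0
    return pct_pos, mean_od, mean_od * pct_pos


def ce_quantify(tile: np.ndarray, config: CDConfig) -> tuple[float, float]:
    """Co-expression percentages ``(%Pos_CE red, %Pos_CE brown)``.

    A pixel counts for a chromogen only if it is positive for that
    chromogen and *not* for the other, so double-stained debris is
    excluded; consequently %Pos_CE <= the CD %Pos for each stain.
    """
    red = _stain_concentration(tile, config, "red") > config.positivity_threshold["red"]
    brown = _stain_concentration(tile, config, "brown") > config.positivity_threshold["brown"]
    ce_red = 100.0 * float((red & ~brown).mean())
    ce_brown = 100.0 * float((brown & ~red).mean())
    return ce_red, ce_brown
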