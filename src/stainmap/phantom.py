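"""Synthetic paired H&E / IHC slide phantoms with exact ground truth.

A phantom emulates one pair of serially-sectioned prostate slides: a grid
of gland clusters drawn on a stromal background, rendered twice through
the forward Beer-Lambert model — once with H&E colors (nuclei purple,
cytoplasm pink, stroma pale pink) and once with IHC chromogens (benign
basal rings brown DAB, malignant epithelium red Fast Red, stroma blue
hematoxylin). The IHC rendering is then displaced by a known rigid
transform, standing in for the section-to-section misalignment that
registration must recover.

Geometry is deliberately simple — elliptical glands with an annular
epithelial band and a central lumen, clustered inside grid-aligned cells —
so that every analysis square has an exact per-pixel class labeling
(glass / stroma / lumen / benign epithelium / malignant epithelium) and a
known % malignant epithelium, and so that squares are cleanly separable
into cancer and benign by the >=75% overlap rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import unary_union

from .colorimetry import StainMatrix, StainVector, DEFAULT_STAIN_MATRIX, od_to_rgb
from .grid import AnalysisSquare, AnnotationRegion, RigidTransform, apply_transform_to_image

__all__ = [
    "PhantomConfig",
    "PhantomPair",
    "render_phantom_pair",
    "truth_percent_malignant",
    "CLASS_GLASS",
    "CLASS_STROMA",
    "CLASS_LUMEN",
    "CLASS_BENIGN_EPI",
    "CLASS_MALIG_EPI",
    "CLASS_NAMES",
]

# Per-pixel ground-truth classes (mutually exclusive).
CLASS_GLASS = 0
CLASS_STROMA = 1
CLASS_LUMEN = 2
CLASS_BENIGN_EPI = 3
CLASS_MALIG_EPI = 4
CLASS_NAMES = {CLASS_GLASS: "glass", CLASS_STROMA: "stroma", CLASS_LUMEN: "lumen",
               CLASS_BENIGN_EPI: "benign_epithelium", CLASS_MALIG_EPI: "malignant_epithelium"}

#: Eosin OD signature used for the H&E rendering of the phantom.
EOSIN = StainVector("eosin", (0.07, 0.99, 0.11))

# Stain concentrations (OD units along each unit basis vector) per tissue
# compartment. IHC order: (red=Fast Red, brown=DAB, blue=hematoxylin).
IHC_CONC = {
    "stroma": (0.0, 0.0, 0.35),
    "benign_epi": (0.0, 0.0, 0.65),
    "malig_epi": (0.8, 0.0, 0.0),
    "basal": (0.0, 0.8, 0.0),
    "artifact": (0.3, 0.3, 0.3),
    "debris": (0.5, 0.5, 0.2),
}
# H&E order: (hematoxylin, eosin).
HE_CONC = {
    "stroma": (0.02, 0.25),
    "cytoplasm": (0.02, 0.60),
    "nuclei": (0.90, 0.10),
}

# Normalized-radius-squared breakpoints of the gland ellipse: lumen core,
# cytoplasmic inner band, nuclear outer band.
_Q_LUMEN = 0.20
_Q_MID = ((math.sqrt(_Q_LUMEN) + 1.0) / 2.0) ** 2


class PhantomConfigError(ValueError):
    """Invalid phantom configuration."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic slide pair.

    Gland clusters occupy cells of side ``cell_px`` aligned with the
    analysis-square grid; the outermost ring of cells is left as clear
    glass. ``n_glands`` glands are grouped into clusters of
    ``glands_per_cluster``; each cluster is malignant with probability
    ``malignant_fraction``. ``rigid_offset`` is the (tx, ty, theta deg)
    misalignment applied to the IHC rendering. ``color_jitter_sd`` is the
    SD of additive Gaussian noise in OD units (stain variability is
    multiplicative in intensity, hence additive in OD).
    """

    width_px: int = 2400
    height_px: int = 1600
    n_glands: int = 120
    malignant_fraction: float = 0.5
    gs_palette: tuple[str, ...] = ("3 + 3", "3 + 4", "4 + 3", "4 + 4", "4 + 5", "5 + 4")
    amacr_dropout: float = 0.0
    artifact_fraction: float = 0.05
    debris_fraction: float = 0.0
    color_jitter_sd: float = 0.02
    rigid_offset: tuple[float, float, float] = (12.0, -7.0, 1.5)
    seed: int = 0
    cell_px: int = 200
    glands_per_cluster: int = 4
    dilation_frac: float = 0.12   # annotation buffer radius as a fraction of cell_px
    i0: float = 255.0

    def __post_init__(self) -> None:
        for name in ("malignant_fraction", "amacr_dropout", "artifact_fraction",
                     "debris_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise PhantomConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.width_px < self.cell_px or self.height_px < self.cell_px:
            raise PhantomConfigError("phantom must cover at least one analysis square")
        if self.n_glands < 0:
            raise PhantomConfigError("n_glands must be non-negative")
        if self.n_glands == 0 and self.malignant_fraction > 0:
            raise PhantomConfigError("malignant_fraction > 0 requires at least one gland")
        if self.glands_per_cluster < 1:
            raise PhantomConfigError("glands_per_cluster must be >= 1")
        if not self.gs_palette:
            raise PhantomConfigError("gs_palette must be non-empty")

    @property
    def n_cells(self) -> tuple[int, int]:
        """(rows, cols) of the cell grid."""
        return self.height_px // self.cell_px, self.width_px // self.cell_px


@dataclass
class PhantomPair:
    """One synthetic H&E / IHC pair with exact ground truth.

    ``he_image`` and ``ihc_image`` are 8-bit RGB; ``ihc_image`` has the
    rigid offset applied. ``he_od`` / ``ihc_od`` are the pre-quantization,
    pre-transform optical-density rasters in the H&E frame (the exact
    forward-model output, kept for sub-quantization verification). All
    truth rasters live in the H&E frame.
    """

    he_image: np.ndarray
    ihc_image: np.ndarray
    he_od: np.ndarray
    ihc_od: np.ndarray
    epithelium_truth: np.ndarray
    cancer_mask: np.ndarray
    negative_mask: np.ndarray
    cancer_regions: list[AnnotationRegion]
    negative_regions: list[AnnotationRegion]
    true_transform: RigidTransform
    config: PhantomConfig
    stain_matrix: StainMatrix = field(default=DEFAULT_STAIN_MATRIX)


def _ellipse_polygon(cx: float, cy: float, a: float, b: float, phi: float,
                     n: int = 48) -> Polygon:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    x = cx + a * np.cos(t) * math.cos(phi) - b * np.sin(t) * math.sin(phi)
    y = cy + a * np.cos(t) * math.sin(phi) + b * np.sin(t) * math.cos(phi)
    return Polygon(np.column_stack([x, y]))


@dataclass
class _Gland:
    cx: float
    cy: float
    a: float
    b: float
    phi: float
    malignant: bool
    amacr_negative: bool


def _paint_gland(gland: _Gland, truth: np.ndarray, basal: np.ndarray,
                 nuclei_band: np.ndarray, cyto_band: np.ndarray) -> None:
    """Rasterize one gland into the class and band rasters."""
    h, w = truth.shape
    r = max(gland.a, gland.b)
    x0, x1 = max(0, int(gland.cx - r - 2)), min(w, int(gland.cx + r + 3))
    y0, y1 = max(0, int(gland.cy - r - 2)), min(h, int(gland.cy + r + 3))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - gland.cx, ys - gland.cy
    c, s = math.cos(gland.phi), math.sin(gland.phi)
    u = (dx * c + dy * s) / gland.a
    v = (-dx * s + dy * c) / gland.b
    q = u * u + v * v

    inside = q <= 1.0
    lumen = q <= _Q_LUMEN
    cyto = inside & (q > _Q_LUMEN) & (q <= _Q_MID)
    nucl = inside & (q > _Q_MID)

    epi_class = CLASS_MALIG_EPI if gland.malignant else CLASS_BENIGN_EPI
    sub = truth[y0:y1, x0:x1]
    sub[cyto | nucl] = epi_class
    sub[lumen] = CLASS_LUMEN
    nuclei_band[y0:y1, x0:x1] |= nucl
    cyto_band[y0:y1, x0:x1] |= cyto

    if not gland.malignant:
        ring_px = 3.0
        factor = (1.0 - ring_px / min(gland.a, gland.b)) ** 2
        basal[y0:y1, x0:x1] |= inside & (q > factor)


def render_phantom_pair(config: PhantomConfig) -> PhantomPair:
    """Render one phantom pair; bit-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    n_rows, n_cols = config.n_cells
    cell = config.cell_px

    # Interior cells (excluding the glass border ring) host tissue.
    interior = [(r, c) for r in range(1, n_rows - 1) for c in range(1, n_cols - 1)]
    if config.n_glands > 0 and not interior:
        raise PhantomConfigError("phantom too small for an interior tissue region")

    truth = np.zeros((h, w), dtype=np.uint8)
    for r, c in interior:
        truth[r * cell:(r + 1) * cell, c * cell:(c + 1) * cell] = CLASS_STROMA

    n_clusters = math.ceil(config.n_glands / config.glands_per_cluster)
    if n_clusters > len(interior):
        raise PhantomConfigError(
            f"{config.n_glands} glands need {n_clusters} cluster cells but only "
            f"{len(interior)} interior cells exist; enlarge the phantom")
    order = rng.permutation(len(interior))
    cluster_cells = [interior[i] for i in order[:n_clusters]]
    free_cells = [interior[i] for i in order[n_clusters:]]

    anchors = [(0.27, 0.27), (0.73, 0.27), (0.27, 0.73), (0.73, 0.73),
               (0.5, 0.5), (0.5, 0.27), (0.27, 0.5), (0.73, 0.5), (0.5, 0.73)]

    basal = np.zeros((h, w), dtype=bool)
    nuclei_band = np.zeros((h, w), dtype=bool)
    cyto_band = np.zeros((h, w), dtype=bool)
    glands: list[_Gland] = []
    cancer_regions: list[AnnotationRegion] = []

    remaining = config.n_glands
    for (r, c) in cluster_cells:
        k = min(config.glands_per_cluster, remaining)
        remaining -= k
        malignant = bool(rng.random() < config.malignant_fraction)
        cell_glands = []
        for j in range(k):
            ax, ay = anchors[j % len(anchors)]
            cx = (c + ax + rng.uniform(-0.03, 0.03)) * cell
            cy = (r + ay + rng.uniform(-0.03, 0.03)) * cell
            a = rng.uniform(0.17, 0.23) * cell
            b = rng.uniform(0.17, 0.23) * cell
            phi = rng.uniform(0, math.pi)
            dropout = malignant and bool(rng.random() < config.amacr_dropout)
            g = _Gland(cx, cy, a, b, phi, malignant, dropout)
            cell_glands.append(g)
            _paint_gland(g, truth, basal, nuclei_band, cyto_band)
        glands.extend(cell_glands)
        if malignant and cell_glands:
            hull = unary_union([_ellipse_polygon(g.cx, g.cy, g.a, g.b, g.phi)
                                for g in cell_glands]).convex_hull
            poly = hull.buffer(config.dilation_frac * cell, quad_segs=8)
            gleason = str(rng.choice(list(config.gs_palette)))
            cancer_regions.append(AnnotationRegion(geometry=poly, kind="cancer",
                                                   gleason=gleason))

    # Negative-annotation artifacts occupy whole gland-free interior cells.
    n_artifacts = int(round(config.artifact_fraction * len(interior)))
    n_artifacts = min(n_artifacts, len(free_cells))
    artifact_cells = free_cells[:n_artifacts]
    negative_mask = np.zeros((h, w), dtype=bool)
    negative_regions: list[AnnotationRegion] = []
    for (r, c) in artifact_cells:
        x0, y0 = c * cell, r * cell
        negative_mask[y0:y0 + cell, x0:x0 + cell] = True
        negative_regions.append(AnnotationRegion(
            geometry=box(x0, y0, x0 + cell, y0 + cell), kind="negative"))

    # Double-stained debris blobs (corpora amylacea stand-in), default off.
    debris = np.zeros((h, w), dtype=bool)
    if config.debris_fraction > 0 and interior:
        target = config.debris_fraction * len(interior) * cell * cell
        radius = 0.05 * cell
        while debris.sum() < target:
            r, c = interior[int(rng.integers(len(interior)))]
            cx = (c + rng.uniform(0.15, 0.85)) * cell
            cy = (r + rng.uniform(0.15, 0.85)) * cell
            ys, xs = np.mgrid[max(0, int(cy - radius - 1)):min(h, int(cy + radius + 2)),
                              max(0, int(cx - radius - 1)):min(w, int(cx + radius + 2))]
            disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
            debris[max(0, int(cy - radius - 1)):min(h, int(cy + radius + 2)),
                   max(0, int(cx - radius - 1)):min(w, int(cx + radius + 2))] |= disk

    # --- Forward rendering -------------------------------------------------
    stroma = truth == CLASS_STROMA
    lumen = truth == CLASS_LUMEN
    benign_epi = truth == CLASS_BENIGN_EPI
    malig_epi = truth == CLASS_MALIG_EPI

    amacr_neg = np.zeros((h, w), dtype=bool)
    for g in glands:
        if g.amacr_negative:
            # re-rasterize the gland interior for the dropout mask
            tmp = np.zeros((h, w), dtype=bool)
            _paint_dropout(g, tmp)
            amacr_neg |= tmp

    ihc_conc = np.zeros((h, w, 3), dtype=float)
    ihc_conc[stroma] = IHC_CONC["stroma"]
    ihc_conc[benign_epi] = IHC_CONC["benign_epi"]
    ihc_conc[malig_epi] = IHC_CONC["malig_epi"]
    ihc_conc[malig_epi & amacr_neg] = IHC_CONC["benign_epi"]
    ihc_conc[basal] = IHC_CONC["basal"]
    ihc_conc[debris & (stroma | lumen)] = IHC_CONC["debris"]
    ihc_conc[negative_mask] = IHC_CONC["artifact"]

    stain_matrix = DEFAULT_STAIN_MATRIX
    ihc_od = ihc_conc @ stain_matrix.normalized_basis

    he_basis = np.vstack([StainVector("hematoxylin", (0.21, 0.276, 0.176)).unit, EOSIN.unit])
    he_conc = np.zeros((h, w, 2), dtype=float)
    he_conc[stroma] = HE_CONC["stroma"]
    he_conc[cyto_band] = HE_CONC["cytoplasm"]
    he_conc[nuclei_band | basal] = HE_CONC["nuclei"]
    he_od = he_conc @ he_basis

    if config.color_jitter_sd > 0:
        he_od = np.clip(he_od + rng.normal(0, config.color_jitter_sd, he_od.shape), 0, None)
        ihc_od = np.clip(ihc_od + rng.normal(0, config.color_jitter_sd, ihc_od.shape), 0, None)

    he_image = np.clip(np.rint(od_to_rgb(he_od, i0=config.i0)), 0, 255).astype(np.uint8)
    ihc_aligned = np.clip(np.rint(od_to_rgb(ihc_od, i0=config.i0)), 0, 255).astype(np.uint8)

    tx, ty, theta = config.rigid_offset
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    true_transform = RigidTransform(tx=tx, ty=ty, theta=theta, center=center)
    if (tx, ty, theta) == (0.0, 0.0, 0.0):
        ihc_image = ihc_aligned.copy()
    else:
        ihc_image = np.clip(np.rint(apply_transform_to_image(
            ihc_aligned, true_transform.inverse(), cval=config.i0)), 0, 255).astype(np.uint8)

    from .grid import rasterize_regions  # local import to avoid cycle at module load
    cancer_mask = rasterize_regions(cancer_regions, (h, w))

    return PhantomPair(
        he_image=he_image, ihc_image=ihc_image, he_od=he_od, ihc_od=ihc_od,
        epithelium_truth=truth, cancer_mask=cancer_mask, negative_mask=negative_mask,
        cancer_regions=cancer_regions, negative_regions=negative_regions,
        true_transform=true_transform, config=config, stain_matrix=stain_matrix,
    )


def _paint_dropout(gland: _Gland, mask: np.ndarray) -> None:
    h, w = mask.shape
    r = max(gland.a, gland.b)
    x0, x1 = max(0, int(gland.cx - r - 2)), min(w, int(gland.cx + r + 3))
    y0, y1 = max(0, int(gland.cy - r - 2)), min(h, int(gland.cy + r + 3))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - gland.cx, ys - gland.cy
    c, s = math.cos(gland.phi), math.sin(gland.phi)
    u = (dx * c + dy * s) / gland.a
    v = (-dx * s + dy * c) / gland.b
    mask[y0:y1, x0:x1] |= (u * u + v * v) <= 1.0


def truth_percent_malignant(pair: PhantomPair, square: AnalysisSquare) -> float:
    """Ground-truth % malignant epithelium inside one analysis square."""
    x0, y0, x1, y1 = square.bounds
    h, w = pair.epithelium_truth.shape
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h or x1 <= x0 or y1 <= y0:
        raise IndexError(f"square bounds {square.bounds} outside raster {h}x{w}")
    sub = pair.epithelium_truth[y0:y1, x0:x1]
    return 100.0 * float((sub == CLASS_MALIG_EPI).mean())
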