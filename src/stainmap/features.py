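"""Per-square predictive features and the unstained-tissue exclusion.

Seven features are computed for every analysis square: three H&E
compartment percentages from positive pixel counting (% nuclei,
% cytoplasm, % stroma) and four IHC chromogen summaries (OD x %Pos for
brown and red from color deconvolution, and the exclusive co-expression
percentages %Pos_CE for brown and red). The derived % unstained
(100 - sum of the H&E percentages) flags squares lying outside the tissue
boundary: squares more than 99% unstained are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .colorimetry import (CDConfig, PPCConfig, cd_quantify, ce_quantify,
                          positive_pixel_percent)
from .grid import AnalysisSquare

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_SETS",
    "extract_features",
    "compute_unstained",
    "apply_unstained_exclusion",
]

#: Canonical feature order; persisted in every feature table header.
FEATURE_NAMES: tuple[str, ...] = (
    "pct_nuclei",
    "pct_cytoplasm",
    "pct_stroma",
    "od_x_pctpos_brown",
    "od_x_pctpos_red",
    "pctpos_ce_brown",
    "pctpos_ce_red",
)

#: Named feature subsets used to train the four regression models.
FEATURE_SETS: Mapping[str, tuple[str, ...]] = {
    "he": FEATURE_NAMES[:3],
    "ihc": FEATURE_NAMES[3:],
    "full_minus_ce": FEATURE_NAMES[:5],
    "full": FEATURE_NAMES,
}


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """The seven predictive features plus % unstained for one square."""

    pct_nuclei: float
    pct_cytoplasm: float
    pct_stroma: float
    od_x_pctpos_brown: float
    od_x_pctpos_red: float
    pctpos_ce_brown: float
    pctpos_ce_red: float
    pct_unstained: float
    square_id: str = ""
    batch_id: str = ""

    def values(self, feature_set: str = "full") -> np.ndarray:
        """Features as an array in canonical order for the named subset."""
        return np.array([getattr(self, name) for name in FEATURE_SETS[feature_set]])


def compute_unstained(pct_nuclei: float, pct_cytoplasm: float, pct_stroma: float,
                      tol: float = 1e-9) -> float:
    """% unstained = 100 - (% nuclei + % cytoplasm + % stroma), floored at 0.

    The three compartment percentages come from disjoint HSB ranges, so
    their sum exceeding 100 indicates a misconfigured PPC.
    """
    total = pct_nuclei + pct_cytoplasm + pct_stroma
    if total > 100.0 + tol:
        raise FeatureError(
            f"PPC percentages sum to {total:.6f} > 100; HSB ranges are not disjoint")
    return max(0.0, 100.0 - total)


def extract_features(he_tile: np.ndarray, ihc_tile: np.ndarray,
                     ppc_config: PPCConfig, cd_config: CDConfig,
                     square_id: str = "", batch_id: str | None = None) -> FeatureVector:
    """Compute the seven features for one registered H&E/IHC tile pair."""
    he = np.asarray(he_tile)
    ihc = np.asarray(ihc_tile)
    if he.shape != ihc.shape:
        raise FeatureError(f"tile shapes differ: H&E {he.shape} vs IHC {ihc.shape}")

    pct_nuclei = positive_pixel_percent(he, ppc_config.ranges["nuclei"])
    pct_cytoplasm = positive_pixel_percent(he, ppc_config.ranges["cytoplasm"])
    pct_stroma = positive_pixel_percent(he, ppc_config.ranges["stroma"])

    _, _, odpct_brown = cd_quantify(ihc, cd_config, "brown")
    _, _, odpct_red = cd_quantify(ihc, cd_config, "red")
    ce_red, ce_brown = ce_quantify(ihc, cd_config)

    return FeatureVector(
        pct_nuclei=pct_nuclei,
        pct_cytoplasm=pct_cytoplasm,
        pct_stroma=pct_stroma,
        od_x_pctpos_brown=odpct_brown,
        od_x_pctpos_red=odpct_red,
        pctpos_ce_brown=ce_brown,
        pctpos_ce_red=ce_red,
        pct_unstained=compute_unstained(pct_nuclei, pct_cytoplasm, pct_stroma),
        square_id=square_id,
        batch_id=batch_id if batch_id is not None else ppc_config.batch_id,
    )


def apply_unstained_exclusion(square: AnalysisSquare, fv: FeatureVector,
                              threshold: float = 99.0) -> AnalysisSquare:
    """Exclude a square whose % unstained strictly exceeds the threshold.

    Such squares lie outside the tissue boundary (clear glass). The
    comparison is strict: exactly 99% unstained is retained.
    """
    if fv.pct_unstained > threshold:
        square.excluded = True
        square.exclusion_reason = "unstained"
        square.label = None
        square.gleason = None
    return square
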