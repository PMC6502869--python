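"""Standard-format I/O: images, GeoJSON annotations, CSV tables, configs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

from .colorimetry import (CDConfig, HSBRange, PPCConfig, StainMatrix, StainVector)
from .features import FEATURE_NAMES, FeatureVector
from .grid import AnalysisSquare, AnnotationRegion

__all__ = [
    "default_ppc_config",
    "default_cd_config",
    "colorimetry_config_to_json",
    "colorimetry_config_from_json",
    "save_image",
    "load_image",
    "regions_to_geojson",
    "regions_from_geojson",
    "squares_to_frame",
    "squares_from_frame",
    "feature_table",
    "config_hash",
]


# HSB boxes matched to the phantom's H&E palette: dark purple nuclei,
# saturated pink cytoplasm, pale pink stroma. Pairwise disjoint (nuclei
# split off by brightness, cytoplasm vs stroma by saturation).
_DEFAULT_PPC_RANGES = {
    "nuclei": HSBRange(230.0, 330.0, 0.15, 1.0, 0.02, 0.55),
    "cytoplasm": HSBRange(280.0, 340.0, 0.52, 1.0, 0.60, 1.0),
    "stroma": HSBRange(280.0, 340.0, 0.08, 0.48, 0.60, 1.0),
}


def default_ppc_config(batch_id: str = "batch1") -> PPCConfig:
    """The stock per-batch PPC configuration for phantom H&E slides."""
    return PPCConfig(ranges=dict(_DEFAULT_PPC_RANGES), batch_id=batch_id)


def default_cd_config() -> CDConfig:
    return CDConfig()


def colorimetry_config_to_json(ppc_by_batch: dict[str, PPCConfig],
                               cd: CDConfig) -> str:
    """Serialize stain vectors, thresholds and per-batch HSB ranges."""
    doc = {
        "stain_vectors": {v.name: list(v.od) for v in cd.stain_matrix.vectors},
        "positivity_threshold": dict(cd.positivity_threshold),
        "i0": cd.i0,
        "ppc_batches": {
            batch: {comp: asdict(r) for comp, r in cfg.ranges.items()}
            for batch, cfg in ppc_by_batch.items()
        },
    }
    return json.dumps(doc, indent=2)


def colorimetry_config_from_json(text: str) -> tuple[dict[str, PPCConfig], CDConfig]:
    doc = json.loads(text)
    vectors = tuple(StainVector(name, tuple(od))
                    for name, od in doc["stain_vectors"].items())
    cd = CDConfig(stain_matrix=StainMatrix(vectors),
                  positivity_threshold=doc["positivity_threshold"],
                  i0=doc.get("i0", 255.0))
    ppc = {
        batch: PPCConfig(ranges={comp: HSBRange(**r) for comp, r in ranges.items()},
                         batch_id=batch)
        for batch, ranges in doc["ppc_batches"].items()
    }
    return ppc, cd


def save_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(image).save(str(path))


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)))


def regions_to_geojson(regions: Sequence[AnnotationRegion]) -> str:
    features = [{
        "type": "Feature",
        "geometry": shapely_mapping(r.geometry),
        "properties": {"kind": r.kind, "gleason": r.gleason},
    } for r in regions]
    return json.dumps({"type": "FeatureCollection", "features": features})


def regions_from_geojson(text: str) -> list[AnnotationRegion]:
    doc = json.loads(text)
    return [AnnotationRegion(geometry=shapely_shape(f["geometry"]),
                             kind=f["properties"]["kind"],
                             gleason=f["properties"].get("gleason"))
            for f in doc["features"]]


def squares_to_frame(squares: Sequence[AnalysisSquare]) -> pd.DataFrame:
    return pd.DataFrame([{
        "row": s.row, "col": s.col,
        "x0": s.bounds[0], "y0": s.bounds[1], "x1": s.bounds[2], "y1": s.bounds[3],
        "label": s.label, "gleason": s.gleason,
        "cancer_overlap": s.cancer_overlap, "negative_overlap": s.negative_overlap,
        "excluded": s.excluded, "exclusion_reason": s.exclusion_reason,
    } for s in squares])


def squares_from_frame(frame: pd.DataFrame) -> list[AnalysisSquare]:
    out = []
    for rec in frame.to_dict("records"):
        sq = AnalysisSquare(
            row=int(rec["row"]), col=int(rec["col"]),
            bounds=(int(rec["x0"]), int(rec["y0"]), int(rec["x1"]), int(rec["y1"])),
            label=rec["label"] if isinstance(rec["label"], str) else None,
            gleason=rec["gleason"] if isinstance(rec["gleason"], str) else None,
            cancer_overlap=float(rec["cancer_overlap"]),
            negative_overlap=float(rec["negative_overlap"]),
            excluded=bool(rec["excluded"]),
            exclusion_reason=(rec["exclusion_reason"]
                              if isinstance(rec["exclusion_reason"], str) else None),
        )
        out.append(sq)
    return out


def feature_table(squares: Sequence[AnalysisSquare],
                  vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """One row per square: identity, label, the seven features, exclusions."""
    rows = []
    for sq, fv in zip(squares, vectors):
        row = {"square_id": sq.square_id, "label": sq.label, "gleason": sq.gleason,
               "batch_id": fv.batch_id}
        row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
        row["pct_unstained"] = fv.pct_unstained
        row["excluded"] = sq.excluded
        row["exclusion_reason"] = sq.exclusion_reason
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
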