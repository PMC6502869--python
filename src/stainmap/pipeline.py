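"""End-to-end phantom study: generate paired slides, register, grid,
extract features, train the four regression models, and evaluate.

The study mirrors the real workflow at desk scale: a training cohort of
WSI pairs contributes a fixed number of meticulously-annotated analysis
squares per pair (ground-truth % malignant epithelium from the phantom's
class raster), four elastic-net models (H&E-only, IHC-only, full without
co-expression, full) are tuned by leave-one-pair-out cross-validation,
and the models are scored on a separate test cohort against the >=75%
overlap square labels with ROC / Youden / hierarchical-bootstrap
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, model as en
from .colorimetry import CDConfig, PPCConfig
from .features import FEATURE_NAMES, FEATURE_SETS, apply_unstained_exclusion, extract_features
from .grid import AnalysisSquare, estimate_rigid, generate_grid, label_squares, \
    apply_transform_to_image
from .io import default_cd_config, default_ppc_config
from .phantom import PhantomConfig, PhantomPair, render_phantom_pair, truth_percent_malignant

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "PairResult", "StudyResult", "process_pair",
           "build_training_set", "run_phantom_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of one phantom study."""

    n_train_pairs: int = 10
    n_test_pairs: int = 20
    squares_per_pair: int = 40
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    alpha_grid: tuple[float, ...] = en.DEFAULT_ALPHA_GRID
    rho_grid: tuple[float, ...] = en.DEFAULT_RHO_GRID
    feature_sets: tuple[str, ...] = ("he", "ihc", "full_minus_ce", "full")
    n_boot: int = 1000
    seed: int = 0
    register: bool = True


@dataclass
class PairResult:
    """All per-square artifacts for one processed WSI pair.

    ``pair`` holds the full rasters only while they are needed; the study
    driver drops it after feature extraction (a rendered pair is ~200 MB
    of rasters) and keeps ``phantom_config`` so any pair can be re-rendered
    bit-identically on demand.
    """

    pair_id: str
    phantom_config: PhantomConfig
    image_shape: tuple[int, int]
    squares: list[AnalysisSquare]
    features: pd.DataFrame          # feature_table rows incl. truth_pct column
    pair: PhantomPair | None = None

    @property
    def usable(self) -> pd.DataFrame:
        return self.features[~self.features["excluded"]]


@dataclass
class StudyResult:
    config: StudyConfig
    train_pairs: list[PairResult]
    test_pairs: list[PairResult]
    training_set: en.TrainingSet
    specs: dict[str, en.ElasticNetSpec]
    cv_reports: dict[str, list[dict]]
    test_table: pd.DataFrame        # scores per model + label + group
    summaries: dict[str, evaluation.EvalSummary]
    pvalues: dict[str, float]
    grade_breakdown: pd.DataFrame


def process_pair(pair: PhantomPair, pair_id: str,
                 ppc_config: PPCConfig | None = None,
                 cd_config: CDConfig | None = None,
                 register: bool = True) -> PairResult:
    """Register, grid, label, and extract features for one phantom pair."""
    ppc = ppc_config or default_ppc_config()
    cd = cd_config or default_cd_config()
    cfg = pair.config

    if register:
        transform = estimate_rigid(pair.he_image, pair.ihc_image)
    else:
        transform = pair.true_transform
    ihc_aligned = np.clip(np.rint(apply_transform_to_image(
        pair.ihc_image, transform, cval=cfg.i0)), 0, 255).astype(np.uint8)

    grid = generate_grid(cfg.width_px, cfg.height_px, square_px=cfg.cell_px)
    squares = label_squares(grid, pair.cancer_regions, pair.negative_regions,
                            image_shape=pair.epithelium_truth.shape)

    rows = []
    for sq in squares:
        fv = extract_features(sq.crop(pair.he_image), sq.crop(ihc_aligned),
                              ppc, cd, square_id=sq.square_id)
        apply_unstained_exclusion(sq, fv)
        row = {"pair_id": pair_id, "square_id": sq.square_id, "label": sq.label,
               "gleason": sq.gleason, "batch_id": fv.batch_id}
        row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
        row["pct_unstained"] = fv.pct_unstained
        row["excluded"] = sq.excluded
        row["exclusion_reason"] = sq.exclusion_reason
        row["truth_pct"] = truth_percent_malignant(pair, sq)
        rows.append(row)
    return PairResult(pair_id=pair_id, phantom_config=cfg,
                      image_shape=pair.epithelium_truth.shape,
                      squares=squares, features=pd.DataFrame(rows), pair=pair)


def _render_pairs(config: StudyConfig, n_pairs: int, rng: np.random.Generator,
                  prefix: str) -> list[PairResult]:
    results = []
    for i in range(n_pairs):
        seed = int(rng.integers(0, 2**31 - 1))
        pair = render_phantom_pair(dc_replace(config.phantom, seed=seed))
        pr = process_pair(pair, pair_id=f"{prefix}{i:02d}",
                          register=config.register)
        pr.pair = None   # free ~200 MB of rasters; re-render from config if needed
        results.append(pr)
    return results


def build_training_set(pair_results: Sequence[PairResult], squares_per_pair: int,
                       rng: np.random.Generator,
                       feature_set: str = "full") -> en.TrainingSet:
    """Sample ``squares_per_pair`` usable squares per pair and assemble the
    training matrix with ground-truth % malignant epithelium targets."""
    names = FEATURE_SETS[feature_set]
    frames = []
    for pr in pair_results:
        usable = pr.usable
        if len(usable) < squares_per_pair:
            raise ValueError(f"pair {pr.pair_id} has only {len(usable)} usable squares; "
                             f"{squares_per_pair} requested")
        take = rng.choice(len(usable), size=squares_per_pair, replace=False)
        frames.append(usable.iloc[np.sort(take)])
    table = pd.concat(frames, ignore_index=True)
    return en.TrainingSet(X=table[list(names)].to_numpy(),
                          y=table["truth_pct"].to_numpy(),
                          groups=table["pair_id"].to_numpy(),
                          feature_names=tuple(names))


def _fit_models(full_train: pd.DataFrame, config: StudyConfig
                ) -> tuple[dict[str, en.ElasticNetSpec], dict[str, list[dict]]]:
    specs, reports = {}, {}
    for fset in config.feature_sets:
        names = FEATURE_SETS[fset]
        ts = en.TrainingSet(X=full_train[list(names)].to_numpy(),
                            y=full_train["truth_pct"].to_numpy(),
                            groups=full_train["pair_id"].to_numpy(),
                            feature_names=tuple(names))
        alpha, rho, report = en.select_hyperparameters(
            ts, config.alpha_grid, config.rho_grid, feature_set=fset)
        specs[fset] = en.fit(ts, alpha, rho, feature_set=fset)
        reports[fset] = report
        logger.info("model %s: alpha=%.4g rho=%.2f", fset, alpha, rho)
    return specs, reports


def _score_test(test_pairs: Sequence[PairResult],
                specs: dict[str, en.ElasticNetSpec]) -> pd.DataFrame:
    table = pd.concat([pr.usable for pr in test_pairs], ignore_index=True)
    table = table[table["label"].isin(["cancer", "benign"])].reset_index(drop=True)
    out = table[["pair_id", "square_id", "label", "gleason", "truth_pct"]].copy()
    out["y_true"] = (table["label"] == "cancer").astype(int)
    out.rename(columns={"pair_id": "group"}, inplace=True)
    for fset, spec in specs.items():
        names = FEATURE_SETS[fset]
        out[f"score_{fset}"] = en.predict(spec, table[list(names)].to_numpy())
    return out


def _summarize(test_table: pd.DataFrame, fset: str, n_boot: int,
               seed: int) -> evaluation.EvalSummary:
    scores = test_table[f"score_{fset}"].to_numpy()
    labels = test_table["y_true"].to_numpy()
    curve = evaluation.roc_curve(scores, labels)
    cutoff, sens, spec = evaluation.youden_cutoff(curve)

    def stat_auc(df):
        return evaluation.auc_score(df[f"score_{fset}"].to_numpy(),
                                    df["y_true"].to_numpy())

    def stat_sens(df):
        y = df["y_true"].to_numpy()
        s = df[f"score_{fset}"].to_numpy() >= cutoff
        if not (y == 1).any():
            raise evaluation.SingleClassError("no cancer squares in replicate")
        return float(s[y == 1].mean())

    def stat_spec(df):
        y = df["y_true"].to_numpy()
        s = df[f"score_{fset}"].to_numpy() >= cutoff
        if not (y == 0).any():
            raise evaluation.SingleClassError("no benign squares in replicate")
        return float((~s[y == 0]).mean())

    ci_auc = evaluation.bootstrap_ci(stat_auc, test_table, mode="test",
                                     n_boot=n_boot, seed=seed)
    ci_sens = evaluation.bootstrap_ci(stat_sens, test_table, mode="test",
                                      n_boot=n_boot, seed=seed + 1)
    ci_spec = evaluation.bootstrap_ci(stat_spec, test_table, mode="test",
                                      n_boot=n_boot, seed=seed + 2)
    return evaluation.EvalSummary(auc=curve.auc, cutoff=cutoff, sensitivity=sens,
                                  specificity=spec, ci_auc=ci_auc, ci_sens=ci_sens,
                                  ci_spec=ci_spec, n_boot=n_boot, seed=seed)


def run_phantom_study(config: StudyConfig) -> StudyResult:
    """Run the full study; deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    train_pairs = _render_pairs(config, config.n_train_pairs, rng, prefix="train")
    test_pairs = _render_pairs(config, config.n_test_pairs, rng, prefix="test")

    training_set = build_training_set(train_pairs, config.squares_per_pair, rng)
    full_train = pd.DataFrame({
        "pair_id": training_set.groups,
        "truth_pct": training_set.y,
        **{name: training_set.X[:, i] for i, name in enumerate(FEATURE_NAMES)},
    })
    specs, cv_reports = _fit_models(full_train, config)
    test_table = _score_test(test_pairs, specs)

    summaries = {fset: _summarize(test_table, fset, config.n_boot, config.seed + 100 + i)
                 for i, fset in enumerate(config.feature_sets)}

    pvalues = {}
    if "full" in specs:
        for fset in config.feature_sets:
            if fset == "full":
                continue

            def stat_diff(df, other=fset):
                return (evaluation.auc_score(df["score_full"].to_numpy(),
                                             df["y_true"].to_numpy())
                        - evaluation.auc_score(df[f"score_{other}"].to_numpy(),
                                               df["y_true"].to_numpy()))

            reps = evaluation.bootstrap_replicates(stat_diff, test_table, mode="test",
                                                   n_boot=config.n_boot,
                                                   seed=config.seed + 500)
            pvalues[f"auc_full_vs_{fset}"] = evaluation.pvalue_by_ci_inversion(reps)

    full_summary = summaries.get("full") or next(iter(summaries.values()))
    full_fset = "full" if "full" in summaries else next(iter(summaries))
    breakdown = evaluation.grade_group_breakdown(
        test_table[f"score_{full_fset}"].to_numpy(), full_summary.cutoff,
        test_table["gleason"].tolist(), test_table["y_true"].to_numpy())

    return StudyResult(config=config, train_pairs=train_pairs, test_pairs=test_pairs,
                       training_set=training_set, specs=specs, cv_reports=cv_reports,
                       test_table=test_table, summaries=summaries, pvalues=pvalues,
                       grade_breakdown=breakdown)
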