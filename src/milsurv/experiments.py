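"""Scenario runner: cross-validated, transfer and combined-cohort experiments
for both paradigms ({MIL, patch} x {all-tissue, tumor-only}), plus attention
heatmap export and visualization-case selection."""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datatypes import RiskPrediction, SlideBag, SurvivalRecord
from .errors import (DegenerateGroupsError, HorizonError, NoEventsError,
                     ParameterError)
from .evaluate import (DEFAULT_HORIZONS, cox_hr_binary, harrell_c, ipcw_auc,
                       stratify_quantile, zscore_by_fold)
from .mil import TrainConfig, fit_mil, predict_mil
from .patch import expand_labels, fit_patch_cox, predict_patch
from .prep import select_patches
from .synthetic import Cohort

log = logging.getLogger(__name__)

PARADIGMS = ("mil", "patch")
TISSUE_MODES = ("all_tissue", "tumor_only")
QUANTILES = (0.25, 0.50, 0.75)


@dataclass
class ExperimentReport:
    scenario: str
    paradigm: str
    tissue_mode: str
    seed: int
    cohort_ids: list[str]
    n_slides: int
    pooled_c: float
    hazard_ratios: dict = field(default_factory=dict)   # quantile -> HR or None
    auc_panel: dict = field(default_factory=dict)       # horizon -> AUC or None
    k: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hazard_ratios"] = {str(k): v for k, v in self.hazard_ratios.items()}
        d["auc_panel"] = {str(k): v for k, v in self.auc_panel.items()}
        return d


def _select_cohort_bags(cohort: Cohort, tissue_mode: str) -> list[SlideBag]:
    return [select_patches(bag, tissue_mode) for bag in cohort.bags]


def _fit_predict(paradigm: str, train_bags, train_surv, test_bags,
                 config: TrainConfig) -> list[RiskPrediction]:
    if paradigm == "mil":
        model = fit_mil(train_bags, train_surv, config)
        return predict_mil(model, test_bags)
    if paradigm == "patch":
        scorer = fit_patch_cox(expand_labels(train_bags, train_surv), config)
        return predict_patch(scorer, test_bags)
    raise ParameterError(f"unknown paradigm {paradigm!r}")


def _summarize(preds: list[RiskPrediction], times: np.ndarray, events: np.ndarray,
               horizons=DEFAULT_HORIZONS):
    """Pooled C, quantile HRs and the AUC panel; degenerate stats become None."""
    z = np.array([p.risk_std for p in preds])
    pooled_c = harrell_c(z, times, events)
    hrs: dict[float, float | None] = {}
    for q in QUANTILES:
        try:
            groups = stratify_quantile(z, q)
            hrs[q] = cox_hr_binary(groups, times, events).hazard_ratio
        except (DegenerateGroupsError, NoEventsError, ParameterError):
            hrs[q] = None
    panel: dict[float, float | None] = {}
    for h in horizons:
        try:
            if h >= times.max():
                raise HorizonError(h, "beyond the last observed time")
            panel[float(h)] = ipcw_auc(z, times, events, h)
        except HorizonError:
            panel[float(h)] = None
    return pooled_c, hrs, panel


def _stratified_folds(labels: np.ndarray, events: np.ndarray, k: int, seed: int,
                      max_retries: int = 5):
    """k-fold partition stratified by ``labels``; every training fold must
    contain at least one event. Re-stratifies with a shifted seed on failure."""
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(labels)), labels))
        if all(events[tr].sum() > 0 for tr, _ in folds):
            return folds
    raise NoEventsError(f"could not build {k} folds with events in every training fold")


def run_cv(cohort: Cohort, paradigm: str = "mil", tissue_mode: str = "all_tissue",
           k: int = 5, seed: int = 0, train_config: TrainConfig | None = None):
    """Slide-level k-fold CV (stratified by event status): each slide is
    predicted exactly once, fold-wise z-scored, and pooled into one
    validation set before computing metrics."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    if train_config is None:
        train_config = TrainConfig()
    bags = _select_cohort_bags(cohort, tissue_mode)
    times, events = cohort.times(), cohort.events()
    folds = _stratified_folds(events, events, k, seed)

    pooled: list[RiskPrediction] = []
    for fold_id, (tr, va) in enumerate(folds):
        cfg = dataclasses.replace(train_config, seed=seed * 1009 + fold_id)
        preds = _fit_predict(paradigm, [bags[i] for i in tr],
                             [cohort.survival[i] for i in tr],
                             [bags[i] for i in va], cfg)
        for p in preds:
            p.fold_id = fold_id
        pooled.extend(preds)
        log.info("cv fold %d/%d done (%s/%s)", fold_id + 1, k, paradigm, tissue_mode)

    pooled, _ = zscore_by_fold(pooled)
    by_id = {b.slide_id: i for i, b in enumerate(cohort.bags)}
    order = np.array([by_id[p.slide_id] for p in pooled])
    pooled_c, hrs, panel = _summarize(pooled, times[order], events[order])
    report = ExperimentReport(
        scenario="cv", paradigm=paradigm, tissue_mode=tissue_mode, seed=seed,
        cohort_ids=[cohort.config.name], n_slides=cohort.n_slides, k=k,
        pooled_c=pooled_c, hazard_ratios=hrs, auc_panel=panel)
    return pooled, report


def run_transfer(train_cohort: Cohort, test_cohort: Cohort, paradigm: str = "mil",
                 tissue_mode: str = "all_tissue", seed: int = 0,
                 train_config: TrainConfig | None = None):
    """Fit on the full training cohort, predict the full test cohort, and
    standardize the test predictions as a single fold."""
    if train_cohort.config.embed_dim != test_cohort.config.embed_dim:
        raise ParameterError("embedding dimensions differ between cohorts")
    if train_config is None:
        train_config = TrainConfig()
    cfg = dataclasses.replace(train_config, seed=seed)
    preds = _fit_predict(paradigm,
                         _select_cohort_bags(train_cohort, tissue_mode),
                         train_cohort.survival,
                         _select_cohort_bags(test_cohort, tissue_mode), cfg)
    for p in preds:
        p.fold_id = 0
    preds, _ = zscore_by_fold(preds)
    times, events = test_cohort.times(), test_cohort.events()
    pooled_c, hrs, panel = _summarize(preds, times, events)
    report = ExperimentReport(
        scenario="transfer", paradigm=paradigm, tissue_mode=tissue_mode, seed=seed,
        cohort_ids=[train_cohort.config.name, test_cohort.config.name],
        n_slides=test_cohort.n_slides, pooled_c=pooled_c,
        hazard_ratios=hrs, auc_panel=panel,
        extra={"train_cohort": train_cohort.config.name,
               "test_cohort": test_cohort.config.name})
    return preds, report


def run_combined(cohorts: list[Cohort], paradigm: str = "mil",
                 tissue_mode: str = "all_tissue", k: int = 5, seed: int = 0,
                 train_config: TrainConfig | None = None):
    """Pooled training over several cohorts with cohort-stratified folds;
    metrics are reported per source cohort."""
    if len(cohorts) < 2:
        raise ParameterError("need >= 2 cohorts")
    names = [c.config.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ParameterError("cohort names must be distinct")
    if len({c.config.embed_dim for c in cohorts}) != 1:
        raise ParameterError("embedding dimensions differ between cohorts")
    if train_config is None:
        train_config = TrainConfig()

    bags, survival, cohort_of = [], [], []
    for ci, c in enumerate(cohorts):
        bags.extend(_select_cohort_bags(c, tissue_mode))
        survival.extend(c.survival)
        cohort_of.extend([ci] * c.n_slides)
    cohort_of = np.array(cohort_of)
    times = np.array([s.time for s in survival])
    events = np.array([s.event for s in survival], dtype=int)
    labels = cohort_of * 2 + events
    folds = _stratified_folds(labels, events, k, seed)

    pooled: list[RiskPrediction] = []
    pooled_idx: list[int] = []
    for fold_id, (tr, va) in enumerate(folds):
        cfg = dataclasses.replace(train_config, seed=seed * 1009 + fold_id)
        preds = _fit_predict(paradigm, [bags[i] for i in tr],
                             [survival[i] for i in tr],
                             [bags[i] for i in va], cfg)
        for p in preds:
            p.fold_id = fold_id
        pooled.extend(preds)
        pooled_idx.extend(va.tolist())
    pooled, _ = zscore_by_fold(pooled)
    pooled_idx = np.array(pooled_idx)

    reports: dict[str, ExperimentReport] = {}
    for ci, c in enumerate(cohorts):
        sel = np.flatnonzero(cohort_of[pooled_idx] == ci)
        sub = [pooled[i] for i in sel]
        sub_idx = pooled_idx[sel]
        pooled_c, hrs, panel = _summarize(sub, times[sub_idx], events[sub_idx])
        reports[c.config.name] = ExperimentReport(
            scenario="combined", paradigm=paradigm, tissue_mode=tissue_mode,
            seed=seed, cohort_ids=names, n_slides=c.n_slides, k=k,
            pooled_c=pooled_c, hazard_ratios=hrs, auc_panel=panel,
            extra={"evaluated_cohort": c.config.name})
    return pooled, reports


def select_visualization_cases(predictions: list[RiskPrediction],
                               survival: list[SurvivalRecord],
                               n_low: int = 25, n_high: int = 25):
    """Pick accurately predicted extremes for visualization.

    'Accurate' is operationalized as: low-risk candidates lie below the
    median risk with follow-up beyond the median time; high-risk candidates
    lie above the median risk and died at or before the median time. The
    n_low lowest / n_high highest risks among candidates are returned as
    disjoint id sets.
    """
    if len(predictions) != len(survival):
        raise ParameterError("predictions and survival must be aligned")
    risk = np.array([p.risk_std if p.risk_std is not None else p.risk_raw
                     for p in predictions])
    ids = np.array([p.slide_id for p in predictions], dtype=object)
    times = np.array([s.time for s in survival])
    events = np.array([s.event for s in survival], dtype=int)
    med_r, med_t = np.median(risk), np.median(times)
    low_cand = np.flatnonzero((risk < med_r) & (times > med_t))
    high_cand = np.flatnonzero((risk > med_r) & (events == 1) & (times <= med_t))
    if len(low_cand) < n_low or len(high_cand) < n_high:
        raise ParameterError(
            f"insufficient qualifying cases: {len(low_cand)} low (need {n_low}), "
            f"{len(high_cand)} high (need {n_high})")
    low = low_cand[np.argsort(risk[low_cand], kind="stable")[:n_low]]
    high = high_cand[np.argsort(-risk[high_cand], kind="stable")[:n_high]]
    return list(ids[low]), list(ids[high])


def export_heatmap(bag: SlideBag, weights, path) -> tuple[Path, Path]:
    """Write attention weights as CSV (row, col, weight) and a PNG raster.

    Weights must align with the bag's patches and sum to one.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (bag.n_patches,):
        raise ParameterError(
            f"{len(w)} weights for {bag.n_patches} patches in {bag.slide_id}")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ParameterError(f"attention weights sum to {w.sum():.6f}, expected 1")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"row": bag.coords[:, 0], "col": bag.coords[:, 1], "weight": w})
    df.to_csv(path, index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.full((bag.coords[:, 0].max() + 1, bag.coords[:, 1].max() + 1), np.nan)
    grid[bag.coords[:, 0], bag.coords[:, 1]] = w
    png_path = path.with_suffix(".png")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, cmap="inferno", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="attention")
    ax.set_title(bag.slide_id)
    fig.savefig(png_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path, png_path


def predictions_to_frame(preds: list[RiskPrediction]) -> pd.DataFrame:
    return pd.DataFrame({
        "slide_id": [p.slide_id for p in preds],
        "fold": [p.fold_id for p in preds],
        "risk_raw": [p.risk_raw for p in preds],
        "risk_std": [p.risk_std for p in preds],
    })
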