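"""Patch-level Cox baseline.

Every patch inherits its slide's (time, event) label, a small per-patch
scorer is trained with the Cox objective over instance-level risk sets
(patches treated as independent — a stated approximation), and the slide
risk is the arithmetic mean of its patch risks.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .datatypes import RiskPrediction, SlideBag, SurvivalRecord
from .errors import EmptyBagError, NoComparablePairsError, NoEventsError, ParameterError
from .evaluate import harrell_c
from .mil import TrainConfig, _cox_loss_grad


@dataclass
class PatchInstance:
    slide_id: str
    embedding: np.ndarray
    time: float
    event: int


def expand_labels(bags: list[SlideBag],
                  survival: list[SurvivalRecord]) -> list[PatchInstance]:
    """One instance per patch, carrying the slide's survival label verbatim."""
    if len(bags) != len(survival):
        raise ParameterError("bags and survival must be aligned")
    instances = []
    for bag, rec in zip(bags, survival):
        if bag.n_patches == 0:  # SlideBag already forbids this; belt and braces
            raise EmptyBagError(f"slide {bag.slide_id}: empty bag")
        for k in range(bag.n_patches):
            instances.append(PatchInstance(slide_id=bag.slide_id,
                                           embedding=bag.embeddings[k],
                                           time=rec.time, event=rec.event))
    return instances


@dataclass
class PatchScorer:
    """Two-layer perceptron mapping one patch embedding to a scalar risk."""

    params: dict[str, np.ndarray]
    embed_dim: int
    hidden_dim: int
    history: dict = field(default_factory=dict, repr=False)

    @classmethod
    def init(cls, embed_dim: int, hidden_dim: int,
             rng: np.random.Generator) -> "PatchScorer":
        params = {
            "W1": _nn.xavier_uniform(rng, (embed_dim, hidden_dim), embed_dim, hidden_dim),
            "b1": np.zeros(hidden_dim),
            "w2": _nn.xavier_uniform(rng, (hidden_dim,), hidden_dim, 1),
            "b2": np.zeros(1),
        }
        return cls(params=params, embed_dim=embed_dim, hidden_dim=hidden_dim)

    def forward(self, X: np.ndarray, with_cache: bool = False):
        p = self.params
        H = np.tanh(X @ p["W1"] + p["b1"])
        r = H @ p["w2"] + p["b2"][0]
        if with_cache:
            return r, (X, H)
        return r

    def backward(self, dr: np.ndarray, cache) -> dict[str, np.ndarray]:
        X, H = cache
        p = self.params
        dH = dr[:, None] * p["w2"][None, :]
        dpre = dH * (1.0 - H ** 2)
        return {"w2": H.T @ dr, "b2": np.array([dr.sum()]),
                "W1": X.T @ dpre, "b1": dpre.sum(axis=0)}

    def score_bag(self, bag: SlideBag) -> np.ndarray:
        if bag.embeddings.shape[1] != self.embed_dim:
            raise ParameterError(f"slide {bag.slide_id}: embedding dim mismatch")
        return self.forward(bag.embeddings)

    def save(self, path) -> None:
        np.savez(path, _meta=np.array([self.embed_dim, self.hidden_dim]), **self.params)

    @classmethod
    def load(cls, path) -> "PatchScorer":
        with np.load(Path(path)) as data:
            meta = data["_meta"]
            params = {k: data[k].copy() for k in data.files if k != "_meta"}
        return cls(params=params, embed_dim=int(meta[0]), hidden_dim=int(meta[1]))


def _subsample_instances(instances: list[PatchInstance], cap: int,
                         rng: np.random.Generator) -> list[PatchInstance]:
    by_slide: dict[str, list[int]] = {}
    for i, inst in enumerate(instances):
        by_slide.setdefault(inst.slide_id, []).append(i)
    keep: list[int] = []
    for idx in by_slide.values():
        if len(idx) <= cap:
            keep.extend(idx)
        else:
            keep.extend(rng.choice(idx, size=cap, replace=False).tolist())
    return [instances[i] for i in sorted(keep)]


def fit_patch_cox(instances: list[PatchInstance], config: TrainConfig) -> PatchScorer:
    """Train the per-patch scorer with instance-level Cox risk sets.

    Early stopping monitors slide-level concordance (mean patch risk per
    slide) on an event-stratified 80/20 split of slides; deterministic
    given ``config.seed``. ``config.instance_cap`` optionally subsamples
    patches per slide to bound the risk-set size.
    """
    if not instances:
        raise ParameterError("no instances")
    if sum(i.event for i in instances) == 0:
        raise NoEventsError("no events among instances")
    rng = np.random.default_rng(config.seed)
    if config.instance_cap is not None:
        instances = _subsample_instances(instances, config.instance_cap, rng)

    slide_ids = sorted({i.slide_id for i in instances})
    slide_event = {i.slide_id: i.event for i in instances}
    ev_by_slide = np.array([slide_event[s] for s in slide_ids], dtype=int)
    order = rng.permutation(len(slide_ids))
    val_slides: set[str] = set()
    if len(slide_ids) >= 5:
        for label in (0, 1):
            lab_idx = [i for i in order if ev_by_slide[i] == label]
            n_val = int(round(config.val_fraction * len(lab_idx)))
            val_slides.update(slide_ids[i] for i in lab_idx[:n_val])
    train_inst = [i for i in instances if i.slide_id not in val_slides]
    val_inst = [i for i in instances if i.slide_id in val_slides]
    if sum(i.event for i in train_inst) == 0:
        train_inst, val_inst = instances, []

    def stack(insts):
        X = np.stack([i.embedding for i in insts])
        t = np.array([i.time for i in insts])
        e = np.array([i.event for i in insts], dtype=int)
        sid = [i.slide_id for i in insts]
        return X, t, e, sid

    Xt, tt, et, _ = stack(train_inst)
    model = PatchScorer.init(Xt.shape[1], config.hidden_dim, rng)

    use_val = False
    if val_inst:
        Xv, _, _, sid_v = stack(val_inst)
        v_slides = sorted(set(sid_v))
        v_groups = [np.array([j for j, s in enumerate(sid_v) if s == vs])
                    for vs in v_slides]
        tv = np.array([next(i.time for i in val_inst if i.slide_id == vs)
                       for vs in v_slides])
        evv = np.array([slide_event[vs] for vs in v_slides], dtype=int)
        comp = (tv[:, None] < tv[None, :]) & (evv[:, None] == 1)
        use_val = bool(comp.any())

    opt = _nn.Adam(model.params, lr=config.lr, weight_decay=config.weight_decay)
    best_metric = -math.inf
    best_params = copy.deepcopy(model.params)
    best_loss = math.inf
    loss_checkpoints: list[float] = []
    train_losses: list[float] = []
    stall = 0
    for _ in range(config.epochs):
        r, cache = model.forward(Xt, with_cache=True)
        loss, dr = _cox_loss_grad(r, tt, et)
        dr /= max(int(et.sum()), 1)  # scale by event count: instance sets are large
        opt.step(model.backward(dr, cache))
        train_losses.append(loss)
        if loss < best_loss:
            best_loss = loss
            loss_checkpoints.append(loss)
        if use_val:
            rv = model.forward(Xv)
            slide_risk = np.array([rv[g].mean() for g in v_groups])
            try:
                metric = harrell_c(slide_risk, tv, evv)
            except NoComparablePairsError:
                metric = 0.5
        else:
            metric = -loss
        if metric > best_metric + 1e-9:
            best_metric = metric
            best_params = copy.deepcopy(model.params)
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                break
    model.params = best_params
    model.history = {"train_loss": train_losses, "loss_checkpoints": loss_checkpoints,
                     "monitored": "val_c" if use_val else "train_loss"}
    return model


def slide_risk_mean(patch_risks) -> np.ndarray:
    """Arithmetic mean per slide; ``patch_risks`` is a sequence of per-slide
    risk vectors."""
    means = []
    for r in patch_risks:
        r = np.asarray(r, dtype=float)
        if r.size == 0:
            raise ParameterError("empty patch-risk vector")
        means.append(float(r.mean()))
    return np.array(means)


def predict_patch(scorer: PatchScorer, bags: list[SlideBag]) -> list[RiskPrediction]:
    """Slide-level predictions: mean patch risk per bag."""
    preds = []
    for bag in bags:
        risk = slide_risk_mean([scorer.score_bag(bag)])[0]
        preds.append(RiskPrediction(slide_id=bag.slide_id, fold_id=None,
                                    risk_raw=risk))
    return preds
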