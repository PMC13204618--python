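"""Attention-based multiple-instance survival model with a Cox objective.

Per slide i with patch embeddings x_ik, a learnable transform phi maps each
patch to a hidden feature, a two-layer tanh attention net scores patches,
softmax-normalized weights a_ik pool them into a slide representation
z_i = sum_k a_ik phi(x_ik), and a linear risk head yields the scalar risk
r_i (higher = higher hazard). Training minimizes the negative Cox partial
log-likelihood over whole-fold batches, with early stopping on a held-out
concordance split of the training data.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .datatypes import RiskPrediction, SlideBag, SurvivalRecord
from .errors import NoComparablePairsError, NoEventsError, ParameterError
from .evaluate import harrell_c


# ---------------------------------------------------------------------------
# Cox negative partial log-likelihood (Breslow ties), with gradient
# ---------------------------------------------------------------------------

def _cox_loss_grad(risks: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Loss and d(loss)/d(risks); risk sets are {j: t_j >= t_i}."""
    order = np.argsort(times, kind="stable")
    r, t, e = risks[order], times[order], events[order]
    m = r.max()
    exp_r = np.exp(r - m)
    suffix = np.cumsum(exp_r[::-1])[::-1]          # sum_{j >= k} exp(r_j - m)
    first = np.searchsorted(t, t, side="left")     # first index of each tied time
    ev = e == 1
    loss = -(r[ev].sum() - (np.log(suffix[first][ev]) + m).sum())

    uniq, inv = np.unique(t, return_inverse=True)
    d_u = np.bincount(inv, weights=e.astype(float))
    s_u = suffix[np.searchsorted(t, uniq, side="left")]
    cum = np.cumsum(d_u / s_u)                     # over event times <= t_j
    grad_sorted = -e.astype(float) + exp_r * cum[inv]
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(loss), grad


def cox_npll(risks, times, events) -> float:
    """Negative Cox partial log-likelihood:
    -sum_{i: event} [r_i - log sum_{j: t_j >= t_i} exp(r_j)]
    with Breslow handling of tied event times (log-sum-exp stabilized)."""
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(r) == len(t) == len(e)):
        raise ParameterError("risks, times, events must be aligned")
    if e.sum() == 0:
        raise NoEventsError("no events: partial likelihood undefined")
    return _cox_loss_grad(r, t, e)[0]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 300
    lr: float = 5e-3
    weight_decay: float = 1e-4
    hidden_dim: int = 32
    attn_dim: int = 16
    seed: int = 0
    patience: int = 30
    val_fraction: float = 0.2
    instance_cap: int | None = None  # per-slide patch cap for the patch paradigm

    def __post_init__(self):
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")


@dataclass
class MILModel:
    """Parameters: phi (W1, b1), attention net (V, c, w), risk head (u, b0)."""

    params: dict[str, np.ndarray]
    embed_dim: int
    hidden_dim: int
    attn_dim: int
    history: dict = field(default_factory=dict, repr=False)

    @classmethod
    def init(cls, embed_dim: int, hidden_dim: int, attn_dim: int,
             rng: np.random.Generator) -> "MILModel":
        params = {
            "W1": _nn.xavier_uniform(rng, (embed_dim, hidden_dim), embed_dim, hidden_dim),
            "b1": np.zeros(hidden_dim),
            "V": _nn.xavier_uniform(rng, (hidden_dim, attn_dim), hidden_dim, attn_dim),
            "c": np.zeros(attn_dim),
            "w": _nn.xavier_uniform(rng, (attn_dim,), attn_dim, 1),
            "u": _nn.xavier_uniform(rng, (hidden_dim,), hidden_dim, 1),
            "b0": np.zeros(1),
        }
        return cls(params=params, embed_dim=embed_dim, hidden_dim=hidden_dim,
                   attn_dim=attn_dim)

    def forward_batch(self, X: np.ndarray, mask: np.ndarray, with_cache: bool = False):
        """X (B, N, d) zero-padded, mask (B, N) boolean."""
        p = self.params
        H = np.tanh(X @ p["W1"] + p["b1"])
        T = np.tanh(H @ p["V"] + p["c"])
        s = T @ p["w"]
        s = np.where(mask, s, -np.inf)
        s_max = s.max(axis=1, keepdims=True)
        exp_s = np.where(mask, np.exp(s - s_max), 0.0)
        a = exp_s / exp_s.sum(axis=1, keepdims=True)
        z = (a[:, :, None] * H).sum(axis=1)
        r = z @ p["u"] + p["b0"][0]
        if with_cache:
            return r, (X, mask, H, T, a, z)
        return r, a, z

    def backward_batch(self, dr: np.ndarray, cache) -> dict[str, np.ndarray]:
        X, mask, H, T, a, z = cache
        p = self.params
        grads = {"u": z.T @ dr, "b0": np.array([dr.sum()])}
        dz = dr[:, None] * p["u"][None, :]
        da = np.einsum("bnh,bh->bn", H, dz)
        dH = a[:, :, None] * dz[:, None, :]
        ds = a * (da - (a * da).sum(axis=1, keepdims=True))
        grads["w"] = np.einsum("bnm,bn->m", T, ds)
        dpre_att = ds[:, :, None] * p["w"][None, None, :] * (1.0 - T ** 2)
        dpre_att *= mask[:, :, None]
        grads["V"] = np.einsum("bnh,bnm->hm", H, dpre_att)
        grads["c"] = dpre_att.sum(axis=(0, 1))
        dH += dpre_att @ p["V"].T
        dpre1 = dH * (1.0 - H ** 2) * mask[:, :, None]
        grads["W1"] = np.einsum("bnd,bnh->dh", X, dpre1)
        grads["b1"] = dpre1.sum(axis=(0, 1))
        return grads

    def save(self, path) -> None:
        meta = np.array([self.embed_dim, self.hidden_dim, self.attn_dim])
        np.savez(path, _meta=meta, **self.params)

    @classmethod
    def load(cls, path) -> "MILModel":
        with np.load(Path(path)) as data:
            meta = data["_meta"]
            params = {k: data[k].copy() for k in data.files if k != "_meta"}
        return cls(params=params, embed_dim=int(meta[0]), hidden_dim=int(meta[1]),
                   attn_dim=int(meta[2]))


def mil_forward(bag: SlideBag, model: MILModel):
    """Forward one bag: returns (risk, attention weights, representation)."""
    if bag.embeddings.shape[1] != model.embed_dim:
        raise ParameterError(
            f"bag dim {bag.embeddings.shape[1]} != model dim {model.embed_dim}")
    X = bag.embeddings[None, :, :]
    mask = np.ones((1, bag.n_patches), dtype=bool)
    r, a, z = model.forward_batch(X, mask)
    return float(r[0]), a[0], z[0]


def _pad_bags(bags: list[SlideBag], embed_dim: int):
    n_max = max(b.n_patches for b in bags)
    X = np.zeros((len(bags), n_max, embed_dim))
    mask = np.zeros((len(bags), n_max), dtype=bool)
    for i, b in enumerate(bags):
        if b.embeddings.shape[1] != embed_dim:
            raise ParameterError(f"slide {b.slide_id}: embedding dim mismatch")
        X[i, :b.n_patches] = b.embeddings
        mask[i, :b.n_patches] = True
    return X, mask


def _event_stratified_split(events: np.ndarray, val_fraction: float,
                            rng: np.random.Generator):
    """Indices (train, val) with both outcome strata spread across the split."""
    n = len(events)
    val_idx = []
    for label in np.unique(events):
        idx = np.flatnonzero(events == label)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.extend(idx[:n_val].tolist())
    val_idx = np.array(sorted(val_idx), dtype=int)
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    return train_idx, val_idx


def fit_mil(train_bags: list[SlideBag], train_survival: list[SurvivalRecord],
            config: TrainConfig) -> MILModel:
    """Train end to end on whole-fold batches of the Cox loss.

    An 80/20 event-stratified split of the training data drives early
    stopping on held-out concordance; if the held-out part has no comparable
    pair, the (monitored) training loss is used instead. The best checkpoint
    is restored. Deterministic given ``config.seed``.
    """
    if len(train_bags) < 2:
        raise ParameterError("need >= 2 slides")
    if len(train_bags) != len(train_survival):
        raise ParameterError("bags and survival must be aligned")
    times = np.array([s.time for s in train_survival])
    events = np.array([s.event for s in train_survival], dtype=int)
    if events.sum() == 0:
        raise NoEventsError("no events in the training data")

    rng = np.random.default_rng(config.seed)
    embed_dim = train_bags[0].embeddings.shape[1]
    model = MILModel.init(embed_dim, config.hidden_dim, config.attn_dim, rng)

    tr_idx, va_idx = _event_stratified_split(events, config.val_fraction, rng)
    if len(tr_idx) < 2 or events[tr_idx].sum() == 0:
        tr_idx, va_idx = np.arange(len(train_bags)), np.array([], dtype=int)
    X, mask = _pad_bags(train_bags, embed_dim)
    Xt, mt = X[tr_idx], mask[tr_idx]
    tt, et = times[tr_idx], events[tr_idx]

    use_val = False
    if len(va_idx) >= 2:
        Xv, mv = X[va_idx], mask[va_idx]
        tv, ev = times[va_idx], events[va_idx]
        comp = (tv[:, None] < tv[None, :]) & (ev[:, None] == 1)
        use_val = bool(comp.any())

    opt = _nn.Adam(model.params, lr=config.lr, weight_decay=config.weight_decay)
    best_metric = -math.inf
    best_params = copy.deepcopy(model.params)
    best_loss = math.inf
    loss_checkpoints: list[float] = []
    train_losses: list[float] = []
    val_cs: list[float] = []
    stall = 0
    for _ in range(config.epochs):
        r, cache = model.forward_batch(Xt, mt, with_cache=True)
        loss, dr = _cox_loss_grad(r, tt, et)
        opt.step(model.backward_batch(dr, cache))
        train_losses.append(loss)
        if loss < best_loss:
            best_loss = loss
            loss_checkpoints.append(loss)

        if use_val:
            rv, _, _ = model.forward_batch(Xv, mv)
            try:
                metric = harrell_c(rv, tv, ev)
            except NoComparablePairsError:
                metric = 0.5
            val_cs.append(metric)
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
    model.history = {"train_loss": train_losses, "val_c": val_cs,
                     "loss_checkpoints": loss_checkpoints,
                     "monitored": "val_c" if use_val else "train_loss"}
    return model


def predict_mil(model: MILModel, bags: list[SlideBag]) -> list[RiskPrediction]:
    """One prediction per bag, with attention weights aligned to patch order."""
    preds = []
    for bag in bags:
        r, a, _ = mil_forward(bag, model)
        preds.append(RiskPrediction(slide_id=bag.slide_id, fold_id=None,
                                    risk_raw=r, attention=a))
    return preds


def top_attention_patches(weights, frac: float = 0.10, cap: int = 200) -> np.ndarray:
    """Indices of the top-fraction attention patches, capped.

    k = min(cap, max(1, ceil(frac * N))); ties broken toward the lower index.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ParameterError("weights must be non-empty")
    if not 0.0 < frac <= 1.0:
        raise ParameterError("frac must lie in (0, 1]")
    k = min(cap, max(1, math.ceil(frac * len(w))))
    order = np.argsort(-w, kind="stable")
    return np.sort(order[:k])
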