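"""Patch bookkeeping: tile grids, tumor-area exclusion, patch selection and
the tissue / non-tissue QC classifier.

The QC model is a three-block CNN (12, 24, 24 filters of 5x5, each block
followed by 2x2 max pooling) with a global-average-pool + sigmoid head,
trained with binary cross-entropy.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .datatypes import SlideBag
from .errors import EmptyBagError, EmptyCohortError, ParameterError
from .synthetic import Cohort, TUMOR_CLASSES

PATCH_SIZE_PX = 360
MICRONS_PER_PX_20X = 0.5  # 100 patches of 360 px at 20x <-> 3.24 mm^2
MIN_TUMOR_AREA_MM2 = 3.24


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class TileGrid:
    """Non-overlapping patch grid over a slide; 0-based (row, col), top-left origin."""

    rows: int
    cols: int
    patch_size_px: int = PATCH_SIZE_PX
    microns_per_px: float = MICRONS_PER_PX_20X
    occupied: set = field(default_factory=set)

    def __post_init__(self):
        if self.patch_size_px <= 0:
            raise ParameterError("patch_size_px must be > 0")
        for r, c in self.occupied:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ParameterError(f"occupied cell {(r, c)} outside grid extent")

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols


def build_tile_grid(slide_dims_px: tuple[int, int],
                    patch_size_px: int = PATCH_SIZE_PX,
                    microns_per_px: float = MICRONS_PER_PX_20X) -> TileGrid:
    h, w = slide_dims_px
    if patch_size_px <= 0:
        raise ParameterError("patch_size_px must be > 0")
    if h < patch_size_px or w < patch_size_px:
        raise ParameterError(f"slide {slide_dims_px} smaller than one {patch_size_px}px patch")
    rows, cols = h // patch_size_px, w // patch_size_px
    occupied = {(r, c) for r in range(rows) for c in range(cols)}
    return TileGrid(rows=rows, cols=cols, patch_size_px=patch_size_px,
                    microns_per_px=microns_per_px, occupied=occupied)


def tumor_area_mm2(n_tumor_patches: int,
                   patch_size_px: int = PATCH_SIZE_PX,
                   microns_per_px: float = MICRONS_PER_PX_20X) -> float:
    """Physical tumor area covered by ``n_tumor_patches`` square patches."""
    if n_tumor_patches < 0:
        raise ParameterError("n_tumor_patches must be >= 0")
    if patch_size_px <= 0 or microns_per_px <= 0:
        raise ParameterError("patch_size_px and microns_per_px must be > 0")
    side_um = patch_size_px * microns_per_px
    # multiply before dividing so the 100-patch / 3.24 mm^2 identity is exact
    return n_tumor_patches * side_um ** 2 / 1e6


def count_tumor_patches(bag: SlideBag) -> int:
    return int(np.isin(bag.tissue_class.astype(str), list(TUMOR_CLASSES)).sum())


def filter_slides_by_tumor_area(cohort: Cohort,
                                min_area_mm2: float = MIN_TUMOR_AREA_MM2,
                                patch_size_px: int = PATCH_SIZE_PX,
                                microns_per_px: float = MICRONS_PER_PX_20X) -> Cohort:
    """Drop slides whose tumor patches cover less than ``min_area_mm2``.

    Slide order is preserved; an empty result raises ``EmptyCohortError``.
    """
    keep = [i for i, bag in enumerate(cohort.bags)
            if tumor_area_mm2(count_tumor_patches(bag), patch_size_px,
                              microns_per_px) >= min_area_mm2 - 1e-12]
    if not keep:
        raise EmptyCohortError(
            f"no slide reaches tumor area {min_area_mm2} mm^2")
    return Cohort(
        bags=[cohort.bags[i] for i in keep],
        survival=[cohort.survival[i] for i in keep],
        truth=cohort.truth.iloc[keep].reset_index(drop=True),
        config=cohort.config,
        archetypes=cohort.archetypes,
    )


# ---------------------------------------------------------------------------
# patch selection
# ---------------------------------------------------------------------------

def select_patches(bag: SlideBag, mode: str, qc_model: "QCModel | None" = None,
                   tiles: np.ndarray | None = None) -> SlideBag:
    """Select the patch subset for one analysis paradigm.

    ``tumor_only`` keeps patches labelled as tumor. ``all_tissue`` keeps
    everything; when a fitted ``qc_model`` plus per-patch raster ``tiles``
    (aligned to the bag) are supplied, patches the QC model rejects as
    non-tissue are removed.
    """
    if mode not in ("all_tissue", "tumor_only"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "tumor_only":
        keep = np.isin(bag.tissue_class.astype(str), list(TUMOR_CLASSES))
        if not keep.any():
            raise EmptyBagError(f"slide {bag.slide_id}: no tumor patches")
    else:
        if qc_model is None:
            return bag
        if tiles is None or len(tiles) != bag.n_patches:
            raise ParameterError("all_tissue QC filtering needs one tile per patch")
        keep = qc_model.predict(tiles).astype(bool)
        if not keep.any():
            raise EmptyBagError(f"slide {bag.slide_id}: QC rejected every patch")
    return SlideBag(slide_id=bag.slide_id,
                    embeddings=bag.embeddings[keep],
                    coords=bag.coords[keep],
                    tissue_class=bag.tissue_class[keep],
                    cohort_id=bag.cohort_id)


# ---------------------------------------------------------------------------
# tissue / non-tissue QC classifier
# ---------------------------------------------------------------------------

FILTER_COUNTS = (12, 24, 24)
KERNEL_SIZE = 5
POOL_SIZE = 2


class QCModel:
    """Three conv-pool blocks (12/24/24 filters, 5x5 kernels, 2x2 max pools)
    followed by global average pooling and a single sigmoid unit."""

    filter_counts = FILTER_COUNTS
    kernel_size = KERNEL_SIZE
    pool_size = POOL_SIZE

    def __init__(self, params: dict[str, np.ndarray]):
        self.params = params

    @classmethod
    def init(cls, rng: np.random.Generator) -> "QCModel":
        k = KERNEL_SIZE
        chans = (1,) + FILTER_COUNTS
        params: dict[str, np.ndarray] = {}
        for i, (cin, cout) in enumerate(zip(chans[:-1], chans[1:]), start=1):
            fan_in, fan_out = cin * k * k, cout * k * k
            params[f"c{i}_w"] = _nn.xavier_uniform(rng, (cout, cin, k, k), fan_in, fan_out)
            params[f"c{i}_b"] = np.zeros(cout)
        params["head_w"] = _nn.xavier_uniform(rng, (FILTER_COUNTS[-1],),
                                              FILTER_COUNTS[-1], 1)
        params["head_b"] = np.zeros(1)
        return cls(params)

    def _forward(self, x: np.ndarray, with_cache: bool = False):
        if x.ndim == 3:
            x = x[:, None, :, :]
        caches = []
        h = x
        for i in (1, 2, 3):
            h, ccache = _nn.conv2d_forward(h, self.params[f"c{i}_w"], self.params[f"c{i}_b"])
            relu_mask = h > 0
            h = h * relu_mask
            if min(h.shape[2:]) < POOL_SIZE:
                raise ParameterError("tile too small for the conv/pool stack")
            h, pcache = _nn.maxpool2_forward(h)
            caches.append((ccache, relu_mask, pcache))
        spatial = h.shape[2] * h.shape[3]
        feat = h.mean(axis=(2, 3))                     # (B, 24)
        logit = feat @ self.params["head_w"] + self.params["head_b"][0]
        if with_cache:
            return logit, (caches, feat, h.shape, spatial)
        return logit

    def _backward(self, dlogit: np.ndarray, cache) -> dict[str, np.ndarray]:
        caches, feat, h_shape, spatial = cache
        grads = {"head_w": feat.T @ dlogit, "head_b": np.array([dlogit.sum()])}
        dfeat = dlogit[:, None] * self.params["head_w"][None, :]
        dh = np.broadcast_to(dfeat[:, :, None, None] / spatial, h_shape).copy()
        for i in (3, 2, 1):
            ccache, relu_mask, pcache = caches[i - 1]
            dh = _nn.maxpool2_backward(dh, pcache)
            dh = dh * relu_mask
            dh, dw, db = _nn.conv2d_backward(dh, ccache)
            grads[f"c{i}_w"] = dw
            grads[f"c{i}_b"] = db
        return grads

    def predict_proba(self, tiles: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for start in range(0, len(tiles), batch_size):
            logit = self._forward(np.asarray(tiles[start:start + batch_size], dtype=float))
            probs.append(_nn.sigmoid(logit))
        return np.concatenate(probs)

    def predict(self, tiles: np.ndarray) -> np.ndarray:
        """1 = tissue, 0 = non-tissue (threshold 0.5)."""
        return (self.predict_proba(tiles) >= 0.5).astype(int)

    def save(self, path) -> None:
        np.savez(path, **self.params)

    @classmethod
    def load(cls, path) -> "QCModel":
        with np.load(Path(path)) as data:
            return cls({k: data[k].copy() for k in data.files})


def fit_tissue_qc(tiles: np.ndarray, labels: np.ndarray, seed: int = 0,
                  epochs: int = 6, batch_size: int = 32,
                  lr: float = 2e-3) -> QCModel:
    """Train the QC classifier; deterministic given the seed."""
    tiles = np.asarray(tiles, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ParameterError("need both tissue and non-tissue examples")
    rng = np.random.default_rng(seed)
    model = QCModel.init(rng)
    opt = _nn.Adam(model.params, lr=lr)
    n = len(tiles)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x, y = tiles[idx], labels[idx]
            logit, cache = model._forward(x, with_cache=True)
            # d/dlogit of mean BCE-with-logits
            dlogit = (_nn.sigmoid(logit) - y) / len(idx)
            opt.step(model._backward(dlogit, cache))
    return model
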