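"""Synthetic whole-slide cohorts with localized prognostic signal.

Each slide is a bag of patch embeddings drawn from Gaussian archetypes
(low/high-grade tumor, necrosis, fibrosis, normal tissue, artifacts).
A latent grade ``g`` in [0, 1] controls the tumor-patch mix (share of
high-grade vs low-grade archetypes) and drives the slide's log-hazard

    eta = beta * grade_scale * g,

so the prognostic signal lives exclusively in tumor patches: non-tumor
patches are sampled independently of ``g``. Survival follows a
proportional-hazards exponential model with exponential right-censoring.
Cohort-level domain shift is modelled as an affine map of embedding space.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .datatypes import SlideBag, SurvivalRecord
from .errors import ParameterError

ARCHETYPE_NAMES = ("tumor_low", "tumor_high", "necrosis", "fibrosis", "normal", "artifact")
TUMOR_CLASSES = frozenset({"tumor_low", "tumor_high"})


@dataclass
class ArchetypeSpec:
    """One patch phenotype: a Gaussian blob in embedding space."""

    name: str
    mean: np.ndarray
    spread: float
    is_tumor: bool
    hazard_weight: float = 0.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        if self.spread <= 0:
            raise ParameterError(f"archetype {self.name}: spread must be > 0")


def default_archetypes(embed_dim: int, seed: int = 0) -> list[ArchetypeSpec]:
    """Well-separated archetype centers; geometry depends only on the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1717]))
    specs = []
    for name in ARCHETYPE_NAMES:
        mean = 3.0 * rng.standard_normal(embed_dim)
        specs.append(ArchetypeSpec(
            name=name,
            mean=mean,
            # artifacts are heterogeneous outliers (pen ink, blur, folds)
            spread=3.0 if name == "artifact" else 1.0,
            is_tumor=name in TUMOR_CLASSES,
            hazard_weight=1.0 if name == "tumor_high" else 0.0,
        ))
    return specs


@dataclass
class CohortConfig:
    """Generator parameters for one synthetic cohort.

    ``beta`` is the grade signal: the slide log-hazard is
    ``beta * grade_scale * g`` with latent grade ``g ~ Uniform(0, 1)``.
    ``baseline_rate`` and ``censor_rate`` are exponential rates per month.
    """

    name: str = "synthetic"
    n_slides: int = 200
    patches_per_slide: tuple[int, int] = (24, 40)
    embed_dim: int = 32
    beta: float = 1.0
    grade_scale: float = 4.0
    baseline_rate: float = 5e-4
    censor_rate: float = 8e-3
    tumor_fraction: float = 0.35
    purity_concentration: float = 6.0  # Beta concentration of per-slide purity
    artifact_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.patches_per_slide = tuple(int(v) for v in self.patches_per_slide)
        if self.n_slides < 2:
            raise ParameterError("n_slides must be >= 2")
        if self.embed_dim < 2:
            raise ParameterError("embed_dim must be >= 2")
        if self.baseline_rate <= 0:
            raise ParameterError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ParameterError("censor_rate must be >= 0")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ParameterError("tumor_fraction must lie in [0, 1]")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ParameterError("artifact_fraction must lie in [0, 1]")
        lo, hi = self.patches_per_slide
        if lo < 1 or hi < lo:
            raise ParameterError("patches_per_slide must satisfy 1 <= min <= max")
        if self.grade_scale <= 0:
            raise ParameterError("grade_scale must be > 0")
        if self.purity_concentration <= 0:
            raise ParameterError("purity_concentration must be > 0")


@dataclass
class Cohort:
    """Bags + survival + generating truth for one synthetic cohort.

    ``truth`` has one row per slide: slide_id, grade (latent g) and eta
    (true log-hazard), aligned with ``bags`` and ``survival``.
    """

    bags: list[SlideBag]
    survival: list[SurvivalRecord]
    truth: pd.DataFrame
    config: CohortConfig
    archetypes: list[ArchetypeSpec] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.bags) == len(self.survival) == len(self.truth)):
            raise ParameterError("bags, survival and truth must be aligned")

    @property
    def n_slides(self) -> int:
        return len(self.bags)

    @property
    def slide_ids(self) -> list[str]:
        return [b.slide_id for b in self.bags]

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.survival])

    def events(self) -> np.ndarray:
        return np.array([s.event for s in self.survival], dtype=int)


def sample_survival(eta: float, config: CohortConfig,
                    rng: np.random.Generator | None = None) -> SurvivalRecord:
    """Draw one (time, event) record under exponential hazards.

    Event time is exponential with rate ``baseline_rate * exp(eta)``; the
    censoring time is exponential with rate ``censor_rate`` (infinite when
    the rate is zero). The observed time is the minimum; ties count as
    events.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    event_time = rng.exponential(1.0 / (config.baseline_rate * np.exp(eta)))
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate)
    else:
        censor_time = np.inf
    time = max(min(event_time, censor_time), 1e-9)
    return SurvivalRecord(time=float(time), event=int(event_time <= censor_time))


def _nontumor_probs(artifact_fraction: float) -> np.ndarray:
    base = np.array([0.75, 0.15, 0.10])  # normal, fibrosis, necrosis
    return np.concatenate([base * (1.0 - artifact_fraction), [artifact_fraction]])


def make_cohort(config: CohortConfig,
                archetypes: list[ArchetypeSpec] | None = None) -> Cohort:
    """Generate a cohort; fully deterministic given ``config`` (incl. seed).

    The patch-sampling stream is independent of ``beta``: two configs that
    differ only in ``beta`` produce identical bags and differ only in the
    sampled survival outcomes.
    """
    if archetypes is None:
        archetypes = default_archetypes(config.embed_dim, config.seed)
    by_name = {a.name: a for a in archetypes}
    missing = set(ARCHETYPE_NAMES) - set(by_name)
    if missing:
        raise ParameterError(f"missing archetypes: {sorted(missing)}")

    lo, hi = config.patches_per_slide
    nontumor_names = np.array(["normal", "fibrosis", "necrosis", "artifact"], dtype=object)
    p_nontumor = _nontumor_probs(config.artifact_fraction)

    children = np.random.SeedSequence(config.seed).spawn(config.n_slides)
    bags, survival, rows = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        g = float(rng.uniform())
        n = int(rng.integers(lo, hi + 1))
        tf = config.tumor_fraction
        if 0.0 < tf < 1.0:
            # per-slide tumor purity fluctuates around the expected share
            kappa = config.purity_concentration
            tf = float(rng.beta(tf * kappa, (1.0 - tf) * kappa))
        n_tumor = int(round(tf * n))
        if config.tumor_fraction > 0:
            n_tumor = max(n_tumor, 1)  # keep tumor-only bags non-empty
        n_tumor = min(n_tumor, n)

        tumor_classes = np.where(rng.uniform(size=n_tumor) < g,
                                 "tumor_high", "tumor_low").astype(object)
        nontumor_classes = rng.choice(nontumor_names, size=n - n_tumor, p=p_nontumor)
        classes = rng.permutation(np.concatenate([tumor_classes, nontumor_classes]))

        noise = rng.standard_normal((n, config.embed_dim))
        emb = np.empty((n, config.embed_dim))
        for name in np.unique(classes.astype(str)):
            sel = classes == name
            spec = by_name[name]
            emb[sel] = spec.mean + spec.spread * noise[sel]

        side = int(np.ceil(np.sqrt(n)))
        cells = np.arange(n)
        coords = np.stack([cells // side, cells % side], axis=1)

        eta = config.beta * config.grade_scale * g
        survival.append(sample_survival(eta, config, rng))
        slide_id = f"{config.name}-{i:04d}"
        bags.append(SlideBag(slide_id=slide_id, embeddings=emb, coords=coords,
                             tissue_class=classes, cohort_id=config.name))
        rows.append({"slide_id": slide_id, "grade": g, "eta": eta})

    truth = pd.DataFrame(rows)
    return Cohort(bags=bags, survival=survival, truth=truth,
                  config=config, archetypes=list(archetypes))


def apply_domain_shift(cohort: Cohort, A: np.ndarray | None = None,
                       b: np.ndarray | None = None,
                       rate_multiplier: float = 1.0,
                       name: str | None = None) -> Cohort:
    """Affine shift of embedding space: every patch x becomes A @ x + b.

    Survival times are optionally rescaled by ``rate_multiplier`` (times are
    divided by it, i.e. a multiplier > 1 accelerates the hazard). Truth and
    tissue classes are untouched.
    """
    d = cohort.config.embed_dim
    if A is None:
        A = np.eye(d)
    A = np.asarray(A, dtype=float)
    if A.shape != (d, d):
        raise ParameterError(f"A must be {d}x{d}, got {A.shape}")
    sign, _ = np.linalg.slogdet(A)
    if sign == 0:
        raise ParameterError("A must be invertible")
    if b is None:
        b = np.zeros(d)
    b = np.asarray(b, dtype=float)
    if b.shape != (d,):
        raise ParameterError(f"b must have length {d}")
    if rate_multiplier <= 0:
        raise ParameterError("rate_multiplier must be > 0")

    new_name = name if name is not None else cohort.config.name
    config = dataclasses.replace(cohort.config, name=new_name)
    bags = [SlideBag(slide_id=bag.slide_id,
                     embeddings=bag.embeddings @ A.T + b,
                     coords=bag.coords.copy(),
                     tissue_class=bag.tissue_class.copy(),
                     cohort_id=new_name)
            for bag in cohort.bags]
    survival = [SurvivalRecord(time=s.time / rate_multiplier, event=s.event)
                for s in cohort.survival]
    shifted_archetypes = [dataclasses.replace(a, mean=A @ a.mean + b)
                          for a in cohort.archetypes]
    return Cohort(bags=bags, survival=survival, truth=cohort.truth.copy(),
                  config=config, archetypes=shifted_archetypes)


# ---------------------------------------------------------------------------
# QC tile fixtures
# ---------------------------------------------------------------------------

def make_qc_tiles(n: int, seed: int = 0, tile_size: int = 36):
    """Balanced grayscale tiles: textured tissue vs artifact/background.

    Returns ``(tiles, labels)`` with tiles of shape (n, tile_size,
    tile_size) in [0, 1] and labels 1 = tissue, 0 = non-tissue. Non-tissue
    tiles cycle through near-uniform background, saturated marker ink and
    heavily blurred (out-of-focus) fields.
    """
    if n < 2 or n % 2 != 0:
        raise ParameterError("n must be an even number >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4242]))
    half = n // 2
    tiles = np.empty((n, tile_size, tile_size))
    labels = np.empty(n, dtype=int)

    for i in range(half):  # tissue: textured eosin-like field + nuclei blobs
        tile = 0.55 + 0.08 * rng.standard_normal((tile_size, tile_size))
        yy, xx = np.mgrid[0:tile_size, 0:tile_size]
        for _ in range(int(rng.integers(6, 15))):
            cy, cx = rng.uniform(2, tile_size - 2, size=2)
            r = rng.uniform(1.5, 3.5)
            tile[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] -= rng.uniform(0.2, 0.35)
        tiles[i] = np.clip(tile, 0.0, 1.0)
        labels[i] = 1

    kinds = ("background", "marker", "blur")
    for i in range(half, n):
        kind = kinds[(i - half) % 3]
        if kind == "background":
            tile = 0.93 + 0.01 * rng.standard_normal((tile_size, tile_size))
        elif kind == "marker":
            tile = rng.uniform(0.05, 0.25) + 0.005 * rng.standard_normal((tile_size, tile_size))
        else:
            tile = 0.70 + 0.6 * gaussian_filter(
                rng.standard_normal((tile_size, tile_size)), sigma=6.0)
        tiles[i] = np.clip(tile, 0.0, 1.0)
        labels[i] = 0

    perm = rng.permutation(n)
    return tiles[perm], labels[perm]


# ---------------------------------------------------------------------------
# serialization: HDF5 bags + CSV survival + YAML config
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, outdir) -> None:
    """Write cohort.h5 (one group per slide), survival.csv and config.yaml."""
    import h5py
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(outdir / "cohort.h5", "w") as f:
        f.attrs["cohort_id"] = cohort.config.name
        slides = f.create_group("slides")
        for bag in cohort.bags:
            grp = slides.create_group(bag.slide_id)
            grp.create_dataset("embeddings", data=bag.embeddings)
            grp.create_dataset("coords", data=bag.coords)
            grp.create_dataset("tissue_class",
                               data=np.array([s.encode() for s in bag.tissue_class]))
        tr = f.create_group("truth")
        tr.create_dataset("slide_id",
                          data=np.array([s.encode() for s in cohort.truth["slide_id"]]))
        tr.create_dataset("grade", data=cohort.truth["grade"].to_numpy())
        tr.create_dataset("eta", data=cohort.truth["eta"].to_numpy())
    surv = pd.DataFrame({
        "slide_id": cohort.slide_ids,
        "time": cohort.times(),
        "event": cohort.events(),
    })
    surv.to_csv(outdir / "survival.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["patches_per_slide"] = list(cfg["patches_per_slide"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_cohort(outdir) -> Cohort:
    import h5py
    from pathlib import Path

    outdir = Path(outdir)
    with open(outdir / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    config = CohortConfig(**cfg)
    surv = pd.read_csv(outdir / "survival.csv")
    surv_by_id = {r.slide_id: SurvivalRecord(time=float(r.time), event=int(r.event))
                  for r in surv.itertuples()}
    bags, survival = [], []
    with h5py.File(outdir / "cohort.h5", "r") as f:
        truth = pd.DataFrame({
            "slide_id": [s.decode() for s in f["truth/slide_id"][...]],
            "grade": f["truth/grade"][...],
            "eta": f["truth/eta"][...],
        })
        for slide_id in truth["slide_id"]:
            grp = f["slides"][slide_id]
            bags.append(SlideBag(
                slide_id=slide_id,
                embeddings=grp["embeddings"][...],
                coords=grp["coords"][...],
                tissue_class=np.array([s.decode() for s in grp["tissue_class"][...]],
                                      dtype=object),
                cohort_id=config.name))
            survival.append(surv_by_id[slide_id])
    return Cohort(bags=bags, survival=survival, truth=truth, config=config,
                  archetypes=default_archetypes(config.embed_dim, config.seed))


# calibrated presets used by the test-bench scenarios -----------------------

def null_config(n_slides: int = 200, seed: int = 0, **overrides) -> CohortConfig:
    """No-signal cohort: beta = 0, event-rich so fold-wise C is estimable."""
    kw = dict(name="null", n_slides=n_slides, beta=0.0,
              baseline_rate=0.02, censor_rate=8e-3, seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


def strong_signal_config(n_slides: int = 300, seed: int = 0, **overrides) -> CohortConfig:
    """High-signal cohort: beta = 2 with the default grade scale."""
    kw = dict(name="strong", n_slides=n_slides, patches_per_slide=(64, 64),
              beta=2.0, seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


def dilution_config(n_slides: int = 260, seed: int = 0, **overrides) -> CohortConfig:
    """Signal-bearing cohort where ~85% of patches are uninformative, tumor
    purity varies strongly between slides, and a quarter of the non-tumor
    compartment is heterogeneous artifact: the regime that separates
    instance-level mean pooling from attention pooling."""
    kw = dict(name="dilute", n_slides=n_slides, patches_per_slide=(24, 36),
              beta=2.0, tumor_fraction=0.15, purity_concentration=1.0,
              artifact_fraction=0.25, seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


def strong_shift(embed_dim: int, seed: int = 0, scale: float = 1.5,
                 offset: float = 4.0):
    """A deterministic 'strong' domain shift: a random rotation scaled by
    ``scale`` plus a Gaussian offset of per-dimension magnitude ``offset``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 977]))
    q, _ = np.linalg.qr(rng.standard_normal((embed_dim, embed_dim)))
    return scale * q, rng.normal(0.0, offset, size=embed_dim)
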