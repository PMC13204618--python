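"""Survival-evaluation statistics.

Implements fold-wise z-score standardization of predicted risks, Harrell's
concordance index, the Kaplan-Meier product-limit estimator, quantile risk
stratification, binary-group Cox hazard ratios, cumulative/dynamic AUC with
inverse-probability-of-censoring weights, and bootstrap model comparison on
the difference in C-index.

Conventions (documented, not inferred): population standard deviation in
z-scores; risk sets include ties (t_j >= t_i) with Breslow handling; in the
censoring Kaplan-Meier, events precede censorings at tied times; quantile
cutoffs use linear interpolation and "<= cutoff" is low-risk.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import RiskPrediction
from .errors import (DegenerateGroupsError, HorizonError, NoComparablePairsError,
                     NoEventsError, ParameterError)


# ---------------------------------------------------------------------------
# fold-wise standardization
# ---------------------------------------------------------------------------

@dataclass
class FoldStats:
    fold_id: int
    mean: float
    std: float

    def __post_init__(self):
        if self.std < 0:
            raise ParameterError("std must be >= 0")


def zscore_by_fold(predictions: list[RiskPrediction]
                   ) -> tuple[list[RiskPrediction], list[FoldStats]]:
    """Standardize raw risks within each fold: z = (r - mu_f) / sigma_f.

    Uses the population standard deviation. A fold with zero spread yields
    all-zero standardized scores plus a warning. Returns the pooled list
    (all folds, input order preserved) and the per-fold statistics.
    """
    folds = sorted({p.fold_id for p in predictions})
    stats = []
    out = list(predictions)
    for f in folds:
        idx = [i for i, p in enumerate(predictions) if p.fold_id == f]
        if len(idx) < 2:
            raise ParameterError(f"fold {f}: need >= 2 predictions to standardize")
        raw = np.array([predictions[i].risk_raw for i in idx])
        mu, sigma = float(raw.mean()), float(raw.std())
        stats.append(FoldStats(fold_id=f, mean=mu, std=sigma))
        if sigma == 0:
            warnings.warn(f"fold {f}: zero risk spread, standardized scores set to 0")
            z = np.zeros_like(raw)
        else:
            z = (raw - mu) / sigma
        for j, i in enumerate(idx):
            p = predictions[i]
            out[i] = RiskPrediction(slide_id=p.slide_id, fold_id=p.fold_id,
                                    risk_raw=p.risk_raw, risk_std=float(z[j]),
                                    attention=p.attention)
    return out, stats


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def harrell_c(risks, times, events) -> float:
    """Harrell's C: pair (i, j) is comparable iff t_i < t_j and i is an event;
    concordant iff r_i > r_j; tied risks count 0.5."""
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(r) == len(t) == len(e)):
        raise ParameterError("risks, times, events must be aligned")
    # comparable[i, j]: i earlier event
    comp = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        raise NoComparablePairsError("no comparable pairs")
    conc = (r[:, None] > r[None, :]) & comp
    tied = (r[:, None] == r[None, :]) & comp
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray          # unique event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size at each event time
    n: int

    def survival_at(self, t: float, side: str = "right") -> float:
        """S(t); ``side='left'`` gives the left limit S(t-)."""
        idx = np.searchsorted(self.times, t, side=side)
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator; censored subjects leave the risk set after
    their observation time (events precede censorings at ties)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ParameterError("need at least one observation")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    surv, at_risk = [], []
    s = 1.0
    for u in uniq:
        n_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return KMCurve(times=uniq, survival=np.array(surv),
                   at_risk=np.array(at_risk, dtype=int), n=len(t))


def censoring_km(times, events) -> KMCurve:
    """KM estimate of the censoring survival function G (censoring = event)."""
    e = np.asarray(events, dtype=int)
    return km_estimate(times, 1 - e)


# ---------------------------------------------------------------------------
# quantile stratification and binary-group Cox HR
# ---------------------------------------------------------------------------

@dataclass
class StratifiedGroups:
    quantile: float
    cutoff: float
    low_idx: np.ndarray
    high_idx: np.ndarray

    @property
    def indicator(self) -> np.ndarray:
        n = len(self.low_idx) + len(self.high_idx)
        x = np.zeros(n, dtype=int)
        x[self.high_idx] = 1
        return x


def stratify_quantile(risks, q: float) -> StratifiedGroups:
    """Split into low (risk <= empirical q-quantile) and high groups."""
    r = np.asarray(risks, dtype=float)
    if not 0.0 < q < 1.0:
        raise ParameterError("q must lie in (0, 1)")
    if len(r) < 2:
        raise ParameterError("need >= 2 risks")
    if np.all(r == r[0]):
        raise DegenerateGroupsError("all risks identical; groups undefined")
    cutoff = float(np.quantile(r, q))
    low = np.flatnonzero(r <= cutoff)
    high = np.flatnonzero(r > cutoff)
    if len(high) == 0:
        raise DegenerateGroupsError(f"no risk exceeds the {q} quantile cutoff")
    return StratifiedGroups(quantile=q, cutoff=cutoff, low_idx=low, high_idx=high)


@dataclass
class HRResult:
    hazard_ratio: float
    log_hr: float
    diverged: bool
    n_iter: int


def _binary_cox_loglik(beta: float, x: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Breslow partial log-likelihood, score and information for one binary
    covariate."""
    order = np.argsort(t, kind="stable")
    x, t, e = x[order], t[order], e[order]
    loglik = score = info = 0.0
    for u in np.unique(t[e == 1]):
        risk = t >= u
        ev = (t == u) & (e == 1)
        d = int(ev.sum())
        n1 = x[risk].sum()               # group-1 members in risk set
        n0 = risk.sum() - n1
        s0 = n0 + n1 * np.exp(beta)
        s1 = n1 * np.exp(beta)
        loglik += beta * x[ev].sum() - d * np.log(s0)
        score += x[ev].sum() - d * s1 / s0
        info += d * (s1 / s0 - (s1 / s0) ** 2)
    return loglik, score, info


def cox_hr_binary(groups: StratifiedGroups | np.ndarray, times, events,
                  max_iter: int = 50, tol: float = 1e-10) -> HRResult:
    """Hazard ratio of high vs low risk group from a one-covariate Cox model,
    maximized by safeguarded Newton iteration.

    Monotone likelihoods (perfect separation) are reported with
    ``diverged=True`` and an infinite (or zero) hazard ratio.
    """
    x = groups.indicator if isinstance(groups, StratifiedGroups) else \
        np.asarray(groups, dtype=int)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(x) == len(t) == len(e)):
        raise ParameterError("group indicator, times, events must be aligned")
    if x.sum() == 0 or x.sum() == len(x):
        raise ParameterError("both groups must be non-empty")
    if e.sum() == 0:
        raise NoEventsError("no events")

    beta = 0.0
    loglik, score, info = _binary_cox_loglik(beta, x, t, e)
    for it in range(1, max_iter + 1):
        if abs(score) < tol * max(1.0, abs(loglik)):
            return HRResult(float(np.exp(beta)), beta, False, it)
        if info <= 0:
            break
        step = score / info
        # step-halving safeguard
        new_beta = beta + step
        for _ in range(30):
            new_ll, new_score, new_info = _binary_cox_loglik(new_beta, x, t, e)
            if new_ll >= loglik - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > 20.0:
            hr = np.inf if beta > 0 else 0.0
            return HRResult(float(hr), beta, True, it)
    if abs(score) < 1e-6 * max(1.0, abs(loglik)):
        return HRResult(float(np.exp(beta)), beta, False, max_iter)
    hr = np.inf if score > 0 else 0.0
    return HRResult(float(hr), beta, True, max_iter)


# ---------------------------------------------------------------------------
# IPCW cumulative/dynamic AUC
# ---------------------------------------------------------------------------

def ipcw_auc(risks, times, events, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW.

    Cases are events at or before the horizon (weighted by 1/G(t_i-)),
    controls survive past it (weighted by 1/G(horizon)); tied risks count
    0.5. G is the Kaplan-Meier estimate of the censoring distribution.
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(r) == len(t) == len(e)):
        raise ParameterError("risks, times, events must be aligned")
    case = (t <= horizon) & (e == 1)
    ctrl = t > horizon
    if not case.any():
        raise HorizonError(horizon, "no cases (events at or before the horizon)")
    if not ctrl.any():
        raise HorizonError(horizon, "no controls (subjects beyond the horizon)")
    G = censoring_km(t, e)
    w_case = np.array([1.0 / max(G.survival_at(ti, side="left"), 1e-12)
                       for ti in t[case]])
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / max(G.survival_at(horizon), 1e-12))
    rc, rk = r[case], r[ctrl]
    gt = (rc[:, None] > rk[None, :]).astype(float)
    eq = (rc[:, None] == rk[None, :]).astype(float)
    wmat = w_case[:, None] * w_ctrl[None, :]
    return float((wmat * (gt + 0.5 * eq)).sum() / wmat.sum())


DEFAULT_HORIZONS = (12.0, 36.0, 60.0)  # 1-, 3- and 5-year horizons in months


def timepoint_auc_panel(risks, times, events,
                        horizons=DEFAULT_HORIZONS) -> dict[float, float]:
    """IPCW AUC at each horizon; an invalid horizon raises ``HorizonError``
    carrying the offending horizon."""
    t = np.asarray(times, dtype=float)
    panel = {}
    for h in horizons:
        if h >= t.max():
            raise HorizonError(h, "beyond the last observed time")
        panel[float(h)] = ipcw_auc(risks, times, events, h)
    return panel


# ---------------------------------------------------------------------------
# bootstrap model comparison
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    delta_c: float            # C_A - C_B on the full data
    ci_low: float
    ci_high: float
    p_value: float
    n_iter: int
    n_redrawn: int = 0
    deltas: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ParameterError("CI bounds out of order")
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError("p-value outside [0, 1]")


def bootstrap_delta_c(risks_a, risks_b, times, events, n_iter: int = 1000,
                      seed: int = 0, max_redraw_factor: int = 100) -> BootstrapResult:
    """Patient-level bootstrap of the C-index difference C_A - C_B.

    Resamples patients with replacement; iterations whose resample has no
    comparable pair are redrawn (counted, capped). The 95% CI is the
    2.5/97.5 percentile band and the two-sided p-value is
    ``2 * min(P(delta <= 0), P(delta >= 0))`` clipped to [0, 1].
    """
    ra = np.asarray(risks_a, dtype=float)
    rb = np.asarray(risks_b, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(t)
    if not (len(ra) == len(rb) == n) or n < 2:
        raise ParameterError("need aligned vectors with n >= 2")
    point = harrell_c(ra, t, e) - harrell_c(rb, t, e)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_iter)
    redrawn = 0
    max_attempts = max_redraw_factor * n_iter
    i = attempts = 0
    while i < n_iter:
        if attempts >= max_attempts:
            raise NoComparablePairsError("too many degenerate bootstrap resamples")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            deltas[i] = harrell_c(ra[idx], t[idx], e[idx]) - \
                harrell_c(rb[idx], t[idx], e[idx])
        except NoComparablePairsError:
            redrawn += 1
            continue
        i += 1
    ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
    frac_le = float((deltas <= 0).mean())
    frac_ge = float((deltas >= 0).mean())
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    return BootstrapResult(delta_c=float(point), ci_low=float(ci_low),
                           ci_high=float(ci_high), p_value=p, n_iter=n_iter,
                           n_redrawn=redrawn, deltas=deltas)
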