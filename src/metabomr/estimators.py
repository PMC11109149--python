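"""Causal-effect estimators for two-sample MR on harmonized effects.

Given per-variant SNP-exposure effects gamma_j (se sg_j) and SNP-outcome
effects Gamma_j (se sG_j), the estimators implemented here are:

* Wald ratio: Gamma_j / gamma_j with first-order SE sG_j / |gamma_j|.
* IVW: weighted regression of Gamma on gamma through the origin with
  weights w_j = 1 / sG_j^2.  The random-effects variant (the primary
  model throughout) multiplies the fixed-effect SE by
  sqrt(max(1, Q / (J - 1))) — multiplicative overdispersion floored at 1,
  so it never undercuts the fixed-effect SE.
* MR-Egger: the same weighted regression with an unconstrained intercept,
  after orienting all variants to gamma_j >= 0; the slope is the causal
  estimate, the intercept the average directional pleiotropy.  Inference
  uses a t distribution with J - 2 df and a freely estimated residual
  scale (exact WLS), keeping the intercept pleiotropy test calibrated.
* Weighted median: the weighted 50% quantile of the ordered Wald ratios
  (linear interpolation at cumulative midpoints), SE by parametric
  bootstrap.
* MR-PRESSO: simulation-based global test on the leave-one-out residual
  sum of squares, per-variant outlier flagging (Bonferroni over J), an
  outlier-corrected IVW re-estimate, and an optional distortion test.

Binary outcomes put Gamma on the log-odds scale, so every estimate
exponentiates to an odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet, HarmonizedVariant


@dataclass(frozen=True)
class MrResult:
    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True)
class EggerFit:
    result: MrResult
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass(frozen=True)
class PressoReport:
    global_rss_observed: float
    global_p: float
    outlier_ids: tuple[str, ...]
    outlier_p: dict[str, float]
    distortion_p: Optional[float]
    n_sim: int
    seed: int


def _mk_result(method: str, n_snp: int, beta: float, se: float, df: Optional[int] = None) -> MrResult:
    """Normal-approximation result, or t with ``df`` degrees of freedom."""
    if df is None:
        crit = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    else:
        crit = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else 1.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return MrResult(
        method=method, n_snp=n_snp, beta=float(beta), se=float(se),
        ci_low=float(beta - crit * se), ci_high=float(beta + crit * se), pval=float(p),
    )


def wald_ratio(v: HarmonizedVariant) -> MrResult:
    """Single-variant causal estimate, first-order delta-method SE."""
    if v.gamma == 0.0:
        raise DegenerateInputError(f"{v.variant_id}: gamma = 0, Wald ratio undefined")
    beta = v.big_gamma / v.gamma
    se = v.se_big_gamma / abs(v.gamma)
    return _mk_result("wald_ratio", 1, beta, se)


def _ivw_core(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Origin-constrained WLS: returns (slope, fixed SE, Q)."""
    sxx = float(np.sum(w * g * g))
    slope = float(np.sum(w * g * G)) / sxx
    se_fixed = 1.0 / math.sqrt(sxx)
    q = float(np.sum(w * (G - slope * g) ** 2))
    return slope, se_fixed, q


def ivw(h: HarmonizedSet, model: str = "random") -> MrResult:
    """Inverse-variance-weighted estimate.

    ``model="random"`` (the primary analysis) inflates the SE by the
    multiplicative overdispersion factor max(1, sqrt(Q/(J-1))).
    """
    j = len(h)
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if j < 1 or (model == "random" and j < 2):
        raise InsufficientInstrumentsError(
            f"IVW ({model}) needs at least {1 if model == 'fixed' else 2} variants, got {j}"
        )
    g, _, G, sG = h.arrays()
    w = 1.0 / sG**2
    slope, se_fixed, q = _ivw_core(g, G, w)
    se = se_fixed
    if model == "random" and j >= 2:
        se = se_fixed * max(1.0, math.sqrt(q / (j - 1)))
    return _mk_result("ivw", j, slope, se)


def mr_egger(h: HarmonizedSet) -> EggerFit:
    """Weighted regression with intercept after orienting gamma >= 0."""
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 variants, got {j}")
    g, _, G, sG = h.arrays()
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    w = 1.0 / sG**2
    # weighted normal equations for [intercept, slope]
    sw, swx = float(np.sum(w)), float(np.sum(w * g))
    swxx = float(np.sum(w * g * g))
    swy, swxy = float(np.sum(w * G)), float(np.sum(w * g * G))
    det = sw * swxx - swx**2
    if det <= 0:
        raise DegenerateInputError("MR-Egger design is singular (no spread in gamma)")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = G - intercept - slope * g
    # residual scale estimated freely (standard WLS t-inference); flooring it
    # at 1 would make the intercept pleiotropy test conservative
    sigma2 = float(np.sum(w * resid**2)) / (j - 2)
    se_slope = math.sqrt(sigma2 * sw / det)
    se_int = math.sqrt(sigma2 * swxx / det)
    result = _mk_result("mr_egger", j, slope, se_slope, df=j - 2)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, j - 2) if se_int > 0 else 1.0
    return EggerFit(result=result, intercept=float(intercept),
                    intercept_se=float(se_int), intercept_p=float(p_int))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    # cumulative midpoint of each ratio's weight interval
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Bowden weighted-median estimate with parametric-bootstrap SE."""
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 variants, got {j}")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    g, sg, G, sG = h.arrays()
    if np.any(g == 0):
        raise DegenerateInputError("weighted median undefined with gamma = 0 instruments")
    ratios = G / g
    weights = g**2 / sG**2  # 1 / first-order ratio variance
    est = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    g_b = rng.normal(g, sg, size=(n_boot, j))
    G_b = rng.normal(G, sG, size=(n_boot, j))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        gb = g_b[i]
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        boots[i] = _weighted_median_point(G_b[i] / gb, gb**2 / sG**2)
    se = float(np.std(boots, ddof=1))
    return _mk_result("weighted_median", j, est, se)


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-constrained WLS slopes, O(J)."""
    sxy = np.sum(w * g * G)
    sxx = np.sum(w * g * g)
    return (sxy - w * g * G) / (sxx - w * g * g)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    distortion: bool = True,
) -> tuple[PressoReport, MrResult, Optional[MrResult]]:
    """Pleiotropy residual sum of squares and outlier test.

    Returns (report, raw IVW estimate, outlier-corrected IVW estimate or
    None when no outlier was flagged or every variant was flagged).
    """
    j = len(h)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 variants, got {j}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    g, _, G, sG = h.arrays()
    w = 1.0 / sG**2
    slopes_loo = _loo_slopes(g, G, w)
    resid_obs = w * (G - slopes_loo * g) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    G_sim = rng.normal(slopes_loo * g, sG, size=(n_sim, j))
    # leave-one-out slopes within each simulated dataset, vectorized over sims
    sxy = G_sim @ (w * g)
    sxx = float(np.sum(w * g * g))
    slopes_sim = (sxy[:, None] - (w * g) * G_sim) / (sxx - w * g * g)
    resid_sim = w * (G_sim - slopes_sim * g) ** 2
    rss_sim = resid_sim.sum(axis=1)
    global_p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)

    ids = [v.variant_id for v in h.variants]
    outlier_p: dict[str, float] = {}
    flagged: list[int] = []
    for idx, vid in enumerate(ids):
        p_raw = (1.0 + float(np.sum(resid_sim[:, idx] >= resid_obs[idx]))) / (n_sim + 1.0)
        p_adj = min(1.0, p_raw * j)  # Bonferroni over the J variants
        outlier_p[vid] = p_adj
        if p_adj < outlier_alpha:
            flagged.append(idx)

    raw = ivw(h, model="random")
    corrected: Optional[MrResult] = None
    distortion_p: Optional[float] = None
    if flagged and len(flagged) < j - 1:
        keep = [v for i, v in enumerate(h.variants) if i not in flagged]
        h_corr = HarmonizedSet(h.exposure_id, h.outcome_id, keep)
        corr = ivw(h_corr, model="random")
        corrected = MrResult("mr_presso_corrected", corr.n_snp, corr.beta, corr.se,
                             corr.ci_low, corr.ci_high, corr.pval)
        if distortion:
            d_obs = corrected.beta - raw.beta
            n_out = len(flagged)
            d_null = np.empty(n_sim)
            for b in range(n_sim):
                drop = rng.choice(j, size=n_out, replace=False)
                mask = np.ones(j, bool)
                mask[drop] = False
                slope_b, _, _ = _ivw_core(g[mask], G[mask], w[mask])
                d_null[b] = slope_b - raw.beta
            distortion_p = (1.0 + float(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_sim + 1.0)

    raw = MrResult("mr_presso_raw", raw.n_snp, raw.beta, raw.se,
                   raw.ci_low, raw.ci_high, raw.pval)
    report = PressoReport(
        global_rss_observed=rss_obs,
        global_p=float(global_p),
        outlier_ids=tuple(ids[i] for i in flagged),
        outlier_p=outlier_p,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )
    return report, raw, corrected
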