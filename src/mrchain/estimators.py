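"""Causal-effect estimators on harmonized instruments.

Five methods: per-SNP Wald ratio, inverse-variance-weighted (fixed and
multiplicative random effects), MR-Egger regression with its pleiotropy
intercept, weighted median, and the two kernel-mode estimators
(simple/weighted). Median and mode standard errors come from a seeded
parametric bootstrap; every estimate is reported with 95% CI, two-sided
p, and the exponentiated odds-ratio scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from mrchain.sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

Z95 = 1.959964
_TINY_P = 5e-324  # smallest subnormal; keeps p in (0, 1]


class EstimatorError(ValueError):
    """Invalid estimator input (too few instruments, zero denominator...)."""


@dataclass
class MRResult:
    method: str
    nsnp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float


@dataclass
class EggerIntercept:
    estimate: float
    se: float
    pval: float


@dataclass
class EggerResult:
    slope: MRResult
    intercept: EggerIntercept


def _norm_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


def _t_p(t: float, df: int) -> float:
    return max(2.0 * stats.t.sf(abs(t), df), _TINY_P)


def _result(method: str, nsnp: int, beta: float, se: float,
            pval: Optional[float] = None, ci_mult: float = Z95) -> MRResult:
    if se > 0:
        lo, hi = beta - ci_mult * se, beta + ci_mult * se
        p = _norm_p(beta / se) if pval is None else pval
    else:  # degenerate (e.g. all ratios identical): point mass
        lo = hi = beta
        p = 1.0 if pval is None else pval
    return MRResult(
        method=method, nsnp=nsnp, beta=beta, se=se,
        ci_low=lo, ci_high=hi, pval=p,
        odds_ratio=math.exp(beta),
        or_ci_low=math.exp(lo), or_ci_high=math.exp(hi),
    )


def _arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (beta_exp, se_exp, beta_out, se_out) from an InstrumentSet
    or any iterable of HarmonizedPair, skipping dropped pairs."""
    if hasattr(instruments, "pairs"):
        pairs = instruments.pairs
    else:
        pairs = list(instruments)
    pairs = [p for p in pairs if p.action != "dropped"]
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, sx, by, sy


def _rsids(instruments) -> list[str]:
    pairs = instruments.pairs if hasattr(instruments, "pairs") else list(instruments)
    return [p.rsid for p in pairs if p.action != "dropped"]


def wald_ratio(pair: HarmonizedPair) -> MRResult:
    """Single-SNP causal estimate beta_out/beta_exp, first-order SE."""
    if pair.beta_exp == 0:
        raise EstimatorError(f"{pair.rsid}: Wald ratio undefined for beta_exp = 0")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return _result("wald_ratio", 1, beta, se)


def ivw(instruments, effects_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted estimate.

    Weighted regression of beta_out on beta_exp through the origin with
    weights 1/se_out^2. The multiplicative random-effects variant scales
    the fixed-effect SE by max(1, sqrt(Q/(nsnp-1))); with a single
    instrument it reduces exactly to the Wald ratio.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown effects_model {effects_model!r}")
    bx, _, by, sy = _arrays(instruments)
    n = len(bx)
    if n == 0:
        raise EstimatorError("IVW requires at least one instrument")
    if np.any(bx == 0):
        raise EstimatorError("IVW undefined with a zero exposure beta")
    if n == 1:
        # exact reduction to the Wald ratio (no accumulated rounding)
        beta = float(by[0] / bx[0])
        method = "ivw_fixed" if effects_model == "fixed" else "ivw_mre"
        return _result(method, 1, beta, float(sy[0] / abs(bx[0])))
    w = bx ** 2 / sy ** 2
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    se = se_fixed
    method = "ivw_fixed"
    if effects_model == "multiplicative_random":
        method = "ivw_mre"
        if n >= 2:
            q = float(np.sum(w * (ratios - beta) ** 2))
            se = se_fixed * max(1.0, math.sqrt(q / (n - 1)))
    return _result(method, n, beta, se)


def mr_egger(instruments) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    Pairs are oriented so beta_exp >= 0 (both members negated when
    needed), then beta_out is regressed on beta_exp with weights
    1/se_out^2. Standard errors are scaled by max(1, sigma) with
    sigma^2 = weighted RSS/(nsnp-2); p-values use t with nsnp-2 df.
    """
    bx, _, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 3:
        raise EstimatorError(f"MR-Egger requires >= 3 instruments, got {n}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip
    w = 1.0 / sy ** 2
    # weighted normal equations for [intercept, slope]
    sw = w.sum()
    swx = (w * bx).sum()
    swxx = (w * bx * bx).sum()
    swy = (w * by).sum()
    swxy = (w * bx * by).sum()
    det = sw * swxx - swx ** 2
    if det <= 0:
        raise EstimatorError("degenerate design in MR-Egger (constant beta_exp?)")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = by - intercept - slope * bx
    rss = float(np.sum(w * resid ** 2))
    sigma = math.sqrt(max(rss, 0.0) / (n - 2))
    scale = max(1.0, sigma)
    se_intercept = math.sqrt(swxx / det) * scale
    se_slope = math.sqrt(sw / det) * scale
    df = n - 2
    tq = float(stats.t.ppf(0.975, df))
    slope_res = _result(
        "egger", n, float(slope), se_slope,
        pval=_t_p(slope / se_slope, df) if se_slope > 0 else 1.0,
        ci_mult=tq,
    )
    icpt = EggerIntercept(
        estimate=float(intercept),
        se=se_intercept,
        pval=_t_p(intercept / se_intercept, df) if se_intercept > 0 else 1.0,
    )
    return EggerResult(slope=slope_res, intercept=icpt)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(instruments, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios are weighted by beta_exp^2/se_out^2 (normalized); the
    estimate interpolates the cumulative-weight function at 0.5. The SE
    is the standard deviation of ``n_boot`` replicates in which
    beta_exp and beta_out are redrawn from normals centred at the
    observed values with the observed SEs.
    """
    bx, sx, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 3:
        raise EstimatorError(f"weighted median requires >= 3 instruments, got {n}")
    if np.any(bx == 0):
        raise EstimatorError("weighted median undefined with a zero exposure beta")
    weights = bx ** 2 / sy ** 2
    est = _weighted_median_point(by / bx, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        boots[b] = _weighted_median_point(byb / bxb, bxb ** 2 / sy ** 2)
    se = float(np.std(boots, ddof=1))
    return _result("weighted_median", n, est, se)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    z = (grid[:, None] - ratios[None, :]) / h
    density = np.exp(-0.5 * z ** 2) @ weights
    return float(grid[int(np.argmax(density))])


def _bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25]))) / 1.34
    spread = min(sd, iqr) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-0.2)


def mode_estimators(
    instruments, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> tuple[MRResult, MRResult]:
    """Simple-mode and weighted-mode estimators.

    Ratios beta_out/beta_exp with SE se_out/|beta_exp| are smoothed with
    a Gaussian kernel (modified Silverman bandwidth, ``phi``
    multiplier) over a fixed 512-point grid; the estimate is the grid
    argmax (ties resolved to the lowest grid value). Simple mode uses
    equal weights, weighted mode weights proportional to inverse ratio
    variance. SEs by the same parametric bootstrap as the weighted
    median. Returns ``(simple_mode, weighted_mode)``.
    """
    bx, sx, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 3:
        raise EstimatorError(f"mode estimators require >= 3 instruments, got {n}")
    if np.any(bx == 0):
        raise EstimatorError("mode estimators undefined with a zero exposure beta")
    ratios = by / bx
    ratio_se = sy / np.abs(bx)
    if np.ptp(ratios) == 0:
        logger.info("mode_estimators: all ratios identical; degenerate density")
        est = float(ratios[0])
        simple = _result("simple_mode", n, est, 0.0)
        weighted = _result("weighted_mode", n, est, 0.0)
        return simple, weighted

    w_simple = np.full(n, 1.0 / n)
    w_mode = 1.0 / ratio_se ** 2
    w_mode = w_mode / w_mode.sum()

    def both(r: np.ndarray, wm: np.ndarray) -> tuple[float, float]:
        h = _bandwidth(r, phi)
        if h <= 0:
            # degenerate IQR/sd with non-degenerate data cannot happen
            # (sd > 0 whenever ptp > 0), but guard anyway
            return float(np.median(r)), float(np.median(r))
        return (_mode_point(r, np.full(len(r), 1.0 / len(r)), h),
                _mode_point(r, wm, h))

    est_simple, est_weighted = both(ratios, w_mode)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        rb = byb / bxb
        seb = sy / np.abs(bxb)
        wb = 1.0 / seb ** 2
        wb = wb / wb.sum()
        if np.ptp(rb) == 0:
            boots[b] = (rb[0], rb[0])
        else:
            boots[b] = both(rb, wb)
    se_simple = float(np.std(boots[:, 0], ddof=1))
    se_weighted = float(np.std(boots[:, 1], ddof=1))
    return (
        _result("simple_mode", n, est_simple, se_simple),
        _result("weighted_mode", n, est_weighted, se_weighted),
    )


def all_methods(
    instruments,
    effects_model: str = "multiplicative_random",
    n_boot: int = 1000,
    seed: int = 0,
    include_supplementary: bool = True,
) -> dict[str, MRResult]:
    """Headline IVW plus, where instrument counts allow, the supplements.

    Returns a dict keyed by method name. With one instrument only the
    Wald ratio/IVW is available; Egger, median, and modes need >= 3.
    """
    results: dict[str, MRResult] = {}
    n = len(_arrays(instruments)[0])
    if n == 0:
        raise EstimatorError("no instruments")
    results["ivw"] = ivw(instruments, effects_model)
    results["ivw_fixed"] = ivw(instruments, "fixed")
    if n >= 3:
        egger = mr_egger(instruments)
        results["egger"] = egger.slope
        results["egger_intercept"] = egger.intercept  # type: ignore[assignment]
        if include_supplementary:
            results["weighted_median"] = weighted_median(instruments, n_boot, seed)
            simple, weighted = mode_estimators(instruments, 1.0, n_boot, seed + 1)
            results["simple_mode"] = simple
            results["weighted_mode"] = weighted
    return results


def results_table(results: Iterable[MRResult]):
    """Tab-separable records for the standard results table."""
    import pandas as pd

    rows = [{
        "method": r.method, "nsnp": r.nsnp, "beta": r.beta, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
        "odds_ratio": r.odds_ratio, "or_ci_low": r.or_ci_low,
        "or_ci_high": r.or_ci_high,
    } for r in results]
    return pd.DataFrame(rows)
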