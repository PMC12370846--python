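"""Heterogeneity, pleiotropy, and outlier diagnostics.

Cochran's Q on Wald ratios, the Egger intercept test (delegated to the
estimators module), leave-one-out IVW, and a residual-simulation
outlier test in the MR-PRESSO style (global test, per-SNP outliers with
Bonferroni adjustment, outlier-corrected estimate, and an informational
distortion test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from mrchain.estimators import (
    EstimatorError,
    MRResult,
    _arrays,
    _rsids,
    ivw,
    mr_egger,
)

logger = logging.getLogger(__name__)


@dataclass
class LooRow:
    rsid: str
    beta: float
    se: float
    pval: float


@dataclass
class PressoResult:
    global_pval: float
    outliers: list[str]
    corrected: Optional[MRResult]
    distortion_pval: Optional[float]


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: Optional[float]
    egger_intercept_pval: Optional[float]
    loo_table: list[LooRow]
    presso_global_pval: Optional[float] = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_corrected: Optional[MRResult] = None
    presso_distortion_pval: Optional[float] = None


def cochran_q(instruments, ivw_beta: Optional[float] = None) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios with weights beta_exp^2/se_out^2.

    ``ivw_beta`` defaults to the fixed-effect IVW estimate (the weighted
    mean of the ratios under these weights). Returns (Q, df, p) with
    df = nsnp - 1 and p from the upper chi-square tail.
    """
    bx, _, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 2:
        raise EstimatorError(f"Cochran's Q requires >= 2 instruments, got {n}")
    w = bx ** 2 / sy ** 2
    ratios = by / bx
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - ivw_beta) ** 2))
    df = n - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, min(max(p, 5e-324), 1.0)


def leave_one_out(
    instruments, effects_model: str = "multiplicative_random"
) -> list[LooRow]:
    """IVW re-estimated with each SNP removed in turn (nsnp rows)."""
    pairs = [p for p in (instruments.pairs if hasattr(instruments, "pairs")
                         else list(instruments)) if p.action != "dropped"]
    n = len(pairs)
    if n < 2:
        raise EstimatorError(f"leave-one-out requires >= 2 instruments, got {n}")
    rows = []
    for j in range(n):
        subset = pairs[:j] + pairs[j + 1:]
        res = ivw(subset, effects_model)
        rows.append(LooRow(rsid=pairs[j].rsid, beta=res.beta, se=res.se,
                           pval=res.pval))
    return rows


def _loo_betas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Vector of leave-one-out fixed-effect IVW estimates."""
    w = 1.0 / sy ** 2
    s1 = np.sum(bx * by * w)
    s2 = np.sum(bx ** 2 * w)
    return (s1 - bx * by * w) / (s2 - bx ** 2 * w)


def mr_presso(
    instruments,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    effects_model: str = "multiplicative_random",
) -> PressoResult:
    """Residual-simulation pleiotropy test.

    The observed statistic is the weighted residual sum of squares
    RSS = sum_j (beta_out_j - b_(-j)*beta_exp_j)^2 / se_out_j^2 with
    b_(-j) the leave-one-out IVW estimate. ``n_sim`` replicate outcome
    vectors are drawn from Normal(b_(-j)*beta_exp_j, se_out_j) and RSS
    recomputed (including the leave-one-out step) on each; the global
    p-value is (1 + #{RSS_sim >= RSS_obs})/(n_sim + 1). Per-SNP outlier
    p-values are the simulated exceedance fractions of each squared
    residual, Bonferroni-adjusted by nsnp. The corrected estimate is
    IVW on non-outliers; the distortion p-value compares the
    corrected-vs-full shift against random same-size exclusions.
    """
    bx, _, by, sy = _arrays(instruments)
    rsids = _rsids(instruments)
    n = len(bx)
    if n < 4:
        raise EstimatorError(f"MR-PRESSO requires >= 4 instruments, got {n}")
    rng = np.random.default_rng(seed)

    loo = _loo_betas(bx, by, sy)
    resid_obs = (by - loo * bx) ** 2 / sy ** 2
    rss_obs = float(resid_obs.sum())

    by_sim = rng.normal(loc=loo * bx, scale=sy, size=(n_sim, n))
    w = 1.0 / sy ** 2
    s1_sim = (bx * by_sim * w).sum(axis=1)
    s2 = float(np.sum(bx ** 2 * w))
    loo_sim = (s1_sim[:, None] - bx * by_sim * w) / (s2 - bx ** 2 * w)
    resid_sim = (by_sim - loo_sim * bx) ** 2 / sy ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)

    outlier_p = (resid_sim >= resid_obs[None, :]).mean(axis=0)
    adjusted = np.minimum(outlier_p * n, 1.0)
    flagged = adjusted < outlier_alpha
    outliers = [r for r, f in zip(rsids, flagged) if f]

    corrected: Optional[MRResult] = None
    distortion_pval: Optional[float] = None
    if outliers and not all(flagged):
        pairs = [p for p in (instruments.pairs if hasattr(instruments, "pairs")
                             else list(instruments)) if p.action != "dropped"]
        keep_pairs = [p for p, f in zip(pairs, flagged) if not f]
        corrected = ivw(keep_pairs, effects_model)
        full = ivw(pairs, effects_model)
        delta_obs = abs(corrected.beta - full.beta)
        n_out = int(flagged.sum())
        deltas = np.empty(n_sim)
        idx = np.arange(n)
        for s in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            keep = np.setdiff1d(idx, drop, assume_unique=True)
            wk = bx[keep] ** 2 / sy[keep] ** 2
            beta_k = np.sum(wk * by[keep] / bx[keep]) / wk.sum()
            deltas[s] = abs(beta_k - full.beta)
        distortion_pval = float(np.mean(deltas >= delta_obs))
    elif outliers:
        logger.warning("mr_presso: every instrument flagged; no corrected estimate")

    return PressoResult(
        global_pval=global_pval,
        outliers=outliers,
        corrected=corrected,
        distortion_pval=distortion_pval,
    )


def sensitivity_report(
    instruments,
    n_sim: int = 1000,
    seed: int = 0,
    effects_model: str = "multiplicative_random",
    run_presso: bool = True,
) -> SensitivityReport:
    """Full diagnostic bundle: Q, Egger intercept, leave-one-out, PRESSO."""
    bx = _arrays(instruments)[0]
    n = len(bx)
    q, df, qp = cochran_q(instruments)
    icpt = icpt_p = None
    if n >= 3:
        egger = mr_egger(instruments)
        icpt, icpt_p = egger.intercept.estimate, egger.intercept.pval
    loo = leave_one_out(instruments, effects_model)
    report = SensitivityReport(
        q_stat=q, q_df=df, q_pval=qp,
        egger_intercept=icpt, egger_intercept_pval=icpt_p,
        loo_table=loo,
    )
    if run_presso and n >= 4:
        presso = mr_presso(instruments, n_sim=n_sim, seed=seed,
                           effects_model=effects_model)
        report.presso_global_pval = presso.global_pval
        report.presso_outliers = presso.outliers
        report.presso_corrected = presso.corrected
        report.presso_distortion_pval = presso.distortion_pval
    return report


def format_report(report: SensitivityReport) -> str:
    """One-block plain-text summary of the diagnostics."""
    lines = [
        f"Cochran Q = {report.q_stat:.4f} (df {report.q_df}), p = {report.q_pval:.4g}",
    ]
    if report.egger_intercept is not None:
        lines.append(
            f"Egger intercept = {report.egger_intercept:.4g}, "
            f"p = {report.egger_intercept_pval:.4g}"
        )
    else:
        lines.append("Egger intercept: unavailable (< 3 instruments)")
    if report.presso_global_pval is not None:
        lines.append(f"MR-PRESSO global p = {report.presso_global_pval:.4g}")
        lines.append(
            "MR-PRESSO outliers: "
            + (", ".join(report.presso_outliers) if report.presso_outliers else "none")
        )
        if report.presso_distortion_pval is not None:
            lines.append(
                f"MR-PRESSO distortion p = {report.presso_distortion_pval:.4g}"
            )
    return "\n".join(lines)
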