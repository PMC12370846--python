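"""Summary-data-based MR test and the HEIDI linkage test.

The SMR statistic combines the top QTL association with the GWAS
association at the same SNP into a single chi-square(1) test of a
shared effect; HEIDI asks whether surrounding SNPs in LD tell the same
effect-size story (null: one shared causal variant) or a discordant one
(alternative: distinct variants in linkage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from mrchain.ld import LDMatrix
from mrchain.sumstats import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

_TINY_P = 5e-324


class SMRError(ValueError):
    """Invalid SMR/HEIDI input."""


@dataclass
class SMRResult:
    top_rsid: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: Optional[float] = None
    n_heidi_snps: int = 0


def smr_test(
    qtl_top: VariantAssociation, gwas_at_top: VariantAssociation
) -> SMRResult:
    """SMR test at the top QTL SNP.

    With z_qtl = beta/se of the QTL association and z_gwas likewise,
    the effect is b_xy = beta_gwas/beta_qtl and the test statistic is
    T = z_qtl^2 * z_gwas^2 / (z_qtl^2 + z_gwas^2) ~ chi-square(1).
    Requires the two records to be on the same allele frame.
    """
    if qtl_top.rsid != gwas_at_top.rsid:
        raise SMRError(
            f"rsid mismatch: {qtl_top.rsid} vs {gwas_at_top.rsid}"
        )
    if (qtl_top.effect_allele != gwas_at_top.effect_allele
            or qtl_top.other_allele != gwas_at_top.other_allele):
        raise SMRError(f"{qtl_top.rsid}: alleles not harmonized")
    if qtl_top.beta == 0:
        raise SMRError(f"{qtl_top.rsid}: zero QTL beta")
    z_qtl = qtl_top.beta / qtl_top.se
    z_gwas = gwas_at_top.beta / gwas_at_top.se
    b_xy = gwas_at_top.beta / qtl_top.beta
    t_smr = (z_qtl ** 2 * z_gwas ** 2) / (z_qtl ** 2 + z_gwas ** 2)
    p_smr = min(max(float(stats.chi2.sf(t_smr, 1)), _TINY_P), 1.0)
    se_xy = abs(b_xy) / math.sqrt(t_smr) if t_smr > 0 else float("inf")
    return SMRResult(top_rsid=qtl_top.rsid, b_xy=b_xy, se_xy=se_xy, p_smr=p_smr)


def _bxy_covariance(
    bq: np.ndarray, sq: np.ndarray,
    bg: np.ndarray, sg: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """First-order covariance of b_xy = b_gwas/b_qtl across SNPs.

    QTL and GWAS samples are independent, so
    cov(b_i, b_j) = r_ij * [ sg_i*sg_j/(bq_i*bq_j)
                             + b_i*b_j*sq_i*sq_j/(bq_i*bq_j) ].
    """
    bxy = bg / bq
    inv = 1.0 / np.outer(bq, bq)
    cov = r * (np.outer(sg, sg) * inv + np.outer(bxy, bxy) * np.outer(sq, sq) * inv)
    return cov


def heidi_test(
    qtl_region: SummaryDataset,
    gwas_region: SummaryDataset,
    ld: LDMatrix,
    top_rsid: str,
    r2_min: float = 0.05,
    r2_max: float = 0.9,
    max_snps: int = 20,
    min_snps: int = 3,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[Optional[float], int]:
    """HEIDI test around a top SNP.

    Candidate SNPs are those in both regions and the LD reference with
    r^2 to the top SNP in [r2_min, r2_max], ranked by QTL significance
    and truncated to ``max_snps``. For each candidate the deviation
    d_i = b_xy(i) - b_xy(top) is formed; the test statistic is
    sum_i d_i^2/var(d_i) and its null distribution is sampled by Monte
    Carlo from the multivariate normal with the first-order covariance
    of d. Returns ``(p_heidi, n_candidates)`` with ``p_heidi`` None
    when fewer than ``min_snps`` candidates are eligible.

    Both regions must already share an allele frame per rsid (use
    :func:`mrchain.sumstats.harmonize` upstream when they do not).
    """
    qtl_index = qtl_region.by_rsid()
    gwas_index = gwas_region.by_rsid()
    if top_rsid not in qtl_index or top_rsid not in gwas_index:
        raise SMRError(f"top SNP {top_rsid} missing from a region dataset")
    if top_rsid not in ld:
        raise SMRError(f"top SNP {top_rsid} missing from the LD reference")

    candidates = []
    for rsid, qrec in qtl_index.items():
        if rsid == top_rsid or rsid not in gwas_index or rsid not in ld:
            continue
        r2 = ld.corr(top_rsid, rsid) ** 2
        if r2_min <= r2 <= r2_max:
            candidates.append((abs(qrec.zscore), rsid))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    chosen = [rsid for _, rsid in candidates[:max_snps]]
    n_candidates = len(chosen)
    if n_candidates < min_snps:
        logger.info(
            "heidi_test(%s): only %d eligible SNPs (< %d); p_heidi unavailable",
            top_rsid, n_candidates, min_snps,
        )
        return None, n_candidates

    snps = [top_rsid] + chosen  # index 0 = top
    bq = np.array([qtl_index[s].beta for s in snps])
    sq = np.array([qtl_index[s].se for s in snps])
    bg = np.array([gwas_index[s].beta for s in snps])
    sg = np.array([gwas_index[s].se for s in snps])
    if np.any(bq == 0):
        raise SMRError("zero QTL beta among HEIDI SNPs")
    sub = ld.submatrix(snps)

    cov_b = _bxy_covariance(bq, sq, bg, sg, sub.r)
    bxy = bg / bq
    d = bxy[1:] - bxy[0]
    m = len(d)
    cov_d = (cov_b[1:, 1:]
             - cov_b[1:, 0][:, None]
             - cov_b[0, 1:][None, :]
             + cov_b[0, 0])
    var_d = np.diag(cov_d).copy()
    if np.any(var_d <= 0):
        raise SMRError("non-positive deviation variance in HEIDI")
    stat_obs = float(np.sum(d ** 2 / var_d))

    eigval, eigvec = np.linalg.eigh((cov_d + cov_d.T) / 2.0)
    floor = -1e-8 * max(float(eigval.max()), 1.0)
    if eigval.min() < floor:
        raise SMRError(
            "HEIDI covariance not positive semi-definite after ridge adjustment "
            f"(min eigenvalue {eigval.min():.3g})"
        )
    eigval = np.clip(eigval, 0.0, None) + 1e-8 * max(float(eigval.max()), 1e-300)
    root = eigvec * np.sqrt(eigval)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, m))
    d_sim = z @ root.T
    stat_sim = np.sum(d_sim ** 2 / var_d, axis=1)
    p_heidi = (1.0 + float(np.sum(stat_sim >= stat_obs))) / (n_mc + 1.0)
    return p_heidi, n_candidates


def smr_with_heidi(
    qtl_region: SummaryDataset,
    gwas_region: SummaryDataset,
    ld: LDMatrix,
    top_rsid: Optional[str] = None,
    **heidi_kwargs,
) -> SMRResult:
    """Convenience wrapper: SMR at the top QTL SNP plus HEIDI around it.

    ``top_rsid`` defaults to the most significant QTL SNP present in
    both regions.
    """
    gwas_index = gwas_region.by_rsid()
    if top_rsid is None:
        shared = [r for r in qtl_region.records if r.rsid in gwas_index]
        if not shared:
            raise SMRError("no shared SNPs between QTL and GWAS regions")
        top_rsid = max(shared, key=lambda r: abs(r.zscore)).rsid
    qtl_index = qtl_region.by_rsid()
    result = smr_test(qtl_index[top_rsid], gwas_index[top_rsid])
    p_heidi, n_snps = heidi_test(
        qtl_region, gwas_region, ld, top_rsid, **heidi_kwargs
    )
    result.p_heidi = p_heidi
    result.n_heidi_snps = n_snps
    return result


def smr_verdict(result: SMRResult, alpha: float = 0.05) -> str:
    """Label the decision rule: SMR p < alpha and HEIDI p > alpha pass.

    Returns one of ``pass``, ``fail_smr``, ``fail_heidi``,
    ``heidi_unavailable``.
    """
    if result.p_smr >= alpha:
        return "fail_smr"
    if result.p_heidi is None:
        return "heidi_unavailable"
    if result.p_heidi <= alpha:
        return "fail_heidi"
    return "pass"
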