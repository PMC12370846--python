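"""Synthetic GWAS summary statistics with known ground truth.

Generates multi-trait summary statistics directly on the standardized
scale (no individual-level genotypes): per-variant joint effects are
assigned on an exposure -> mediator -> outcome causal chain, propagated
to marginal effects through a block LD matrix (marginal = R @ joint),
and observed with sampling noise of SE = 1/sqrt(n). A region-level
generator produces shared-causal-variant vs linkage scenarios for
SMR/HEIDI testing, and a small fixture registry serves deterministic
unit-test inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from mrchain.ld import LDMatrix
from mrchain.sumstats import HarmonizedPair, SummaryDataset, VariantAssociation

_TINY_P = 5e-324


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    n_variants: int = 100
    n_blocks: int = 20
    within_block_r: float = 0.0
    ld_model: str = "exchangeable"  # or "ar1"
    n_instruments: int = 50
    effect_sd: float = 0.05
    n_exp: int = 100_000
    n_med: int = 100_000
    n_out: int = 100_000
    beta1_true: float = 0.0
    beta2_true: float = 0.0
    direct_true: float = 0.0
    # mediator-specific instruments (variants with direct effects on the
    # mediator only), so the mediator -> outcome leg has its own IVs
    n_med_instruments: int = 0
    med_effect_sd: float = 0.05
    pleiotropy: str = "none"  # "none" | "balanced" | "directional"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments + self.n_med_instruments > self.n_variants:
            raise SimulationError(
                f"{self.n_instruments}+{self.n_med_instruments} instruments "
                f"> {self.n_variants} variants"
            )
        for n in (self.n_exp, self.n_med, self.n_out):
            if n < 100:
                raise SimulationError(f"sample size {n} < 100")
        if not 0.0 <= self.within_block_r < 1.0:
            raise SimulationError("within_block_r must lie in [0, 1)")
        if self.ld_model not in ("exchangeable", "ar1"):
            raise SimulationError(f"unknown ld_model {self.ld_model!r}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise SimulationError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError(f"maf_range {self.maf_range} not within (0, 0.5]")

    @property
    def beta_total_true(self) -> float:
        return self.direct_true + self.beta1_true * self.beta2_true


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated study."""

    marginal: dict[str, np.ndarray]
    joint: dict[str, np.ndarray]
    instrument_idx: np.ndarray
    mediator_instrument_idx: np.ndarray
    beta_total_true: float
    beta1_true: float
    beta2_true: float
    proportion_true: Optional[float]
    ld: LDMatrix


@dataclass
class SimulatedStudy:
    exposure: SummaryDataset
    mediator: SummaryDataset
    outcome: SummaryDataset
    ld: LDMatrix
    truth: SyntheticTruth


def _block_ld(config: SimulationConfig) -> np.ndarray:
    m = config.n_variants
    r = np.eye(m)
    if config.within_block_r == 0.0:
        return r
    sizes = np.full(config.n_blocks, m // config.n_blocks)
    sizes[: m % config.n_blocks] += 1
    start = 0
    for size in sizes:
        if size > 1:
            idx = np.arange(start, start + size)
            if config.ld_model == "exchangeable":
                block = np.full((size, size), config.within_block_r)
                np.fill_diagonal(block, 1.0)
            else:  # ar1
                lags = np.abs(idx[:, None] - idx[None, :])
                block = config.within_block_r ** lags
            r[np.ix_(idx, idx)] = block
        start += size
    return r


def _dataset(
    trait_id: str,
    trait_type: str,
    marginal: np.ndarray,
    n: int,
    maf: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> SummaryDataset:
    m = len(marginal)
    se = 1.0 / math.sqrt(n)
    beta_obs = marginal + rng.normal(0.0, se, m)
    z = beta_obs / se
    pvals = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _TINY_P)
    records = [
        VariantAssociation(
            rsid=f"rs{i + 1}",
            chrom="1",
            pos=int(positions[i]),
            effect_allele="A",
            other_allele="G",
            eaf=float(maf[i]),
            beta=float(beta_obs[i]),
            se=se,
            pval=float(pvals[i]),
            n=n,
            trait_id=trait_id,
        )
        for i in range(m)
    ]
    return SummaryDataset(trait_id=trait_id, trait_type=trait_type, records=records)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate an exposure -> mediator -> outcome chain.

    Joint instrument effects on the exposure are Normal(0, effect_sd^2)
    at ``n_instruments`` randomly chosen variants; mediator joint
    effects are beta1_true times the exposure effects plus optional
    mediator-specific instruments; outcome joint effects are
    direct_true * exposure + beta2_true * mediator plus optional
    pleiotropy draws on a fraction of the exposure instruments.
    Marginal effects are the LD-propagated joint effects and the
    observed betas add Normal(0, 1/n) noise. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    r = _block_ld(config)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    # non-palindromic alleles throughout; clumping is therefore r^2-driven
    positions = (np.arange(m) + 1) * 2000

    perm = rng.permutation(m)
    instr_idx = np.sort(perm[: config.n_instruments])
    med_idx = np.sort(perm[config.n_instruments:
                           config.n_instruments + config.n_med_instruments])

    joint_exp = np.zeros(m)
    joint_exp[instr_idx] = rng.normal(0.0, config.effect_sd, len(instr_idx))
    joint_med = config.beta1_true * joint_exp
    if len(med_idx):
        joint_med[med_idx] += rng.normal(0.0, config.med_effect_sd, len(med_idx))

    pleio = np.zeros(m)
    if config.pleiotropy != "none" and len(instr_idx):
        n_pleio = int(round(config.pleiotropy_frac * len(instr_idx)))
        chosen = rng.choice(instr_idx, size=n_pleio, replace=False)
        if config.pleiotropy == "directional":
            # directional relative to the exposure-increasing allele:
            # drawn on the oriented scale, then mapped back, so the
            # pleiotropic push is sign-consistent with each instrument
            draws = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                               n_pleio)
            pleio[chosen] = draws * np.sign(joint_exp[chosen])
        else:  # balanced
            pleio[chosen] = rng.normal(0.0, config.pleiotropy_sd, n_pleio)

    joint_out = (config.direct_true * joint_exp
                 + config.beta2_true * joint_med
                 + pleio)

    if config.within_block_r == 0.0:
        marg_exp, marg_med, marg_out = joint_exp, joint_med, joint_out
    else:
        marg_exp = r @ joint_exp
        marg_med = r @ joint_med
        marg_out = r @ joint_out

    rsids = [f"rs{i + 1}" for i in range(m)]
    ld = LDMatrix(rsids=rsids, r=r, positions=positions)

    exposure = _dataset("exposure", "quantitative", marg_exp, config.n_exp,
                        maf, positions, rng)
    mediator = _dataset("mediator", "quantitative", marg_med, config.n_med,
                        maf, positions, rng)
    outcome = _dataset("outcome", "binary", marg_out, config.n_out,
                       maf, positions, rng)

    total = config.beta_total_true
    truth = SyntheticTruth(
        marginal={"exposure": marg_exp, "mediator": marg_med, "outcome": marg_out},
        joint={"exposure": joint_exp, "mediator": joint_med, "outcome": joint_out},
        instrument_idx=instr_idx,
        mediator_instrument_idx=med_idx,
        beta_total_true=total,
        beta1_true=config.beta1_true,
        beta2_true=config.beta2_true,
        proportion_true=(
            None if total == 0
            else config.beta1_true * config.beta2_true / total
        ),
        ld=ld,
    )
    return SimulatedStudy(exposure=exposure, mediator=mediator, outcome=outcome,
                          ld=ld, truth=truth)


def simulate_smr_region(
    shared_causal: bool,
    r_between_causals: float = 0.6,
    region_size: int = 60,
    z_at_causal: float = 12.0,
    seed: int = 0,
    n_qtl: int = 10_000,
    n_gwas: int = 10_000,
    ar1_rho: float = 0.9,
) -> tuple[SummaryDataset, SummaryDataset, LDMatrix, str]:
    """One QTL/GWAS region under a shared-causal or linkage scenario.

    AR1(``ar1_rho``) LD across ``region_size`` SNPs. With
    ``shared_causal`` one central variant drives both signals (the HEIDI
    null); otherwise the GWAS causal variant sits at the AR1 lag whose
    correlation with the QTL causal variant is closest to
    ``r_between_causals``. Observed z-scores are the LD-propagated true
    z-scores plus LD-correlated noise. Returns
    (qtl_region, gwas_region, ld, top_rsid) with ``top_rsid`` the
    observed top QTL SNP.
    """
    if region_size < 25:
        raise SimulationError(f"region_size {region_size} < 25")
    rng = np.random.default_rng(seed)
    m = region_size
    lags = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
    r = ar1_rho ** lags

    c_qtl = m // 2
    if shared_causal or r_between_causals >= 1.0:
        c_gwas = c_qtl
    else:
        lag = max(1, int(round(math.log(r_between_causals) / math.log(ar1_rho))))
        c_gwas = min(c_qtl + lag, m - 1)

    z_qtl_true = r[:, c_qtl] * z_at_causal
    z_gwas_true = r[:, c_gwas] * z_at_causal

    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    z_qtl_obs = z_qtl_true + chol @ rng.standard_normal(m)
    z_gwas_obs = z_gwas_true + chol @ rng.standard_normal(m)

    maf = rng.uniform(0.05, 0.5, m)
    positions = (np.arange(m) + 1) * 1000
    rsids = [f"rs{i + 1}" for i in range(m)]
    ld = LDMatrix(rsids=rsids, r=r, positions=positions)

    def build(z_obs: np.ndarray, n: int, trait: str, ttype: str) -> SummaryDataset:
        se = 1.0 / math.sqrt(n)
        beta = z_obs * se
        pvals = np.maximum(2.0 * stats.norm.sf(np.abs(z_obs)), _TINY_P)
        records = [
            VariantAssociation(
                rsid=rsids[i], chrom="1", pos=int(positions[i]),
                effect_allele="A", other_allele="G", eaf=float(maf[i]),
                beta=float(beta[i]), se=se, pval=float(pvals[i]),
                n=n, trait_id=trait,
            )
            for i in range(m)
        ]
        return SummaryDataset(trait_id=trait, trait_type=ttype, records=records)

    qtl = build(z_qtl_obs, n_qtl, "qtl", "quantitative")
    gwas = build(z_gwas_obs, n_gwas, "gwas", "binary")
    top_rsid = rsids[int(np.argmax(np.abs(z_qtl_obs)))]
    return qtl, gwas, ld, top_rsid


def _pairs(bx, sx, by, sy, eaf=0.3, n=20_000) -> list[HarmonizedPair]:
    return [
        HarmonizedPair(
            rsid=f"fix{i + 1}",
            beta_exp=float(bxi), se_exp=float(sxi), eaf_exp=eaf,
            beta_out=float(byi), se_out=float(syi), eaf_out=eaf,
            action="kept", n_exp=n,
        )
        for i, (bxi, sxi, byi, syi) in enumerate(zip(bx, sx, by, sy))
    ]


def _fixture_ivw_basic() -> list[HarmonizedPair]:
    """5-SNP IVW fixture.

    Expected fixed-effect IVW (weighted least squares through the
    origin, weights 1/se_out^2): beta = 0.20516405832473722,
    se = 0.02168938924228125.
    """
    bx = [0.12, 0.09, 0.15, 0.11, 0.08]
    sx = [0.010, 0.012, 0.009, 0.011, 0.010]
    by = [0.024, 0.020, 0.031, 0.021, 0.017]
    sy = [0.005, 0.006, 0.005, 0.007, 0.006]
    return _pairs(bx, sx, by, sy)


def _fixture_egger_affine() -> list[HarmonizedPair]:
    """6 SNPs exactly on beta_out = 0.01 + 0.3 * beta_exp (RSS = 0)."""
    bx = [0.05, 0.08, 0.10, 0.12, 0.15, 0.20]
    by = [0.01 + 0.3 * b for b in bx]
    sx = [0.005] * 6
    sy = [0.010, 0.011, 0.009, 0.012, 0.010, 0.011]
    return _pairs(bx, sx, by, sy)


def _fixture_presso_outlier() -> list[HarmonizedPair]:
    """8 SNPs: seven ratios near 0.3, one planted at 3.0 with small SE."""
    bx = [0.10] * 8
    by = [0.030, 0.029, 0.031, 0.030, 0.032, 0.028, 0.030, 0.300]
    sx = [0.005] * 8
    sy = [0.020] * 8
    return _pairs(bx, sx, by, sy)


def _fixture_median_seven() -> list[HarmonizedPair]:
    """7 SNPs with unequal weights for the weighted-median oracle."""
    bx = [0.10, 0.12, 0.08, 0.15, 0.09, 0.11, 0.13]
    sx = [0.010, 0.008, 0.012, 0.009, 0.011, 0.010, 0.009]
    by = [0.031, 0.034, 0.027, 0.049, 0.024, 0.038, 0.036]
    sy = [0.004, 0.006, 0.005, 0.004, 0.007, 0.005, 0.006]
    return _pairs(bx, sx, by, sy)


_FIXTURES = {
    "ivw_basic": _fixture_ivw_basic,
    "egger_affine": _fixture_egger_affine,
    "presso_outlier": _fixture_presso_outlier,
    "median_seven": _fixture_median_seven,
}


def make_fixture(name: str) -> list[HarmonizedPair]:
    """Deterministic hard-coded test inputs by registry name."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise SimulationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return factory()
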