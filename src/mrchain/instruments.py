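"""Instrumental-variable selection.

Four steps: genome-wide significance screen, MAF filter, greedy LD
clumping (p-value ordered, distance + r^2 pruning), and per-SNP
instrument-strength filtering on the F statistic with

    R^2 = beta^2 / (beta^2 + N * SE^2)
    F   = R^2 * (N - 1 - K) / (K * (1 - R^2))

on standardized effects; the 2*EAF*(1-EAF) factor of the textbook
variance-explained form cancels between numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from mrchain.config import MRConfig
from mrchain.ld import LDMatrix
from mrchain.sumstats import (
    HarmonizedPair,
    SummaryDataset,
    VariantAssociation,
    harmonize,
    retained,
)

logger = logging.getLogger(__name__)


class InstrumentError(ValueError):
    """Invalid input to instrument selection."""


@dataclass
class InstrumentSet:
    """Harmonized instruments with per-SNP variance explained and F."""

    pairs: list[HarmonizedPair]
    r2_exposure: np.ndarray = field(default_factory=lambda: np.empty(0))
    f_stat: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.r2_exposure = np.asarray(self.r2_exposure, dtype=float)
        self.f_stat = np.asarray(self.f_stat, dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [p.rsid for p in self.pairs]

    @property
    def beta_exp(self) -> np.ndarray:
        return np.array([p.beta_exp for p in self.pairs])

    @property
    def se_exp(self) -> np.ndarray:
        return np.array([p.se_exp for p in self.pairs])

    @property
    def beta_out(self) -> np.ndarray:
        return np.array([p.beta_out for p in self.pairs])

    @property
    def se_out(self) -> np.ndarray:
        return np.array([p.se_out for p in self.pairs])


def filter_significance(
    dataset: SummaryDataset, p_threshold: float = 5e-8
) -> SummaryDataset:
    """Retain records with p strictly below the significance threshold."""
    kept = [r for r in dataset.records if r.pval < p_threshold]
    if not kept:
        logger.info(
            "filter_significance(%s): no SNP below %.3g", dataset.trait_id, p_threshold
        )
    return SummaryDataset(dataset.trait_id, dataset.trait_type, kept)


def filter_maf(dataset: SummaryDataset, maf_min: float = 0.01) -> SummaryDataset:
    """Retain records with minor-allele frequency strictly above ``maf_min``.

    Records with missing eaf are retained with a warning (frequency is
    only mandatory later, for palindrome resolution and R^2).
    """
    kept = []
    n_missing = 0
    for rec in dataset.records:
        if rec.maf is None:
            n_missing += 1
            kept.append(rec)
        elif rec.maf > maf_min:
            kept.append(rec)
    if n_missing:
        logger.warning(
            "filter_maf(%s): %d records have no eaf; retained unchecked",
            dataset.trait_id, n_missing,
        )
    return SummaryDataset(dataset.trait_id, dataset.trait_type, kept)


def clump(
    dataset: SummaryDataset,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
    missing: str = "independent",
) -> SummaryDataset:
    """Greedy p-value-ordered LD clumping.

    SNPs are sorted by ascending p (ties broken by rsid); the best
    remaining SNP becomes an index and removes every remaining SNP that
    lies within ``window_kb`` of it and has r^2 >= ``r2_threshold`` with
    it. SNPs absent from the LD reference are either assumed independent
    (``missing="independent"``, default, logged) or dropped
    (``missing="drop"``).
    """
    if missing not in ("independent", "drop"):
        raise InstrumentError(f"unknown missing-SNP policy {missing!r}")
    recs = list(dataset.records)
    absent = [r.rsid for r in recs if r.rsid not in ld]
    if absent:
        if missing == "drop":
            logger.warning("clump: dropping %d SNPs absent from LD", len(absent))
            recs = [r for r in recs if r.rsid in ld]
        else:
            logger.warning(
                "clump: %d SNPs absent from LD reference, assumed independent",
                len(absent),
            )
    order = sorted(recs, key=lambda r: (r.pval, r.rsid))
    window_bp = window_kb * 1000.0
    removed: set[str] = set()
    indices: set[str] = set()
    for idx_rec in order:
        if idx_rec.rsid in removed:
            continue
        indices.add(idx_rec.rsid)
        in_ld = idx_rec.rsid in ld
        pos_i = ld.position(idx_rec.rsid) if in_ld else idx_rec.pos
        for other in order:
            if other.rsid == idx_rec.rsid or other.rsid in removed or other.rsid in indices:
                continue
            other_in_ld = other.rsid in ld
            if not (in_ld and other_in_ld):
                continue  # assumed independent
            pos_j = ld.position(other.rsid)
            if abs(pos_j - pos_i) > window_bp:
                continue
            if ld.corr(idx_rec.rsid, other.rsid) ** 2 >= r2_threshold:
                removed.add(other.rsid)
    return dataset.subset(indices)


def instrument_strength(
    record: VariantAssociation, k_instruments: int = 1
) -> tuple[float, float]:
    """Per-SNP variance explained and F statistic.

    Requires eaf and n; errors otherwise. With K = ``k_instruments``:
    R^2 = beta^2/(beta^2 + N*SE^2), F = R^2*(N-1-K)/(K*(1-R^2)).
    """
    if record.eaf is None:
        raise InstrumentError(f"{record.rsid}: eaf required for R^2/F")
    if record.n is None:
        raise InstrumentError(f"{record.rsid}: sample size required for R^2/F")
    if record.n <= k_instruments + 1:
        raise InstrumentError(
            f"{record.rsid}: n={record.n} too small for K={k_instruments}"
        )
    b2 = record.beta ** 2
    r2 = b2 / (b2 + record.n * record.se ** 2)
    f = r2 * (record.n - 1 - k_instruments) / (k_instruments * (1.0 - r2))
    return r2, f


def _pair_strength(pair: HarmonizedPair, k_instruments: int) -> tuple[float, float]:
    if pair.eaf_exp is None:
        raise InstrumentError(f"{pair.rsid}: exposure eaf required for R^2/F")
    if pair.n_exp is None:
        raise InstrumentError(f"{pair.rsid}: exposure n required for R^2/F")
    if pair.n_exp <= k_instruments + 1:
        raise InstrumentError(f"{pair.rsid}: n={pair.n_exp} too small")
    b2 = pair.beta_exp ** 2
    r2 = b2 / (b2 + pair.n_exp * pair.se_exp ** 2)
    f = r2 * (pair.n_exp - 1 - k_instruments) / (k_instruments * (1.0 - r2))
    return r2, f


def build_instrument_set(
    pairs: list[HarmonizedPair], k_instruments: int = 1
) -> InstrumentSet:
    """Attach per-SNP R^2 and F to retained harmonized pairs."""
    kept = retained(pairs)
    strengths = [_pair_strength(p, k_instruments) for p in kept]
    r2 = np.array([s[0] for s in strengths])
    f = np.array([s[1] for s in strengths])
    return InstrumentSet(pairs=kept, r2_exposure=r2, f_stat=f)


def filter_f(instruments: InstrumentSet, f_min: float = 20.0) -> InstrumentSet:
    """Exclude instruments with F < ``f_min`` (strict); F = f_min is retained."""
    keep = instruments.f_stat >= f_min
    n_drop = int((~keep).sum())
    if n_drop:
        dropped = [p.rsid for p, k in zip(instruments.pairs, keep) if not k]
        logger.info("filter_f: excluded %d weak instruments: %s", n_drop, dropped[:10])
    return InstrumentSet(
        pairs=[p for p, k in zip(instruments.pairs, keep) if k],
        r2_exposure=instruments.r2_exposure[keep],
        f_stat=instruments.f_stat[keep],
    )


def joint_f(instruments: InstrumentSet) -> float:
    """Informational joint F over all retained instruments (K = nsnp)."""
    k = len(instruments)
    if k == 0:
        return float("nan")
    r2_total = min(float(instruments.r2_exposure.sum()), 1.0 - 1e-12)
    n = min(p.n_exp for p in instruments.pairs if p.n_exp is not None)
    return r2_total * (n - 1 - k) / (k * (1.0 - r2_total))


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    config: MRConfig | None = None,
) -> InstrumentSet:
    """Full selection cascade: significance -> MAF -> clump -> harmonize -> F.

    Pairs with missing exposure eaf or n at the strength step are dropped
    with a warning rather than failing the whole run.
    """
    config = config or MRConfig()
    ds = filter_significance(exposure, config.p_threshold)
    ds = filter_maf(ds, config.maf_min)
    if len(ds) == 0:
        return InstrumentSet(pairs=[])
    ds = clump(ds, ld, config.clump_r2, config.clump_kb, config.clump_missing)
    try:
        pairs, _ = harmonize(ds, outcome, config.palindrome_window)
    except Exception:
        logger.warning(
            "select_instruments(%s): no overlap with outcome", exposure.trait_id
        )
        return InstrumentSet(pairs=[])
    kept = retained(pairs)
    usable, skipped = [], []
    for p in kept:
        if p.eaf_exp is None or p.n_exp is None:
            skipped.append(p.rsid)
        else:
            usable.append(p)
    if skipped:
        logger.warning(
            "select_instruments(%s): %d pairs lack eaf/n for F, dropped: %s",
            exposure.trait_id, len(skipped), skipped[:10],
        )
    iset = build_instrument_set(usable, config.k_instruments)
    return filter_f(iset, config.f_min)
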