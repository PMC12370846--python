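"""GWAS summary-statistics data model, I/O, and allele harmonization.

The atoms of the pipeline are per-SNP association records
(:class:`VariantAssociation`) grouped into per-trait datasets
(:class:`SummaryDataset`). :func:`harmonize` places an exposure and an
outcome dataset on a common effect-allele frame, resolving strand flips
and palindromic SNPs via allele frequency, and dropping irreconcilable
allele pairs.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column names of the on-disk tab-separated format.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

#: Columns that must be present (directly or via ``column_map``).
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]


class SumstatsError(ValueError):
    """Malformed summary-statistics input."""


class HarmonizationError(ValueError):
    """Exposure/outcome pair cannot be harmonized (e.g. empty rsid overlap)."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele estimate (log odds for binary
    traits); ``eaf`` is the effect-allele frequency and may be missing
    (``None``); ``n`` may be missing when the source does not report
    per-SNP sample sizes.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: Optional[int]
    trait_id: str

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise SumstatsError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not a single base"
            )
        if self.other_allele not in _VALID_ALLELES:
            raise SumstatsError(
                f"{self.rsid}: other allele {self.other_allele!r} is not a single base"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise SumstatsError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise SumstatsError(f"{self.rsid}: beta must be finite, got {self.beta}")
        if not (0 < self.pval <= 1):
            raise SumstatsError(f"{self.rsid}: pval must be in (0, 1], got {self.pval}")
        if self.n is not None and self.n < 1:
            raise SumstatsError(f"{self.rsid}: n must be >= 1, got {self.n}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise SumstatsError(
                f"{self.rsid}: eaf must be strictly in (0, 1), got {self.eaf}"
            )

    @property
    def maf(self) -> Optional[float]:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; None if eaf missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G allele pairs (strand-ambiguous)."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryDataset:
    """Per-trait container of :class:`VariantAssociation` with unique rsids."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.trait_id != self.trait_id:
                raise SumstatsError(
                    f"record {rec.rsid} has trait_id {rec.trait_id!r}, "
                    f"dataset is {self.trait_id!r}"
                )
            if rec.rsid in seen:
                raise SumstatsError(f"duplicate rsid {rec.rsid} in {self.trait_id}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_rsid(self) -> dict[str, VariantAssociation]:
        return {rec.rsid: rec for rec in self.records}

    def subset(self, rsids) -> "SummaryDataset":
        """New dataset restricted to ``rsids``, preserving record order."""
        keep = set(rsids)
        return SummaryDataset(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.rsid in keep],
        )


@dataclass
class IngestAudit:
    """Row accounting for :func:`read_sumstats`."""

    n_rows: int = 0
    n_kept: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)


@dataclass
class HarmonizedPair:
    """One SNP's exposure/outcome effects on a common allele frame.

    ``action`` records what happened during harmonization: ``kept``
    (outcome already on the exposure frame), ``flipped`` (outcome beta
    negated, eaf mirrored), or ``dropped`` (with ``drop_reason``).
    ``eaf_exp``/``n_exp`` are carried along for downstream instrument
    strength computation.
    """

    rsid: str
    beta_exp: float
    se_exp: float
    eaf_exp: Optional[float]
    beta_out: float
    se_out: float
    eaf_out: Optional[float]
    action: str = "kept"
    drop_reason: str = ""
    n_exp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.action not in ("kept", "flipped", "dropped"):
            raise SumstatsError(f"invalid action {self.action!r}")
        if (self.action == "dropped") != bool(self.drop_reason):
            raise SumstatsError("action 'dropped' iff drop_reason non-empty")
        if self.action != "dropped" and (self.se_exp <= 0 or self.se_out <= 0):
            raise SumstatsError(f"{self.rsid}: non-positive SE in retained pair")


@dataclass
class HarmonizeAudit:
    n_intersection: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)


def _parse_optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "nan", "."):
        return None
    return float(value)


def _parse_optional_int(value) -> Optional[int]:
    f = _parse_optional_float(value)
    return None if f is None else int(round(f))


def read_sumstats(
    path,
    trait_id: str,
    trait_type: str = "quantitative",
    column_map: Optional[dict[str, str]] = None,
    sep: str = "\t",
) -> tuple[SummaryDataset, IngestAudit]:
    """Read a delimited summary-statistics table.

    ``column_map`` maps canonical names (``SNP``, ``CHR``, ``POS``,
    ``EA``, ``OA``, ``EAF``, ``BETA``, ``SE``, ``P``, ``N``) to the
    source file's headers, so arbitrary source formats are mappable via
    configuration. Rows violating :class:`VariantAssociation`
    invariants are skipped and counted in the returned audit; a missing
    EAF field is parsed as missing, never as zero.
    """
    column_map = column_map or {}
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except OSError as exc:
        raise SumstatsError(f"cannot read {path}: {exc}") from exc

    resolved = {canon: column_map.get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [
        canon for canon in MANDATORY_COLUMNS if resolved[canon] not in df.columns
    ]
    if missing:
        raise SumstatsError(
            f"{path}: missing mandatory column(s) {missing} "
            f"(available: {list(df.columns)})"
        )

    def col(row, canon, default=None):
        name = resolved[canon]
        return row[name] if name in df.columns else default

    audit = IngestAudit(n_rows=len(df))
    records: list[VariantAssociation] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        try:
            rsid = str(col(row, "SNP")).strip()
            if rsid in seen:
                raise SumstatsError(f"duplicate rsid {rsid}")
            ea = str(col(row, "EA")).strip().upper()
            oa = str(col(row, "OA")).strip().upper()
            rec = VariantAssociation(
                rsid=rsid,
                chrom=str(col(row, "CHR", "0")).strip(),
                pos=_parse_optional_int(col(row, "POS")) or 0,
                effect_allele=ea,
                other_allele=oa,
                eaf=_parse_optional_float(col(row, "EAF")),
                beta=float(col(row, "BETA")),
                se=float(col(row, "SE")),
                pval=float(col(row, "P")),
                n=_parse_optional_int(col(row, "N")),
                trait_id=trait_id,
            )
        except (SumstatsError, ValueError, TypeError) as exc:
            audit.n_skipped += 1
            audit.skip_reasons[type(exc).__name__ + ": " + str(exc)[:60]] += 1
            continue
        seen.add(rsid)
        records.append(rec)
        audit.n_kept += 1

    if audit.n_skipped:
        logger.info(
            "read_sumstats(%s): skipped %d/%d rows (%s)",
            path, audit.n_skipped, audit.n_rows, dict(audit.skip_reasons),
        )
    return SummaryDataset(trait_id=trait_id, trait_type=trait_type, records=records), audit


def write_sumstats(dataset: SummaryDataset, path) -> None:
    """Write a dataset as canonical tab-separated text (round-trip safe).

    Missing eaf/n are written as empty fields so that
    ``read_sumstats(write_sumstats(d))`` reproduces ``d`` exactly.
    """
    rows = []
    for rec in dataset.records:
        rows.append({
            "SNP": rec.rsid,
            "CHR": rec.chrom,
            "POS": rec.pos,
            "EA": rec.effect_allele,
            "OA": rec.other_allele,
            "EAF": "" if rec.eaf is None else repr(rec.eaf),
            "BETA": repr(rec.beta),
            "SE": repr(rec.se),
            "P": repr(rec.pval),
            "N": "" if rec.n is None else rec.n,
        })
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def _complement_record(rec: VariantAssociation) -> VariantAssociation:
    return replace(
        rec,
        effect_allele=_COMPLEMENT[rec.effect_allele],
        other_allele=_COMPLEMENT[rec.other_allele],
    )


def _flip_record(rec: VariantAssociation) -> VariantAssociation:
    """Re-express the record with effect and other allele swapped."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_window: float = 0.08,
) -> tuple[list[HarmonizedPair], HarmonizeAudit]:
    """Place outcome effects on the exposure's effect-allele frame.

    Pairs are formed on the rsid intersection (exposure record order).
    Non-palindromic SNPs are matched directly, after allele swap, or
    after strand complementation; irreconcilable allele sets (e.g. A/G
    vs A/C) are dropped as incompatible. Palindromic SNPs (A/T, C/G)
    are resolved by allele frequency: dropped when either frequency is
    missing or within ``palindrome_window`` of 0.5, kept when both
    frequencies fall on the same side of 0.5, flipped otherwise.

    Returns the pair list (kept, flipped, and dropped entries) and an
    audit whose counts satisfy kept + flipped + dropped = intersection.
    """
    out_index = outcome.by_rsid()
    pairs: list[HarmonizedPair] = []
    audit = HarmonizeAudit()
    w = palindrome_window

    for exp in exposure.records:
        out = out_index.get(exp.rsid)
        if out is None:
            continue
        audit.n_intersection += 1

        exp_set = {exp.effect_allele, exp.other_allele}
        out_set = {out.effect_allele, out.other_allele}
        comp_out_set = {_COMPLEMENT[a] for a in out_set}

        action = None
        drop_reason = ""
        aligned = out

        if exp.is_palindromic:
            if out_set != exp_set:
                action, drop_reason = "dropped", "incompatible"
            else:
                # Nominal alignment first (swap if EA labels disagree),
                # then resolve residual strand ambiguity by frequency.
                n_flips = 0
                if out.effect_allele != exp.effect_allele:
                    aligned = _flip_record(out)
                    n_flips += 1
                if exp.eaf is None or aligned.eaf is None:
                    action, drop_reason = "dropped", "palindromic_missing_eaf"
                elif (abs(exp.eaf - 0.5) <= w + 1e-12
                      or abs(aligned.eaf - 0.5) <= w + 1e-12):
                    action, drop_reason = "dropped", "palindromic_ambiguous"
                else:
                    if (exp.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
                        aligned = _flip_record(aligned)
                        n_flips += 1
                    action = "flipped" if n_flips % 2 else "kept"
        else:
            if out_set == exp_set:
                pass  # same strand
            elif comp_out_set == exp_set:
                aligned = _complement_record(out)
            else:
                action, drop_reason = "dropped", "incompatible"
            if action is None:
                if aligned.effect_allele == exp.effect_allele:
                    action = "kept"
                else:
                    aligned = _flip_record(aligned)
                    action = "flipped"

        if action == "dropped":
            audit.n_dropped += 1
            audit.drop_reasons[drop_reason] += 1
            pairs.append(HarmonizedPair(
                rsid=exp.rsid,
                beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
                beta_out=out.beta, se_out=out.se, eaf_out=out.eaf,
                action="dropped", drop_reason=drop_reason, n_exp=exp.n,
            ))
        else:
            if action == "kept":
                audit.n_kept += 1
            else:
                audit.n_flipped += 1
            pairs.append(HarmonizedPair(
                rsid=exp.rsid,
                beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
                beta_out=aligned.beta, se_out=aligned.se, eaf_out=aligned.eaf,
                action=action, n_exp=exp.n,
            ))

    if audit.n_intersection == 0:
        raise HarmonizationError(
            f"no rsid overlap between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )
    logger.info(
        "harmonize(%s vs %s): %d shared SNPs — kept %d, flipped %d, dropped %d %s",
        exposure.trait_id, outcome.trait_id, audit.n_intersection,
        audit.n_kept, audit.n_flipped, audit.n_dropped, dict(audit.drop_reasons),
    )
    return pairs, audit


def retained(pairs: list[HarmonizedPair]) -> list[HarmonizedPair]:
    """Kept + flipped pairs, dropping the dropped."""
    return [p for p in pairs if p.action != "dropped"]
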