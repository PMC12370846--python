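"""Shared test helpers: quick builders for records, datasets, and pairs."""

from __future__ import annotations

import numpy as np
import pytest

from mrchain.sumstats import HarmonizedPair, SummaryDataset, VariantAssociation


def mk_record(
    rsid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
    beta=0.1, se=0.01, pval=1e-10, n=20_000, trait_id="trait",
) -> VariantAssociation:
    return VariantAssociation(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n, trait_id=trait_id,
    )


def mk_dataset(records, trait_id="trait", trait_type="quantitative") -> SummaryDataset:
    from dataclasses import replace

    records = [r if r.trait_id == trait_id else replace(r, trait_id=trait_id)
               for r in records]
    return SummaryDataset(trait_id=trait_id, trait_type=trait_type,
                          records=records)


def mk_pairs(bx, by, sy, sx=None, eaf=0.3, n=20_000) -> list[HarmonizedPair]:
    sx = sx if sx is not None else [0.01] * len(bx)
    return [
        HarmonizedPair(
            rsid=f"rs{i + 1}", beta_exp=float(b), se_exp=float(s),
            eaf_exp=eaf, beta_out=float(o), se_out=float(so), eaf_out=eaf,
            action="kept", n_exp=n,
        )
        for i, (b, s, o, so) in enumerate(zip(bx, sx, by, sy))
    ]


def random_pairs(rng: np.random.Generator, n: int) -> list[HarmonizedPair]:
    """Random but well-conditioned instrument fixtures."""
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1.0, 1.0], n)
    sx = rng.uniform(0.005, 0.02, n)
    by = 0.2 * bx + rng.normal(0, 0.01, n)
    sy = rng.uniform(0.005, 0.02, n)
    return mk_pairs(bx, by, sy, sx=sx)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)
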