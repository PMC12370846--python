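"""sumstats_core: ingestion, round-trip I/O, and harmonization rules."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrchain.sumstats import (
    HarmonizationError,
    SumstatsError,
    VariantAssociation,
    harmonize,
    read_sumstats,
    retained,
    write_sumstats,
)

from conftest import mk_dataset, mk_record

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, rows, name="ss.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(rows))
    return path


class TestRead:
    def test_three_wellformed_rows(self, tmp_path):
        rows = [
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-10\t10000\n",
            "rs2\t1\t200\tC\tT\t0.2\t-0.05\t0.02\t0.01\t10000\n",
            "rs3\t2\t300\tG\tA\t0.4\t0.0\t0.01\t0.99\t10000\n",
        ]
        ds, audit = read_sumstats(_write(tmp_path, rows), trait_id="x")
        assert len(ds) == 3
        assert audit.n_skipped == 0
        assert ds.records[0].rsid == "rs1"
        assert ds.records[1].beta == -0.05

    def test_zero_se_row_skipped(self, tmp_path):
        rows = [
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-10\t10000\n",
            "rs2\t1\t200\tC\tT\t0.2\t0.05\t0\t0.01\t10000\n",
        ]
        ds, audit = read_sumstats(_write(tmp_path, rows), trait_id="x")
        assert len(ds) == 1
        assert audit.n_skipped == 1

    def test_missing_eaf_kept_as_missing(self, tmp_path):
        rows = ["rs1\t1\t100\tA\tG\t\t0.1\t0.01\t1e-10\t10000\n"]
        ds, audit = read_sumstats(_write(tmp_path, rows), trait_id="x")
        assert audit.n_skipped == 0
        assert ds.records[0].eaf is None

    def test_indel_rejected(self, tmp_path):
        rows = ["rs1\t1\t100\tAT\tG\t0.3\t0.1\t0.01\t1e-10\t10000\n"]
        ds, audit = read_sumstats(_write(tmp_path, rows), trait_id="x")
        assert len(ds) == 0
        assert audit.n_skipped == 1

    def test_column_map(self, tmp_path):
        path = tmp_path / "mapped.tsv"
        path.write_text(
            "rsids\tref\talt\tbeta\tsebeta\tpval\n"
            "rs1\tG\tA\t0.1\t0.01\t1e-9\n"
        )
        ds, _ = read_sumstats(
            path, trait_id="x",
            column_map={"SNP": "rsids", "EA": "alt", "OA": "ref",
                        "BETA": "beta", "SE": "sebeta", "P": "pval"},
        )
        assert len(ds) == 1
        assert ds.records[0].effect_allele == "A"
        assert ds.records[0].n is None

    def test_missing_mandatory_column_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tEA\tOA\n" "rs1\tA\tG\n")
        with pytest.raises(SumstatsError, match="mandatory"):
            read_sumstats(path, trait_id="x")


class TestWrite:
    def test_empty_dataset_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_sumstats(mk_dataset([]), path)
        assert path.read_text().strip().split("\n") == [HEADER.strip()]

    def test_three_records_four_lines(self, tmp_path):
        ds = mk_dataset([mk_record(rsid=f"rs{i}") for i in range(3)])
        path = tmp_path / "out.tsv"
        write_sumstats(ds, path)
        assert len(path.read_text().strip().split("\n")) == 4

    def test_roundtrip_missing_eaf(self, tmp_path):
        ds = mk_dataset([mk_record(eaf=None), mk_record(rsid="rs2", eaf=0.25)])
        path = tmp_path / "rt.tsv"
        write_sumstats(ds, path)
        back, audit = read_sumstats(path, trait_id="trait")
        assert audit.n_skipped == 0
        assert back.records[0].eaf is None
        assert back.records[1].eaf == 0.25


_allele_pair = st.sampled_from(
    [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
)


@st.composite
def _variant(draw, rsid: str):
    ea, oa = draw(_allele_pair)
    eaf = draw(st.one_of(st.none(), st.floats(0.01, 0.99)))
    return VariantAssociation(
        rsid=rsid, chrom="1", pos=draw(st.integers(1, 10**6)),
        effect_allele=ea, other_allele=oa, eaf=eaf,
        beta=draw(st.floats(-2, 2, allow_nan=False)),
        se=draw(st.floats(1e-6, 1.0)),
        pval=draw(st.floats(1e-30, 1.0, exclude_min=False)),
        n=draw(st.one_of(st.none(), st.integers(1, 10**6))),
        trait_id="trait",
    )


@st.composite
def _dataset(draw, min_size=0, max_size=8):
    size = draw(st.integers(min_size, max_size))
    return mk_dataset([draw(_variant(f"rs{i}")) for i in range(size)])


@settings(max_examples=50, deadline=None)
@given(_dataset())
def test_roundtrip_property(tmp_path_factory, ds):
    path = tmp_path_factory.mktemp("rt") / "ds.tsv"
    write_sumstats(ds, path)
    back, audit = read_sumstats(path, trait_id="trait")
    assert audit.n_skipped == 0
    assert back.records == ds.records


class TestHarmonize:
    def test_swapped_alleles_flip(self):
        exp = mk_dataset([mk_record(ea="A", oa="G", beta=0.10)], trait_id="e")
        out = mk_dataset(
            [mk_record(ea="G", oa="A", beta=0.05, eaf=0.70, trait_id="o")],
            trait_id="o",
        )
        pairs, audit = harmonize(exp, out)
        assert pairs[0].action == "flipped"
        assert pairs[0].beta_out == -0.05
        assert pairs[0].eaf_out == pytest.approx(0.30)
        assert audit.n_flipped == 1

    def test_incompatible_dropped(self):
        exp = mk_dataset([mk_record(ea="A", oa="G")], trait_id="e")
        out = mk_dataset([mk_record(ea="A", oa="C", trait_id="o")], trait_id="o")
        pairs, audit = harmonize(exp, out)
        assert pairs[0].action == "dropped"
        assert pairs[0].drop_reason == "incompatible"
        assert audit.drop_reasons["incompatible"] == 1

    def test_strand_complement(self):
        # exposure A/G vs outcome T/C: same variant on opposite strands
        exp = mk_dataset([mk_record(ea="A", oa="G", beta=0.1)], trait_id="e")
        out = mk_dataset(
            [mk_record(ea="T", oa="C", beta=0.05, trait_id="o")], trait_id="o"
        )
        pairs, _ = harmonize(exp, out)
        assert pairs[0].action == "kept"
        assert pairs[0].beta_out == 0.05

    @pytest.mark.parametrize(
        "eaf_out, expected_action, expected_beta",
        [(0.88, "flipped", -0.05), (0.12, "kept", 0.05)],
    )
    def test_palindromic_frequency_inference(self, eaf_out, expected_action,
                                             expected_beta):
        exp = mk_dataset(
            [mk_record(ea="A", oa="T", eaf=0.10, beta=0.1)], trait_id="e"
        )
        out = mk_dataset(
            [mk_record(ea="A", oa="T", eaf=eaf_out, beta=0.05, trait_id="o")],
            trait_id="o",
        )
        pairs, _ = harmonize(exp, out)
        assert pairs[0].action == expected_action
        assert pairs[0].beta_out == pytest.approx(expected_beta)

    def test_palindromic_missing_eaf_dropped(self):
        exp = mk_dataset([mk_record(ea="A", oa="T", eaf=0.10)], trait_id="e")
        out = mk_dataset(
            [mk_record(ea="A", oa="T", eaf=None, trait_id="o")], trait_id="o"
        )
        pairs, _ = harmonize(exp, out)
        assert pairs[0].action == "dropped"
        assert pairs[0].drop_reason == "palindromic_missing_eaf"

    @pytest.mark.parametrize("eaf", [0.42, 0.5, 0.58])
    def test_palindromic_ambiguous_window(self, eaf):
        exp = mk_dataset([mk_record(ea="C", oa="G", eaf=eaf)], trait_id="e")
        out = mk_dataset(
            [mk_record(ea="C", oa="G", eaf=0.2, trait_id="o")], trait_id="o"
        )
        pairs, _ = harmonize(exp, out)
        assert pairs[0].drop_reason == "palindromic_ambiguous"

    def test_empty_intersection_raises(self):
        exp = mk_dataset([mk_record(rsid="rs1")], trait_id="e")
        out = mk_dataset([mk_record(rsid="rs2", trait_id="o")], trait_id="o")
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_conservation_property(data):
    """kept + flipped + dropped equals the rsid intersection size."""
    n = data.draw(st.integers(1, 10))
    exp = mk_dataset(
        [data.draw(_variant(f"rs{i}")) for i in range(n)], trait_id="trait"
    )
    out = mk_dataset(
        [data.draw(_variant(f"rs{i}")) for i in range(n)], trait_id="trait"
    )
    pairs, audit = harmonize(exp, out)
    assert audit.n_kept + audit.n_flipped + audit.n_dropped == audit.n_intersection
    assert audit.n_intersection == n
    assert len(pairs) == n


def test_involution_property(rng):
    """Swapping outcome alleles and negating betas leaves the retained
    set and the final harmonized beta_out values unchanged."""
    from dataclasses import replace

    exp_records, out_records = [], []
    alleles = [("A", "G"), ("C", "T"), ("A", "T"), ("C", "G"), ("G", "T")]
    for i, (ea, oa) in enumerate(alleles * 3):
        eaf_e = float(rng.uniform(0.05, 0.95))
        eaf_o = float(rng.uniform(0.05, 0.95))
        exp_records.append(mk_record(
            rsid=f"rs{i}", ea=ea, oa=oa, eaf=eaf_e,
            beta=float(rng.normal(0, 0.1)),
        ))
        out_records.append(mk_record(
            rsid=f"rs{i}", ea=ea, oa=oa, eaf=eaf_o,
            beta=float(rng.normal(0, 0.1)), trait_id="o",
        ))
    exp = mk_dataset(exp_records, trait_id="trait")
    out = mk_dataset(out_records, trait_id="o")
    swapped = mk_dataset(
        [replace(r, effect_allele=r.other_allele, other_allele=r.effect_allele,
                 beta=-r.beta, eaf=None if r.eaf is None else 1 - r.eaf)
         for r in out_records],
        trait_id="o",
    )
    pairs_a, _ = harmonize(exp, out)
    pairs_b, _ = harmonize(exp, swapped)
    kept_a = {p.rsid: p.beta_out for p in retained(pairs_a)}
    kept_b = {p.rsid: p.beta_out for p in retained(pairs_b)}
    assert set(kept_a) == set(kept_b)
    for rsid in kept_a:
        assert kept_a[rsid] == pytest.approx(kept_b[rsid], abs=1e-12)


def test_dataset_invariants():
    with pytest.raises(SumstatsError, match="duplicate"):
        mk_dataset([mk_record(), mk_record()])
    with pytest.raises(SumstatsError):
        mk_record(ea="A", oa="A")
    with pytest.raises(SumstatsError):
        mk_record(pval=0.0)
    with pytest.raises(SumstatsError):
        mk_record(eaf=1.0)
    with pytest.raises(SumstatsError):
        mk_record(se=-1.0)
    assert mk_record(pval=1.0).pval == 1.0
    assert math.isclose(mk_record(eaf=0.7).maf, 0.3)
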