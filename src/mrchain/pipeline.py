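"""Three-stage orchestration, configuration, and report writing.

Stage 1 screens candidate exposures against the outcome with the five
MR methods and the joint IVW-p + Egger-direction rule, optionally
validated by SMR + HEIDI at the region level. Stage 2 runs upstream
mediation (e.g. methylation -> gene -> outcome), stage 3 downstream
mediation (gene -> trait -> outcome). ``run_pipeline`` drives all
stages from a single TOML config (real input files or a ``[simulate]``
block) and writes deterministic tab-separated tables plus a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from mrchain import __version__
from mrchain.config import MRConfig
from mrchain.estimators import MRResult
from mrchain.instruments import select_instruments
from mrchain.ld import LDMatrix, read_ld_matrix, write_ld_matrix
from mrchain.mediation import (
    MediationResult,
    mediation_table,
    two_step_mediation,
    MediationError,
)
from mrchain.sensitivity import SensitivityReport, format_report, sensitivity_report
from mrchain.simulate import SimulationConfig, simulate_smr_region, simulate_study
from mrchain.smr import SMRResult, smr_verdict, smr_with_heidi
from mrchain.sumstats import SummaryDataset, read_sumstats, write_sumstats

logger = logging.getLogger(__name__)

VERDICTS = (
    "significant", "rejected_pvalue", "rejected_direction",
    "rejected_sensitivity", "rejected_smr", "rejected_heidi",
)


class PipelineError(ValueError):
    """Configuration or input problem at the pipeline level."""


@dataclass
class StageDecision:
    unit_id: str
    mr_results: dict[str, MRResult] = field(default_factory=dict)
    sensitivity: Optional[SensitivityReport] = None
    smr: Optional[SMRResult] = None
    verdict: str = "rejected_pvalue"
    notes: list[str] = field(default_factory=list)


def _decide(methods: dict, sensitivity: Optional[SensitivityReport],
            alpha: float, strict: bool) -> tuple[str, list[str]]:
    """The screening rule: IVW p < alpha and IVW/Egger signs aligned.

    Heterogeneity (Q) and Egger-intercept findings warn rather than
    reject unless ``strict`` gating is on.
    """
    notes: list[str] = []
    ivw_res = methods["ivw"]
    if not ivw_res.pval < alpha:
        return "rejected_pvalue", notes
    if "egger" in methods:
        if ivw_res.beta * methods["egger"].beta <= 0:
            return "rejected_direction", notes
    else:
        notes.append("egger_unavailable")
    if sensitivity is not None:
        if sensitivity.q_pval < alpha:
            notes.append("heterogeneity_warning")
        if (sensitivity.egger_intercept_pval is not None
                and sensitivity.egger_intercept_pval < alpha):
            notes.append("pleiotropy_warning")
        if strict and ("heterogeneity_warning" in notes
                       or "pleiotropy_warning" in notes):
            return "rejected_sensitivity", notes
    return "significant", notes


def stage1_screen(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    ld: LDMatrix,
    config: MRConfig | None = None,
) -> list[StageDecision]:
    """Screen each exposure against the outcome with the five MR methods."""
    from mrchain.estimators import all_methods

    config = config or MRConfig()
    decisions = []
    for exposure in exposures:
        decision = StageDecision(unit_id=exposure.trait_id)
        instruments = select_instruments(exposure, outcome, ld, config)
        if len(instruments) == 0:
            decision.verdict = "rejected_pvalue"
            decision.notes.append("no_instruments")
            logger.warning("stage1: %s has no surviving instruments",
                           exposure.trait_id)
            decisions.append(decision)
            continue
        methods = all_methods(
            instruments,
            effects_model=config.effects_model,
            n_boot=config.n_boot,
            seed=config.seed,
            include_supplementary=config.record_all_methods,
        )
        decision.mr_results = {
            k: v for k, v in methods.items() if isinstance(v, MRResult)
        }
        if len(instruments) >= 2:
            decision.sensitivity = sensitivity_report(
                instruments, seed=config.seed,
                effects_model=config.effects_model,
                run_presso=len(instruments) >= 4,
            )
        decision.verdict, decision.notes = _decide(
            methods, decision.sensitivity, config.alpha,
            config.strict_sensitivity,
        )
        decisions.append(decision)
    return decisions


def stage1_validate_smr(
    candidates: list[StageDecision],
    qtl_regions: dict[str, SummaryDataset],
    gwas_region: SummaryDataset,
    ld: LDMatrix,
    config: MRConfig | None = None,
) -> list[StageDecision]:
    """SMR + HEIDI validation of stage-1 significant candidates.

    A candidate stays significant only when SMR p < alpha and HEIDI
    p > alpha; ``heidi_unavailable`` is recorded as a note when fewer
    than ``heidi_min_snps`` SNPs are eligible.
    """
    config = config or MRConfig()
    for decision in candidates:
        if decision.verdict != "significant":
            continue
        if decision.unit_id not in qtl_regions:
            raise PipelineError(f"no QTL region data for {decision.unit_id}")
        result = smr_with_heidi(
            qtl_regions[decision.unit_id], gwas_region, ld,
            r2_min=config.smr_r2_min, r2_max=config.smr_r2_max,
            max_snps=config.heidi_max_snps, min_snps=config.heidi_min_snps,
            n_mc=config.heidi_n_mc, seed=config.seed,
        )
        decision.smr = result
        label = smr_verdict(result, config.alpha)
        if label == "fail_smr":
            decision.verdict = "rejected_smr"
        elif label == "fail_heidi":
            decision.verdict = "rejected_heidi"
        elif label == "heidi_unavailable":
            decision.notes.append("heidi_unavailable")
    return candidates


def stage2_upstream(
    methylation_ds_list: list[SummaryDataset],
    gene_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    ld: LDMatrix,
    config: MRConfig | None = None,
) -> list[MediationResult]:
    """Upstream mediation: each CpG -> gene -> outcome chain."""
    config = config or MRConfig()
    results = []
    for cpg in methylation_ds_list:
        try:
            results.append(
                two_step_mediation(cpg, gene_ds, outcome_ds, ld, config)
            )
        except MediationError as exc:
            logger.info("stage2: %s skipped (%s)", cpg.trait_id, exc)
    return results


def stage3_downstream(
    gene_ds: SummaryDataset,
    immune_ds_list: list[SummaryDataset],
    outcome_ds: SummaryDataset,
    ld: LDMatrix,
    config: MRConfig | None = None,
) -> list[MediationResult]:
    """Downstream mediation: gene -> each immune trait -> outcome chain."""
    config = config or MRConfig()
    results = []
    for trait in immune_ds_list:
        try:
            results.append(
                two_step_mediation(gene_ds, trait, outcome_ds, ld, config)
            )
        except MediationError as exc:
            logger.info("stage3: %s skipped (%s)", trait.trait_id, exc)
    return results


# ---------------------------------------------------------------- run_pipeline

def _mr_table(decisions: list[StageDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        for name, r in sorted(d.mr_results.items()):
            rows.append({
                "unit": d.unit_id, "method": name, "nsnp": r.nsnp,
                "beta": r.beta, "se": r.se, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "pval": r.pval,
                "odds_ratio": r.odds_ratio, "or_ci_low": r.or_ci_low,
                "or_ci_high": r.or_ci_high,
                "verdict": d.verdict, "notes": ";".join(d.notes),
            })
        if not d.mr_results:
            rows.append({"unit": d.unit_id, "method": "", "nsnp": 0,
                         "verdict": d.verdict, "notes": ";".join(d.notes)})
    return pd.DataFrame(rows)


def _sensitivity_table(decisions: list[StageDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        s = d.sensitivity
        if s is None:
            continue
        rows.append({
            "unit": d.unit_id, "q_stat": s.q_stat, "q_df": s.q_df,
            "q_pval": s.q_pval,
            "egger_intercept": s.egger_intercept,
            "egger_intercept_pval": s.egger_intercept_pval,
            "presso_global_pval": s.presso_global_pval,
            "presso_outliers": ";".join(s.presso_outliers),
            "presso_distortion_pval": s.presso_distortion_pval,
        })
    return pd.DataFrame(rows)


def _smr_table(decisions: list[StageDecision], alpha: float) -> pd.DataFrame:
    rows = []
    for d in decisions:
        if d.smr is None:
            continue
        rows.append({
            "unit": d.unit_id, "top_rsid": d.smr.top_rsid,
            "b_xy": d.smr.b_xy, "se_xy": d.smr.se_xy,
            "p_smr": d.smr.p_smr,
            "p_heidi": d.smr.p_heidi,
            "n_heidi_snps": d.smr.n_heidi_snps,
            "verdict": smr_verdict(d.smr, alpha),
        })
    return pd.DataFrame(rows)


def _load_config(config_path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise PipelineError(f"config file {path} does not exist")
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(
    config_path,
    out_dir: Optional[str] = None,
    seed: Optional[int] = None,
) -> Path:
    """Execute the configured stages end to end; returns the report dir.

    The TOML config has a ``[run]`` table (stages, seed, out_dir), a
    ``[thresholds]`` table mapping onto :class:`MRConfig`, and either a
    ``[simulate]`` block (self-contained synthetic run) or an
    ``[inputs]`` table of summary-statistics/LD file paths. Reruns with
    the same config and seed produce byte-identical tables.
    """
    raw = _load_config(config_path)
    run_cfg = raw.get("run", {})
    stages = run_cfg.get("stages", ["mr", "smr", "mediate_up", "mediate_down"])
    if seed is None:
        seed = int(run_cfg.get("seed", 0))
    out = Path(out_dir or run_cfg.get("out_dir", "mrchain_out"))
    out.mkdir(parents=True, exist_ok=True)

    thresholds = dict(raw.get("thresholds", {}))
    thresholds["seed"] = seed
    config = MRConfig.from_dict(thresholds)

    if "simulate" in raw:
        data = _simulated_inputs(raw["simulate"], seed, out)
    elif "inputs" in raw:
        data = _file_inputs(raw["inputs"])
    else:
        raise PipelineError("config needs a [simulate] or [inputs] section")

    decisions: list[StageDecision] = []
    if "mr" in stages:
        decisions = stage1_screen(data["exposures"], data["outcome"],
                                  data["ld"], config)
        _write_tsv(_mr_table(decisions), out / "stage1_mr.tsv")
        _write_tsv(_sensitivity_table(decisions), out / "stage1_sensitivity.tsv")

    if "smr" in stages and decisions and data.get("qtl_regions"):
        stage1_validate_smr(decisions, data["qtl_regions"],
                            data["gwas_region"], data["region_ld"], config)
        _write_tsv(_smr_table(decisions, config.alpha), out / "stage1_smr.tsv")

    if "mediate_up" in stages and data.get("methylation"):
        up = stage2_upstream(data["methylation"], data["gene"],
                             data.get("outcome_up", data["outcome"]),
                             data["ld_up"], config)
        _write_tsv(mediation_table(up), out / "stage2_mediation.tsv")

    if "mediate_down" in stages and data.get("immune"):
        down = stage3_downstream(data["gene_down"], data["immune"],
                                 data["outcome_down"], data["ld_down"], config)
        _write_tsv(mediation_table(down), out / "stage3_mediation.tsv")

    _write_summary(out, decisions)
    _write_manifest(out, config_path, seed)
    logger.info("pipeline complete: %s", out)
    return out


def _simulated_inputs(sim_cfg: dict, seed: int, out: Path) -> dict:
    """Build all stage inputs from two simulated chains plus one region.

    The downstream chain (gene -> immune trait -> outcome) doubles as
    the stage-1 screen input (gene vs outcome); the upstream chain
    simulates CpG -> gene -> outcome.
    """
    base = {k: v for k, v in sim_cfg.items()
            if k not in ("seed", "region_size", "shared_causal")}
    down = simulate_study(SimulationConfig(seed=seed, **base))
    up = simulate_study(SimulationConfig(seed=seed + 1, **base))
    qtl, gwas, region_ld, _top = simulate_smr_region(
        shared_causal=bool(sim_cfg.get("shared_causal", True)),
        region_size=int(sim_cfg.get("region_size", 60)),
        seed=seed + 2,
    )

    def relabel(ds: SummaryDataset, trait_id: str) -> SummaryDataset:
        from dataclasses import replace
        return SummaryDataset(
            trait_id=trait_id, trait_type=ds.trait_type,
            records=[replace(r, trait_id=trait_id) for r in ds.records],
        )

    gene = relabel(down.exposure, "gene")
    write_sumstats(gene, out / "sim_gene.tsv")
    write_sumstats(down.outcome, out / "sim_outcome.tsv")
    write_ld_matrix(down.ld, out / "sim_ld.txt", out / "sim_ld_pos.txt")

    return {
        "exposures": [gene],
        "outcome": relabel(down.outcome, "outcome"),
        "ld": down.ld,
        "qtl_regions": {"gene": qtl},
        "gwas_region": gwas,
        "region_ld": region_ld,
        "methylation": [relabel(up.exposure, "cpg_site")],
        "gene": relabel(up.mediator, "gene"),
        "outcome_up": relabel(up.outcome, "outcome"),
        "ld_up": up.ld,
        "gene_down": gene,
        "immune": [relabel(down.mediator, "immune_trait")],
        "outcome_down": relabel(down.outcome, "outcome"),
        "ld_down": down.ld,
    }


def _file_inputs(inputs: dict) -> dict:
    """Load stage inputs from configured file paths."""
    def load(entry: dict, default_type="quantitative") -> SummaryDataset:
        ds, _ = read_sumstats(
            entry["path"],
            trait_id=entry.get("trait_id", Path(entry["path"]).stem),
            trait_type=entry.get("trait_type", default_type),
            column_map=entry.get("column_map"),
        )
        return ds

    exposures = [load(e) for e in inputs.get("exposures", [])]
    if not exposures:
        raise PipelineError("[inputs] must list at least one exposure")
    outcome = load(inputs["outcome"], "binary")
    ld = read_ld_matrix(inputs["ld_matrix"], inputs["ld_positions"])
    data = {
        "exposures": exposures, "outcome": outcome, "ld": ld,
        "qtl_regions": {}, "methylation": [], "immune": [],
    }
    if "gene" in inputs:
        data["gene"] = load(inputs["gene"])
        data["gene_down"] = data["gene"]
        data["outcome_down"] = outcome
        data["ld_up"] = ld
        data["ld_down"] = ld
        data["methylation"] = [load(e) for e in inputs.get("methylation", [])]
        data["immune"] = [load(e) for e in inputs.get("immune", [])]
    return data


def _write_summary(out: Path, decisions: list[StageDecision]) -> None:
    lines = ["mrchain pipeline summary", "=" * 30]
    for d in decisions:
        lines.append(f"\n[{d.unit_id}] verdict: {d.verdict}")
        if d.notes:
            lines.append("  notes: " + ", ".join(d.notes))
        if "ivw" in d.mr_results:
            r = d.mr_results["ivw"]
            lines.append(
                f"  IVW: beta={r.beta:.4f} (se {r.se:.4f}), "
                f"OR={r.odds_ratio:.3f} [{r.or_ci_low:.3f}, {r.or_ci_high:.3f}], "
                f"p={r.pval:.3g}, nsnp={r.nsnp}"
            )
        if d.sensitivity is not None:
            lines.append("  " + format_report(d.sensitivity).replace("\n", "\n  "))
        if d.smr is not None:
            heidi = "NA" if d.smr.p_heidi is None else f"{d.smr.p_heidi:.3g}"
            lines.append(
                f"  SMR: b_xy={d.smr.b_xy:.4f}, p_smr={d.smr.p_smr:.3g}, "
                f"p_heidi={heidi} ({d.smr.n_heidi_snps} SNPs)"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def _write_manifest(out: Path, config_path, seed: int) -> None:
    config_bytes = Path(config_path).read_bytes()
    manifest = {
        "package": "mrchain",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_bytes).hexdigest(),
        "config_path": str(config_path),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
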