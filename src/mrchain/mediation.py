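"""Two-step mediation MR: effect decomposition along a causal chain.

The total effect beta of an exposure on the outcome is decomposed into
an indirect component beta1*beta2 routed through a mediator (exposure ->
mediator effect beta1, mediator -> outcome effect beta2, each from its
own univariable MR leg) and the direct remainder beta - beta1*beta2.
The directional-consistency filter keeps only chains whose component
signs multiply to the sign of the total effect.

Note: beta2 comes from univariable MR of the mediator on the outcome —
not from multivariable MR adjusting for the exposure. The legs are
independent screens; when the mediator's instruments overlap the
exposure's, the beta2 leg can absorb part of the direct path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from mrchain.config import MRConfig
from mrchain.estimators import MRResult, all_methods
from mrchain.instruments import select_instruments
from mrchain.ld import LDMatrix
from mrchain.sumstats import SummaryDataset

logger = logging.getLogger(__name__)

_TINY_P = 5e-324


class MediationError(ValueError):
    """Mediation analysis cannot proceed (e.g. a leg with no instruments)."""


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    se_total: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    p_indirect: float
    proportion: Optional[float]
    direct: float
    consistent: bool
    legs_significant: bool = True
    signs_agree: bool = True
    component_results: dict = field(default_factory=dict)

    @property
    def reported(self) -> bool:
        """True when the chain survives every reporting gate."""
        return self.legs_significant and self.signs_agree and self.consistent


def directional_filter(beta_total: float, beta1: float, beta2: float) -> bool:
    """Sign-consistency rule for a mediation chain.

    True iff sign(beta1*beta2) equals sign(beta_total): a positive total
    effect requires beta1 and beta2 to share a sign, a negative one
    requires opposite signs. Any exactly-zero input fails the filter
    (degenerate, logged).
    """
    if beta_total == 0 or beta1 == 0 or beta2 == 0:
        logger.info(
            "directional_filter: zero effect among (%.3g, %.3g, %.3g); fails",
            beta_total, beta1, beta2,
        )
        return False
    return (beta1 * beta2 > 0) == (beta_total > 0)


def mediation_effect(
    beta_total: float,
    se_total: float,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Decompose a total effect given the three leg estimates.

    indirect = beta1*beta2 with first-order (delta-method) SE
    sqrt(beta1^2*se2^2 + beta2^2*se1^2); proportion = indirect/total;
    direct = total - indirect. Proportions outside [0, 1] are reported
    as computed with a warning.
    """
    if beta_total == 0:
        raise MediationError("proportion undefined: beta_total = 0")
    indirect = beta1 * beta2
    se_indirect = math.sqrt(beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2)
    if se_indirect > 0:
        p_indirect = max(2.0 * stats.norm.sf(abs(indirect) / se_indirect), _TINY_P)
    else:
        p_indirect = 1.0 if indirect == 0 else _TINY_P
    proportion = indirect / beta_total
    direct = beta_total - indirect
    if not 0.0 <= proportion <= 1.0:
        logger.warning(
            "mediation %s->%s->%s: proportion mediated %.3f outside [0, 1]",
            exposure_id, mediator_id, outcome_id, proportion,
        )
    return MediationResult(
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        beta_total=beta_total, se_total=se_total,
        beta1=beta1, se1=se1, beta2=beta2, se2=se2,
        indirect=indirect, se_indirect=se_indirect, p_indirect=p_indirect,
        proportion=proportion, direct=direct,
        consistent=directional_filter(beta_total, beta1, beta2),
    )


def _run_leg(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    config: MRConfig,
    leg_name: str,
    seed_offset: int,
) -> dict[str, MRResult]:
    instruments = select_instruments(exposure, outcome, ld, config)
    if len(instruments) == 0:
        raise MediationError(
            f"leg {leg_name} ({exposure.trait_id} -> {outcome.trait_id}): "
            "no surviving instruments"
        )
    return all_methods(
        instruments,
        effects_model=config.effects_model,
        n_boot=config.n_boot,
        seed=config.seed + seed_offset,
        include_supplementary=config.record_all_methods,
    )


def _signs_agree(methods: dict[str, MRResult]) -> bool:
    """IVW/Egger direction agreement; vacuously true when Egger is absent."""
    if "egger" not in methods:
        return True
    return methods["ivw"].beta * methods["egger"].beta > 0


def two_step_mediation(
    exposure_ds: SummaryDataset,
    mediator_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    ld: LDMatrix,
    config: MRConfig | None = None,
) -> MediationResult:
    """Three univariable MR legs assembled into a mediation decomposition.

    Leg (i) exposure -> outcome gives the total effect, leg (ii)
    exposure -> mediator gives beta1, leg (iii) mediator -> outcome
    gives beta2 (each with its own instrument selection; IVW is the
    headline, all configured methods recorded). The result is flagged
    as reported only when every leg's IVW p < alpha, IVW and Egger
    agree in sign on every leg, and the directional filter passes.
    """
    config = config or MRConfig()
    leg_total = _run_leg(exposure_ds, outcome_ds, ld, config, "total", 11)
    leg1 = _run_leg(exposure_ds, mediator_ds, ld, config, "beta1", 22)
    leg2 = _run_leg(mediator_ds, outcome_ds, ld, config, "beta2", 33)

    ivw_total, ivw1, ivw2 = leg_total["ivw"], leg1["ivw"], leg2["ivw"]
    result = mediation_effect(
        ivw_total.beta, ivw_total.se,
        ivw1.beta, ivw1.se,
        ivw2.beta, ivw2.se,
        exposure_id=exposure_ds.trait_id,
        mediator_id=mediator_ds.trait_id,
        outcome_id=outcome_ds.trait_id,
    )
    result.legs_significant = all(
        r.pval < config.alpha for r in (ivw_total, ivw1, ivw2)
    )
    result.signs_agree = all(
        _signs_agree(leg) for leg in (leg_total, leg1, leg2)
    )
    result.component_results = {
        "total": leg_total, "beta1": leg1, "beta2": leg2,
    }
    return result


def mediation_table(results: list[MediationResult]):
    """Tab-separable mediation report (proportion as a percentage)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "exposure": r.exposure_id, "mediator": r.mediator_id,
            "outcome": r.outcome_id,
            "beta_total": r.beta_total, "beta1": r.beta1, "beta2": r.beta2,
            "indirect": r.indirect, "se_indirect": r.se_indirect,
            "p_indirect": r.p_indirect,
            "proportion_pct": (
                "" if r.proportion is None else round(100.0 * r.proportion, 2)
            ),
            "direct": r.direct,
            "consistent": r.consistent,
            "verdict": "reported" if r.reported else "excluded",
        })
    return pd.DataFrame(rows)
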