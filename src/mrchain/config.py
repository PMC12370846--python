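"""Analysis thresholds and knobs shared by the pipeline stages.

Every threshold keeps its conventional printed default: genome-wide
significance p < 5e-8, clumping r^2 < 0.001 within a 10,000 kb window,
MAF > 1%, instruments excluded when F < 20, decision alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class MRConfig:
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 20.0
    k_instruments: int = 1
    palindrome_window: float = 0.08
    effects_model: str = "multiplicative_random"  # IVW headline variant
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    # record weighted median / mode estimates alongside IVW + Egger;
    # disable in large simulation sweeps where only the headline matters
    record_all_methods: bool = True
    # gate verdicts on Q / Egger-intercept p < alpha instead of warning
    strict_sensitivity: bool = False
    # missing-from-LD handling during clumping: "independent" | "drop"
    clump_missing: str = "independent"
    smr_r2_min: float = 0.05
    smr_r2_max: float = 0.9
    heidi_min_snps: int = 3
    heidi_max_snps: int = 20
    heidi_n_mc: int = 100_000

    @classmethod
    def from_dict(cls, d: dict) -> "MRConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)
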