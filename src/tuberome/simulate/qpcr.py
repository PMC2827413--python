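"""Synthetic qPCR Ct tables inverted from chosen true expression ratios.

Given a true ratio r and efficiencies E_t, E_r, the target delta-Ct is
obtained by inverting the Pfaffl relation

    dCt_t = (ln r + dCt_r * ln E_r) / ln E_t

after fixing the reference delta-Ct; technical-replicate jitter (cycles)
is then added to every Ct. Zero jitter round-trips the true ratios to
floating precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QpcrSimSpec", "QpcrTruth", "generate_qpcr"]

REFERENCE_GENE = "ubi3"  # ubiquitin reference control


@dataclass(frozen=True)
class QpcrSimSpec:
    """True ratios and assay parameters for a simulated qPCR run."""

    true_ratios: tuple[tuple[str, float], ...] = (("GBSS", 4.0), ("GPT", 0.5), ("Susy", 1.0))
    e_target: float = 2.0
    e_reference: float = 2.0
    n_technical: int = 3
    jitter_sd: float = 0.1  # cycles
    base_ct: float = 22.0
    reference_delta_ct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for e, name in ((self.e_target, "e_target"), (self.e_reference, "e_reference")):
            if not (1.0 < e <= 2.0):
                raise ValueError(f"{name} must be in (1, 2], got {e}")
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for gene, r in self.true_ratios:
            if r <= 0:
                raise ValueError(f"true ratio for {gene!r} must be > 0")


@dataclass
class QpcrTruth:
    ratios: dict[str, float]
    delta_ct_target: dict[str, float] = field(default_factory=dict)
    delta_ct_reference: float = 0.0


def generate_qpcr(spec: QpcrSimSpec) -> tuple[pd.DataFrame, QpcrTruth]:
    """Simulate a long-format Ct table (gene, role, group, replicate, ct, efficiency)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    rows = []

    def emit(gene: str, role: str, group: str, clean_ct: float, eff: float) -> None:
        for rep in range(1, spec.n_technical + 1):
            ct = clean_ct + rng.normal(0.0, spec.jitter_sd)
            rows.append(
                {
                    "gene": gene,
                    "role": role,
                    "group": group,
                    "replicate": rep,
                    "ct": ct,
                    "efficiency": eff,
                }
            )

    ref_control = spec.base_ct
    ref_sample = spec.base_ct - spec.reference_delta_ct
    emit(REFERENCE_GENE, "reference", "control", ref_control, spec.e_reference)
    emit(REFERENCE_GENE, "reference", "sample", ref_sample, spec.e_reference)

    truth = QpcrTruth(ratios={}, delta_ct_reference=spec.reference_delta_ct)
    for gene, ratio in spec.true_ratios:
        d_t = (math.log(ratio) + spec.reference_delta_ct * math.log(spec.e_reference)) / math.log(
            spec.e_target
        )
        emit(gene, "target", "control", spec.base_ct, spec.e_target)
        emit(gene, "target", "sample", spec.base_ct - d_t, spec.e_target)
        truth.ratios[gene] = ratio
        truth.delta_ct_target[gene] = d_t
    return pd.DataFrame(rows), truth
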