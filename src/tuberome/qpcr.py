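"""Efficiency-corrected relative qPCR quantification (Pfaffl method).

The relative expression of a target gene in a sample vs a control,
corrected by a reference gene (ubiquitin in the original assays), is

    ratio = E_t ** dCt_t / E_r ** dCt_r,   dCt = Ct(control) - Ct(sample)

where E is the per-cycle fold amplification in (1, 2] (2 = perfect
doubling). Technical replicates are aggregated to a mean Ct first. With
E_t = E_r = 2 the formula reduces to the familiar 2**(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmplificationMeasurement",
    "RelativeExpression",
    "aggregate_technical",
    "pfaffl_ratio",
    "ratios_from_table",
]


def _check_efficiency(e: float, name: str) -> None:
    if not (1.0 < e <= 2.0):
        raise ValueError(f"{name} must be in (1, 2], got {e}")


def _check_cts(cts: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(cts, dtype=float)
    if arr.size == 0:
        raise ValueError(f"missing Ct group: {name}")
    if np.any(arr <= 0):
        raise ValueError(f"{name} Ct values must be positive")
    return arr


@dataclass(frozen=True)
class AmplificationMeasurement:
    """Ct values (technical replicates) for target and reference genes.

    Four Ct groups — target/reference x control/sample — each with >= 1
    technical replicate, plus the two amplification efficiencies.
    """

    e_target: float
    e_reference: float
    target_control: tuple[float, ...]
    target_sample: tuple[float, ...]
    reference_control: tuple[float, ...]
    reference_sample: tuple[float, ...]

    def __post_init__(self) -> None:
        _check_efficiency(self.e_target, "target efficiency")
        _check_efficiency(self.e_reference, "reference efficiency")
        for name in ("target_control", "target_sample", "reference_control", "reference_sample"):
            _check_cts(getattr(self, name), name)


@dataclass(frozen=True)
class RelativeExpression:
    """Reference-corrected fold change of target in sample vs control."""

    ratio: float
    delta_ct_target: float
    delta_ct_reference: float
    sd_ct_target: float
    sd_ct_reference: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")


def aggregate_technical(cts: Sequence[float]) -> tuple[float, float]:
    """Mean and sample sd (ddof=1; 0 for a single replicate) of technical Cts."""
    arr = _check_cts(cts, "technical replicates")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def pfaffl_ratio(m: AmplificationMeasurement) -> RelativeExpression:
    """Pfaffl relative expression ratio from a measurement.

    Technical replicates are averaged per group, then
    ratio = E_t**(Ct_t,control - Ct_t,sample) / E_r**(Ct_r,control - Ct_r,sample).
    An induced target (lower sample Ct) gives ratio > 1.
    """
    tc, tc_sd = aggregate_technical(m.target_control)
    ts, ts_sd = aggregate_technical(m.target_sample)
    rc, rc_sd = aggregate_technical(m.reference_control)
    rs, rs_sd = aggregate_technical(m.reference_sample)
    d_t = tc - ts
    d_r = rc - rs
    ratio = m.e_target**d_t / m.e_reference**d_r
    return RelativeExpression(
        ratio=float(ratio),
        delta_ct_target=float(d_t),
        delta_ct_reference=float(d_r),
        sd_ct_target=float(np.hypot(tc_sd, ts_sd)),
        sd_ct_reference=float(np.hypot(rc_sd, rs_sd)),
    )


def ratios_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Compute Pfaffl ratios for every target gene in a long-format Ct table.

    Expected columns: gene, role (``target``/``reference``), group
    (``control``/``sample``), replicate, ct, efficiency. Exactly one
    reference gene is required; every other gene is quantified against it.
    """
    required = {"gene", "role", "group", "replicate", "ct", "efficiency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    refs = table.loc[table["role"] == "reference", "gene"].unique()
    if len(refs) != 1:
        raise ValueError(f"need exactly one reference gene, found {list(refs)}")
    ref = refs[0]

    def cts(gene: str, group: str) -> tuple[float, ...]:
        sub = table[(table["gene"] == gene) & (table["group"] == group)]
        return tuple(sub["ct"].astype(float))

    def eff(gene: str) -> float:
        return float(table.loc[table["gene"] == gene, "efficiency"].iloc[0])

    rows = []
    for gene in table.loc[table["role"] == "target", "gene"].unique():
        m = AmplificationMeasurement(
            e_target=eff(gene),
            e_reference=eff(ref),
            target_control=cts(gene, "control"),
            target_sample=cts(gene, "sample"),
            reference_control=cts(ref, "control"),
            reference_sample=cts(ref, "sample"),
        )
        r = pfaffl_ratio(m)
        rows.append(
            {
                "gene": gene,
                "ratio": r.ratio,
                "delta_ct_target": r.delta_ct_target,
                "delta_ct_reference": r.delta_ct_reference,
                "sd_ct_target": r.sd_ct_target,
                "sd_ct_reference": r.sd_ct_reference,
            }
        )
    return pd.DataFrame(rows)
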