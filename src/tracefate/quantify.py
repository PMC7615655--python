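"""Internal-standard GC-MS quantification and physiological normalizations.

Molar abundances are computed against a scyllo-inositol internal standard
(SI, 1 nmol added per sample by default) using molar relative response
factors (MRRF) calibrated from a standard metabolite mix run in parallel:

    MRRF(met)   = (SI_nmol_mm / met_nmol_mm) * (met_int_mm / SI_int_mm)
    met_nmol_s  = (met_int_s / SI_int_s) * SI_nmol / MRRF(met)

so quantifying the standard mix itself returns the known amounts exactly.
Also provides the secreted-metabolite normalization (delta metabolite /
delta glucose), the glucose uptake rate ((% consumed / delta OD595) x
growth rate) and the biomass yield coefficient (dry weight / delta
glucose).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .vocab import INTERNAL_STANDARD

logger = logging.getLogger(__name__)


@dataclass
class IntegralTable:
    """Long-format GC-MS ion-fragment integrals.

    ``frame`` columns: sample_id, metabolite, integral.  Each sample must
    contain exactly one internal-standard row with a positive integral.
    """

    frame: pd.DataFrame
    si_nmol: float = 1.0

    def __post_init__(self) -> None:
        required = {"sample_id", "metabolite", "integral"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"integral table missing columns: {sorted(missing)}")
        if (self.frame["integral"] < 0).any():
            raise InputError("negative integrals in table")
        si = self.frame[self.frame["metabolite"] == INTERNAL_STANDARD]
        counts = si.groupby("sample_id").size()
        for sample in self.frame["sample_id"].unique():
            if counts.get(sample, 0) != 1:
                raise InputError(
                    f"sample {sample!r} must have exactly one "
                    f"{INTERNAL_STANDARD} row"
                )
        if (si["integral"] <= 0).any():
            raise InputError("internal-standard integral must be positive")

    def si_integral(self, sample_id) -> float:
        si = self.frame[
            (self.frame["metabolite"] == INTERNAL_STANDARD)
            & (self.frame["sample_id"] == sample_id)
        ]
        return float(si["integral"].iloc[0])


@dataclass
class StandardMix:
    """Known amounts and measured integrals of the standard metabolite mix."""

    amounts: dict[str, float]      # met -> nmol in the mix
    integrals: dict[str, float]    # met -> integral in the mix run
    si_nmol: float
    si_integral: float

    def __post_init__(self) -> None:
        if self.si_nmol <= 0 or self.si_integral <= 0:
            raise InputError("standard-mix SI amount and integral must be > 0")
        for name in self.amounts:
            if self.amounts[name] <= 0:
                raise InputError(f"standard-mix amount for {name} must be > 0")
            if self.integrals.get(name, 0) <= 0:
                raise InputError(f"standard-mix integral for {name} must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StandardMix":
        required = {"metabolite", "nmol", "integral"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"mix table missing columns: {sorted(missing)}")
        si = df[df["metabolite"] == INTERNAL_STANDARD]
        if len(si) != 1:
            raise InputError(
                f"mix table must have exactly one {INTERNAL_STANDARD} row"
            )
        rest = df[df["metabolite"] != INTERNAL_STANDARD]
        return cls(
            amounts=dict(zip(rest["metabolite"], rest["nmol"].astype(float))),
            integrals=dict(zip(rest["metabolite"],
                               rest["integral"].astype(float))),
            si_nmol=float(si["nmol"].iloc[0]),
            si_integral=float(si["integral"].iloc[0]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metabolite": m, "nmol": self.amounts[m],
             "integral": self.integrals[m]}
            for m in self.amounts
        ]
        rows.append({"metabolite": INTERNAL_STANDARD, "nmol": self.si_nmol,
                     "integral": self.si_integral})
        return pd.DataFrame(rows)


@dataclass
class ResponseFactorTable:
    """Per-metabolite molar relative response factors."""

    mrrf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.mrrf.items():
            if not np.isfinite(v) or v <= 0:
                raise InputError(f"MRRF for {name} must be positive and finite")


@dataclass
class QuantResult:
    """Per-sample per-metabolite molar amounts.

    ``frame`` columns: sample_id, metabolite, nmol, flag; ``flag`` is
    ``quantified`` or ``unquantified`` (no response factor available, the
    value is then a relative integral/SI ratio, not nmol).
    """

    frame: pd.DataFrame


def compute_mrrf(mix: StandardMix) -> ResponseFactorTable:
    """Calibrate molar relative response factors from the standard mix."""
    return ResponseFactorTable({
        name: (mix.si_nmol / mix.amounts[name])
        * (mix.integrals[name] / mix.si_integral)
        for name in mix.amounts
    })


def quantify_samples(t: IntegralTable, rf: ResponseFactorTable) -> QuantResult:
    """Convert sample integrals to nmol via the internal standard."""
    rows = []
    for sample_id, group in t.frame.groupby("sample_id", sort=False):
        si_int = t.si_integral(sample_id)
        for _, row in group.iterrows():
            name = row["metabolite"]
            if name == INTERNAL_STANDARD:
                continue
            rel = row["integral"] / si_int
            if name in rf.mrrf:
                rows.append({
                    "sample_id": sample_id, "metabolite": name,
                    "nmol": rel * t.si_nmol / rf.mrrf[name],
                    "flag": "quantified",
                })
            else:
                logger.warning(
                    "no response factor for %s; reporting relative value", name
                )
                rows.append({
                    "sample_id": sample_id, "metabolite": name,
                    "nmol": rel, "flag": "unquantified",
                })
    return QuantResult(pd.DataFrame(
        rows, columns=["sample_id", "metabolite", "nmol", "flag"]
    ))


def secreted_normalization(delta_met: float, delta_glucose: float) -> float:
    """Change in a secreted metabolite per nmol of glucose consumed.

    Returns NaN (an undefined marker) when no glucose was consumed.
    """
    if delta_glucose <= 0:
        return float("nan")
    return delta_met / delta_glucose


def glucose_uptake_rate(pct_consumed: float, delta_od: float,
                        growth_rate: float) -> float:
    """Glucose uptake normalized to biomass increase and growth rate.

    ``(% consumed / delta OD595) x growth rate (h^-1)``.
    """
    if delta_od <= 0:
        raise InputError(f"delta_od must be > 0, got {delta_od}")
    if growth_rate <= 0:
        raise InputError(f"growth_rate must be > 0, got {growth_rate}")
    return (pct_consumed / delta_od) * growth_rate


def biomass_yield(dry_weight: float, delta_glucose: float) -> float:
    """Biomass yield coefficient: dry weight per mass of glucose consumed."""
    if delta_glucose <= 0:
        raise InputError(f"delta_glucose must be > 0, got {delta_glucose}")
    return dry_weight / delta_glucose
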