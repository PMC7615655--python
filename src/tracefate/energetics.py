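"""Stoichiometric per-glucose ATP and NADH accounting.

Compares the metabolic strategies of a fermenting versus a
respiro-fermenting yeast with a complex-I-less electron transport chain:

* glycolysis invests 2 ATP per glucose and pays off 2 ATP per triose
  phosphate that completes lower glycolysis, so the fermentative net yield
  is 2 ATP and drops as a fraction ``f`` of triose phosphate is diverted
  to glycerol-3-phosphate by Gpd1;
* a respiring cell additionally earns TCA substrate-level phosphorylation
  plus ETC credits for NADH and FADH2 (10 NADH + 2 FADH2 per fully
  oxidized glucose); with 1 ATP per NADH and per FADH2 (no proton-pumping
  complex I) complete oxidation lands at 16 ATP per glucose, inside the
  16-18 range cited for complex-I-less yeasts;
* cytosolic redox: GAPDH produces one NADH per non-diverted triose, the
  Gpd1 shunt consumes one NADH per diverted triose, and alcohol
  dehydrogenase consumes one NADH per fermented pyruvate — pure
  fermentation with no diversion is exactly redox-neutral.

``balance_fermentation`` closes the cytosolic ledger analytically: the
fermented fraction ``x`` that restores NADH balance for a diversion
fraction ``f`` solves ``(2-f) - f - x*(2-f) = 0``, i.e.
``x = (2-2f)/(2-f)``, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, Field, model_validator


class StrategyConfig(BaseModel):
    """Configuration of a metabolic strategy.

    ``fermentation_fraction`` defaults to 1 for non-respiring strategies
    (all pyruvate reduced to ethanol) and 0 for respiring ones.
    """

    respiring: bool = False
    atp_per_nadh: float = Field(default=1.0, ge=0.0)
    atp_per_fadh2: float = Field(default=1.0, ge=0.0)
    slp_glycolysis: float = Field(default=2.0, ge=0.0)
    slp_tca: float = Field(default=2.0, ge=0.0)
    g3p_diversion: float = Field(default=0.0, ge=0.0, le=1.0)
    fermentation_fraction: float | None = Field(default=None, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _default_fermentation(self) -> "StrategyConfig":
        if self.fermentation_fraction is None:
            object.__setattr__(
                self, "fermentation_fraction",
                0.0 if self.respiring else 1.0,
            )
        return self


@dataclass
class EnergyBudget:
    """Per-glucose ATP and cytosolic NADH ledger."""

    atp_produced: float
    atp_consumed: float
    nadh_produced: float
    nadh_consumed: float

    @property
    def atp_net(self) -> float:
        return self.atp_produced - self.atp_consumed

    @property
    def nadh_net(self) -> float:
        return self.nadh_produced - self.nadh_consumed


_NADH_PER_GLUCOSE = 10.0   # glycolysis 2 + PDH 2 + TCA 6, fully oxidized
_FADH2_PER_GLUCOSE = 2.0
_ATP_INVESTMENT = 2.0      # hexokinase + phosphofructokinase
_PAYOFF_PER_TRIOSE = 2.0   # phosphoglycerate kinase + pyruvate kinase


def energy_budget(cfg: StrategyConfig) -> EnergyBudget:
    """Full ATP + cytosolic NADH budget for a strategy."""
    f = cfg.g3p_diversion
    ff = cfg.fermentation_fraction
    trioses = 2.0 - f  # trioses completing lower glycolysis per glucose

    atp_produced = _PAYOFF_PER_TRIOSE * trioses
    if cfg.respiring:
        # fraction of glucose carbon fully oxidized: trioses neither
        # diverted to G3P nor fermented, relative to the 2 of a fully
        # oxidized glucose
        oxidized = trioses * (1.0 - ff) / 2.0
        atp_produced += oxidized * (
            cfg.slp_tca
            + cfg.atp_per_nadh * _NADH_PER_GLUCOSE
            + cfg.atp_per_fadh2 * _FADH2_PER_GLUCOSE
        )
    atp_consumed = _ATP_INVESTMENT

    nadh_produced = trioses            # GAPDH, cytosolic
    nadh_consumed = f + ff * trioses   # Gpd1 shunt + alcohol dehydrogenase
    return EnergyBudget(atp_produced, atp_consumed,
                        nadh_produced, nadh_consumed)


def atp_yield(cfg: StrategyConfig) -> EnergyBudget:
    """ATP ledger per glucose (see :func:`energy_budget`)."""
    return energy_budget(cfg)


def redox_balance(cfg: StrategyConfig) -> EnergyBudget:
    """Cytosolic NADH ledger per glucose (see :func:`energy_budget`).

    The ledger is explicitly cytosolic: NADH handed to the mitochondrial
    ETC in a respiring strategy appears here as un-consumed (positive
    ``nadh_net``).
    """
    return energy_budget(cfg)


def balance_fermentation(cfg: StrategyConfig) -> float:
    """Fermented fraction that makes the cytosolic NADH ledger net zero.

    Closed form ``x = (2 - 2f)/(2 - f)`` clipped to [0, 1];
    ``redox_balance`` at this fraction has ``|nadh_net| < 1e-12``.
    """
    f = cfg.g3p_diversion
    if f >= 2.0:
        raise ValueError("g3p_diversion must be < 2")
    x = (2.0 - 2.0 * f) / (2.0 - f)
    return min(1.0, max(0.0, x))
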