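"""TCA-architecture inference from diagnostic isotopologue fractions.

Fumarate and succinate — product and substrate of succinate dehydrogenase
— plus aspartate (a proxy for oxaloacetate) are the diagnostic
metabolites: M+2 fumarate marks the oxidative cycle, M+3 fumarate the
reductive branch, M+4 fumarate/aspartate repeated oxidative turns or
carboxylation with recycled labeled bicarbonate.  Candidate topologies
are scored by how many presence/absence calls their simulated
diagnostics share with the observed profile; the score is a matching
count, not a likelihood — no noise model for MID fractions is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .isotope_sim import PoolState, SimulationConfig, simulate
from .network import Topology

#: diagnostic keys: (metabolite, mass shift)
DIAGNOSTIC_KEYS: tuple[tuple[str, int], ...] = (
    ("FUM", 2), ("FUM", 3), ("FUM", 4),
    ("SUC", 2), ("SUC", 3), ("SUC", 4),
    ("ASP", 3), ("ASP", 4),
)

DEFAULT_THETA = 0.01


def key_name(met: str, shift: int) -> str:
    return f"{met}_M{shift}"


@dataclass
class DiagnosticProfile:
    """Observed diagnostic isotopologue fractions with a presence threshold."""

    fractions: dict[str, float]
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0,1), got {self.theta}")
        for k, v in self.fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {k}={v} out of [0,1]")

    def calls(self) -> dict[str, bool]:
        return {
            key_name(m, s): self.fractions.get(key_name(m, s), 0.0) > self.theta
            for m, s in DIAGNOSTIC_KEYS
        }


@dataclass
class TopologyScore:
    """Consistency of one candidate topology with an observed profile."""

    topology: str
    score: float
    verdicts: dict[str, bool] = field(default_factory=dict)  # per-key match
    predicted: dict[str, bool] = field(default_factory=dict)
    equivalent_to: tuple[str, ...] = ()


def predict_diagnostics(t: Topology, cfg: SimulationConfig,
                        theta: float = DEFAULT_THETA
                        ) -> tuple[dict[str, bool], dict[str, float]]:
    """Expected presence/absence of each diagnostic under a topology.

    Simulates from fully labeled inputs (the topology's declared entry
    metabolites, fed from U-13C glucose) and calls a diagnostic present
    when its simulated fraction exceeds ``theta`` at the final turn.
    Metabolites absent from the topology yield fraction 0.
    """
    init = PoolState.for_topology(t, labeled=set(t.inputs))
    tc = simulate(t, init, cfg)
    last = tc.turns()[-1]
    fractions: dict[str, float] = {}
    for met_name, shift in DIAGNOSTIC_KEYS:
        if met_name in tc.metabolites():
            fractions[key_name(met_name, shift)] = float(
                tc.mid(met_name, last).fractions[shift]
            )
        else:
            fractions[key_name(met_name, shift)] = 0.0
    calls = {k: v > theta for k, v in fractions.items()}
    return calls, fractions


def profile_from_timecourse(tc, turn=None,
                            theta: float = DEFAULT_THETA) -> DiagnosticProfile:
    """Extract a diagnostic profile from a label time course."""
    if turn is None:
        turn = tc.turns()[-1]
    fractions = {}
    for met_name, shift in DIAGNOSTIC_KEYS:
        if met_name in tc.metabolites():
            fractions[key_name(met_name, shift)] = float(
                tc.mid(met_name, turn).fractions[shift]
            )
    return DiagnosticProfile(fractions, theta)


def infer(profile: DiagnosticProfile, candidates: list[Topology],
          cfg: SimulationConfig) -> list[TopologyScore]:
    """Rank candidate topologies by diagnostic consistency.

    Score = matching presence calls / number of diagnostics; ties broken
    by fewer predicted-present diagnostics (parsimony), then name.
    Candidates with identical predicted call sets are observationally
    equivalent on this profile and are cross-referenced, not hidden.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    observed = profile.calls()
    scored: list[TopologyScore] = []
    for t in candidates:
        predicted, _ = predict_diagnostics(t, cfg, profile.theta)
        verdicts = {k: predicted[k] == observed[k] for k in predicted}
        score = sum(verdicts.values()) / len(verdicts)
        scored.append(TopologyScore(t.name, score, verdicts, predicted))
    by_preds: dict[tuple, list[str]] = {}
    for sc in scored:
        by_preds.setdefault(
            tuple(sorted(sc.predicted.items())), []
        ).append(sc.topology)
    for sc in scored:
        group = by_preds[tuple(sorted(sc.predicted.items()))]
        sc.equivalent_to = tuple(n for n in group if n != sc.topology)
    scored.sort(key=lambda sc: (
        -sc.score, sum(sc.predicted.values()), sc.topology
    ))
    return scored
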