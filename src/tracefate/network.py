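"""Carbon-transition networks for central-carbon label tracing.

Defines metabolites, carbon-balanced reactions with explicit atom maps, and
named topology presets for the pathway variants relevant to fission-yeast
central carbon metabolism:

``glycolysis``
    glucose -> trioses -> pyruvate -> acetaldehyde (+ the Gpd1 shunt to
    glycerol-3-phosphate).
``oxidative_tca``
    citrate synthase -> aconitase -> isocitrate dehydrogenase (CO2 loss) ->
    alpha-ketoglutarate dehydrogenase (CO2 loss) -> succinate ->
    [succinate dehydrogenase] -> fumarate -> malate -> oxaloacetate.
``reductive_branch``
    pyruvate carboxylase (CO2 fixed) -> oxaloacetate -> malate -> fumarate
    -> [fumarate reductase] -> succinate.
``bifurcated_tca``
    the union of the oxidative branch truncated at succinate (no SDH) and
    the reductive branch, fed from pyruvate, with a configurable fraction
    of the carboxylation carbon drawn from the internal released-CO2 pool
    (bicarbonate recycling).
``ppp_shunt``
    oxidative pentose-phosphate branch (CO2 loss at 6-phosphogluconate
    dehydrogenase) followed by the non-oxidative block lumped as
    3 x C5 -> 2 x C6 + 1 x C3 with the canonical transketolase /
    transaldolase carbon maps.

Atom maps use the standard carbon-transition conventions of 13C flux
analysis.  In particular citrate synthase writes Cit(d c b f a... ) such
that the two CO2 molecules released in the first oxidative turn both
derive from oxaloacetate carboxyl carbons, never from acetyl carbons;
this stereospecific handling is what makes a single oxidative turn from
M+2 acetyl-CoA and M+0 oxaloacetate yield M+2 (not M+1 or M+3) fumarate.

Carbon positions are 1-based throughout.  A source is either
``(slot, carbon)`` — carbon of the slot-th substrate — or the token
``CO2_IN``, drawing from the CO2 pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Union

import networkx as nx

from .errors import ConfigurationError
from .vocab import CANONICAL

CO2_IN = "CO2_IN"

PRESET_NAMES = (
    "glycolysis",
    "oxidative_tca",
    "reductive_branch",
    "bifurcated_tca",
    "ppp_shunt",
)

CarbonSource = Union[tuple[int, int], str]


@dataclass(frozen=True)
class Metabolite:
    """A tracked backbone-carbon species."""

    name: str
    n_carbons: int
    symmetric: bool = False  # 2-fold rotational carbon symmetry

    def __post_init__(self) -> None:
        if not (1 <= self.n_carbons <= 7):
            raise ConfigurationError(
                f"{self.name}: n_carbons must be in 1..7, got {self.n_carbons}"
            )


def met(name: str) -> Metabolite:
    """Build a Metabolite from the controlled vocabulary."""
    n, sym = CANONICAL[name]
    return Metabolite(name, n, sym)


@dataclass(frozen=True)
class Loss:
    """A substrate carbon not incorporated into any product.

    ``fate`` is ``"co2"`` (routed to the CO2 pool) or ``"discard"``.
    """

    slot: int
    carbon: int
    fate: str = "co2"


@dataclass(frozen=True)
class Reaction:
    """A carbon-balanced reaction with an explicit atom map.

    ``substrates``/``products`` are metabolite names; repeated names denote
    independent slots (e.g. three pentose slots of the lumped non-oxidative
    PPP block).  ``product_sources[i][c]`` is the source of carbon ``c+1``
    of the i-th product.
    """

    name: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    product_sources: tuple[tuple[CarbonSource, ...], ...]
    losses: tuple[Loss, ...] = ()
    symmetric_products: frozenset[str] = frozenset()

    @property
    def n_co2_in(self) -> int:
        return sum(
            1 for srcs in self.product_sources for s in srcs if s == CO2_IN
        )


@dataclass(frozen=True)
class CO2Policy:
    """Fraction of carboxylation carbon drawn from the internal CO2 pool.

    The remainder comes from an infinite unlabeled external reservoir.
    """

    recycle_fraction: float = 0.0


@dataclass(frozen=True)
class Topology:
    name: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    inputs: tuple[str, ...] = ()
    co2_policy: CO2Policy = field(default_factory=CO2Policy)

    def metabolite(self, name: str) -> Metabolite:
        return self._by_name[name]

    @property
    def _by_name(self) -> dict[str, Metabolite]:
        return {m.name: m for m in self.metabolites}

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc_src(s: CarbonSource):
            return s if s == CO2_IN else f"S{s[0]}.C{s[1]}"

        return {
            "name": self.name,
            "metabolites": [
                {"name": m.name, "n_carbons": m.n_carbons, "symmetric": m.symmetric}
                for m in self.metabolites
            ],
            "inputs": list(self.inputs),
            "co2_policy": {"recycle_fraction": self.co2_policy.recycle_fraction},
            "reactions": [
                {
                    "name": r.name,
                    "substrates": list(r.substrates),
                    "products": list(r.products),
                    "atom_map": [
                        [enc_src(s) for s in srcs] for srcs in r.product_sources
                    ],
                    "losses": [
                        {"slot": l.slot, "carbon": l.carbon, "fate": l.fate}
                        for l in r.losses
                    ],
                    "symmetric_products": sorted(r.symmetric_products),
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        def dec_src(s: str) -> CarbonSource:
            if s == CO2_IN:
                return CO2_IN
            slot, carbon = s.split(".")
            return (int(slot[1:]), int(carbon[1:]))

        return cls(
            name=d["name"],
            metabolites=tuple(
                Metabolite(m["name"], m["n_carbons"], m.get("symmetric", False))
                for m in d["metabolites"]
            ),
            reactions=tuple(
                Reaction(
                    name=r["name"],
                    substrates=tuple(r["substrates"]),
                    products=tuple(r["products"]),
                    product_sources=tuple(
                        tuple(dec_src(s) for s in srcs) for srcs in r["atom_map"]
                    ),
                    losses=tuple(
                        Loss(l["slot"], l["carbon"], l["fate"]) for l in r["losses"]
                    ),
                    symmetric_products=frozenset(r["symmetric_products"]),
                )
                for r in d["reactions"]
            ),
            inputs=tuple(d.get("inputs", ())),
            co2_policy=CO2Policy(d["co2_policy"]["recycle_fraction"]),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_json(cls, text: str) -> "Topology":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_topology(t: Topology) -> list[str]:
    """Check a topology; return the list of violations (empty when valid)."""
    violations: list[str] = []
    names = [m.name for m in t.metabolites]
    dupes = {n for n in names if names.count(n) > 1}
    for n in sorted(dupes):
        violations.append(f"duplicate metabolite name: {n}")
    by_name = {m.name: m for m in t.metabolites}

    if not 0.0 <= t.co2_policy.recycle_fraction <= 1.0:
        violations.append(
            f"co2_policy.recycle_fraction out of [0,1]: "
            f"{t.co2_policy.recycle_fraction}"
        )

    for r in t.reactions:
        for n in (*r.substrates, *r.products):
            if n not in by_name:
                violations.append(f"{r.name}: unknown metabolite {n}")
        if any(n not in by_name for n in (*r.substrates, *r.products)):
            continue
        if len(r.product_sources) != len(r.products):
            violations.append(f"{r.name}: atom map does not cover all products")
            continue
        # every product carbon has exactly one source
        for pi, (pname, srcs) in enumerate(zip(r.products, r.product_sources)):
            if len(srcs) != by_name[pname].n_carbons:
                violations.append(
                    f"{r.name}: product {pname} (index {pi}) has "
                    f"{len(srcs)} sources for {by_name[pname].n_carbons} carbons"
                )
        # every substrate carbon appears exactly once across sources + losses
        used: dict[tuple[int, int], int] = {}
        for srcs in r.product_sources:
            for s in srcs:
                if s != CO2_IN:
                    used[s] = used.get(s, 0) + 1
        for l in r.losses:
            used[(l.slot, l.carbon)] = used.get((l.slot, l.carbon), 0) + 1
        expected = {
            (slot, c + 1)
            for slot, sn in enumerate(r.substrates)
            for c in range(by_name[sn].n_carbons)
        }
        for key in sorted(expected - set(used)):
            violations.append(
                f"{r.name}: substrate carbon S{key[0]}.C{key[1]} unused "
                "(carbon conservation violated)"
            )
        for key in sorted(set(used) - expected):
            violations.append(f"{r.name}: source S{key[0]}.C{key[1]} out of range")
        for key, cnt in used.items():
            if cnt > 1 and key in expected:
                violations.append(
                    f"{r.name}: substrate carbon S{key[0]}.C{key[1]} used "
                    f"{cnt} times"
                )
        # explicit carbon balance
        n_sub = sum(by_name[n].n_carbons for n in r.substrates)
        n_prod = sum(by_name[n].n_carbons for n in r.products)
        if n_prod + len(r.losses) != n_sub + r.n_co2_in:
            violations.append(
                f"{r.name}: carbon balance broken "
                f"({n_sub}+{r.n_co2_in} in, {n_prod}+{len(r.losses)} out)"
            )
        for sp in r.symmetric_products:
            if sp not in r.products:
                violations.append(f"{r.name}: symmetric product {sp} not a product")

    # reachability of every product from the declared inputs; pools that
    # are consumed but never produced act as initial-condition sources
    # (e.g. the oxaloacetate seed of a truncated oxidative branch)
    if t.inputs:
        g = nx.DiGraph()
        g.add_nodes_from(by_name)
        for r in t.reactions:
            for s in r.substrates:
                for p in r.products:
                    g.add_edge(s, p)
        produced = {p for r in t.reactions for p in r.products}
        consumed = {s for r in t.reactions for s in r.substrates}
        sources = set(t.inputs) | (consumed - produced)
        reachable = set(sources)
        for src in sources:
            if src in g:
                reachable |= nx.descendants(g, src)
        for p in sorted(produced - reachable):
            violations.append(f"product {p} unreachable from inputs {t.inputs}")

    return violations


# ---------------------------------------------------------------------------
# preset construction
# ---------------------------------------------------------------------------

def _identity(slot_met: str, slot: int = 0) -> tuple[CarbonSource, ...]:
    n = CANONICAL[slot_met][0]
    return tuple((slot, c) for c in range(1, n + 1))


def _r(name, substrates, products, maps, losses=(), symmetric=()) -> Reaction:
    return Reaction(
        name=name,
        substrates=tuple(substrates),
        products=tuple(products),
        product_sources=tuple(tuple(m) for m in maps),
        losses=tuple(losses),
        symmetric_products=frozenset(symmetric),
    )


def _oxidative_reactions(include_sdh: bool) -> list[Reaction]:
    rs = [
        # Cit(1..6) = OAA C4, OAA C3, OAA C2, Ac C2, Ac C1, OAA C1
        _r("CS", ["ACA", "OAA"], ["CIT"],
           [[(1, 4), (1, 3), (1, 2), (0, 2), (0, 1), (1, 1)]]),
        _r("ACO", ["CIT"], ["ICT"], [_identity("CIT")]),
        # CO2 released at IDH is Cit C6 = OAA C1
        _r("IDH", ["ICT"], ["AKG"],
           [[(0, 1), (0, 2), (0, 3), (0, 4), (0, 5)]],
           losses=[Loss(0, 6, "co2")]),
        # CO2 released at AKGDH is AKG C1 = OAA C4; succinate = (OAA3, OAA2, Ac2, Ac1)
        _r("AKGDH", ["AKG"], ["SUC"],
           [[(0, 2), (0, 3), (0, 4), (0, 5)]],
           losses=[Loss(0, 1, "co2")], symmetric=["SUC"]),
    ]
    if include_sdh:
        rs.append(_r("SDH", ["SUC"], ["FUM"], [_identity("SUC")], symmetric=["FUM"]))
        rs.append(_r("FH", ["FUM"], ["MAL"], [_identity("FUM")]))
        rs.append(_r("MDH", ["MAL"], ["OAA"], [_identity("MAL")]))
    rs.append(_r("AAT", ["OAA"], ["ASP"], [_identity("OAA")]))
    return rs


def _reductive_reactions(include_fr: bool) -> list[Reaction]:
    rs = [
        # pyruvate C1-C3 -> OAA C1-C3; fixed CO2 -> OAA C4
        _r("PC", ["PYR"], ["OAA"], [[(0, 1), (0, 2), (0, 3), CO2_IN]]),
        _r("MDHr", ["OAA"], ["MAL"], [_identity("OAA")]),
        _r("FHr", ["MAL"], ["FUM"], [_identity("MAL")], symmetric=["FUM"]),
    ]
    if include_fr:
        rs.append(_r("FR", ["FUM"], ["SUC"], [_identity("FUM")], symmetric=["SUC"]))
    rs.append(_r("AATr", ["OAA"], ["ASP"], [_identity("OAA")]))
    return rs


_PDH = _r("PDH", ["PYR"], ["ACA"], [[(0, 2), (0, 3)]], losses=[Loss(0, 1, "co2")])


def _preset_glycolysis(**_opts) -> Topology:
    mets = ["GLC", "G6P", "F6P", "DHAP", "GAP", "PYR", "G3P", "ACD"]
    rs = [
        _r("HK", ["GLC"], ["G6P"], [_identity("GLC")]),
        _r("PGI", ["G6P"], ["F6P"], [_identity("G6P")]),
        # aldolase: F6P C1-C3 -> DHAP (reversed), C4-C6 -> GAP
        _r("FBA", ["F6P"], ["DHAP", "GAP"],
           [[(0, 3), (0, 2), (0, 1)], [(0, 4), (0, 5), (0, 6)]]),
        _r("GPD", ["DHAP"], ["G3P"], [_identity("DHAP")]),
        _r("TPI", ["DHAP"], ["GAP"], [[(0, 3), (0, 2), (0, 1)]]),
        # lower glycolysis lumped: GAP C1 becomes the pyruvate carboxyl
        _r("PYK", ["GAP"], ["PYR"], [_identity("GAP")]),
        # pyruvate decarboxylase: carboxyl C1 lost to CO2
        _r("PDC", ["PYR"], ["ACD"], [[(0, 2), (0, 3)]], losses=[Loss(0, 1, "co2")]),
    ]
    return Topology("glycolysis", tuple(met(m) for m in mets), tuple(rs),
                    inputs=("GLC",), co2_policy=CO2Policy(0.0))


def _preset_oxidative(include_sdh: bool = True, recycle_fraction: float = 0.0,
                      **_opts) -> Topology:
    mets = ["ACA", "OAA", "CIT", "ICT", "AKG", "SUC", "ASP"]
    if include_sdh:
        mets += ["FUM", "MAL"]
    rs = _oxidative_reactions(include_sdh)
    return Topology("oxidative_tca", tuple(met(m) for m in mets), tuple(rs),
                    inputs=("ACA",), co2_policy=CO2Policy(recycle_fraction))


def _preset_reductive(include_fumarate_reductase: bool = True,
                      recycle_fraction: float = 0.0, **_opts) -> Topology:
    mets = ["PYR", "OAA", "MAL", "FUM", "ASP"]
    if include_fumarate_reductase:
        mets.append("SUC")
    rs = _reductive_reactions(include_fumarate_reductase)
    return Topology("reductive_branch", tuple(met(m) for m in mets), tuple(rs),
                    inputs=("PYR",), co2_policy=CO2Policy(recycle_fraction))


def _preset_bifurcated(recycle_fraction: float = 1.0,
                       include_fumarate_reductase: bool = True,
                       **_opts) -> Topology:
    mets = ["PYR", "ACA", "OAA", "CIT", "ICT", "AKG", "SUC", "MAL", "FUM", "ASP"]
    rs = [_PDH] + _reductive_reactions(include_fumarate_reductase)[:-1] \
        + _oxidative_reactions(include_sdh=False)
    return Topology("bifurcated_tca", tuple(met(m) for m in mets), tuple(rs),
                    inputs=("PYR",), co2_policy=CO2Policy(recycle_fraction))


def _preset_ppp(recycle_fraction: float = 0.0, **_opts) -> Topology:
    mets = ["G6P", "6PGA", "Ru5P", "F6P", "GAP"]
    # lumped non-oxidative block, canonical TK/TA maps with slots
    # 0 = X5P(P), 1 = R5P(Q), 2 = X5P(R):
    #   F6P#1 = (P1, P2, Q1, P3, P4, P5)
    #   F6P#2 = (R1, R2, Q2, Q3, Q4, Q5)
    #   GAP   = (R3, R4, R5)
    rs = [
        _r("G6PDH", ["G6P"], ["6PGA"], [_identity("G6P")]),
        _r("6PGDH", ["6PGA"], ["Ru5P"],
           [[(0, 2), (0, 3), (0, 4), (0, 5), (0, 6)]],
           losses=[Loss(0, 1, "co2")]),
        _r("nonox_ppp", ["Ru5P", "Ru5P", "Ru5P"], ["F6P", "F6P", "GAP"],
           [
               [(0, 1), (0, 2), (1, 1), (0, 3), (0, 4), (0, 5)],
               [(2, 1), (2, 2), (1, 2), (1, 3), (1, 4), (1, 5)],
               [(2, 3), (2, 4), (2, 5)],
           ]),
    ]
    return Topology("ppp_shunt", tuple(met(m) for m in mets), tuple(rs),
                    inputs=("G6P",), co2_policy=CO2Policy(recycle_fraction))


_BUILDERS = {
    "glycolysis": _preset_glycolysis,
    "oxidative_tca": _preset_oxidative,
    "reductive_branch": _preset_reductive,
    "bifurcated_tca": _preset_bifurcated,
    "ppp_shunt": _preset_ppp,
}

_VALID_OPTIONS = {
    "glycolysis": set(),
    "oxidative_tca": {"include_sdh", "recycle_fraction"},
    "reductive_branch": {"include_fumarate_reductase", "recycle_fraction"},
    "bifurcated_tca": {"include_fumarate_reductase", "recycle_fraction"},
    "ppp_shunt": {"recycle_fraction"},
}


def build_topology(preset: str, *, recycle_fraction: float | None = None,
                   include_sdh: bool | None = None,
                   include_fumarate_reductase: bool | None = None) -> Topology:
    """Build a named topology preset.

    Parameters
    ----------
    preset
        One of ``glycolysis``, ``oxidative_tca``, ``reductive_branch``,
        ``bifurcated_tca``, ``ppp_shunt``.
    recycle_fraction
        Fraction of carboxylation carbon drawn from the internal released
        CO2 pool (presets default to 0 except ``bifurcated_tca``, which
        defaults to 1: endogenous bicarbonate recycling).
    include_sdh
        Whether the oxidative preset runs succinate dehydrogenase.  With
        ``False`` the oxidative branch is truncated after the
        succinyl-CoA ligase step (succinate is its terminus).
    include_fumarate_reductase
        Whether the reductive branch extends from fumarate to succinate.
    """
    if preset not in _BUILDERS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; expected one of {PRESET_NAMES}"
        )
    opts: dict = {}
    given = {
        "recycle_fraction": recycle_fraction,
        "include_sdh": include_sdh,
        "include_fumarate_reductase": include_fumarate_reductase,
    }
    for key, val in given.items():
        if val is None:
            continue
        if key not in _VALID_OPTIONS[preset]:
            raise ConfigurationError(
                f"option {key!r} is not meaningful for preset {preset!r}"
            )
        opts[key] = val
    if "recycle_fraction" in opts and not 0.0 <= opts["recycle_fraction"] <= 1.0:
        raise ConfigurationError(
            f"recycle_fraction must be in [0,1], got {opts['recycle_fraction']}"
        )
    t = _BUILDERS[preset](**opts)
    bad = validate_topology(t)
    if bad:  # pragma: no cover - presets are valid by construction
        raise ConfigurationError(f"preset {preset} failed validation: {bad}")
    return t


def restrict_topology(t: Topology, reaction_names: set[str]) -> Topology:
    """Return a copy of ``t`` keeping only the named reactions.

    Used to compare restricted instances, e.g. the bifurcated preset with
    zero oxidative flux against the reductive preset.
    """
    return replace(
        t,
        name=f"{t.name}[restricted]",
        reactions=tuple(r for r in t.reactions if r.name in reaction_names),
    )


def load_preset_json(preset: str) -> Topology:
    """Load a preset from the packaged JSON files (external interface)."""
    path = resources.files("tracefate").joinpath(f"data/presets/{preset}.json")
    return Topology.from_json(path.read_text())
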