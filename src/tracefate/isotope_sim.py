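"""Positional 13C label propagation through a carbon-transition topology.

An ``IsotopomerDist`` is a probability distribution over the 2^n carbon
labeling patterns of an n-carbon metabolite (bit ``i`` set means carbon
``i+1`` is 13C).  The deterministic engine propagates these distributions
exactly through atom-mapped reactions under the independent-substrate
assumption; ``monte_carlo`` simulates individual molecules as label
bit-vectors through the same reaction sequence and serves as the
stochastic cross-check.

Turn semantics: reactions are applied in their declared order within a
turn, each seeing the pools as already updated earlier in the same turn,
so one turn corresponds to one "cycle" of the pathway (label fed as
acetyl-CoA reaches fumarate within the first turn of the oxidative TCA
preset).  Each product pool is refreshed as ``(1-m) * old + m * new`` with
mixing fraction ``m``; ``m < 1`` reproduces the pre-steady-state mixtures
sampled in pulse-labeling time courses.  CO2 released by decarboxylations
is mixed into a single scalar labeled-fraction pool at the end of each
turn; carboxylations draw labeled carbon with probability
``recycle_fraction * labeled_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
from pydantic import BaseModel, Field

from .errors import ContractError
from .mid_analysis import LabelTimeCourse
from .network import CO2_IN, Metabolite, Reaction, Topology

_TOL = 1e-9


def popcount_table(n_carbons: int) -> np.ndarray:
    """Number of set bits for every pattern of an n-carbon metabolite."""
    return np.array(
        [bin(i).count("1") for i in range(1 << n_carbons)], dtype=np.int64
    )


def bitrev_table(n_carbons: int) -> np.ndarray:
    """Pattern index after reversing the carbon order (C1<->Cn, ...)."""
    out = np.empty(1 << n_carbons, dtype=np.int64)
    for p in range(1 << n_carbons):
        out[p] = int(f"{p:0{n_carbons}b}"[::-1], 2)
    return out


@dataclass
class IsotopomerDist:
    """Probability distribution over the 2^n labeling patterns."""

    metabolite: Metabolite
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (1 << self.metabolite.n_carbons,):
            raise ContractError(
                f"{self.metabolite.name}: expected "
                f"{1 << self.metabolite.n_carbons} weights, "
                f"got {self.weights.shape}"
            )
        if np.any(self.weights < -_TOL):
            raise ContractError(f"{self.metabolite.name}: negative weights")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ContractError(
                f"{self.metabolite.name}: weights sum to {self.weights.sum()}"
            )
        self.weights = np.clip(self.weights, 0.0, None)
        self.weights = self.weights / self.weights.sum()

    @classmethod
    def unlabeled(cls, m: Metabolite) -> "IsotopomerDist":
        w = np.zeros(1 << m.n_carbons)
        w[0] = 1.0
        return cls(m, w)

    @classmethod
    def fully_labeled(cls, m: Metabolite) -> "IsotopomerDist":
        w = np.zeros(1 << m.n_carbons)
        w[-1] = 1.0
        return cls(m, w)

    @classmethod
    def from_patterns(cls, m: Metabolite, patterns: dict[int, float]
                      ) -> "IsotopomerDist":
        w = np.zeros(1 << m.n_carbons)
        for p, v in patterns.items():
            w[p] = v
        return cls(m, w)

    def mid(self) -> np.ndarray:
        """Popcount marginal: fractions M+0 .. M+n."""
        return np.bincount(
            popcount_table(self.metabolite.n_carbons),
            weights=self.weights,
            minlength=self.metabolite.n_carbons + 1,
        )

    def carbon_label_probability(self, carbon: int) -> float:
        """Marginal probability that 1-based ``carbon`` is labeled."""
        idx = np.arange(len(self.weights))
        return float(self.weights[(idx >> (carbon - 1)) & 1 == 1].sum())

    def expected_labeled_carbons(self) -> float:
        return float(
            (popcount_table(self.metabolite.n_carbons) * self.weights).sum()
        )


@dataclass
class PoolState:
    """Per-metabolite isotopomer distributions and pool sizes (nmol)."""

    dists: dict[str, IsotopomerDist]
    sizes: dict[str, float]

    @classmethod
    def for_topology(cls, t: Topology, labeled: set[str] | None = None,
                     sizes: dict[str, float] | None = None) -> "PoolState":
        labeled = labeled or set()
        dists = {}
        for m in t.metabolites:
            dists[m.name] = (
                IsotopomerDist.fully_labeled(m)
                if m.name in labeled
                else IsotopomerDist.unlabeled(m)
            )
        sz = {m.name: 1.0 for m in t.metabolites}
        if sizes:
            sz.update(sizes)
        return cls(dists, sz)

    def copy(self) -> "PoolState":
        return PoolState(
            {k: IsotopomerDist(v.metabolite, v.weights.copy())
             for k, v in self.dists.items()},
            dict(self.sizes),
        )


@dataclass
class CO2PoolState:
    """Labeled fraction of the internal released-CO2 (bicarbonate) pool."""

    labeled_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ContractError(
                f"CO2 labeled_fraction out of [0,1]: {self.labeled_fraction}"
            )


class SimulationConfig(BaseModel):
    """Turn count, pool mixing and Monte-Carlo settings."""

    n_turns: int = Field(default=4, ge=1)
    mixing_fraction: float = Field(default=1.0, gt=0.0, le=1.0)
    seed: int = 0
    n_molecules: int = Field(default=100_000, ge=1)


# ---------------------------------------------------------------------------
# exact propagation
# ---------------------------------------------------------------------------

def propagate(r: Reaction, sub_dists: list[IsotopomerDist],
              co2_labeled_p: float = 0.0
              ) -> tuple[list[IsotopomerDist], list[float]]:
    """Propagate substrate distributions through one reaction exactly.

    Returns one product distribution per product slot (same order as
    ``r.products``; symmetric products are symmetrized) and the labeled
    fraction of each CO2 released via the reaction's losses.
    """
    if len(sub_dists) != len(r.substrates):
        raise ContractError(
            f"{r.name}: expected {len(r.substrates)} substrates, "
            f"got {len(sub_dists)}"
        )
    for d, name in zip(sub_dists, r.substrates):
        if d.metabolite.name != name:
            raise ContractError(
                f"{r.name}: substrate slot expects {name}, "
                f"got {d.metabolite.name}"
            )
    n_co2 = r.n_co2_in
    vecs = [d.weights for d in sub_dists]
    vecs += [np.array([1.0 - co2_labeled_p, co2_labeled_p])] * n_co2
    joint = reduce(np.kron, vecs)
    sizes = [len(v) for v in vecs]

    # component index of each vec in the flat kron order (vec 0 most
    # significant)
    J = np.arange(len(joint))
    comps: list[np.ndarray] = [None] * len(vecs)  # type: ignore[list-item]
    stride = 1
    for i in reversed(range(len(vecs))):
        comps[i] = (J // stride) % sizes[i]
        stride *= sizes[i]

    co2_entries = [
        (pi, ci)
        for pi, srcs in enumerate(r.product_sources)
        for ci, s in enumerate(srcs)
        if s == CO2_IN
    ]
    co2_bit_index = {entry: len(sub_dists) + k
                     for k, entry in enumerate(co2_entries)}

    products: list[IsotopomerDist] = []
    for pi, srcs in enumerate(r.product_sources):
        pat = np.zeros(len(joint), dtype=np.int64)
        for ci, src in enumerate(srcs):
            if src == CO2_IN:
                bit = comps[co2_bit_index[(pi, ci)]]
            else:
                slot, carbon = src
                if carbon > sub_dists[slot].metabolite.n_carbons:
                    raise ContractError(
                        f"{r.name}: carbon {carbon} out of range for "
                        f"{r.substrates[slot]}"
                    )
                bit = (comps[slot] >> (carbon - 1)) & 1
            pat |= bit << ci
        n_p = len(srcs)
        w = np.bincount(pat, weights=joint, minlength=1 << n_p)
        pname = r.products[pi]
        pmet = Metabolite(pname, n_p, pname in r.symmetric_products or
                          _is_symmetric(pname))
        dist = IsotopomerDist(pmet, w / w.sum())
        if pname in r.symmetric_products:
            dist = symmetrize(dist)
        products.append(dist)

    released: list[float] = []
    for l in r.losses:
        if l.carbon > sub_dists[l.slot].metabolite.n_carbons:
            raise ContractError(
                f"{r.name}: loss carbon {l.carbon} out of range for "
                f"{r.substrates[l.slot]}"
            )
        if l.fate == "co2":
            released.append(
                sub_dists[l.slot].carbon_label_probability(l.carbon)
            )
    return products, released


def _is_symmetric(name: str) -> bool:
    from .vocab import CANONICAL
    return name in CANONICAL and CANONICAL[name][1]


def condense(a: IsotopomerDist, b: IsotopomerDist, r: Reaction
             ) -> IsotopomerDist:
    """Condense two substrates into the reaction's (first) product.

    Assumes independence of the substrate pools: the joint labeling
    distribution is the product of the marginals.
    """
    if len(r.substrates) != 2:
        raise ContractError(f"{r.name}: condense needs exactly 2 substrate slots")
    prods, _ = propagate(r, [a, b])
    return prods[0]


def transform(d: IsotopomerDist, r: Reaction, co2_labeled_p: float = 0.0
              ) -> tuple[IsotopomerDist, float | None]:
    """Apply a single-substrate reaction.

    Returns the product distribution and, when a carbon is lost to the CO2
    pool, the probability that the released carbon was labeled (``None``
    when the reaction releases no CO2).
    """
    if len(r.substrates) != 1:
        raise ContractError(f"{r.name}: transform needs exactly 1 substrate slot")
    prods, released = propagate(r, [d], co2_labeled_p=co2_labeled_p)
    return prods[0], (released[0] if released else None)


def symmetrize(d: IsotopomerDist) -> IsotopomerDist:
    """Average each pattern with its carbon-order reversal.

    Models the 2-fold rotational symmetry of succinate/fumarate; the MID
    (popcount marginal) is unchanged.
    """
    if not d.metabolite.symmetric:
        raise ContractError(
            f"{d.metabolite.name} is not flagged as a symmetric metabolite"
        )
    rev = bitrev_table(d.metabolite.n_carbons)
    w = 0.5 * (d.weights + d.weights[rev])
    return IsotopomerDist(d.metabolite, w)


# ---------------------------------------------------------------------------
# turn-by-turn simulation
# ---------------------------------------------------------------------------

def step_turn(t: Topology, s: PoolState, c: CO2PoolState,
              cfg: SimulationConfig) -> tuple[PoolState, CO2PoolState]:
    """Advance one turn; returns the new pool and CO2 states."""
    m = cfg.mixing_fraction
    state = s.copy()
    co2_p = t.co2_policy.recycle_fraction * c.labeled_fraction
    released_all: list[float] = []
    for r in t.reactions:
        subs = []
        for name in r.substrates:
            if name not in state.dists:
                raise ContractError(f"{r.name}: no pool for substrate {name}")
            if state.sizes.get(name, 0.0) <= 0.0 and name not in t.inputs:
                raise ContractError(
                    f"{r.name}: empty pool {name} used as sole substrate source"
                )
            subs.append(state.dists[name])
        prods, released = propagate(r, subs, co2_labeled_p=co2_p)
        released_all.extend(released)
        # average product slots sharing a pool, then mix once per reaction
        new_by_name: dict[str, list[np.ndarray]] = {}
        for pname, pdist in zip(r.products, prods):
            new_by_name.setdefault(pname, []).append(pdist.weights)
        for pname, ws in new_by_name.items():
            new_w = np.mean(ws, axis=0)
            old = state.dists[pname]
            mixed = (1.0 - m) * old.weights + m * new_w
            state.dists[pname] = IsotopomerDist(old.metabolite, mixed)
    if released_all:
        new_frac = (1.0 - m) * c.labeled_fraction + m * float(
            np.mean(released_all)
        )
        c = CO2PoolState(min(1.0, max(0.0, new_frac)))
    return state, c


def simulate(t: Topology, init: PoolState, cfg: SimulationConfig,
             co2: CO2PoolState | None = None,
             return_state: bool = False):
    """Run ``cfg.n_turns`` turns and record MIDs and pool sizes per turn.

    The returned :class:`LabelTimeCourse` includes the initial state as
    turn 0.  Input pools (``t.inputs``) are held at their initial
    distributions throughout (constant feed).
    """
    state, c = init.copy(), (co2 or CO2PoolState())
    rows = []

    def record(turn: int, st: PoolState) -> None:
        for name, d in st.dists.items():
            rows.append((name, turn, st.sizes.get(name, 1.0), d.mid()))

    record(0, state)
    input_dists = {n: init.dists[n] for n in t.inputs}
    for turn in range(1, cfg.n_turns + 1):
        state, c = step_turn(t, state, c, cfg)
        for n, d in input_dists.items():  # constant external feed
            state.dists[n] = d
        record(turn, state)
    tc = LabelTimeCourse.from_records(rows)
    if return_state:
        return tc, state, c
    return tc


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass
class MCEstimate:
    """Monte-Carlo MID estimate with per-component binomial standard errors."""

    mid: np.ndarray
    se: np.ndarray
    n_molecules: int = 0


def monte_carlo(t: Topology, init: PoolState, cfg: SimulationConfig
                ) -> dict[str, MCEstimate]:
    """Simulate individual molecules through the same reaction sequence.

    Each pool is an array of ``cfg.n_molecules`` label bit-vectors; per
    reaction, substrate molecules are sampled with replacement, product
    patterns assembled by the atom map, and a fraction ``m`` of each
    product pool replaced.  Reproducible per seed.
    """
    if cfg.n_molecules < 1000:
        raise ContractError("monte_carlo needs n_molecules >= 1000")
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_molecules
    mols: dict[str, np.ndarray] = {}
    for name, d in init.dists.items():
        mols[name] = rng.choice(len(d.weights), size=N, p=d.weights)
    co2_frac = 0.0
    m = cfg.mixing_fraction
    for _ in range(cfg.n_turns):
        co2_p = t.co2_policy.recycle_fraction * co2_frac
        released_means: list[float] = []
        for r in t.reactions:
            subs = [mols[name][rng.integers(0, N, N)] for name in r.substrates]
            new_by_name: dict[str, list[np.ndarray]] = {}
            for srcs, pname in zip(r.product_sources, r.products):
                pat = np.zeros(N, dtype=np.int64)
                for ci, src in enumerate(srcs):
                    if src == CO2_IN:
                        bit = (rng.random(N) < co2_p).astype(np.int64)
                    else:
                        slot, carbon = src
                        bit = (subs[slot] >> (carbon - 1)) & 1
                    pat |= bit << ci
                if pname in r.symmetric_products:
                    rev = bitrev_table(len(srcs))
                    flip = rng.random(N) < 0.5
                    pat = np.where(flip, rev[pat], pat)
                new_by_name.setdefault(pname, []).append(pat)
            for pname, pats in new_by_name.items():
                if len(pats) == 1:
                    new = pats[0]
                else:
                    pick = rng.integers(0, len(pats), N)
                    new = np.choose(pick, pats)
                mask = rng.random(N) < m
                mols[pname] = np.where(mask, new, mols[pname])
            for l in r.losses:
                if l.fate == "co2":
                    bits = (subs[l.slot] >> (l.carbon - 1)) & 1
                    released_means.append(float(bits.mean()))
        for name in t.inputs:  # constant external feed
            mols[name] = rng.choice(
                len(init.dists[name].weights), size=N,
                p=init.dists[name].weights,
            )
        if released_means:
            co2_frac = (1.0 - m) * co2_frac + m * float(
                np.mean(released_means)
            )
    out: dict[str, MCEstimate] = {}
    for name, pats in mols.items():
        n_c = init.dists[name].metabolite.n_carbons
        counts = np.bincount(popcount_table(n_c)[pats], minlength=n_c + 1)
        p = counts / N
        out[name] = MCEstimate(p, np.sqrt(p * (1 - p) / N), N)
    return out


def labeled_carbon_balance(r: Reaction, sub_dists: list[IsotopomerDist],
                           co2_labeled_p: float = 0.0) -> tuple[float, float]:
    """Expected labeled carbon entering vs leaving one reaction.

    In: substrate label + labeled CO2 fixed.  Out: product label + labeled
    CO2 released (+ labeled discarded carbons).  Equal for every valid
    atom map — the per-reaction conservation law the propagation engine
    must satisfy.
    """
    prods, released = propagate(r, sub_dists, co2_labeled_p=co2_labeled_p)
    label_in = sum(d.expected_labeled_carbons() for d in sub_dists)
    label_in += r.n_co2_in * co2_labeled_p
    label_out = sum(d.expected_labeled_carbons() for d in prods)
    label_out += sum(released)
    for l in r.losses:
        if l.fate == "discard":
            label_out += sub_dists[l.slot].carbon_label_probability(l.carbon)
    return label_in, label_out
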