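"""Mass-isotopologue-distribution (MID) analysis.

Collapses positional isotopomer distributions to MIDs (the M+0..M+n
fractions read off GC-MS spectra), corrects for natural 13C abundance,
and computes fractional labeling, labeled-pool synthesis and the
steady-state diagnostic ratios used to compare glycolytic and
pentose-phosphate flux organisation between strains.

Fractional labeling is the molecule fraction carrying at least one tracer
carbon, ``1 - M+0`` — a molecule-level quantity, not carbon-weighted mean
enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import ContractError, InputError
from .network import Metabolite

_MAX_M = 7  # largest tracked backbone (sedoheptulose-7-phosphate)

#: panel used for the 3PGA share of the glycolytic intermediate pool
GLYCOLYTIC_PANEL = ("G6P", "F6P", "DHAP", "3PGA", "2PGA", "PEP", "PYR")


@dataclass
class MID:
    """Mass-isotopologue vector M+0..M+n for one metabolite."""

    metabolite: Metabolite
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.metabolite.n_carbons + 1,):
            raise ContractError(
                f"{self.metabolite.name}: MID length "
                f"{len(self.fractions)} != n_carbons+1"
            )
        if np.any(self.fractions < -1e-9):
            raise ContractError(f"{self.metabolite.name}: negative MID fraction")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ContractError(
                f"{self.metabolite.name}: MID sums to {self.fractions.sum()}"
            )
        self.fractions = np.clip(self.fractions, 0.0, None)
        self.fractions = self.fractions / self.fractions.sum()

    def max_shift(self, threshold: float = 1e-9) -> int:
        """Largest mass shift with fraction above ``threshold``."""
        nz = np.nonzero(self.fractions > threshold)[0]
        return int(nz[-1]) if len(nz) else 0

    def labeled_shifts(self, threshold: float = 1e-9) -> list[int]:
        """Mass shifts > 0 with fraction above ``threshold``."""
        return [int(k) for k in np.nonzero(self.fractions > threshold)[0]
                if k > 0]


def collapse_to_mid(d) -> MID:
    """Popcount marginal of an isotopomer distribution.

    M+k is the total weight of labeling patterns with exactly k set bits.
    Accepts any object with ``metabolite`` and ``weights`` attributes.
    """
    n = d.metabolite.n_carbons
    pc = np.array([bin(i).count("1") for i in range(1 << n)])
    return MID(d.metabolite, np.bincount(pc, weights=d.weights,
                                         minlength=n + 1))


@dataclass
class LabelTimeCourse:
    """Tidy per-turn MIDs and pool sizes.

    Backed by a DataFrame with columns ``metabolite, turn, pool_nmol,
    m0..m7`` (m-columns beyond a metabolite's carbon count are NaN).
    Round-trips losslessly through CSV.
    """

    frame: pd.DataFrame

    COLUMNS = ("metabolite", "turn", "pool_nmol",
               *[f"m{k}" for k in range(_MAX_M + 1)])

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS[:3]) - set(self.frame.columns)
        if missing:
            raise InputError(f"LabelTimeCourse missing columns: {sorted(missing)}")
        turns = np.sort(self.frame["turn"].unique())
        if len(turns) > 1 and not np.all(np.diff(turns) > 0):
            raise InputError("time points must be strictly increasing")

    @classmethod
    def from_records(cls, rows) -> "LabelTimeCourse":
        """rows: iterable of (metabolite, turn, pool_nmol, mid_array)."""
        recs = []
        for name, turn, pool, mid in rows:
            rec = {"metabolite": name, "turn": turn, "pool_nmol": pool}
            for k in range(_MAX_M + 1):
                rec[f"m{k}"] = mid[k] if k < len(mid) else np.nan
            recs.append(rec)
        return cls(pd.DataFrame(recs, columns=list(cls.COLUMNS)))

    def turns(self) -> list:
        return sorted(self.frame["turn"].unique())

    def metabolites(self) -> list[str]:
        return sorted(self.frame["metabolite"].unique())

    def _row(self, metabolite: str, turn) -> pd.Series:
        sel = self.frame[(self.frame["metabolite"] == metabolite)
                         & (self.frame["turn"] == turn)]
        if sel.empty:
            raise InputError(f"no record for {metabolite} at turn {turn}")
        return sel.iloc[0]

    def mid(self, metabolite: str, turn) -> MID:
        row = self._row(metabolite, turn)
        vals = row[[f"m{k}" for k in range(_MAX_M + 1)]].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        n = len(vals) - 1
        met = Metabolite(metabolite, n) if n >= 1 else Metabolite(metabolite, 1)
        return MID(met, vals)

    def pool(self, metabolite: str, turn) -> float:
        return float(self._row(metabolite, turn)["pool_nmol"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabelTimeCourse":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# natural-abundance correction
# ---------------------------------------------------------------------------

def correction_matrix(n_carbons: int, p13: float) -> np.ndarray:
    """Lower-triangular matrix mapping tracer MID to observed MID.

    Column j gives the observed isotopologue distribution of a molecule
    with j tracer carbons whose remaining ``n-j`` backbone carbons carry
    13C at natural abundance ``p13``:
    ``C[i, j] = Binom(n-j, p13).pmf(i-j)`` for ``i >= j``.
    """
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        C[j:, j] = binom.pmf(np.arange(n + 1 - j), n - j, p13)
    return C


def forward_convolve(tracer: MID, p13: float) -> MID:
    """Apply natural-abundance smearing to a tracer-pure MID."""
    C = correction_matrix(tracer.metabolite.n_carbons, p13)
    return MID(tracer.metabolite, C @ tracer.fractions)


def natural_abundance_correct(observed: MID, p13: float = 0.0107) -> MID:
    """Remove natural 13C abundance from an observed MID.

    Solves the lower-triangular system ``C x = observed`` for the tracer
    MID ``x`` by forward substitution, clipping each component to zero as
    it is computed (so noise in one observed fraction cannot inject a
    spurious oscillating tail into heavier isotopologues), then
    renormalizes.  On exactly-convolved input no clipping triggers and
    the solve is exact.  Models backbone carbons only (derivatization
    atoms are assumed stripped upstream by fragment selection).
    """
    if not 0.0 <= p13 <= 0.05:
        raise InputError(f"p13 must be in [0, 0.05], got {p13}")
    if p13 == 0.0:
        return MID(observed.metabolite, observed.fractions.copy())
    C = correction_matrix(observed.metabolite.n_carbons, p13)
    if np.any(np.abs(np.diag(C)) < 1e-12):
        raise InputError(
            f"correction matrix singular for n={observed.metabolite.n_carbons}, "
            f"p13={p13}"
        )
    n = observed.metabolite.n_carbons
    x = np.zeros(n + 1)
    for i in range(n + 1):
        resid = observed.fractions[i] - C[i, :i] @ x[:i]
        x[i] = max(0.0, resid / C[i, i])
    s = x.sum()
    if s <= 0:
        raise InputError("natural-abundance correction produced an empty MID")
    return MID(observed.metabolite, x / s)


# ---------------------------------------------------------------------------
# fractional labeling and synthesis
# ---------------------------------------------------------------------------

def fractional_labeling(m: MID) -> float:
    """Fraction of the pool carrying at least one tracer carbon (1 - M+0)."""
    return float(1.0 - m.fractions[0])


def labeled_synthesis(tc: LabelTimeCourse, metabolite: str, turn) -> float:
    """nmol of 13C-labeled metabolite at a recorded time point.

    ``fractional_labeling x pool size``; dividing by the elapsed time
    gives a synthesis rate when the caller picks a point inside the
    linear-increase window (the 1 min point for glycerol-3-phosphate in
    pulse-labeling experiments).
    """
    return fractional_labeling(tc.mid(metabolite, turn)) * tc.pool(
        metabolite, turn
    )


# ---------------------------------------------------------------------------
# diagnostic ratios
# ---------------------------------------------------------------------------

def diagnostics(abundances) -> dict[str, float]:
    """Steady-state diagnostic ratios from per-metabolite abundances.

    Accepts a mapping ``{metabolite: nmol}`` or a QuantResult (averaged
    over samples).  Missing metabolites yield absent ratios; division by
    zero yields NaN, never an exception.  All ratios are scale-invariant.
    """
    pools = _as_pools(abundances)

    def get(*names):
        vals = [pools[n] for n in names if n in pools]
        return sum(vals) if len(vals) == len(names) else None

    out: dict[str, float] = {}

    def ratio(key, num, den):
        if num is None or den is None:
            return
        out[key] = num / den if den != 0 else float("nan")

    ratio("G6P/F6P", get("G6P"), get("F6P"))
    ratio("G6P/6PGA", get("G6P"), get("6PGA"))
    ratio("(6PGA+Ru5P)/(R5P+SH7P)", get("6PGA", "Ru5P"), get("R5P", "SH7P"))
    ratio("3PGA/glycolytic_sum", get("3PGA"), get(*GLYCOLYTIC_PANEL))
    ratio("Ru5P/R5P", get("Ru5P"), get("R5P"))
    ratio("R5P/SH7P", get("R5P"), get("SH7P"))
    ratio("6PGA/Ru5P", get("6PGA"), get("Ru5P"))
    return out


def _as_pools(abundances) -> dict[str, float]:
    from .vocab import canonical_name

    if hasattr(abundances, "frame"):  # QuantResult
        df = abundances.frame
        grouped = df.groupby("metabolite")["nmol"].mean()
        return {canonical_name(k): float(v) for k, v in grouped.items()}
    return {canonical_name(k): float(v) for k, v in dict(abundances).items()}
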