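"""Synthetic GC-MS and labeling data with known ground truth.

Emulates the raw inputs of an internal-standard GC-MS metabolomics study
— long-format ion-fragment integral tables with a 1 nmol scyllo-inositol
internal standard and a parallel standard-mix run, pulse-labeling MID
time courses under a chosen topology preset, and exponential
growth/glucose-depletion series — so that every pipeline stage is
testable without any instrument data.

Noise is multiplicative log-normal (GC-MS intensity noise is
approximately proportional to signal); MID components are perturbed the
same way and renormalized.  Replicate layout mirrors common practice:
6 replicates for abundance panels, 4 for isotope tracing.  All output is
bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import InputError
from .isotope_sim import PoolState, SimulationConfig, simulate
from .mid_analysis import LabelTimeCourse, MID, forward_convolve
from .network import build_topology
from .quantify import IntegralTable, StandardMix
from .vocab import INTERNAL_STANDARD

#: plausible exponential-phase pools (nmol per extracted sample) and
#: response factors for the default panel
DEFAULT_NMOL = {
    "G6P": 0.8, "F6P": 0.45, "DHAP": 0.6, "3PGA": 1.2, "2PGA": 0.25,
    "PEP": 0.5, "PYR": 2.5, "G3P": 1.5, "CIT": 0.9, "AKG": 0.35,
    "SUC": 0.7, "FUM": 0.4, "MAL": 1.1, "ASP": 1.8, "GLU": 4.0,
    "6PGA": 0.3, "Ru5P": 0.28, "R5P": 0.33, "SH7P": 0.5,
}
DEFAULT_MRRF = {
    "G6P": 0.9, "F6P": 0.85, "DHAP": 1.4, "3PGA": 1.1, "2PGA": 1.05,
    "PEP": 0.75, "PYR": 2.0, "G3P": 1.3, "CIT": 0.6, "AKG": 0.8,
    "SUC": 1.6, "FUM": 1.5, "MAL": 1.2, "ASP": 0.95, "GLU": 0.7,
    "6PGA": 0.5, "Ru5P": 0.65, "R5P": 0.68, "SH7P": 0.4,
}


class GeneratorSpec(BaseModel):
    """Ground truth and noise structure for the synthetic generators."""

    true_nmol: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_NMOL))
    true_mrrf: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MRRF))
    noise_cv: float = Field(default=0.05, ge=0.0)
    si_nmol: float = Field(default=1.0, gt=0.0)
    si_integral: float = Field(default=1e6, gt=0.0)
    preset: str = "bifurcated_tca"
    recycle_fraction: float | None = None
    sim: SimulationConfig = Field(
        default_factory=lambda: SimulationConfig(n_turns=4, mixing_fraction=0.5)
    )
    natural_abundance: bool = False
    p13: float = Field(default=0.0107, ge=0.0, le=0.05)
    seed: int = 0


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


@dataclass
class IntegralTruth:
    nmol: dict[str, float]
    mrrf: dict[str, float]


def gen_integral_table(spec: GeneratorSpec, n_samples: int = 6
                       ) -> tuple[IntegralTable, StandardMix, IntegralTruth]:
    """Synthesize a sample integral table plus a noise-free standard mix.

    ``integral(met, sample) = MRRF(met) * nmol(met) / SI_nmol * SI_integral
    * lognormal(CV)``; the internal-standard rows get the same
    multiplicative noise so SI normalization is itself imperfect, as in a
    real run.
    """
    if set(spec.true_nmol) - set(spec.true_mrrf):
        raise InputError("every metabolite with a true nmol needs a true MRRF")
    rng = np.random.default_rng(spec.seed)
    rows = []
    mets = sorted(spec.true_nmol)
    for i in range(n_samples):
        sample = f"S{i + 1:02d}"
        noise = _lognormal_noise(rng, spec.noise_cv, len(mets) + 1)
        for j, name in enumerate(mets):
            base = (spec.true_mrrf[name] * spec.true_nmol[name]
                    / spec.si_nmol * spec.si_integral)
            rows.append({"sample_id": sample, "metabolite": name,
                         "integral": base * noise[j]})
        rows.append({"sample_id": sample, "metabolite": INTERNAL_STANDARD,
                     "integral": spec.si_integral * noise[-1]})
    table = IntegralTable(pd.DataFrame(rows), si_nmol=spec.si_nmol)
    # standard mix measured noise-free at 1 nmol per metabolite
    mix = StandardMix(
        amounts={m: 1.0 for m in mets},
        integrals={m: spec.true_mrrf[m] / spec.si_nmol * spec.si_integral
                   for m in mets},
        si_nmol=spec.si_nmol,
        si_integral=spec.si_integral,
    )
    return table, mix, IntegralTruth(dict(spec.true_nmol), dict(spec.true_mrrf))


def gen_label_timecourse(spec: GeneratorSpec
                         ) -> tuple[LabelTimeCourse, LabelTimeCourse]:
    """Simulate a pulse-labeling time course and add measurement noise.

    Returns (noisy, ground truth).  Optionally forward-convolves natural
    13C abundance before the noise so downstream correction can be
    exercised end to end.
    """
    top = build_topology(spec.preset, recycle_fraction=spec.recycle_fraction)
    init = PoolState.for_topology(top, labeled=set(top.inputs))
    truth = simulate(top, init, spec.sim)
    rng = np.random.default_rng(spec.seed)
    noisy = truth.frame.copy()
    mcols = [c for c in noisy.columns
             if c.startswith("m") and c[1:].isdigit()]
    for idx, row in noisy.iterrows():
        vals = row[mcols].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        mid = vals[mask]
        if spec.natural_abundance:
            n = len(mid) - 1
            if n >= 1:
                from .network import Metabolite
                mid = forward_convolve(
                    MID(Metabolite(str(row["metabolite"]), n), mid), spec.p13
                ).fractions
        mid = mid * _lognormal_noise(rng, spec.noise_cv, len(mid))
        mid = mid / mid.sum()
        vals[mask] = mid
        noisy.loc[idx, mcols] = vals
    return LabelTimeCourse(noisy), truth


def gen_growth_glucose(rate: float, uptake: float, duration_h: float = 2.0,
                       n_points: int = 13, noise_cv: float = 0.0,
                       seed: int = 0, od0: float = 0.1,
                       glucose0_pct: float = 100.0
                       ) -> pd.DataFrame:
    """Exponential OD series with a consistent glucose-depletion series.

    Constructed so that on noise-free output
    ``glucose_uptake_rate(pct_consumed, delta_od, rate)`` recovers
    ``uptake`` exactly over any window starting at t=0:
    ``pct(t) = glucose0 - uptake * (OD(t) - OD(0)) / rate``.
    """
    if rate <= 0:
        raise InputError(f"growth rate must be > 0, got {rate}")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_h, n_points)
    od = od0 * np.exp(rate * t)
    pct_consumed = uptake * (od - od0) / rate
    od_noisy = od * _lognormal_noise(rng, noise_cv, n_points)
    # measurement noise applies to the consumed amount (paired glucose
    # assays against the fresh-medium reference), not the absolute level
    consumed_noisy = pct_consumed * _lognormal_noise(rng, noise_cv, n_points)
    glucose_noisy = glucose0_pct - consumed_noisy
    # the t=0 anchors are reference measurements, kept noise-free
    od_noisy[0] = od[0]
    glucose_noisy[0] = glucose0_pct
    return pd.DataFrame({
        "time_h": t, "od595": od_noisy, "glucose_pct": glucose_noisy,
    })
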