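# Methods

## Label propagation model

Each tracked metabolite (1–7 backbone carbons; cofactor moieties such as
CoA and phosphate are ignored) carries a probability distribution over
its 2ⁿ positional labeling patterns. Reactions are carbon-balanced atom
maps: every product carbon has exactly one source — a substrate carbon
or the CO₂ pool — and every substrate carbon is used exactly once across
products and losses. Validation enforces this bookkeeping plus name
uniqueness and reachability of every product from the declared input
pools (pools consumed but never produced count as initial-condition
sources, e.g. the oxaloacetate seed of the truncated oxidative branch).

Exact propagation enumerates the joint substrate pattern space (≤ 2¹⁵
states for the lumped non-oxidative PPP block, ≤ 2¹⁶ with a CO₂ entry)
under the independent-pools assumption; condensation products are the
atom-map-restricted convolution of the substrate distributions. This is
deliberately a full-isotopomer representation rather than an EMU
decomposition: at n ≤ 7 the state space is trivial, and positional
tracking is required to get decarboxylation MIDs right.

**Stereospecificity.** Citrate synthase writes citrate so that the CO₂
released at isocitrate dehydrogenase is the oxaloacetate C1 and the CO₂
released at α-ketoglutarate dehydrogenase is the oxaloacetate C4 — the
standard carbon-transition convention of ¹³C flux analysis. A first
oxidative turn from M+2 acetyl-CoA therefore loses only oxaloacetate
carbons and yields M+2 succinate/fumarate; this is the property the
architecture diagnostics rest on, and it is asserted as a test
invariant (no first-turn fumarate isotopologue above M+2).

**Symmetry.** Succinate and fumarate have 2-fold rotational carbon
symmetry; their distributions are averaged with the carbon-reversed
patterns after production. The MID is invariant under symmetrization
(tested); only downstream positional fates change.

**Turn semantics.** Reactions run in declared pathway order within a
turn, each seeing pools already updated earlier in the same turn, so one
turn corresponds to one full "cycle" (label fed as acetyl-CoA reaches
fumarate in turn 1; the M+4 fumarate of repeated cycling appears from
turn 3). Each product pool is refreshed as `(1−m)·old + m·new` with the
mixing fraction `m ∈ (0,1]`; `m = 1` converges to the pathway's
fixed-point labeling, `m < 1` emulates sampling before isotopic steady
state. Pools are label ledgers, not mass balances: sizes are constant
and substrates are not depleted, which suffices for MID logic but means
whole-system label content is not conserved across turns; the
conservation law that *does* hold — and is property-tested on every
preset — is per reaction: expected labeled carbon in products plus
released CO₂ equals that in substrates plus fixed CO₂.

**CO₂ pool.** A single well-mixed scalar labeled fraction. Released CO₂
from a turn is mixed in at the end of that turn with the same mixing
fraction `m`, against an infinite unlabeled external reservoir;
carboxylations in turn *k* draw labeled carbon with probability
`recycle_fraction × fraction(k−1)`. This is the minimal structure needed
to represent endogenous bicarbonate recycling (M+4 oxaloacetate from M+3
pyruvate + M+1 CO₂).

## Topology presets

| preset | contents | CO₂ recycle default |
|---|---|---|
| `glycolysis` | hexokinase→aldolase→triose steps→pyruvate→acetaldehyde, plus the Gpd1 shunt DHAP→G3P | 0 |
| `oxidative_tca` | CS→aconitase→IDH (CO₂ loss)→AKGDH (CO₂ loss)→succinate→[SDH]→fumarate→malate→OAA, OAA→Asp | 0 |
| `reductive_branch` | pyruvate carboxylase (CO₂ in)→OAA→malate→fumarate→[fumarate reductase]→succinate, OAA→Asp | 0 |
| `bifurcated_tca` | PDH + both branches, no SDH | 1.0 |
| `ppp_shunt` | G6P→6PGA→(CO₂ loss)→Ru5P, lumped 3×C5 → 2×F6P + GAP with canonical TK/TA maps | 0 |

`include_sdh=False` truncates the oxidative branch after the
succinyl-CoA ligase step (succinate terminus). The bifurcated preset
defaults to full bicarbonate recycling; because the pool's labeled
fraction stays below 1 during a time course, both M+3 and M+4
oxaloacetate/aspartate appear, as observed in vivo. Presets are also
shipped as packaged JSON files in the documented serialization; a test
pins them to the in-code builders.

## Monte-Carlo oracle

`monte_carlo` pushes individual molecules (label bit-vectors) through
the identical reaction sequence: substrates sampled with replacement,
product patterns assembled by the atom map, a Bernoulli CO₂ bit per
carboxylation, random 50/50 orientation for symmetric products, and
per-molecule pool replacement with probability `m`. It shares no code
path with the exact engine beyond the reaction definitions and agrees
with it within 4 binomial standard errors at 10⁵ molecules on every
preset (tested). It is an oracle, not a performance path.

## MID analysis

* MIDs are popcount marginals; collapse is linear and mass-preserving.
* Fractional labeling is the molecule fraction `1 − M+0` (the pool
  fraction containing tracer), not mean carbon enrichment.
* Natural-abundance correction uses the binomial lower-triangular
  matrix `C[i,j] = Binom(n−j, p13).pmf(i−j)` over backbone carbons only
  (fragment/derivatization atoms are out of scope), default
  `p13 = 0.0107`, and is **off** by default for simulator output, which
  is tracer-pure. The system `C·x = observed` is solved by forward
  substitution with per-component clipping to zero; on
  exactly-convolved input no clipping triggers and the round-trip is
  exact to 1e-9 (tested). Clipping during substitution rather than
  after a full solve prevents a noise-induced negative component from
  injecting an oscillating tail into heavier isotopologues and
  preserves the monotonicity expected from the triangular structure
  (correcting a pure-M+0 observation returns pure M+0).
* Labeled synthesis at a time point is `fractional labeling × pool
  nmol`; rate extraction (choosing the linear window) is left to the
  caller.
* Diagnostic ratios (G6P/F6P, G6P/6PGA, oxidative/non-oxidative PPP,
  3PGA share of the glycolytic pool, Ru5P/R5P, R5P/SH7P, 6PGA/Ru5P) are
  computed from mean per-metabolite abundances, are scale-invariant,
  and return NaN on division by zero.

## Quantification

Eq.-style internal-standard quantification with MRRFs calibrated on a
standard mix; quantifying the mix itself returns the known amounts
exactly (identity tested). Metabolites without a response factor are
reported as relative integral/SI values flagged `unquantified` rather
than silently dropped or guessed. The secreted-metabolite, glucose
uptake and biomass yield normalizations are direct ratio formulas with
input validation.

## Architecture inference

Eight diagnostics — fumarate M+2/3/4, succinate M+2/3/4, aspartate
M+3/4 — are called present when their fraction exceeds θ (default 0.01,
configurable; presence/absence is how such bar-plot data are actually
read). A candidate topology's expected calls come from simulating it
from fully labeled inputs under the same configuration (default 4 turns,
mixing 0.5 — a pre-steady-state sampling regime). The score is the
matching-call count over 8; ties break toward fewer predicted-present
diagnostics (parsimony), then name. No likelihood is constructed: there
is no credible noise model for these fractions, and inventing one would
only add tunable structure. Candidates with identical predicted call
sets are observationally equivalent on the given profile and are
cross-referenced in the result rather than hidden. Under the defaults
the three TCA architectures have mutually distinct call sets
(oxidative: FUM M+2 present; reductive: M+3 only; bifurcated: M+3/M+4
with no FUM M+2), and self-recovery holds for each.

## Energetics

Whole-cell ATP ledger, cytosolic NADH ledger. Defaults: 2 ATP invested,
2 ATP payoff per triose completing lower glycolysis, 2 TCA
substrate-level phosphorylations, 10 NADH + 2 FADH₂ per fully oxidized
glucose, and 1 ATP per NADH and per FADH₂ — one consistent choice that
places complete oxidation at 16 ATP/glucose, inside the 16–18 range
cited for yeasts lacking proton-pumping complex I; both P/O-like
parameters are configurable. Respiratory terms scale with the fraction
of trioses neither diverted to G3P nor fermented. The fermented
fraction defaults to 1 for non-respiring and 0 for respiring
strategies. Mitochondrial and cytosolic NADH are not separated except
in the explicitly cytosolic redox ledger. `balance_fermentation` is the
closed form `(2−2f)/(2−f)` clipped to [0,1] and zeroes the ledger to
1e-12 across the diversion range (tested).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
integral tables with `integral = MRRF × nmol / SI_nmol × SI_integral ×
lognormal(CV)` (the internal-standard row receives the same
multiplicative noise, so SI normalization is itself imperfect), a
noise-free standard mix at 1 nmol per metabolite, default 5% CV,
6 replicates for abundance panels and 4 for tracing, and label time
courses from the simulator with optional natural-abundance convolution
and per-component multiplicative noise followed by renormalization.
Growth/glucose series are exponential OD with consumption constructed
so the uptake-rate formula recovers the true rate exactly at zero
noise; measurement noise applies to the consumed-glucose differences
(what paired assays against fresh medium measure), not the absolute
glucose level. Defaults for the true pools and response factors are a
fixed, plausible exponential-phase panel.

What passing recovery tests show — and do not show: the generator
reproduces multiplicative detector noise, replicate structure and
topology-consistent labeling, but not retention-time drift, fragment
cross-talk, matrix effects, compartment-specific pools or
non-stationary fluxes; recovery under the generator is therefore a
correctness check of the analysis pipeline, not a validation against
real chromatograms.

## Numerical choices and problem sizes

Distributions are validated to sum to 1 within 1e-9 after every
operation (inputs accepted to 1e-6 and renormalized). Monte-Carlo
checks use 10⁵ molecules; end-to-end topology recovery uses 100 seeds
at 5% noise over the five presets; all default simulations are ≤ 6
turns, so the whole suite runs in well under a minute on one CPU.

## Known limitations

* No kinetics, thermodynamics, flux estimation or reversible exchange;
  branch fluxes in mixed topologies are not quantified (the inference
  is presence/absence only).
* No compartmentation: the observation that fumarate reductase can
  favor M+4 fumarate, plausibly via compartmentalized fumarate pools,
  has no mechanistic model here and is outside the scored diagnostics.
* Turn index is not mapped to minutes; no rate constants are assumed.
* Natural abundance is modeled for carbon only, and only at the
  analysis/generation boundary — propagation itself is tracer-pure.
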