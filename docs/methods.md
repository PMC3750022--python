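# Methods

## The circuit and its models

The system is a bifunctional two-component signaling pair: a sensor
histidine kinase Q (PhoQ-type) that both phosphorylates and, through a
separate phosphatase activity, dephosphorylates its response regulator P
(PhoP-type).  Phosphorylated regulator P\* is a transcription factor that
activates the operon encoding both proteins, closing a positive feedback
loop.  All three proteins are stable; the only loss term is
growth-mediated dilution at rate λ.  Everything is dimensionless:
concentrations are in units of the feedback half-saturation scale `K_f`
and time is set by the default growth rate λ = 0.02.

Three deterministic model levels share the production nonlinearity

    F(P*) = V_0 + V_f · P*^h / (K_f^h + P*^h),

a saturating activation on a constitutive floor.

**Reduced (3 species: P, Q, P\*).**  Kinase flux `k_k·P·Q`, phosphatase
flux `k_p·P*·Q`, co-production of P and Q at `F(P*)` (one operon), dilution
`−λX` on every species.  The two bilinear fluxes plus feedback saturation
are the nonlinearities that matter.

**Detailed (6 species).**  Adds autophosphorylation `Q → Q*` (k_a), the
phosphotransfer complex `P + Q* ⇌ C_t → P* + Q`, and the phosphatase
complex `P* + Q ⇌ C_p → P + Q`, with dilution on the complexes too.  With
fast cycling and matched effective rates
(`k_on_t·k_cat_t/(k_off_t+k_cat_t+λ) ≈ k_k`, analogously for the
phosphatase side, unsaturated complex occupancy) it collapses onto the
reduced model; the packaged defaults are in that regime and the collapse
is verified to 5% in the tests.

**Decoupled.**  The engineered variant in which the kinase is expressed
from a feedback-insensitive promoter while the regulator side stays
autoregulated.  Two forms: a 2-species form with `Q = Q_tot` clamped, and
a 5-species sequestration form (P, P\*, Q, Q\*, C_p) with direct
phosphotransfer `P + Q* → P* + Q` (k_t) and a catalytically dead
phosphatase complex C_p of dissociation constant `K_d = k_off_p/k_on_p`.

## Hill coefficient: default h = 1

Bistability in this architecture does not require transcriptional
cooperativity: the kinase and phosphatase fluxes are products of two
concentrations that *both* grow with feedback, which supplies the
effective second-order nonlinearity.  We therefore default to `h = 1`
(configurable).  This is also a structural requirement for the
architecture result below: with a fixed kinase pool, an `h = 1` feedback
map is concave and hence provably monostable, so decoupling kinase
expression genuinely abolishes bistability.  With `h ≥ 2` the regulator's
own feedback can be bistable at fixed kinase, and the architecture
comparison would be confounded.

## Default parameter set

Defaults live in `src/tcswitch/configs/*.yaml` and were located by the
package's own bifurcation sweeps and 2-D scans, not assumed:

| field | value | meaning |
|---|---|---|
| `k_k` | 1.0 (wild type) | kinase rate constant |
| `k_p` | 50 (wild type) | phosphatase rate constant |
| `V_0` | 5·10⁻⁵ | constitutive production |
| `V_f` | 0.2 | maximal feedback production |
| `K_f` | 1 | feedback half-saturation (concentration unit) |
| `h`   | 1 | Hill coefficient |
| `lam` | 0.02 | growth/dilution rate |

The mutant transform applies κ = 0.1 to the kinase rate and zeroes the
phosphatase (`k_p`, and `k_cat_p` in the detailed model); the ΔP2
transform additionally applies δ = 0.1 to `V_0` (residual basal
transcription, not zero).  κ and δ are calibration knobs, not measured
quantities.  At these defaults the mutant is bistable over
`k_k ∈ (≈10⁻³, ≈0.21)` and over `λ ∈ (≈0.016, ≈0.068)`; λ = 0.02 sits
inside the window, and lowering λ below ≈0.016 makes ON the only stable
state — the deterministic mechanism of priming.  The wild type is
monostable over the whole kinase sweep because the phosphatase flux
dominates dilution (`k_p·Q ≫ λ` at every branch).

## Steady states and bifurcation structure

For every model the steady-state condition reduces to one scalar balance
equation in P\*:

* reduced: operon balance gives the protein scale `T = F(P*)/λ`, with
  `Q = T`, `P = T − P*`, leaving
  `g(P*) = k_k(T−P*)T − k_p·P*·T − λP*`;
* detailed: at fixed P\* the complex and Q\* balances are linear in free
  Q, and the remaining equation for free P is strictly increasing, so the
  inner solve is unique (monotone bisection) and `g(P*)` single-valued;
* decoupled: same construction with the Q family clamped to `Q_tot`.

Roots are bracketed by sign changes on a 4000-point log-spaced grid over
`[0, 1.05·(V_0+V_f)/λ]` (the OFF root can sit five decades below the ON
root, which is why the grid is logarithmic) and polished by Brent's
method to machine precision; each root must satisfy `|rhs| < 10⁻⁹` or the
solver errors out.  Stability is the sign of the leading eigenvalue of
the numerical Jacobian; real parts within ±10⁻⁹ of zero are flagged
`marginal` and excluded from regime calls.  Fold points are localized by
bisection on the swept parameter between grid cells where the root count
changes (relative tolerance 10⁻⁶).  Regimes: two stable states →
`bistable`; one stable state → `monostable_off`/`monostable_on` against a
reference scale, defaulting to the geometric mean of the OFF/ON branches
at the nearest bistable sweep point and falling back to `K_f`.  Display
values in 2-D maps are floored at 10⁻⁴.  The test suite checks the root
finder against an independent dense-grid sign scan (≥10⁵ points, plain
bisection) on 200 random parameter draws, and stability labels against
forward integration from perturbed states.

## Why the decoupled circuit needs a *tight* complex to switch

With a weak complex the decoupled circuit is monostable at every
induction level (concave feedback map, above).  A tight, catalytically
dead P\*·Q complex restores bistability by molecular titration: free P\*
is suppressed while unphosphorylated Q remains to absorb it, and rises
steeply once production outruns the sequestration capacity.  A pure
dead-end complex cannot do this — at the would-be ON state nearly all Q
is sequestered, so autophosphorylation (`k_a` × free Q) cannot supply the
flux λ·P\* that dilution removes, and the ON state never exists.  We
therefore let the complexed kinase still autophosphorylate, resolving the
complex as `C_p → P* + Q*` at `k_a` (the phosphatase-competent
conformation is the unphosphorylated kinase; once it autophosphorylates,
the complex releases its cargo).  Sequestration then throttles free P\*
at OFF without capping kinase supply at ON.  With
`k_t = 0.5, k_a = 0.1, k_on_p = 100` the scan over (Q_tot, V_0) shows a
bistable Q_tot band at `K_d = 10⁻³` and none at `K_d = 10`, closing at
both ends: too little kinase at low Q_tot, runaway activation at high
sequestration capacity exhausted.

## Stochastic simulation

Counts are concentrations × system size Ω; promoter propensities use the
count-space form `C_P2 + C_P1·n^h/((K_f·Ω)^h + n^h)` with `C_P1 = Ω·V_f`,
`C_P2 = Ω·V_0`.  The default network mirrors the reduced scheme
(operon production emitting one P and one Q per event, kinase,
phosphatase); the six-species detailed scheme is selectable and is the
one checked term-by-term against the detailed rate equations.  Mutant
networks simply omit zero-rate reactions, so the phosphatase catalysis is
absent from the T281R reaction list.  Growth is a simulation policy, not
a reaction:

* `generations` (default): exact SSA for one doubling time `ln 2/λ`, then
  every count is split binomially (p = 1/2) into the followed daughter —
  the realistic partitioning-noise model;
* `dilution`: continuous first-order loss `λ·n`, whose ensemble mean
  follows the rate equations exactly;
* `none`: pure chemistry, for isolating the reaction core.

The generation policy produces a within-generation sawtooth whose
time-average sits ≈4% above the continuous-dilution steady state; this is
a property of the growth model, not an error, so quantitative SSA-vs-ODE
checks (ensemble mean within 3 SE of the ODE at 10 checkpoints, Ω = 10⁴)
use the dilution policy, while state-retention, priming and bimodality
runs use the generation policy at Ω = 100 (about 10³ molecules in the ON
state, single molecules in the OFF state — the discreteness that makes
OFF→ON ignition a rare event).  The per-run endpoint statistic is the
time-averaged P\* count over the final generation.  Runs are reproducible
given (config, seed); ensembles derive per-run seeds from a base seed.

Endpoint classification: the priming threshold defaults to the geometric
mean of the OFF/ON deterministic references; bimodality reports the
fractions of runs within one third of the OFF–ON log-separation of each
reference and flags a set bimodal when both modes hold ≥5% of runs.
Switch detection requires a full crossing of the hysteresis band
(OFF threshold < ON threshold); chatter inside the band is ignored.

## Protocol emulation

**Priming assay.**  A schedule of phases (duration in generations, growth
rate, multiplicative parameter overrides) integrated deterministically;
the endpoint is classified against the baseline OFF/ON references.  The
stimulus (e.g. Mg²⁺ for this circuit) is represented *only* as a phase
override on the kinase rate or expression rate — the models carry no
explicit ligand, and the mutant's inverted stimulus response is an input
scenario, not a mechanism.  The assay outcome is invariant under time
rescaling of the whole schedule because phase durations are in
generations.

**Induction sweep.**  For each induction level (target total kinase,
constant-rate phoQ production `λ·k_cons·Q_tot·Ω`), SSA ensembles start
from the uninduced and the fully induced steady state and run 15
generations; medians and their large-sample standard errors
(`1.2533·sd/√n`) are reported per (level, start).  Pre-formed kinase
dilutes only 2× per generation, so convergence within 15 generations
bounds the resolvable induction range: the default grid spans
`Q_tot ∈ [0.1, 5]` (≈1.7 decades around the response midpoint
`λ/k_k = 0.2`); a much wider range leaves a start-dependent washout
transient at the low end that is not hysteresis.  The autoregulated
mutant run under the same two-start design retains full start dependence
— the actual hysteresis control.

**Serial-dilution lineages.**  A two-state population process, not
per-cell chemistry — at ~10⁹ cells per culture only state fractions
matter.  Each day: a binomial bottleneck of `n_b = 2000` founders drawn
from the previous day's fractions, `log2(10⁶) ≈ 20` generations of
doubling with per-generation binomial switching in both directions, then
binomial stationary-phase survival (`s_on` on ON cells).  Defaults
`p(ON→OFF) = 10⁻⁴` per generation and `s_on = 0.5` per stationary block
are free inputs chosen to produce the qualitative pattern the package
tests (near-100% ON lineages at day 3, divergence by day 5); no measured
values exist for them.

## Quantification

Cells are classified on the YFP/CFP ratio.  The default threshold is the
geometric midpoint of a two-component Gaussian mixture fitted to the log
ratios (deterministic initialization from the quartiles); a fixed
threshold can be supplied instead.  Percent ON is invariant under common
rescaling of both channels.  Competition statistics from plate counts:
`CR = C(10)·L(0) / (C(0)·L(10))` (neutral = 1; bounded by 2 in a 1:1
design, the bound attained at sensitive elimination) and
`CI = [C10/(L10−C10)] / [C0/(L0−C0)]`, which errors when the sensitive
count falls below detection rather than returning a number.  Counts may
be dilution-backscaled floats; subset invariants are checked with a 10⁻⁶
rounding tolerance.  Serial-dilution arithmetic: `log2(d)` doublings to
regrow a d-fold dilution; minority-presence probability `1 − (1−f)ⁿ`.

## Synthetic data

The cell generator draws CFP lognormal (state-independent), YFP/CFP
lognormal per latent state with medians separated by `fold` (default 60),
and width truncated-normal with ON cells narrower than OFF; channel CV
defaults to 0.3 on the log scale, chosen so the two modes are clearly
separated.  Optional extras: a YFP ceiling (reporter saturation in the ON
state) and nothing else — reporter-dilution memory after switching is not
modeled by default.  The competition generator solves for the sensitive
survival fraction that reproduces a requested CR exactly, then optionally
Poisson-resamples each plated subpopulation.  All generators are
deterministic given seeds and return/encode their ground truth, and every
generated parameter (ON fraction, fold, CR) is recovered by the
corresponding quantification within 3 SE or 10% at n = 10⁴ in the tests.

What passing these tests does *not* show: the generators draw clean
mixtures with independent cells — no segmentation errors, background
gradients, autofluorescence tails, cell-cycle covariance between channel
intensity and width, or plate-count over-dispersion beyond Poisson.
Recovery on this synthetic structure validates the estimators'
arithmetic, not their robustness to real microscopy artifacts.

## Problem sizes

Stochastic checks use Ω = 100, 150–300 runs per condition and 25–35
generations (the deterministic-limit check uses Ω = 10⁴ with 30 runs);
the root-finder oracle uses 200 random parameter draws against a
≥10⁵-point scan; 2-D scans use 13×5 grids.  These sizes give binomial
standard errors of a few percent on every reported fraction, which is the
resolution at which the qualitative claims are stated.

## Known limitations

* No explicit mRNA or translational bursting (burst noise would raise
  switching rates at equal Ω); transcription and translation are lumped
  into one production rate.
* Mg²⁺ sensing, membrane localization, ATP cycling and kinase
  dimerization are out of scope; stimulus enters only via parameter
  overrides.
* In the six-species model, fast autophosphorylation can starve the
  phosphatase of its substrate-competent (unphosphorylated) form at very
  low kinase consumption, producing bistability where the reduced model
  has none; the shipped detailed defaults avoid this corner (unsaturated
  phosphatase, `K_M = 40` above the ON scale), and the reduced model is
  the reference for sweep-wide wild-type monostability.
* The lineage model ignores growth-rate differences during exponential
  phase and treats stationary-phase selection as a single per-day
  survival factor.
* Whether the original detailed treatment diluted intermediate complexes
  is not determinable from available sources; we dilute every species,
  complexes included.
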