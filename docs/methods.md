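# Methods

## The biological system and the modelling question

In syncytial *Drosophila* embryos, mother centrioles recruit a large
pericentriolar-material (PCM) scaffold before each mitosis ("centrosome
maturation"). Live imaging shows a surprising choreography: centrosomal Polo
kinase rises and falls first, Spd-2 follows with its own pulse, and the Cnn
scaffold keeps growing and then plateaus even while Polo and Spd-2 are
already declining before nuclear envelope breakdown (NEB). `polopulse`
implements two coupled well-mixed ODE models that explain this choreography,
the in-silico genetics built on them, and the measurement pipeline used to
quantify such recruitment dynamics from centrosome-intensity tracks and FRAP
series.

## Model 1 — scaffold assembly driven by centriolar Polo activity

State variables are amounts (arbitrary intensity units, a.u.) in a
well-mixed two-compartment picture (cytoplasm vs centrosome); time is in
minutes. A centriolar pool of active Polo — the *drive* — acts on a
receptor-bound pool of Spd-2:

| # | reaction | rate law |
|---|----------|----------|
| 1 | S + RS_free ⇌ RS_bound | k_bind·S·RS_free / k_unbind·RS_bound |
| 2 | RS_bound → S\* + RS_free | k_phos_S·drive·RS_bound |
| 3 | S\* → S | k_dephos_S·S\* |
| 4 | S\* + P + C → S̄ | k_stab·S\*·P·C |
| 5 | S̄ → S + P + C | k_destab·S̄ |
| 6 | S̄ → S\* + P + C\* | k_cat_C·S̄ |
| 7 | C\* → C | (k_dephos_C + γ_C·C\*)·C\* |

S\* is the weak phospho-Spd-2 scaffold (reverts fast), S̄ the stable
Spd-2·Polo·Cnn unit with 1:1:1 stoichiometry (reverts slowly; the parameter
validator enforces k_dephos_S > k_destab), and C\* the Cnn scaffold whose
per-unit disassembly rate grows linearly with its own size — the simplest
form of size-dependent disassembly, and the term that makes the Cnn curve
plateau rather than grow without bound. Reaction 6 realises catalytic Cnn
conversion: the stable unit releases activated Cnn and returns its Spd-2 to
the weak scaffold, so one Spd-2 can convert many Cnn.

The trimolecular step 4 is a single effective transition rather than
sequential binding; intermediate occupancy states would only delay and
damp the pulse, and the model is deliberately minimal. Phosphatases act at
constant cytoplasmic levels, hence the first-order reversion terms.

Observed totals mirror what centrosomal fluorescence sums over:
`total_polo = drive + S̄`, `total_spd2 = S* + S̄`, `total_cnn = S̄ + C*`.

In **imposed-pulse mode** the drive is an external raised-cosine bump
(`PulseSpec`): zero at cycle start, maximum (default amplitude 1 a.u.) at
mid-S-phase, zero again at the S/M boundary. The shape family is a named,
swappable strategy (a triangular variant ships too); nothing downstream
depends on the exact form beyond non-negativity, a zero start and
unimodality.

## Model 2 — the delayed-negative-feedback pulse generator

The centriolar Polo receptor (Ana1-like, pool RP_tot) cycles through four
states:

- R_off → R_on at k_R_on (phosphorylation by a cell-cycle-regulated kinase;
  this single rate is the handle through which the cell-cycle oscillator
  paces the pulse),
- R_on + P → R_occ at k_P_on·R_on·P (Polo loading and local activation),
- R_occ → R_on + P at k_P_off (release),
- R_occ → R_dead at k_inh·R_occ·(R_occ + S̄) (feedback inactivation).

The activator thus creates its own inhibitor — locally active Polo
phosphorylates occupied receptors at additional sites — and receptor-bound
Polo (R_occ) rises and falls as a pulse. Two structural choices matter:

1. **The inactivation rate scales with total local active Polo**
   (R_occ + S̄), not first-order in R_occ alone. A purely first-order
   inactivation is dose-invariant and cannot reproduce the half-dose
   phenotypes: with it, halving either pool rescales the pulse without
   changing its relative shape.
2. **Inactivated receptors keep their Polo.** R_dead is the *occupied*
   off-state: its Polo is sequestered (inactive, not counted in the observed
   total) until the receptor is reset by a mitotic phosphatase — a step
   outside the modelled window, so within a cycle R_dead is an absorbing
   Polo sink. This choice is load-bearing. Polo is limiting (P_tot = 1 a.u.
   against a receptor pool of 0.95 and a scaffold that holds up to ~0.3), so
   wild-type embryos, which burn through their receptors faster, lock more
   Polo away and starve their own scaffold late in S-phase. That asymmetry —
   the receptor pool is a Polo *sink*, the Spd-2 pool is the scaffold
   *substrate* — is what lets Ana1 half-dose end S-phase with *more*
   centrosomal Polo while Spd-2 half-dose ends with less, robustly across
   the whole parameter sweep. With the released-Polo variant (inactivation
   returning P to the cytoplasm) we could not find any parameter set, by
   extensive scored search, for which both half-dose directionalities hold;
   the two final-amount ratios pin against 1 from opposite sides.

In **coupled mode** the scaffold drive at time t is R_occ(t), and Polo
conservation reads P + S̄ + R_occ + R_dead = P_tot.

With the feedback removed (k_inh = 0) the pulse disappears: R_occ ends the
cycle at its maximum. It is not strictly monotone sample-to-sample — there
is a ≲2% transient dip mid-cycle while the growing scaffold briefly
outcompetes receptors for the limiting free Polo — but there is no decline.

## The two-cycle protocol and in-silico genetics

All reported curves come from a two-cycle protocol: a burn-in cycle from
zero scaffold, then a boundary step in which each scaffold species is halved
(the PCM is divided between two new centrosomes), cytoplasmic pools are
replenished to conserve totals, and the receptor pool is reset to fully
inactive (the mitotic reset happens between modelled cycles). The second
cycle is reported, so centrosomes start with inherited PCM but the pulse
restarts from zero — matching how embryonic centrosomes actually enter each
cycle.

Defaults model a cycle-12-like cycle: 12 min S-phase + 3 min mitosis.
`set_cycle_rate` conditions the model on cycles 11/12/13 by scaling k_R_on
by 1.0/0.7/0.5 and lengthening S-phase (10/12/14 min) — the oscillator
slows at successive cycles, so receptor activation and S-phase length move
together.

Genetic perturbations are parameter edits: half-dose Spd-2 halves S_tot,
half-dose Ana1 halves RP_tot; the phospho-site recruitment mutants scale
k_P_on (centriole receptor) or k_stab (PCM scaffold). The robustness scan
halves/doubles each of the 13 reaction rates; the dose sweep varies each
rate over a 7-point log grid on [0.5, 2] and reports half-dose/WT ratios of
the Polo-pulse peak amount, peak time and end-of-S-phase amount (ratio < 1
means the half-dose condition is lower). The peak-amount ratio under Ana1
half-dose is recorded but its sign is not asserted anywhere: it genuinely
flips in parts of the swept regime, which is expected behaviour of the
model, not a defect.

## Calibrated default parameters

The defaults in `polopulse.params` are a calibrated in-house set: they were
chosen, by scored search over the rate space, to satisfy all the qualitative
behaviours above simultaneously — the peak ordering Polo < Spd-2 < Cnn with
Polo/Spd-2 declining below 90% of peak by end of S-phase and Cnn drawing
down ≤ 10%, in both drive modes, under 2-fold perturbation of every rate,
and with the half-dose directionalities holding over the full sweep grid —
and then rounded. They are stated in arbitrary units and are not fitted to
any embryo data. Two deliberate features of the regime: Polo loading is
partially rate-limiting (k_P_on·P is comparable to k_R_on), so halving the
Polo pool measurably delays as well as lowers the receptor pulse; and the
scaffold holds more end-of-S Polo than the receptors do, so the Spd-2 dose
dominates the late total.

## Numerics

LSODA (stiff-capable, adaptive) at rtol 1e-8 / atol 1e-10, dense output on
a 0.05-min grid. Conservation of all five pools (Spd-2, Cnn, both receptor
pools, Polo) is checked post-hoc; drift is ≤ 1e-6 relative on every run
(observed ~1e-15). An independent fixed-step classical RK4 integrator at
dt = 1e-3 min serves as a brute-force oracle; adaptive and fixed-step
solutions agree to < 1e-4 maximum relative difference (observed ~3e-8),
with per-species differences scaled by each species' own trajectory
amplitude. Integration failures raise with the failure time; species more
negative than -1e-9 abort the run.

## Measurement pipeline

**Pulse features.** Initial intensity is read at the track's first S-phase
timepoint; the peak is located on a centred moving average (default window
3 samples — the source protocol does not state one) with the maximum read
from the raw series; growth rate is (maximum − initial)/growth period.
Tracks without an interior peak are flagged rather than rejected; a flat
track gets growth rate 0 over the full span. An optional sub-sample
refinement (`refine_peak=True`) replaces the argmax by the intensity-weighted
centroid of the contiguous region above 70% of the smoothed dynamic range:
on slowly-varying pulses sampled every 30 s, the raw argmax has a standard
error of 1–2 sample intervals, which drowns the between-embryo timing signal;
the centroid estimator recovers it (at the cost of a small, consistent bias
that cancels in comparisons across tracks). The correlation analysis of
growth period against S-phase length uses this refined estimator.

**Cnn growth curves.** Three nested candidates are fit per track — linear
rise, rise-to-plateau, rise-then-fall (continuous piecewise-linear, free
breakpoint profiled over interior sample times then refined by bounded 1-d
minimisation, both segments ≥ 3 samples) — by weighted least squares with
weights 1/y, matching the multiplicative noise of fluorescence data;
unweighted fits systematically over-select bent models because late,
brighter, noisier samples dominate the residual. Selection is by AICc
(counting the breakpoint and residual variance as parameters), with ties
preferring the simpler model, and a rise-then-fall candidate is only
admitted if its fitted second segment actually declines (slope
< −0.05·|rise|). At 5% noise and 30-s sampling of cycle-like archetypes this
selects the generative class in ≥ 95% of tracks per class.

**OM/NM pairing.** Centrosome pairs are formed greedily by ascending
inter-centrosome distance at the first S-phase timepoint, accepting pairs
under the distance threshold; distance ties break on the lower centrosome
id, making the labelling invariant to input order. Within a pair the
brighter centrosome at its first S-phase timepoint is the old mother.

**Correlation statistics.** Pearson r with p-value and the least-squares
regression line; the premise of bivariate normality is assessed with the
Henze–Zirkler test (via pingouin, log-normal p-value approximation). Its
type-I error at n = 30 calibrates to 0.046–0.059 over 2000 null replicates.

**FRAP.** Recovery series are fit to I(t) = b + A(1 − e^(−kt)) by nonlinear
least squares from a closed-form initial guess (baseline from the first
point, amplitude from the tail, rate from log-linearised early points).
The initial recovery rate is reported both model-based (A·k, the analytic
t = 0 derivative of the fit) and model-free (slope of the first three
samples; a known underestimate since the curve is concave) because the
estimator used for the published quantity is not specified. Half-time is
ln 2/k. Non-convergent or signal-free series keep the initial guess and are
flagged. Cross-cycle comparisons use Welch's ANOVA followed by pairwise
Welch t-tests with Šidák correction — a practical approximation to
Dunnett's T3 procedure (T3 uses the studentised maximum modulus
distribution; the Šidák-corrected Welch tests are very slightly more
conservative at these group sizes).

## Synthetic data

The generators emulate the live-imaging data the pipeline was built for,
with known ground truth:

- **Embryo cohorts**: per-embryo model trajectories (two-cycle protocol)
  sampled at a 30-s imaging interval (an assumption — the source frame rate
  is unstated), aligned to NEB (t = 0, S-phase negative), with per-embryo
  S-phase-length jitter (log-scale CV 5%) coupled inversely into k_R_on —
  one latent oscillator pace drives both observables. Noise is
  multiplicative log-normal with stated CV, unit mean, so `noise_cv=0`
  reproduces the model exactly.
- **OM/NM pairs**: pairs 1 µm apart on an 8-µm grid, OM planted 1.5× brighter,
  isotropic Gaussian position jitter per timepoint.
- **Cnn archetypes**: the three growth-curve classes with defaults slope
  2 a.u./min, breakpoint 6 min, fall slope −1 a.u./min over a 12-min track.
- **FRAP**: the exponential-saturation model at the protein-specific imaging
  intervals (4/15/30 s for Polo/Spd-2/Cnn), default k = 0.0693 s⁻¹
  (half-time 10 s, Polo-like).

All generators are pure functions of their parameters and an integer seed.

What passing on these cohorts does **not** show: robustness to the
photobleaching, background and tracking artefacts of real image-derived
tracks (assumed corrected upstream), to centrosome-to-centrosome
heterogeneity within an embryo (one average track per embryo per protein),
to non-log-normal noise, or to FRAP recoveries that are not
single-exponential (diffusion-limited or two-component recoveries).

## Known limitations

- Well-mixed compartments: no outward flux of scaffold, no spatial
  structure, no daughter-centriole growth.
- Mitotic-exit PCM disassembly ("flares"/"packets") is not modelled; runs
  simply end at the cycle boundary and the reset is bookkeeping.
- The mitotic reset of inactivated receptors (R_dead → R_off) happens only
  between cycles, never within one.
- The cell-cycle oscillator is not modelled; it enters only as a static
  per-cycle scaling of k_R_on.
- Default parameters are a calibrated stand-in, in arbitrary units; none of
  the quantitative outputs should be read as fitted to embryo measurements.
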