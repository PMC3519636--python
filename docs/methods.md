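# Methods

## Gating model

Channels are described phenomenologically, in the separable
Hodgkin–Huxley form `I = g_max · Po(t) · h(t) · (V − E_K)`. This
matches the level at which whole-channel voltage-clamp studies report
their results — Boltzmann midpoints and slopes, exponential time
constants — rather than microscopic rate constants, which such data do
not constrain.

**Activation.** The steady state is a single Boltzmann
`Po_∞(V) = 1/(1 + exp(−(V − V50)/s))`. Kinetics are first order with a
direction-dependent time constant: depolarizations relax with
`τ_act(V) = τ_act(+60 mV) · exp((60 − V)/v_slope)` and
repolarizations with `τ_deact(V) = τ_deact(−100 mV) · exp((V + 100)/v_slope)`,
i.e. log-linear voltage dependence in both directions (activation
slows toward threshold, deactivation slows with depolarization). Three
simulation modes share this steady state:

- *macroscopic* — `Po` itself relaxes mono-exponentially. Used for all
  quantitative parameter-recovery runs: the fitted Boltzmann and
  exponential parameters then equal the configured ones up to
  measurement design, not model mismatch.
- *mechanistic* — `Po = m^n` with `n` independent two-state gates.
  The per-gate Boltzmann (V50′, s′) is calibrated in closed form so
  that `Po_∞` crosses 0.5 at the configured V50 with the configured
  local slope: `s′ = 2 n s (1 − 2^(−1/n))`,
  `V50′ = V50 + s′ ln(2^(1/n) − 1)`. This mode produces the sigmoidal
  activation delay caused by closed–closed transitions; with `n = 1`
  it reduces exactly to the macroscopic mode.
- *instantaneous activation* — `Po` jumps to `Po_∞(V)` at each step.
  An idealized readout used where activation kinetics would
  contaminate a measurement of another process (see below).

**Inactivation.** Zero or more first-order components, each with a
fractional amplitude `f_j`, a decreasing Boltzmann availability
`h_∞,j(V)`, an inactivation τ (defined at +60 mV and treated as
voltage-independent above 0 mV) and a recovery τ (used below 0 mV).
Total availability is `h = (1 − Σf_j) + Σ f_j h_j`; an amplitude sum
below 1 leaves a non-inactivating pedestal (partial inactivation).
Components carry a mechanism tag:

- *N-type* (ball-and-chain): removed by the `truncated` flag
  (N-terminal deletion constructs), insensitive to external K⁺.
- *C-type* (pore collapse): both its inactivation and recovery rates
  scale as `k_half/(k_half + [K⁺]_out)`. Because the tabulated time
  constants were measured in the standard 2 mM-external solution, the
  stored τ is referenced to 2 mM: the applied rate scale is
  `(k_half + 2)/(k_half + [K⁺]_out)`, so 140 mM external K⁺ slows a
  `k_half = 5 mM` component ~21-fold (≤4 % of its zero-K⁺ rate).
- *unspecified*: affected by neither truncation nor K⁺, for phenotypes
  whose mechanism could not be assigned (NvShak6's partial
  inactivation).

**Heteromers.** Co-expression with a regulatory subunit is modelled as
a two-population mixture: `I = (1 − f)·I_homomer + f·I_heteromer` with
`f` the heteromeric conductance fraction (default 0.5). No subunit
stoichiometry is inferred.

## Simulation

Within an epoch of constant command voltage every state variable
relaxes exponentially, so sweeps are integrated in closed form: state
is propagated analytically across epoch boundaries and evaluated on
the sample grid. There is no ODE truncation error at any sampling
interval; the sampling-interval warning (`dt > τ_min/5`, counting only
relaxations with non-negligible amplitude) concerns the *analysis*
resolution of fast components, not simulation accuracy.

Default sampling: 0.05 ms for ≤400 ms epochs, 0.25 ms for protocols
containing 5 s conditioning pre-pulses (0.1 ms where sub-millisecond
activation kinetics shape a peak measurement), chosen to keep a full
study desk-scale (the complete six-channel summary runs in ~2 s).

Artifacts are additive: linear leak `g_leak (V − e_leak)`, capacitive
spikes at epoch boundaries (exponential, τ = 0.1 ms, charge
`c_mem·ΔV`, hence strictly linear in the step) and optional Gaussian
noise from a seeded generator recorded in the sweep provenance.
P/N subtraction is implemented as P/−4 from a −100 mV sub-holding:
sub-sweeps scale every excursion by −1/N, so channels stay closed;
the baseline-referenced, rescaled sub-sweep mean cancels any strictly
linear component exactly. A linearity check on the sub-sweeps warns if
channels activated in the sub-pulse range.

## Measurement design

Each summary measurement mirrors its experimental counterpart:

- **GV**: 100 ms steps (−60..+60 mV) with isochronal tails at
  −100 mV in symmetrical 140 mM K⁺, on the truncated construct so
  N-type inactivation does not obscure activation; tail amplitude is
  the back-extrapolation of the tail-decay exponential to the
  repolarization instant (robust to the 0.3 ms capacitive blanking
  window), divided by the tail driving force. Per-cell normalization,
  normalized Boltzmann fit (asymptotes 0 and 1), reported V50/s = mean
  of per-cell fits.
- **SSI**: 5 s pre-pulses (−120..0 mV), +60 mV test pulse, peak
  absolute test current after the blanking window, per-cell
  normalization, decreasing normalized Boltzmann (hyperpolarized
  asymptote fixed at 1, free pedestal). The 5 s conditioning is ≥25×
  every availability time constant, so pre-pulse equilibration is
  complete. The test pulse is read out in instantaneous-activation
  mode: activation at +60 mV is ~100-fold faster than conditioning,
  and the idealized readout makes the peak exactly proportional to
  availability. With finite activation kinetics the peak is inflated
  for pre-pulses that pre-open channels; for a channel whose
  activation and inactivation midpoints coincide (NvShak1, −19.5 vs
  −20.3 mV) that bias exceeds 4 mV — a genuine limitation of
  peak-current SSI measurements that the idealized readout
  deliberately removes.
- **Inactivation kinetics**: 600 ms step to +60 mV in
  instantaneous-activation mode; single-exponential fit from the
  peak, with double-exponential model selection by a nested F-test at
  α = 0.01 plus two practical-significance guards: the time constants
  must be separated more than 3-fold and both fractional amplitudes
  must reach 5 %. (On noiseless synthetic data the F-test alone
  rejects the single exponential for arbitrarily small second
  components; the amplitude guard keeps the selection aligned with
  what a fit to real, noisy data would resolve.) Ties prefer the
  simpler model.
- **Activation delay**: exponential fit of the late phase (samples at
  ≥50 % of the final rise); delay = closed-form zero-current intercept
  `t₀ − τ ln(−I_i/A)` minus the pulse start. Zero for a
  single-exponential rise, positive and increasing with gate count.
- **Deactivation**: +50 mV activation then 100 ms tails at −160..−80
  mV in symmetrical K⁺; single-exponential τ per tail voltage
  (log-linear in V for this model by construction).
- **Heteromer comparison**: inactivation from the difference between
  test currents after hyperpolarized vs depolarized 5 s pre-pulses.
  Only the positive (outward-direction) part of the difference counts:
  a genuine heteromeric component appears as extra decaying outward
  current, whereas activation-rate differences between the two
  conditioning states produce transients of the opposite sign; a
  10 ms settling window after the test step is skipped as well.
  Class cutoffs: τ < 15 ms very fast, < 60 ms fast, otherwise slow —
  calibration constants anchored to the qualitative observations
  (~1 s completion for the slowest, complete within 50 ms for the
  fastest). Threshold shift uses the most hyperpolarized grid step
  whose steady current exceeds 1 % of the most depolarized step's
  (10/20/≥30 mV → small/medium/large). Activation rate compares
  time-to-half-maximum at +20 mV (ratio > 1.5 slow, < 1/1.5 fast) and
  is reported undetermined when the mixture decays > 20 % from peak
  during the step (inactivation obscures the rise); deactivation rate
  compares −40 mV tail-decay τ. Properties whose recording is absent
  from a bundle are undetermined, mirroring experiments in which only
  the pre-pulse protocol was analyzed.
- **Threshold class**: high iff GV V50 ≥ 0 mV (closed boundary to make
  the rule total). Note one borderline case: a channel with a printed
  V50 of −0.8 ± 1.8 mV is classified "low" by this rule even though
  narratively it belongs with the high-threshold group.

## Fixture parameters

The six channel entries carry the published steady-state values
verbatim (inactivation τ at +60 mV with fractional amplitudes, SSI
V50/slope, GV V50/slope). Quantities published only as plots are
encoded qualitatively and flagged illustrative:

- activation τ at +60 mV: 2.5/1.6/1.6/1.0/0.7/1.2 ms for NvShak1–6
  (NvShak5 fastest, NvShak1 slowest, half-activation times under
  ~4 ms), e-fold per 40 mV;
- deactivation τ at −100 mV: 12/4/4/5/3/1.2 ms (NvShak6 fastest,
  NvShak1 slowest, 10-fold span), e-fold per 40 mV;
- NvShak6's partial inactivation: amplitude 0.6 (pedestal 0.4),
  mechanism-unspecified, τ = 30 ms — fast enough that the partial
  decay develops within a 100 ms step, as the published current family
  shows;
- recovery τ: 50 ms (N-type), 200 ms (C-type, at 2 mM external K⁺),
  30 ms (NvShak6); C-type `k_half` = 5 mM;
- `g_max`: 0.05 µS for excised-patch presets (~8 nA at +60 mV in
  2/140 K⁺), 1 µS for whole-oocyte (TEV) presets. Solutions: 2 mM
  external / 140 mM internal K⁺ standard, 140/140 symmetrical for
  tails; 295 K.

Heteromer presets modify a whole-oocyte NvShak3 reference whose
first detectable current falls at +10 mV on the −20..+20 mV grid
(GV V50 +20 mV — whole-cell recordings place NvShak3 activation at
more depolarized voltages than excised patches). Regulatory-subunit
effects are encoded as: hyperpolarizing V50 shifts of 10/20/30 mV
(small/medium/large), activation τ ×4 (slow) or ×0.25 (fast),
deactivation τ ×8 (slow; the channel family spans ~10-fold),
heteromeric inactivation τ of 250 ms (slowest), 30 ms with a 0.2
pedestal (intermediate) and 10 ms (fastest, complete within 50 ms).
These are qualitative anchors, not measured values.

## PDZ motif scanner

Class I consensus at positions −3..0: acidic (E/D), S/T, any,
hydrophobic (V/L/I). Near-consensus = exactly one constrained position
deviating through the allowed-substitution table −3 → {H, Q},
−2 → {F, G}, 0 → {F}, which is reverse-engineered from the observed
near-consensus termini rather than derived from a substitution matrix,
and is fully overridable (`PdzConsensus`). For the terminus -DGFV the
deviation is taken at −2 (G), with D accepted as the acidic −3
consensus; which residue was considered the substitution is not
recoverable from the source, so this assignment is uncertain. The call
is a pure function of the final four residues.

## What the generator does and does not emulate

Emulated: step families, conditioning pre-pulses, isochronal and
deactivation tails, long heteromer protocols, symmetrical-K⁺
solutions, linear leak (tens of nA), capacitive transients, additive
Gaussian noise, P/N subtraction, cell-to-cell replication.

Not emulated: single-channel stochasticity, series-resistance and
space-clamp errors, electrode drift, temperature dependence, non-K⁺
permeation, state-dependent (open-state-coupled) inactivation, and
any coupling between activation and inactivation beyond
multiplicative separability. Passing parameter-recovery tests
therefore demonstrates the internal consistency of the analysis
chain — that the fitting procedures measure what they claim on data
obeying the model — not robustness to the full error structure of
oocyte recordings. The noise-robustness Monte-Carlo (Boltzmann
midpoint bias < 0.3 mV at σ = 0.02) probes only additive Gaussian
noise.

## Numerical choices

Nonlinear fits use Levenberg–Marquardt least squares (lmfit) with
data-driven initialization: Boltzmann V50 from the half-range
crossing, s = 5 mV, amplitudes from the data extremes; exponential τ
from the time to (1 − 1/e) of the span, offset from the last sample.
Slopes and time constants are bounded positive; fit times are
referenced to the window start for conditioning. Flat traces raise a
degenerate-fit error; a Boltzmann fit is flagged low-confidence when
the data cover < 80 % of the fitted span or fewer than 5 points.
Peak and tail measurements skip a 0.3 ms post-step blanking window
(capacitive settling); back-extrapolation makes the tail conductance
insensitive to the blank. Numeric serialization uses 9 significant
digits (`%.9g`), which round-trips the text format bit-identically.
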