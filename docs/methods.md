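# Methods

## The physical model

The simulator represents a whole-cell recording from a voltage-sensor
domain that conducts protons through two distinct pathways plus leak:

- **AQ** — the intrinsic aqueous proton conductance, open in the
  activated state (depolarization-activated, rising Boltzmann);
- **SH** — a resting-state proton shuttle carried by a histidine at the
  first S4 arginine, open at rest (hyperpolarization-activated, falling
  Boltzmann);
- **LEAK** — voltage-independent ohmic membrane leak reversing at 0 mV.

Each gated conductance is a two-state Hodgkin–Huxley gate: the gating
variable m relaxes mono-exponentially toward the steady-state open
probability p∞(V) with a fixed activation time constant when p∞
increased at a voltage change and a fixed deactivation time constant
otherwise. There is no voltage-dependent τ(V), no multi-state Markov
scheme and no coupling between the two gates: the two conductances are
independent Boltzmann processes, which matches how they are fit. Within
each constant-voltage epoch the update is the exact exponential
solution evaluated at the sample times, so the simulation carries no
integration-step error; halving the sampling interval reproduces the
shared samples to machine precision (this is a tested invariant).

The proton reversal potential is Nernstian,
E_H = (RT/F)·ln 10·(pH_i − pH_o), with CODATA constants and a default
temperature of 293.15 K, where RT/F = 25.3 mV and the Nernst slope is
58.2 mV/pH unit (both to one decimal). Extracellular pH shifts each
gated midpoint linearly, V_eff = V_0.5 + s·(pH_o − 6.5) with
s = −40 mV/pH unit by default; pH 6.5 is the reference at which all
midpoints are quoted.

**Block.** The N4R phenotype is modelled as an instantaneous,
voltage-dependent block of outward current only: a sigmoid
b(V) = b_max/(1 + exp(−(V − V_b)/k_b)) multiplied into the gated
current whenever that current is outward, with no state variable (relief
on hyperpolarization is instantaneous). Defaults V_b = −80 mV,
k_b = 15 mV, b_max = 0.998: the block is essentially complete across
the entire outward range, which reproduces the observed phenotype
(outward AQ current invisible, inward tail currents untouched) and
leaves the outward limb of the I–V relation purely ohmic — the property
the leak-estimation step relies on. Note the block gates the
*conductance seen by outward current*: below E_H the AQ current is
inward and therefore unblocked, whatever the voltage.

## Reference parameter sets

`reference_parameter_sets()` returns the model panel used by the
reproduction pipeline, at symmetric pH 6.5:

| set | SH (g, V_0.5, dx) | AQ (g, V_0.5, dx) | notes |
|---|---|---|---|
| R1H | 4.6 nS, −189 mV, 42.1 | 22.2 nS, +29.4 mV, 24.9 | |
| R1H-N4R | same | same + outward block | |
| D185A-R1H | same | AQ midpoint +65 mV | |
| D185H-R1H | same | AQ midpoint +105 mV | |
| WT | — | 22.2 nS, +61.4 mV, 24.9 | slower kinetics |

Leak is 1.5 nS throughout. The SH parameters are the constrained-fit
values (midpoint fixed at the derivative-Gaussian estimate); the AQ
parameters are the leak-subtracted conductance fit. The WT-like midpoint
is the R1H value shifted +32 mV — the observed activation shift between
the two backgrounds — because no direct WT Boltzmann fit is reported.
Kinetics are not constrained by published time-constant data; the
defaults (SH 5/3 ms, AQ 20/10 ms, WT 100/50 ms activation/deactivation)
respect the reported ordering (SH gating clearly faster than AQ; the
R1H background faster than WT) and are long relative to nothing in the
analysis: every measurement window is several time constants long, so
their exact values do not move the recovered gating parameters.

## What the generator emulates, and what it does not

It emulates the statistical structure the analysis assumes: families of
step sweeps (hold → test step → tail) whose tail decay is
mono-exponential, U-shaped steady-state G–V relations composed of two
opposite-polarity Boltzmann components on top of ohmic leak, Nernstian
reversal, and rigid −40 mV/pH_o gating shifts. It does **not** emulate
capacitance transients, series-resistance error, pH-buffer depletion
drift of I_STEP, single-channel noise, or coupled multi-state gating.
Passing tests therefore demonstrate that the estimators are correct and
unbiased under the model's assumptions — not that those assumptions
hold in any particular recording. In real data, tail "hooks", drift and
seal instability would all need attention before this pipeline's numbers
could be trusted.

## Measurement conventions

- **I_STEP**: by default the signed sample of largest magnitude in the
  step epoch ("peak"); a "steady" policy (mean of the final 10% of the
  step) exists because steady-state conductance is what the G–V
  analysis needs. The pipeline uses "steady".
- **I_TAIL**: a mono-exponential I(t) = I₀ + A·exp(−(t − t₀)/τ) is fit
  over a window that by default starts two samples after the tail onset
  (skipping the instantaneous jump sample) and ends at five times an
  initial τ guess taken from the 1/e decay point; the reported
  instantaneous amplitude is I₀ + A, the fit value extrapolated to the
  moment of the voltage change. Fits are single-exponential only.
- **E_rev from tails**: a fixed activating step followed by a family of
  tail voltages; the zero crossing of instantaneous I_TAIL vs V_tail is
  interpolated linearly between the bracketing points (a full linear
  fit is optional). No sign change raises a no-bracket error.
- **V_THR**: threshold-by-eye is operationalized as the smallest step
  voltage at which the leak-subtracted |I_TAIL| exceeds
  max(k·σ_baseline, f·max|I_TAIL|) and stays above it at every more
  positive voltage; defaults k = 3, f = 2%. Absolute thresholds depend
  on f by construction (a 2% amplitude criterion sits ≈ 3.9 slope
  factors below the midpoint); *shifts* between constructs are
  f-invariant, and those are what the analysis compares.
- **Conductance transform**: G = I/(V − E_rev), with voltages inside a
  ±1 mV guard band of E_rev flagged as undefined rather than computed.
  In the pipeline the leak *current* is subtracted before dividing,
  which keeps the chord conductance finite through E_rev when E_rev ≠ 0
  (raw G contains a term g_leak·V/(V − E_rev) that diverges there).

## Fitting conventions

- **Boltzmann fits** store dx > 0 with an explicit polarity flag that
  sets the sign inside the exponential; any of the four parameters can
  be fixed exactly, and several datasets can be fit jointly with shared
  parameters (e.g. one slope factor across pH conditions). Bounded
  least squares via lmfit.
- **Derivative**: second-order central differences at interior points
  (correct weights on nonuniform grids), one-sided at the ends,
  reported at the measurement voltages.
- **Gaussian peak fits** use the area-amplitude form
  baseline + (A/(ω√(π/2)))·exp(−2(V − V_PEAK)²/ω²). The published
  formula for this relation is typographically garbled; this is the
  standard form consistent with the printed symbols and with the
  printed (A, ω, V_PEAK) triples, and it is the documented convention
  here. Fit windows are always explicit arguments — truncation changes
  the estimate, so no window is ever inferred. The peak direction
  ("up"/"down") is inferred from the data or forced by the caller; the
  area's sign is bounded accordingly and V_PEAK is bounded to the window
  ± its span, which prevents sign-flip local minima on strongly
  truncated data (out-of-window centers are flagged, not hidden).
- **Two-conductance decomposition** fits
  G(V) = G_SH·B↓(V) + G_AQ·B↑(V) with five seeded, jittered starts and
  keeps the best solution; components are identified by polarity, which
  breaks the labelling tie, and a component whose maximum collapses
  below 0.5% of the data maximum is flagged "collapsed".
- **Valence**: z_G = (RT/F)/dx at the recording temperature.

On noiseless data fully spanning both plateaus the Boltzmann fit
recovers its generating parameters to ≤ 10⁻⁶ relative error, the
decomposition to ≤ 10⁻⁴, and V_PEAK agrees with V_0.5 within 2 mV; all
midpoint estimators are equivariant under rigid voltage shifts. These
are tested properties, not aspirations.

## The reproduction pipeline

`run_reproduction` simulates the variant panel at pH_o 5.5/6.5/7.5
(noiseless by default, seed recorded) with steps of 10 mV from a
holding potential of −60 mV and tails at −90 mV. Steps descend to
−240 mV — deeper than a typical recording — so that the strongly
hyperpolarized shuttle gating at pH_o 7.5 (midpoint near −229 mV)
remains partially resolved; the most positively shifted variant extends
to +190 mV.

Stage order and the reasoning behind it:

1. **Leak** is estimated by an OLS line through the steady-state step
   I–V inside an ohmic window. Only the blocked background has such a
   window on the outward limb (just above E_H, where AQ carries no
   current); the unblocked variants *borrow* the blocked background's
   leak at the same pH — the same cross-variant subtraction the
   original analysis uses. The WT-like set (no shuttle) uses its linear
   inward limb instead. Recovered leak is within 5% of the injected
   1.5 nS in all conditions.
2. **AQ gating** comes from a Boltzmann fit of the leak-subtracted
   instantaneous tail currents at steps ≥ −60 mV (below that, residual
   shuttle tails contaminate the relation). Tail-based midpoints are
   insensitive to leak errors, which only offset the plateau.
3. **V_THR** is detected after removing a tail baseline line fitted
   over −160…−100 mV (AQ closed, shuttle tails approximately linear)
   and continued as a constant outside that range — extrapolating the
   line across the activation range would corrupt the positive limb.
4. **SH gating** comes from a Gaussian fit to the *signed* derivative
   of the leak-subtracted G_STEP–V relation, where the shuttle is a
   negative trough and the AQ limb is positive, so the two cannot be
   confused. The window is capped 6.5 slope factors below the measured
   AQ midpoint (where the AQ derivative is an order of magnitude below
   the trough); ω is determined by a free fit at the lowest pH_o — the
   most depolarized, best-resolved trough — and held fixed for the
   other pH conditions, the constrained-width strategy this analysis
   depends on for truncated curves; the baseline is fixed at zero, as
   appropriate for leak-subtracted data.

Recovered AQ midpoints are within ~0.5 mV (≤ 1.8 mV for strongly
truncated low-pH curves) of the generating values; SH V_PEAK is within
1–7 mV wherever the trough center lies inside the voltage range, and
the V_PEAK-vs-pH_o slope in the blocked background reproduces the
generator's −40 mV/pH within 2 mV/pH.

## Numerical choices and degenerate inputs

Exponentials are argument-clipped at ±700 to avoid overflow; τ is
bounded positive in tail fits and flagged when it hits a bound;
flat Boltzmann data are flagged "ill-conditioned"/"flat" rather than
reported as converged; duplicate voltages, empty windows, negative
noise SDs and out-of-range pH raise immediately. CSV round-trips write
17 significant digits so stored sweep sets reproduce the in-memory
float64 arrays bit-exactly.

## Known limitations

- The shuttle conductance's midpoint at pH_o 7.5 in the most shifted
  variants sits near or beyond the −240 mV protocol edge; the
  constrained Gaussian fit then extrapolates and can carry a bias of
  ~10–25 mV (D185H-R1H at pH 7.5 is the worst case). This is a
  truncation limit of the method itself, visible in the recovery table,
  not a defect of the fit code.
- Absolute V_THR values are criterion-dependent (see above); only
  threshold shifts are comparable across studies.
- Derivative-Gaussian V_PEAK from central differences is essentially
  unbiased toward V_0.5 on a 10 mV grid; one-sided derivative
  conventions displace it by about half a grid step. pH-slope and shift
  quantities are invariant to that convention; absolute V_PEAK values
  are grid- and window-banded.
- The simulator's independence of the two gates means it cannot test
  claims about sequential (coupled) activation; it reproduces the
  fitted description, which treats the curves independently.
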