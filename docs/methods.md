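# Methods

## The two-state photoselection model

Steady-state tryptophan emission red-shifts with increasing excitation
wavelength because lower-energy excitation photoselects fluorophore–solvent
substates that are progressively less relaxed at the moment of emission.
The observable is the center of spectral mass (CSM), the intensity-weighted
mean emission wavelength computed on the discrete instrument grid with no
interpolation or trapezoidal weighting — the statistic is deliberately the
raw first moment, so it is invariant to intensity rescaling and equivariant
under wavelength shifts, two properties the test suite checks exactly.

The CSM-versus-λEx curve is modelled as a two-state equilibrium between the
Franck–Condon (FC) and relaxed (R) emissive states. The free-energy gap is
taken linear in excitation wavelength, ΔG(λEx) = −m·(λEx − λEx50%), giving a
relaxed-state Boltzmann fraction p = e^(−ΔG/RT)/(1+e^(−ΔG/RT)) and

    CSM(λEx) = CSM_FC·(1−p) + CSM_R·p.

Both baselines weight the logistic. A variant with the FC term unweighted
(upper asymptote CSM_FC + CSM_R ≈ 750 nm, which no emission spectrum can
reach) is retained behind `literal_form=True` for comparison only; the
default form has asymptotes exactly CSM_FC and CSM_R and saturates at the
relaxed baseline, as complete red-edge datasets do.

Parameter conventions and defaults:

| parameter | meaning | units | notes |
| --- | --- | --- | --- |
| CSM_FC | FC baseline; tracks solvent exposure | nm | free; bounded by the emission window |
| CSM_R | relaxed baseline; fixed property of fluorophore+solvent | nm | free, shared, or fixed (398.7 solution Trp; 395.4 pooled protein) |
| m | gradient of ΔG vs λEx; flexibility statistic | J mol⁻¹ nm⁻¹ | larger m ⇒ steeper transition ⇒ more rigid ensemble |
| λEx50% | transition midpoint (ΔG = 0) | nm | typically above the measured window |
| T | temperature | K | from the dataset; 298.15 K fallback with a warning |
| R | gas constant | J mol⁻¹ K⁻¹ | 8.314 |

A note on the magnitude of m: values of order 10³ J mol⁻¹ nm⁻¹ are needed
for the logistic argument m·Δλ/RT to traverse the transition within tens of
nm at room temperature (RT ≈ 2479 J mol⁻¹). Published gradients are
sometimes quoted on a much smaller numeric scale; `reesfit` reports m
exactly as fitted, in J mol⁻¹ nm⁻¹, and applies no rescaling.

## Fitting

All fits are bounded nonlinear least squares (lmfit/`least_squares`),
weighted by 1/σ(CSM) when replicate errors are present (equal weights
reproduce the unweighted fit). Initialisation reflects observed curve
shapes: CSM_FC from the curve minimum, CSM_R at 398.7 nm unless fixed,
λEx50% just above the measured window, m set so the logistic argument spans
about two units across the window. Five jittered starts (seeded) guard
against local minima; the lowest-SSE converged solution is returned with the
multiplicity recorded. Standard errors come from the Jacobian-based
covariance at the optimum; `fit(bootstrap=N)` substitutes a seeded residual
bootstrap, which is more honest for short curves.

**Identifiability.** Over the experimentally accessible window
(λEx ≲ 310 nm) the curve never approaches saturation, so a free CSM_R is
poorly determined: its uncertainty inflates sharply on truncated data (a
property test asserts the inflation) and unconstrained estimates can run
away — estimates at the 1000 nm plausibility ceiling are flagged rather than
silently accepted. The two practical remedies are built in: a global fit
stacking several curves under one shared CSM_R, and fixing CSM_R at a
reference value. Refitting a protein-like curve with CSM_R pinned anywhere
in 387–440 nm changes m smoothly by only a few percent and leaves CSM_FC
essentially unchanged (<0.01 nm). This insensitivity is *conditional on the
curve shape*: for solution-like curves whose midpoint lies near the
accessible window, the extracted CSM_FC does couple to the assumed CSM_R
(drifts approaching 1 nm across the same range), so the fixed-baseline
shortcut should be reserved for protein-type data.

The legacy empirical exponential, CSM = CSM₀ + A·e^(Rc·ΔλEx), is kept for
continuity (`QubesModel`). Near the blue edge the two-state sigmoid is
asymptotically exponential, and the exponential fitted to noiseless sigmoid
data on 292–300 nm leaves residuals well under 0.05 nm RMS; the exponential
simply lacks the saturating baseline, so it cannot extrapolate.

**Comparisons and trends.** `delta_delta_g` differences m between two fits
with errors combined in quadrature (fits assumed independent).
`temperature_trend` regresses m on temperature; with `allow_breakpoint=True`
it also fits a continuous two-segment broken line, searching the breakpoint
over interior observed temperatures by least squares and reporting it only
when an F-test (2 extra parameters; default α = 0.05) prefers it to the
single line — the guard that keeps noise from manufacturing unfolding
onsets. Exact-line data short-circuit to "no breakpoint".

## CD melt fits

Ellipticity at 222 nm is modelled as the population-weighted mix of two
linear baselines under a two-state van't Hoff equilibrium,
Ku = exp(−ΔH(1−T/Tm)/RT), so Ku(Tm) = 1 and the unfolded limb dominates
above Tm. (The sign convention follows the standard unfolding free energy
ΔG = ΔH(1−T/Tm); the opposite sign, which would place unfolding below Tm,
is available as `literal_sign=True` for comparison, as is the variant that
leaves the folded baseline unweighted.) Initialisation takes Tm from the
point of steepest signal change (or above the data range when the unfolded
limb is restrained), ΔH at 300 kJ mol⁻¹, and baselines from linear fits to
the outer thirds. Melts indistinguishable from a straight line raise a
non-identifiability error rather than returning an arbitrary ΔH. For very
stable proteins measured below their transition, `restrain_unfolded_to_zero`
pins the unfolded intercept and slope at zero (in the data's native units)
and the fit may legitimately place Tm above the data range; such results are
flagged as extrapolated.

## The synthetic generator

Each excitation wavelength gets a Siano–Metzler log-normal band (unit-height
peak, FWHM 60 nm, red-skew ratio 1.2 — typical tryptophan emission shape)
whose position is solved by bisection so that the windowed discrete CSM
equals the two-state prediction to ~1e−6 nm; additive Gaussian intensity
noise and replicate structure come from a single seeded generator, and band
amplitude decays exponentially with excitation wavelength (e-folding 25 nm)
to emulate the fall of absorption toward the red edge, with an optional
extra noise inflation beyond 310 nm. Default ground truths: a
solution-like system (CSM_FC 355 nm, CSM_R 398 nm, m 300 J mol⁻¹ nm⁻¹,
midpoint 315 nm, 298.15 K), and a protein-like variant with the midpoint at
335 nm (~2 nm rise across 292–310 nm). The generator reproduces band shape,
the CSM sigmoid, replicate scatter and detector noise; it does not simulate
solvent-relaxation kinetics, scatter/Raman artifacts, instrument spectral
response or wavelength-correlated noise — so passing recovery tests
establish estimator correctness under the stated noise model, not robustness
to every instrumental pathology.

## Validation studies and problem sizes

`reesfit.studies` closes the generator→analyzer loop for every estimator;
the suite and `scripts/acceptance.py` run them at these sizes, chosen to
give stable Monte-Carlo summaries:

- m/CSM_FC recovery: 100 curves (19 points each, σ = 0.1 nm CSM noise,
  CSM_R fixed at truth), repeated at σ ∈ {0.5, 0.1, 0.02} nm to confirm the
  error shrinks with noise.
- Shared-CSM_R coverage: 100 experiments × 5 curves on the extended
  292–340 nm grid (where the shared baseline is identifiable), checking the
  normal-approximation 95% CI against truth.
- Fixed-CSM_R sensitivity: one noiseless protein-like curve, CSM_R pinned
  over 387–440 nm in 2 nm steps.
- Melt recovery: 100 melts (84 points, 1% of signal span noise); truncated
  restrained scenario with Tm ≈ 105 °C against data ending at 95 °C.
- Breakpoint: 100 runs, 13 temperatures (15–75 °C, 5 °C steps), slopes
  −0.1×10⁻³ / −0.25×10⁻³ J mol⁻¹ nm⁻¹ K⁻¹ with ~1% noise.

## Numerical choices and edge cases

- Logistics are evaluated via `scipy.special.expit`; van't Hoff exponents
  are clipped at the float64 limit, so extreme parameters saturate instead
  of overflowing. The empirical exponential raises on overflow rather than
  returning infinity.
- Degenerate spectra (non-positive total intensity) raise, naming the
  offending excitation wavelength; negative post-subtraction intensities
  are kept by default (clipping at zero biases the CSM weighting) with
  clipping available as an explicit option.
- Emission grids are harmonized by exact wavelength match only — mismatches
  are errors, never silent interpolation. Blank subtraction defaults to
  running before windowing (the order is configurable and the two commute,
  which is tested).
- Replicate CSM errors are sample standard deviations (ddof = 1) across
  replicate datasets.
- Temperatures are Celsius at user interfaces and Kelvin internally
  (offset 273.15).

## Known limitations

- The two-state treatment collapses the ladder of partially relaxed
  substates into one effective equilibrium; m is an effective gradient, not
  a microscopic energy gap.
- For multi-tryptophan proteins the curve is an ensemble average over
  residue environments; fixing CSM_R at a pooled value is a pragmatic
  restraint, and the sensitivity analysis above bounds (but does not
  eliminate) its influence on m.
- The normal-approximation CIs inherit the usual nonlinear-regression
  caveats; measured coverage of the shared-baseline CI is ~92–94% at the
  nominal 95%.
- The power planner extrapolates a log-linear excitation spectrum; real
  spectra deviate from log-linearity far from the fit window, and the
  reference power is instrument-specific and must be supplied.
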