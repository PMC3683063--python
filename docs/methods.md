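# Methods

## The model

All competition dynamics come from one consumer-resource closure.  Each
population i (a focal *E. coli* strain or a background species) grows on one
or more substitutable resources r with Monod kinetics and is subject to slow
biomass turnover; consumed resource is converted to biomass through a yield,
and a fraction of turned-over biomass is recycled back into the resource
pools:

    dN_i/dt = [ Σ_r μ_max,ir · s_r/(K_ir + s_r) − d_i ] · N_i
    ds_r/dt = − Σ_i μ_ir(s_r) · N_i / Y_ir  +  ρ · Σ_i d_i · N_i · w_ir

- N_i — biomass density (g/L); s_r — resource concentration (g/L).
- μ_max (1/h), K_s (g/L) — Monod parameters per population and resource.
- Y (g biomass / g resource) — yield closing the mass balance; with d = 0
  and ρ = 0 the quantity s + Σ N_i/Y_i is exactly conserved on one resource
  (verified to ≤1e-6 relative drift in the tests).
- d (1/h) — slow stationary-phase biomass turnover; ρ ∈ [0,1) — the fraction
  of turned-over biomass returned to the resource pools with composition
  weights w (default: uniform over the resources the population consumes).

The turnover-plus-recycling term is the mechanism behind every "late"
phenomenon in the package: after a batch exhausts its pool, the system
settles at a low quasi-steady concentration s_q (where recycled supply
balances uptake) at which the low-K_s gleaner out-grows the high-μ_max
exploiter.  It encodes the interpretation that the stationary-phase reversal
reflects a changed nutrient environment rather than differential death: both
focal strains share one d, and what differs is only their Monod response to
the resulting low-resource regime.

Serial transfer multiplies all densities by the dilution factor and resets
resources to the fresh-medium recipe at each transfer (integration is
stop-restart at the discontinuity, never interpolation across it).
Integration uses LSODA with rtol 1e-8 / atol 1e-10; reported state is
clipped at zero (undershoot is at solver-tolerance scale).  A deliberately
independent fixed-step forward-Euler integrator (dt = 1e-3 h) is kept in the
package as a validation reference; adaptive and Euler solutions agree within
0.5% on all shipped scenarios.

Simulated compositions are exact; the ~5% detection limit of the trace-based
abundance measurements enters only as reporting flags, never as censoring of
simulator state.

## Calibrated study conditions

The focal pair is gleaner EDM106 versus exploiter EDM530 on a single
"peptone" pool (the resource on which the strains demonstrably trade off);
EDM116 appears in the isocline analysis.  Parameters:

| quantity | value | basis |
|---|---|---|
| μ_max EDM106 / EDM116 / EDM530 | 0.736 / 0.816 / 0.848 /h | ln2 ÷ measured anaerobic doubling times (56.50 / 50.97 / 49.03 min) |
| K_s EDM106 / EDM116 / EDM530 | 0.3 / 0.55 / 1.0 g/L | illustrative; only the ordering (gleaner lowest) is measured |
| crossover s\* (106 vs 530) | ≈4.3 g/L | implied; sits between the 10% and 100% peptone pools |
| rich-medium peptone pool | 15 g/L | typical peptone content of a rich anaerobe broth |
| yield Y | 0.3 g/g | typical biomass yield on complex substrate |
| turnover d (strains) | 0.01 /h | slow stationary-phase turnover (~3-day half-life) |
| recycling ρ | 0.5 | half of turned-over biomass re-enters the pool |
| transfer dilution | 1:100 | common serial-batch convention; configurable |
| inoculum | 0.005 g/L per strain | ~1:100 of a saturated culture |

The joint choice of (K_s gap, d, ρ) is a genuine calibration: the gleaner's
starvation-phase advantage scales with ρ·d·Y while the exploiter's
growth-phase advantage is set by the μ_max gap and the dilution factor, and
only a window of that balance reproduces the full observed pattern —
exclusion of the gleaner at *every* renewal period from 0.5 to 4 days (with
strictly more transfers needed at longer periods) *and* reversal in a fully
un-renewed 16-day culture.  Outside the window the model produces either
stable coexistence at long periods (starvation term too strong) or no
stationary reversal (too weak).  The calibration targets these qualitative
direction laws; no quantitative outcome is fitted.

Background species (single-resource stand-ins):

- *C. perfringens*: μ_max 2.0 /h, K_s 2.0 g/L, Y 0.3, d 0.1 /h.  A
  live-fast/die-fast proteolytic depleter — among the fastest-growing
  bacteria known — whose rapid turnover keeps recycled peptone trickling
  into the pool.  Its dominance therefore both shortens the high-resource
  window and raises the post-depletion quasi-steady concentration, the
  combination that flips the strain competition to the gleaner.  Its higher
  K_s also leaves residual peptone unscavenged late, matching its observed
  usage profile.
- *B. thetaiotaomicron* / *B. longum*: μ_max 0.30 / 0.25 /h, K_s 5.0 / 4.0
  g/L, high yields.  Weak competitors on this resource; they never dominate
  and never flip the pair — the negative control.

Glucose scenarios give both strains near-identical glucose kinetics (0.84 vs
0.85 /h at K_s 0.5 g/L): the exploiter keeps a uniform slight edge, so no
concentration of glucose reverses the outcome — localising the context
dependence to the trade-off resource.

## Doubling times from OD curves

Plate-reader curves are processed as: subtract the optical background
(minimum of the first three readings); restrict to the mid-log band (10–75%
of the post-subtraction maximum); fit log(OD) by least squares on every
window of ≥5 consecutive points; accept windows with positive slope and
R² ≥ 0.99 and return the **longest** (ties → higher R²), reporting doubling
time ln2/slope in minutes with the window bounds and R².  The band keeps the
fit away from the background-dominated start — where subtraction makes the
log curve artificially steep — and from the plateau; preferring the longest
window over the steepest avoids the upward selection bias that noisy short
windows would otherwise introduce.  The estimate is exactly invariant to
uniform OD scaling and to adding a constant background.  Replicates are
aggregated as mean ± standard error.

## Monod fitting

Nonlinear least squares of μ(s) = μ_max·s/(K_s+s) (trust-region reflective,
parameters bounded positive), initialised at μ_max⁰ = max observed rate and
K_s⁰ = the concentration whose rate is nearest μ_max⁰/2, with five random
multiplicative restarts on failure.  Saturated designs (rate spread ≤0.1% of
the mean, or K_s standard error >10× the estimate) are flagged
`ks_unidentifiable` rather than rejected.  At the reference design (five
concentrations spanning K_s to ~5K_s, triplicate, 1% noise) the median
worst-parameter relative error over 50 seeds is ~1%, well inside the 10%
contract.

## Isocline analysis

With co-culture equilibrium (N1\*, N2\*) = (p1·K_co, (1−p1)·K_co), the zero
isoclines N1\*+α₁₂N2\* = K1 and N2\*+α₂₁N1\* = K2 give the competition
coefficients in closed form.  Classification is by mutual invasibility
(α₁₂ ≶ K1/K2, α₂₁ ≶ K2/K1); boundary equality raises a degeneracy error, as
does α₁₂α₂₁ = 1 (parallel isoclines) for the equilibrium solve.  Negative
solved coefficients (possible when the co-culture over-yields strongly) are
returned with a facilitation warning, not clipped.  p1 is an input — the
observed proportion is approximate — defaulting to 0.55 only in the shipped
worked configuration.  Capacities stay in measured units (g dry weight per
30 ml); classification is invariant to their common scale and to the
intrinsic rates r1, r2.

## Trace unmixing

Unit-spectrum columns are scaled to unit sum (coefficients then read as
signal fractions); the mixed trace is regressed on them by non-negative
least squares and the coefficients renormalised to sum to one.  When no
non-negativity constraint is active the solution is taken directly from the
ordinary least-squares solve, so noiseless mixtures are recovered to
floating precision.  R² and the overall F-test p-value of the unconstrained
multiple regression (no intercept) are reported as diagnostics either way;
an unconstrained variant is available behind a flag.  Unit spectra with
condition number >1e6 raise an unidentifiability error.  Components under
the 5% detection limit are flagged, never zeroed.  Traces are assumed
baseline-corrected; a rolling-minimum baseline subtraction is provided but
off by default.  Chromatogram physics (dye crosstalk, mobility shifts) and
`.ab1` parsing are out of scope — the contract is aligned intensity vectors.

## Statistics

Two-sample t-tests are computed from printed (mean, s.e., n) summaries:
Welch (Satterthwaite df) by default, pooled as an option, one- or two-sided;
the headline generation-time contrasts are significant at 1% under every
variant combination.  The Mann-Whitney U test is exact: all C(n_a+n_b, n_a)
assignments of the pooled mid-ranks are enumerated (ties handled exactly),
capped at n_a+n_b ≤ 25, with a flagged normal approximation beyond.
p-values come from scipy's t and F distributions.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`) and byte-reproducible;
each returns its ground truth alongside the data.  Defaults: OD noise 1%
multiplicative lognormal on the biological signal (blank 0.05, inoculum
signal 0.001, plateau 1.2, 12 h at 10-min readings — a realistic
plate-reader geometry); rate noise 1% lognormal; trace noise 1% of maximum
intensity additive Gaussian on sums of strain-specific Gaussian peak sets;
composition sampling by multinomial at depth 200.  What they do *not*
emulate: lag phases, diauxie, plate effects, chromatogram alignment error,
or overdispersed counting noise — so passing recovery tests demonstrate
correctness of the inference layers under the stated noise models, not
robustness to every artefact of real instruments.

## Known limitations

- Single-pool peptone: the real substrate is a mixture of peptides of
  varying accessibility.  One consequence is accepted and documented: in
  monoculture depletion assays the simulated gleaner's residual crosses
  below the exploiter's soon after depletion (~15–20 h), so the package
  asserts the exploiter's faster early draw-down at 6–12 h and the gleaner's
  deeper scavenging at 48 h, but cannot place the crossing between 24 h and
  48 h as a two-pool (labile/refractory) model could.
- In the background-community scenario the fast species reaches dominance
  within the first few transfers (a 1e-6 g/L inoculum is amplified in one
  long first growth window), earlier than the ~10-day onset seen in the
  motivating system; the flip, not its onset time, is the modelled claim.
- No oxygen, pH, toxic-byproduct, cross-feeding or spatial state; the
  microaerophilic condition is representable only as suppressed background
  growth rates, and the EDM106/EDM116 over-yielding is analysed through the
  Lotka-Volterra layer, not mechanistically.
- Strain K_s values (and hence s\* ≈ 4.3 g/L) are illustrative calibrations;
  conclusions that depend only on their ordering are the supported ones.
- Deterministic ODEs: no demographic stochasticity, so "exclusion" is the
  detection-limit crossing of a continuous trajectory, not true extinction.
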