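# Methods

This note documents the models, conventions and numerical choices behind
`nmrbind`, and what the synthetic-data tests do and do not demonstrate.

## Units and numbering

Concentrations are µM, rates s⁻¹, shifts ppm, heats µcal, enthalpies
kcal/mol (1 kcal = 10⁹ µcal).  Residue numbering is 1-based on the
full-length protein; every construct carries `first_residue_number`
explicitly, so segment-local tables are placed on the full-length axis by
declaration, never by guessing.

## 1:1 binding model

For A + B ⇌ AB with dissociation constant K_D, the complex concentration is
the smaller root of the binding quadratic, evaluated in the
multiply-by-conjugate form 2ab/(s+√(s²−4ab)) (s = a+b+K_D) to avoid
catastrophic cancellation when K_D ≪ the concentrations.  Derivations used
throughout:

* bound fraction of A: p_B = [AB]/[A]_tot;
* K_D from a measured p_B: K_D = [A]free·[B]free/[AB] with [AB] = p_B·a;
* kinetic split of an exchange rate: k_off = (1−p_B)·k_ex,
  k_on = p_B·k_ex/[B]free, which reproduces K_D = k_off/k_on exactly.

## Residue-wise K_D from R₁ρ (fast exchange, weak binding)

In fast exchange the observed R₁ρ is the population-weighted average of the
free- and bound-state rates.  Under weak binding ([B]free ≈ [B]tot) the
bound fraction is approximated by [B]/(K_D+[A]), making R₁ρ linear in the
partner concentration.  The per-residue fit is an inverse-variance weighted
straight line of R₁ρ against [B]tot; with the bound-state rate R₁ρᴮ
measured on the partner, K_D = (R₁ρᴮ − intercept)/slope − [A]tot.

Conventions and caveats:

* R₁ρ is the fitted mono-exponential decay rate (two parameters, I₀ and R)
  without R₁/tilt-angle correction — appropriate when R₁ changes little
  through the titration under a strong (1.5 kHz) spin lock.
* Decay-rate errors are Monte-Carlo: the intensities are resampled from
  their stated Gaussian errors (default 500 draws, seeded) and refit; the
  rate error is the standard deviation of the refits.  K_D intervals are
  2.5/97.5 % Monte-Carlo percentiles because the (r_bound−i)/s − a transform
  is nonlinear and the resulting distribution skewed.
* Fits are declared `no_binding` when |slope| does not exceed its standard
  error, and `invalid` when the slope is negative or the intercept reaches
  R₁ρᴮ.
* Validity of the weak-binding linearisation: its bound-fraction relative
  error is exactly ([B]−[AB])/(K_D+[A]), hence bounded by [B]/(K_D+[A]).
  It is below 5 % only for partner admixtures up to roughly 4–5 % of
  K_D+[A]tot; at [B] = 0.1·(K_D+[A]) it reaches ≈ 9–10 % whenever the
  complex is small against [B].  Separately, when binding is tight
  (K_D ≪ [A]tot) the titration response is no longer linear in [B] at all
  and the slope-derived K_D is biased — this, not the pointwise
  bound-fraction error, is the failure mode that matters in practice, and
  the suite demonstrates it with an exact-model generator.

## Constant-time CPMG relaxation dispersion

R₂ᵉᶠᶠ = −ln(I/I₀)/T with T the constant relaxation time (32 ms default).
The refocusing grid obeys the integer-cycle rule n = round(ν·T) ≥ 1, so the
14-point default grid spans 31.25 Hz (1 cycle) to 1000 Hz (32 cycles); a
nominal 31.35 Hz request maps onto the same single-cycle point.

Two-state exchange A ⇌ B (k_AB = p_B·k_ex, k_BA = p_A·k_ex) with a ¹⁵N
shift difference Δω = 2π · field · (γN/γH) · δ(ppm), γN/γH = 0.101329.

Two forward models:

* `simulate_bm` — the numerical oracle: the transverse magnetization vector
  is propagated through every (τ–180°–2τ–180°–τ) cycle explicitly, with
  ideal instantaneous 180° pulses modeled as complex conjugation, starting
  from population-weighted magnetization and detecting the magnitude of the
  total transverse magnetization.  Because conjugation is an antilinear
  involution, one cycle is the linear operator E(τ)·conj(E(2τ))·E(τ); 2×2
  matrix exponentials are evaluated analytically through exp(m±q) so that
  very fast exchange cannot overflow.
* `simulate_cr` — the fit kernel: an exact closed form of the same cycle
  propagator.  Its eigenvalues come from the quadratic formula (the
  determinant is exp(−(R₂ᴬ+R₂ᴮ+k_ex)/ν) in closed form) and the initial
  magnetization is decomposed onto the eigenmodes, so the detected signal is
  c₊λ₊ⁿ + c₋λ₋ⁿ.  Retaining the mode amplitudes c± is essential: the
  classic rate-only Carver–Richards expression (kept as
  `carver_richards_rate`) drops them and deviates by up to several s⁻¹ from
  any explicit propagation when the minor population is large and exchange
  slow, while the exact form tracks the oracle to numerical precision
  (< 10⁻¹¹ s⁻¹ over the validated grid: k_ex ∈ [100, 3000] s⁻¹,
  p_B ∈ [0.01, 0.2], Δω ∈ [0.5, 4] ppm, 600/850 MHz, all 14 frequencies).
  In the fast-exchange regime the rate-only expression is excellent and
  underlies the R_ex = p_A·p_B·Δω²/k_ex identity, which the exact model
  reproduces within 5 % (within ~2 % at a genuinely refocusing-free
  frequency; at 31.25 Hz the Luz–Meiboom finite-spacing factor
  2·tanh(k_ex·τ/2)/(k_ex·τ) already costs ~6 % at k_ex = 10·Δω).

Known limitation: pulses are ideal (no finite width, no off-resonance
effects); Δω is constrained non-negative because its sign is not
identifiable from CPMG data alone.

### Global fit

Weighted least squares over all residues and fields, minimising
Σ((data−model)/σ)² with shared (k_ex, p_B), per-residue |Δω| in ppm
(field-independent), and one baseline R₂⁰ per residue per field.  Point
errors are floored at 0.5 s⁻¹ before fitting.  Initialization is a 5×4
multi-start grid over k_ex ∈ {100, 300, 600, 1000, 2000} s⁻¹ ×
p_B ∈ {0.02, 0.05, 0.1, 0.2}: each start is screened with a
bounded-iteration trust-region fit (Δω and R₂⁰ seeded from the observed
dispersion amplitudes and high-frequency plateaus), the best two starts are
polished to convergence, and ties are broken toward smaller k_ex.
Uncertainties come from the covariance at the optimum scaled by the reduced
χ²; optional seeded Monte-Carlo resampling replaces the (k_ex, p_B) errors
when requested.  A single residue at a single field is fit but flagged
degenerate (k_ex/p_B/Δω are not separable there); p_B pinned at a bound is
flagged.  Concentrations enter only after the fit, through the 1:1
derivation of K_D, k_on and k_off from p_B.

Dispersion detection uses the amplitude statistic ΔR₂ = R₂ᵉᶠᶠ(31.35 Hz) −
R₂ᵉᶠᶠ(1000 Hz) (nearest grid points within 25 % of the requested
frequencies; the error is the sum of the two point errors), flagging a
residue when ΔR₂ > 3× that error.

## ITC

Perfect-mixing displaced-volume model: injection i of volume v dilutes the
cell contents by (1−v/V₀) and adds syringe titrant at c_syr·v/V₀; the heat
is ΔH·V₀·([AB]ᵢ − [AB]ᵢ₋₁·(1−v/V₀)) + offset, with [AB] from the exact
quadratic using n·[cell] as the binding-site concentration.  The fit runs
in log K_D with three K_D starts around the cell concentration; the first
injection is excluded by default (standard practice for the
diffusion-contaminated first aliquot); a Wiseman c = n·[cell]/K_D outside
[1, 1000] triggers a poorly-determined-K_D warning.  The displaced-volume
bookkeeping means total heat equals ΔH × limiting moles only in the
small-displacement limit; at 19×2 µL into 200 µL the difference is a few
percent, which is physical, not an error.

## Secondary shifts and propensities

SCS = observed − random coil (positive Cα SCS ⇒ helix).  The random-coil
and fully-formed helix/strand deviation tables are bundled, documented
resources (see `src/nmrbind/data/PROVENANCE.md`) and can be replaced by the
user.  The propensity estimator projects each windowed Cα/Cβ SCS onto its
reference deviation with |reference|-weighted averaging and sign-dependent
normalisation (helix-ward components divide by the helix reference,
strand-ward by the strand reference), so a window exactly at the helix
reference scores +1, at the strand reference −1, linear in amplitude in
between, and the sign always equals the sign of the window-mean
(ΔδCα − ΔδCβ).  Defaults: window 5, Cα/Cβ only (CO can be enabled); both
are configuration-exposed because neither is dictated by the underlying
observables.  Glycine contributes no Cβ; propensities are undefined (absent)
where a window holds no carbon data.

## Chemical-shift perturbations

The combined CSP multiplies the ¹H difference by 6.5 before quadrature with
the ¹⁵N difference.  This convention up-weights the proton axis relative to
the more common down-weighting of nitrogen; it is a uniform rescaling, so
per-residue patterns and relative comparisons are unchanged.  Disappeared
peaks are encoded as intensity ratio 0 with a flag (so broadening maps onto
profiles) and are omitted from CSP profiles.  Default nearest-neighbour
matching tolerances: 0.05 ppm (¹H), 0.5 ppm (¹⁵N); a titrated peak claimed
by two reference peaks, or two candidates within one ellipse, is flagged
ambiguous and excluded.

## Motifs and interaction windows

Patterns: D-L-[LF] (clathrin box, one class covering DLL and DLF), D-P-F
and F-x-D-x-F (adaptor appendage).  Overlapping hits are all reported; the
degenerate D-[LI]-[LF] variant is behind an opt-in flag.  Interaction
windows are 21 residues, centred on the hydrophobic residue
({L,F,I,V,M,W,Y}; alanine excluded as a flanking rather than anchoring
residue) with the highest rate increase inside each contiguous region
exceeding the prominence threshold (default 2 s⁻¹ above baseline, exposed
in configuration since no principled value exists), gap-padded at termini,
ranked by central rate with ties broken by position.  The
position-frequency matrix counts letters per window position, excluding
gaps.

## Synthetic data

Generators emulate: per-residue shift tables with planted transient helices
(shifts = coil + population × helix deviation + noise), titration R₁ρ
profiles from a per-residue K_D map under either the weak-binding linear
relation or the exact quadratic, 7-delay exponential decay series,
two-state CPMG dispersion at two fields via the Bloch–McConnell oracle, and
1:1 ITC thermograms.  Default conditions are the study design (100 µM
observed protein; 0/50/100/150 % admixtures; 1500 Hz spin lock with delays
10–230 ms; 600/850 MHz, 32 ms, 14 frequencies, 0.5 s⁻¹ error floor; 30 µM
cell / 300 µM syringe / 19×2 µL — cell volume 200 µL and injection count
are generator conventions).  Default noise: 2 % relative on rates, 0.5 s⁻¹
absolute on R₂ᵉᶠᶠ, 1 % of the largest heat on ITC.  The background
amino-acid composition is a fixed disorder-promoting convention (G/S/A/P/D/E
enriched).  Identical (config, seed) reproduce byte-identical outputs, and
every generator records its ground truth separately from the observables.

What passing recovery tests show: the estimators invert their own forward
models at realistic noise and design.  What they do not show: robustness to
peak overlap, assignment errors, baseline drift, off-resonance effects,
temperature/pH shift dependences, or model misspecification (three-state
exchange, cooperative binding) — real-data features the generators do not
emulate.

## Problem sizes used in the distributed checks

The acceptance script runs the global CPMG recovery as medians over 5
seeded replicates of the full 22-residue × 2-field design, the residue-wise
K_D recovery over 50 replicates per ground truth, and the ITC recovery over
30 replicates; the test suite runs the CPMG recovery over 20 replicates.
These sizes give stable medians for the recovery statements above.
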