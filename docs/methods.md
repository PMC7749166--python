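# Methods

This note documents the models the package implements, the numerical choices
made where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Physical models

**Thermal energy and units.** Forces in pN, lengths in nm, energies
internally in pN·nm and reported in kcal/mol (1 kcal/mol = 6.9477 pN·nm per
molecule). The default temperature is 297.15 K (room temperature, ≈24 °C,
the condition of the experiments this pipeline models); k_B T = 4.103 pN·nm
= 0.5905 kcal/mol. All constants are echoed into result records for
provenance.

**WLC tether.** The PEG linker is modelled with the standard worm-like-chain
interpolation formula F(x) = (k_BT/L_p)[1/(4(1−x/L_c)²) − 1/4 + x/L_c],
the universal convention for AFM tether fitting. It is accurate to a few
percent against the exact solution, which is irrelevant here because L_p and
L_c are free fit parameters per event. Defaults: L_p = 0.38 nm, L_c = 10 nm
(an extended PEG linker of ~10 nm).

**Bond kinetics.** Unbinding follows Bell kinetics,
k_off(F) = k_off(F_eq)·exp((F−F_eq)/f_β) with f_β = k_BT/x_t. Rebinding uses
the detailed-balance construction against the harmonic probe potential,
k_on(F) = k_off(F_eq)·exp((F_eq²−F²)/(2 k_eff k_BT)), which makes the two
rates balance exactly at F_eq — the equilibrium condition underlying the
FNdY picture. The mean rupture force of this two-state process under a
force ramp is what the FNdY interpolation
⟨F⟩(r) = F_eq + f_β ln(1 + e^(−γ) r/r₀), r₀ = k_off(F_eq)·f_β approximates;
the package's central validity check (test suite and acceptance script)
verifies simulator and closed form agree within ~1 pN over three decades of
loading rate.

**Thermodynamic conversions.** ΔG_bu = −F_eq²/(2 k_eff) (negative =
favourable; pulling forces positive); K_d from
ΔG_bu = k_BT ln(0.018 K_d), with 0.018 l/mol the partial molar volume of
water setting the reference concentration; τ_0.5 = ln2/k_off(F_eq), the
half-life of an exponential bound-state dwell at the equilibrium force —
the most literal reading of a receptor–ligand residence half-life.
Uncertainties are first-order propagations: σ(ΔG) = 2|ΔG|σ_F/F_eq,
σ(K_d) = K_d·σ(ΔG)/k_BT, σ(τ) = τ·σ_k/k.

**k_eff.** The effective probe stiffness (series stiffness of cantilever and
tether at rupture) links F_eq to ΔG_bu but does not appear in the
mean-force-vs-loading-rate curve, so it cannot be fitted from a DFS cloud.
It is a per-experiment configuration quantity (default 13.1 pN/nm, the value
consistent with the published (50 pN, −13.7 kcal/mol) pair); when events
carry their retract velocities, `estimate_k_eff` recovers it as the median
loading-rate/velocity ratio.

## Curve processing

Per retract segment: a line is fitted to the far tail (last 25% by distance
— beyond the 10±5 nm specific window plus margin) and removed; the noise SD
is the tail residual SD. Event detection runs on a boxcar-smoothed force
signal (window ≈ 2.5% of the record, 5–25 samples): on raw white noise the
minimum of ~10³ samples is ≈ −3σ, so only a smoothed, sustained dip is a
meaningful detection statistic. The rupture index is refined with a
matched-filter step localizer (difference of m-sample means before/after),
which is robust where a single-sample difference is not, and the adhesion
force is read from a quadratic fit of the raw force ending at the rupture —
unbiased under noise and near-exact on noiseless records, where a straight
line systematically underestimates the convex tether load. Detection
requires the smoothed dip to reach 80% of the force threshold (the boxcar
clips a genuine peak by the rise over ~half a window) and the refined F_adh
to reach the full threshold max(2·noise SD, 25 pN).

The loading rate is the slope of the force–time curve at the rupture index
from a quadratic fit over the larger of 10 samples and the last 2 nm of
extension, widening ×2/×4 if the noisy endpoint derivative comes out
non-positive. WLC validation fits L_p, L_c over the adhesion region with
L_c bounded to ≤ 3·d_rup — the likelihood is nearly flat in L_c under noise,
and a tether-mediated event must detach in the nonlinear stretch regime —
and declares the fit valid when the rms residual is ≤ max(2σ, 1 pN) and
d_rup/L_c ≥ 1/3 (a Hookean profile is mimicked by a WLC stretched to only
~1/5 of its contour, so residuals alone cannot reject it). An event is
**specific** iff 5 ≤ d_rup ≤ 15 nm (inclusive), F_adh ≥ max(2σ, 25 pN), the
WLC fit is valid and the loading rate positive. One event per curve (the
deepest qualifying minimum). These detector internals were calibrated on
synthetic validation batches at 10–15 pN noise: recall of planted specific
events 96.5–98.2% and false-positive rate ≤ 0.5% across independent seeds.

## DFS inference

The FNdY mean-force curve is fitted to per-event (loading rate, force)
points by unweighted Levenberg–Marquardt least squares (no binning; a
binned-means mode exists for comparison). Initialization is deterministic:
F_eq from the 5th force percentile, f_β from the semi-log slope over the
upper loading-rate decade, k_off = 10³ s⁻¹; all parameters bounded positive.
Parameter s.e.m. come from the covariance at the optimum. Confidence bands
use the delta method with analytic gradients; prediction bands add the
residual variance, and their 99% empirical coverage is verified against
fresh simulated data. A loading-rate span under two decades triggers a
warning (f_β and k_off are then poorly identified). The cooperativity ledger
computes ΔΔG = ΔG_full − ΣΔG_parts with quadrature-propagated errors and
calls the interaction positive/none/negative by comparing |ΔΔG| with its
propagated error.

## Topography

Maps are plane-flattened and referenced to the bilayer as the mode of the
height histogram (0.05 nm bins; a second plane fit restricted to
near-bilayer pixels removes the tilt bias particles introduce); referencing
fails loudly when no level holds ≥50% of pixels. Particles are local maxima
above a prominence threshold with a minimum separation. Height is the
sub-pixel apex from a log-paraboloid (Gaussian-exact) interpolation minus
the local background (median of the analysis-window border); the diameter is
the FWHM of the radially averaged profile about the apex (a single-section
mode is provided for parity with line-profile practice). Population modes
are Gaussian mixtures (EM, k-means initialization, fixed seed, tolerance
1e-8), components sorted by mean. Orientation: protrusion height < 1.75 nm
→ extracellular face up; ≥ 1.75 nm → intracellular face up (the boundary is
assigned to the upper class by convention — arbitrary but fixed).

With the two height populations (1.1 ± 0.5 and 2.8 ± 1.2 nm) treated as
population SDs, the overlap of the two Gaussians caps any threshold
classifier at ≈86% accuracy (the 1.75 nm threshold is essentially optimal —
the best achievable is ≈86% at 1.87 nm). Orientation calls on *individual*
particles from the overlapping mixture are therefore intrinsically
uncertain; high-confidence identification requires the separated populations
that orientation-specific probes actually select.

The multiplex overlay assigns each probe-specific adhesion event to the
nearest particle within that particle's FWHM (as a radius) and reports the
concordance between the probe chemistry and the height-based orientation
call; events with no particle in range are tallied unassigned.

## Umbrella sampling and WHAM

The all-atom pulling system is replaced by a 1-D overdamped Langevin
particle (Euler–Maruyama, stability check dt·k_total/friction < 0.1) on
analytic model potentials with known extrema; the default dissociation
profile is a double well built from two Gaussians (bound well −1.38
kcal/mol, barrier 2.15 kcal/mol — the published all-atom values scaled by
1/10 so that desk-scale sampling crosses all barriers). 36 windows span the
coordinate at 0.1 nm spacing. The bias constant defaults to 59 kcal/mol/nm²,
chosen so the biased fluctuation √(k_BT/k_w) ≈ 0.1 nm equals the window
spacing: with the all-atom constant (1000 kJ/mol/nm² ≈ 239 kcal/mol/nm²,
exported as `PAPER_PARITY_BIAS_K`) the adjacent-histogram overlap is so thin
at desk-scale sample counts that the window-to-window free-energy random
walk alone is ~0.25 kcal/mol rms. At the defaults (30k samples/window,
thinning 20) the recovered well depth is within ~0.1 kcal/mol of truth.

WHAM is the standard self-consistent iteration of the unbiased density and
per-window free energies (200 uniform bins, tolerance 1e-6 kcal/mol,
iteration cap 1e5, residual trace exposed); adjacent windows must share
occupied bins or the solver raises a gap error naming them. Errors come from
a block bootstrap (block length = the window's integrated autocorrelation
time), warm-started from the baseline window free energies; each resampled
profile is min-zeroed and the per-bin SD taken across resamples. ΔG_bu is
read as G(well) − G(plateau) with the plateau the mean over the last 10% of
the coordinate; the barrier is the maximum between well and plateau
(equal to the well depth when the profile rises monotonically); profiles
with no minimum at least 0.25 kcal/mol below the plateau raise a
no-bound-state error.

## Synthetic data: what it emulates, what it does not

The generator reproduces: force-volume linear ramps (1 µm/s approach,
0.5–2 µm/s retract, 150 nm ramp) and sinusoidal drives (250 Hz, 100 nm
peak-to-peak); quasi-static series mechanics of a WLC tether and a
cantilever spring (default 100 pN/nm); two-state Gillespie bond kinetics
with the detailed-balance rebinding rate above; Gaussian force noise
(10–15 pN regime); sparse binding (probability 0.2 per contact, emulating
sparse specific events in adhesion maps); and bilayer height maps with
Gaussian-bump particles drawn from the measured height (1.1 ± 0.5 /
2.8 ± 1.2 nm) and diameter (8.6 ± 0.4 / 14.1 ± 0.3 / 23.4 ± 1.2 nm)
populations on a correlated-roughness background. Loading-rate ground truth
is d F/dt of the noiseless signal just before rupture, mirroring the
measurement definition.

Not emulated: cantilever ringing and hydrodynamic drag, deflection dynamics
of the oscillating lever (the force signal is quasi-static), scanner drift
and line noise, tip-shape convolution of particle profiles, multivalent or
multiple-tether events. Passing tests therefore demonstrate correctness of
the analysis under the stated stochastic model of the instrument, not
robustness to instrument artifacts beyond it.

Problem sizes in the test suite and acceptance script (10⁴ Gillespie
replicates per loading rate; 100 synthetic DFS datasets of 500 events; 400
curves per classifier arm; 4000 mixture draws; 36×30k umbrella samples with
200 bootstrap resamples) were chosen so that Monte-Carlo error is small
against each tolerance while the whole acceptance run completes in well
under a minute of compute per stage.

## Degenerate inputs and tie-breaks

Monotone z-records raise a malformed-curve error; a too-short baseline tail
raises an insufficient-baseline error; absence of a rupture event is a valid
result (status `none`), not an error. All-equal mixture input returns the
common value with an SD at the regularization floor. Orientation threshold
ties go to the intracellular class. Fit non-convergence raises an error
carrying the last iterate. Every generator is bit-reproducible given (seed,
config), and pipeline reports are byte-identical across runs with the same
config and seed (timestamps live only in the run manifest).

## Known limitations

* The FNdY mean-force form assumes a single barrier and ν = 1; multi-barrier
  (Dudko–Hummer–Szabo) kinetics, freely-jointed-chain or extensible-WLC
  tethers are out of scope.
* k_eff is configuration, not inference (see above); reported ΔG_bu inherits
  its uncertainty only through F_eq unless a k_eff error is supplied.
* The Langevin/WHAM stage is a methodological stand-in at 1/10 energy scale;
  it validates the estimator chain, not any all-atom free energy.
* Measured loading rates on noisy curves carry ~30–50% scatter (endpoint
  derivatives are intrinsically noisy); this enters the DFS fit only through
  ln r and is absorbed by the per-event scatter.
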