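# forcespec

Single-molecule force spectroscopy analysis for FD-based AFM experiments on
membrane receptors: from raw force–distance cycles to binding thermodynamics
and kinetics, receptor-orientation calls from topography, a two-site
cooperativity ledger, and a desk-scale umbrella-sampling/WHAM free-energy
stage.

## The problem

In dynamic force spectroscopy (DFS) a ligand tethered to an AFM tip through a
PEG linker is repeatedly pulled off its receptor while the pulling speed — and
with it the loading rate *r* = dF/dt — is varied over several decades. Each
approach/retract cycle yields a force–distance curve; specific unbinding
events are identified, their rupture force and loading rate measured, and the
(r, F) cloud fitted with the Friddle–Noy–de Yoreo (FNdY) model of the mean
rupture force:

    ⟨F⟩(r) = F_eq + f_β · ln(1 + e^(−γ) · r / r₀),     r₀ = k_off(F_eq) · f_β

where F_eq is the equilibrium force at which unbinding and rebinding balance,
f_β = k_B T / x_t the thermal force scale, k_off(F_eq) the unbinding rate at
F_eq, and γ the Euler–Mascheroni constant. The fit gives direct access to the
binding free energy, dissociation constant and bond half-life:

    ΔG_bu = −F_eq² / (2 k_eff)
    ΔG_bu = k_B T · ln(0.018 · K_d)       (0.018 l/mol: partial molar volume of water)
    τ_0.5 = ln 2 / k_off(F_eq)

Membrane receptors reconstituted in a bilayer adsorb in both orientations;
the protrusion height measured by AFM topography (two populations, ~1.1 and
~2.8 nm, threshold 1.75 nm) calls which face points up, so force measurements
can be gated to natively oriented receptors. Comparing the full-ligand ΔG_bu
with the sum of the individually measured binding-site energies quantifies
inter-site cooperativity. A 1-D overdamped-Langevin umbrella-sampling stage
with a from-scratch WHAM solver reproduces the free-energy-profile workflow
(well depth, barrier height, bootstrap errors) at desk scale.

Because raw instrument data for this kind of experiment are rarely public,
the package ships a synthetic-data module that emulates the instrument — WLC
tether + cantilever mechanics, two-state Gillespie bond kinetics under
linear-ramp and sinusoidal drives, 10–15 pN force noise, bilayer height maps
with known particle populations — with ground truth recorded for every
artifact, so every pipeline stage is verifiable.

## Worked example

```python
import forcespec as fs

# 1. simulate a DFS condition at known truth and fit it
truth = fs.BondTruth()      # F_eq=50 pN, f_beta=10 pN, k_off=1e3/s, k_eff=13.1 pN/nm
ds, _ = fs.gen_dfs_dataset(500, truth, lr_range=(1e2, 1e6), scatter_sd=10.0, seed=1)
fit = fs.fit_fndy(ds)
thermo = fs.derive_thermo(fit)
print(f"F_eq = {fit.model.F_eq:.1f} ± {fit.sems['F_eq']:.1f} pN")
print(f"dG_bu = {thermo.deltaG_bu:.1f} ± {thermo.deltaG_sem:.1f} kcal/mol")
print(f"Kd = {thermo.Kd*1e9:.1f} nM, tau_0.5 = {thermo.tau_half*1e3:.2f} ms")
```

prints

```
F_eq = 48.5 ± 0.8 pN
dG_bu = -12.9 ± 0.4 kcal/mol
Kd = 16.8 nM, tau_0.5 = 0.78 ms
```

— the fitted equilibrium force sits within 2σ of the generating 50 pN, the
free energy −12.9 ± 0.4 kcal/mol is close to the true −13.7 (quadratic in
F_eq, so the 3% force error doubles), and the nanomolar K_d and
sub-millisecond residence half-life follow from the conversion relations
above (K_d is exponentially sensitive to ΔG: one noisy dataset of 500 events
pins it to the right order of magnitude, and the CI-coverage study in the
acceptance checks shows the quoted uncertainties are calibrated).

The same flow from the shell, including full curve-level processing:

```bash
forcespec simulate-fd --out curves/ --n 200 --seed 1     # FD cycles + truth
forcespec process --curves curves/ --out events.csv      # rupture events
forcespec simulate-map --out map.csv --seed 2            # bilayer height map
forcespec topo --map map.csv --out particles.csv         # heights/FWHM/orientation
forcespec dfs-fit --config condition.yaml --seed 1 --out run/
forcespec compare run1/report_full.json run2/report_siteA.json \
    run3/report_siteB.json --full full --parts siteA,siteB
forcespec wham --out pmf/ --seed 3                       # toy umbrella + WHAM
```

## Layout

| module | contents |
|---|---|
| `forcespec.physics` | WLC, Bell, FNdY closed forms; thermodynamic conversions |
| `forcespec.curves` | FD-curve segmentation, baseline/noise, rupture detection, loading rates, WLC validation, specificity calls |
| `forcespec.topography` | map referencing, particle detection/measurement, mixture fits, orientation calls, multiplex overlay |
| `forcespec.dfs` | DFS assembly, FNdY fitting, confidence/prediction bands, thermodynamics, cooperativity ledger |
| `forcespec.wham` | Langevin umbrella sampler, WHAM solver, block bootstrap, ΔG/barrier readout |
| `forcespec.simulate` | synthetic FD curves, DFS ensembles, height maps — all with truth sidecars |
| `forcespec.pipeline`, `forcespec.cli` | config-driven condition runs, reports, comparison, CLI |

See `docs/methods.md` for the models, numerical choices and limitations.
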