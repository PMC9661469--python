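# Methods

## Model and assumptions

The transport model is a hybrid of a compartmental pharmacokinetic model and
a Krogh-cylinder tissue model. An infinite capillary (radius `R_c`, µm)
supplies an annulus of uniform interstitial tissue out to the Krogh radius
`R_k`, where a no-flux condition represents the symmetry plane between
neighbouring capillaries. Everything is written per unit capillary length, so
compartment "volumes" are areas (µm²): the capillary plasma volume is
`V_cap = π R_c²` and the systemic volume is `V_sys = V_cap / V_ratio`.
Units are µm, min and µM throughout the model; unit conversions happen only
at I/O boundaries.

Assumptions the implementation commits to:

* **Radial-only transport.** The capillary is treated as infinite and axially
  uniform; there is no axial convection or variation. Oxygen/metabolic
  modelling, haemodynamics and particle margination are out of scope.
* **Quasi-equilibrium plasma protein binding.** Plasma binding enters only
  through the free fraction `f_u`; no explicit plasma-bound species is
  tracked, because only free drug crosses the wall and no plasma-binding
  kinetics are resolved on the minutes timescale of interest.
* **Saturable tissue binding and uptake.** Interstitial protein binding and
  cellular uptake follow Michaelis–Menten kinetics; unbinding is first order
  (`k_unbind = 0` recovers irreversible binding). Bound drug cannot cross the
  capillary wall and diffuses more slowly than free drug (`D_b ≤ D_f`).
* **Cellular uptake as an interstitial-volume sink.** Intracellular drug is
  bookkept per interstitial volume (no separate cellular volume fraction), so
  mass balance weights all three tissue species by `phi_i` times the cell
  ring volume. Cellular efflux `k_eff` defaults to 0, giving monotone
  intracellular accumulation; it is configurable for drugs with significant
  efflux.
* **Heaviside release.** The carrier (or infusion pump) releases at constant
  mass rate `dose/τ` over the half-open interval `[0, τ)`. The half-open
  convention makes the dose integral exact and the discretisation
  unambiguous. The measured exponential release law is used for data
  analysis, not as the PDE source: with release rate constants near
  0.5 min⁻¹, the box of equal duration is an adequate idealisation and keeps
  the four delivery modes exactly equally dosed by construction.

## Default parameters

All defaults are placeholders for a doxorubicin-like small molecule in lung
tissue and are meant to be overridden from a config file for any specific
system.

| parameter | default | units | meaning |
|---|---|---|---|
| `R_c` | 5 | µm | capillary radius |
| `R_k` | 155 | µm | Krogh radius (~300 µm inter-capillary spacing) |
| `D_f` | 9600 | µm²/min | free-drug interstitial diffusivity (~1.6·10⁻⁶ cm²/s) |
| `D_b` | 600 | µm²/min | bound-drug diffusivity (protein-sized solute) |
| `P` | 6 | µm/min | capillary-wall permeability to free drug |
| `f_u` | 0.25 | — | free plasma fraction |
| `V_bind`, `K_bind` | 10, 1 | µM/min, µM | interstitial protein-binding kinetics |
| `k_unbind` | 0.06 | 1/min | unbinding rate (bound-pool half-life ≈ 12 min) |
| `V_up`, `K_up` | 2, 2 | µM/min, µM | cellular-uptake kinetics |
| `k_eff` | 0 | 1/min | cellular efflux |
| `k_out` | 1 | 1/min | capillary ↔ systemic exchange |
| `k_el` | 0.02 | 1/min | systemic elimination (plasma half-life ≈ 35 min) |
| `V_ratio` | 0.02 | — | target-organ capillary / systemic volume ratio |
| `phi_i` | 0.4 | — | interstitial volume fraction |

The binding/uptake constants and `V_ratio` are not independently measured
quantities; they were chosen once so that the default model reproduces the
qualitative kinetics the delivery concept rests on — tissue bound-cargo
signal at 50 µm from a capillary rising over the first half hour and then
decaying over ~3 h, interstitial kinetics faster than intracellular
accumulation, and the strong advantage of rapid intravascular release — and
were not revisited afterwards. The default dose equals `V_sys`, i.e. the
dose that would equilibrate at 1 µM if delivered purely systemically, which
keeps concentrations in an experimentally familiar range; all comparison
metrics scale with dose only weakly nonlinearly (through the saturable
kinetics).

The default scenario fraction `f_seq = 0.6` reflects carrier trapping of
roughly 60% of the injected dose in the target-organ vasculature.

## Numerical scheme

* **Space.** Cell-centred finite volumes on exact annular volumes
  `π(r_{i+1}² − r_i²)`, uniform face spacing, default `n_cells = 200`.
  Chosen over finite differences because interior face fluxes then telescope
  exactly, making mass conservation a testable invariant rather than a
  convergence property. `n_cells = 1` is legal and used for kinetics-only
  unit tests.
* **Wall condition.** The Robin flux `P (f_u C_p − C_f,wall)` is discretised
  with the series-resistance conductance `1/(1/P + Δr/2 D_f)`, which accounts
  for the half-cell diffusion path to the first cell centre and converges to
  `P` under refinement.
* **Time.** Stiff BDF integration (`scipy.integrate.solve_ivp`) with
  `rtol = 1e−8`, `atol = 1e−10` µM and an explicit Jacobian sparsity pattern
  (tridiagonal diffusion blocks plus local kinetic couplings), which keeps a
  200-cell, 603-state run below a second. The integration is split at the
  release cutoff `τ` so the discontinuous source never sits inside a step.
* **Degenerate inputs.** Zero-dose scenarios are legal (mass-balance residual
  defined as 0). Concentrations more negative than `1e−8 ×` the solution
  maximum raise a solver error; smaller negative excursions are clipped to
  zero with a warning.
* **Fitting.** Release fits use bounded trust-region least squares with a
  log-linear initial rate estimate; standard errors come from the Jacobian at
  the optimum. The fluorescence fit `I(t) = s·C_bnd(r, t) + b` runs one
  forward simulation and interpolates bilinearly in `(r, t)` during
  optimisation; because the objective can be multi-modal in `r`, the fit is
  multi-started at r ∈ {10, 25, 50, 100} µm and the lowest-RSS candidate is
  kept. An optional bi-exponential surrogate was considered and rejected as
  the primary path: fitting the model output directly avoids inventing a
  functional family the model does not define.
* **Degradation time.** The 85%-decrease threshold uses the trace max and min
  over the whole record (robust to a pre-mixing baseline), with the crossing
  searched only after the maximum and located by linear interpolation. No
  smoothing by default; a moving-average window is available for spiky
  records.

## Synthetic data

The generators produce exactly the statistical structure the fitters assume:
the corresponding noiseless model curve plus i.i.d. Gaussian noise, seeded
and reproducible. Default sampling mirrors the experimental designs being
emulated (release: 1-min cadence over 0–30 min; tissue fluorescence: 15, 30,
60 and 180 min post injection; photoacoustic traces: 1-s cadence).

What they deliberately do **not** emulate: heteroscedastic or correlated
measurement noise, inter-animal variability, imaging artefacts (the
fluorescence series stands in for an already-averaged ROI intensity), drift
or baseline wander in photoacoustic records, and release clipping is the
only non-Gaussian feature (cumulative percentages are clipped to [0, 100],
a small bias source near the bounds). Passing the recovery tests therefore
shows the estimators are consistent and well-conditioned under the assumed
noise model, not that they are robust to every feature of real measurements.

## Problem sizes used in the checks

The acceptance checks run the full default grid (200 cells) for mass balance
and the mode comparison; the brute-force cross-check uses a 20-cell grid with
linearised kinetics and an explicit-Euler step of 10⁻⁴ min, where the
reference integration is cheap; parameter-recovery studies use 200 release
replicates (σ = 2 percentage points) and 100 fluorescence replicates
(σ = 5% of dynamic range). These sizes give Monte-Carlo errors comfortably
below the tolerances being checked.

## Known limitations

* The equal-dose comparison assumes the free drug experiences the same
  first-pass exposure geometry as carrier-delivered drug with `f_seq = 0`;
  organ-level recirculation is collapsed into the two-compartment exchange.
* Tissue parameters are effective, homogenised constants; tumour tissue
  heterogeneity (variable capillary spacing, necrotic regions) is not
  represented.
* The fitted capillary distance is an *effective* depth for an averaged
  fluorescence signal; with only four time points it is identifiable but has
  appreciable variance at 5% noise (median recovery within a few percent,
  single-fit spread of tens of percent).
* The wall-flux reversal (tissue → blood effusion after the plasma pool is
  cleared) emerges at the defaults only after ~5 h, because tissue protein
  binding retains drug far longer than the plasma half-life.
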