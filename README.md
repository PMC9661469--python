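# kroghpk

Modelling and analysis of **rapid intravascular drug release** — delivery of a
small-molecule drug by nanocarriers that become trapped in the capillaries of a
target organ (e.g. metastasised lung) and release their cargo there within
minutes, driving gradient diffusion of the drug across the vessel wall and deep
into the tissue. The package is aimed at researchers in nanomedicine and
pharmacokinetic modelling who want to compare intravascular burst release
against slow carrier release and free-drug infusion, and to analyse the
accompanying bench measurements (cargo-release curves, tissue-fluorescence
kinetics, photoacoustic carrier-degradation traces).

## The model

Tissue is idealised as a Krogh cylinder: an annulus of interstitium between a
capillary of radius $R_c$ and a no-flux outer radius $R_k$, per unit capillary
length. Three tissue species are tracked radially — free drug $C_f$, protein-
bound drug $C_b$, intracellular drug $C_c$ — coupled to two well-mixed plasma
compartments, the target-organ capillary plasma $C_p$ and the systemic pool
$C_{sys}$:

$$
\begin{aligned}
\frac{\partial C_f}{\partial t} &= D_f \nabla^2_{cyl} C_f
  - \frac{V_{bind}\,C_f}{K_{bind}+C_f} + k_{unbind} C_b
  - \frac{V_{up}\,C_f}{K_{up}+C_f},\\
\frac{\partial C_b}{\partial t} &= D_b \nabla^2_{cyl} C_b
  + \frac{V_{bind}\,C_f}{K_{bind}+C_f} - k_{unbind} C_b,\qquad
\frac{\partial C_c}{\partial t} = \frac{V_{up}\,C_f}{K_{up}+C_f} - k_{eff} C_c,
\end{aligned}
$$

with a Robin condition at the wall, $-D_f\,\partial_r C_f|_{R_c} =
P\,(f_u C_p - C_f)$ — only the free plasma fraction $f_u$ crosses — and
no-flux conditions at $R_k$ and for the bound and intracellular species at the
wall. The capillary exchanges with the systemic pool at rate $k_{out}$, which
is cleared at $k_{el}$. Release is a Heaviside box: constant mass rate
$\mathrm{dose}/\tau$ over $[0,\tau)$ with $\tau = 3$ min (rapid) or 180 min
(slow); carrier modes route the sequestered fraction $f_{seq}$ of the dose
into the local capillary plasma, free-infusion modes deliver systemically.

The radial problem is discretised by a cell-centred finite-volume scheme on
exact annular volumes and integrated with a stiff BDF method (method of
lines), so total drug mass is conserved to integrator tolerance — a property
the test suite checks directly.

Around the transport core the package implements the associated data
analyses:

* `release_kinetics` — the cumulative-release law $C = a(1-e^{-kt})$, its
  nonlinear least-squares fit and time-to-fraction utilities;
* `tissue_fit` — fitting measured tissue-fluorescence kinetics to the
  model-predicted bound-cargo curve with the **distance from the capillary**
  as the fitting parameter;
* `degradation_stats` — the 85%-decrease degradation time of photoacoustic
  amplitude traces and the amplitude-to-concentration calibration;
* `synthetic_data` — seeded generators for every input the pipeline reads.

## Worked example

Compare the four equally dosed delivery modes at the default
doxorubicin-like parameters (peak intracellular concentration at 50 µm from
the capillary wall, 100-min horizon):

```python
import kroghpk as kp

p = kp.TransportParameters()
g = kp.build_grid(p.R_c, p.R_k, 200)
comp = kp.compare_modes(p, g, dose=p.V_sys, f_seq=0.6, r_query=50.0,
                        horizon=100.0)
print(comp.to_frame().to_string(index=False))
```

```
         mode  rank  t_peak_min  C_peak_uM  AUC_uM_min
carrier_rapid     1       100.0   0.028413    1.745243
   free_rapid     2       100.0   0.015392    0.801023
 carrier_slow     3       100.0   0.009922    0.386740
    free_slow     4       100.0   0.004578    0.155859
```

Rapid release from capillary-sequestered carriers delivers a ~1.8× higher
intracellular peak than a rapid free-drug infusion and ~2.9× higher than slow
carrier release: the brief, very high intracapillary concentration drives the
steepest trans-wall gradient. Intracellular drug is still accumulating at the
horizon (efflux is off by default), so `t_peak` sits at the horizon end.

Fitting a noisy synthetic release curve recovers the release-rate constant:

```python
t, y = kp.gen_release_curve(a=72.1, k=0.48, noise_sd=2.0, seed=7)
fit = kp.fit_release(t, y)
print(f"a = {fit.a:.2f} +/- {fit.se_a:.2f} %   "
      f"k = {fit.k:.3f} +/- {fit.se_k:.3f} 1/min")
print(f"t90 = {kp.time_to_fraction(fit.k, 0.9):.2f} min")
```

```
a = 71.04 +/- 0.35 %   k = 0.487 +/- 0.018 1/min
t90 = 4.73 min
```

i.e. a carrier with $k \approx 0.48\,\mathrm{min}^{-1}$ unloads 90% of its
cargo in under 5 minutes.

The same operations are available from the shell via the `kroghpk` command
(`simulate`, `compare-modes`, `fit-release`, `fit-tissue`,
`degradation-time`, `synth`); see `examples/config.yaml` for the
configuration format.

## Documentation

`docs/methods.md` describes the model assumptions, the default parameter set
and its rationale, the numerical scheme, what the synthetic-data generators
do and do not emulate, and known limitations.
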