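# myxoripple

Agent-based simulation and analysis of *Myxococcus xanthus* predatory
rippling — the traveling "accordion waves" that dense swarms of this
predatory soil bacterium form while consuming prey.

Cells are modeled as self-propelled rods that glide along their long axis,
reverse direction when an internal noisy phase clock φ crosses a half-cycle
boundary (native period T ≈ 8 min), and additionally reverse early when an
antiparallel, laterally touching, sufficiently overlapping neighbour
signals them (probability p₀ per contact per time step) — unless they are
still inside the refractory sector φ₀ = ω·T₀ (T₀ ≈ 2.7 min) that follows
every reversal.  A local nematic alignment keeps the swarm's axes parallel.
Above a signaling-probability threshold (~5–10%), these ingredients
self-organize a uniform population into counter-propagating density waves
whose crests reflect off each other; the package's claim structure centres
on the wavelength relation

    λ = 2·v·τ + 2·Δ

(agent speed v, reversal period τ, wave-crest width Δ), the
signaling-probability bifurcation, the co-localization of reversals with
crest collisions, the flux advantage of signaling swarms expanding over
prey, and the suppression of random drift (MSD slope) in rippling
populations.

The toolbox quantifies both simulated and generic tracked data: wavelength
and crest width by continuous 1-D wavelet transform of density kymographs,
a ripple order parameter, reversal detection from trajectories
(principal-axis projection with multi-frame confirmation), mean-square
displacement with no-intercept slope fits, and cumulative plane-crossing
flux.  See `docs/methods.md` for model equations, parameter provenance,
estimator definitions, and known limitations.

## Worked example

Simulate a rippling swarm at reduced scale and quantify it:

```python
import myxoripple as mx
from myxoripple import analysis

params = mx.ModelParams(domain_x=250.0, domain_y=50.0, n_agents=3000)
rec = mx.run_simulation(params, duration=300.0, seed=11, n_tracked=200)

kym = rec.kymograph.window(180, 300)          # steady-state window
wl = analysis.estimate_wavelength(kym)
cw = analysis.estimate_crest_width(kym)
tau = mx.mean_reversal_interval(rec.events, t_min=180)
print(f"wavelength  {wl.wavelength:.1f} +- {wl.spread:.1f} um")
print(f"crest width {cw.width:.1f} um")
print(f"reversal interval {tau:.2f} min")
print(f"order param {analysis.order_parameter(kym):.3f} "
      f"(uniform baseline {analysis.shuffled_baseline_op(kym):.3f})")
print(f"lambda = 2 v tau + 2 delta -> "
      f"{analysis.predicted_wavelength(params.v, tau, cw.width):.1f} um")
```

prints (seed 11):

```
wavelength  54.4 +- 2.9 um
crest width 15.9 um
reversal interval 4.35 min
order param 0.034 (uniform baseline 0.002)
lambda = 2 v tau + 2 delta -> 83.9 um
```

— a ~54 µm wave with ~16 µm crests whose order parameter stands ~17× above
the structure-free baseline; the same run with `p0=0.03` stays uniform
(order parameter ≈ baseline).  The wavelength sits below the closed-form
prediction because the estimator reports the realized crest spacing while
the relation uses the population-mean reversal interval; their agreement is
tracked quantitatively by the sweep regressions in the acceptance suite.

The same operations run from the shell:

```
myxoripple simulate --scenario ripple --seed 11 --out run1/
myxoripple analyze run1/
myxoripple sweep --scenario sweep_tau --points 5,12,20,30 --out sweep/
myxoripple make-fixture --kind sin_kymograph --lambda 60 --delta 12 --out fx/
```

`analyze` also accepts any trajectory table with columns
(t_min, id, x_um, y_um), so experimental tracks can be processed with the
identical code path.

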