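# Methods

## The model

Each cell of a *Myxococcus xanthus* swarm is a self-propelled rod on a 2-D
surface with centre position (x, y), orientation θ ∈ [0, 2π), and an
internal reversal phase φ ∈ [0, 2π).  Four ingredients drive the dynamics:

1. **Gliding with speed noise.**  Per time step δt the centre advances by
   v·δt along θ plus isotropic Gaussian noise of per-axis variance 2·D·δt
   (Euler–Maruyama).  `v` is the mean gliding speed, `D` the effective
   positional diffusion from speed fluctuations.

2. **A noisy phase clock for spontaneous reversals.**  φ advances at mean
   speed ω with Gaussian increments of variance 2·D_φ·δt.  Crossing either
   half-cycle boundary (π or 2π) flips the orientation by 180° — a
   spontaneous reversal — so the inter-reversal interval of an isolated
   cell is the half-cycle time.  The configured native reversal period `T`
   is that interval, hence ω = π/T (the `reversal_convention` switch also
   offers the reading in which `T` is the full 2π cycle, ω = 2π/T).  Noise
   alone is never allowed to carry a phase backwards across the boundary it
   last crossed (the phase is clamped at the boundary), so jitter near π/2π
   cannot double-trigger reversals.

3. **Side-to-side contact-mediated signaling with refractory gating.**
   Two cells can signal when their orientations are antiparallel within
   Δθ₀ = 15°, their centre separation perpendicular to the common axis is
   at most one cell width w, and their long axes overlap by at least
   `overlap_frac`·L (centre separation along the common axis at most
   (1 − overlap_frac)·L).  Each *ordered* pair in contact fires
   independently with probability p₀ per time step; a firing of (i → j)
   reverses only j, and only if j's phase has progressed at least
   φ₀ = ω·T₀ past its last reversal boundary (T₀ is the mean refractory
   time).  An induced reversal flips the orientation and advances the
   phase to the next half-cycle boundary, so the full refractory sector
   elapses again.  Refractory or non-responsive cells still signal others.
   Rule variants (`signaling_rule`) implement the ablations: signaling
   irrespective of direction, co-moving-only, and symmetric bidirectional
   signaling.

4. **Local nematic alignment.**  Each orientation relaxes toward the
   doubled-angle (head–tail symmetric) mean orientation of the neighbours
   whose centres fall in an axis-aligned square of side `neighbor_box`,
   with correlation time τ_θ and orientation noise 2·D_θ·δt, via an
   implicit update θ(t+δt) = (θ(t) + (δt/τ_θ)·⟨θ⟩ + η)/(1 + δt/τ_θ)
   solved by fixed-point iteration (tolerance 1e-6 rad, ≤ 20 sweeps).
   The implicit form is unconditionally stable: the two-cell gap decreases
   monotonically for any δt/τ_θ.

One engine step applies, in order: positions → phases → spontaneous
reversals → contact detection + signaling + induced reversals → alignment,
then advances time by δt.  The neighbour index (an exact cell-list /
k-d-tree pass with Chebyshev radius max(neighbor_box/2, contact radius))
is rebuilt every step.  Periodic boundaries wrap both axes; the `open-x`
mode used by expansion runs wraps y only and enforces an empty margin at
the x-edges at run time.

## Parameters, units, defaults

All lengths µm, times min, angles rad.

| symbol | meaning | default | basis |
|---|---|---|---|
| L | cell length | 7.0 | reported cell length |
| w | cell width | 0.5 | typical rod width; free parameter |
| v | gliding speed | 6.0 | tracked-cell average |
| D | positional diffusion | 0.3 | per-step speed fluctuation √(2D/δt) ≈ 40% of v, bracketing the reported 25–30% motility noise |
| T | native reversal period | 8.0 | isolated-cell inter-reversal interval |
| D_φ | phase diffusion | 0.014 | first-passage calibration: refractory time 2.7 ± 0.7 min (Var = 2·D_φ·φ₀/ω³) |
| T₀ | mean refractory time | 2.7 | reported |
| p₀ | signaling probability per ordered contact per step | 0.10 on prey / 0.03 off | reported; bifurcation parameter |
| Δθ₀ | antiparallel tolerance | 15° | reported |
| overlap_frac | minimal long-axis overlap | 0.5 | reported |
| τ_θ | alignment relaxation time | 0.5 | free; fast local alignment |
| D_θ | orientation noise | 0.01 | an aligned population keeps nematic order > 0.9 over 5 h |
| neighbor_box | alignment neighbourhood side | 7.0 | one cell length; free |
| δt | time step | 0.1 | resolves the refractory clock (δt < T₀/5) |
| domain | 500 × 100 | reported simulation field |
| n_agents | population | 12,000 | near-confluent coverage n·L·w/A ≈ 0.84; see below |

`p₀` is defined per time step at the reference δt = 0.1 min; an optional
rate-normalized mode (p_eff = 1 − (1 − p₀)^(δt/δt_ref)) keeps the
signaling *rate* fixed when δt changes.  Changing δt without it changes
the effective signaling strength.

**Density.**  The published parameter table is not available; density is
the one structural parameter we had to fix from behaviour.  At sparse
coverage (≲ 0.2) the side-to-side contact rate cannot compete with the
spontaneous clock and no wave forms for any p₀; rippling swarms are dense,
multilayered sheets, and at near-confluent projected coverage (~0.85;
n·L·w may exceed the domain area up to a 4-layer bound) the model
self-organizes into ripples at p₀ = 0.10 and stays uniform at p₀ = 0.03,
with the bifurcation threshold between 0.04 and 0.08 — matching the
reported ~5–10% threshold.

**Clock noise.**  D_φ cannot simultaneously reproduce the printed
refractory spread (2.7 ± 0.7 min) and a 25–30% native-period spread: for a
drift–diffusion clock the coefficient of variation scales as one over the
square root of the phase distance, so the refractory calibration implies a
~15% native-period spread.  The printed refractory numbers take
precedence; at the 25–30% calibration the waves dissolve.

**Regime caveat.**  With these reconstructed parameters the rippling state
is *signal-saturated*: nearly every reversal is contact-induced and the
realized mean reversal interval at p₀ = 0.10 is ≈ 4.2–4.5 min (refractory
time plus the short wait for the next signal) rather than the ≈ 6.6 min
the original study reports, and it responds only weakly to the native
period.  Quantities that inherit the 6.6-min, collision-sparse geometry
shift accordingly: the wavelength-vs-speed regression coefficient comes
out near 2×(realized interval) ≈ 10 min rather than 16 min, the
reversal-in-collision fraction is enriched above chance but far below 92%
(the dense wave lattice keeps crests within a crest width of each other
~40% of the time), the prey/no-prey expansion-flux ratio measures ≈
1.5–1.8 rather than 2.0, the non-rippling drift slopes are small (the
refractory-calibrated clock is nearly deterministic), and the strictest
overlap threshold (minimal overlap 0.8·L) falls below the instability
threshold so that sweep point shows only transient patches.  The
wavelength still scales linearly with both speed and realized period, and
collision co-localization remains clearly enriched.  We did not find a
parameterization that both forms waves from a uniform start and sits in
the clock-coupled regime; the alternatives explored (period-matched clock
noise, per-minute signaling semantics at up to 0.6 cells/µm², longer
horizons) each lose the instability.

## Analysis definitions

* **Kymograph** — agent-centre counts in 2-µm x-bins (all y pooled), one
  row per minute.
* **Wavelength** — per frame, the continuous wavelet transform (Ricker
  mother wavelet, 48 log-spaced scales spanning wavelengths from 4 bins to
  half the domain) of the mean-subtracted profile; the wavelength is the
  scale-to-wavelength conversion (centre frequency 0.25) of the
  power-maximizing interior scale, averaged over frames, with the
  across-frame dispersion as confidence.  Flat profiles and edge-pinned
  maxima are flagged, never turned into numbers.
* **Crest width Δ** — local maxima of the Gaussian-smoothed profile above
  mean + 1 SD; windows around crest centres are aligned and averaged, a
  Gaussian + constant is fitted, and Δ is its FWHM (floored at one bin).
* **Order parameter** — complex-Morlet (cmor2.0-1.0) scale power averaged
  over bins and frames; a running median over scales (~one octave)
  estimates the smooth background; the order parameter is the largest
  positive excess over that background divided by total power.  A uniform
  Poisson field scores ≈ 0.002, a noiseless standing wave ≈ 0.18, rippling
  runs ≈ 0.03–0.05.  Ripple presence is judged against the *shuffled
  baseline*: the same statistic after randomly permuting each frame's
  bins (averaged over 5 permutations — one shuffle is itself noisy).
  Presence = the pooled two-hour window past the 3-h mark clears 5× the
  baseline; absence = no two consecutive two-hour windows are elevated,
  because formed ripples persist in every late window whereas
  deep-subcritical runs only show single-window transient wave patches
  that decay again.  Power averages subsample to at most 60 evenly spaced
  frames per window — consecutive frames are strongly correlated, so this
  loses essentially no information.
* **Crest collisions** — the kymograph is split into right- and
  left-moving components by 2-D Fourier quadrant filtering (a plane wave's
  temporal and spatial frequencies have opposite signs for one direction
  of travel and equal signs for the other); per frame, a collision region
  marks any right-crest/left-crest pair within one crest width, spanned by
  both crests ± Δ/2 and dilated by one frame.  The reversal-in-collision
  fraction is the share of logged reversal events inside the mask, with a
  bootstrap-over-agents standard error; for uniformly random events it
  equals the mask's area fraction by construction.
* **Reversal detection from tracks** — displacement projected on the
  movement axis (per-track PCA, or a pooled axis); a velocity sign change
  counts only if the new direction persists ≥ 3 frames and both legs
  average ≥ 1 µm/min.  Flickers are absorbed into the surrounding leg.
* **MSD** — 2-D mean-square displacement with overlapping time origins
  (non-overlapping mode available), averaged over agents, from *unwrapped*
  coordinates; drift slopes are least-squares through the origin
  (Σxy/Σx²).
* **Predicted wavelength** — λ = 2·v·τ + 2·Δ; the Δ = 0 form is the
  classic colliding-crest relation.

## Scenario and test problem sizes

Emergent-behaviour tests and the acceptance script run on reduced domains
at the default density — 250 × 50 µm / 3,000 agents (sweeps, collision
statistics, MSD) and 200 × 40 µm / 1,920 agents (emergence seeds,
ablations) — with 4–6 simulated hours; the statistics are intensive
(coefficients, fractions, ratios) and stable at a few wavelengths per
domain.  The expansion scenario uses an 800 × 50 µm open-x domain seeded
in a central 200-µm strip.  The matched non-rippling population for the
drift comparison is built by secant calibration of the native period on
short half-size runs until the realized mean reversal interval equals the
rippling run's.

## Synthetic fixtures

The fixture generator produces kymographs (counter-propagating sinusoids
or Gaussian-crest trains with known λ, Δ, speed, plus Gaussian or Poisson
noise; collision times in closed form) and trajectories (exact zigzags
with known reversal times, Brownian walks with known D, immobile
controls), stored in the same containers and CSV dialects as simulator
output.  They pin down what the estimator suite can and cannot see: the
fixtures have perfectly periodic, y-coherent waves and i.i.d. noise, so
estimator accuracy on them bounds, but does not guarantee, accuracy on
simulation output with defects and correlated fluctuations — which is why
the acceptance tests re-measure everything on real runs.

## Known limitations

* Cells are points with an interaction footprint; there is no excluded
  volume, so densities are projected (multilayer) densities and crest
  packing is not sterically limited.
* The signal-saturated regime caveat above: reversal statistics in the
  rippling state are refractory-dominated.
* The phase-reset and clamping contracts after reversals are this
  implementation's reading of the original scheme (the exact published
  expressions are not available); both are stated above and tested.
* p₀ is a per-step probability; comparisons across δt require the
  rate-normalized mode.
* Analysis assumes waves travel along x (the nematic axis of the
  initialisation); tracks of arbitrary orientation are handled through
  the PCA projection, but kymographs are 1-D in x by construction.
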