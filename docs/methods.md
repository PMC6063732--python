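# Methods

## Model

The package centres on a one-dimensional description of the cortex along
the axis perpendicular to the contractile ring.  Myosin engaged in the
ring/Rho zone (a band of half-width w = 5 µm around the equator) compresses
cortical surface at a local rate ∂ε/∂t = −α·m(x,t); the resulting velocity
field v(x,t) = −α∫₀ˣ m dx′ advects myosin conservatively, and cortex
entering the zone at ±w carries the loading concentration m_rho.
Integrating over the zone gives dM_ring/dt = α·m_rho·M_ring: the engaged
per-unit-length myosin grows exponentially with timescale τ = 1/(α·m_rho),
and the inflow speed per side is v_flow = α·M_ring/2.  Ring shortening is
proportional to myosin, −(1/R)dR/dt = β·M_ring, which in the half-closure
time frame (R̄(0) = 1/2, t̄ = t/τ) yields the closed form
R̄(t̄) = R̄_ini(2R̄_ini)^(−exp t̄) with the dimensionless characteristic
size R̄_ini held at 1.1.  In that frame M0_ring = ln(2R̄_ini)/(βτ) and the
per-side dimensionless flow speed is (α/2β)·ln(2R̄_ini)·e^t̄ — the factor
½ reflects inflow from both sides of the ring.

Assumptions worth keeping in mind: the around-the-ring direction is purely
constriction-coupled disassembly (per-unit-length amounts unaffected by
shortening); the polar cortex yields freely (no resistive tension), so all
myosin-generated force works against ring-internal friction; and the zone
width, α, β and m_rho are constants of a given embryo.

## Parameters

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| R_emb | embryo radius | µm | 14.7 (SD 0.7) | measured population mean |
| t_CK | cytokinesis duration | s | 200 (SD 30) | measured population mean |
| 2w | compression-zone width | µm | 10 | flow-gradient span at the equator |
| z_att | attenuation depth | µm | 15 | shared-depth exponential fit |
| R̄_ini | characteristic ring size | — | 1.1 (fixed) | as in the analytical solution |
| τ | myosin accumulation timescale | s | t_CK/2.761 | the line-fit duration of the closed form equals t_CK (2.761 is the computed span factor) |
| α/β | compressed area per unit shortening | µm | 10 | sets the inflow/plane-growth flux ratio ≈ 1.3–2.7 over closure, matching the observed 1.5–2× scale |
| m_rho | loading concentration | amount/µm² | 1 | sets the (arbitrary) intensity unit |
| pixel size | cortex/division camera | µm/px | 0.16 | typical spinning-disk EMCCD sampling |
| pixel size | whole-embryo stacks | µm/px | 0.10 | makes the mid-plane mask area (~115k px²) consistent with the 120,000 ± 50,000 px² acceptance window used by the segmentation stage |

## Synthetic data: what it emulates, what it does not

The generator reproduces the study conditions end to end: population
variability (normal radius/duration, uniform ingression-axis angles,
normal onset jitter), ring trajectories following the closed form (clamped
at R_emb before ingression) with a linear center drift along the ingression
axis that crosses the embryo axis at mid-closure (amplitude
0.3·(R_emb − R); the asymmetry is described but not parameterized in the
source data, so this is the simplest shape with the right sign and timing);
flow fields with constant-speed flanks, a linear ramp through the zone
(uniform strain −v_flow/w), a linear taper over the polar caps
(|x| > 0.75·half-length, where surface is gained), and a top/bottom
modulation 1 + 0.3(1 − 2t̂)cos θ tracking the drift; myosin-foci movies on
the experimental imaging cadence (15 frames at 2 s, then an ~6–8 s z-stack
gap per 36 s cycle); division-plane z-stacks with per-slab arc content, exp(−z/z_att)
attenuation, constant background and multiplicative 5 % noise; and
whole-embryo stacks (cylinder + spherical caps, brighter anterior rim).

Deliberately not emulated: photorealistic cortex texture, rotational flow
(the analysis removes it by mirror folding anyway, so the generator omits
it), 3-D membrane rendering, bleach-spot geometry, and camera physics
beyond multiplicative Gaussian noise and integer quantization.  Passing
tests therefore demonstrate that the algorithms recover known truth under
realistic geometry, sampling and noise — not that they are robust to
debris, z-drift, or segmentation-confounding neighbours, which real movies
contain.

One bookkeeping subtlety: in the synthetic world the flank flow is carried
on the full embryo circumference, so the budget-derived per-unit-length
compression rate scales as αM_ring/R̄ rather than αM_ring.  The
model-fitting series are generated from the closed forms directly, so
parameter recovery is unaffected; the budget stage is validated through its
exact identity and the flux-ratio property instead.

## Numerical choices

* **Circle fits**: Kåsa algebraic initialization, geometric
  Levenberg–Marquardt refinement; validated against an exhaustive 0.05 µm
  grid search.
* **Segmentation threshold**: local minima of a Gaussian-smoothed 256-bin
  histogram; among minima whose largest connected component falls in the
  expected-area window, the one nearest the midpoint of the flanking modes
  (stable in a flat valley).  Boundary crossings are interpolated to
  sub-pixel.
* **Provisional time frames**: the 30–80 % closure window is widened in
  0.05 steps (at most to 15–95 %) when fewer than three samples fall
  inside, as happens at the 36 s cadence; the iterative refinement against
  ⟨R̄⟩(t̂) supplies the accuracy either way.  Refinement uses Nelder–Mead
  per embryo, keeps a frame only if it lowers the residual, rescales all
  frames so the 0.8–0.3 line of ⟨R̄⟩ intercepts (0, 1) and (1, 0), and
  stops when the curve changes < 0.001 on average.
* **Flow maps**: grid t̂ ∈ [−0.3, 1.1] step 0.05, x ∈ [−15, 15] µm step
  1 µm, θ step 10°; cells with < 5 embryos flagged low-coverage; empty
  cells stay NaN.  Linear interpolation bridges ≤ 4 s frame gaps only, so
  acquisition gaps stay missing.  |x| < 2 µm is flagged as the near-plane
  projection artifact and excluded from template fits.
* **Zone template**: constant–ramp–constant least squares; a ramp narrow
  enough to hide inside the excluded gap (≤ 2·2 µm + one sample spacing)
  or a residual > 20 % of the flank speed is reported as "no zone".
* **Budget**: trapezoidal integration starting exactly at t̂₀ = −0.2;
  division-plane area counts both new surfaces, 2π(⟨R⟩²(t̂₀) − ⟨R⟩²(t̂)).
* **PDE**: first-order conservative upwind finite volume with CFL-safe
  (0.5) adaptive steps; the boundary-flux telescoping makes
  dM_ring/dt = αm_rho M_ring exact in space, so accuracy is limited by the
  time step (first-order convergence verified over grid refinements).
* **Fits**: exponentials are initialized from a log-linear regression on
  baseline-subtracted data; residual blocks are scaled by each series' RMS
  so fluorescence units do not dominate; model comparison uses AICc on the
  scaled series residuals with the feedback rate shared with the ring
  trajectory (the model couples them), and per-series SSRs are reported for
  paired comparisons.  The Retention fit (base + B/R̄) is linear and solved
  exactly.
* **Photometry**: background is estimated per z-plane from two 11 × 11 µm
  boxes 2 µm from the plane and subtracted before attenuation correction
  (correcting first would amplify the camera offset with depth); the
  annular band half-width is 0.5 µm; renderers round to the nearest camera
  count to keep quantization unbiased.

## Design choices where the design was open

* The flank speed during ingression is v_pull + v_flow, with
  v_pull = R̄·(−dR/dt) exactly feeding division-plane growth and zero
  before the ring leaves the embryo surface (R̄ clamped at 1).  The
  pre-ingression profile is therefore a pure compression ramp, which is
  what the zone-width analysis measures.
* "Pre-ingression" sampling happens at t̂ = −0.28: with the line-fit time
  convention, the closed-form trajectory crosses R̄ = 1 near t̂ ≈ −0.21,
  so earlier bins are the ones with no furrow.
* Equal embryo weighting in all averages (per-sample weighting would favour
  slowly dividing embryos).
* Total ring fluorescence integrates the per-arc values (arc sums × arc
  length) rather than re-summing pixels, so total and arcs are consistent
  by construction.
* The laser-cut calculator treats the control closure rate as an opaque
  measured input and only propagates the area arithmetic.

## Limitations

* The geometry stage assumes one embryo per field of view, oriented within
  the frame, with a bimodal intensity histogram.
* The block-matching flow backend has no sub-window deformation model; it
  measures translations at the window scale (30 px) and drops low-
  correlation vectors rather than regularizing them.
* Parameter recovery is demonstrated at 5 % multiplicative noise and the
  stated cadences; much sparser sampling leaves τ and the half-closure
  time partially confounded in single-series fits (the ring trajectory
  resolves this in the joint fit).
* Analyses use 10–48 embryos per run to keep runtimes interactive; the
  statistical headroom reported by the scripts scales accordingly.
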