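# Methods

## The model

Five volume-fraction fields live on a 2-D periodic domain: free protein
`P`, two free RNA species `R1`, `R2`, and the two protein-RNA complexes
`K1`, `K2`.  Complexes form and dissolve by mass action,

    P + R1 <-> K1   (rates a1, a2),      P + R2 <-> K2   (rates a3, a4),

and demix from the passive solvent `S = 1 - K1 - K2` under the
Flory-Huggins free energy

    F[K1,K2] = ∫ (ε²/2)(|∇K1|² + |∇K2|²)
               + A·(K1 ln K1 + K2 ln K2 + S ln S
                    + χ₁₂ K1 K2 + χ_S K1 S + χ_S K2 S) dx ,

with A = 0.2, χ_S = 4.25, χ₁₂ = 4.5.  The complexes follow conserved
Cahn-Hilliard dynamics, ∂K_i/∂t = ∇·[λ_i M ∇(δF/δK_i)] + (reactions), with
constant mobility M = 1; the free species diffuse Fickian-ly.  Baseline
rates and the sensitivity ranges of the nine varied parameters (five
diffusivities λ, four kinetic rates a) are in
`llps_gsa.model.ModelParameters` / `SENSITIVITY_RANGES`.

Two scalar quantities of interest (QoIs) summarise a run: the
whole-second **time of phase separation** (first recorded second at which
the droplet detector finds at least one droplet) and the **K1 droplet
count fraction** at that second.  Runs that have not separated when the
cap time is reached keep the cap as their time and the sentinel value
1.25 as their fraction; both conventions follow the source study (cap
1000 s for the screening stage, 10 s for the variance stage).

## Numerical scheme

The solver is semi-implicit Fourier-spectral on the periodic grid.  Stiff
linear operators (ε²∇⁴ for the complexes, λ∇² for the free species) are
implicit; the nonlinear bulk potential and the reactions are explicit,
with a constant stabilisation shift `s` moved to the implicit side of the
complex update.  All fluxes vanish at wavenumber zero and the reaction
sources cancel pointwise, so the means of P+K1+K2, R1+K1 and R2+K2 are
conserved to rounding error.

Two numerical choices deserve emphasis:

* **Regularised entropy.**  The logarithms in F are continued linearly
  below δ = 0.02 (`LOG_CLAMP`), the neighbourhood of the dilute
  Flory-Huggins branch at the study's χ values.  The continuation is C¹,
  so the potential remains monotone-restoring (fields are pushed back
  towards positive values) while the bulk stiffness is bounded by
  f'' ≤ A/δ.  Energy and chemical potentials use the same continuation
  and remain an exact discrete variational pair on both branches; the
  spectral gradient energy is evaluated in Fourier space with the same
  -k² symbol as the Laplacian so the pairing holds at the Nyquist modes
  too.  The regularisation leaves an O(A·δ) offset in the energy of a
  nearly-empty field and slightly softens the dilute branch; it does not
  affect fields above δ.

* **Stabilisation shift.**  With the stiffness bound above, a fixed shift
  s ≥ max|f''|/2 makes the scheme stable at a practical time step.  The
  default s = 8 keeps the marginal-resolution working grids retry-free; a
  blow-up still triggers a halving-on-failure retry of the current
  one-second interval (up to 6 halvings).

Defaults: 128×128 cells over L = 2.5 µm (h ≈ 0.02 µm), dt = 5·10⁻⁴ s,
and a *fixed physical* interface width ε = 0.039 µm (two reference-grid
spacings).  Sampled studies run on 64×64 cells over the same domain with
the same ε, i.e. the same dynamics observed at coarser spatial sampling
(ε = h there, at the resolution limit — which is why the larger shift is
the default).  The inner loops are numba-compiled and cross-checked
against the plain-numpy model functions in the test suite.

## Initial conditions

There are no preformed complexes (K1 = K2 = 0).  The protein field is P0
plus band-limited uniform noise: an i.i.d. uniform draw low-pass filtered
at a correlation length of 0.08 µm and rescaled to the standard deviation
of the unfiltered ±0.45 draw.  The RNA fields are computed pointwise from
the protein field, R1 = w(1-P), R2 = (1-w)(1-P), so P + R1 + R2 = 1
everywhere at t = 0.  The split fraction w is itself a noise field about
the mean ratio share (1/2, 2/3 or 3/4): the two RNA species are placed
independently in a well-mixed solution, so their density fluctuations are
independent.  A perfectly proportional split would hand every fluctuation
to both complexes at once, and the faster-diffusing K1 complex would then
win every nucleation site — an artificially K1-homogeneous droplet field.

Why these choices matter: free protein diffuses fast (λ_P = 3.75 µm²/s),
so protein noise at sub-micron scales is erased within milliseconds —
long before complexes accumulate.  What seeds the spinodal instability on
the observed few-second timescale is the structure the complex fields
inherit from the noisy RNA fields.  The band limit keeps that structure
off the grid scale, where the dilute-limit entropic stiffness would
otherwise force an impractically small time step.  Amplitudes,
correlation length, domain size and ε are not stated by the source study;
they were fixed once by requiring the four canonical binding-dynamics
scenarios to reproduce their reported behaviour (fast K1-homogeneous,
slow K2-dominated, fast heterogeneous, fast K2-homogeneous fields), and
are recorded in every output file.

## Droplet detection

A droplet is a connected component (8-connectivity with periodic
wraparound) of cells with total complex K1 + K2 ≥ θ, discarding
components smaller than 4 cells.  θ defaults to the midpoint between the
dilute and dense branches at the study's χ values (see
`DetectorConfig`).  Droplets are classified K1- or K2-type by their
dominant mean species (ties → K1-type, documented and configurable); the
K1 fraction is count-based by default with an area-weighted variant
available.  Whole-second recording implements the ceiling convention for
fractional separation times.

## Sensitivity machinery

**Morris screening** uses radial one-at-a-time sampling: r i.i.d. uniform
base points on the unit-scaled parameter cube, each perturbed by a fixed
Δ = 0.001 per coordinate (reflected at the upper boundary), costing
r(p+1) evaluations.  μ* is the mean absolute elementary effect; σ is
reported in two conventions — the standard deviation about the signed
mean (default, matching the common reference implementation) and an
"as-printed" variant whose deviations are taken about μ* itself.
Screening retains parameters with μ* ≥ α·max μ* (α = 0.4 default); a
largest-gap rule is available.  Non-separating runs enter the effects at
their capped/sentinel values; no exclusion.

**Sobol' indices** use Saltelli sampling from a scrambled Sobol' sequence
in 2p dimensions (A and B base matrices plus AB, and BA when pairwise
indices are requested): n(p+2) evaluations without second order —
matching the evaluation-count rule of the source study — or n(2p+2) with.
Estimators are Saltelli-2010 (S1), Jansen (ST) and the closed
Saltelli-2002 pair form (S2); negative S2 estimates are additionally
reported clipped to zero, raw values retained.  The convergence loop
doubles n until every |ΔST|/|ST| < 0.1 between consecutive doublings,
treating |ST| < 0.01 as converged to avoid near-zero division; because
sequential draws extend the scrambled sequence, all prior evaluations are
reused at each doubling.

The estimators are validated against closed-form decompositions (linear,
pure-product, Ishigami) and a dense-quadrature oracle for a discontinuous
capped-step surrogate that mimics the capped/sentinel QoI geometry.

## Pipeline

For each (QoI, ratio) cell: Morris over all nine parameters → retain →
Sobol' over the retained set with the others frozen at their baseline
values → distribution summaries (median, quartiles by linear
interpolation, percent capped, with capped runs included at their
cap/sentinel values).  One simulation cache serves both QoIs of a cell,
so each distinct parameter vector is simulated once per stage.  Per-run
seeds are a SHA-256 hash of (study seed, stage, parameter vector), making
results independent of evaluation order and reproducible under partial
re-runs.  Presets: `smoke` (32², r=4, n=4), `desk` (64², r=16, n=16),
`full` (128², r=1000, n=1024 with convergence doubling) — the last
matches the source study's scale and is not intended for interactive use.

## What the synthetic fixtures do and do not show

The fixture module paints tanh-profiled droplet fields with an exact
census, assembles trajectories that separate at a known second, and
provides the analytic surrogates above.  Tests built on them verify the
detector, the QoI conventions and the sensitivity estimators exactly, but
they bypass the PDE: agreement there says nothing about the physical
realism of the simulated droplet fields.  Conversely, the
simulation-level checks (conservation, energy dissipation, variational
consistency, the canonical scenario anchors) validate the solver but at
reduced problem sizes chosen for a desk-scale budget: 64²–128² grids,
n of 16–32 Saltelli samples (~130–160 PDE runs per cell), far below the
source study's converged runs.  Medians of whole-second times are robust
to that reduction; index estimates at these n carry Monte-Carlo error of
order 0.1 and are exercised against surrogates instead.

## Known limitations

* The interface width, domain size, grid, time step, noise and detector
  threshold are not stated by the source study; this package's defaults
  were calibrated once against the four canonical scenario anchors and
  all results are conditional on that configuration.
* Two canonical scenarios separate later here than reported: the
  fast-K1 scenario detects at 4 s instead of 3 s, and the slow scenario
  (weak K1, slow-forming K2) at ~19 s instead of 12 s.  With
  deterministic initial seeds that decay before the mixture enters its
  spinodal region, the detected time is entry plus a growth phase that
  re-amplifies from sub-percent residual structure — and this sum is
  nearly invariant to ε, domain size, time step, noise settings and the
  detector threshold, because seed decay and growth rate rescale
  together.  The reported times are consistent with detection about one
  second after spinodal entry, which requires a persistent perturbation
  source that the model equations do not contain.  The lag propagates as
  roughly +1 s to the sampled separation-time distributions.
* Constant mobility M = 1 (as in the study); no phase-dependent slowdown,
  no 3-D, no post-separation coarsening statistics.
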