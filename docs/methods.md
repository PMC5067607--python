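# Methods

`activegel` models and analyses the contraction of a reconstituted
actomyosin gel in which myosin II motors are switched on locally by light
(photo-inactivation of blebbistatin). The activated region contracts
against the passive gel that surrounds it and stays attached to it; the
force balance at the active/passive boundary governs both the final shape
and the dynamics. The package contains four scientific components — a
static spring-network model, a stimulation-efficiency model, a minimal
critically damped dynamic model and the image analyses (PIV and fibre
orientation) — plus a synthetic-data generator that stands in for the
microscopy inputs.

## Static spring-network model

The gel is a regular `nx × ny` array of crosslinker nodes in a periodic
simulation cell, each node joined to its four nearest neighbours by
harmonic springs with **vanishing rest length**. Passive springs have
coefficient `k_w`; springs whose **both endpoints** lie inside the
activated geometry are stiffened to `k_s = k_w / K`, with the
spring-coefficient ratio `K = k_w / k_s ∈ (0, 1]`. Forces are linear in
positions, so the force-free final state solves a sparse linear system:
with zero rest lengths the x and y displacements decouple and each
satisfies `L u = f`, where `L` is the weighted graph Laplacian and `f` the
net spring force of the initial configuration (nonzero only near the
stiffness contrast). The pure-translation nullspace is removed by fixing
the mean displacement to zero (equivalent to pinning the centroid); cell
vectors are held fixed — with zero rest lengths a relaxing cell would
collapse entirely, so the fixed cell is what represents the surrounding
material. A direct sparse factorization is used up to 10⁵ nodes, conjugate
gradients (tolerance 1e−10) beyond; the residual nodal force at the
solution is checked against `1e−8 · k_s · spacing · √N`.

### What the model actually predicts for a circle

Each displacement component minimizes a weighted Dirichlet energy
`½∫k|∇u|²`. For an activated disk of radius `R` in an infinite passive
surround the equilibrium inside the disk is an exact uniform scaling
`x → a·x`, and matching the normal flux `k ∂_r u` across the interface
gives

    a = 2K / (1 + K).

The often-quoted identity "contraction ratio = K" is the **one-dimensional**
result (a chain of strong springs embedded in a long weak chain contracts
exactly by K; the package reproduces this with the uniform-tension closed
form `d_s = K·d_w`, `d_w = L/(M + mK)`). In two dimensions the transverse
coupling of the zero-rest-length springs stiffens the passive surround's
response and the disk contracts less: at `K = 0.13` the model yields
`C_fin/C_init → 2·0.13/1.13 ≈ 0.230` in the large-cell limit (0.2337 at a
cell six diameters wide), not 0.13. Both the sparse solver and an
independent dense Newton minimization of the total energy agree on this to
1e−8, and the measured ratio converges to `2K/(1+K)` as the cell grows.
Notably, a display ratio of 0.23 is exactly the experimentally observed
contraction at 20 stimulation cycles, which is presumably why `K = 0.13`
is the "suitable" display value for the reference figures; the package
reports what the defined model computes and documents the difference
rather than reconciling it silently.

Shape phenomenology is as observed in experiments: circles contract shape
preserving (per-node radius-ratio cv < 0.02 for radius ≥ 16 spacings);
full squares develop concave edges (positive concavity score =
inward-normal displacement of the edge midpoint minus that of its
corners); hollow squares round their inner boundary (polygon circularity
`4πA/P²` of the ordered inner-boundary nodes strictly increases); thick
hollow squares show both signatures.

Numerical/defaults: node `(i, j)` sits at `(i·s, j·s)`; masks are
evaluated at node coordinates with inclusive boundaries; geometries must
keep a margin of one spacing to the cell edge; the both-endpoint
activation rule keeps the activated boundary crisp and symmetric;
`boundary_radius_cv` is the cv of the **per-node** final/initial boundary
radius ratio, which measures shape preservation without the
lattice-discretization spread of the initial radii.

## Stimulation-efficiency model

Each scan cycle activates a fraction `P` of the not-yet-activated
material (nothing is stimulated twice), so

    K(n) = 1 + (K_inf − 1)[1 − (1 − P)^n],

decaying from `K(0) = 1` to the saturated ratio `K_inf`. At the reference
parameters `P = 0.11`, `K_inf = 0.15`, twenty cycles give `K(20) ≈ 0.233`.
`fit_stimulation` estimates `(P, K_inf)` from `(n, ratio)` tables by
bounded trust-region least squares with multi-start in `P`
({0.05, 0.2, 0.5}; the objective can be flat when the sampled range misses
the knee), returning Jacobian-based ~95% confidence half-widths. The
maximal contraction speed after `n` cycles is modelled as
`v_max(n) = D_init (1 − K(n)) / (e·τ_c)` with `D_init` the initial
distance between opposing boundaries — the critically damped maximum
combined with the observed proportionality to the initial span.

## Minimal critically damped dynamic model

Every linear dimension relaxes like the step response of a critically
damped oscillator started at rest:

    L(t) = K·L_init + (1 − K)·L_init (1 + t/τ) e^(−t/τ).

This closed form carries all the properties attributed to the dynamics —
speed zero at `t = 0`, a single maximum `L_init(1−K)/(e·τ)` at the
compression time `t = τ`, and a long-time exponential tail with the same
`τ` — so it is used directly instead of integrating an ODE, and each
property is exactly testable. Defaults ship as the reference preset
`K = 0.23`, `τ_c = 12 min`, `γ = 0.4`.

Rectangles (`α = X_init/Y_init ≥ 1`) couple their axes through the
compression times

    τ_X = τ_c · α^((1−γ)/2),   τ_Y = τ_c · α^(−(1−γ)/2),

which preserves `τ_X·τ_Y = τ_c²`, reduces to the square limit at `α = 1`,
and gives a maximal-speed ratio `v_max_X / v_max_Y = α^γ` (the empirical
γ-scaling; `γ = 1` is the naive uncoupled expectation where the ratio
equals α). Because `τ_Y < τ_c < τ_X`, the short axis contracts first: the
aspect ratio transiently overshoots to `α_max > α` and returns to `α` at
long times (both axes share K). Known limitation: this independent-axis
parametrization does not reproduce the observed unit ratio of interface
speeds at `t → 0⁺` (the t→0 speed-per-length ratio is `α^(2γ−1) ≠ 1` for
`γ ≠ 0.5`); the short-time coupling of the real system must differ, and we
document rather than hide this.

`fit_trajectory` fits `(L_init, K, τ)` by bounded least squares with
multi-start in τ; constant series return `K = 1` with τ flagged
unidentifiable. `gamma_scan` simulates rectangles at fixed area, extracts
each axis's maximal speed by central differences on a grid of step
`τ/200`, and regresses log speed-ratio on log aspect-ratio.

## Particle image velocimetry

Iterative normalized cross-correlation: an interrogation window (default
32 px) from frame A is matched inside a larger search window (default
64 px) of frame B (`skimage.feature.match_template`); the correlation peak
gives the integer displacement, refined to sub-pixel precision by
three-point parabolic fits per axis. Later iterations (default 3)
re-centre the search windows on the previous field, with invalid vectors
first repaired from their neighbours, so false peaks from sparse texture
are avoided. Vectors with peak correlation below the threshold (default
0.5), featureless windows, or out-of-bounds search windows are flagged
invalid; `repair_vectors` replaces them by the componentwise median of
their valid 8-neighbours (idempotent; vectors with no valid neighbour stay
invalid). Sub-pixel refinement is skipped when the integer peak is exact
(correlation ≥ 1 − 1e−9) or the parabola is degenerate, so pure integer
shifts are recovered exactly. The default output grid pitch is 10 px
(10 μm at the synthetic scenes' 1 μm/px). Local strain rates are
least-squares slopes of the velocity component against the coordinate over
the valid vectors inside an axis-aligned box, divided by the frame
interval.

## Fibre-orientation analysis

The image is chopped into square tiles (default 128 px); each tile is mean
subtracted, Hann windowed, and its 2D Fourier power spectrum is
accumulated in polar coordinates with a 3 px DC disk excluded and Gaussian
angular weighting of width `σ = bin_width/2`. Structures oriented at θ
produce spectral power at θ + 90°, so the wave-vector angle is rotated by
90° before binning and the reported angle is the real-space orientation.
Binning uses `N = ceil(180°/bin_width)` **equal circular bins** covering
[0°, 180°): a literal final truncated bin would receive about half the
angular measure of the others, making a flat histogram impossible, whereas
equal bins keep the histogram sum at 1 with an isotropic level of exactly
`1/N` in every bin — `1/23 ≈ 0.0435 ≈ 0.044` for the 8° default. The
distribution is invariant to affine intensity rescaling and equivariant
(mod 180°) under image rotation.

## Synthetic data

Bead movies: beads are placed uniformly (density such that ~98 beads fall
in a 10 μm × 10 μm window at 1 μm/px) and advected **analytically** by a
displacement field — no integration error, so PIV error is attributable to
PIV alone — then rendered as Gaussian spots (σ = 1 px) with additive
Gaussian noise and optional Poisson statistics. Two model fields are
provided: `radial_contraction_field` scales a disk uniformly with the
contraction curve (displacement decaying as 1/r outside the rim), and
`penetrating_contraction_field` delays each material point by its distance
to the boundary over a front speed (default `R/τ`), reproducing the
boundary-first strain-rate pattern that PIV observes in the experiments
while reaching the same uniform final scaling. Fibre textures:
anti-aliased line segments with orientations uniform on [0°, 180°) or
axial von Mises (sampled on the doubled angle; κ = 0 reduces to uniform).
Observation tables: `K(n)` ratios with multiplicative Gaussian noise
(default 2%) and circle/rectangle trajectories with additive noise
(default 1% of the initial length) on the model curves at the reference
parameters, with a JSON manifest of the generating values. All generators
are deterministic under a fixed seed.

What the synthetic data do not emulate: bead bleaching, depth/confocal
sectioning, gel densification texture, non-affine local rearrangements and
detection noise of real microscopy. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
assumptions, not performance on raw microscopy.

## Problem sizes used in tests

The suite verifies the solver against a dense energy-minimization oracle
on grids up to 7×7, measures circle convergence at cell/diameter ratios
3–12 (up to 240² nodes), runs Monte-Carlo recovery studies with 100
replicates, and evaluates PIV on 256² movies and orientation histograms on
images up to 2048² (the isotropic-flatness check uses 80,000 fibres at the
same fibre density as 5,000 on 512², so the per-bin Monte-Carlo error sits
well below the 0.004 acceptance band).
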