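# Methods

## The model

`harlequin` simulates a two-species activator–inhibitor
(Gierer–Meinhardt-type) reaction–diffusion system for anthocyanin
pigmentation patterning on *Phalaenopsis* sepals/petals. The activator A
stands for the PeMYB11 regulatory system (transcription through
translation), the inhibitor H for the diffusible PeMYBx repressor system:

    dA/dt = G_A·A²/(H + k) + ρ_A + D_A·ΔA − μ_A·A
    dH/dt = G_H·A²                + D_H·ΔH − μ_H·H

on a periodic square domain with unit grid spacing. Concentrations are in
μM; time and space are treated as dimensionless (no physical time unit or
grid spacing is defined for this system, so none is invented). The three
interaction rules the equations encode: A self-activates (saturating in k,
repressed by H), A drives H production quadratically, and both decay
linearly. Patterns require the inhibitor to out-diffuse the activator
(D_H ≫ D_A); the `KineticParams` type enforces D_H ≥ D_A, with equality
permitted only so the no-pattern control can be constructed.

The standard coefficient set is
D_A=0.01, D_H=0.5, μ_A=μ_H=0.03, G_A=0.08, G_H=0.12, ρ_A=0.01, k=0.001.
Its homogeneous fixed point is (A*, H*) ≈ (0.99983, 3.99867) — found by a
bracketed scalar root solve on A after eliminating H = (G_H/μ_H)A², taking
the largest positive root (the upper branch) when several exist, and
verifying both reaction residuals below 1e-10.

Linear stability: perturbations ~exp(λt + iq·x) grow at the largest real
eigenvalue of [[f_A − D_A q², f_H], [g_A, g_H − D_H q²]], with the reaction
Jacobian evaluated analytically at the fixed point. The default wavenumber
grid is 200 points on [0, π] (grid units), which brackets the unstable
band for every scenario here. For the standard set the fastest-growing
mode is q ≈ 0.647, wavelength ≈ 9.7 grid units — which is why a 100×100
domain carries on the order of a hundred spots.

## Scenarios

Each biological hypothesis is one named preset perturbing the standard set:

| preset | change | interpretation |
|---|---|---|
| `standard` | — | wild-type spotting |
| `solo_ltr_2x` | G_A=0.1632 | solo-LTR promoter enhancement (~2×) |
| `tetraploid` | G_A=0.66 | the 2× value scaled ×4 for tetraploids |
| `yushan_expression` | G_A=2.712 | 33.9× expression ratio in purple tissue |
| `vc_high` / `vc_veryhigh` | G_A=7 / 70 | high-drive probes |
| `mir858_low` | μ_A=0.01 | reduced miR858 → slower activator decay |
| `combined_066` / `combined_2712` | both | drive + slow decay |
| `heterogeneous` | piece-wise G_A (7 / 0.0296), μ_A=0.01 | mixed solo-LTR / full-length tissue |

Presets store the literature's printed values verbatim (0.66, not the
exact product 0.6528); the scaling helpers `fold_scaled_GA` and
`ploidy_scaled_GA` themselves are exact.

For the heterogeneous preset the tissue layout is a binary mask (1 =
enhanced G_A_pur, 0 = repressed G_A_whi). The original assignment rule is
published only as a picture, so masks here are explicit synthetic
stand-ins: Bernoulli cells, rectangle unions, smoothed-noise "blobs"
(default; contiguous patches hitting a target cover fraction by quantile
thresholding), or a user CSV. Conclusions drawn from the heterogeneous
scenario are therefore property-level (patchy bimodal patterns, fusion),
never pixel-level.

## Numerics

*Stepping.* The default scheme is first-order IMEX: diffusion **and**
linear decay are inverted exactly in Fourier space (the periodic 5-point
Laplacian is diagonal there); the nonlinear reaction terms are explicit.
Folding decay into the implicit operator keeps the update stable at high
drive. A key property: the scheme's fixed points coincide with the PDE's
steady states for any dt, so step size affects the path, not the
attractor. Explicit Euler is provided as an independent reference scheme;
on matched runs the two converge to patterns whose 2 μM masks differ in
well under 2% of cells.

*Step control.* Default dt=0.1 with step-doubling adaptivity (relative
tolerance 1e-3 against the field scale, step capped at 50× the initial
dt). Adaptivity matters twice: the initial condition A ~ U(0,1), H = 0
makes G_A·A²/k enormous at t=0 (the solver drops to dt ~ 1e-3 for a few
steps), and the high-G_A scenarios are stiff throughout. The `vc_veryhigh`
(G_A=70) preset integrates correctly but slowly (hundreds of thousands of
accepted steps); no routine check simulates it.

*Stopping.* The study never states its stopping time, so integration stops
on a convergence criterion: max field change per unit time, relative to
(1 + max A), below `steady_tol`. The default tolerance is 1e-9 with a
time cap t_end=60000. The tolerance must sit well below the standard
scenario's Turing growth rate signature: the unstable mode grows at only
λ_max ≈ 8e-4, so a looser tolerance (e.g. 1e-6) declares convergence
while the pattern is still microscopic and returns a uniform field. Run
logs always report steps, final residual and the convergence flag.

*Positivity.* Concentrations are clamped at zero after each step
(default on); with it off, transient explicit overshoot can produce small
negative values that the reaction terms reject.

*Determinism.* All randomness flows through numpy's PCG64
(`np.random.default_rng`). A run seed is split via `SeedSequence.spawn`
into independent streams for the initial noise and the mask, so one seed
pins the whole run; identical seed + config gives bit-identical fields.

## Pattern metrics

* `threshold_mask`: strict `A > threshold`; the visualization threshold is
  2 μM. For piece-wise G_A runs an additional deep-layer threshold is the
  (G_A_whi/G_A_pur) proportion of max A, clamped from below at the basic
  2 μM — the clamp matters because for GA_whi/GA_pur = 0.0296/7 the
  proportion alone would fall below the basic layer.
* `label_spots`: connected components, 4-connectivity by default,
  merged across opposite edges to match the solver's periodic topology
  (8-connectivity and non-periodic labeling are flags). Verified against
  a brute-force BFS flood fill.
* Fusion index: largest spot area / total above-threshold area. It is
  dimensionless, equals 1 for a single fused patch, and is monotone under
  spot merging.
* In-phase check: Pearson correlation of the flattened A and H fields.
  The two species peak together in this model, so r is strongly positive
  (~0.9 on standard runs); "in-phase" is asserted as r > 0.5.
* Radial decay: per spot, cells are binned by torus distance from the
  spot's peak cell (rounded to integer rings); the score is the fraction
  of consecutive ring pairs with non-increasing mean A (ties count as
  non-increasing, so flat disks score 1), summarized as the median over
  spots.

## Test and acceptance problem sizes

Simulation-backed checks run on the study's 100×100 grid with a matched
panel of 5 seeds and compare medians; the scheme-equivalence check runs
both integrators on a 50×50 grid; labeling is cross-checked on 1,000
random 20×20 masks; the equal-diffusion collapse control uses a 32×32
grid. These sizes make the full suite and the acceptance script each run
in minutes on one core while leaving every claim seed-robust.

## Known limitations

* First-order time accuracy; trajectories (not attractors) carry O(dt)
  error. The study's object is the steady pattern, which is insensitive.
* Only G_A may vary in space; the other seven coefficients are uniform.
* The synthetic masks emulate patch statistics, not the real spatial
  distribution of retrotransposon insertions; no image-derived masks.
* The model has no three-species/MBW-complex extension and no petal
  geometry; the domain is a flat periodic square, which cannot reproduce
  boundary effects of a real sepal.
* Spot counts are stochastic in the initial noise; assertions use seed
  medians and generous bands, not exact counts.
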