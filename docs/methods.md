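# Model and methods

`cryptsim` is an off-lattice, individual-cell-based 3D model of a murine
small-intestinal crypt.  Cells are adhesive elastic spheres crawling on a
fixed triangulated basal-membrane (BM) network; curvature-coupled Wnt
signalling and contact-coupled Notch signalling drive a reversible lineage
state machine; proliferation, migration, terminal differentiation and cell
removal then produce the crypt's steady-state turnover, its clonal dynamics
and its response to signalling perturbations as emergent behaviour.  No
stem-cell population is imposed: "stemness" is a position in the
signalling landscape.

## Units

All internal quantities use one consistent system: length µm, force nN,
time h, energy nN·µm (= 1e-15 N·m), pressure nN/µm² (= kPa).  Literature
values (N·m, N·s/m, µN/m, days) are converted once in the parameter
defaults.

## Crypt surface and curvature

The BM is a surface of revolution about the z axis, junction at z = 0 and
closed base at z = -z0.  The profile is

    r(z) = r0 [1 - λ1(√(u+u0) - √u0) - λ2 u] √(1 - u^8),   u = -z/z0,

with u0 = 0.01 a slope regulariser at the mouth.  The taper factor narrows
the crypt from r0 = 60 µm at the junction to ≈ 0.65 r0 at the bottom; the
√-term is the flare into the villus junction and gives the upper crypt its
negative Gaussian curvature; the last factor closes the base with a wide
smooth cap.  The exponent 8 of the cap factor was chosen so that the
Gaussian curvature at the basal cap is ≈ 6e-4 /µm² (a ~40 µm cap radius),
≈ 4e-4 /µm² at the priming-threshold position z_p = -125 µm and ≈ 0 at
the differentiation-threshold position z_d = -87.5 µm, with the sign
change just above z_d — the curvature landmarks the Wnt-threshold logic
is calibrated to.  Setting λ1 = 0 yields the "simple" one-parameter shape
family used in shape sweeps.

Gaussian and mean curvature are computed analytically from the profile
(`K = -r''/(r(1+r'²)²)`); the discrete mesh is used only for mechanics.
Wnt activity is a monotone function f(z) of this curvature: it follows
K(z) from the base through the entire threshold region, plateaus below
the curvature maximum on the cap (which sits a few µm above the pole),
and is continued linearly with a small negative slope above the curvature
minimum in the flare.  The thresholds are TP_wnt = f(z_p) and
TD_wnt = f(z_d), so fate changes occur exactly when cells cross z_p or
z_d.

## Basal-membrane network

Knots are placed as a ring lattice on the surface: rings at near-equilateral
arc spacing (1.06·λ_MAX; the constant reproduces the reference
density of ~30,000 knots at λ_MAX = 1.25 µm for this surface area of
45,700 µm²), ring counts matched to the local circumference, seeded random
ring phases, zipper triangulation between rings and a fan-closed apex.
Every triangle inradius is far below the λ_MAX bound, the
coordination-number CV is < 0.05, knot count scales as 1/λ_MAX², and no
hole admits a minimal-radius cell.

A cell within one radius R of a knot interacts with it through a
truncated-shifted soft potential in y = ΩR/d,

    V = (ε_K / W) [y - 2√y - (Ω - 2√Ω)] t(d/R),

zero at d = R, minimum at the threshold distance ΩR (Ω = 0.95), weakly
adhesive above it, divergently (~1/d) repulsive below.  t is a C¹ taper
(smoothstep between (1+Ω)/2 and 1) and W = max(Σ t, 1) a smooth effective
knot count, so the total cell–BM coupling is insensitive to mesh density
(<10% change under mesh halving) while the discrete lattice exerts no
artificial force discontinuities.  The soft exponents keep the residual
tangential corrugation of the knot lattice (≈ 1-2 nN rms) well below the
cell migration forces; stiffer kernel exponents would pin slow cells on
the lattice.  Paneth(-lineage) cells anchor with ε_K = 35e-12 N·m, all
others with 5.5e-12 N·m.

## Cell mechanics

Pairwise cell–cell interactions: adhesion -ε_c·A with A the sphere-sphere
intersection-disc area; Hertz deformation energy
(8/15)E*√R_eff δ^(5/2) with 1/E* = 2(1-ν²)/E; and a compression penalty
K(V_a - V_t)²/(2V_t).  The actual volume V_a is the sphere clipped at the
radical plane of every contact and at the local BM tangent plane
(evaluated at the analytic surface foot point).  The bulk modulus is not
an experimentally tabulated parameter of this model family; it is set to K = 5 kPa — cells
resist volume change far more stiffly than shape change (the equivalent
isotropic Poisson ratio is ≈ 0.47).  At K = 1 kPa the Paneth migration
press compacts the niche below the contact-inhibition threshold and
homeostasis fails; 5 kPa is the smallest of the scanned values (1, 5, 10,
20 kPa) that sustains it.

All forces are exact negative gradients of the implemented energies
(verified against central differences in the test suite at every run).
Active migration adds a constant tangential force to cells in BM contact:
-7.5 nN (down the crypt) for Paneth-primed and Paneth cells, +4.5 nN (up)
for all other *primed* cells — progenitors and terminal
enterocytes/Goblets still inside the crypt.  Undifferentiated cells are
not primed and are passive by default (`f_a_undiff`, sweepable); giving
them the upward force empties the niche faster than it can divide and the
crypt dies deterministically.

Motion is overdamped and inertialess.  Each step solves the coupled
linear system

    (η_BM + Σ_j η_c A_ij) v_i - Σ_j η_c A_ij v_j = F_i

for all velocities in parallel (Jacobi-preconditioned conjugate
gradients), with a semi-implicit diagonal term dt·J_i — the positive
semidefinite part of the knot-force Jacobian — that makes the stiff
BM-normal mode unconditionally stable without touching tangential
(migratory) dynamics.  Radii relax analogously against η_VO with a scalar
stiffness bound.  The adaptive step keeps every displacement below
0.1·R_min and rejects (halving dt) any step that would push the closest
pair separation below 0.2(R_i+R_j) beyond its current value.

## Lineage state machine

I_notch is the sum of ligand weights LP over direct contacts
(d < R_i + R_j): 0.35 per Paneth or Paneth-primed neighbour, 1.00 per
Goblet or Goblet-progenitor neighbour, 0 otherwise.  Secretory
*progenitors* present ligand like their terminal types — lateral
inhibition needs the primed cells to signal, otherwise no mosaic pattern
can form.  Activities exactly at a threshold count as high, so a single
Goblet contact suffices for Notch activation.

The truth table: Wnt ≥ TP & Notch ≥ 1 → undifferentiated; Wnt ≥ TP &
Notch < 1 → Paneth-primed; TD ≤ Wnt < TP → enterocyte progenitor
(Notch ≥ 1) or Goblet progenitor (Notch < 1); Wnt < TD → terminal
enterocyte or Goblet by the same Notch branch.  All transitions among
non-terminal states are allowed; terminal states are absorbing.  A
Paneth-primed cell turns terminally Paneth when its running cell cycle
(if any) completes; terminal transitions of cycling cells likewise wait
for the cycle to finish.

The per-step state update is a *sequential* pass over the cells in a
seeded random order, each cell classified against the current states of
its neighbours.  A synchronous update makes adjacent low-Notch pairs
oscillate between Goblet-progenitor and enterocyte-progenitor forever (a
well-known artefact of lateral-inhibition rules); the sequential pass
resolves each pair into a stable ligand-presenter/receiver arrangement.

## Proliferation, division, removal

Growth is a chain of 50 stochastic volume increments with exponential
waiting times (doubling time ~ Γ(50, τ/50), mean τ = 14 h, CV ≈ 14%);
increments pause while the cell is contact-inhibited.  The inhibition
threshold is the absolute volume V_p = 0.88·V_0 (the tabulated
value; the alternative relative reading V_a < 0.88·V_t is available as a
config switch but arrests the crowded niche).  At V_t = 2V_0 the cell
divides into two daughters of target volume V_0, placed one daughter
radius apart along a seeded random BM-tangent direction and snapped to
their own equilibrium height above the membrane (a smaller daughter left
at the taller mother's height would be born outside its knot-interaction
range).  Daughters of proliferative mothers enter their first cycle at
birth unless born above z_d; this gives secretory-primed cells the
one-cycle reversibility window before terminal Paneth conversion.

Cells are removed at the crypt-villus junction (z > 0; the villus is not
modelled and the open boundary keeps the top of the crypt at zero
pressure), by anoikis when no knot is inside their interaction range, and
as terminal Paneth cells after the 57-day lifespan.

Every stochastic draw comes from a counter-based Philox stream keyed by
(master seed, cell id, draw counter), so trajectories are bit-reproducible,
replay exactly from checkpoints, and do not depend on iteration order.

## Initialisation

Cells are seeded as a monolayer slightly inside the knot-potential
minimum, from the base pole to the junction, with a greedy minimum-distance
filter where the inward offset makes rings converge.  Initial lineage
states use a positional heuristic with a randomly seeded secretory subset
per zone (a cold classify pass on a ligand-free lattice would prime every
basal cell for Paneth at once); the configured warm-up erases this
initial condition.  The packing is mechanically relaxed (no growth, no
migration) before the clock starts.

## What the simulations show — and known gaps

With the table parameter set the reference crypt self-organises into a
homeostatic state: turnover ≈ 2-3 days, spontaneous anoikis well below
5%/day, a persistent pool of ~25-35 undifferentiated cells intermingled
with Paneth cells at the base, progenitors migrating and differentiating
above z_d, monoclonal conversion on the multi-week timescale with the
winning clone descending from a basal undifferentiated founder, the four
constitutive Wnt/Notch perturbations reproducing the expected population
shifts, and recovery from single-subpopulation ablations within days.

Known quantitative gaps, all reproducible from the tests:

- **Basal compartment size.** The reconstructed profile carries a wide
  basal cap (the curvature landmarks pin it), so the region below z_p
  holds many more cells than the ~40 of the original fit; Paneth cells
  accumulate toward their lifespan-limited equilibrium (~130 at the
  reference scale).  Census-level compartment numbers should therefore be
  read as shape-dependent.
- **Cell-cycle dispersion.** Under the absolute contact-inhibition rule
  basal cells are rarely inhibited, so essentially all undifferentiated
  cells divide within 48 h and none stays quiescent beyond a week; the
  documented 94%/1% split requires a stronger inhibition coupling than
  this parameter reading produces.
- **De-differentiation rate.** Cells hovering at the z_p boundary flicker
  between progenitor and undifferentiated as mechanical jitter carries
  them across the threshold position, which inflates the counted
  transition rate (~0.03-0.05 per progenitor-day) above the ≤0.01
  steady-state figure.
- **Terminal Paneth persistence.** Terminal fates are irreversible and
  Paneth cells live ~57 days, so perturbation endpoints that demand their
  disappearance within 5 days (constitutive low Wnt, blocked Notch) retain
  the pre-existing Paneth population.
- **Slow census transient.** Because the Paneth pool equilibrates on the
  lifespan timescale, strict stationarity of the total census sets in
  only after ~8 simulated weeks; shorter windows show a slow upward
  drift while the Paneth pool fills.

The half-size test fixture (`mini_crypt`: z0 = 75 µm, r0 = 30 µm,
λ_MAX = 2.5 µm) places its fate thresholds at the same absolute curvature
landmarks as the reference (z_p = -50 µm, z_d = -35 µm) and shows the same
qualitative behaviour at ~110 cells, including monoclonal conversion in
~50 days; experiment timescales shorten roughly with crypt length.

## Problem sizes used

The packaged analyses run the reference crypt (~500-550 cells, ~30,000
knots) for 24 simulated days (10-day warm-up, 14-day measurement window),
the four perturbations for 5 days each, and the mini crypt for the
ablation (3 × 7 days per lineage) and clonal (30-60 days) experiments.
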