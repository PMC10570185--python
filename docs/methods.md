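# Methods

This note records the model class, discretisation, parameter choices and
design decisions behind rxdiff, and what the bundled validation problems do
and do not demonstrate.

## Model class and algebraic species

The solver advances systems of up to (in practice: any number of) coupled
unknowns on a rectangle, each unknown either differential,

    du_i/dt = sum_j div( D_ij grad u_j ) + f_i(u, grad u, x, y, t),

or algebraic — an explicit assignment recomputed from the other unknowns
whenever a right-hand side is evaluated.  Algebraic unknowns are ordered by
a topological sort of their dependency graph; cycles (including
self-reference) are rejected at validation.  They are the mechanism by which
higher-order spatial operators enter: a fourth-order term such as the
Swift–Hohenberg `(1+∇²)²u` or the Cahn–Hilliard `∇²(u³−u−γ∇²u)` is split
through an intermediate algebraic field, and KdV's third derivative becomes
`−v_xx` with `v = φ_x`.  Whether algebraic fields should be refreshed once
per step or at every integrator stage is a genuine choice; rxdiff refreshes
them at **every stage evaluation**, which is the consistent reduction to an
ODE system in the differential unknowns alone, at the cost of slightly more
work per step.

Kinetics may reference first and second unmixed derivative tokens of any
species.  Mixed derivatives are excluded from the token set and diagnosed
at validation.  Derivative tokens inside kinetics use central differences;
one-sided differences for upwinding are deliberately **explicit opt-in**
tokens (`u_x_b`, `u_x_f`, `u_y_b`, `u_y_f`) chosen by the model author,
because no automatic flow-direction rule is correct for every system (the
Klausmeier preset shows the pattern: water advecting downhill uses the
forward difference, the stable side for leftward characteristics under
forward Euler).

## Grid and boundary handling

One user step `dx` applies to both axes.  The domain splits into
`Nx = floor(Lx/dx)` by `Ny = floor(Ly/dx)` cells with **nodes at cell
centres** `x_i = (i + 1/2) dx_eff`, `dx_eff = Lx/Nx`.  Cell centres make
periodic wrap, masking and midpoint quadrature uniform, and place the
physical wall halfway between the boundary-adjacent node and its ghost.
Analytic comparisons in the tests depend on this placement (for instance
`cos(kπx/L)` is an exact discrete eigenvector of the masked Laplacian with
mirror ghosts, because the even reflection across a wall lands exactly on a
node).

One ghost layer per edge encodes boundary conditions:

* **periodic** — wrap (must be paired across the axis);
* **neumann / robin** with data `g` — `ghost = mirror + h·g`, with `g` the
  outward-normal derivative evaluated at the boundary-adjacent node.  Robin
  conditions are the same formula with `g` allowed to reference the species
  itself (evaluated on the current iterate; no linearisation is attempted),
  so robin generalises inhomogeneous Neumann.  With cell-centred nodes this
  one-ghost formula makes the discrete boundary flux exactly `D·g` per unit
  boundary, which the mass-balance test exercises.
* **dirichlet** — the boundary-adjacent node is pinned to the data value
  (re-evaluated at each new time for time-dependent data) and its time
  derivative forced to zero; the operators are untouched.  Because no node
  sits exactly on the wall, the imposed value converges to the wall
  condition at O(h) — a documented bias of the cell-centre layout.

Boundary data may depend on `x, y, t`, parameters and species values, so
time-dependent and inhomogeneous conditions are just expressions.

Non-rectangular domains are indicator subsets: a node is simulated iff the
indicator expression is positive at its coordinates.  Edges between a
simulated and an excluded node are handled by the same ghost mechanism as
the outer boundary and default to **zero flux** (the excluded neighbour's
value and diffusivity are replaced by the centre values, which cancels that
edge's flux term exactly).  Dirichlet data on internal mask boundaries is
not supported.  Derivative-based conditions on jagged indicator boundaries
should be interpreted with care; the mask models the geometry only to one
cell.

## Spatial operators

First derivatives: central `(F(x+h) − F(x−h))/2h`; upwind one-sided
first-order differences.  Second derivative: the standard three-point
stencil.  The divergence term uses, per axis,

    (1/2h²) { D_c [u_l − 2 u_c + u_r] + D_l [u_l − u_c] + D_r [u_r − u_c] },

algebraically identical to the conservative flux form
`Σ_nb (D_c+D_nb)/2 · (u_nb−u_c)/h²`; it reduces to `D` times the five-point
Laplacian for constant `D` and its periodic sum telescopes, so total mass
is conserved to rounding for any smooth positive `D(x,y,u)` (measured drift
≲ 1e−13 relative over 10⁴ steps; the suite asserts ≤ 1e−11).  Two numerical
details matter and are deliberate:

* the stencil is grouped as `D_c((u_l+u_r) − 2u_c) + (D_l(u_l−u_c) +
  D_r(u_r−u_c))`, which makes mirror-symmetric data produce **bitwise**
  mirror-symmetric results (floating-point addition commutes but does not
  associate);
* the coefficient field `D` is evaluated at nodes and padded by wrap on
  periodic edges and mirror reflection elsewhere — this fixes how
  `D(x±Δx)` is read in boundary-adjacent stencils, where the stencil
  formula alone leaves the extension open.

All arithmetic is double precision throughout.  (Single precision is a
GPU-texture constraint of browser implementations of this scheme family,
not a property of the method, and is not emulated here.)

## Time integration

Four explicit fixed-step schemes advance the method-of-lines system:
forward Euler; the midpoint method; two-step Adams–Bashforth with the first
step delegated to midpoint so second-order accuracy survives startup (the
history is cleared whenever dt or the scheme changes); and classical RK4.
Measured convergence orders on the heat-cosine problem, against the exact
solution of the space-discretised system so the fixed spatial error
cancels, are 1.000, 2.001, 1.999 and 4.035.

dt is never adapted.  A stability advisory `dt ≤ h²/(2·dim·Dmax)` (Dmax
estimated on the initial state) is logged as a warning but not enforced —
guidance, not a gate; it is deliberately diffusion-based and therefore
conservative-to-meaningless for wave-like systems, where the CFL number is
the relevant quantity.  Any non-finite value trips blow-up detection at the
step boundary and raises a "solution blew up at t=…" error carrying the
partial result; expression-level division by zero or `log` of non-positive
values therefore flow through as non-finite data rather than exceptions.

Runs are deterministic given the config (the `rand` symbol available to
initial conditions draws from a generator seeded by `config.seed` per
species).  Checkpoints store the full state plus the config hash and the
AB2 history, so restoring reproduces the continuation bit-identically.
Scheme switching mid-run is declarative (time segments in the config)
rather than interactive, to keep every run reproducible from the config
file alone.  Brush events (disc set/add, additive Gaussian) fire once when
their time is reached and also reset multistep history.

## Views, rendering, images, serialization

A view is an arbitrary expression over species, coordinates, time and
derivative tokens, evaluated on the current state; masked-out nodes are
flagged no-data and non-finite values render as a sentinel colour rather
than raising.  Adaptive scaling maps the frame min→0, max→1 with a flat
field sent to the midpoint; fixed scaling clamps.  Colormaps: viridis
(perceptually uniform, the default for accessibility), a diverging RdBu,
and a multi-hue "flame" map; 1D runs render as line plots.  The domain
integral uses midpoint quadrature `Σ f · dx_eff · dy_eff` over simulated
nodes, exact for the cell-centre layout's symmetries.

Uploaded rasters become spatial functions: Rec. 601 luminance
(0.299R + 0.587G + 0.114B) normalised to [0,1], sampled bilinearly with
border clamping; image x spans `[0,Lx]` and the top row maps to `y = Ly`
(y points up in the model, down in the raster) — both conventions are
choices and are fixed here.

Configs serialize to JSON (schema in `docs/config_format.md`) with unknown
keys rejected by name.  The `share` profile captures exactly what
reproduces the simulation from its specified initial conditions — it
excludes brush events and contains image *paths*, never pixels; the `full`
profile keeps everything and round-trips bit-identically.

## Validation problems and the synthetic generator

The analytic cases double as the test-data generator; no external data is
used anywhere.

* **Heat cosine** (`cos(kπx/L)`, insulated walls): exact decay
  `exp(−D(kπ/L)²t)`.  Default dt is half the explicit stability bound.
  Used for temporal-order sweeps (via the semidiscrete reference), the
  spatial-order residual and the terminal-error check (relative error
  6×10⁻⁶ at N=256).
* **d'Alembert pulse**: compact-support Gaussian (a 1e−12 floor is
  subtracted so the tails are exactly zero and cannot leak through
  periodic/Neumann seams), zero initial velocity; exact solution two
  half-amplitude copies at speed ±c, valid before boundary contact
  (L∞ error 0.035% of amplitude at N=512).
* **KdV solitons**: `φ = (c/2)sech²(√c/2(x−ct−x₀))` on a periodic interval
  wide enough that the seam tails are < 1e−8.  Default dt sits at half the
  RK4 imaginary-axis limit for the linearised dispersive operator
  (|λ|max ≈ 2.60/h³) plus an advective allowance.  One full transit
  preserves peak height to 0.22% and speed to 0.36%; a two-soliton
  collision restores both heights to 0.21%.  Explicit non-symplectic
  stepping cannot conserve this system's infinitely many invariants — the
  small drift is expected and measured, not hidden.
* **Noisy step image**: two-level step plus seeded Gaussian noise, written
  as PNG; feeds the Perona–Malik denoising check (total variation falls to
  ~7% of its initial value while the step height is retained to 99.9%).

Preset parameter values the upstream examples do not pin down are standard
literature formulations, chosen a priori by linear stability analysis where
patterning is the point (e.g. Gierer–Meinhardt with b=0.5, Du/Dv=0.02 —
Turing band k ∈ [1.04, 4.79] on a 40×40 domain; Brusselator a=2, b=3,
Dv/Du=10; Gray–Scott at Pearson's F=0.037, k=0.06 on a 2.5×2.5 domain at
dx=0.01, dt=0.5), each recorded in the preset's provenance note.  Timesteps
are set from the relevant explicit stability bound with a safety margin,
not tuned per run.

What the synthetic problems do **not** show: behaviour on experimental
data, non-smooth coefficients beyond indicator jumps, curved boundaries
resolved better than one cell, stiff kinetics that would demand implicit
integration, and long-time statistics of chaotic systems (the
Kuramoto–Sivashinsky and Klausmeier presets are asserted only to stay
bounded and non-trivial).

## Problem sizes

The test suite and the acceptance script size their runs to stay
interactive on a single CPU: convergence sweeps on N = 8–128 1D grids,
KdV at N = 512 (≈26k RK4 steps per transit), conservation on 16² for 10⁴
steps per scheme, Gray–Scott on 250² for 10⁴ steps, Gierer–Meinhardt on
100² to t = 50, Perona–Malik on 64².  These sizes are the package's chosen
study conditions; the solver itself has no hard-coded limits.

## Known limitations

* Explicit schemes only: stiff problems force small dt (Cahn–Hilliard's
  biharmonic term is the worst bundled case, dt = 2×10⁻⁶).
* Dirichlet data is imposed at cell centres (O(h) wall bias) and is not
  available on masked internal boundaries.
* No mixed spatial derivatives, no implicit or adaptive stepping, no
  symplectic integrators, no unstructured meshes.
* The expression language is numeric only: no user-defined functions, no
  symbolic simplification or automatic differentiation.
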