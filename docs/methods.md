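# Methods

`crossfeed` models a spatially structured community of two cell types
that modify each other's growth through short-range molecular exchange.
It has three layers: a biophysical layer that turns molecular parameters
into *local interaction rules*; an analytical layer (a pair
approximation on a directed graph) that turns local rules into
community-level steady states; and a stochastic lattice simulator that
realizes the same birth–replacement process exactly and serves as the
numerical check on the analytics.

## 1. Local rules from biophysics

A molecule leaks out of producer cells at rate `r_l`, diffuses with
coefficient `D` through a medium in which cells occupy volume fraction
`rho`, and is removed by uptake at rate `r_u`.  The distance over which
one cell's leakage affects another cell's growth — the interaction range
— is

    R = beta / (2 (1 - rho)) * sqrt( 2 D / (rho (2 + rho) (r_u + r_l)) )
        * ln( x + sqrt(x^2 + 4 x) + 4 ),        x = r_l / gamma

where `beta` is a dimensionless calibration constant and `gamma` is the
composite rate `2 mu_wt K / I_C` (Monod constant `K`, internal
concentration `I_C`).  The square root is the diffusion length scale, so
`R` is governed mainly by the ratio of uptake to diffusion; the
logarithmic factor in the leakage ratio `x` varies slowly and tends to
`ln 4` as leakage vanishes.  The maximum growth rate of a consumer
completely surrounded by producers,

    mu_hat = mu_wt * ( sqrt(x^2 + 2 x) - x ),

increases monotonically with the leakage rate and saturates at the
wild-type rate: a cross-fed cell can never outgrow a cell supplied
externally at saturation.  Per-type uptake/leakage rates are supported
through composite constants `theta` (growth) and `delta` (range) which
reduce exactly to `x` at equal rates; the unit tests assert these
reductions to machine precision over random parameter draws.

The neighborhood size `r` counts the cells inside the interaction range.
For a rod-shaped cell of length `l` and width `w` in a monolayer the
interaction zone is a stadium-shaped shell of width `R`, giving

    r_2D = [ 2 R (l - w) + pi (R + w/2)^2 - pi (w/2)^2 ] * rho_2D .

The 3D analog uses the shell around a spherocylinder; both formulas are
verified against rejection-sampling Monte-Carlo oracles (1% / 2%).
Because `r` grows like `R^2` in monolayers but `R^3` in 3D aggregates,
dimensionality alone changes the effective neighborhood size by orders
of magnitude at equal range.  Neighborhood sizes are kept continuous in
the analytical layer and rounded (half-up) only when a lattice
simulation is built from them.

`beta` and `gamma` have no package defaults: they are calibration
constants that must come from the user's configuration.

## 2. Pair approximation on a directed graph

Two types A and B fully occupy a regular directed graph at constant
total size.  Every A cell receives building blocks from `r_A` neighbors,
every B cell from `r_B >= r_A` (a labeling convention); unequal ranges
make the graph directed.  Growth is set by a per-type growth function of
the neighborhood composition; a reproducing cell is chosen
proportionally to growth rate and its offspring overwrites a uniformly
random cell in the replication neighborhood, taken equal to the smaller
interaction neighborhood (`r_R = r_A`).

The dynamics close on three variables — `P(A)`, `P(B|A, r_A)`,
`P(A|B, r_B)` — tracked through the four directed link counts
`N_{X<-Y}`.  Two event classes change them, with rates (frequency-linear
growth)

    T+ = P(A) p [1 + p (r_A - 1)] / r_A * mu_hat_A,        p = P(B|A, r_A)
    T- = P(B) s [1 + s (r_B - 1)] / r_B * mu_hat_B * kappa, s = P(A|B, r_B)

where the bracketed factor is the growth-weighted composition of the
reproducer's neighborhood (neighbors treated as i.i.d. given the
conditional frequency) and `kappa` is the probability that the replaced
partner lies inside the smaller replication neighborhood.  The link
bookkeeping vectors `Delta±` re-type the replaced cell's in-links and
the links of every cell that received from it, with the reproducing
parent counted as one known neighbor of the replaced cell.

**Cross-range closure.**  The bookkeeping needs conditionals at a type's
non-native range (`P(A|B, r_A)`, `P(B|A, r_B)`).  We close them with the
local-to-global law

    P(partner | focal, r) = g(r) * P(partner),   g(r) = (r - 2)/(r - 1),

anchored on the *global* composition, and correspondingly `kappa =
g(r_A) P(A) / P(A|B, r_B)`.  This is the step where a design choice was
genuinely open.  Two alternatives fail structurally: taking the
cross-range conditionals equal to the native ones (`kappa = 1`) gives an
ODE whose fixed point contradicts the closed-form equilibrium below, and
scaling the conditionals off each other (`P(A|B,r_A) = P(A|B,r_B)
g(r_A)/g(r_B)`) collapses the two independent structure equations into
one, leaving a line of fixed points.  The global-frequency anchoring is
self-consistent at steady state, makes the interior fixed point unique,
and leaves it locally stable everywhere we tested.

**Steady states.**  Setting the link derivatives to zero yields, for
frequency-linear growth,

    P(A)* = [ mu_A (r_A-2)/r_A + mu_A/r_A - mu_B/r_B ]
            / [ mu_A (r_A-2)/r_A + mu_B (r_B-2)/r_B ] ,

which tends to the well-mixed equilibrium `mu_A/(mu_A+mu_B)` for large
neighborhoods (the gap is below one percentage point from r = 100), and
the universal local-structure law `P(B|A,r_A)/P(B) = g(r_A)`,
`P(A|B,r_B)/P(A) = g(r_B)`.  The law is growth-model independent because
the bookkeeping vectors do not involve the growth functions; at `r = 3`
a cell sees only half the partner frequency the global composition
suggests.  Values of `P(A)*` outside (0, 1) mean one type fixes; for
cross-feeders fixation stops all turnover (community collapse,
productivity zero).  Coexistence requires the growth-rate ratio to lie
in the open interval `( r_A / (r_B (r_A-1)),  r_A (r_B-1) / r_B )` —
(1/2, 2) at `r_A = r_B = 3`, widening without bound as neighborhoods
grow: spatial structure destabilizes asymmetric mutualisms.

**Productivity.**  Community productivity is the mean birth rate
`P(A) mu_A P(B|A) + P(B) mu_B P(A|B)` at equilibrium.  The well-mixed
reference evaluates the growth functions at global composition with its
own equilibrium (for frequency-linear growth this is exactly the
well-mixed closed form).  Clustering always depresses cross-feeding
productivity (ratio <= 1) and always helps under mutual inhibition
(ratio >= 1).

**Other growth models.**  Density-linear growth (rate `mu_hat` per
partner cell in range) and inhibition-linear growth reuse the same
bookkeeping with their own growth-weighting factors; their equilibria
solve the scalar balance `T+ = T-` on the local-structure manifold by
bracketed root-finding (Brent, bracket `(1e-9, 1 - 1e-9)`).  For the
density model the balance point is controlled by the product
`mu_hat * r`; exactly equal products give `P(A) = 1/2`.  Custom growth
functions are supported through binomial expectations over the
neighborhood composition (requiring integer `r`).  When several balance
roots exist (mutual inhibition is bistable around its interior balance
point), the root closest to the frequency reached by integration from a
50:50 start is reported.

**Numerics.**  The link ODE is integrated with LSODA at rtol 1e-8 /
atol 1e-10 on the three independent coordinates, with the fourth count
reconstructed from the in-degree identities; terminal events stop the
integration at effective fixation (either frequency within 1e-9 of a
boundary) or at equilibrium (max |dN/dt|/N < 1e-9).  Known limitation:
for strong asymmetry near the collapse boundary (e.g. ratio 3 at
`r_A = r_B = 5`) the interior equilibrium is locally stable but its
basin excludes generic initial conditions — deterministic trajectories
overshoot into fixation, as the stochastic lattice also tends to do
there.  At the cross-feeding community parameterization used throughout
(ratio 0.22/0.78, r 10/130) all tested starts converge to the closed
form within 1e-4.

## 3. Lattice simulation

The simulator realizes the same process with no moment closure: cells
on a periodic square lattice (default 100×100, the only implemented
boundary condition), per-type extended Moore interaction ranges `d_A`,
`d_B` (neighborhood size `(2d+1)^2 - 1`), replication range `d_R =
min(d_A, d_B)` by default.  One event = one replacement: a reproducer is
drawn proportionally to growth rate (rejection sampling against the
per-model maximum rate, O(1) amortized per event), and a uniformly
random site in its replication neighborhood takes its type — including
same-type sites, which consume the event without changing composition.
Partner counts are cached per range and updated incrementally over the
affected window at each flip, so a 100,000-event replicate runs in
seconds.  Runs are bit-reproducible from `(config, seed)`
(`numpy.random.default_rng`); fixation terminates a run early with an
absorbed flag.

The simulator validates the analytics: at the community
parameterization (ranges 1 and 5, ratio 0.22/0.78) twenty 100,000-event
replicates give a mean equilibrium frequency near 0.19 for the
small-range type against the closed form's 0.20; across growth-rate
ratios in [0.5, 2] in the same directed geometry the closed form tracks
the ensemble mean within 3 percentage points.  Agreement degrades with
symmetric *small* neighborhoods at the edges of that ratio range
(r = 8 on both sides: gap ≈ 3 pp), the known regime where pair closures
strain.  A "time step" is interpreted as one replacement event
throughout.

## 4. Observables and the randomization experiment

Snapshot statistics compute the global frequency (count fraction), the
mean local partner frequency around each focal type at that type's own
range (reported as NaN, never silently zero, when the focal type is
absent), and the community mean growth rate under the configured growth
model.  The clustered-vs-randomized experiment compares a snapshot's
mean growth rate with the average over 20 label permutations that
preserve composition exactly; values below one quantify how much
clustering costs a cross-feeding community (about one for unstructured
lattices, above one under mutual inhibition).  The lattice growth
function plays the role of the single-cell growth predictor here;
synthetic fixture lattices (random, checkerboard, striped, patchy by
nearest-seed growth) give every observable a ground-truth-computable
input.

What the lattice does *not* emulate about real communities: cells are
uniform unit squares (no size variation, so count-based and area-based
frequency estimates coincide), replacement stands in for growth with
pushing, population size is strictly constant, and molecular transport
is collapsed into fixed interaction ranges rather than resolved
concentration fields.  Passing tests therefore demonstrate internal
consistency of the three layers and reproduction of the model-side
predictions, not quantitative accuracy for any particular experimental
system.

## 5. Problem sizes

The test suite and the acceptance script use 100×100 lattices with
100,000–300,000 events and 4–20 replicates per configuration, 60×60 or
smaller for auxiliary property checks, Monte-Carlo geometry oracles at
10^6 samples, and closed-form evaluations on grids of ≈40 ratio points.
These sizes put replicate standard errors on equilibrium frequencies
near 0.002, comfortably inside the tolerances asserted.
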