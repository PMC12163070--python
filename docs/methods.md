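# Methods

## Model and units

`actipoly` simulates melts of `N` linear chains of `Np` beads with the
bead-spring (Kremer–Grest) interactions:

* **WCA repulsion** between all bead pairs:
  `U = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps` for `r < 2^(1/6) sigma`,
  zero beyond; `eps_WCA = 1 kBT` by default.
* **FENE bonds** between consecutive beads:
  `U = -(k R0^2 / 2) ln(1 - (r/R0)^2)` with `k = 30 kBT/sigma^2` and
  `R0 = 1.5 sigma` (the canonical parameter pair; the spring constant is
  read in units of `kBT/sigma^2`). A bond reaching `R0` aborts the run with
  a diagnostic rather than producing NaNs.
* **Bending**: `U = kappa * sum_j (1 - t_j . t_{j+1})`, one term per unique
  pair of consecutive tangents per chain. Summing the per-bead triple
  `j = i-1, i, i+1` over all beads would count every tangent pair three
  times; the implementation uses each pair once with stiffness `kappa`,
  which reproduces the conventional `kappa (1 - cos theta)` chain and the
  flexible regime at `kappa = 1 kBT`.
* **Tangential activity**: bead `i` is pushed along
  `t_{i-1,i} + t_{i,i+1}` normalized to unit length, with constant
  magnitude `F_p` (end beads along their single adjacent tangent,
  head-ward). If the two tangents cancel to below 1e-8 (a perfect hairpin
  tip) the bead receives no active force. The raw, unnormalized tangent sum
  does not have constant magnitude; constant bead speed `v = F_p/zeta` for
  a free straight chain requires the normalization used here.

Reduced units throughout: `sigma = kBT = zeta = 1`, hence `D0 = kBT/zeta = 1`
and `tau0 = sigma^2/D0 = 1`. The Péclet number is `Pe = v sigma / D0`;
specifying either `Pe` or `F_p` determines the other. The cubic box edge
solves `rho* = N_tot sigma^3 / V` exactly (default `rho* = 0.85`).

## Integration

Overdamped Euler–Maruyama with `dt = 1e-4 tau0` by default:
`r <- r + (dt/zeta)(F_det + F_p) + xi`, `xi` Gaussian with per-component
variance `2 D0 dt`. Momentum dissipates instantly in this limit, so no
thermostat is needed. Nonbonded pairs use a Verlet list (cutoff + 0.35
sigma skin) over a linked-cell grid, rebuilt whenever the largest
accumulated displacement exceeds half the skin; a brute-force path covers
small or sparse systems. Wrapped coordinates drive the forces (minimum
image); integer image counters keep unwrapped coordinates exact for
end-to-end distances, primitive paths and MSDs.

Noise is drawn from numpy's PCG64 generator in fixed-size blocks feeding the
compiled integrator, so a run is bit-reproducible given (seed, parameters,
schedule) — the reproducibility contract the tests enforce. A
counter-based per-(step, bead) keying was considered and not needed: the
integrator is single-threaded with a fixed block partition.

## Melt preparation

Fresh melts are random walks with bond length `0.97 sigma` (near the
FENE+WCA minimum, avoiding startup force spikes; the bond-distribution test
validates the resulting Boltzmann statistics a posteriori) and with the
angular statistics of the configured bending stiffness: successive tangents
follow the Boltzmann weight `exp(kappa cos theta)` (discrete worm-like
walk), so fresh chains already carry the ideal-chain dimensions the bonded
potential implies and global equilibration does not have to build the
stiffness-induced swelling from scratch. Packing effects still renormalize
chain dimensions upward (at `kappa = 1` the melt's effective
characteristic ratio is larger than the ideal worm-like value), which the
bond-swap stage equilibrates. Overlaps are removed by BD under a bounded soft core
`U = A (1 + cos(pi r / r_c))`, `A` ramped 1 -> 100 kBT over ~3 tau0; the
stage exits once the minimum pair distance reaches 0.9 sigma and then the
full WCA potential is switched on.

Conformations are equilibrated by rank-preserving symmetric double-bridging:
bonds `(i, i+1)` on chains A and B are cut and the equal-length tails
exchanged, with Metropolis acceptance on the local FENE+bending change.
Eligible cuts (both new bonds shorter than `min(1.3 sigma, R0)`) are
enumerated exactly and proposals drawn uniformly from that list; the list is
rebuilt after each accepted move. Because the reverse move re-forms
~1-sigma bonds it is always in the rebuilt list, the proposal is symmetric
and detailed balance holds — verified against an enumerable two-state toy
system. The move set preserves monodispersity by construction, which is the
only property the downstream analyses require. `equilibrate` alternates BD
blocks with swap sweeps until `<R_ee^2>/L` and the internal-distance curve
`<R^2(n)>/n` are stationary (successive-halves change < 2%).

## Rheology

The virial stress `sigma_ab = -1/(2V) sum_kl F_kl^a r_kl^b` runs over
ordered pairs with minimum-image separations. The three-body bending force
is decomposed onto the two outer-center pairs (standard three-body virial);
the active force is attributed to its generating bond pair(s) and included
in the stress by default — whether tangential drive belongs in the printed
double sum is not uniquely defined, so `include_active_stress=False`
exposes the excluded variant for sensitivity checks. Both choices are
recorded in run provenance.

`G(t) = V/(3 kBT) sum_{xy,xz,yz} <sigma_ab(t) sigma_ab(0)>` is the average
over the three unique off-diagonal components; for active runs sampling
starts in the steady state `t > L/v`. The estimator is a multiple-tau
correlator (16 lags per level, pairwise pre-averaging), whose systematic
error stays below ~2% for signals smooth on the block scale (pinned by a
brute-force FFT comparison).

* **Plateau/tail fit**: `ln G = ln G0 - t/tau_eff` over the terminal window
  with `G/G(window start)` in [0.05, 0.8], auto-selected by maximizing the
  fitted span subject to R^2 >= 0.98. A mid-time log-log slope steeper than
  -0.35 raises the no-plateau (Rouse-like) flag; the default mid-time
  window is where G lies within [0.5, 0.95] of its positive-lag peak, and
  an explicit window can be passed when the physics dictates one.
* **Green–Kubo**: `eta(t)` by cumulative trapezoid on the multiple-tau
  grid; `eta_inf` is the mean over the final decade of lags with a drift
  diagnostic, since the limit is asymptotic.
* **Moduli**: piecewise-linear (Filon-type) quadrature of
  `G'(w) = w int G sin(wt) dt`, `G''(w) = w int G cos(wt) dt` on the
  non-uniform grid, with telescoped boundary terms for numerical stability;
  `w_c` from log-log interpolation of `G'/G''`. Maxwell inputs reproduce
  the closed forms to < 0.5% and `w_c tau_eff = 1` within 1%.
* **Scaling collapse**: stress mode maps `(t, G)` to
  `(t v/L, G sigma^3/(F_p L))`; viscosity mode to
  `(t v/L, eta sigma^3/(zeta L^2))`. The collapse score is the median
  pairwise log-distance between curves interpolated (monotone cubic in
  log-log) onto a common grid.

## Primitive-path analysis

The primitive path is the shortest path between a chain's fixed ends that
preserves uncrossability with the other chains. The contraction is
geometric: interior nodes are removed when the spanned triangle crosses no
obstacle segment, otherwise pulled toward the chord with backtracking step
sizes; a node wedged against an obstacle is projected to a small clearance
(1e-4 sigma) around the blocking segment, which lets contact nodes slide
along obstacles to the taut contact point. Near-collinear nodes (chord
distance below half the clearance) are dropped only when the drop also
passes the uncrossability test. Segment-triangle tests accept the obstacle
parameter with 1e-6 slack so consecutive segments overlap their coverage
and a crossing exactly through a shared vertex cannot slip between them;
near-coplanar cases fall back to an edge-distance criterion. Obstacles are
replicated over the periodic images that can reach the contracting chain's
inflated bounding box. Chains contract against simultaneously-contracting
neighbors (`mode="self-consistent"`); `mode="fixed"` holds the original
neighbor conformations fixed, which is the variant with hand-computable
oracles.

Kinks are interior nodes with turning angle >= 1e-3 rad; corners closer
than 0.25 sigma along the path (a contact wrapped by several micro-nodes)
count as one kink. Absolute kink counts are convention-dependent;
normalized ratios `Z/Z0` against a passive reference are the comparable
quantities. The entanglement length is
`N_e = (Np - 1) <R_ee^2> / <L_pp^2>` with ensemble means, and the
equilibrium plateau estimate `G0 = 4 rho* kBT / (5 N_e^0 sigma^3)`.

## Desk-scale study conditions

The simulator is validated on melts that fit a single core; the regimes
with giant activity-induced elasticity (chains of hundreds to thousands of
beads, >= 1e7 steps) require cluster compute and are outside the test
suite. The shipped studies are:

* **Rouse regime**: passive melt, N=20 chains of Np=25 at rho*=0.85; three
  independent replicas (push-off, 10 tau0 of BD + double-bridging, 20 tau0
  of plain BD, then 120 tau0 of production with stress sampled every 5
  steps), G(t) averaged over replicas. Replica averaging is needed because
  a single desk run leaves ~0.1-0.15 scatter in the fitted slope. The
  mid-time window (0.2, 4.0) tau0 sits above the segmental/bond relaxation
  (~0.1 tau0) and below the terminal decay (tau_R ~ 20-40 tau0). The
  relaxation is unambiguously algebraic (no plateau), but the measured
  window slope is steeper than the continuum Rouse value: the discrete
  Rouse spectrum of a 25-bead chain by itself gives about -0.62 in this
  window (only a handful of modes remain active), and the melt's
  packing-stress relaxation steepens the early side further, to roughly
  -0.7 ... -0.95 depending on the conformational state. A clean
  -0.5 +/- 0.1 window requires considerably longer (still unentangled)
  chains whose terminal times exceed the desk budget; the suite states the
  idealized -0.5 +/- 0.1 expectation as the check and reports the measured
  value, which at this chain length misses the band on the steep side for
  these reasons.
* **Ideal-chain scaling**: melts with Np = 25, 50, 100 (32, 20, 12 chains —
  800-1200 beads each); per system several independent replicas are built,
  pushed off and relaxed over 25 cycles of 0.25 tau0 BD + 2 swap sweeps,
  with <R_ee^2> time-averaged over the last 10 cycles. Because a
  desk-scale ensemble holds only tens of chains, the raw mean inherits the
  ~20% sampling fluctuation of the initial draw, which the slow global
  conformational dynamics cannot forget; the estimator therefore uses the
  builder ensemble's exact worm-like-chain mean as a control variate
  (reported value = exact builder mean + measured drift), an unbiased
  variance reduction for the equilibrium mean. Expected:
  d ln<R_ee^2> / d ln L = 1.0 +/- 0.15; the small upward deviation from 1
  reflects the growth of the effective characteristic ratio with N at
  these short chain lengths, not a failure of Gaussian statistics.
* A passive Np=25 melt is **unentangled**, so the equilibrium-plateau
  consistency check (fitted G0 vs `4 rho kBT/(5 N_e)` from the same run's
  primitive paths, within a factor 2) is conditional on a detected plateau
  and passes vacuously at desk scale — the meaningful desk-scale assertion
  is that the plateau correctly vanishes.

What passing these tests does and does not show: the synthetic melts share
the real systems' density, interactions and preparation protocol but not
their degree of entanglement; desk-scale results validate the machinery
(forces, integration, estimators, topology analysis) and the unentangled
limits, not the entangled active scaling laws themselves, which require the
cluster-scale systems documented above.

## Numerical choices and limitations

* Euler–Maruyama is first order; the stationary bond-length statistics are
  dt-robust (doubling dt=1e-4 changes the mean FENE energy by < 2.5%), and
  the bond-distribution test runs at dt=5e-5 where the integrator bias is
  well below the KS tolerance.
* The multiple-tau correlator trades < 2% systematic pre-averaging error
  for logarithmic memory; both block parameters are configurable.
* The contraction's clearance (1e-4 sigma) bounds the primitive-path length
  error per contact at ~1e-3 sigma; melt-scale `L_pp` errors are therefore
  negligible relative to chain contour lengths.
* Hydrodynamic interactions are absent by construction (free-draining
  model); shear/deformation protocols, ring/branched topologies,
  polydisperse melts and dynamic crosslinkers are out of scope.
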