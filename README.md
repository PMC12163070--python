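# actipoly

Brownian-dynamics simulation and viscoelastic analysis of **tangentially
self-propelled, entangled polymer melts**.

Active polymer systems — treadmilling cytoskeletal filaments, growing
filamentous microbes, entangled worm blobs, soft robotic filament grippers —
are driven along their own contour and far from equilibrium. In dense,
highly entangled solutions this tangential drive changes the viscoelastic
response qualitatively: the stress plateau (elasticity) is set by the active
energy scale `F_p L` instead of the entanglement density, and the terminal
relaxation is ballistic tube escape, `tau_eff ~ L/v`, instead of reptation's
`~ L^3`. `actipoly` implements the full methodology needed to study this at
coarse-grained resolution:

* **Model.** Kremer–Grest bead-spring chains: WCA repulsion
  (`eps_WCA = 1 kBT`, cutoff `2^(1/6) sigma`), FENE bonds
  (`k = 30 kBT/sigma^2`, `R0 = 1.5 sigma`), bending
  `U = kappa * sum_j (1 - t_j . t_{j+1})`, and a tangential active force of
  constant magnitude `F_p` per bead along the local contour direction, so a
  free bead moves at `v = F_p / zeta` and `Pe = v sigma / D0`.
* **Dynamics.** Overdamped (free-draining) Langevin equation,
  `zeta dr/dt = -grad U + F_p + F_r`, with
  `<F_r F_r> = 2 kBT zeta delta(t - t')`, integrated by Euler–Maruyama in a
  cubic periodic box at reduced density `rho* = N_tot sigma^3 / V = 0.85`.
* **Preparation.** Capped-cosine soft push-off removes overlaps of fresh
  random-walk melts; rank-preserving double-bridging Monte Carlo (tails of
  equal length exchanged between chains with Metropolis acceptance)
  equilibrates large-scale conformations far faster than reptation.
* **Rheology.** Virial stress `sigma_ab = -1/(2V) sum_kl F_kl^a r_kl^b`
  sampled on the fly; stress relaxation modulus
  `G(t) = V/(3 kBT) * sum_{xy,xz,yz} <sigma_ab(t) sigma_ab(0)>` via a
  multiple-tau correlator; plateau modulus `G0` and disengagement time
  `tau_eff` from the exponential tail; Green–Kubo running viscosity
  `eta(t) = int_0^t G dt'`; dynamic moduli `G'(w)`, `G''(w)` by Filon-type
  Fourier transform, with the crossover `w_c ~ 1/tau_eff`; the
  activity rescalings `G sigma^3/(F_p L)` vs `t v/L` and
  `eta sigma^3/(zeta L^2)` vs `t v/L` with a collapse-quality score; and the
  interpolation `tau_eff = 1/(D0 sigma/L^3 + v/L)`.
* **Topology.** Geometric primitive-path contraction (shortest end-fixed
  path preserving uncrossability, Z1-style), kink counts `Z`, and the
  entanglement length `N_e = (Np - 1) <R_ee^2> / <L_pp^2>`, plus the
  equilibrium plateau prediction `G0 ~ 4 rho kBT / (5 N_e)`.

See `docs/methods.md` for the modelling choices, numerical parameters and
limitations.

## Worked example

Build, equilibrate, run and analyze a small passive melt from Python:

```python
import actipoly as ap
from actipoly.equilibration import soft_pushoff
from actipoly import rheology

p = ap.SimulationParameters(N=20, Np=25, rho_star=0.85, seed=1)
cfg = ap.build_random_melt(p)
cfg = soft_pushoff(cfg, p)                      # remove overlaps
cfg.time = 0.0
sch = ap.RunSchedule(n_steps=1_200_000, sample_stride_stress=5)
res = ap.run(cfg, p, sch, seed=2)               # ~2 min on one core
corr = rheology.accumulate_g(res.stress)
fit = rheology.fit_plateau_and_tau(corr, midtime_window=(0.2, 4.0))
print(f"mid-time log-log slope of G(t): {fit.midtime_slope:.2f}")
print(f"no-plateau (Rouse-like) flag:   {fit.no_plateau}")
```

Typical output for this unentangled passive melt:

```
mid-time log-log slope of G(t): -0.66
no-plateau (Rouse-like) flag:   True
```

i.e. the stress relaxes algebraically — there is no elastic plateau, the
Rouse-like signature of unentangled chains. (The slope is steeper than the
continuum Rouse value `-1/2` because a 25-bead chain keeps only a handful
of active Rouse modes in this window; see `docs/methods.md`. Replica
averaging, as done in `scripts/acceptance.py`, tightens the estimate.)
The closed-form side of the analysis is instant:

```python
rheology.tau_eff_prediction(L=100.0, v=8.0)     # -> 12.4998 tau0
rheology.tau_eff_prediction(L=100.0, v=0.0)     # -> 1e6 tau0 (passive L^3)
```

The same workflow is available from the shell:

```bash
actipoly pipeline --config run.toml --out-dir out --seed 7
```

which chains build → push-off → equilibrate → production → rheology/PPA
analysis and writes a manifest with seeds and artifact checksums.

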