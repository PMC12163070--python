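"""Melt preparation: capped-repulsion push-off and bond-swap Monte Carlo.

Fresh random-walk melts contain hard-core overlaps.  :func:`soft_pushoff`
removes them by integrating under a bounded cosine repulsion whose amplitude
is ramped up, after which the full WCA interaction can be switched on safely.
Large-scale conformations are then equilibrated by rank-preserving symmetric
double-bridging (:func:`bond_swap_sweep`): tails of equal length are exchanged
between two chains whose cut points are close in space, with Metropolis
acceptance on the local bonded-energy change.  The move set preserves the
chain-length distribution exactly, and its eligibility sets are invariant
under the move, so the proposal is symmetric and detailed balance holds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import _kernels
from .forcefield import fene_energy
from .system_model import PolymerConfiguration, SimulationParameters

__all__ = [
    "PushoffError",
    "SwapMove",
    "EquilibrationProtocol",
    "soft_pushoff",
    "bond_swap_sweep",
    "internal_distance_curve",
    "equilibrate",
]


class PushoffError(RuntimeError):
    """Push-off failed to reach the minimum-distance criterion."""


@dataclasses.dataclass
class SwapMove:
    """Record of one attempted double-bridging move."""

    chain_a: int
    chain_b: int
    rank: int
    delta_u: float
    accepted: bool


def soft_pushoff(
    config: PolymerConfiguration,
    params: SimulationParameters,
    ramp_steps: int = 30_000,
    a_start: float = 1.0,
    a_end: float = 100.0,
    seed: int | None = None,
    min_distance: float = 0.9,
    extra_blocks: int = 6,
    extra_block_steps: int = 5_000,
) -> PolymerConfiguration:
    """BD under the capped repulsion ``U = A (1 + cos(pi r/r_c))``, A ramped up.

    The amplitude ramps linearly from ``a_start`` (~1 kBT, overlaps cost
    little) to ``a_end`` (~100 kBT, effectively hard), FENE bonds and bending
    stay on.  Exits once the minimum pair distance reaches ``min_distance``;
    raises :class:`PushoffError` with diagnostics if the criterion is still
    unmet after ``extra_blocks`` additional full-amplitude blocks.
    """
    from .bd_engine import SimulationUnstableError, _drive

    cfg = config.copy()
    seed32 = int((params.seed if seed is None else seed) & 0x7FFFFFFF)
    rng = np.random.default_rng(seed32)
    try:
        _drive(
            cfg, params, ramp_steps, rng, use_soft=True,
            soft_a0=a_start, soft_a1=a_end, ramp_total=ramp_steps,
            Fp_override=0.0,
        )
        for _ in range(extra_blocks):
            dmin = _kernels.min_pair_distance(cfg.positions, cfg.box_edge)
            if dmin >= min_distance:
                break
            _drive(
                cfg, params, extra_block_steps, rng, use_soft=True,
                soft_a0=a_end, soft_a1=a_end, ramp_total=0,
                Fp_override=0.0,
            )
    except SimulationUnstableError as exc:
        raise PushoffError(f"push-off unstable: {exc}") from exc
    dmin = _kernels.min_pair_distance(cfg.positions, cfg.box_edge)
    if dmin < min_distance:
        raise PushoffError(
            f"minimum pair distance {dmin:.4g} < {min_distance} after ramp"
        )
    cfg.time = config.time + ramp_steps * params.dt
    return cfg


# ----------------------------------------------------------------- bond swaps
def _local_bonded_energy(X: np.ndarray, Y: np.ndarray, rank: int, params,
                         box: float) -> float:
    """FENE + bending energy of the terms touching bond (rank, rank+1).

    ``X`` and ``Y`` are the two full chains (wrapped coordinates); bonded
    geometry uses minimum-image differences.
    """

    def mi(d):
        return d - box * np.rint(d / box)

    e = 0.0
    for C in (X, Y):
        Np = len(C)
        i = rank
        e += fene_energy(
            float(np.linalg.norm(mi(C[i + 1] - C[i]))), params.eps_fene, params.R0
        )
        if params.kappa != 0.0:
            for j in (i - 1, i + 1):
                if 0 < j < Np - 1:
                    u = mi(C[j] - C[j - 1])
                    v = mi(C[j + 1] - C[j])
                    cth = float(
                        u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    )
                    e += params.kappa * (1.0 - cth)
            j = i  # the joint at the cut bead itself
            if 0 < j < Np - 1:
                u = mi(C[j] - C[j - 1])
                v = mi(C[j + 1] - C[j])
                cth = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
                e += params.kappa * (1.0 - cth)
    return e


def bond_swap_sweep(
    config: PolymerConfiguration,
    params: SimulationParameters,
    rng: np.random.Generator,
    temperature: float | None = None,
    eligibility_radius: float = 1.3,
    attempts: int | None = None,
    collect_moves: bool = False,
) -> tuple[PolymerConfiguration, float] | tuple[PolymerConfiguration, float, list]:
    """One sweep (= N_tot attempts by default) of double-bridging moves.

    A move cuts bond (i, i+1) on chain A and bond (i, i+1) on chain B and
    reconnects A_i - B_{i+1} and B_i - A_{i+1}, exchanging the two equal-length
    tails; monodispersity is preserved by construction.  Proposals whose new
    bonds would reach R0 are auto-rejected (FENE domain); otherwise the move is
    accepted with probability ``min(1, exp(-dU/kBT))`` where dU collects the
    FENE and bending terms touching the cut.  The configuration is modified in
    place; returns ``(config, acceptance_fraction)``.
    """
    kT = params.kBT if temperature is None else temperature
    N, Np = config.n_chains, config.beads_per_chain
    box = config.box_edge
    n_att = attempts if attempts is not None else config.n_beads
    pos = config.positions.reshape(N, Np, 3)
    img = config.images.reshape(N, Np, 3)
    accepted = 0
    moves: list[SwapMove] = []
    if N < 2:
        return (config, 0.0, moves) if collect_moves else (config, 0.0)

    def mi(d):
        return d - box * np.rint(d / box)

    # Enumerate every eligible cut (a, b, i): proposals are drawn uniformly
    # from this list, which is rebuilt after each accepted move (a tail swap
    # permutes which coordinates sit at a given (chain, rank) slot).  The
    # reverse of an accepted move re-forms the original ~1-sigma bonds and is
    # therefore always present in the rebuilt list, keeping the proposal
    # symmetric.
    rcut = min(eligibility_radius, params.R0)

    def build_eligible() -> list[tuple[int, int, int]]:
        out: list[tuple[int, int, int]] = []
        for i in range(Np - 1):
            d1 = mi(pos[:, None, i, :] - pos[None, :, i + 1, :])  # A_i - B_{i+1}
            r1 = np.linalg.norm(d1, axis=2)
            ok = (r1 < rcut) & (r1.T < rcut)
            np.fill_diagonal(ok, False)
            for a, b in zip(*np.nonzero(ok)):
                if a < b:
                    out.append((int(a), int(b), int(i)))
        return out

    eligible = build_eligible()
    if not eligible:
        return (config, 0.0, moves) if collect_moves else (config, 0.0)

    for _ in range(n_att):
        a, b, i = eligible[int(rng.integers(len(eligible)))]
        A_old, B_old = pos[a].copy(), pos[b].copy()
        A_new = np.concatenate([A_old[: i + 1], B_old[i + 1 :]])
        B_new = np.concatenate([B_old[: i + 1], A_old[i + 1 :]])
        e_old = _local_bonded_energy(A_old, B_old, i, params, box)
        e_new = _local_bonded_energy(A_new, B_new, i, params, box)
        du = e_new - e_old
        if du <= 0 or rng.random() < np.exp(-du / kT):
            pos[a], pos[b] = A_new, B_new
            tail_a, tail_b = img[a, i + 1 :].copy(), img[b, i + 1 :].copy()
            img[a, i + 1 :], img[b, i + 1 :] = tail_b, tail_a
            # re-anchor tail images so each chain's unwrapped line stays continuous
            for c in (a, b):
                unw = pos[c] + img[c] * box
                d = unw[i + 1] - unw[i]
                shift = np.rint(d / box - mi(d) / box).astype(np.int64)
                img[c, i + 1 :] -= shift
            accepted += 1
            eligible = build_eligible()
            if collect_moves:
                moves.append(SwapMove(a, b, i, du, True))
        elif collect_moves:
            moves.append(SwapMove(a, b, i, du, False))
    frac = accepted / n_att
    return (config, frac, moves) if collect_moves else (config, frac)


# ----------------------------------------------------------------- equilibrate
def internal_distance_curve(
    config: PolymerConfiguration, n_values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared internal distance <R^2(n)>/n against chemical distance n."""
    Np = config.beads_per_chain
    if n_values is None:
        n_values = np.unique(
            np.round(np.geomspace(1, Np - 1, 12)).astype(int)
        )
    unw = config.positions_unwrapped
    out = np.zeros(len(n_values))
    chains = [unw[config.chain_index == c] for c in np.unique(config.chain_index)]
    for k, n in enumerate(n_values):
        acc, cnt = 0.0, 0
        for X in chains:
            d = X[n:] - X[:-n]
            acc += float(np.sum(d * d))
            cnt += len(d)
        out[k] = acc / cnt / n
    return n_values, out


@dataclasses.dataclass
class EquilibrationProtocol:
    bd_steps_per_cycle: int = 5_000
    sweeps_per_cycle: int = 2
    max_cycles: int = 40
    min_cycles: int = 4
    rel_tol: float = 0.02


def equilibrate(
    config: PolymerConfiguration,
    params: SimulationParameters,
    protocol: EquilibrationProtocol | None = None,
    seed: int | None = None,
) -> tuple[PolymerConfiguration, dict]:
    """Alternate BD blocks and swap sweeps until conformations are stationary.

    Convergence: the mean of <R_ee^2>/L and of the internal-distance curve over
    the two successive halves of the cycle history agree to ``rel_tol``.
    Non-convergence within ``max_cycles`` emits a warning; the configuration
    and report are returned either way.
    """
    from .bd_engine import _drive

    proto = protocol or EquilibrationProtocol()
    cfg = config.copy()
    seed32 = int((params.seed if seed is None else seed) & 0x7FFFFFFF)
    bd_rng = np.random.default_rng(seed32)
    rng = np.random.default_rng(seed32 + 1)
    ree_hist: list[float] = []
    idc_hist: list[np.ndarray] = []
    acc_hist: list[float] = []
    n_vals, _ = internal_distance_curve(cfg)
    converged = False
    cycles = 0
    for cycles in range(1, proto.max_cycles + 1):
        _drive(cfg, params, proto.bd_steps_per_cycle, bd_rng,
               include_active_stress=False)
        cfg.time += proto.bd_steps_per_cycle * params.dt
        acc = 0.0
        for _ in range(proto.sweeps_per_cycle):
            _, a = bond_swap_sweep(cfg, params, rng)
            acc += a
        acc_hist.append(acc / max(proto.sweeps_per_cycle, 1))
        ree_hist.append(float(np.mean(cfg.end_to_end_sq())) / params.L)
        _, idc = internal_distance_curve(cfg, n_vals)
        idc_hist.append(idc)
        if cycles >= proto.min_cycles and cycles % 2 == 0:
            h = cycles // 2
            r1, r2 = np.mean(ree_hist[:h]), np.mean(ree_hist[h:])
            c1 = np.mean(np.asarray(idc_hist[:h]), axis=0)
            c2 = np.mean(np.asarray(idc_hist[h:]), axis=0)
            dr = abs(r2 - r1) / max(abs(r1), 1e-300)
            dc = float(np.max(np.abs(c2 - c1) / np.maximum(np.abs(c1), 1e-300)))
            if dr < proto.rel_tol and dc < proto.rel_tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            "equilibration did not converge within the cycle budget",
            RuntimeWarning,
        )
    report = {
        "converged": converged,
        "cycles": cycles,
        "ree_sq_over_L": np.asarray(ree_hist),
        "internal_distance_n": n_vals,
        "internal_distance_curves": np.asarray(idc_hist),
        "swap_acceptance": np.asarray(acc_hist),
    }
    return cfg, report
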