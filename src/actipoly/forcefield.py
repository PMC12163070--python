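"""Deterministic forces (WCA, FENE, bending, tangential active) and virial stress.

This module is the readable reference implementation in plain numpy.  The
integrator uses the numba kernels in :mod:`actipoly._kernels`, which are
cross-checked against these functions in the test suite, so both routes must
agree force-by-force and component-by-component.

Conventions
-----------
* Pair separation vectors are ``r_kl = r_k - r_l`` under minimum image.
* A pair force entry ``F_kl`` is the force on bead k due to bead l; central
  pair interactions contribute both ordered entries (``F_lk = -F_kl``).
* The virial stress is the printed double sum
  ``sigma_ab = -1/(2V) sum_kl F_kl^a r_kl^b``.
* The tangential active force has constant magnitude ``Fp`` per bead.  Its
  stress contribution is attributed to the generating bond pairs and included
  by default (``include_active`` switch for sensitivity checks).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .system_model import PolymerConfiguration

__all__ = [
    "SingularOverlapError",
    "BondOverstretchError",
    "PerBeadForces",
    "StressSample",
    "RC_WCA",
    "wca_pair_force",
    "wca_energy",
    "fene_bond_force",
    "fene_energy",
    "bending_forces",
    "active_forces",
    "per_bead_forces",
    "pair_decomposition",
    "compute_stress",
    "total_potential_energy",
]

RC_WCA = 2.0 ** (1.0 / 6.0)


class SingularOverlapError(FloatingPointError):
    """Two beads at zero separation: the pair force is singular."""


class BondOverstretchError(RuntimeError):
    """A FENE bond reached its maximum extension R0 (simulation abort)."""


@dataclasses.dataclass
class PerBeadForces:
    """Per-bead force decomposition; ``f_total`` is the row-wise sum."""

    f_wca: np.ndarray
    f_fene: np.ndarray
    f_ang: np.ndarray
    f_active: np.ndarray

    @property
    def f_total(self) -> np.ndarray:
        return self.f_wca + self.f_fene + self.f_ang + self.f_active


@dataclasses.dataclass
class StressSample:
    """Virial stress tensor components of one configuration (units kBT/sigma^3)."""

    time: float
    sxy: float
    sxz: float
    syz: float
    sxx: float
    syy: float
    szz: float
    volume: float


# --------------------------------------------------------------------- pairwise
def wca_pair_force(
    r_vec: np.ndarray, eps_wca: float = 1.0, sigma: float = 1.0
) -> np.ndarray:
    """Force on the first bead of a WCA pair separated by ``r_vec = r1 - r2``.

    Purely repulsive 12-6 potential truncated and shifted at ``2^(1/6) sigma``.
    """
    r_vec = np.asarray(r_vec, dtype=np.float64)
    r = np.linalg.norm(r_vec)
    if r == 0.0:
        raise SingularOverlapError("WCA pair at zero separation")
    if r >= RC_WCA * sigma:
        return np.zeros(3)
    sr6 = (sigma / r) ** 6
    fmag_over_r = 24.0 * eps_wca * (2.0 * sr6 * sr6 - sr6) / r**2
    return fmag_over_r * r_vec


def wca_energy(r: float, eps_wca: float = 1.0, sigma: float = 1.0) -> float:
    if r >= RC_WCA * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * eps_wca * (sr6 * sr6 - sr6) + eps_wca


def fene_bond_force(
    r_vec: np.ndarray, eps_fene: float = 30.0, R0: float = 1.5
) -> np.ndarray:
    """Attractive FENE spring force on the first bead, ``F = -k r /(1-(r/R0)^2)``.

    ``eps_fene`` is the spring constant k in kBT/sigma^2.  Raises
    :class:`BondOverstretchError` at or beyond R0.
    """
    r_vec = np.asarray(r_vec, dtype=np.float64)
    r = np.linalg.norm(r_vec)
    if r >= R0:
        raise BondOverstretchError(f"bond length {r:.6g} >= R0 = {R0:.6g}")
    return -eps_fene * r_vec / (1.0 - (r / R0) ** 2)


def fene_energy(r: float, eps_fene: float = 30.0, R0: float = 1.5) -> float:
    if r >= R0:
        raise BondOverstretchError(f"bond length {r:.6g} >= R0 = {R0:.6g}")
    return -0.5 * eps_fene * R0**2 * np.log(1.0 - (r / R0) ** 2)


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.rint(d / box)


def _chain_arrays(config: PolymerConfiguration) -> list[np.ndarray]:
    return [
        np.flatnonzero(config.chain_index == c)
        for c in np.unique(config.chain_index)
    ]


# --------------------------------------------------------------------- bending
def bending_forces(
    config: PolymerConfiguration, kappa: float, overcount: int = 1
) -> tuple[np.ndarray, float]:
    """Analytic forces of ``U_bend = kappa * sum_j (1 - t_j . t_{j+1})``.

    The sum runs over each unique pair of consecutive tangents once per
    chain; per-triplet forces sum to zero (translation invariance).  A
    per-bead triple sum over j = i-1, i, i+1 would count every tangent pair
    three times; ``overcount=3`` exposes that literal reading for
    sensitivity checks (it simply rescales kappa).  Returns
    ``(forces, energy)``.
    """
    if overcount not in (1, 3):
        raise ValueError("overcount must be 1 or 3")
    kappa = kappa * overcount
    n = config.n_beads
    f = np.zeros((n, 3))
    energy = 0.0
    box = config.box_edge
    pos = config.positions
    for idx in _chain_arrays(config):
        if len(idx) < 3:
            continue
        X = pos[idx]
        u = _min_image(np.diff(X, axis=0), box)
        b = np.linalg.norm(u, axis=1)
        if np.any(b < 1e-12):
            raise SingularOverlapError("zero-length bond gives a singular tangent")
        t = u / b[:, None]
        c = np.einsum("ij,ij->i", t[:-1], t[1:])
        energy += kappa * np.sum(1.0 - c)
        dc_du = (t[1:] - c[:, None] * t[:-1]) / b[:-1, None]
        dc_dv = (t[:-1] - c[:, None] * t[1:]) / b[1:, None]
        f1 = -kappa * dc_du
        f3 = kappa * dc_dv
        np.add.at(f, idx[:-2], f1)
        np.add.at(f, idx[2:], f3)
        np.add.at(f, idx[1:-1], -(f1 + f3))
    return f, energy


# --------------------------------------------------------------------- active
def active_forces(
    config: PolymerConfiguration, Fp: float, raw_sum: bool = False
) -> np.ndarray:
    """Tangential self-propulsion with constant magnitude ``Fp`` per bead.

    Interior beads are driven along the normalized sum of their two adjacent
    tangents; end beads along their single adjacent tangent, oriented towards
    the high-rank (head) end.  A bead whose adjacent tangents cancel to below
    1e-8 (a perfect hairpin tip) receives zero active force.

    ``raw_sum=True`` skips the normalization (force ``Fp (t1 + t2)``, whose
    magnitude varies with the local bend) for sensitivity checks; the
    default enforces the constant per-bead magnitude that makes a free
    straight chain crawl at exactly ``v = Fp/zeta``.
    """
    n = config.n_beads
    f = np.zeros((n, 3))
    box = config.box_edge
    pos = config.positions
    for idx in _chain_arrays(config):
        X = pos[idx]
        u = _min_image(np.diff(X, axis=0), box)
        b = np.linalg.norm(u, axis=1)
        if np.any(b < 1e-12):
            raise SingularOverlapError("zero-length bond gives a singular tangent")
        t = u / b[:, None]
        f[idx[0]] = Fp * t[0]
        f[idx[-1]] = Fp * t[-1]
        if len(idx) > 2:
            s = t[:-1] + t[1:]
            if raw_sum:
                f[idx[1:-1]] = Fp * s
            else:
                norms = np.linalg.norm(s, axis=1)
                good = norms >= 1e-8
                out = np.zeros_like(s)
                out[good] = Fp * s[good] / norms[good, None]
                f[idx[1:-1]] = out
    return f


def per_bead_forces(config: PolymerConfiguration, params) -> PerBeadForces:
    """Full per-bead force decomposition (WCA, FENE, bending, active)."""
    n = config.n_beads
    box = config.box_edge
    pos = config.positions
    f_wca = np.zeros((n, 3))
    if params.eps_wca != 0.0:
        for i in range(n - 1):
            d = _min_image(pos[i] - pos[i + 1 :], box)
            r = np.linalg.norm(d, axis=1)
            close = np.flatnonzero(r < RC_WCA * params.sigma)
            for j in close:
                fij = wca_pair_force(d[j], params.eps_wca, params.sigma)
                f_wca[i] += fij
                f_wca[i + 1 + j] -= fij
    f_fene = np.zeros((n, 3))
    for idx in _chain_arrays(config):
        d = _min_image(pos[idx[:-1]] - pos[idx[1:]], box)
        for k in range(len(idx) - 1):
            fij = fene_bond_force(d[k], params.eps_fene, params.R0)
            f_fene[idx[k]] += fij
            f_fene[idx[k + 1]] -= fij
    f_ang, _ = bending_forces(config, params.kappa)
    f_act = active_forces(config, params.Fp) if params.Fp else np.zeros((n, 3))
    return PerBeadForces(f_wca, f_fene, f_ang, f_act)


# --------------------------------------------------------------------- stress
def pair_decomposition(
    config: PolymerConfiguration, params, include_active: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered pairwise contributions ``(F_kl, r_kl)`` of all interactions.

    Central interactions (WCA, FENE) appear with both orders.  The three-body
    bending force is decomposed onto the two outer-center pairs (standard
    three-body virial decomposition), also with both orders.  The active force
    on each bead is split along its generating tangent(s) and attributed to
    the corresponding bond pair, one-sidedly (activity has no reaction force).
    """
    F: list[np.ndarray] = []
    R: list[np.ndarray] = []
    box = config.box_edge
    pos = config.positions
    n = config.n_beads

    def add_central(fij, rij):
        F.append(fij)
        R.append(rij)
        F.append(-fij)
        R.append(-rij)

    if params.eps_wca != 0.0:
        for i in range(n - 1):
            d = _min_image(pos[i] - pos[i + 1 :], box)
            r = np.linalg.norm(d, axis=1)
            for j in np.flatnonzero(r < RC_WCA * params.sigma):
                add_central(wca_pair_force(d[j], params.eps_wca, params.sigma), d[j])
    for idx in _chain_arrays(config):
        d = _min_image(pos[idx[:-1]] - pos[idx[1:]], box)
        for k in range(len(idx) - 1):
            add_central(fene_bond_force(d[k], params.eps_fene, params.R0), d[k])
        if params.kappa != 0.0 and len(idx) >= 3:
            X = pos[idx]
            u = _min_image(np.diff(X, axis=0), box)
            b = np.linalg.norm(u, axis=1)
            t = u / b[:, None]
            c = np.einsum("ij,ij->i", t[:-1], t[1:])
            dc_du = (t[1:] - c[:, None] * t[:-1]) / b[:-1, None]
            dc_dv = (t[:-1] - c[:, None] * t[1:]) / b[1:, None]
            for k in range(len(idx) - 2):
                f1 = -params.kappa * dc_du[k]
                f3 = params.kappa * dc_dv[k]
                add_central(f1, -u[k])  # pair (k, k+1): r = r_k - r_{k+1}
                add_central(f3, u[k + 1])  # pair (k+2, k+1)
        if include_active and params.Fp:
            X = pos[idx]
            u = _min_image(np.diff(X, axis=0), box)
            b = np.linalg.norm(u, axis=1)
            t = u / b[:, None]
            m = len(idx)
            for k in range(m):
                if k == 0:
                    F.append(params.Fp * t[0])
                    R.append(-u[0])
                elif k == m - 1:
                    F.append(params.Fp * t[-1])
                    R.append(u[-1])
                else:
                    s = t[k - 1] + t[k]
                    norm = np.linalg.norm(s)
                    if norm < 1e-8:
                        continue
                    scale = params.Fp / norm
                    F.append(scale * t[k - 1])
                    R.append(u[k - 1])
                    F.append(scale * t[k])
                    R.append(-u[k])
    if not F:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return np.asarray(F), np.asarray(R)


def compute_stress(
    pair_forces: np.ndarray,
    pair_separations: np.ndarray,
    volume: float,
    time: float = 0.0,
) -> StressSample:
    """Virial stress from an ordered pairwise force list.

    ``sigma_ab = -1/(2V) sum F^a r^b`` over the supplied entries; an unordered
    central pair must therefore appear twice (handled by the 1/2).
    """
    F = np.asarray(pair_forces, dtype=np.float64).reshape(-1, 3)
    R = np.asarray(pair_separations, dtype=np.float64).reshape(-1, 3)
    if F.shape != R.shape:
        raise ValueError("pair force and separation lists must have equal shapes")
    if volume <= 0:
        raise ValueError("volume must be positive")
    if len(F) == 0:
        w = np.zeros((3, 3))
    else:
        w = F.T @ R
    s = -w / (2.0 * volume)
    return StressSample(
        time=time,
        sxy=s[0, 1],
        sxz=s[0, 2],
        syz=s[1, 2],
        sxx=s[0, 0],
        syy=s[1, 1],
        szz=s[2, 2],
        volume=volume,
    )


def total_potential_energy(config: PolymerConfiguration, params) -> float:
    """WCA + FENE + bending energy of a configuration (reference path)."""
    box = config.box_edge
    pos = config.positions
    n = config.n_beads
    e = 0.0
    if params.eps_wca != 0.0:
        for i in range(n - 1):
            d = _min_image(pos[i] - pos[i + 1 :], box)
            r = np.linalg.norm(d, axis=1)
            for rr in r[r < RC_WCA * params.sigma]:
                e += wca_energy(rr, params.eps_wca, params.sigma)
    for idx in _chain_arrays(config):
        d = _min_image(pos[idx[:-1]] - pos[idx[1:]], box)
        for rr in np.linalg.norm(d, axis=1):
            e += fene_energy(rr, params.eps_fene, params.R0)
    _, e_bend = bending_forces(config, params.kappa)
    return e + e_bend
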