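"""Simulation parameters, polymer configurations, melt builders and geometric fixtures.

Reduced units are used throughout: the bead diameter ``sigma`` is the unit of
length, the thermal energy ``kBT`` the unit of energy, and the monomer friction
``zeta`` the unit of friction, so that the monomer diffusivity ``D0 = kBT/zeta``
and the diffusive time ``tau0 = sigma**2/D0`` are both unity by default.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

__all__ = [
    "ParameterError",
    "SimulationParameters",
    "PolymerConfiguration",
    "build_random_melt",
    "validate_topology",
    "make_fixture",
    "FIXTURE_NAMES",
]


class ParameterError(ValueError):
    """Raised for inconsistent or non-physical model parameters."""


@dataclasses.dataclass(frozen=True)
class SimulationParameters:
    """All model constants and dimensionless groups; single source of truth for units.

    Exactly one of ``Pe`` and ``Fp`` may be given; the other is derived from
    ``Pe = v*sigma/D0`` with ``v = Fp/zeta``.  Leaving both unset gives a
    passive (equilibrium) system.

    Parameters
    ----------
    N : int
        Number of chains.
    Np : int
        Beads per chain (>= 2).
    rho_star : float
        Dimensionless number density ``N_tot sigma^3 / V``.
    eps_wca : float
        WCA repulsion strength in units of kBT.
    eps_fene : float
        FENE spring constant ``k`` in units of kBT/sigma^2 (the canonical
        bead-spring convention with R0 = 1.5 sigma).
    R0 : float
        Maximum FENE bond extension.
    kappa : float
        Bending stiffness in units of kBT.
    dt : float
        Integration time step in tau0.
    """

    N: int
    Np: int
    rho_star: float = 0.85
    sigma: float = 1.0
    kBT: float = 1.0
    zeta: float = 1.0
    eps_wca: float = 1.0
    eps_fene: float = 30.0
    R0: float = 1.5
    kappa: float = 1.0
    Pe: float | None = None
    Fp: float | None = None
    dt: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.Np < 2:
            raise ParameterError("need N >= 1 chains and Np >= 2 beads per chain")
        for name in ("rho_star", "sigma", "kBT", "zeta", "dt"):
            if getattr(self, name) <= 0 and not (name == "kBT" and self.kBT == 0.0):
                raise ParameterError(f"{name} must be positive")
        if self.R0 <= self.sigma:
            raise ParameterError("R0 must exceed sigma")
        if self.Pe is not None and self.Fp is not None:
            raise ParameterError("specify at most one of Pe and Fp")
        if self.Pe is None and self.Fp is None:
            object.__setattr__(self, "Fp", 0.0)
        if self.Fp is None:
            # Pe = v sigma / D0, v = Fp / zeta  =>  Fp = Pe * kBT / sigma
            object.__setattr__(self, "Fp", self.Pe * self.kBT / self.sigma)
        pe = (
            self.Fp * self.sigma / (self.zeta * self.D0)
            if self.D0 > 0
            else 0.0
        )
        object.__setattr__(self, "Pe", pe)

    # ------------------------------------------------------------------ derived
    @property
    def D0(self) -> float:
        """Monomer short-time diffusivity kBT/zeta."""
        return self.kBT / self.zeta

    @property
    def tau0(self) -> float:
        """Diffusive time sigma^2/D0."""
        return self.sigma**2 / self.D0

    @property
    def v(self) -> float:
        """Free self-propulsion speed Fp/zeta."""
        return self.Fp / self.zeta

    @property
    def L(self) -> float:
        """Contour length Np*sigma."""
        return self.Np * self.sigma

    @property
    def n_beads(self) -> int:
        return self.N * self.Np

    @property
    def box_edge(self) -> float:
        """Cubic box edge solving rho_star = N_tot sigma^3 / V exactly."""
        return (self.n_beads * self.sigma**3 / self.rho_star) ** (1.0 / 3.0)

    def replace(self, **kw) -> "SimulationParameters":
        if "Fp" in kw and "Pe" not in kw:
            kw["Pe"] = None
        elif "Pe" in kw and "Fp" not in kw:
            kw["Fp"] = None
        elif "Pe" not in kw and "Fp" not in kw:
            kw["Pe"] = None  # keep the stored Fp as the activity authority
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class PolymerConfiguration:
    """Bead coordinates plus chain topology in a cubic periodic box.

    ``positions`` are wrapped into ``[0, box_edge)``; ``images`` hold the
    accumulated integer image shifts so that the unwrapped coordinates are
    ``positions + images*box_edge``.  Beads are stored sorted by
    (chain_index, bead_rank).  Unwrapped coordinates are the authority for
    end-to-end distances, primitive paths and mean-squared displacements;
    wrapped coordinates are used for forces.
    """

    positions: np.ndarray
    images: np.ndarray
    chain_index: np.ndarray
    bead_rank: np.ndarray
    box_edge: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.images = np.ascontiguousarray(self.images, dtype=np.int64)
        self.chain_index = np.asarray(self.chain_index, dtype=np.int64)
        self.bead_rank = np.asarray(self.bead_rank, dtype=np.int64)

    # -------------------------------------------------------------- construction
    @classmethod
    def from_unwrapped(
        cls,
        unwrapped: np.ndarray,
        chain_index: np.ndarray,
        bead_rank: np.ndarray,
        box_edge: float,
        time: float = 0.0,
    ) -> "PolymerConfiguration":
        unwrapped = np.asarray(unwrapped, dtype=np.float64)
        images = np.floor(unwrapped / box_edge).astype(np.int64)
        wrapped = unwrapped - images * box_edge
        return cls(wrapped, images, chain_index, bead_rank, box_edge, time)

    # -------------------------------------------------------------- properties
    @property
    def positions_wrapped(self) -> np.ndarray:
        return self.positions

    @property
    def positions_unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box_edge

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_index))

    @property
    def beads_per_chain(self) -> int:
        counts = np.bincount(self.chain_index)
        counts = counts[counts > 0]
        if not np.all(counts == counts[0]):
            raise ValueError("melt is not monodisperse")
        return int(counts[0])

    @property
    def volume(self) -> float:
        return self.box_edge**3

    def copy(self) -> "PolymerConfiguration":
        return PolymerConfiguration(
            self.positions.copy(),
            self.images.copy(),
            self.chain_index.copy(),
            self.bead_rank.copy(),
            self.box_edge,
            self.time,
        )

    # -------------------------------------------------------------- geometry
    def chain_positions(self, chain: int, unwrapped: bool = True) -> np.ndarray:
        mask = self.chain_index == chain
        pos = self.positions_unwrapped[mask] if unwrapped else self.positions[mask]
        return pos[np.argsort(self.bead_rank[mask])]

    def bond_vectors(self) -> np.ndarray:
        """Consecutive-bead bond vectors from unwrapped coordinates, all chains."""
        unw = self.positions_unwrapped
        vecs = []
        for c in np.unique(self.chain_index):
            X = unw[self.chain_index == c]
            vecs.append(np.diff(X, axis=0))
        return np.concatenate(vecs, axis=0)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def end_to_end(self) -> np.ndarray:
        """Per-chain end-to-end distances (unwrapped)."""
        unw = self.positions_unwrapped
        out = []
        for c in np.unique(self.chain_index):
            X = unw[self.chain_index == c]
            out.append(np.linalg.norm(X[-1] - X[0]))
        return np.asarray(out)

    def end_to_end_sq(self) -> np.ndarray:
        return self.end_to_end() ** 2


def _chain_labels(N: int, Np: int) -> tuple[np.ndarray, np.ndarray]:
    chain = np.repeat(np.arange(N, dtype=np.int64), Np)
    rank = np.tile(np.arange(Np, dtype=np.int64), N)
    return chain, rank


def _wlc_steps(rng: np.random.Generator, n: int, kappa: float) -> np.ndarray:
    """Unit tangents of a discrete worm-like walk at stiffness ``kappa``.

    Successive tangents follow the Boltzmann weight exp(kappa cos(theta)) of
    the bending potential, so fresh chains start in the conformational
    ensemble the bending term itself dictates (kappa = 0 recovers the freely
    jointed walk).
    """
    t = np.empty((n, 3))
    v = rng.normal(size=3)
    t[0] = v / np.linalg.norm(v)
    if kappa <= 0:
        t[1:] = rng.normal(size=(n - 1, 3))
        t[1:] /= np.linalg.norm(t[1:], axis=1, keepdims=True)
        return t
    u = rng.uniform(size=n - 1)
    # inverse CDF of p(cos) ~ exp(kappa cos) on [-1, 1]
    cos_th = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    sin_th = np.sqrt(np.maximum(0.0, 1.0 - cos_th**2))
    phi = rng.uniform(0.0, 2 * np.pi, size=n - 1)
    for k in range(1, n):
        prev = t[k - 1]
        # orthonormal frame around the previous tangent
        a = np.array([1.0, 0.0, 0.0]) if abs(prev[0]) < 0.9 else np.array(
            [0.0, 1.0, 0.0]
        )
        e1 = np.cross(prev, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(prev, e1)
        t[k] = (
            cos_th[k - 1] * prev
            + sin_th[k - 1] * (np.cos(phi[k - 1]) * e1 + np.sin(phi[k - 1]) * e2)
        )
    return t


def ideal_wlc_ree_sq(params: SimulationParameters) -> float:
    """Exact ensemble mean of R_ee^2 for the builder's discrete worm-like walk.

    For n = Np-1 bonds of length b with tangent correlation
    lambda = <cos theta> = coth(kappa) - 1/kappa,
    ``<R_ee^2> = b^2 n C_n`` with
    ``C_n = (1+l)/(1-l) - 2 l (1 - l^n) / (n (1-l)^2)``.
    Used as a control variate when estimating melt chain dimensions from
    small ensembles.
    """
    n = params.Np - 1
    b2 = (0.97 * params.sigma) ** 2
    kappa = params.kappa / params.kBT if params.kBT > 0 else params.kappa
    if kappa <= 0:
        return b2 * n
    lam = 1.0 / np.tanh(kappa) - 1.0 / kappa
    cn = (1 + lam) / (1 - lam) - 2 * lam * (1 - lam**n) / (n * (1 - lam) ** 2)
    return b2 * n * cn


def build_random_melt(
    params: SimulationParameters, seed: int | None = None
) -> PolymerConfiguration:
    """Build N random-walk chains with exact initial bond length ``0.97*sigma``.

    Chain conformations are discrete worm-like walks whose angular
    distribution is the Boltzmann weight of the configured bending stiffness,
    so the melt starts with the ideal-chain statistics the bonded potential
    implies.  Overlaps between beads are permitted here; they are removed
    afterwards by the capped-repulsion push-off
    (:func:`actipoly.equilibration.soft_pushoff`).  The cubic box edge solves
    the density definition rho_star = N_tot sigma^3/V exactly.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    N, Np = params.N, params.Np
    box = params.box_edge
    b0 = 0.97 * params.sigma
    kappa = params.kappa / params.kBT if params.kBT > 0 else params.kappa
    unwrapped = np.empty((N * Np, 3), dtype=np.float64)
    for c in range(N):
        start = rng.uniform(0.0, box, size=3)
        steps = _wlc_steps(rng, Np - 1, kappa)
        X = np.empty((Np, 3))
        X[0] = start
        X[1:] = start + np.cumsum(b0 * steps, axis=0)
        unwrapped[c * Np : (c + 1) * Np] = X
    chain, rank = _chain_labels(N, Np)
    return PolymerConfiguration.from_unwrapped(unwrapped, chain, rank, box, 0.0)


def validate_topology(
    config: PolymerConfiguration, params: SimulationParameters | None = None
) -> dict:
    """Report-only diagnostics: bond extremes, chain-length histogram, density.

    Flags any FENE bond at or beyond R0 and any broken chain (bead ranks not
    running 0..Np-1 exactly once per chain).
    """
    R0 = params.R0 if params is not None else 1.5
    lengths = config.bond_lengths()
    violations = int(np.sum(lengths >= R0))
    hist: dict[int, int] = {}
    broken = 0
    for c in np.unique(config.chain_index):
        ranks = np.sort(config.bead_rank[config.chain_index == c])
        n = len(ranks)
        hist[n] = hist.get(n, 0) + 1
        if not np.array_equal(ranks, np.arange(n)):
            broken += 1
    density = config.n_beads / config.volume
    return {
        "bond_min": float(lengths.min()),
        "bond_max": float(lengths.max()),
        "bond_violations": violations,
        "broken_chains": broken,
        "chain_length_histogram": hist,
        "density": density,
        "ok": violations == 0 and broken == 0,
    }


FIXTURE_NAMES = (
    "straight_chain",
    "hairpin_chain",
    "isolated_pair",
    "wrapped_pair",
    "phantom_ideal_chain",
)


def _config_from_chains(
    chains: Iterable[np.ndarray], box_edge: float
) -> PolymerConfiguration:
    chains = [np.asarray(c, dtype=np.float64) for c in chains]
    unwrapped = np.concatenate(chains, axis=0)
    chain = np.concatenate(
        [np.full(len(c), i, dtype=np.int64) for i, c in enumerate(chains)]
    )
    rank = np.concatenate([np.arange(len(c), dtype=np.int64) for c in chains])
    return PolymerConfiguration.from_unwrapped(unwrapped, chain, rank, box_edge, 0.0)


def make_fixture(name: str, **geometry) -> PolymerConfiguration:
    """Deterministic, analytically specified test configurations.

    ``straight_chain``
        Np beads on a line with uniform spacing (default 0.97).
    ``hairpin_chain``
        A chain folded back on itself: exactly one bead whose adjacent
        tangents are antiparallel (geometry fixture; the fold superimposes
        beads, so it is not meant for pair-potential evaluation).
    ``isolated_pair``
        Two parallel straight chains too far apart to interact.
    ``wrapped_pair``
        Chain 0 is a long straight chain on the x axis; chain 1 starts and
        ends below it and winds once around it near x=0, so chain 1's
        shortest non-crossing path is two straight segments meeting at the
        origin: length 2*sqrt(a^2 + h^2), computable by hand.
    ``phantom_ideal_chain``
        A single freely-jointed random-walk chain (seeded), for ideal-chain
        statistics with pair forces switched off.
    """
    if name == "straight_chain":
        Np = geometry.get("Np", 10)
        spacing = geometry.get("spacing", 0.97)
        box = geometry.get("box_edge", 1000.0)
        X = np.zeros((Np, 3))
        X[:, 0] = spacing * np.arange(Np)
        X += np.asarray(geometry.get("origin", (box / 2, box / 2, box / 2)))
        return _config_from_chains([X], box)

    if name == "hairpin_chain":
        Np = geometry.get("Np", 11)
        spacing = geometry.get("spacing", 0.97)
        fold = geometry.get("fold", Np // 2)
        box = geometry.get("box_edge", 1000.0)
        xs = np.concatenate(
            [np.arange(fold + 1), fold - 1 - np.arange(Np - fold - 1)]
        ).astype(float)
        X = np.zeros((Np, 3))
        X[:, 0] = spacing * xs
        X += box / 2
        return _config_from_chains([X], box)

    if name == "isolated_pair":
        Np = geometry.get("Np", 10)
        spacing = geometry.get("spacing", 0.97)
        sep = geometry.get("separation", 50.0)
        box = geometry.get("box_edge", 1000.0)
        A = np.zeros((Np, 3))
        A[:, 0] = spacing * np.arange(Np)
        B = A.copy()
        B[:, 1] += sep
        A += box / 2
        B += box / 2
        return _config_from_chains([A, B], box)

    if name == "wrapped_pair":
        a = geometry.get("a", 4.0)  # half-span of chain-1 endpoints along x
        h = geometry.get("h", 3.0)  # endpoint depth below the obstacle chain
        zc = geometry.get("end_z", 1.0)  # endpoint offset out of the x-y plane
        rho0 = geometry.get("loop_radius", 0.8)
        x_loop = geometry.get("x_loop", 0.3)
        box = geometry.get("box_edge", 200.0)
        n_leg = geometry.get("n_leg", 8)
        n_loop = geometry.get("n_loop", 16)
        half = geometry.get("obstacle_half_length", 10.0)
        n_obs = geometry.get("obstacle_beads", 21)
        # chain 0: straight obstacle along x through the origin
        A = np.zeros((n_obs, 3))
        A[:, 0] = np.linspace(-half, half, n_obs)
        # chain 1: leg down-left -> full loop around the x axis -> leg down-right;
        # its taut path is E1 -> origin -> E2, length 2*sqrt(a^2 + h^2 + zc^2)
        E1 = np.array([-a, -h, zc])
        E2 = np.array([a, -h, zc])
        Ls = np.array([-x_loop, -rho0, 0.0])
        Le = np.array([x_loop, -rho0, 0.0])
        leg1 = E1 + np.linspace(0, 1, n_leg, endpoint=False)[:, None] * (Ls - E1)
        alpha = np.linspace(0.0, 2 * np.pi, n_loop, endpoint=False)
        loop = np.stack(
            [
                -x_loop + (alpha / (2 * np.pi)) * 2 * x_loop,
                -rho0 * np.cos(alpha),
                rho0 * np.sin(alpha),
            ],
            axis=1,
        )
        leg2 = Le + np.linspace(0, 1, n_leg + 1)[:, None] * (E2 - Le)
        B = np.concatenate([leg1, loop, leg2], axis=0)
        center = np.array([box / 2, box / 2, box / 2])
        return _config_from_chains([A + center, B + center], box)

    if name == "phantom_ideal_chain":
        Np = geometry.get("Np", 50)
        spacing = geometry.get("spacing", 0.97)
        seed = geometry.get("seed", 0)
        box = geometry.get("box_edge", 1000.0)
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(Np - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        X = np.zeros((Np, 3))
        X[1:] = np.cumsum(spacing * steps, axis=0)
        X += box / 2
        return _config_from_chains([X], box)

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
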