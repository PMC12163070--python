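"""Geometric primitive-path contraction and entanglement statistics.

The primitive path of a chain is the shortest path between its two (fixed)
ends that preserves topological uncrossability with the other chains.  It is
found here by iterative geometric minimization: interior nodes are removed, or
pulled towards the local chord, whenever the swept triangles intersect no
segment of any other chain (segment-triangle tests under minimum image, with
obstacle segments replicated over the periodic images that can reach the
contracting chain).  Remaining interior corners are the kinks; their count Z
estimates the number of entanglement points, and the entanglement length
follows from N_e = (Np - 1) <R_ee^2> / <L_pp^2>.

Absolute kink counts depend on counting conventions (nearby corners produced
by one obstacle are coalesced within ``kink_merge_tol``); ratios such as
Z/Z0 against a passive reference are the robust observables.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from numba import njit

from .system_model import PolymerConfiguration

__all__ = [
    "PrimitivePathResult",
    "contract",
    "entanglement_length",
    "equilibrium_plateau_prediction",
    "ppa_timeseries",
]


# ------------------------------------------------------------------ geometry
@njit(cache=True, inline="always")
def _seg_seg_dist2(a0, a1, b0x, b0y, b0z, b1x, b1y, b1z):
    """Squared distance between segments a0-a1 and b0-b1 (clamped closed form)."""
    ux, uy, uz = a1[0] - a0[0], a1[1] - a0[1], a1[2] - a0[2]
    vx, vy, vz = b1x - b0x, b1y - b0y, b1z - b0z
    wx, wy, wz = a0[0] - b0x, a0[1] - b0y, a0[2] - b0z
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    den = a * c - b * b
    if den > 1e-18:
        s = (b * e - c * d) / den
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    if c > 1e-18:
        t = (e + b * s) / c
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    # refine s for the clamped t
    if a > 1e-18:
        s = (b * t - d) / a
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    dx = wx + s * ux - t * vx
    dy = wy + s * uy - t * vy
    dz = wz + s * uz - t * vz
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _tri_seg_hit(p0, p1, p2, q0, q1):
    """Does segment q0-q1 cross triangle (p0, p1, p2)?  Conservative on touch.

    The obstacle-segment parameter is accepted with a 1e-6 slack so that
    consecutive segments of an obstacle polyline overlap their coverage and a
    crossing exactly through a shared vertex cannot slip between them.
    Near-parallel (ill-conditioned) configurations fall back to an
    edge-distance criterion.
    """
    e1x, e1y, e1z = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    e2x, e2y, e2z = p2[0] - p0[0], p2[1] - p0[1], p2[2] - p0[2]
    # degenerate (zero-area) sweep cannot be crossed
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    n2 = nx * nx + ny * ny + nz * nz
    if n2 < 1e-24:
        return False
    dx, dy, dz = q1[0] - q0[0], q1[1] - q0[1], q1[2] - q0[2]
    d2 = dx * dx + dy * dy + dz * dz
    hx = dy * e2z - dz * e2y
    hy = dz * e2x - dx * e2z
    hz = dx * e2y - dy * e2x
    a = e1x * hx + e1y * hy + e1z * hz
    if abs(a) < 1e-9 * np.sqrt(n2 * d2):
        # nearly coplanar: block if the segment passes close to any edge
        tol2 = 1e-12
        if _seg_seg_dist2(q0, q1, p0[0], p0[1], p0[2], p1[0], p1[1], p1[2]) < tol2:
            return True
        if _seg_seg_dist2(q0, q1, p1[0], p1[1], p1[2], p2[0], p2[1], p2[2]) < tol2:
            return True
        if _seg_seg_dist2(q0, q1, p2[0], p2[1], p2[2], p0[0], p0[1], p0[2]) < tol2:
            return True
        return False
    f = 1.0 / a
    sx, sy, sz = q0[0] - p0[0], q0[1] - p0[1], q0[2] - p0[2]
    u = f * (sx * hx + sy * hy + sz * hz)
    eps = 1e-9
    if u < -eps or u > 1.0 + eps:
        return False
    qx = sy * e1z - sz * e1y
    qy = sz * e1x - sx * e1z
    qz = sx * e1y - sy * e1x
    v = f * (dx * qx + dy * qy + dz * qz)
    if v < -eps or u + v > 1.0 + eps:
        return False
    tpar = f * (e2x * qx + e2y * qy + e2z * qz)
    eps_t = 1e-6
    return -eps_t <= tpar <= 1.0 + eps_t


@njit(cache=True)
def _first_hit(p0, p1, p2, segs):
    """Index of the first obstacle segment crossing the triangle, or -1."""
    lo0 = min(p0[0], min(p1[0], p2[0]))
    hi0 = max(p0[0], max(p1[0], p2[0]))
    lo1 = min(p0[1], min(p1[1], p2[1]))
    hi1 = max(p0[1], max(p1[1], p2[1]))
    lo2 = min(p0[2], min(p1[2], p2[2]))
    hi2 = max(p0[2], max(p1[2], p2[2]))
    for s in range(segs.shape[0]):
        q0 = segs[s, 0:3]
        q1 = segs[s, 3:6]
        if max(q0[0], q1[0]) < lo0 or min(q0[0], q1[0]) > hi0:
            continue
        if max(q0[1], q1[1]) < lo1 or min(q0[1], q1[1]) > hi1:
            continue
        if max(q0[2], q1[2]) < lo2 or min(q0[2], q1[2]) > hi2:
            continue
        if _tri_seg_hit(p0, p1, p2, q0, q1):
            return s
    return -1


@njit(cache=True, inline="always")
def _tri_hits_any(p0, p1, p2, segs):
    return _first_hit(p0, p1, p2, segs) >= 0


CLEARANCE = 1e-4  # obstacle hugging distance for projected (blocked) moves


@njit(cache=True, inline="always")
def _closest_on_seg(seg, p):
    """Closest point to p on the obstacle segment (seg = [q0, q1] flat)."""
    dx = seg[3] - seg[0]
    dy = seg[4] - seg[1]
    dz = seg[5] - seg[2]
    d2 = dx * dx + dy * dy + dz * dz
    if d2 < 1e-24:
        return seg[0], seg[1], seg[2]
    t = ((p[0] - seg[0]) * dx + (p[1] - seg[1]) * dy + (p[2] - seg[2]) * dz) / d2
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return seg[0] + t * dx, seg[1] + t * dy, seg[2] + t * dz


@njit(cache=True)
def _path_length(path, m):
    total = 0.0
    for i in range(m - 1):
        dx = path[i + 1, 0] - path[i, 0]
        dy = path[i + 1, 1] - path[i, 1]
        dz = path[i + 1, 2] - path[i, 2]
        total += np.sqrt(dx * dx + dy * dy + dz * dz)
    return total


@njit(cache=True)
def _sweep(path, m, segs, lam_min):
    """One contraction sweep.  Returns the new node count."""
    i = 1
    while i < m - 1:
        a = path[i - 1]
        x = path[i].copy()
        b = path[i + 1]
        if not _tri_hits_any(a, x, b, segs):
            for k in range(i, m - 1):
                path[k, 0] = path[k + 1, 0]
                path[k, 1] = path[k + 1, 1]
                path[k, 2] = path[k + 1, 2]
            m -= 1
            continue
        # partial pull towards the closest point on chord a-b
        abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
        ab2 = abx * abx + aby * aby + abz * abz
        if ab2 > 1e-24:
            tproj = ((x[0] - a[0]) * abx + (x[1] - a[1]) * aby +
                     (x[2] - a[2]) * abz) / ab2
            if tproj < 0.0:
                tproj = 0.0
            elif tproj > 1.0:
                tproj = 1.0
            tx = a[0] + tproj * abx
            ty = a[1] + tproj * aby
            tz = a[2] + tproj * abz
            dxp = tx - x[0]
            dyp = ty - x[1]
            dzp = tz - x[2]
            old_len = np.sqrt(
                (x[0] - a[0]) ** 2 + (x[1] - a[1]) ** 2 + (x[2] - a[2]) ** 2
            ) + np.sqrt(
                (b[0] - x[0]) ** 2 + (b[1] - x[1]) ** 2 + (b[2] - x[2]) ** 2
            )
            lam = 1.0
            nx = np.empty(3)
            while lam > lam_min:
                nx[0] = x[0] + lam * dxp
                nx[1] = x[1] + lam * dyp
                nx[2] = x[2] + lam * dzp
                if (not _tri_hits_any(a, x, nx, segs)) and (
                    not _tri_hits_any(x, b, nx, segs)
                ):
                    path[i, 0] = nx[0]
                    path[i, 1] = nx[1]
                    path[i, 2] = nx[2]
                    break
                # blocked: project the proposal to a small clearance around
                # the blocking obstacle segment (on the node's side), so the
                # node can hug the obstacle and slide along it
                blk = _first_hit(a, x, nx, segs)
                if blk < 0:
                    blk = _first_hit(x, b, nx, segs)
                if blk >= 0:
                    qx, qy, qz = _closest_on_seg(segs[blk], x)
                    sdx = x[0] - qx
                    sdy = x[1] - qy
                    sdz = x[2] - qz
                    sn = np.sqrt(sdx * sdx + sdy * sdy + sdz * sdz)
                    if sn > 1e-12:
                        sdx /= sn
                        sdy /= sn
                        sdz /= sn
                        px, py, pz = _closest_on_seg(segs[blk], nx)
                        nx[0] = px + CLEARANCE * sdx
                        nx[1] = py + CLEARANCE * sdy
                        nx[2] = pz + CLEARANCE * sdz
                        new_len = np.sqrt(
                            (nx[0] - a[0]) ** 2 + (nx[1] - a[1]) ** 2
                            + (nx[2] - a[2]) ** 2
                        ) + np.sqrt(
                            (b[0] - nx[0]) ** 2 + (b[1] - nx[1]) ** 2
                            + (b[2] - nx[2]) ** 2
                        )
                        if (
                            new_len < old_len
                            and not _tri_hits_any(a, x, nx, segs)
                            and not _tri_hits_any(x, b, nx, segs)
                        ):
                            path[i, 0] = nx[0]
                            path[i, 1] = nx[1]
                            path[i, 2] = nx[2]
                            break
                lam *= 0.5
        i += 1
    return m


@njit(cache=True)
def _drop_collinear(path, m, dist_tol, segs):
    """Remove near-collinear interior nodes, never across an obstacle.

    A node qualifies when its perpendicular distance from the chord of its
    neighbors is below ``dist_tol``; the removal is additionally vetoed if
    the swept triangle (a, x, b) intersects any obstacle segment, so drops
    obey the same uncrossability rule as moves.
    """
    i = 1
    while i < m - 1:
        ax = path[i, 0] - path[i - 1, 0]
        ay = path[i, 1] - path[i - 1, 1]
        az = path[i, 2] - path[i - 1, 2]
        cx = path[i + 1, 0] - path[i - 1, 0]
        cy = path[i + 1, 1] - path[i - 1, 1]
        cz = path[i + 1, 2] - path[i - 1, 2]
        c2 = cx * cx + cy * cy + cz * cz
        drop = False
        if ax * ax + ay * ay + az * az < 1e-24:
            drop = True
        elif c2 > 1e-24:
            t = (ax * cx + ay * cy + az * cz) / c2
            if 0.0 <= t <= 1.0:
                px = ax - t * cx
                py = ay - t * cy
                pz = az - t * cz
                if px * px + py * py + pz * pz < dist_tol * dist_tol:
                    drop = not _tri_hits_any(
                        path[i - 1], path[i], path[i + 1], segs
                    )
        if drop:
            for k in range(i, m - 1):
                path[k, 0] = path[k + 1, 0]
                path[k, 1] = path[k + 1, 1]
                path[k, 2] = path[k + 1, 2]
            m -= 1
        else:
            i += 1
    return m


# ------------------------------------------------------------------- results
@dataclasses.dataclass
class PrimitivePathResult:
    """Per-chain primitive-path observables and the ensemble entanglement length."""

    Lpp: np.ndarray
    Z: np.ndarray
    Ree: np.ndarray
    Ne: float
    Np: int
    paths: list
    converged: bool

    def as_dict(self) -> dict:
        return {
            "Lpp": self.Lpp.tolist(),
            "Z": self.Z.tolist(),
            "Ree": self.Ree.tolist(),
            "Ne": self.Ne,
            "Np": self.Np,
            "converged": self.converged,
        }


def _unwrapped_chains(config: PolymerConfiguration) -> list[np.ndarray]:
    return [
        config.chain_positions(c, unwrapped=True)
        for c in np.unique(config.chain_index)
    ]


def _obstacle_segments(
    target: np.ndarray, others: list[np.ndarray], box: float, shell: float = 1.0
) -> np.ndarray:
    """Segments of all other chains, replicated over the periodic images that
    can reach the target chain's bounding box inflated by ``shell``."""
    lo = target.min(axis=0) - shell
    hi = target.max(axis=0) + shell
    segs = []
    for X in others:
        s0, s1 = X[:-1], X[1:]
        smin = np.minimum(s0, s1)
        smax = np.maximum(s0, s1)
        shifts = []
        for d in range(3):
            kmin = int(np.floor((lo[d] - smax[:, d].max()) / box))
            kmax = int(np.ceil((hi[d] - smin[:, d].min()) / box))
            shifts.append(range(kmin, kmax + 1))
        for kx, ky, kz in itertools.product(*shifts):
            off = np.array([kx, ky, kz], dtype=float) * box
            keep = np.all(smax + off >= lo, axis=1) & np.all(
                smin + off <= hi, axis=1
            )
            if np.any(keep):
                segs.append(
                    np.concatenate([s0[keep] + off, s1[keep] + off], axis=1)
                )
    if not segs:
        return np.zeros((0, 6))
    return np.ascontiguousarray(np.concatenate(segs, axis=0))


def _count_kinks(path: np.ndarray, angle_tol: float, merge_tol: float) -> int:
    m = len(path)
    if m < 3:
        return 0
    kinks = []
    for i in range(1, m - 1):
        a = path[i] - path[i - 1]
        b = path[i + 1] - path[i]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            continue
        c = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
        if np.arccos(c) >= angle_tol:
            kinks.append(path[i])
    if not kinks:
        return 0
    count = 1
    for prev, cur in zip(kinks[:-1], kinks[1:]):
        if np.linalg.norm(cur - prev) > merge_tol:
            count += 1
    return count


def contract(
    config: PolymerConfiguration,
    mode: str = "self-consistent",
    max_sweeps: int = 2000,
    length_tol: float = 1e-6,
    kink_angle: float = 1e-3,
    kink_merge_tol: float = 0.25,
    lam_min: float = 1e-6,
) -> PrimitivePathResult:
    """Contract every chain to its primitive path with ends held fixed.

    ``mode='self-consistent'`` contracts all chains against each other's
    current (shrinking) paths, sweeping chains in index order until the total
    length decrease per sweep falls below ``length_tol``; this matches
    primitive-path-network practice.  ``mode='fixed'`` keeps the *original*
    conformations of the other chains as obstacles (the oracle-friendly
    variant).  Nodes wedged against an obstacle slide along it towards the
    taut contact point.  Deterministic given the node ordering (chain index,
    then rank).
    """
    if mode not in ("self-consistent", "fixed"):
        raise ValueError("mode must be 'self-consistent' or 'fixed'")
    chains = _unwrapped_chains(config)
    originals = [X.copy() for X in chains]
    box = config.box_edge
    counts = [len(X) for X in chains]
    bufs = [np.ascontiguousarray(X.copy()) for X in chains]

    converged = False
    prev_total = sum(
        _path_length(bufs[c], counts[c]) for c in range(len(bufs))
    )
    for _ in range(max_sweeps):
        for c in range(len(bufs)):
            cur = bufs[c][: counts[c]]
            if mode == "fixed":
                others = [originals[k] for k in range(len(bufs)) if k != c]
            else:
                others = [
                    bufs[k][: counts[k]] for k in range(len(bufs)) if k != c
                ]
            segs = _obstacle_segments(cur, others, box)
            m = _sweep(bufs[c], counts[c], segs, lam_min)
            m = _drop_collinear(bufs[c], m, 0.5 * CLEARANCE, segs)
            counts[c] = m
        total = sum(_path_length(bufs[c], counts[c]) for c in range(len(bufs)))
        if prev_total - total < length_tol:
            converged = True
            break
        prev_total = total
    if not converged:
        warnings.warn(
            "primitive-path contraction hit the sweep budget before converging",
            RuntimeWarning,
        )
    final_paths = [bufs[c][: counts[c]].copy() for c in range(len(bufs))]
    Lpp = np.array([_path_length(p, len(p)) for p in final_paths])
    Z = np.array(
        [_count_kinks(p, kink_angle, kink_merge_tol) for p in final_paths],
        dtype=np.int64,
    )
    Ree = np.array([float(np.linalg.norm(X[-1] - X[0])) for X in originals])
    try:
        Np = config.beads_per_chain
    except ValueError:  # mixed-length fixtures: use the mean chain length
        Np = int(round(np.mean([len(X) for X in originals])))
    Ne = entanglement_length_from_values(Ree, Lpp, Np)
    return PrimitivePathResult(Lpp, Z, Ree, Ne, Np, final_paths, converged)


def entanglement_length_from_values(
    Ree: np.ndarray, Lpp: np.ndarray, Np: int
) -> float:
    lpp2 = float(np.mean(np.asarray(Lpp) ** 2))
    if lpp2 == 0:
        raise ZeroDivisionError("mean squared primitive-path length is zero")
    return (Np - 1) * float(np.mean(np.asarray(Ree) ** 2)) / lpp2


def entanglement_length(results: PrimitivePathResult, Np: int | None = None) -> float:
    """Entanglement length ``N_e = (Np - 1) <R_ee^2> / <L_pp^2>`` (ensemble means)."""
    return entanglement_length_from_values(
        results.Ree, results.Lpp, results.Np if Np is None else Np
    )


def equilibrium_plateau_prediction(
    rho_star: float, Ne0: float, kBT: float = 1.0, sigma: float = 1.0
) -> float:
    """Equilibrium tube-model plateau estimate ``G0 = 4 rho kBT / (5 Ne0)``.

    With the reduced density rho* and Ne0 the passive entanglement length;
    returned in kBT/sigma^3.
    """
    if Ne0 <= 0:
        raise ValueError("Ne0 must be positive")
    return 4.0 * rho_star * kBT / (5.0 * Ne0 * sigma**3)


def ppa_timeseries(
    frames: list,
    reference: PrimitivePathResult | None = None,
    v: float | None = None,
    L: float | None = None,
    mode: str = "self-consistent",
    **contract_kw,
) -> dict:
    """Primitive-path observables along a trajectory, optionally normalized.

    Returns arrays of time (and rescaled time t*v/L when both are supplied),
    mean L_pp, Z, N_e and R_ee; when a passive reference result is given, the
    normalized ratios L_pp/L_pp0, Z/Z0 and N_e/N_e0 are included as well.
    """
    t, lpp, z, ne, ree = [], [], [], [], []
    for f in frames:
        res = contract(f, mode=mode, **contract_kw)
        t.append(f.time)
        lpp.append(float(np.mean(res.Lpp)))
        z.append(float(np.mean(res.Z)))
        ne.append(res.Ne)
        ree.append(float(np.mean(res.Ree)))
    out = {
        "time": np.asarray(t),
        "Lpp": np.asarray(lpp),
        "Z": np.asarray(z),
        "Ne": np.asarray(ne),
        "Ree": np.asarray(ree),
    }
    if v is not None and L is not None and v > 0:
        out["tv_over_L"] = out["time"] * v / L
    if reference is not None:
        lpp0 = float(np.mean(reference.Lpp))
        z0 = float(np.mean(reference.Z))
        ne0 = reference.Ne
        out["Lpp_ratio"] = out["Lpp"] / lpp0
        out["Z_ratio"] = out["Z"] / z0 if z0 > 0 else np.full_like(out["Z"], np.nan)
        out["Ne_ratio"] = out["Ne"] / ne0
    return out
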