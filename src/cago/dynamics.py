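"""Langevin dynamics over a Go topology.

Forces are the exact negative gradient of the potential (no neighbour-list
approximations at desk scale); the integrator is a BAOAB-split Langevin
leapfrog that reduces to velocity Verlet (NVE) at zero friction.  All
randomness comes from one seeded generator and replaying a seed
reproduces frames bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from cago.sbm import SBMTopology

__all__ = ["Trajectory", "potential_energy", "forces", "run_langevin"]


@dataclass(frozen=True)
class Trajectory:
    """Simulation frames with per-frame energies (reduced units)."""

    frames: np.ndarray            # (F, n, 3)
    potential_energy: np.ndarray  # (F,)
    kinetic_energy: np.ndarray    # (F,)
    step_indices: np.ndarray      # (F,)
    T: float
    seed: int
    dt: float
    friction: float
    topology_provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.frames) != len(self.step_indices):
            raise ValueError("frame count must match step_indices")
        if not np.all(np.isfinite(self.potential_energy)):
            raise ValueError("non-finite energies in trajectory")


@njit(cache=True)
def _eval_forces(x, f, e, bond_idx, bond_r0, k_bond,
                 angle_idx, angle_theta0, k_angle,
                 dih_idx, dih_phi0, k_dih,
                 c_idx, c_sigma, c_eps,
                 nn_mask, sigma_nn, eps_nn, rcut_nn):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_dih = 0.0
    e_contact = 0.0
    e_nn = 0.0

    # bonds: V = k (r - r0)^2
    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - bond_r0[b]
        e_bond += k_bond * dr * dr
        fac = -2.0 * k_bond * dr / r
        f[i, 0] += fac * dx0
        f[i, 1] += fac * dx1
        f[i, 2] += fac * dx2
        f[j, 0] -= fac * dx0
        f[j, 1] -= fac * dx1
        f[j, 2] -= fac * dx2

    # angles: V = k (theta - theta0)^2
    for a in range(angle_idx.shape[0]):
        i, j, k = angle_idx[a, 0], angle_idx[a, 1], angle_idx[a, 2]
        r0 = x[i, 0] - x[j, 0]
        r1 = x[i, 1] - x[j, 1]
        r2_ = x[i, 2] - x[j, 2]
        s0 = x[k, 0] - x[j, 0]
        s1 = x[k, 1] - x[j, 1]
        s2_ = x[k, 2] - x[j, 2]
        nij = np.sqrt(r0 * r0 + r1 * r1 + r2_ * r2_)
        nkj = np.sqrt(s0 * s0 + s1 * s1 + s2_ * s2_)
        cost = (r0 * s0 + r1 * s1 + r2_ * s2_) / (nij * nkj)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        dtheta = theta - angle_theta0[a]
        e_angle += k_angle * dtheta * dtheta
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        coef = 2.0 * k_angle * dtheta / sint  # = -dV/dtheta * dtheta/dcos
        inv_ij_kj = 1.0 / (nij * nkj)
        inv_ij2 = cost / (nij * nij)
        inv_kj2 = cost / (nkj * nkj)
        di0 = coef * (s0 * inv_ij_kj - r0 * inv_ij2)
        di1 = coef * (s1 * inv_ij_kj - r1 * inv_ij2)
        di2 = coef * (s2_ * inv_ij_kj - r2_ * inv_ij2)
        dk0 = coef * (r0 * inv_ij_kj - s0 * inv_kj2)
        dk1 = coef * (r1 * inv_ij_kj - s1 * inv_kj2)
        dk2 = coef * (r2_ * inv_ij_kj - s2_ * inv_kj2)
        f[i, 0] += di0
        f[i, 1] += di1
        f[i, 2] += di2
        f[k, 0] += dk0
        f[k, 1] += dk1
        f[k, 2] += dk2
        f[j, 0] -= di0 + dk0
        f[j, 1] -= di1 + dk1
        f[j, 2] -= di2 + dk2

    # dihedrals: V = k [(1 - cos(phi - phi0)) + 0.5 (1 - cos 3(phi - phi0))]
    for q in range(dih_idx.shape[0]):
        i, j, k, l = dih_idx[q, 0], dih_idx[q, 1], dih_idx[q, 2], dih_idx[q, 3]
        b10 = x[j, 0] - x[i, 0]
        b11 = x[j, 1] - x[i, 1]
        b12 = x[j, 2] - x[i, 2]
        b20 = x[k, 0] - x[j, 0]
        b21 = x[k, 1] - x[j, 1]
        b22 = x[k, 2] - x[j, 2]
        b30 = x[l, 0] - x[k, 0]
        b31 = x[l, 1] - x[k, 1]
        b32 = x[l, 2] - x[k, 2]
        n10 = b11 * b22 - b12 * b21
        n11 = b12 * b20 - b10 * b22
        n12 = b10 * b21 - b11 * b20
        n20 = b21 * b32 - b22 * b31
        n21 = b22 * b30 - b20 * b32
        n22 = b20 * b31 - b21 * b30
        nb2 = np.sqrt(b20 * b20 + b21 * b21 + b22 * b22)
        cx = n11 * n22 - n12 * n21
        cy = n12 * n20 - n10 * n22
        cz = n10 * n21 - n11 * n20
        y = (cx * b20 + cy * b21 + cz * b22) / nb2
        xdot = n10 * n20 + n11 * n21 + n12 * n22
        phi = np.arctan2(y, xdot)
        dphi = phi - dih_phi0[q]
        e_dih += k_dih * ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dv = k_dih * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))  # dV/dphi
        n1sq = n10 * n10 + n11 * n11 + n12 * n12
        n2sq = n20 * n20 + n21 * n21 + n22 * n22
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # dphi/dr_i = -|b2|/|n1|^2 n1 ; dphi/dr_l = |b2|/|n2|^2 n2
        p = nb2 / n1sq
        s = nb2 / n2sq
        inv_b2sq = 1.0 / (nb2 * nb2)
        b1b2 = (b10 * b20 + b11 * b21 + b12 * b22) * inv_b2sq
        b3b2 = (b30 * b20 + b31 * b21 + b32 * b22) * inv_b2sq
        ca = -1.0 - b1b2
        cb = -1.0 - b3b2
        for d in range(3):
            if d == 0:
                n1d, n2d = n10, n20
            elif d == 1:
                n1d, n2d = n11, n21
            else:
                n1d, n2d = n12, n22
            dpi = -p * n1d
            dpl = s * n2d
            dpj = ca * dpi + b3b2 * dpl
            dpk = b1b2 * dpi + cb * dpl
            f[i, d] -= dv * dpi
            f[j, d] -= dv * dpj
            f[k, d] -= dv * dpk
            f[l, d] -= dv * dpl

    # native contacts: V = eps [5 (s/r)^12 - 6 (s/r)^10]
    for c in range(c_idx.shape[0]):
        i, j = c_idx[c, 0], c_idx[c, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        s2 = c_sigma[c] * c_sigma[c] / r2
        s10 = s2 ** 5
        s12 = s10 * s2
        e_contact += c_eps[c] * (5.0 * s12 - 6.0 * s10)
        # dV/dr * 1/r = eps (-60 s12 + 60 s10)/r^2
        fac = -c_eps[c] * 60.0 * (s12 - s10) / r2
        f[i, 0] -= fac * dx0
        f[i, 1] -= fac * dx1
        f[i, 2] -= fac * dx2
        f[j, 0] += fac * dx0
        f[j, 1] += fac * dx1
        f[j, 2] += fac * dx2

    # excluded volume: V = eps_nn [(sigma_nn/r)^12 - (sigma_nn/rcut)^12], r < rcut
    rcut2 = rcut_nn * rcut_nn
    shift = eps_nn * (sigma_nn / rcut_nn) ** 12
    n_beads = x.shape[0]
    for i in range(n_beads):
        for j in range(i + 1, n_beads):
            if not nn_mask[i, j]:
                continue
            dx0 = x[i, 0] - x[j, 0]
            dx1 = x[i, 1] - x[j, 1]
            dx2 = x[i, 2] - x[j, 2]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            if r2 >= rcut2:
                continue
            s12 = (sigma_nn * sigma_nn / r2) ** 6
            e_nn += eps_nn * s12 - shift
            fac = 12.0 * eps_nn * s12 / r2
            f[i, 0] += fac * dx0
            f[i, 1] += fac * dx1
            f[i, 2] += fac * dx2
            f[j, 0] -= fac * dx0
            f[j, 1] -= fac * dx1
            f[j, 2] -= fac * dx2

    e[0] = e_bond
    e[1] = e_angle
    e[2] = e_dih
    e[3] = e_contact
    e[4] = e_nn


@njit(cache=True)
def _integrate(x0, v0, masses, n_steps, dt, friction, T, save_every, seed,
               bond_idx, bond_r0, k_bond, angle_idx, angle_theta0, k_angle,
               dih_idx, dih_phi0, k_dih, c_idx, c_sigma, c_eps,
               nn_mask, sigma_nn, eps_nn, rcut_nn):
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = v0.copy()
    n_frames = n_steps // save_every
    frames = np.empty((n_frames, n, 3))
    epot = np.empty(n_frames)
    ekin = np.empty(n_frames)
    steps = np.empty(n_frames, dtype=np.int64)

    f = np.zeros((n, 3))
    e = np.zeros(5)
    _eval_forces(x, f, e, bond_idx, bond_r0, k_bond, angle_idx, angle_theta0,
                 k_angle, dih_idx, dih_phi0, k_dih, c_idx, c_sigma,
                 c_eps, nn_mask, sigma_nn, eps_nn, rcut_nn)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1) * T))
    frame = 0
    blowup_step = -1
    for step in range(n_steps):
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d] * inv_m
                x[i, d] += 0.5 * dt * v[i, d]
        if friction > 0.0:
            for i in range(n):
                sd = c2 / np.sqrt(masses[i])
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + sd * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                x[i, d] += 0.5 * dt * v[i, d]
        _eval_forces(x, f, e, bond_idx, bond_r0, k_bond, angle_idx,
                     angle_theta0, k_angle, dih_idx, dih_phi0, k_dih,
                     c_idx, c_sigma, c_eps, nn_mask, sigma_nn, eps_nn,
                     rcut_nn)
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d] * inv_m
        if (step + 1) % save_every == 0:
            et = e[0] + e[1] + e[2] + e[3] + e[4]
            ke = 0.0
            ok = True
            for i in range(n):
                for d in range(3):
                    ke += 0.5 * masses[i] * v[i, d] * v[i, d]
                    if not np.isfinite(x[i, d]):
                        ok = False
            if (not ok) or (not np.isfinite(et)):
                blowup_step = step + 1
                break
            frames[frame] = x
            epot[frame] = et
            ekin[frame] = ke
            steps[frame] = step + 1
            frame += 1
    return frames, epot, ekin, steps, frame, blowup_step, x, v


def _topo_args(topo: SBMTopology):
    c_idx, c_sigma, c_eps = topo.contact_arrays()
    return (
        np.ascontiguousarray(topo.bond_idx, dtype=np.int64),
        np.ascontiguousarray(topo.bond_r0, dtype=np.float64),
        float(topo.k_bond),
        np.ascontiguousarray(topo.angle_idx, dtype=np.int64),
        np.ascontiguousarray(topo.angle_theta0, dtype=np.float64),
        float(topo.k_angle),
        np.ascontiguousarray(topo.dih_idx, dtype=np.int64),
        np.ascontiguousarray(topo.dih_phi0, dtype=np.float64),
        float(topo.k_dih),
        np.ascontiguousarray(c_idx.reshape(-1, 2), dtype=np.int64),
        np.ascontiguousarray(c_sigma, dtype=np.float64),
        np.ascontiguousarray(c_eps, dtype=np.float64),
        np.ascontiguousarray(topo.nn_exclusion_mask()),
        float(topo.sigma_nn),
        float(topo.eps_nn),
        float(topo.rcut_nn),
    )


_TERMS = ("bonds", "angles", "dihedrals", "contacts", "non_native")


def potential_energy(topo: SBMTopology, coords: np.ndarray):
    """Total potential energy and its per-term breakdown.

    Returns ``(total, breakdown)`` where breakdown maps term name
    (bonds, angles, dihedrals, contacts, non_native) to its energy.
    """
    x = np.ascontiguousarray(coords, dtype=np.float64)
    if x.shape != (topo.n_beads, 3):
        raise ValueError(f"coords must have shape ({topo.n_beads}, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    f = np.zeros((topo.n_beads, 3))
    e = np.zeros(5)
    _eval_forces(x, f, e, *_topo_args(topo))
    breakdown = dict(zip(_TERMS, map(float, e)))
    return float(e.sum()), breakdown


def forces(topo: SBMTopology, coords: np.ndarray) -> np.ndarray:
    """Per-bead force vectors, the exact negative potential gradient."""
    x = np.ascontiguousarray(coords, dtype=np.float64)
    if x.shape != (topo.n_beads, 3):
        raise ValueError(f"coords must have shape ({topo.n_beads}, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    f = np.zeros((topo.n_beads, 3))
    e = np.zeros(5)
    _eval_forces(x, f, e, *_topo_args(topo))
    return f


def run_langevin(
    topo: SBMTopology,
    T: float,
    n_steps: int,
    dt: float = 0.0005,
    friction: float = 1.0,
    seed: int = 0,
    save_every: int = 100,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
) -> Trajectory:
    """Langevin (BAOAB) trajectory at reduced temperature T.

    Starts from the native coordinates unless ``x0`` is given; initial
    velocities are Maxwell-Boltzmann at T unless ``v0`` is given.
    ``friction = 0`` yields NVE velocity-Verlet dynamics (no thermostat).
    Deterministic given ``seed``.
    """
    if dt <= 0 or T < 0 or friction < 0:
        raise ValueError("dt must be > 0 and T, friction >= 0")
    if n_steps < save_every:
        raise ValueError("n_steps must be >= save_every")
    seed = int(seed) & 0x7FFFFFFF
    x = np.ascontiguousarray(
        topo.native_coords if x0 is None else x0, dtype=np.float64
    ).copy()
    if x.shape != (topo.n_beads, 3):
        raise ValueError(f"x0 must have shape ({topo.n_beads}, 3)")
    masses = np.ascontiguousarray(topo.masses, dtype=np.float64)
    if v0 is None:
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((topo.n_beads, 3)) * np.sqrt(T / masses)[:, None]
    else:
        v = np.ascontiguousarray(v0, dtype=np.float64).copy()
    frames, epot, ekin, steps, n_ok, blowup, _, _ = _integrate(
        x, v, masses, int(n_steps), float(dt), float(friction), float(T),
        int(save_every), seed, *_topo_args(topo)
    )
    if blowup >= 0:
        raise RuntimeError(f"numerical blow-up (non-finite state) at step {blowup}")
    return Trajectory(
        frames=frames[:n_ok],
        potential_energy=epot[:n_ok],
        kinetic_energy=ekin[:n_ok],
        step_indices=steps[:n_ok],
        T=float(T),
        seed=seed,
        dt=float(dt),
        friction=float(friction),
        topology_provenance=topo.provenance,
    )
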