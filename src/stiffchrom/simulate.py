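"""Confined multichain bead-spring dynamics.

The nucleus is modeled as ``n_chains`` identical block-copolymer chains
confined to a hard sphere whose radius is set by the requested bead volume
fraction.  Dynamics are overdamped Langevin (kT = 1, friction gamma = 1):

    x(t + dt) = x(t) + F(x) dt + sqrt(2 dt) eta,   eta ~ N(0, 1)

with per-step displacements capped for numerical robustness and positions
reflected at the confinement sphere.  The force field is documented in
:mod:`stiffchrom.energy`.

Everything stochastic is driven by explicit integer seeds; the same
(configuration, seed) pair reproduces bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .energy import EnergyModel
from .layout import ChainLayout

_MAX_DISP = 0.15  # per-step cap on the force displacement (sigma)


@dataclass
class NucleusEnsemble:
    """State of one simulated nucleus (possibly with stored samples).

    ``positions`` holds the current coordinates, shape (n_beads_total, 3),
    in units of sigma.  ``samples`` holds conformations stored during a run,
    shape (n_samples, n_beads_total, 3), or None before any run.
    """

    layout: ChainLayout
    n_chains: int
    R_confine: float
    positions: np.ndarray
    replicate_seed: int
    samples: np.ndarray | None = None

    @property
    def n_beads_total(self) -> int:
        return self.n_chains * self.layout.n_beads

    @property
    def chain_of_bead(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.layout.n_beads)

    @property
    def label_codes(self) -> np.ndarray:
        return np.tile(self.layout.label_codes, self.n_chains)


def confinement_radius(n_beads_total: int, volume_fraction: float, sigma: float = 1.0) -> float:
    """Sphere radius giving the requested bead volume fraction.

    Beads of diameter sigma have volume (pi/6) sigma^3, so
    phi = n (pi/6) sigma^3 / ((4/3) pi R^3)  =>  R = (n sigma^3 / (8 phi))^(1/3).
    """
    return (n_beads_total * sigma**3 / (8.0 * volume_fraction)) ** (1.0 / 3.0)


def init_system(
    layout: ChainLayout,
    n_chains: int,
    volume_fraction: float = 0.10,
    seed: int = 0,
    min_separation: float = 0.8,
    max_attempts: int = 40,
) -> NucleusEnsemble:
    """Place chains as confined self-avoiding random walks.

    Each chain starts from a uniformly drawn interior point and grows as a
    unit-step random walk reflected at the confinement sphere; candidate
    steps placing a bead closer than ``min_separation`` (sigma) to any
    already-placed bead are rejected (with single-bead backtracking when a
    growth front jams).  Deterministic for a fixed seed.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if not (0 < volume_fraction < 0.5):
        raise ValueError("volume_fraction must lie in (0, 0.5)")
    n = layout.n_beads
    N = n * n_chains
    R = confinement_radius(N, volume_fraction)
    rng = np.random.default_rng(seed)
    min_sep2 = min_separation**2

    # occupancy grid with unit cell size for O(1) neighborhood checks
    grid: dict[tuple[int, int, int], list[int]] = {}
    placed = np.empty((N, 3))
    n_placed = 0

    def cell_key(x: np.ndarray) -> tuple[int, int, int]:
        return (int(np.floor(x[0])), int(np.floor(x[1])), int(np.floor(x[2])))

    def clear(x: np.ndarray) -> bool:
        kx, ky, kz = cell_key(x)
        for ax in range(kx - 1, kx + 2):
            for ay in range(ky - 1, ky + 2):
                for az in range(kz - 1, kz + 2):
                    for idx in grid.get((ax, ay, az), ()):
                        d = placed[idx] - x
                        if d @ d < min_sep2:
                            return False
        return True

    def put(x: np.ndarray) -> int:
        nonlocal n_placed
        placed[n_placed] = x
        grid.setdefault(cell_key(x), []).append(n_placed)
        n_placed += 1
        return n_placed - 1

    def pop() -> None:
        nonlocal n_placed
        n_placed -= 1
        grid[cell_key(placed[n_placed])].remove(n_placed)

    total_backtracks = 0
    backtrack_budget = 200 * N
    for c in range(n_chains):
        for _ in range(10_000):
            x0 = rng.uniform(-0.9 * R, 0.9 * R, size=3)
            if np.linalg.norm(x0) < 0.9 * R and clear(x0):
                break
        else:
            raise RuntimeError("packing infeasible: could not seed a chain start")
        put(x0)
        grown = 1
        while grown < n:
            ok = False
            last = placed[n_placed - 1]
            for _ in range(max_attempts):
                v = rng.standard_normal(3)
                v /= np.linalg.norm(v)
                x = last + v
                r = np.linalg.norm(x)
                if r > R:
                    x = x * ((2 * R - r) / r)
                if clear(x):
                    put(x)
                    grown += 1
                    ok = True
                    break
            if not ok:
                if grown > 1:
                    pop()
                    grown -= 1
                    total_backtracks += 1
                    if total_backtracks > backtrack_budget:
                        raise RuntimeError(
                            "packing infeasible: chain growth exceeded its "
                            "backtracking budget (volume fraction too high?)"
                        )
                else:
                    raise RuntimeError("packing infeasible: chain start jammed")

    return NucleusEnsemble(
        layout=layout,
        n_chains=n_chains,
        R_confine=R,
        positions=placed.copy(),
        replicate_seed=seed,
    )


@njit(cache=True)
def _compute_forces(
    pos,
    forces,
    codes,
    n_chains,
    n_per_chain,
    KA,
    KB,
    Kbase,
    EAA,
    EBB,
    bond_k,
    bond_r0,
    ev_eps,
    cutoff,
    R,
    head,
    nxt,
    ncell,
    cell_size,
):
    N = pos.shape[0]
    for i in range(N):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    # bonds
    for c in range(n_chains):
        base = c * n_per_chain
        for j in range(n_per_chain - 1):
            i0 = base + j
            i1 = i0 + 1
            dx = pos[i1, 0] - pos[i0, 0]
            dy = pos[i1, 1] - pos[i0, 1]
            dz = pos[i1, 2] - pos[i0, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-12:
                continue
            f = bond_k * (r - bond_r0) / r
            forces[i0, 0] += f * dx
            forces[i0, 1] += f * dy
            forces[i0, 2] += f * dz
            forces[i1, 0] -= f * dx
            forces[i1, 1] -= f * dy
            forces[i1, 2] -= f * dz

    # bending: U = K (1 + cos theta) at each interior bead
    for c in range(n_chains):
        base = c * n_per_chain
        for j in range(1, n_per_chain - 1):
            i = base + j
            code = codes[i]
            if code == 0:
                K = KA
            elif code == 1:
                K = KB
            else:
                K = Kbase
            if K == 0.0:
                continue
            ux = pos[i - 1, 0] - pos[i, 0]
            uy = pos[i - 1, 1] - pos[i, 1]
            uz = pos[i - 1, 2] - pos[i, 2]
            vx = pos[i + 1, 0] - pos[i, 0]
            vy = pos[i + 1, 1] - pos[i, 1]
            vz = pos[i + 1, 2] - pos[i, 2]
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            if nu < 1e-12 or nv < 1e-12:
                continue
            ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            # d(cos)/du = v/(|u||v|) - cos * u/|u|^2  (and symmetric in v)
            gux = vx / (nu * nv) - ct * ux / (nu * nu)
            guy = vy / (nu * nv) - ct * uy / (nu * nu)
            guz = vz / (nu * nv) - ct * uz / (nu * nu)
            gvx = ux / (nu * nv) - ct * vx / (nv * nv)
            gvy = uy / (nu * nv) - ct * vy / (nv * nv)
            gvz = uz / (nu * nv) - ct * vz / (nv * nv)
            forces[i - 1, 0] -= K * gux
            forces[i - 1, 1] -= K * guy
            forces[i - 1, 2] -= K * guz
            forces[i + 1, 0] -= K * gvx
            forces[i + 1, 1] -= K * gvy
            forces[i + 1, 2] -= K * gvz
            forces[i, 0] += K * (gux + gvx)
            forces[i, 1] += K * (guy + gvy)
            forces[i, 2] += K * (guz + gvz)

    # nonbonded: WCA core for all pairs, attractive LJ tail for like pairs
    wca_cut = 2.0 ** (1.0 / 6.0)
    cut2 = cutoff * cutoff
    use_cells = ncell > 0
    if use_cells:
        # rebuild linked-cell list
        for k in range(head.shape[0]):
            head[k] = -1
        for i in range(N):
            cx = int((pos[i, 0] + R) / cell_size)
            cy = int((pos[i, 1] + R) / cell_size)
            cz = int((pos[i, 2] + R) / cell_size)
            if cx < 0:
                cx = 0
            if cy < 0:
                cy = 0
            if cz < 0:
                cz = 0
            if cx >= ncell:
                cx = ncell - 1
            if cy >= ncell:
                cy = ncell - 1
            if cz >= ncell:
                cz = ncell - 1
            k = (cx * ncell + cy) * ncell + cz
            nxt[i] = head[k]
            head[k] = i

    for i in range(N):
        if use_cells:
            cx = int((pos[i, 0] + R) / cell_size)
            cy = int((pos[i, 1] + R) / cell_size)
            cz = int((pos[i, 2] + R) / cell_size)
            if cx < 0:
                cx = 0
            if cy < 0:
                cy = 0
            if cz < 0:
                cz = 0
            if cx >= ncell:
                cx = ncell - 1
            if cy >= ncell:
                cy = ncell - 1
            if cz >= ncell:
                cz = ncell - 1
            for ox in range(-1, 2):
                gx = cx + ox
                if gx < 0 or gx >= ncell:
                    continue
                for oy in range(-1, 2):
                    gy = cy + oy
                    if gy < 0 or gy >= ncell:
                        continue
                    for oz in range(-1, 2):
                        gz = cz + oz
                        if gz < 0 or gz >= ncell:
                            continue
                        j = head[(gx * ncell + gy) * ncell + gz]
                        while j != -1:
                            if j > i:
                                _pair_force(
                                    pos, forces, codes, i, j,
                                    n_per_chain, EAA, EBB, ev_eps,
                                    wca_cut, cut2,
                                )
                            j = nxt[j]
        else:
            for j in range(i + 1, N):
                _pair_force(
                    pos, forces, codes, i, j,
                    n_per_chain, EAA, EBB, ev_eps, wca_cut, cut2,
                )


@njit(cache=True, inline="always")
def _pair_force(pos, forces, codes, i, j, n_per_chain, EAA, EBB, ev_eps, wca_cut, cut2):
    # skip bonded neighbors (same chain, adjacent index)
    if j == i + 1 and (i % n_per_chain) != n_per_chain - 1:
        return
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= cut2 or r2 < 1e-12:
        return
    ci = codes[i]
    cj = codes[j]
    eps_att = 0.0
    if ci == cj:
        if ci == 0:
            eps_att = EAA
        elif ci == 1:
            eps_att = EBB
    inv_r2 = 1.0 / r2
    inv_r6 = inv_r2 * inv_r2 * inv_r2
    f = 0.0
    if r2 < wca_cut * wca_cut and ev_eps > 0.0:
        # WCA: F/r = 24 eps (2/r^12 - 1/r^6)/r^2
        f += 24.0 * ev_eps * (2.0 * inv_r6 * inv_r6 - inv_r6) * inv_r2
    if eps_att > 0.0 and r2 >= wca_cut * wca_cut:
        # attractive LJ tail scaled by well depth
        f += 24.0 * eps_att * (2.0 * inv_r6 * inv_r6 - inv_r6) * inv_r2
    if f != 0.0:
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz


@njit(cache=True)
def _run_dynamics(
    pos,
    codes,
    n_chains,
    n_per_chain,
    KA,
    KB,
    Kbase,
    EAA,
    EBB,
    bond_k,
    bond_r0,
    ev_eps,
    cutoff,
    R,
    dt,
    n_steps,
    eq_steps,
    sample_every,
    n_samples,
    seed,
    max_disp,
):
    np.random.seed(seed)
    N = pos.shape[0]
    forces = np.zeros((N, 3))
    samples = np.zeros((n_samples, N, 3))
    if np.isfinite(R):
        cell_size = max(cutoff, 2.0 * R / 64.0)
        ncell = max(1, int(2.0 * R / cell_size))
        cell_size = 2.0 * R / ncell + 1e-9
    else:
        ncell = 0
        cell_size = 1.0
    head = np.full(max(1, ncell**3), -1, dtype=np.int64)
    nxt = np.full(N, -1, dtype=np.int64)
    amp = np.sqrt(2.0 * dt)
    s_idx = 0
    for step in range(n_steps):
        _compute_forces(
            pos, forces, codes, n_chains, n_per_chain,
            KA, KB, Kbase, EAA, EBB, bond_k, bond_r0,
            ev_eps, cutoff, R, head, nxt, ncell, cell_size,
        )
        for i in range(N):
            for d in range(3):
                fdx = forces[i, d] * dt
                # cap only the deterministic term; noise stays unbiased
                if fdx > max_disp:
                    fdx = max_disp
                elif fdx < -max_disp:
                    fdx = -max_disp
                pos[i, d] += fdx + amp * np.random.standard_normal()
            if np.isfinite(R):
                r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                if r > R:
                    scale = (2.0 * R - r) / r
                    pos[i, 0] *= scale
                    pos[i, 1] *= scale
                    pos[i, 2] *= scale
        if step + 1 > eq_steps and (step + 1 - eq_steps) % sample_every == 0:
            if s_idx < n_samples:
                for i in range(N):
                    samples[s_idx, i, 0] = pos[i, 0]
                    samples[s_idx, i, 1] = pos[i, 1]
                    samples[s_idx, i, 2] = pos[i, 2]
                s_idx += 1
        if (step + 1) % 200 == 0:
            ok = True
            for i in range(N):
                if not (
                    np.isfinite(pos[i, 0])
                    and np.isfinite(pos[i, 1])
                    and np.isfinite(pos[i, 2])
                ):
                    ok = False
                    break
            if not ok:
                return samples, s_idx, step + 1
    return samples, s_idx, -1


def run_simulation(
    ensemble: NucleusEnsemble,
    energy_model: EnergyModel,
    n_steps: int,
    sample_every: int = 500,
    seed: int = 0,
    equilibration_fraction: float = 0.5,
    dt: float = 0.005,
) -> NucleusEnsemble:
    """Run overdamped Langevin dynamics and store conformational samples.

    The first ``equilibration_fraction`` of steps are discarded; thereafter a
    conformation is stored every ``sample_every`` steps.  ``n_steps = 0``
    returns the input ensemble unchanged.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps == 0:
        return ensemble
    eq_steps = int(n_steps * equilibration_fraction)
    n_samples = max(0, (n_steps - eq_steps)) // sample_every
    if n_samples == 0 and n_steps > eq_steps:
        # guarantee at least the final conformation is stored
        sample_every = n_steps - eq_steps
        n_samples = 1
    pos = ensemble.positions.copy()
    samples, s_idx, bad_step = _run_dynamics(
        pos,
        ensemble.label_codes,
        ensemble.n_chains,
        ensemble.layout.n_beads,
        float(energy_model.K_theta_A * energy_model.K_theta_base),
        float(energy_model.K_theta_B * energy_model.K_theta_base),
        float(energy_model.K_theta_base),
        float(energy_model.E_AA),
        float(energy_model.E_BB),
        float(energy_model.bond_k),
        float(energy_model.bond_r0),
        float(energy_model.ev_epsilon),
        float(energy_model.attraction_cutoff),
        float(ensemble.R_confine),
        float(dt),
        int(n_steps),
        int(eq_steps),
        int(sample_every),
        int(n_samples),
        int(seed) % (2**31 - 1),
        _MAX_DISP,
    )
    if bad_step >= 0:
        raise FloatingPointError(
            f"non-finite coordinate detected at step {bad_step}"
        )
    return replace(ensemble, positions=pos, samples=samples[:s_idx])
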