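"""Reduced-unit NVT molecular dynamics of droplets on a tabulated pair potential.

Units: length in droplet radii R, energy in k_BT, mass m = 1, time in
tau = R*sqrt(m/k_BT).  The integrator is velocity Verlet with periodic
boundaries and minimum-image forces interpolated from a
:class:`~microemu.potential.TabulatedPotential`.  Temperature control is
velocity rescaling during equilibration and a Nose-Hoover thermostat (single
chain, weak coupling) during production, so that production dynamics remain
deterministic and momentum-conserving; pure NVE production is available for
energy-conservation checks.

Pair forces use a linked-cell list when the box accommodates at least three
cells per edge, with an O(N^2) minimum-image fallback (also the test oracle)
otherwise.  Kernels are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from .potential import TabulatedPotential
from .units import box_length

__all__ = [
    "SimulationConfig",
    "Configuration",
    "Trajectory",
    "init_configuration",
    "compute_forces",
    "compute_forces_brute",
    "step_nve",
    "run",
]


@dataclass(frozen=True)
class SimulationConfig:
    N: int = 1000
    phi: float = 0.0698
    dt: float = 0.001
    T_star: float = 1.0
    n_equil: int = 5000
    n_prod: int = 20000
    save_stride: int = 10
    seed: int = 0
    thermostat: Literal["nose-hoover", "velocity-rescale", "none"] = "nose-hoover"
    nh_damping: float = 0.1  # Nose-Hoover time constant, 100*dt by default

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0 < self.phi < 0.74:
            raise ValueError("phi must lie in (0, 0.74)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def L(self) -> float:
        return box_length(self.N, self.phi)


@dataclass
class Configuration:
    L: float
    positions: np.ndarray   # (N, 3), wrapped into [0, L)
    velocities: np.ndarray  # (N, 3)

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def kinetic_temperature(self) -> float:
        ke = 0.5 * float(np.sum(self.velocities**2))
        return 2.0 * ke / (3.0 * (self.N - 1))


@dataclass
class Trajectory:
    """Production frames: times plus unwrapped and wrapped coordinates."""

    times: np.ndarray                 # (n_frames,)
    unwrapped: np.ndarray             # (n_frames, N, 3)
    L: float
    config: SimulationConfig
    potential_params: dict
    temperature_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    energy_series: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def wrapped(self) -> np.ndarray:
        return np.mod(self.unwrapped, self.L)

    def write_xyz(self, path) -> None:
        with open(path, "w") as fh:
            for t, frame in zip(self.times, self.wrapped):
                fh.write(f"{frame.shape[0]}\nt={t}\n")
                for x, y, z in frame:
                    fh.write(f"ME {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# force kernels

@njit(cache=True)
def _forces_brute(pos, L, r_tab0, dr_inv, Ftab, Utab, rc):
    N = pos.shape[0]
    forces = np.zeros((N, 3))
    epot = 0.0
    virial = 0.0
    overlaps = 0
    rc2 = rc * rc
    n_tab = Ftab.shape[0]
    for i in range(N - 1):
        for j in range(i + 1, N):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            s = (r - r_tab0) * dr_inv
            if s < 0.0:
                overlaps += 1
                s = 0.0
            k = int(s)
            if k >= n_tab - 1:
                k = n_tab - 2
            w = s - k
            f = Ftab[k] * (1.0 - w) + Ftab[k + 1] * w
            u = Utab[k] * (1.0 - w) + Utab[k + 1] * w
            epot += u
            virial += f * r
            fx = f * dx / r
            fy = f * dy / r
            fz = f * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return forces, epot, virial, overlaps


@njit(cache=True)
def _forces_cells(pos, L, r_tab0, dr_inv, Ftab, Utab, rc):
    N = pos.shape[0]
    forces = np.zeros((N, 3))
    epot = 0.0
    virial = 0.0
    overlaps = 0
    rc2 = rc * rc
    n_tab = Ftab.shape[0]

    nc = int(L / rc)
    if nc < 3:
        return _forces_brute(pos, L, r_tab0, dr_inv, Ftab, Utab, rc)
    cell_edge = L / nc
    ncell = nc * nc * nc

    head = -np.ones(ncell, dtype=np.int64)
    nxt = -np.ones(N, dtype=np.int64)
    for i in range(N):
        cx = int(pos[i, 0] / cell_edge) % nc
        cy = int(pos[i, 1] / cell_edge) % nc
        cz = int(pos[i, 2] / cell_edge) % nc
        c = (cx * nc + cy) * nc + cz
        nxt[i] = head[c]
        head[c] = i

    for i in range(N):
        cx = int(pos[i, 0] / cell_edge) % nc
        cy = int(pos[i, 1] / cell_edge) % nc
        cz = int(pos[i, 2] / cell_edge) % nc
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    c = (((cx + ox) % nc) * nc + ((cy + oy) % nc)) * nc + ((cz + oz) % nc)
                    j = head[c]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= L * np.rint(dx / L)
                            dy -= L * np.rint(dy / L)
                            dz -= L * np.rint(dz / L)
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2:
                                r = np.sqrt(r2)
                                s = (r - r_tab0) * dr_inv
                                if s < 0.0:
                                    overlaps += 1
                                    s = 0.0
                                k = int(s)
                                if k >= n_tab - 1:
                                    k = n_tab - 2
                                w = s - k
                                f = Ftab[k] * (1.0 - w) + Ftab[k + 1] * w
                                u = Utab[k] * (1.0 - w) + Utab[k + 1] * w
                                epot += u
                                virial += f * r
                                fx = f * dx / r
                                fy = f * dy / r
                                fz = f * dz / r
                                forces[i, 0] += fx
                                forces[i, 1] += fy
                                forces[i, 2] += fz
                                forces[j, 0] -= fx
                                forces[j, 1] -= fy
                                forces[j, 2] -= fz
                        j = nxt[j]
    return forces, epot, virial, overlaps


class _ReducedTable:
    """Reduced-unit view of a tabulated potential for the kernels."""

    def __init__(self, pot: TabulatedPotential):
        red = pot.to_reduced()
        self.r0 = red.r[0]
        self.dr_inv = 1.0 / (red.r[1] - red.r[0])
        self.U = np.ascontiguousarray(red.U)
        self.F = np.ascontiguousarray(red.F)
        self.rc = red.r[-1]


def compute_forces(conf: Configuration, pot: TabulatedPotential,
                   raise_on_overlap: bool = False):
    """Minimum-image pair forces, potential energy and virial (cell list).

    Returns ``(forces, epot, virial)``.  A pair below the tabulation range is
    a core overlap; it is counted and reported via an exception when
    ``raise_on_overlap`` (otherwise the innermost table value is used, which
    is strongly repulsive).
    """
    tab = _ReducedTable(pot)
    f, e, w, n_over = _forces_cells(conf.positions, conf.L, tab.r0, tab.dr_inv,
                                    tab.F, tab.U, tab.rc)
    if n_over and raise_on_overlap:
        raise RuntimeError(f"{n_over} pair(s) below the tabulated core range")
    return f, e, w


def compute_forces_brute(conf: Configuration, pot: TabulatedPotential):
    """O(N^2) reference force evaluation (oracle for the cell list)."""
    tab = _ReducedTable(pot)
    f, e, w, _ = _forces_brute(conf.positions, conf.L, tab.r0, tab.dr_inv,
                               tab.F, tab.U, tab.rc)
    return f, e, w


# ---------------------------------------------------------------------------
# initialization and integration

def init_configuration(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Configuration:
    """Particles on a simple-cubic lattice, Maxwell-Boltzmann velocities.

    The lattice guarantees no core overlaps (min distance > sigma = 2); net
    momentum is removed and velocities rescaled to T_star exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.L
    n_side = int(np.ceil(cfg.N ** (1 / 3)))
    a = L / n_side
    if a <= 2.0:
        raise ValueError(
            f"phi={cfg.phi} too high for an overlap-free simple-cubic lattice of {cfg.N}"
        )
    idx = np.arange(n_side)
    gx, gy, gz = np.meshgrid(idx, idx, idx, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) * a + 0.5 * a
    pos = sites[: cfg.N].astype(float)

    vel = rng.normal(0.0, np.sqrt(cfg.T_star), size=(cfg.N, 3))
    vel -= vel.mean(axis=0)
    T_now = np.sum(vel**2) / (3.0 * (cfg.N - 1))
    vel *= np.sqrt(cfg.T_star / T_now)
    return Configuration(L=L, positions=pos, velocities=vel)


def step_nve(conf: Configuration, pot: TabulatedPotential, dt: float,
             forces: np.ndarray | None = None):
    """One velocity-Verlet step; returns the new forces (for chaining)."""
    if forces is None:
        forces, _, _ = compute_forces(conf, pot)
    conf.velocities += 0.5 * dt * forces
    conf.positions += dt * conf.velocities
    conf.positions %= conf.L
    forces, epot, vir = compute_forces(conf, pot)
    conf.velocities += 0.5 * dt * forces
    return forces, epot, vir


def _nh_half(vel: np.ndarray, xi: float, dt: float, T: float, Q: float, g: int):
    ke2 = float(np.sum(vel**2))
    xi = xi + 0.5 * dt * (ke2 - g * T) / Q
    vel *= np.exp(-0.5 * dt * xi)
    return xi


def run(cfg: SimulationConfig, pot: TabulatedPotential,
        production_thermostat: str | None = None) -> Trajectory:
    """Equilibrate then produce; returns the production trajectory.

    Equilibration always uses per-step velocity rescaling to ``T_star``.
    Production uses ``cfg.thermostat`` unless overridden.  Identical seeds
    give bit-identical trajectories.
    """
    thermostat = production_thermostat or cfg.thermostat
    rng = np.random.default_rng(cfg.seed)
    conf = init_configuration(cfg, rng)
    dt = cfg.dt
    tab = _ReducedTable(pot)

    def forces_now(pos):
        return _forces_cells(pos, conf.L, tab.r0, tab.dr_inv, tab.F, tab.U, tab.rc)

    forces, _, _, _ = forces_now(conf.positions)
    for _ in range(cfg.n_equil):
        conf.velocities += 0.5 * dt * forces
        conf.positions += dt * conf.velocities
        conf.positions %= conf.L
        forces, _, _, _ = forces_now(conf.positions)
        conf.velocities += 0.5 * dt * forces
        T_now = conf.kinetic_temperature()
        conf.velocities *= np.sqrt(cfg.T_star / T_now)

    g = 3 * (cfg.N - 1)
    Q = g * cfg.T_star * cfg.nh_damping**2
    xi = 0.0

    n_frames = cfg.n_prod // cfg.save_stride + 1
    unwrapped = np.empty((n_frames, cfg.N, 3))
    times = np.empty(n_frames)
    temps = np.empty(n_frames)
    energies = np.empty(n_frames)

    upos = conf.positions.copy()  # unwrapped accumulator
    frame = 0
    unwrapped[frame] = upos
    times[frame] = 0.0
    temps[frame] = conf.kinetic_temperature()
    _, epot0, _, _ = forces_now(conf.positions)
    energies[frame] = epot0 / cfg.N
    frame += 1

    epot = epot0
    for istep in range(1, cfg.n_prod + 1):
        if thermostat == "nose-hoover":
            xi = _nh_half(conf.velocities, xi, dt, cfg.T_star, Q, g)
        conf.velocities += 0.5 * dt * forces
        dx = dt * conf.velocities
        if np.max(np.abs(dx)) > 0.5 * tab.rc:
            raise FloatingPointError(
                f"step {istep}: displacement exceeds half the interaction range; "
                "integration unstable (reduce dt)"
            )
        conf.positions += dx
        conf.positions %= conf.L
        upos += dx
        forces, epot, vir, _ = forces_now(conf.positions)
        conf.velocities += 0.5 * dt * forces
        if thermostat == "nose-hoover":
            xi = _nh_half(conf.velocities, xi, dt, cfg.T_star, Q, g)
        elif thermostat == "velocity-rescale":
            conf.velocities *= np.sqrt(cfg.T_star / conf.kinetic_temperature())

        if istep % cfg.save_stride == 0:
            unwrapped[frame] = upos
            times[frame] = istep * dt
            temps[frame] = conf.kinetic_temperature()
            energies[frame] = epot / cfg.N
            frame += 1

    return Trajectory(
        times=times[:frame],
        unwrapped=unwrapped[:frame],
        L=conf.L,
        config=cfg,
        potential_params=pot.params.as_dict(),
        temperature_series=temps[:frame],
        energy_series=energies[:frame],
    )
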