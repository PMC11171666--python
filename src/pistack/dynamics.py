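"""Rigid-body propagation of molecules under nonbonded forces.

Each monomer moves as a rigid body: its centre of mass follows velocity
Verlet on the net force, and its orientation follows the torque about the
COM through an exact rotation-map update of the body frame (angular momentum
is the propagated variable, so the discrete dynamics conserves the total
linear and angular momentum of an isolated pairwise system to round-off).
Internal geometry is reconstructed from the body frame every step, so rigid
bonds cannot drift.

Two thermostats are supported: ``none`` (pure NVE — enforced during steered
pulls) and ``langevin``, an Ornstein-Uhlenbeck kick on COM velocity and
angular momentum used for the free-diffusion dimerization phase.  The
integration step defaults to 1 fs.

For the dimerization experiment an optional reflecting spherical boundary
(``confine_radius``) keeps the monomers in a droplet-sized region, standing
in for the finite solvated box of a conventional periodic simulation; open
vacuum diffusion is transient and two monomers would otherwise simply drift
apart.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np

from . import _kernels as kernels
from .forcefield import NonbondedConfig, NonbondedModel
from .model import SimSystem
from .units import KB_KCAL_MOL_K, KCAL_PER_MOL_TO_INTERNAL

__all__ = [
    "IntegratorConfig",
    "IntegrationError",
    "step",
    "run_md",
    "run_free_md",
    "MDResult",
]

ForceFn = Callable[[SimSystem], tuple[np.ndarray, float]]


class IntegrationError(RuntimeError):
    """Non-finite forces or state; carries the offending frame for inspection."""

    def __init__(self, message: str, system: Optional[SimSystem] = None) -> None:
        super().__init__(message)
        self.frame = system.copy() if system is not None else None


@dataclasses.dataclass
class IntegratorConfig:
    timestep: float = 0.001  # ps (1 fs)
    thermostat: str = "none"  # "none" | "langevin"
    temperature: float = 300.0  # K
    friction: float = 1.0  # 1/ps
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError(f"timestep must be positive, got {self.timestep}")
        if self.thermostat not in ("none", "langevin"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")


def _kick(system: SimSystem, forces: np.ndarray, half_dt: float) -> None:
    """Impulse update of COM velocities and angular momenta from atomic forces."""
    kernels.kick(
        system.x,
        forces,
        system.coms,
        system.vels,
        system.ang_mom,
        system.mol_masses,
        system.offsets,
        system.fixed_flags,
        half_dt,
    )


def _drift(system: SimSystem, dt: float) -> None:
    """Translate/rotate each free molecule and rebuild world coordinates."""
    kernels.drift_sync(
        system.x,
        system.coms,
        system.rots,
        system.vels,
        system.ang_mom,
        system.inv_inertia,
        system.body,
        system.offsets,
        system.fixed_flags,
        dt,
    )
    system.time += dt


def _langevin_kick(system: SimSystem, cfg: IntegratorConfig, rng: np.random.Generator) -> None:
    c1 = np.exp(-cfg.friction * cfg.timestep)
    c2 = np.sqrt(1.0 - c1 * c1)
    kt = KB_KCAL_MOL_K * cfg.temperature * KCAL_PER_MOL_TO_INTERNAL
    for i in range(system.n_molecules):
        if system.fixed_flags[i]:
            continue
        system.vels[i] = c1 * system.vels[i] + c2 * np.sqrt(
            kt / system.mol_masses[i]
        ) * rng.standard_normal(3)
        w = system.inertia_principal[i]
        l_body = system.rots[i].T @ system.ang_mom[i]
        sigma = np.where(w > 1e-8, np.sqrt(kt * np.maximum(w, 0.0)), 0.0)
        l_body = c1 * l_body + c2 * sigma * rng.standard_normal(3)
        system.ang_mom[i] = system.rots[i] @ l_body


def step(
    system: SimSystem,
    forces: np.ndarray,
    cfg: IntegratorConfig,
    force_fn: ForceFn,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, float]:
    """Advance the system by one timestep.

    ``forces`` must be the per-atom forces evaluated at the current
    coordinates; ``force_fn`` is called once at the new coordinates for the
    closing half-kick.  Returns the new forces and potential energy so the
    caller can chain steps without re-evaluating.
    """
    dt = cfg.timestep
    _kick(system, forces, 0.5 * dt)
    _drift(system, dt)
    new_forces, potential = force_fn(system)
    if not np.all(np.isfinite(new_forces)):
        raise IntegrationError(
            f"non-finite force at t = {system.time:.6f} ps; aborting", system
        )
    _kick(system, new_forces, 0.5 * dt)
    if cfg.thermostat == "langevin":
        if rng is None:
            raise ValueError("langevin thermostat requires a random generator")
        _langevin_kick(system, cfg, rng)
    return new_forces, potential


def _confine(system: SimSystem, radius: float) -> None:
    """Reflect molecules whose COM leaves a sphere of ``radius`` about the origin."""
    moved = False
    for i in range(system.n_molecules):
        if system.fixed_flags[i]:
            continue
        r2 = float(system.coms[i] @ system.coms[i])
        if r2 > radius * radius:
            r = np.sqrt(r2)
            n = system.coms[i] / r
            vn = float(system.vels[i] @ n)
            if vn > 0:
                system.vels[i] -= 2.0 * vn * n
            system.coms[i] = n * (2.0 * radius - r)
            moved = True
    if moved:
        system.sync_coords()


@dataclasses.dataclass
class MDResult:
    """Recorded observables of one MD run."""

    times: np.ndarray  # ps
    com_distance: np.ndarray  # A, molecules 0-1 (nan for single molecule)
    potential: np.ndarray  # kcal/mol
    kinetic: np.ndarray  # kcal/mol
    frames: list[tuple[float, list[np.ndarray]]]  # (time, per-molecule coords)
    final_system: SimSystem

    def com_trace(self):
        import pandas as pd

        return pd.DataFrame({"time_ps": self.times, "distance_A": self.com_distance})

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic


def run_md(
    system: SimSystem,
    cfg: IntegratorConfig,
    duration: float,
    record_every: float = 1.0,
    nb_cfg: Optional[NonbondedConfig] = None,
    force_fn: Optional[ForceFn] = None,
    stop_when: Optional[Callable[[SimSystem], bool]] = None,
    confine_radius: Optional[float] = None,
) -> MDResult:
    """Propagate ``system`` for ``duration`` ps, recording every ``record_every`` ps.

    The system is advanced in place (work on a copy to preserve the input).
    ``stop_when`` is checked at record points and ends the run early.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    dt = cfg.timestep
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_every / dt)))
    rng = np.random.default_rng(cfg.seed)

    times, com_d, epot, ekin = [], [], [], []
    frames: list[tuple[float, list[np.ndarray]]] = []

    def record(potential: float) -> None:
        times.append(system.time)
        com_d.append(system.com_separation() if system.n_molecules > 1 else np.nan)
        epot.append(potential)
        ekin.append(system.kinetic_energy())
        frames.append((system.time, [m.coords.copy() for m in system.molecules]))

    if force_fn is None:
        # fast path: call the compiled kernels directly with reused buffers
        model = NonbondedModel(system, nb_cfg)
        if model.static_coords is not None:
            x_full = np.vstack([system.x, model.static_coords])
        else:
            x_full = system.x
        forces = np.zeros_like(x_full)
        nm = system.n_mobile_atoms
        half = 0.5 * dt

        def pair() -> float:
            if x_full is not system.x:
                x_full[:nm] = system.x
            return kernels.pair_energy_forces(
                x_full, model.ii, model.jj, model.pair_eps, model.pair_rmin2,
                model.pair_qq, model._ron2, model._roff2, model._inv_denom, forces,
            )

        langevin = cfg.thermostat == "langevin"
        if langevin:
            c1 = np.exp(-cfg.friction * dt)
            c2 = np.sqrt(1.0 - c1 * c1)
            kt = KB_KCAL_MOL_K * cfg.temperature * KCAL_PER_MOL_TO_INTERNAL
            free = [i for i in range(system.n_molecules) if not system.fixed_flags[i]]
            sv = {i: np.sqrt(kt / system.mol_masses[i]) for i in free}
            sa = {
                i: np.where(
                    system.inertia_principal[i] > 1e-8,
                    np.sqrt(kt * np.maximum(system.inertia_principal[i], 0.0)),
                    0.0,
                )
                for i in free
            }

        potential = pair()
        record(potential)
        for istep in range(n_steps):
            kernels.kick(
                x_full, forces, system.coms, system.vels, system.ang_mom,
                system.mol_masses, system.offsets, system.fixed_flags, half,
            )
            kernels.drift_sync(
                system.x, system.coms, system.rots, system.vels, system.ang_mom,
                system.inv_inertia, system.body, system.offsets, system.fixed_flags, dt,
            )
            system.time += dt
            potential = pair()
            if not np.isfinite(potential):
                raise IntegrationError(
                    f"non-finite energy at t = {system.time:.6f} ps; aborting", system
                )
            kernels.kick(
                x_full, forces, system.coms, system.vels, system.ang_mom,
                system.mol_masses, system.offsets, system.fixed_flags, half,
            )
            if langevin:
                noise = rng.standard_normal((len(free), 6))
                for k, i in enumerate(free):
                    system.vels[i] = c1 * system.vels[i] + c2 * sv[i] * noise[k, :3]
                    r = system.rots[i]
                    lb = c1 * (r.T @ system.ang_mom[i]) + c2 * sa[i] * noise[k, 3:]
                    system.ang_mom[i] = r @ lb
            if confine_radius is not None:
                _confine(system, confine_radius)
            if (istep + 1) % stride == 0:
                record(potential)
                if stop_when is not None and stop_when(system):
                    break
    else:
        forces, potential = force_fn(system)
        record(potential)
        for istep in range(n_steps):
            forces, potential = step(system, forces, cfg, force_fn, rng)
            if confine_radius is not None:
                _confine(system, confine_radius)
            if (istep + 1) % stride == 0:
                record(potential)
                if stop_when is not None and stop_when(system):
                    break
    return MDResult(
        np.array(times), np.array(com_d), np.array(epot), np.array(ekin), frames, system
    )


def run_free_md(
    system: SimSystem,
    cfg: IntegratorConfig,
    duration: float,
    record_every: float = 1.0,
    nb_cfg: Optional[NonbondedConfig] = None,
    stop_when: Optional[Callable[[SimSystem], bool]] = None,
    confine_radius: Optional[float] = None,
) -> MDResult:
    """Free-diffusion MD phase; identical seed gives an identical trajectory."""
    return run_md(
        system.copy(),
        cfg,
        duration,
        record_every=record_every,
        nb_cfg=nb_cfg,
        stop_when=stop_when,
        confine_radius=confine_radius,
    )
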