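"""Constant-velocity steered pulling of one rigid monomer.

A dummy point starts at the pulled molecule's centre of mass and moves at
constant velocity along the pulling direction; a harmonic spring of
stiffness ``k_spring`` (default 4 kcal/(mol*A^2), i.e. ~278 pN/A) connects
it to the COM.  Following the constant-velocity SMD convention, the applied
force is the spring extension *projected on the pulling direction*:

    F(t) = k * [ (x_dummy(t) - x_com(t)) . n ] * n

so transverse motion of the pulled molecule is unrestrained (this is what
lets a stacked dimer slide apart ring by ring instead of popping off in one
step).  The force is applied at the COM, mass-weighted over the atoms, so it
exerts no torque.

Protocol constraints are enforced, not merely defaulted: the temperature
control must be off during pulling (the noise-reduction rationale), exactly
one molecule is pulled, and any partner is fixed.  Replicas differ only in
the seed used to draw the pulled molecule's initial thermal velocities; the
same seed reproduces a bitwise-identical force curve.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernels as kernels
from .dynamics import IntegratorConfig, IntegrationError
from .forcefield import NonbondedConfig, NonbondedModel
from .model import SimSystem
from .units import PN_PER_KCAL_MOL_A

__all__ = [
    "SMDConfig",
    "ForceCurve",
    "ProtocolError",
    "kcal_per_molA2_to_pN_per_A",
    "spring_force",
    "run_smd",
]


class ProtocolError(RuntimeError):
    """The steered-pulling protocol was violated (e.g. thermostat requested)."""


def kcal_per_molA2_to_pN_per_A(k: float) -> float:
    """Convert a spring constant from kcal/(mol*A^2) to pN/A (4.0 -> 277.9)."""
    return k * PN_PER_KCAL_MOL_A


@dataclasses.dataclass
class SMDConfig:
    """Constant-velocity pulling parameters.

    ``pull_direction`` of None means "resolve at run time" as the unit vector
    from the fixed molecule's COM to the pulled molecule's COM — the natural
    dissociation coordinate.  ``origin`` is the dummy start (the pulled COM
    at t = 0) and is filled in by :func:`run_smd`.
    """

    k_spring: float = 4.0  # kcal/(mol*A^2)
    pull_velocity: float = 0.01  # A/ps
    pull_direction: Optional[np.ndarray] = None
    origin: Optional[np.ndarray] = None
    record_every: float = 0.1  # ps

    def __post_init__(self) -> None:
        if self.k_spring <= 0:
            raise ValueError(f"k_spring must be positive, got {self.k_spring}")
        if self.pull_direction is not None:
            d = np.asarray(self.pull_direction, dtype=float)
            n = np.linalg.norm(d)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError("pull_direction must be a unit vector")
            self.pull_direction = d / n

    @property
    def k_pn(self) -> float:
        """Spring constant in pN/A."""
        return kcal_per_molA2_to_pN_per_A(self.k_spring)


def spring_force(
    t: float, attachment_pos: np.ndarray, cfg: SMDConfig
) -> tuple[np.ndarray, float]:
    """Applied spring force (kcal/(mol*A)) and the recorded scalar (pN).

    The dummy sits at ``origin + v t n``; both the applied force and the
    recorded scalar use the extension component along the pulling direction.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    n = cfg.pull_direction if cfg.pull_direction is not None else np.array([0.0, 0.0, 1.0])
    origin = cfg.origin if cfg.origin is not None else np.zeros(3)
    dummy = origin + cfg.pull_velocity * t * n
    ext = float((dummy - np.asarray(attachment_pos, dtype=float)) @ n)
    return cfg.k_spring * ext * n, cfg.k_pn * ext


@dataclasses.dataclass
class ForceCurve:
    """Recorded time series of one pulling run."""

    times: np.ndarray  # ps
    force_pN: np.ndarray  # spring force projected on the pull direction
    displacement_A: np.ndarray  # attachment-point displacement along the pull
    com_A: np.ndarray  # COM separation pulled vs fixed (nan without partner)

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.force_pN) == len(self.displacement_A) == len(self.com_A) == n):
            raise ValueError("force-curve arrays must have equal length")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_ps": self.times,
                "force_pN": self.force_pN,
                "displacement_A": self.displacement_A,
                "com_A": self.com_A,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ForceCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["time_ps"].to_numpy(),
            df["force_pN"].to_numpy(),
            df["displacement_A"].to_numpy(),
            df["com_A"].to_numpy(),
        )


def _resolve_roles(system: SimSystem) -> tuple[int, Optional[int]]:
    free = [i for i, f in enumerate(system.fixed_flags) if not f]
    if len(free) != 1:
        raise ProtocolError(
            "steered pulling requires exactly one mobile (pulled) molecule; "
            f"got {len(free)} mobile of {system.n_molecules}"
        )
    fixed = [i for i, f in enumerate(system.fixed_flags) if f]
    return free[0], (fixed[0] if fixed else None)


def run_smd(
    system: SimSystem,
    smd_cfg: SMDConfig,
    integ_cfg: IntegratorConfig,
    duration: float,
    replicas: Sequence[Optional[int]] = (None,),
    nb_cfg: Optional[NonbondedConfig] = None,
    return_trajectories: bool = False,
    trajectory_every: float = 10.0,
):
    """Run constant-velocity pulls; one ForceCurve per replica seed.

    A replica seed of None starts from rest; an integer seed draws
    Maxwell-Boltzmann initial velocities for the pulled molecule at
    ``integ_cfg.temperature``.  The thermostat must be ``none``.
    """
    if integ_cfg.thermostat != "none":
        raise ProtocolError(
            "constant temperature control must be disabled during steered pulls "
            f"(got thermostat={integ_cfg.thermostat!r})"
        )
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    pulled, fixed = _resolve_roles(system)

    dt = integ_cfg.timestep
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(smd_cfg.record_every / dt)))

    curves: list[ForceCurve] = []
    trajectories: list[list[tuple[float, list[np.ndarray]]]] = []
    for seed in replicas:
        sys_r = system.copy()
        sys_r.time = 0.0
        if seed is not None:
            rng = np.random.default_rng(seed)
            sys_r.set_thermal_velocities(pulled, integ_cfg.temperature, rng)

        cfg_r = dataclasses.replace(smd_cfg)
        cfg_r.origin = sys_r.coms[pulled].copy()
        if cfg_r.pull_direction is None:
            if fixed is None:
                raise ProtocolError(
                    "pull_direction must be given explicitly when there is no "
                    "fixed partner to define the dissociation axis"
                )
            axis = sys_r.coms[pulled] - sys_r.coms[fixed]
            cfg_r.pull_direction = axis / np.linalg.norm(axis)
        n = np.ascontiguousarray(cfg_r.pull_direction, dtype=float)
        masses = sys_r.molecules[pulled].masses
        weights = np.ascontiguousarray(masses / masses.sum())

        model = NonbondedModel(sys_r, nb_cfg)
        if model.static_coords is not None:
            x_full = np.vstack([sys_r.x, model.static_coords])
        else:
            x_full = sys_r.x.copy()
        forces = np.zeros_like(x_full)

        if return_trajectories:
            traj = _chunked_pull(
                sys_r, model, cfg_r, n, weights, x_full, forces, pulled, fixed,
                n_steps, dt, stride, max(1, int(round(trajectory_every / dt))),
            )
            curves.append(traj[0])
            trajectories.append(traj[1])
            continue

        n_expected = n_steps // stride + 1
        rec_t = np.empty(n_expected)
        rec_f = np.empty(n_expected)
        rec_d = np.empty(n_expected)
        rec_c = np.empty(n_expected)
        n_rec, abort = kernels.pull_loop(
            n_steps, dt, stride, x_full, forces,
            model.ii, model.jj, model.pair_eps, model.pair_rmin2, model.pair_qq,
            model._ron2, model._roff2, model._inv_denom,
            sys_r.coms, sys_r.rots, sys_r.vels, sys_r.ang_mom,
            sys_r.inv_inertia, sys_r.body, sys_r.offsets, sys_r.fixed_flags,
            sys_r.mol_masses, pulled, -1 if fixed is None else fixed,
            weights, cfg_r.k_spring, cfg_r.k_pn, cfg_r.pull_velocity,
            n, cfg_r.origin, rec_t, rec_f, rec_d, rec_c,
        )
        sys_r.x[:] = x_full[: sys_r.n_mobile_atoms]
        sys_r.time = n_steps * dt
        if abort >= 0:
            raise IntegrationError(
                f"non-finite energy at t = {(abort + 1) * dt:.6f} ps during pull", sys_r
            )
        curves.append(
            ForceCurve(rec_t[:n_rec], rec_f[:n_rec], rec_d[:n_rec], rec_c[:n_rec])
        )
    if return_trajectories:
        return curves, trajectories
    return curves


def _chunked_pull(
    sys_r, model, cfg_r, n, weights, x_full, forces, pulled, fixed,
    n_steps, dt, stride, traj_stride,
):
    """Slow path used when frames are requested: kernel pulls in chunks."""
    times, f_rec, d_rec, c_rec = [], [], [], []
    traj = [(0.0, [m.coords.copy() for m in sys_r.molecules])]
    done = 0
    first = True
    while done < n_steps:
        chunk = min(traj_stride, n_steps - done)
        n_expected = chunk // stride + 2
        rec_t = np.empty(n_expected)
        rec_f = np.empty(n_expected)
        rec_d = np.empty(n_expected)
        rec_c = np.empty(n_expected)
        origin_shifted = cfg_r.origin + cfg_r.pull_velocity * (done * dt) * n
        n_rec, abort = kernels.pull_loop(
            chunk, dt, stride, x_full, forces,
            model.ii, model.jj, model.pair_eps, model.pair_rmin2, model.pair_qq,
            model._ron2, model._roff2, model._inv_denom,
            sys_r.coms, sys_r.rots, sys_r.vels, sys_r.ang_mom,
            sys_r.inv_inertia, sys_r.body, sys_r.offsets, sys_r.fixed_flags,
            sys_r.mol_masses, pulled, -1 if fixed is None else fixed,
            weights, cfg_r.k_spring, cfg_r.k_pn, cfg_r.pull_velocity,
            n, origin_shifted, rec_t, rec_f, rec_d, rec_c,
        )
        sys_r.x[:] = x_full[: sys_r.n_mobile_atoms]
        if abort >= 0:
            raise IntegrationError(
                f"non-finite energy at t = {(done + abort + 1) * dt:.6f} ps during pull",
                sys_r,
            )
        lo = 0 if first else 1
        for k in range(lo, n_rec):
            times.append(done * dt + rec_t[k])
            f_rec.append(rec_f[k])
            d_rec.append(
                rec_d[k]
                + float((origin_shifted - cfg_r.origin) @ n)
            )
            c_rec.append(rec_c[k])
        done += chunk
        traj.append((done * dt, [m.coords.copy() for m in sys_r.molecules]))
        first = False
    sys_r.time = n_steps * dt
    curve = ForceCurve(np.array(times), np.array(f_rec), np.array(d_rec), np.array(c_rec))
    return curve, traj
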