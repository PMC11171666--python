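"""End-to-end pipelines: optimal dimers, replica pulls, desk-scale reproduction.

``smd_binding_energy`` is the canonical study: build the force-field-optimal
stacked dimer of a PAH, pull it apart in four independent constant-velocity
replicas (thermostat off, partner fixed) and extract the binding energy from
the force curves.  ``reproduce`` chains the full protocol — free-diffusion
MD, stable-dimer (plateau) frame selection, four pulls, analysis — at a
desk-scale problem size.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .analysis import (
    BindingEnergyResult,
    binding_energy,
    detect_plateaus,
    results_table,
    write_report,
)
from .dynamics import IntegratorConfig, run_free_md
from .forcefield import NonbondedConfig
from .model import Molecule, SimSystem
from .pes import direct_binding_energy, refine_minimum, scan
from .smd import ForceCurve, SMDConfig, run_smd
from .structures import DimerGeometry, build_pah, build_stacked_dimer, write_xyz_trajectory

logger = logging.getLogger("pistack")

__all__ = ["optimal_dimer", "smd_binding_energy", "reproduce", "SMDStudy", "DimerOptimum"]

SCAN_SEPARATIONS = np.arange(3.0, 4.76, 0.25)
SCAN_OFFSETS = np.arange(0.0, 2.76, 0.25)


@dataclasses.dataclass
class DimerOptimum:
    molecule: Molecule
    geometry: DimerGeometry
    system: SimSystem  # fixed partner + mobile pulled copy
    direct_energy: float  # kcal/mol, energy-difference convention


@dataclasses.dataclass
class SMDStudy:
    kind: str
    result: BindingEnergyResult
    curves: list[ForceCurve]
    direct_energy: float
    geometry: DimerGeometry
    duration: float


def optimal_dimer(kind: str, nb_cfg: Optional[NonbondedConfig] = None) -> DimerOptimum:
    """Force-field-optimal stacked dimer of a PAH (grid scan + local refine)."""
    mol = build_pah(kind)
    profile = scan(mol, SCAN_SEPARATIONS, SCAN_OFFSETS, cfg=nb_cfg)
    geom, _ = refine_minimum(mol, profile.minimum[0], cfg=nb_cfg)
    system = build_stacked_dimer(mol, geom, fixed=(True, False))
    return DimerOptimum(mol, geom, system, direct_binding_energy(system, nb_cfg))


def smd_binding_energy(
    kind: str,
    seeds: Sequence[Optional[int]] = (1, 2, 3, 4),
    pull_velocity: float = 0.01,
    k_spring: float = 4.0,
    temperature: float = 300.0,
    timestep: float = 0.001,
    com_stop: float = 11.5,
    margin: float = 2.0,
    nb_cfg: Optional[NonbondedConfig] = None,
    start_system: Optional[SimSystem] = None,
    **detect_kwargs,
) -> SMDStudy:
    """Pull a stacked PAH dimer apart and extract its binding energy.

    Starts each replica from the force-field-optimal dimer (or
    ``start_system``), draws the pulled molecule's initial velocities at
    ``temperature`` from the replica seed (None = start at rest), pulls at
    ``pull_velocity`` until the COM separation comfortably exceeds the 10 A
    stacking cutoff, and sums the per-transition spring-energy releases.
    """
    opt = optimal_dimer(kind, nb_cfg)
    system = start_system if start_system is not None else opt.system
    com0 = system.com_separation()
    duration = (com_stop - com0 + margin) / pull_velocity
    smd_cfg = SMDConfig(k_spring=k_spring, pull_velocity=pull_velocity)
    integ_cfg = IntegratorConfig(timestep=timestep, thermostat="none", temperature=temperature)
    curves = run_smd(system, smd_cfg, integ_cfg, duration, replicas=list(seeds), nb_cfg=nb_cfg)
    result = binding_energy(curves, smd_cfg.k_pn, **detect_kwargs)
    logger.info(
        "%s: %.2f +/- %.2f kcal/mol over %d replicas (direct %.2f)",
        kind, result.mean, result.sd, result.n_replicas, opt.direct_energy,
    )
    return SMDStudy(kind, result, curves, opt.direct_energy, opt.geometry, duration)


# ----------------------------------------------------------------------
# full protocol reproduction at desk scale
# ----------------------------------------------------------------------

DESK_SCALE = {
    "md_duration": 2000.0,  # ps of free-diffusion MD
    "md_record_every": 1.0,  # ps
    "start_separation": 15.0,  # A between monomer COMs
    "confine_radius": 25.0,  # A reflecting droplet boundary
    "plateau_dwell": 50.0,  # ps
    "plateau_threshold": 6.0,  # A
    "plateau_var_tol": 1.5,  # A^2
}
FULL_SCALE = {
    **DESK_SCALE,
    "md_duration": 100_000.0,
    "plateau_dwell": 1000.0,
}


def _system_from_frame(
    molecules: Sequence[Molecule], frame_coords: Sequence[np.ndarray]
) -> SimSystem:
    mols = []
    for m, xyz in zip(molecules, frame_coords):
        c = m.copy()
        c.coords = np.asarray(xyz, dtype=float)
        mols.append(c)
    return SimSystem(mols, fixed=[True, False])


def reproduce(
    system_name: str,
    scale: str = "desk",
    seed: int = 7,
    out_dir: Optional[Union[str, Path]] = None,
    overrides: Optional[dict] = None,
    n_replicas: int = 4,
    pull_velocity: float = 0.01,
    k_spring: float = 4.0,
    nb_cfg: Optional[NonbondedConfig] = None,
) -> dict:
    """Free MD -> stable-dimer frame selection -> pulls -> binding energy.

    Two monomers start ``start_separation`` A apart and diffuse under a
    Langevin thermostat inside a reflecting droplet; the replica pulls start
    from frames inside the detected COM plateaus (the longest plateaus'
    midpoints, padded by evenly spaced in-plateau frames when fewer plateaus
    than replicas exist).  If no stable dimer ever forms — expected for
    benzene — the pulls fall back to the constructed optimal stacked dimer,
    with a warning.
    """
    if scale not in ("desk", "full"):
        raise ValueError(f"scale must be 'desk' or 'full', got {scale!r}")
    params = dict(DESK_SCALE if scale == "desk" else FULL_SCALE)
    if overrides:
        params.update(overrides)

    mol = build_pah(system_name)
    a = mol.translated([-params["start_separation"] / 2.0, 0.0, 0.0])
    b = mol.translated([params["start_separation"] / 2.0, 0.0, 0.0])
    b.name = f"{mol.name}_2"
    md_system = SimSystem([a, b])
    md_cfg = IntegratorConfig(thermostat="langevin", temperature=300.0, friction=1.0, seed=seed)
    md = run_free_md(
        md_system,
        md_cfg,
        params["md_duration"],
        record_every=params["md_record_every"],
        nb_cfg=nb_cfg,
        confine_radius=params["confine_radius"],
    )
    plateaus = detect_plateaus(
        md.times,
        md.com_distance,
        dist_threshold=params["plateau_threshold"],
        dwell=params["plateau_dwell"],
        var_tol=params["plateau_var_tol"],
    )
    logger.info("free MD: %d plateau(s) detected", len(plateaus))

    starts: list[SimSystem] = []
    if plateaus:
        ranked = sorted(plateaus, key=lambda p: -p.duration)
        pick_times: list[float] = [0.5 * (p.t_start + p.t_end) for p in ranked[:n_replicas]]
        k = 0
        while len(pick_times) < n_replicas:  # pad inside the longest plateau
            p = ranked[k % len(ranked)]
            frac = 0.25 + 0.5 * ((k // len(ranked)) % 2)
            pick_times.append(p.t_start + frac * p.duration)
            k += 1
        for tp in pick_times:
            idx = int(np.argmin(np.abs(md.times - tp)))
            starts.append(_system_from_frame([a, b], md.frames[idx][1]))
    else:
        warnings.warn(
            f"no stable dimer plateau found for {system_name}; "
            "falling back to the constructed stacked start"
        )
        opt = optimal_dimer(system_name, nb_cfg)
        starts = [opt.system.copy() for _ in range(n_replicas)]

    smd_cfg = SMDConfig(k_spring=k_spring, pull_velocity=pull_velocity)
    integ_cfg = IntegratorConfig(thermostat="none", temperature=300.0)
    rng = np.random.default_rng(seed)
    replica_seeds = rng.integers(1, 2**31 - 1, size=n_replicas)
    curves: list[ForceCurve] = []
    for s, rseed in zip(starts, replica_seeds):
        com0 = s.com_separation()
        duration = max((11.5 - com0 + 2.0) / pull_velocity, 50.0)
        curves += run_smd(
            s, smd_cfg, integ_cfg, duration, replicas=[int(rseed)], nb_cfg=nb_cfg
        )
    result = binding_energy(curves, smd_cfg.k_pn)
    out = {
        "system": system_name,
        "result": result,
        "curves": curves,
        "plateaus": plateaus,
        "md": md,
        "replica_seeds": [int(x) for x in replica_seeds],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        md.com_trace().to_csv(out_dir / "com_trace.csv", index=False)
        names = list(a.atom_names) + list(b.atom_names)
        write_xyz_trajectory(
            out_dir / "free_md.xyz",
            names,
            [(t, np.vstack(fr)) for t, fr in md.frames[:: max(1, len(md.frames) // 200)]],
        )
        for i, c in enumerate(curves):
            c.to_csv(out_dir / f"forcecurve_replica{i}.csv")
        results_table({system_name: result}).to_csv(out_dir / "results.csv", index=False)
        write_report({system_name: result}, out_dir / "report.txt")
    return out
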