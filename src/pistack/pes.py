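"""Direct potential-energy-surface oracle for rigid dimers.

The force-field binding energy of a rigid dimer follows the energy-
difference convention  E(monomer 1) + E(monomer 2) - E(dimer): with rigid
monomers the self-energies cancel exactly, so the binding energy is simply
minus the intermolecular energy, positive for a bound pair.  A rigid grid
scan over (separation, lateral offset, twist) with local refinement locates
the optimal stacking geometry — for aromatic dimers the parallel-displaced
(staggered) arrangement, not the electrostatically repulsive sandwich.

These direct energies are the independent check that the pulling/force-curve
pipeline must reproduce in the quasi-static limit.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .forcefield import NonbondedConfig, NonbondedModel
from .model import Molecule, SimSystem
from .structures import DimerGeometry, build_stacked_dimer, dimer_coords

__all__ = ["PESProfile", "direct_binding_energy", "scan", "refine_minimum"]

OVERLAP_DISTANCE = 0.5  # A


@dataclasses.dataclass
class PESProfile:
    """A rigid dimer scan: geometries, energies and the grid minimum."""

    geometries: list[DimerGeometry]
    energies: np.ndarray  # intermolecular energies, kcal/mol
    minimum: tuple[DimerGeometry, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "separation_A": [g.separation for g in self.geometries],
                "offset_x_A": [g.lateral_offset[0] for g in self.geometries],
                "offset_y_A": [g.lateral_offset[1] for g in self.geometries],
                "twist_deg": [g.twist for g in self.geometries],
                "energy_kcal_mol": self.energies,
            }
        )


def direct_binding_energy(
    dimer: SimSystem, cfg: Optional[NonbondedConfig] = None
) -> float:
    """Force-field binding energy of a rigid dimer, kcal/mol (positive = bound)."""
    if dimer.n_molecules < 2:
        raise ValueError("binding energy needs two molecules")
    model = NonbondedModel(dimer, cfg)
    coords = dimer.mobile_coords()
    if model.min_pair_distance(coords) < OVERLAP_DISTANCE:
        raise ValueError(
            f"overlapping atoms (pair distance < {OVERLAP_DISTANCE} A); "
            "not a physical dimer geometry"
        )
    return -model.energy(coords=coords)


def _scan_energy(
    model: NonbondedModel, mol: Molecule, geom: DimerGeometry
) -> float:
    coords = np.vstack([mol.coords, dimer_coords(mol, geom)])
    if model.min_pair_distance(coords) < OVERLAP_DISTANCE:
        return np.inf
    return model.energy(coords=coords)


def scan(
    mol: Molecule,
    separations: Sequence[float],
    offsets: Sequence[float],
    twists: Sequence[float] = (0.0,),
    offsets_y: Sequence[float] = (0.0,),
    cfg: Optional[NonbondedConfig] = None,
) -> PESProfile:
    """Full-grid rigid scan of the stacked-dimer energy surface.

    ``offsets`` slide the top monomer along the first in-plane principal
    axis (the long axis for an acene), ``offsets_y`` along the second.
    Overlapping geometries get +inf and never win the minimum.
    """
    separations = list(separations)
    offsets = list(offsets)
    twists = list(twists)
    offsets_y = list(offsets_y)
    if not (separations and offsets and twists and offsets_y):
        raise ValueError("scan grids must be non-empty")
    model = NonbondedModel(build_stacked_dimer(mol, DimerGeometry(separations[0])), cfg)
    geoms: list[DimerGeometry] = []
    energies: list[float] = []
    for s in separations:
        for ox in offsets:
            for oy in offsets_y:
                for tw in twists:
                    g = DimerGeometry(s, (ox, oy), tw)
                    geoms.append(g)
                    energies.append(_scan_energy(model, mol, g))
    energies_arr = np.array(energies)
    i_min = int(np.argmin(energies_arr))
    return PESProfile(geoms, energies_arr, (geoms[i_min], float(energies_arr[i_min])))


def refine_minimum(
    mol: Molecule,
    start: DimerGeometry,
    cfg: Optional[NonbondedConfig] = None,
) -> tuple[DimerGeometry, float]:
    """Local descent from a grid minimum over (separation, offset, twist)."""
    model = NonbondedModel(build_stacked_dimer(mol, start), cfg)

    def objective(x: np.ndarray) -> float:
        sep = x[0]
        if sep <= 0.5:
            return np.inf
        return _scan_energy(model, mol, DimerGeometry(sep, (x[1], x[2]), x[3]))

    x0 = np.array([start.separation, *start.lateral_offset, start.twist])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000, "maxfev": 8000},
    )
    geom = DimerGeometry(res.x[0], (res.x[1], res.x[2]), res.x[3])
    return geom, float(res.fun)
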