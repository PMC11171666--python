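"""Domain containers: rigid molecules and the propagated simulation system.

A :class:`Molecule` is a rigid monomer — atom names, CHARMM type labels,
partial charges and coordinates.  The monomer is the unit that is moved,
pulled or fixed as a whole; its internal geometry never changes during a
simulation.

A :class:`SimSystem` holds two (or more) molecules plus optional static
"scenery" atoms (a frozen solvent shell), and the rigid-body state advanced
by the integrator: per-molecule centre of mass, orientation, COM velocity
and angular momentum.  Each molecule's body frame is its principal-axis
frame, so the body inertia tensor is diagonal.  World coordinates live in
one contiguous array (``x``); each molecule's ``coords`` is a view into it.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .units import KB_KCAL_MOL_K, KCAL_PER_MOL_TO_INTERNAL, mass_of

_INERTIA_TOL = 1e-8


@dataclasses.dataclass
class Molecule:
    """A rigid monomer with per-atom types, charges and coordinates."""

    name: str
    atom_names: list[str]
    type_labels: list[str]
    charges: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (len(self.type_labels) == self.charges.shape[0] == self.coords.shape[0] == n):
            raise ValueError(
                f"inconsistent atom counts in molecule {self.name!r}: "
                f"{n} names, {len(self.type_labels)} types, "
                f"{self.charges.shape[0]} charges, {self.coords.shape[0]} coordinates"
            )
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(t) for t in self.type_labels])

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def com(self) -> np.ndarray:
        m = self.masses
        return (self.coords * m[:, None]).sum(axis=0) / m.sum()

    def copy(self) -> "Molecule":
        return Molecule(
            self.name,
            list(self.atom_names),
            list(self.type_labels),
            self.charges.copy(),
            self.coords.copy(),
        )

    def translated(self, vec: Sequence[float]) -> "Molecule":
        out = self.copy()
        out.coords = out.coords + np.asarray(vec, dtype=float)
        return out


def inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Inertia tensor (amu*A^2) of a point set about its own origin."""
    r2 = np.einsum("ij,ij->i", coords, coords)
    return float(masses @ r2) * np.eye(3) - np.einsum("i,ij,ik->jk", masses, coords, coords)


class SimSystem:
    """Rigid-body state of a set of molecules plus optional static scenery.

    Parameters
    ----------
    molecules:
        The mobile (rigid) monomers.  Their coordinates at construction
        define both the initial configuration and the body frames.
    fixed:
        Per-molecule flags; a fixed molecule never moves and keeps zero
        velocities (the pulling protocol's "one of the dimer components was
        fixed" role).
    static_atoms:
        Optional frozen scenery (e.g. a jittered TIP3P shell) stored as a
        Molecule; these atoms exert forces but are never propagated.
    """

    def __init__(
        self,
        molecules: Sequence[Molecule],
        fixed: Optional[Sequence[bool]] = None,
        static_atoms: Optional[Molecule] = None,
        time: float = 0.0,
    ) -> None:
        if not molecules:
            raise ValueError("SimSystem needs at least one molecule")
        self.molecules = [m.copy() for m in molecules]
        n = len(self.molecules)
        self.fixed_flags = np.array(
            fixed if fixed is not None else [False] * n, dtype=bool
        )
        if self.fixed_flags.shape[0] != n:
            raise ValueError("fixed flags must match the number of molecules")
        self.static_atoms = static_atoms.copy() if static_atoms is not None else None
        self.time = float(time)

        counts = [m.n_atoms for m in self.molecules]
        self.offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.slices = [
            slice(int(self.offsets[i]), int(self.offsets[i + 1])) for i in range(n)
        ]
        self.n_mobile_atoms = int(self.offsets[-1])

        self.mol_masses = np.array([m.total_mass for m in self.molecules])
        self.coms = np.array([m.com() for m in self.molecules])
        self.x = np.vstack([m.coords for m in self.molecules])
        body_rows = []
        rots = []
        inert = []
        for i, m in enumerate(self.molecules):
            body = m.coords - self.coms[i]
            itens = inertia_tensor(body, m.masses)
            w, evecs = np.linalg.eigh(itens)
            if np.linalg.det(evecs) < 0:
                evecs = evecs.copy()
                evecs[:, 2] *= -1
            body_rows.append(body @ evecs)
            rots.append(evecs)
            inert.append(np.clip(w, 0.0, None))
        self.body = np.vstack(body_rows)
        self.rots = np.ascontiguousarray(np.stack(rots))
        self.inertia_principal = np.array(inert)
        scale = np.maximum(self.inertia_principal.max(axis=1, keepdims=True), 1.0)
        self.inv_inertia = np.where(
            self.inertia_principal > _INERTIA_TOL * scale,
            1.0 / np.maximum(self.inertia_principal, 1e-300),
            0.0,
        )

        # COM velocities (A/ps) and angular momenta (amu*A^2/ps, lab frame).
        self.vels = np.zeros((n, 3))
        self.ang_mom = np.zeros((n, 3))
        self._attach_views()
        self.sync_coords()

    def _attach_views(self) -> None:
        for i, m in enumerate(self.molecules):
            m.coords = self.x[self.slices[i]]

    # ------------------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def sync_coords(self) -> None:
        """Rebuild world coordinates exactly from the rigid-body state."""
        for i in range(self.n_molecules):
            sl = self.slices[i]
            self.x[sl] = self.coms[i] + self.body[sl] @ self.rots[i].T

    def mobile_coords(self) -> np.ndarray:
        """The live (n_mobile, 3) coordinate array; treat as read-only."""
        return self.x

    def com_separation(self, i: int = 0, j: int = 1) -> float:
        return float(np.linalg.norm(self.coms[i] - self.coms[j]))

    def inertia_lab_inv(self, i: int) -> np.ndarray:
        r = self.rots[i]
        return r @ np.diag(self.inv_inertia[i]) @ r.T

    @property
    def com_velocities(self) -> np.ndarray:
        return self.vels

    @property
    def angular_velocities(self) -> np.ndarray:
        """Per-molecule angular velocity (rad/ps, lab frame)."""
        return np.array(
            [self.inertia_lab_inv(i) @ self.ang_mom[i] for i in range(self.n_molecules)]
        )

    def kinetic_energy(self) -> float:
        """Total rigid-body kinetic energy in kcal/mol."""
        ke = 0.5 * float(np.sum(self.mol_masses[:, None] * self.vels**2))
        for i in range(self.n_molecules):
            ke += 0.5 * float(self.ang_mom[i] @ (self.inertia_lab_inv(i) @ self.ang_mom[i]))
        return ke / KCAL_PER_MOL_TO_INTERNAL

    def translational_kinetic_energy(self, i: int) -> float:
        """Translational kinetic energy of molecule ``i`` in kcal/mol."""
        return (
            0.5 * self.mol_masses[i] * float(self.vels[i] @ self.vels[i])
        ) / KCAL_PER_MOL_TO_INTERNAL

    def linear_momentum(self) -> np.ndarray:
        return (self.mol_masses[:, None] * self.vels).sum(axis=0)

    def angular_momentum(self) -> np.ndarray:
        """Total angular momentum about the lab origin (amu*A^2/ps)."""
        orbital = np.cross(self.coms, self.mol_masses[:, None] * self.vels).sum(axis=0)
        return orbital + self.ang_mom.sum(axis=0)

    def set_thermal_velocities(self, i: int, temperature: float, rng: np.random.Generator) -> None:
        """Draw Maxwell-Boltzmann COM velocity and angular momentum for molecule i."""
        if self.fixed_flags[i]:
            return
        kt = KB_KCAL_MOL_K * temperature * KCAL_PER_MOL_TO_INTERNAL
        self.vels[i] = np.sqrt(kt / self.mol_masses[i]) * rng.standard_normal(3)
        w = self.inertia_principal[i]
        sigma = np.where(w > _INERTIA_TOL, np.sqrt(kt * np.maximum(w, 0.0)), 0.0)
        self.ang_mom[i] = self.rots[i] @ (sigma * rng.standard_normal(3))

    def copy(self) -> "SimSystem":
        out = SimSystem.__new__(SimSystem)
        out.molecules = [m.copy() for m in self.molecules]
        out.fixed_flags = self.fixed_flags.copy()
        out.static_atoms = self.static_atoms.copy() if self.static_atoms is not None else None
        out.time = self.time
        out.offsets = self.offsets.copy()
        out.slices = list(self.slices)
        out.n_mobile_atoms = self.n_mobile_atoms
        out.mol_masses = self.mol_masses.copy()
        out.coms = self.coms.copy()
        out.x = self.x.copy()
        out.body = self.body.copy()
        out.rots = self.rots.copy()
        out.inertia_principal = self.inertia_principal.copy()
        out.inv_inertia = self.inv_inertia.copy()
        out.vels = self.vels.copy()
        out.ang_mom = self.ang_mom.copy()
        out._attach_views()
        return out
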