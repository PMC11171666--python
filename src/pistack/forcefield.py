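"""CHARMM-style nonbonded energetics between rigid molecules.

The stacking interaction is carried entirely by the nonbonded terms: a 12-6
Lennard-Jones potential

    E_LJ(r) = eps_ij * [ (Rmin_ij / r)^12 - 2 (Rmin_ij / r)^6 ]

whose minimum is exactly ``-eps_ij`` at ``r = Rmin_ij``, plus a Coulomb term
``332.0636 q_i q_j / r``.  Pair parameters follow the CHARMM combination
rules (geometric mean for eps, sum of the tabulated Rmin/2 values).  Both
terms are damped to zero between ``switch_on`` and ``cutoff`` by the CHARMM
energy-switching function, so energy and forces are continuous everywhere.

Only intermolecular pairs are evaluated: the monomers are rigid, so
intramolecular (bonded) terms are excluded by construction.
"""
from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .model import SimSystem
from .units import COULOMB_CONSTANT

__all__ = [
    "AtomTypeParams",
    "NonbondedConfig",
    "ParameterLookupError",
    "ConfigurationError",
    "load_parameter_table",
    "combine_pair",
    "lj_energy",
    "coulomb_energy",
    "NonbondedModel",
    "nonbonded_energy_forces",
]


class ParameterLookupError(KeyError):
    """An atom type could not be resolved in the parameter table."""


class ConfigurationError(ValueError):
    """A system is missing types/charges or a config value is inconsistent."""


@dataclasses.dataclass(frozen=True)
class AtomTypeParams:
    """One vdW parameter row: well depth, Rmin/2 and a default partial charge.

    Tabulated well depths are negative by convention; they are stored here as
    positive magnitudes (sign-normalized at load time).
    """

    type_name: str
    epsilon: float
    rmin_half: float
    default_charge: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "epsilon", abs(float(self.epsilon)))
        if self.rmin_half <= 0:
            raise ConfigurationError(
                f"Rmin/2 must be positive for type {self.type_name!r}, got {self.rmin_half}"
            )


@dataclasses.dataclass
class NonbondedConfig:
    """Cutoff scheme for the nonbonded sum (defaults: switch 10 A, cutoff 12 A)."""

    cutoff: float = 12.0
    switch_on: float = 10.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if not (0.0 < self.switch_on < self.cutoff):
            raise ConfigurationError(
                f"require 0 < switch_on < cutoff, got switch_on={self.switch_on}, "
                f"cutoff={self.cutoff}"
            )


def load_parameter_table(
    path: Optional[Union[str, Path]] = None,
) -> dict[str, AtomTypeParams]:
    """Load the shipped parameter table, or a user file of the same layout.

    The format is whitespace-separated columns ``type epsilon rmin_half
    [default_charge]``; ``#`` starts a comment.
    """
    if path is None:
        text = resources.files("pistack.data").joinpath("charmm36_nb.par").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, AtomTypeParams] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (3, 4):
            raise ConfigurationError(f"malformed parameter line: {raw!r}")
        name = fields[0]
        charge = float(fields[3]) if len(fields) == 4 else 0.0
        table[name] = AtomTypeParams(name, float(fields[1]), float(fields[2]), charge)
    return table


def lookup(table: dict[str, AtomTypeParams], type_name: str) -> AtomTypeParams:
    try:
        return table[type_name]
    except KeyError:
        raise ParameterLookupError(
            f"unknown atom type {type_name!r}; known types: {sorted(table)}"
        ) from None


def combine_pair(t_i: AtomTypeParams, t_j: AtomTypeParams) -> tuple[float, float]:
    """CHARMM combination: geometric-mean eps, arithmetic Rmin = Rmin/2_i + Rmin/2_j."""
    return float(np.sqrt(t_i.epsilon * t_j.epsilon)), t_i.rmin_half + t_j.rmin_half


def lj_energy(r, epsilon_ij: float, rmin_ij: float):
    """12-6 Lennard-Jones energy (kcal/mol) at separation ``r`` (A)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ energy requires r > 0")
    s6 = (rmin_ij / r) ** 6
    out = epsilon_ij * (s6 * s6 - 2.0 * s6)
    return float(out) if out.ndim == 0 else out


def coulomb_energy(r, q_i: float, q_j: float, ke: float = COULOMB_CONSTANT):
    """Coulomb energy (kcal/mol) between point charges (e) at ``r`` (A)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Coulomb energy requires r > 0")
    out = ke * q_i * q_j / r
    return float(out) if out.ndim == 0 else out


def switching_function(r: np.ndarray, cfg: NonbondedConfig) -> tuple[np.ndarray, np.ndarray]:
    """CHARMM energy switch S(r) and dS/dr (1 below switch_on, 0 beyond cutoff)."""
    r = np.asarray(r, dtype=float)
    ron2, roff2 = cfg.switch_on**2, cfg.cutoff**2
    r2 = r * r
    denom = (roff2 - ron2) ** 3
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r2 > ron2) & (r2 < roff2)
    rm2 = r2[mid]
    s[mid] = (roff2 - rm2) ** 2 * (roff2 + 2.0 * rm2 - 3.0 * ron2) / denom
    ds[mid] = 12.0 * r[mid] * (roff2 - rm2) * (ron2 - rm2) / denom
    off = r2 >= roff2
    s[off] = 0.0
    ds[off] = 0.0
    return s, ds


class NonbondedModel:
    """Precompiled pair table + evaluator for one system composition.

    Pairs are every intermolecular mobile-mobile pair plus every
    mobile-static pair; static-static interactions are a constant of the
    motion and are skipped.  Forces are returned for the mobile atoms (the
    scenery never moves).
    """

    def __init__(
        self,
        system: SimSystem,
        cfg: Optional[NonbondedConfig] = None,
        params: Optional[dict[str, AtomTypeParams]] = None,
    ) -> None:
        self.cfg = cfg if cfg is not None else NonbondedConfig()
        table = params if params is not None else load_parameter_table()

        groups = [(m.type_labels, m.charges) for m in system.molecules]
        if system.static_atoms is not None:
            groups.append((system.static_atoms.type_labels, system.static_atoms.charges))
            self.static_coords = system.static_atoms.coords.copy()
        else:
            self.static_coords = None
        self.n_mobile = system.n_mobile_atoms

        eps_half = []
        rmin_half = []
        charges = []
        for labels, q in groups:
            q = np.asarray(q, dtype=float)
            if not np.all(np.isfinite(q)):
                raise ConfigurationError("non-finite partial charge in system")
            p = [lookup(table, t) for t in labels]
            eps_half.append(np.array([x.epsilon for x in p]))
            rmin_half.append(np.array([x.rmin_half for x in p]))
            charges.append(q)
        sqrt_eps = np.sqrt(np.concatenate(eps_half))
        rh = np.concatenate(rmin_half)
        qq = np.concatenate(charges)

        sizes = [len(g[0]) for g in groups]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        n_static_group = 1 if self.static_coords is not None else 0
        ii_list, jj_list = [], []
        ngroups = len(groups)
        for a in range(ngroups):
            for b in range(a + 1, ngroups):
                if n_static_group and a >= ngroups - 1:
                    continue  # static-static
                ia = np.arange(offsets[a], offsets[a + 1])
                ib = np.arange(offsets[b], offsets[b + 1])
                gi, gj = np.meshgrid(ia, ib, indexing="ij")
                ii_list.append(gi.ravel())
                jj_list.append(gj.ravel())
        if ii_list:
            self.ii = np.concatenate(ii_list).astype(np.int64)
            self.jj = np.concatenate(jj_list).astype(np.int64)
        else:
            self.ii = np.empty(0, dtype=np.int64)
            self.jj = np.empty(0, dtype=np.int64)
        self.pair_eps = sqrt_eps[self.ii] * sqrt_eps[self.jj]
        rmin = rh[self.ii] + rh[self.jj]
        self.pair_rmin2 = rmin * rmin
        self.pair_qq = self.cfg.coulomb_constant * qq[self.ii] * qq[self.jj]
        self._ntot = int(offsets[-1])
        self._ron2 = self.cfg.switch_on**2
        self._roff2 = self.cfg.cutoff**2
        self._inv_denom = 1.0 / (self._roff2 - self._ron2) ** 3

    # ------------------------------------------------------------------
    def energy_forces(
        self, system: Optional[SimSystem] = None, coords: Optional[np.ndarray] = None
    ) -> tuple[float, np.ndarray]:
        """Total switched intermolecular energy (kcal/mol) and forces on the
        mobile atoms (kcal/(mol*A))."""
        from ._kernels import pair_energy_forces

        if coords is None:
            coords = system.mobile_coords()
        if self.static_coords is not None:
            x = np.vstack([coords, self.static_coords])
        else:
            x = np.ascontiguousarray(coords, dtype=float)
        forces = np.zeros((self._ntot, 3))
        energy = pair_energy_forces(
            x,
            self.ii,
            self.jj,
            self.pair_eps,
            self.pair_rmin2,
            self.pair_qq,
            self._ron2,
            self._roff2,
            self._inv_denom,
            forces,
        )
        return float(energy), forces[: self.n_mobile]

    def energy(self, system: Optional[SimSystem] = None, coords: Optional[np.ndarray] = None) -> float:
        return self.energy_forces(system, coords)[0]

    def min_pair_distance(self, coords: np.ndarray) -> float:
        if self.ii.size == 0:
            return np.inf
        if self.static_coords is not None:
            x = np.vstack([coords, self.static_coords])
        else:
            x = coords
        d = x[self.ii] - x[self.jj]
        return float(np.sqrt(np.einsum("ij,ij->i", d, d).min()))


def nonbonded_energy_forces(
    system: SimSystem,
    cfg: Optional[NonbondedConfig] = None,
    params: Optional[dict[str, AtomTypeParams]] = None,
) -> tuple[float, np.ndarray]:
    """One-shot switched LJ + Coulomb energy and per-atom forces.

    Returns the total intermolecular energy (kcal/mol) and the forces on the
    mobile atoms (kcal/(mol*A)); forces are the exact negative gradient of
    the switched energy, so they sum to zero when no scenery is present.
    """
    return NonbondedModel(system, cfg, params).energy_forces(system)
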