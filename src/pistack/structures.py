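"""Generation of PAH monomers, stacked dimers and frozen solvent scenery.

Monomers are built as idealized planar fused-hexagon lattices: aromatic
C-C = 1.39 A, C-H = 1.08 A, 120 degree angles.  Aromatic carbons bonded to a
hydrogen carry -0.115 e and their hydrogen +0.115 e (the CHARMM aromatic
convention); ring-fusion carbons carry no hydrogen and zero charge, so every
monomer is exactly neutral.  Anthracene is the linear tri-fused acene and
phenanthrene the angular isomer — identical composition (C14H10), different
shape.

H-type (face-to-face) dimer starts are parameterized by a
:class:`DimerGeometry`: separation along the ring-plane normal, an in-plane
lateral offset (zero offset is the exact "sandwich", a nonzero offset the
parallel-displaced/staggered arrangement) and a twist about the stacking
axis.

The frozen solvent shell emulates the observation that during pulling the
water acts as static scenery: TIP3P three-site waters on a jittered cubic
lattice around the solute, flagged static so the integrator never moves
them.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .model import Molecule, SimSystem

__all__ = [
    "DimerGeometry",
    "build_pah",
    "build_stacked_dimer",
    "build_frozen_solvent_shell",
    "dimer_coords",
    "plane_frame",
    "write_xyz",
    "read_xyz",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "write_pdb",
    "read_pdb",
]

CC_BOND = 1.39
CH_BOND = 1.08
TIP3P_OH = 0.9572
TIP3P_ANGLE_DEG = 104.52
TIP3P_Q_O = -0.834
TIP3P_Q_H = 0.417
WATER_NUMBER_DENSITY = 0.0334  # molecules per A^3

_HEX_SPACING = math.sqrt(3.0) * CC_BOND  # centre-to-centre distance of fused hexagons

# Fused-hexagon centres in units of _HEX_SPACING.
_PAH_CENTERS: dict[str, list[tuple[float, float]]] = {
    "benzene": [(0.0, 0.0)],
    "anthracene": [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)],
    "phenanthrene": [(0.0, 0.0), (1.0, 0.0), (1.5, math.sqrt(3.0) / 2.0)],
}

_PAH_FORMULAS = {"benzene": (6, 6), "anthracene": (14, 10), "phenanthrene": (14, 10)}


@dataclasses.dataclass
class DimerGeometry:
    """Stacked-dimer placement: plane separation, in-plane offset, twist."""

    separation: float
    lateral_offset: tuple[float, float] = (0.0, 0.0)
    twist: float = 0.0  # degrees about the stacking axis

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError(f"separation must be positive, got {self.separation}")
        self.lateral_offset = (float(self.lateral_offset[0]), float(self.lateral_offset[1]))


# ----------------------------------------------------------------------
# monomer builders
# ----------------------------------------------------------------------

def build_pah(kind: str) -> Molecule:
    """Build an idealized planar PAH monomer (benzene/anthracene/phenanthrene)."""
    kind = kind.lower()
    if kind not in _PAH_CENTERS:
        raise ValueError(
            f"unknown PAH kind {kind!r}; supported kinds: {sorted(_PAH_CENTERS)}"
        )
    centers = np.array(_PAH_CENTERS[kind]) * _HEX_SPACING

    # collect unique hexagon vertices (the carbons)
    verts: list[np.ndarray] = []
    for c in centers:
        for k in range(6):
            ang = math.radians(30.0 + 60.0 * k)
            v = c + CC_BOND * np.array([math.cos(ang), math.sin(ang)])
            if not any(np.linalg.norm(v - u) < 1e-6 for u in verts):
                verts.append(v)
    carbons = np.array(sorted(verts, key=lambda p: (round(p[0], 6), round(p[1], 6))))

    # ring bonds: vertex pairs at the construction bond length
    n_c = len(carbons)
    neighbors: list[list[int]] = [[] for _ in range(n_c)]
    for i in range(n_c):
        for j in range(i + 1, n_c):
            if abs(np.linalg.norm(carbons[i] - carbons[j]) - CC_BOND) < 1e-6:
                neighbors[i].append(j)
                neighbors[j].append(i)

    names: list[str] = []
    types: list[str] = []
    charges: list[float] = []
    coords: list[list[float]] = []
    h_entries: list[tuple[str, list[float]]] = []
    n_h = 0
    for i, c in enumerate(carbons):
        names.append(f"C{i + 1}")
        types.append("CA")
        coords.append([c[0], c[1], 0.0])
        if len(neighbors[i]) == 2:
            u = np.zeros(2)
            for j in neighbors[i]:
                b = c - carbons[j]
                u += b / np.linalg.norm(b)
            u /= np.linalg.norm(u)
            h = c + CH_BOND * u
            n_h += 1
            h_entries.append((f"H{n_h}", [h[0], h[1], 0.0]))
            charges.append(-0.115)
        else:
            charges.append(0.0)  # ring-fusion carbon, no hydrogen
    for name, xyz in h_entries:
        names.append(name)
        types.append("HA")
        charges.append(0.115)
        coords.append(xyz)

    nc_expected, nh_expected = _PAH_FORMULAS[kind]
    assert n_c == nc_expected and n_h == nh_expected, (kind, n_c, n_h)

    mol = Molecule(kind, names, types, np.array(charges), np.array(coords))
    mol.coords = mol.coords - mol.com()  # centred, plane exactly z = 0
    return mol


# ----------------------------------------------------------------------
# dimers
# ----------------------------------------------------------------------

def plane_frame(mol: Molecule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane axes and plane normal of a (near-)planar molecule via SVD."""
    centered = mol.coords - mol.com()
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    a1, a2, normal = vt[0], vt[1], vt[2]
    if s[2] > 1e-6 * max(s[0], 1.0):
        raise ValueError(f"molecule {mol.name!r} is not planar (residual {s[2]:.3g})")
    if normal[2] < 0 or (normal[2] == 0 and normal[np.argmax(np.abs(normal))] < 0):
        normal = -normal
    if np.linalg.det(np.stack([a1, a2, normal])) < 0:
        a2 = -a2
    return a1, a2, normal


def dimer_coords(mol: Molecule, geom: DimerGeometry) -> np.ndarray:
    """Coordinates of the second monomer placed above ``mol`` per ``geom``."""
    a1, a2, normal = plane_frame(mol)
    com = mol.com()
    theta = math.radians(geom.twist)
    k = normal
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + math.sin(theta) * kx + (1.0 - math.cos(theta)) * (kx @ kx)
    shift = (
        geom.separation * normal
        + geom.lateral_offset[0] * a1
        + geom.lateral_offset[1] * a2
    )
    return (mol.coords - com) @ rot.T + com + shift


def build_stacked_dimer(
    mol: Molecule,
    geom: DimerGeometry,
    fixed: Sequence[bool] = (False, False),
) -> SimSystem:
    """Stack a twisted/offset copy of ``mol`` above itself as an H-type dimer."""
    copy2 = mol.copy()
    copy2.name = f"{mol.name}_2"
    copy2.coords = dimer_coords(mol, geom)
    return SimSystem([mol.copy(), copy2], fixed=list(fixed))


# ----------------------------------------------------------------------
# frozen solvent scenery
# ----------------------------------------------------------------------

def _tip3p_template() -> np.ndarray:
    half = math.radians(TIP3P_ANGLE_DEG / 2.0)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [TIP3P_OH * math.sin(half), 0.0, TIP3P_OH * math.cos(half)],
            [-TIP3P_OH * math.sin(half), 0.0, TIP3P_OH * math.cos(half)],
        ]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_frozen_solvent_shell(
    system: SimSystem,
    thickness: float,
    exclusion: float = 2.8,
    seed: int = 0,
    jitter: float = 0.3,
) -> SimSystem:
    """Surround the solute with a static, jittered-lattice TIP3P shell.

    Water oxygens are placed on a cubic lattice at the bulk number density
    (0.0334 molecules/A^3) with a uniform positional jitter and random
    orientations, keeping every oxygen at least ``exclusion`` A and at most
    ``thickness`` A from the nearest solute atom.  The returned system shares
    the solute molecules (velocities reset) with the waters flagged static:
    they exert forces but are never moved by the integrator.
    """
    if thickness <= 0:
        raise ValueError(f"shell thickness must be positive, got {thickness}")
    if exclusion >= thickness:
        raise ValueError(
            f"exclusion ({exclusion} A) must be smaller than thickness ({thickness} A); "
            "no room to place water"
        )
    rng = np.random.default_rng(seed)
    solute = system.mobile_coords()
    spacing = WATER_NUMBER_DENSITY ** (-1.0 / 3.0)
    lo = solute.min(axis=0) - thickness
    hi = solute.max(axis=0) + thickness
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sites = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)

    template = _tip3p_template()
    names: list[str] = []
    types: list[str] = []
    charges: list[float] = []
    coords: list[np.ndarray] = []
    n_w = 0
    for site in sites:
        dmin = np.sqrt(((solute - site) ** 2).sum(axis=1)).min()
        if dmin < exclusion or dmin > thickness:
            continue
        n_w += 1
        water = template @ _random_rotation(rng).T + site
        names += [f"OW{n_w}", f"HW{n_w}A", f"HW{n_w}B"]
        types += ["OH1", "H", "H"]
        charges += [TIP3P_Q_O, TIP3P_Q_H, TIP3P_Q_H]
        coords.append(water)
    shell = Molecule(
        "tip3p_shell",
        names,
        types,
        np.array(charges) if charges else np.empty(0),
        np.vstack(coords) if coords else np.empty((0, 3)),
    )
    return SimSystem(
        system.molecules, fixed=list(system.fixed_flags), static_atoms=shell, time=system.time
    )


# ----------------------------------------------------------------------
# XYZ / PDB readers and writers
# ----------------------------------------------------------------------

def _atom_lines(names: Sequence[str], coords: np.ndarray) -> list[str]:
    return [
        f"{n:<4s} {x:14.6f} {y:14.6f} {z:14.6f}"
        for n, (x, y, z) in zip(names, np.asarray(coords, dtype=float))
    ]


def write_xyz(
    path: Union[str, Path],
    names: Sequence[str],
    coords: np.ndarray,
    comment: str = "",
) -> None:
    lines = [str(len(names)), comment.replace("\n", " ")]
    lines += _atom_lines(names, coords)
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz_trajectory(
    path: Union[str, Path],
    names: Sequence[str],
    frames: Sequence[tuple[float, np.ndarray]],
) -> None:
    """Multi-frame XYZ; the comment line carries the frame time in ps."""
    blocks = []
    for t, coords in frames:
        blocks.append(str(len(names)))
        blocks.append(f"t= {t:.6f} ps")
        blocks.extend(_atom_lines(names, coords))
    Path(path).write_text("\n".join(blocks) + "\n")


def read_xyz(path: Union[str, Path]) -> tuple[list[str], np.ndarray, str]:
    frames = read_xyz_trajectory(path)
    names, coords, comment = frames[0]
    return names, coords, comment


def read_xyz_trajectory(path: Union[str, Path]) -> list[tuple[list[str], np.ndarray, str]]:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        names, coords = [], []
        for line in lines[i + 2 : i + 2 + n]:
            parts = line.split()
            names.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append((names, np.array(coords), comment))
        i += 2 + n
    return frames


def write_pdb(
    path: Union[str, Path],
    names: Sequence[str],
    coords: np.ndarray,
    resname: str = "LIG",
    elements: Optional[Sequence[str]] = None,
) -> None:
    """Minimal fixed-column PDB: coordinate records only, single MODEL."""
    coords = np.asarray(coords, dtype=float)
    if elements is None:
        elements = [n.strip()[0] for n in names]
    out = ["MODEL        1"]
    for i, (name, (x, y, z), el) in enumerate(zip(names, coords, elements), start=1):
        out.append(
            f"ATOM  {i:5d} {name[:4]:<4s} {resname:<3s} A{1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
        )
    out += ["ENDMDL", "END"]
    Path(path).write_text("\n".join(out) + "\n")


def read_pdb(path: Union[str, Path]) -> tuple[list[str], np.ndarray, list[str]]:
    names, coords, elements = [], [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")):
            names.append(line[12:16].strip())
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            el = line[76:78].strip() if len(line) >= 78 else ""
            elements.append(el or names[-1][0])
    return names, np.array(coords), elements
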