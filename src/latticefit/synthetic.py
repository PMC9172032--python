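"""Synthetic SHELX fixtures with known ground truth.

Generates small-molecule models placed in a known "true" cell, derives 1,2
(bonded) and 1,3 (angle) distance restraints from the geometry, perturbs the
cell on the crystal system's free parameters, and emits a parseable RES text
plus a manifest recording the ground truth.  Restraint targets are computed
from the *emitted* (decimal-formatted) fractional coordinates under the true
cell through the same metric-tensor distance used by the objective, so a
zero-noise fixture has a residual of exactly 0 at the true cell.

The generator stands in for a chemical restraint dictionary: bonding is
simple distance-cutoff perception over C/N/O/H-like labels, with optional
independent Gaussian noise on restraint targets and/or Cartesian coordinates.
It emulates the geometry of the optimization problem, not diffraction data —
recovering a cell here demonstrates the optimizer, not data-driven
refinement.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .lattice import (
    CrystalSystem,
    UnitCell,
    get_system,
    metric_tensor_derivatives,
)
from .shelx import ANGLE_13, BOND_12, DEFAULT_SIGMA, Structure, parse_res, _fmt

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "restraints_from_geometry",
    "hexagon_planar",
    "tetrahedral",
    "chain",
    "write_fixture",
]


def hexagon_planar(bond: float = 1.39) -> tuple[np.ndarray, list[str]]:
    """Regular 6-ring in the Cartesian x–y plane (circumradius = bond)."""
    ang = np.arange(6) * math.pi / 3.0
    xyz = np.stack([bond * np.cos(ang), bond * np.sin(ang), np.zeros(6)], axis=1)
    return xyz, ["C"] * 6


def tetrahedral(bond: float = 1.54) -> tuple[np.ndarray, list[str]]:
    """Methane-like fragment: a central atom with four tetrahedral neighbours."""
    dirs = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / math.sqrt(3.0)
    xyz = np.vstack([[0.0, 0.0, 0.0], bond * dirs])
    return xyz, ["C"] * 5


def chain(n: int = 6, bond: float = 1.54,
          angle: float = 109.47) -> tuple[np.ndarray, list[str]]:
    """n-atom zigzag chain in the x–y plane with the given bond angle."""
    if n < 2:
        raise ValueError("chain needs at least 2 atoms")
    half = math.radians(angle) / 2.0
    xyz = np.zeros((n, 3))
    for k in range(1, n):
        xyz[k, 0] = xyz[k - 1, 0] + bond * math.sin(half)
        xyz[k, 1] = xyz[k - 1, 1] + bond * math.cos(half) * (1 if k % 2 else -1)
    return xyz, ["C"] * n


_MOLECULES = {
    "hexagon_planar": hexagon_planar,
    "tetrahedral": tetrahedral,
    "chain": chain,
}


def restraints_from_geometry(
    xyz: np.ndarray,
    elements: Sequence[str],
    bond_cutoff: Union[float, dict] = 1.8,
) -> tuple[list[tuple[str, int, int, float]], dict]:
    """Derive 1,2 and 1,3 distance restraints from Cartesian geometry.

    Bonding is distance-based: a pair is bonded when its distance is below
    the cutoff (a scalar, or a dict keyed by frozenset of element labels).
    Returns ``(restraints, info)`` where each restraint is
    ``(kind, i, j, target)`` with targets equal to the current distances, and
    ``info`` flags disconnected atom sets (restraints are still emitted for
    the connected parts).
    """
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    if n < 2:
        raise ValueError("need at least 2 atoms to derive restraints")

    def cutoff(i, j):
        if isinstance(bond_cutoff, dict):
            return bond_cutoff[frozenset((elements[i], elements[j]))]
        return float(bond_cutoff)

    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    bonded = [[] for _ in range(n)]
    out: list[tuple[str, int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < cutoff(i, j):
                bonded[i].append(j)
                bonded[j].append(i)
                out.append((BOND_12, i, j, float(dist[i, j])))
    bonded_pairs = {(min(i, j), max(i, j)) for _, i, j, _ in out}
    for m in range(n):
        nb = sorted(bonded[m])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                i, j = nb[x], nb[y]
                if (min(i, j), max(i, j)) not in bonded_pairs:
                    out.append((ANGLE_13, i, j, float(dist[i, j])))
    # dedupe 1,3 pairs reachable through several shared neighbours
    seen = set()
    unique = []
    for kind, i, j, t in out:
        key = (kind, min(i, j), max(i, j))
        if key not in seen:
            seen.add(key)
            unique.append((kind, i, j, t))

    # connectivity check
    comp = list(range(n))

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for i in range(n):
        for j in bonded[i]:
            comp[find(i)] = find(j)
    n_components = len({find(i) for i in range(n)})
    info = {
        "n_components": n_components,
        "disconnected": n_components > 1,
    }
    return unique, info


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure with known ground truth.

    ``cell_perturbation`` is the signed fractional change applied
    multiplicatively to each free cell parameter (scalar, or one value per
    free parameter); noise standard deviations are in Å.  Identical
    ``seed`` + spec yields a byte-identical fixture.
    """

    system: Union[str, CrystalSystem] = "triclinic"
    true_cell: UnitCell = field(default_factory=lambda: UnitCell(10, 12, 14, 85, 95, 100))
    molecule: Union[str, np.ndarray] = "tetrahedral"
    elements: Optional[Sequence[str]] = None
    bond_length: Optional[float] = None
    n_copies: int = 1
    placement_offsets: Optional[Sequence[Sequence[float]]] = None
    bond_cutoff: Union[float, dict] = 1.8
    cell_perturbation: Union[float, Sequence[float]] = 0.0
    restraint_noise_sd: float = 0.0
    coordinate_noise_sd: float = 0.0
    explicit_sigmas: bool = False
    seed: int = 0


def _molecule_coords(spec: FixtureSpec) -> tuple[np.ndarray, list[str]]:
    if isinstance(spec.molecule, str):
        try:
            builder = _MOLECULES[spec.molecule]
        except KeyError:
            raise ValueError(
                f"unknown molecule {spec.molecule!r}; expected one of "
                f"{sorted(_MOLECULES)} or a coordinate array"
            ) from None
        kwargs = {}
        if spec.bond_length is not None:
            kwargs["bond"] = spec.bond_length
        return builder(**kwargs)
    xyz = np.asarray(spec.molecule, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or len(xyz) < 2:
        raise ValueError("custom molecule must be an (n>=2, 3) coordinate array")
    elements = list(spec.elements) if spec.elements is not None else ["C"] * len(xyz)
    return xyz, elements


def generate_fixture(spec: FixtureSpec) -> tuple[Structure, UnitCell, dict]:
    """Build a fixture: structure at the perturbed cell, true cell, manifest."""
    system = get_system(spec.system)
    true_cell = spec.true_cell
    system.check(true_cell)
    rng = np.random.default_rng(spec.seed)

    xyz, elements = _molecule_coords(spec)
    if spec.coordinate_noise_sd > 0:
        xyz = xyz + rng.normal(0.0, spec.coordinate_noise_sd, size=xyz.shape)

    offsets = spec.placement_offsets
    if offsets is None:
        offsets = [
            (0.25 + 0.4 * k, 0.25, 0.25) for k in range(spec.n_copies)
        ]
    if len(offsets) != spec.n_copies:
        raise ValueError("placement_offsets length must equal n_copies")

    # bonding/1,3 topology from the clean single-copy geometry
    clean_xyz, _ = _molecule_coords(
        FixtureSpec(**{**spec.__dict__, "coordinate_noise_sd": 0.0})
    ) if spec.coordinate_noise_sd > 0 else (xyz, elements)
    topo, conn_info = restraints_from_geometry(clean_xyz, elements, spec.bond_cutoff)

    minv = np.linalg.inv(true_cell.orthogonalization_matrix())
    n_mol = len(xyz)

    # free cell perturbation (multiplicative, free parameters only)
    free = system.free_vector(true_cell)
    amp = np.asarray(spec.cell_perturbation, dtype=float)
    if amp.ndim == 0:
        amp = np.full(len(free), float(amp))
    if len(amp) != len(free):
        raise ValueError(
            f"cell_perturbation needs {len(free)} values for {system.name}"
        )
    perturbed_cell = system.to_cell(free * (1.0 + amp))

    sfac = sorted(set(elements))
    lines: list[str] = []
    lines.append(f"TITL synthetic {system.name} fixture (seed {spec.seed})")
    lines.append(
        "CELL 0.02510 "
        + " ".join(_fmt(v, 4) for v in perturbed_cell.as_tuple()[:3])
        + " "
        + " ".join(_fmt(v, 3) for v in perturbed_cell.as_tuple()[3:])
    )
    lines.append("ZERR 1 0 0 0 0 0 0")
    lines.append("LATT -1")
    lines.append("SFAC " + " ".join(sfac))
    lines.append("UNIT " + " ".join(
        str(spec.n_copies * elements.count(e)) for e in sfac))

    # fractional coordinates per copy, formatted exactly as emitted
    frac_by_copy: list[np.ndarray] = []
    for copy_idx in range(spec.n_copies):
        frac = (minv @ xyz.T).T + np.asarray(offsets[copy_idx], dtype=float)
        frac = np.array(
            [[float(_fmt(v, 6)) for v in row] for row in frac]
        )
        frac_by_copy.append(frac)

    # restraint targets from the emitted coordinates at the true cell
    restraint_lines: list[str] = []
    for kind, i, j, _t in topo:
        target = true_cell.distance(frac_by_copy[0][i], frac_by_copy[0][j])
        if spec.restraint_noise_sd > 0:
            target = max(target + rng.normal(0.0, spec.restraint_noise_sd), 0.05)
        cmd = "DFIX" if kind == BOND_12 else "DANG"
        sig = f" {_fmt(DEFAULT_SIGMA[kind], 3)}" if spec.explicit_sigmas else ""
        for copy_idx in range(spec.n_copies):
            if spec.n_copies > 1:
                a1 = f"{elements[i]}{i + 1}_{copy_idx + 1}"
                a2 = f"{elements[j]}{j + 1}_{copy_idx + 1}"
            else:
                a1 = f"{elements[i]}{i + 1}"
                a2 = f"{elements[j]}{j + 1}"
            restraint_lines.append(f"{cmd} {_fmt(target, 6)}{sig} {a1} {a2}")
    lines.extend(restraint_lines)

    for copy_idx in range(spec.n_copies):
        if spec.n_copies > 1:
            lines.append(f"RESI {copy_idx + 1} MOL")
        for k in range(n_mol):
            sfac_idx = sfac.index(elements[k]) + 1
            coords = " ".join(_fmt(v, 6) for v in frac_by_copy[copy_idx][k])
            lines.append(f"{elements[k]}{k + 1} {sfac_idx} {coords} 11.00000 0.05")
    lines.append("END")
    text = "\n".join(lines) + "\n"

    structure = parse_res(text)

    # observability of each free parameter at the true cell
    dG = metric_tensor_derivatives(true_cell)
    observable = {}
    for group in system.groups:
        s = 0.0
        for r in structure.restraints:
            dx = structure.atoms[r.i].frac - structure.atoms[r.j].frac
            for p in group:
                s += abs(dx @ dG[p] @ dx)
        observable[group[0]] = bool(s > 1e-9)

    manifest = {
        "system": system.name,
        "true_cell": list(true_cell.as_tuple()),
        "perturbed_cell": list(perturbed_cell.as_tuple()),
        "seed": spec.seed,
        "cell_perturbation": [float(v) for v in amp],
        "restraint_noise_sd": spec.restraint_noise_sd,
        "coordinate_noise_sd": spec.coordinate_noise_sd,
        "n_atoms": len(structure.atoms),
        "n_restraints": len(structure.restraints),
        "observable": observable,
        "disconnected_warning": conn_info["disconnected"],
        "n_components": conn_info["n_components"],
    }
    return structure, true_cell, manifest


def write_fixture(spec: FixtureSpec, res_path, manifest_path=None) -> None:
    """Emit a fixture as a RES file plus a JSON manifest next to it."""
    structure, _true, manifest = generate_fixture(spec)
    with open(res_path, "w") as fh:
        fh.write("\n".join(structure.lines) + "\n")
    if manifest_path is None:
        manifest_path = str(res_path) + ".manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
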