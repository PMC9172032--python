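"""Unit-cell geometry: metric tensor, distances and crystal-system constraints.

A unit cell is described by lengths ``a, b, c`` (Å) and angles ``alpha, beta,
gamma`` (degrees).  All distance computation goes through the cell metric
tensor ``G``: for a fractional difference vector ``Δx`` the squared Cartesian
distance is ``Δxᵀ G Δx``, which makes every derived quantity independent of
the orthogonalization convention.  Angles are degrees at every public
interface; radians appear only inside trigonometric evaluation.

A :class:`CrystalSystem` maps between the full six-parameter cell and the
reduced vector of free optimization variables (e.g. a single ``a`` for cubic),
with fixed angles held exactly at 90°/120° and tied lengths exactly equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "UnitCell",
    "CrystalSystem",
    "CellValidationError",
    "CellConstraintError",
    "CRYSTAL_SYSTEMS",
    "get_system",
    "metric_tensor",
    "metric_tensor_derivatives",
    "distance",
]

PARAM_NAMES = ("a", "b", "c", "alpha", "beta", "gamma")
_LENGTHS = ("a", "b", "c")
_ANGLES = ("alpha", "beta", "gamma")
_DEG = math.pi / 180.0


class CellValidationError(ValueError):
    """Raised when six cell parameters do not describe a valid lattice."""


class CellConstraintError(ValueError):
    """Raised when a cell violates its declared crystal system's constraints."""


@dataclass(frozen=True)
class UnitCell:
    """Six unit-cell parameters: lengths in Å, angles in degrees.

    The cell is validated on construction: lengths must be positive, angles
    strictly inside (0°, 180°), and the three angles must be mutually
    compatible (positive cell volume, i.e. positive-definite metric tensor).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in _LENGTHS:
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0.0:
                raise CellValidationError(
                    f"cell length {name}={v!r} must be finite and > 0"
                )
        for name in _ANGLES:
            v = float(getattr(self, name))
            if not math.isfinite(v) or not (0.0 < v < 180.0):
                raise CellValidationError(
                    f"cell angle {name}={v!r} must lie strictly in (0, 180) degrees"
                )
        ca, cb, cg = (math.cos(_DEG * getattr(self, n)) for n in _ANGLES)
        # determinant factor of G / (abc)^2; > 0 iff G is positive definite
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise CellValidationError(
                f"angles alpha={self.alpha}, beta={self.beta}, gamma={self.gamma} "
                "are incompatible (non-positive cell volume)"
            )

    # -- derived quantities ------------------------------------------------

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def metric_tensor(self) -> np.ndarray:
        """3×3 symmetric positive-definite metric tensor in Å²."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(_DEG * getattr(self, n)) for n in _ANGLES)
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (closed form, not via the metric determinant)."""
        ca, cb, cg = (math.cos(_DEG * getattr(self, n)) for n in _ANGLES)
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(disc)

    def orthogonalization_matrix(self) -> np.ndarray:
        """Fractional → Cartesian matrix ``M`` (columns are the cell vectors).

        Convention: **a** along the first Cartesian axis, **b** in the first
        coordinate plane.  ``M`` is upper triangular and ``Mᵀ M`` equals the
        metric tensor.  Only exported Cartesian coordinates depend on this
        choice; all internal distance math uses the metric tensor.
        """
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(_DEG * getattr(self, n)) for n in _ANGLES)
        sg = math.sin(_DEG * self.gamma)
        cz2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * math.sqrt(cz2) / sg],
            ]
        )

    def distance(self, frac1: Sequence[float], frac2: Sequence[float]) -> float:
        """Distance in Å between two fractional positions (no periodic wrap)."""
        dx = np.asarray(frac1, dtype=float) - np.asarray(frac2, dtype=float)
        return float(math.sqrt(max(dx @ self.metric_tensor() @ dx, 0.0)))


def metric_tensor(cell: UnitCell) -> np.ndarray:
    return cell.metric_tensor()


def distance(cell: UnitCell, frac1: Sequence[float], frac2: Sequence[float]) -> float:
    return cell.distance(frac1, frac2)


def metric_tensor_derivatives(cell: UnitCell) -> dict[str, np.ndarray]:
    """Partial derivatives ∂G/∂τ for each of the six cell parameters.

    Angle derivatives are taken with respect to *degrees* (the public unit),
    i.e. the radian derivative is scaled by π/180.
    """
    a, b, c = cell.a, cell.b, cell.c
    ca, cb, cg = (math.cos(_DEG * getattr(cell, n)) for n in _ANGLES)
    sa, sb, sg = (math.sin(_DEG * getattr(cell, n)) for n in _ANGLES)

    d: dict[str, np.ndarray] = {}
    d["a"] = np.array(
        [[2.0 * a, b * cg, c * cb], [b * cg, 0.0, 0.0], [c * cb, 0.0, 0.0]]
    )
    d["b"] = np.array(
        [[0.0, a * cg, 0.0], [a * cg, 2.0 * b, c * ca], [0.0, c * ca, 0.0]]
    )
    d["c"] = np.array(
        [[0.0, 0.0, a * cb], [0.0, 0.0, b * ca], [a * cb, b * ca, 2.0 * c]]
    )
    d["alpha"] = _DEG * np.array(
        [[0.0, 0.0, 0.0], [0.0, 0.0, -b * c * sa], [0.0, -b * c * sa, 0.0]]
    )
    d["beta"] = _DEG * np.array(
        [[0.0, 0.0, -a * c * sb], [0.0, 0.0, 0.0], [-a * c * sb, 0.0, 0.0]]
    )
    d["gamma"] = _DEG * np.array(
        [[0.0, -a * b * sg, 0.0], [-a * b * sg, 0.0, 0.0], [0.0, 0.0, 0.0]]
    )
    return d


@dataclass(frozen=True)
class CrystalSystem:
    """Lattice constraints of a crystal system and its free-variable map.

    ``groups`` lists, per free optimization variable, the cell parameters it
    controls (tied parameters share one variable); ``fixed`` maps constrained
    angles to their exact values.  Monoclinic is implemented with four free
    variables (a, b, c, β; unique axis b), the full set left free by the
    constraints α = γ = 90°.
    """

    name: str
    groups: tuple[tuple[str, ...], ...]
    fixed: tuple[tuple[str, float], ...]

    @property
    def free_parameter_count(self) -> int:
        return len(self.groups)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.groups)

    def to_cell(self, free: Sequence[float]) -> UnitCell:
        """Expand a free-variable vector into a full conforming cell."""
        free = list(free)
        if len(free) != self.free_parameter_count:
            raise ValueError(
                f"{self.name} expects {self.free_parameter_count} free "
                f"parameters, got {len(free)}"
            )
        params = dict(self.fixed)
        for value, group in zip(free, self.groups):
            for p in group:
                params[p] = float(value)
        return UnitCell(**params)

    def free_vector(self, cell: UnitCell) -> np.ndarray:
        """Project a conforming cell onto its free variables (exact inverse)."""
        self.check(cell)
        return np.array([getattr(cell, g[0]) for g in self.groups], dtype=float)

    def check(self, cell: UnitCell) -> None:
        """Raise :class:`CellConstraintError` unless the cell conforms exactly."""
        for p, v in self.fixed:
            if getattr(cell, p) != v:
                raise CellConstraintError(
                    f"cell does not conform to {self.name}: {p}="
                    f"{getattr(cell, p)!r}, expected exactly {v!r} "
                    "(fix the cell or relax to triclinic)"
                )
        for group in self.groups:
            first = getattr(cell, group[0])
            for p in group[1:]:
                if getattr(cell, p) != first:
                    raise CellConstraintError(
                        f"cell does not conform to {self.name}: {p}="
                        f"{getattr(cell, p)!r} must equal {group[0]}={first!r}"
                    )

    def conforms(self, cell: UnitCell) -> bool:
        try:
            self.check(cell)
        except CellConstraintError:
            return False
        return True

    def reduce_gradient(self, full_gradient: Iterable[float]) -> np.ndarray:
        """Collapse a 6-vector of ∂/∂τ onto the free variables.

        Tied parameters accumulate their partials; fixed angles are dropped.
        """
        g = dict(zip(PARAM_NAMES, full_gradient))
        return np.array([sum(g[p] for p in group) for group in self.groups])


_R90 = 90.0
_R120 = 120.0

CRYSTAL_SYSTEMS: dict[str, CrystalSystem] = {
    s.name: s
    for s in (
        CrystalSystem(
            "triclinic",
            (("a",), ("b",), ("c",), ("alpha",), ("beta",), ("gamma",)),
            (),
        ),
        CrystalSystem(
            "monoclinic",
            (("a",), ("b",), ("c",), ("beta",)),
            (("alpha", _R90), ("gamma", _R90)),
        ),
        CrystalSystem(
            "orthorhombic",
            (("a",), ("b",), ("c",)),
            (("alpha", _R90), ("beta", _R90), ("gamma", _R90)),
        ),
        CrystalSystem(
            "hexagonal",
            (("a", "b"), ("c",)),
            (("alpha", _R90), ("beta", _R90), ("gamma", _R120)),
        ),
        CrystalSystem(
            "tetragonal",
            (("a", "b"), ("c",)),
            (("alpha", _R90), ("beta", _R90), ("gamma", _R90)),
        ),
        CrystalSystem(
            "cubic",
            (("a", "b", "c"),),
            (("alpha", _R90), ("beta", _R90), ("gamma", _R90)),
        ),
    )
}


def get_system(system: str | CrystalSystem) -> CrystalSystem:
    """Look up a crystal system by name (case-insensitive) or pass one through.

    Rhombohedral/trigonal lattices are handled in the hexagonal setting and
    accepted as aliases of ``hexagonal``.
    """
    if isinstance(system, CrystalSystem):
        return system
    key = system.strip().lower()
    if key in ("trigonal", "rhombohedral"):
        key = "hexagonal"
    try:
        return CRYSTAL_SYSTEMS[key]
    except KeyError:
        raise ValueError(
            f"unknown crystal system {system!r}; expected one of "
            f"{sorted(CRYSTAL_SYSTEMS)}"
        ) from None
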