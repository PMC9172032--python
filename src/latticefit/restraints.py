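"""Restraint residual (the optimization target) and its analytic gradient.

For each restraint *R* between two atoms with fractional difference ``Δx``,
the current distance is ``d_R = sqrt(Δxᵀ G Δx)`` with ``G`` the cell metric
tensor.  The primary target function compares *squared* distances,

    total = Σ_R (1/σ_R²) (d_R² − Δ_R²)² ,

which avoids the modulus, has smooth derivatives, and attains its minimum at
the same cell as the conventional least-squares form

    total_ls = Σ_R (1/σ_R²) (d_R − Δ_R)²

(selectable via ``form="least_squares"``).  "Inverse variation" weighting is
1/σ² for the squared objectives; the hill-climbing fitting criterion is the
weighted mean absolute deviation Σ (1/σ)|d − Δ| / Σ (1/σ).

The gradient with respect to a cell parameter τ follows by the chain rule
through the metric tensor:

    ∂total/∂τ = Σ_R (2/σ_R²)(d_R² − Δ_R²) · (Δxᵀ ∂G/∂τ Δx)

and is projected onto a crystal system's free variables by summing partials
of tied parameters and dropping fixed angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import (
    PARAM_NAMES,
    CrystalSystem,
    UnitCell,
    get_system,
    metric_tensor_derivatives,
)
from .shelx import Structure

__all__ = ["ObjectiveValue", "residual", "gradient", "deviation_report",
           "NothingToOptimizeError", "OBJECTIVE_FORMS"]

OBJECTIVE_FORMS = ("squared", "least_squares")


class NothingToOptimizeError(ValueError):
    """The structure carries no restraints, so the objective is undefined."""


@dataclass(frozen=True)
class ObjectiveValue:
    """The weighted restraint residual and its per-restraint breakdown."""

    total: float
    distances: np.ndarray  # d_R in Å
    deviations: np.ndarray  # d_R − Δ_R in Å (signed)
    contributions: np.ndarray  # weighted terms summing to total
    weighted_mean_abs_dev: float  # Σ (1/σ)|d−Δ| / Σ (1/σ), in Å

    @property
    def per_restraint(self) -> list[tuple[int, float, float, float]]:
        return [
            (i, float(d), float(dev), float(c))
            for i, (d, dev, c) in enumerate(
                zip(self.distances, self.deviations, self.contributions)
            )
        ]


def _arrays(structure: Structure):
    """Stack restraint data into arrays: Δx (n,3), targets, sigmas."""
    if not structure.restraints:
        raise NothingToOptimizeError(
            "structure has no DFIX/DANG restraints: nothing to optimize"
        )
    dx = np.empty((len(structure.restraints), 3))
    targets = np.empty(len(structure.restraints))
    sigmas = np.empty(len(structure.restraints))
    for k, r in enumerate(structure.restraints):
        dx[k] = structure.atoms[r.i].frac - structure.atoms[r.j].frac
        targets[k] = r.target
        sigmas[k] = r.sigma
    return dx, targets, sigmas


def residual(
    structure: Structure, cell: UnitCell | None = None, form: str = "squared"
) -> ObjectiveValue:
    """Evaluate the restraint residual of a structure at a (trial) cell.

    Atom fractional coordinates are taken literally (no periodic wrapping);
    ``cell`` defaults to the structure's own cell.
    """
    if form not in OBJECTIVE_FORMS:
        raise ValueError(f"form must be one of {OBJECTIVE_FORMS}, got {form!r}")
    cell = cell if cell is not None else structure.cell
    dx, targets, sigmas = _arrays(structure)
    G = cell.metric_tensor()
    d2 = np.einsum("ki,ij,kj->k", dx, G, dx)
    d = np.sqrt(np.maximum(d2, 0.0))
    if form == "squared":
        contrib = (d2 - targets**2) ** 2 / sigmas**2
    else:
        contrib = (d - targets) ** 2 / sigmas**2
    w = 1.0 / sigmas
    wmad = float(np.sum(w * np.abs(d - targets)) / np.sum(w))
    return ObjectiveValue(
        total=float(np.sum(contrib)),
        distances=d,
        deviations=d - targets,
        contributions=contrib,
        weighted_mean_abs_dev=wmad,
    )


def gradient(
    structure: Structure,
    cell: UnitCell | None = None,
    system: CrystalSystem | str = "triclinic",
    form: str = "squared",
) -> np.ndarray:
    """Analytic gradient of the residual w.r.t. a system's free cell variables.

    Angle components are per degree.  Length = ``system.free_parameter_count``.
    """
    if form not in OBJECTIVE_FORMS:
        raise ValueError(f"form must be one of {OBJECTIVE_FORMS}, got {form!r}")
    system = get_system(system)
    cell = cell if cell is not None else structure.cell
    dx, targets, sigmas = _arrays(structure)
    G = cell.metric_tensor()
    d2 = np.einsum("ki,ij,kj->k", dx, G, dx)
    if form == "squared":
        # ∂/∂τ Σ (1/σ²)(d²−Δ²)² = Σ (2/σ²)(d²−Δ²)·(Δxᵀ ∂G/∂τ Δx)
        prefac = 2.0 * (d2 - targets**2) / sigmas**2
    else:
        # ∂/∂τ Σ (1/σ²)(d−Δ)² = Σ (1/σ²)(d−Δ)/d·(Δxᵀ ∂G/∂τ Δx)
        d = np.sqrt(np.maximum(d2, 0.0))
        safe = np.where(d > 0.0, d, 1.0)
        prefac = (d - targets) / (sigmas**2 * safe)
        prefac = np.where(d > 0.0, prefac, 0.0)
    dG = metric_tensor_derivatives(cell)
    full = np.array(
        [
            float(np.sum(prefac * np.einsum("ki,ij,kj->k", dx, dG[p], dx)))
            for p in PARAM_NAMES
        ]
    )
    return system.reduce_gradient(full)


def deviation_report(
    structure: Structure, cell: UnitCell | None = None, form: str = "squared"
) -> pd.DataFrame:
    """Per-restraint deviation table (signed deviations in Å).

    Columns: restraint id, atom labels, kind, target Δ, sigma σ, current
    distance d, deviation d − Δ, and the weighted contribution to the total.
    """
    obj = residual(structure, cell, form=form)

    def label(key):
        resid, name = key
        return name if resid is None else f"{name}_{resid}"

    rows = []
    for k, r in enumerate(structure.restraints):
        rows.append(
            {
                "id": k,
                "atom1": label(r.ref_i),
                "atom2": label(r.ref_j),
                "kind": r.kind,
                "target": r.target,
                "sigma": r.sigma,
                "distance": float(obj.distances[k]),
                "deviation": float(obj.deviations[k]),
                "contribution": float(obj.contributions[k]),
            }
        )
    return pd.DataFrame(rows)
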