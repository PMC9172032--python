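"""Cell-optimization drivers and the iterative cell/coordinate alternation.

Two drivers minimize the restraint residual over a crystal system's free cell
parameters, holding fractional coordinates fixed:

* :class:`BFGSCellOptimizer` — quasi-Newton (BFGS) descent with the analytic
  metric-tensor gradient; finds a local minimum of the squared objective.
* :class:`HillClimbCellOptimizer` — multi-level hill climbing: each round
  proposes ±step on every free parameter, scores proposals by the weighted
  mean absolute restraint deviation, keeps only the single best improving
  modification, halves the step after an improvement-free round, and aborts
  after ten consecutive improvement-free rounds.

:class:`IterativeCellRefiner` alternates cell optimization with a coordinate
refinement step.  The coordinate step is pluggable: an external refinement
program invoked via a command template on RES files (the production setup,
where a data-driven refiner supplies coordinates), the built-in
restraints-only :func:`regularize_coordinates`, or nothing (single-shot cell
optimization).  Alternation stops when the cell change drops below tolerance
or after 25 iterations.

All estimators follow scikit-learn conventions: parameters are set in
``__init__``, ``fit(structure)`` computes, fitted results live in
trailing-underscore attributes (``cell_``, ``trace_``, ``converged_``).
There is no randomness anywhere in the drivers.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.base import BaseEstimator, clone

from .lattice import (
    CellConstraintError,
    CellValidationError,
    CrystalSystem,
    UnitCell,
    get_system,
)
from .restraints import NothingToOptimizeError, gradient, residual
from .shelx import Structure, parse_res, write_res

__all__ = [
    "IterationRecord",
    "OptimizationTrace",
    "BFGSCellOptimizer",
    "HillClimbCellOptimizer",
    "IterativeCellRefiner",
    "ExternalRefiner",
    "RefinerError",
    "regularize_coordinates",
    "optimize_cell_bfgs",
    "optimize_cell_hillclimb",
    "iterate",
]

# termination reasons
GRADIENT_TOLERANCE = "gradient_tolerance"
STEP_EXHAUSTED = "step_exhausted"
MAX_ITERATIONS = "max_iterations"
NO_IMPROVEMENT = "no_improvement"
CELL_TOLERANCE = "cell_tolerance"  # iterate: cell change below tolerance
REFINER_ERROR = "refiner_error"


@dataclass
class IterationRecord:
    index: int
    cell: UnitCell
    objective: float
    weighted_mean_abs_dev: float
    meta: dict = field(default_factory=dict)
    refiner_score: Optional[float] = None


@dataclass
class OptimizationTrace:
    """Per-iteration record of an optimization run (the data behind
    convergence plots: cell parameters, objective, step metadata)."""

    iterations: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    termination_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.iterations:
            a, b, c, al, be, ga = rec.cell.as_tuple()
            rows.append(
                {
                    "iteration": rec.index,
                    "a": a,
                    "b": b,
                    "c": c,
                    "alpha": al,
                    "beta": be,
                    "gamma": ga,
                    "objective": rec.objective,
                    "mean_abs_dev": rec.weighted_mean_abs_dev,
                    "refiner_score": rec.refiner_score,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def final_cell(self) -> UnitCell:
        return self.iterations[-1].cell


def _record(structure: Structure, cell: UnitCell, index: int, form: str,
            **meta) -> IterationRecord:
    obj = residual(structure, cell, form=form)
    return IterationRecord(
        index=index,
        cell=cell,
        objective=obj.total,
        weighted_mean_abs_dev=obj.weighted_mean_abs_dev,
        meta=meta,
    )


class BFGSCellOptimizer(BaseEstimator):
    """Gradient-based (BFGS) minimization of the restraint residual.

    Parameters
    ----------
    system:
        Crystal system name or :class:`CrystalSystem`; determines the free
        variables and the constraints kept exact throughout.
    form:
        Objective form, ``"squared"`` (default) or ``"least_squares"``.
    step:
        Initial step scale (the default 0.01 is safe across the use cases
        this tool targets); realized as the initial inverse-Hessian scale.
    grad_tol:
        Termination threshold on the gradient infinity norm.
    max_iter:
        Iteration cap for the underlying quasi-Newton loop.

    Attributes (after ``fit``)
    --------------------------
    cell_ : UnitCell — best conforming cell found.
    trace_ : OptimizationTrace — accepted iterates.
    converged_ : bool, termination_reason_ : str, n_iter_ : int.
    """

    def __init__(self, system="triclinic", form="squared", step=0.01,
                 grad_tol=1e-6, max_iter=500):
        self.system = system
        self.form = form
        self.step = step
        self.grad_tol = grad_tol
        self.max_iter = max_iter

    def fit(self, structure: Structure, y=None):
        system = get_system(self.system)
        system.check(structure.cell)  # non-conforming start is an error
        residual(structure, form=self.form)  # raises if no restraints
        x0 = system.free_vector(structure.cell)
        n = len(x0)

        best = {"f": np.inf, "x": x0.copy()}

        def fun(x):
            try:
                cell = system.to_cell(x)
            except CellValidationError:
                return 1e30, np.zeros(n)
            f = residual(structure, cell, form=self.form).total
            if f < best["f"]:
                best["f"], best["x"] = f, np.array(x, dtype=float)
            g = gradient(structure, cell, system, form=self.form)
            return f, g

        trace = OptimizationTrace()
        trace.iterations.append(
            _record(structure, structure.cell, 0, self.form, driver="bfgs")
        )

        def callback(xk):
            try:
                cell = system.to_cell(xk)
            except CellValidationError:
                return
            trace.iterations.append(
                _record(structure, cell, len(trace.iterations), self.form,
                        driver="bfgs")
            )

        res = scipy.optimize.minimize(
            fun,
            x0,
            jac=True,
            method="BFGS",
            callback=callback,
            options={
                "gtol": self.grad_tol,
                "maxiter": self.max_iter,
                "hess_inv0": self.step * np.eye(n),
            },
        )
        x_final = res.x if np.isfinite(res.fun) and res.fun <= best["f"] else best["x"]
        cell = system.to_cell(x_final)
        if not trace.iterations or trace.iterations[-1].cell != cell:
            trace.iterations.append(
                _record(structure, cell, len(trace.iterations), self.form,
                        driver="bfgs")
            )
        g_norm = float(np.max(np.abs(
            gradient(structure, cell, system, form=self.form))))
        if g_norm <= self.grad_tol:
            converged, reason = True, GRADIENT_TOLERANCE
        elif res.status == 1:
            converged, reason = False, MAX_ITERATIONS
        else:
            converged, reason = False, STEP_EXHAUSTED
        trace.converged = converged
        trace.termination_reason = reason
        self.cell_ = cell
        self.trace_ = trace
        self.converged_ = converged
        self.termination_reason_ = reason
        self.n_iter_ = int(res.nit)
        return self

    def fit_optimize(self, structure: Structure) -> tuple[UnitCell, OptimizationTrace]:
        self.fit(structure)
        return self.cell_, self.trace_


class HillClimbCellOptimizer(BaseEstimator):
    """Multi-level hill climbing over the free cell parameters.

    Each round tests ±step on every free parameter (0.1 Å / 0.1° initially)
    and keeps only the modification with the largest improvement of the
    fitting criterion; an improvement-free round halves the step; the search
    aborts after ``abort_cycles`` consecutive improvement-free rounds (a
    halving counts as such a round; any accepted modification resets the
    counter).  Ties break on fixed parameter order a, b, c, α, β, γ with "+"
    before "−".

    ``criterion="mean_abs_dev"`` (default) scores proposals by the weighted
    mean absolute restraint deviation; ``criterion="objective"`` uses the
    squared objective so the driver can be compared head-to-head with BFGS.
    """

    def __init__(self, system="triclinic", initial_step=0.1, abort_cycles=10,
                 criterion="mean_abs_dev", form="squared", max_rounds=100000):
        self.system = system
        self.initial_step = initial_step
        self.abort_cycles = abort_cycles
        self.criterion = criterion
        self.form = form
        self.max_rounds = max_rounds

    def _score(self, structure, cell):
        obj = residual(structure, cell, form=self.form)
        if self.criterion == "mean_abs_dev":
            return obj.weighted_mean_abs_dev
        if self.criterion == "objective":
            return obj.total
        raise ValueError(
            f"criterion must be 'mean_abs_dev' or 'objective', "
            f"got {self.criterion!r}"
        )

    def fit(self, structure: Structure, y=None):
        system = get_system(self.system)
        system.check(structure.cell)
        residual(structure, form=self.form)
        x = system.free_vector(structure.cell)
        step = float(self.initial_step)
        score = self._score(structure, structure.cell)

        trace = OptimizationTrace()
        trace.iterations.append(
            _record(structure, structure.cell, 0, self.form,
                    driver="hillclimb", step=step, accepted=None)
        )
        no_improve = 0
        rounds = 0
        reason = NO_IMPROVEMENT
        while no_improve < self.abort_cycles:
            rounds += 1
            if rounds > self.max_rounds:
                reason = MAX_ITERATIONS
                break
            best_score = score
            best_move = None
            for i in range(len(x)):
                for sign in (+1.0, -1.0):
                    cand = x.copy()
                    cand[i] += sign * step
                    try:
                        cell = system.to_cell(cand)
                    except CellValidationError:
                        continue
                    s = self._score(structure, cell)
                    if s < best_score:  # strict: ties are not improvements
                        best_score = s
                        best_move = (i, sign, cand)
            if best_move is None:
                step *= 0.5
                no_improve += 1
                continue
            i, sign, x = best_move
            score = best_score
            no_improve = 0
            cell = system.to_cell(x)
            trace.iterations.append(
                _record(structure, cell, len(trace.iterations), self.form,
                        driver="hillclimb",
                        parameter=system.free_names[i],
                        sign=int(sign), step=step,
                        accepted=True)
            )
        trace.converged = reason == NO_IMPROVEMENT
        trace.termination_reason = reason
        self.cell_ = system.to_cell(x)
        self.trace_ = trace
        self.converged_ = trace.converged
        self.termination_reason_ = reason
        self.n_iter_ = rounds
        return self

    def fit_optimize(self, structure: Structure) -> tuple[UnitCell, OptimizationTrace]:
        self.fit(structure)
        return self.cell_, self.trace_


# ---------------------------------------------------------------------------
# coordinate regularization (restraints-only stand-in for a data-driven
# refinement step)


def regularize_coordinates(
    structure: Structure,
    cell: Optional[UnitCell] = None,
    form: str = "squared",
    gtol: float = 1e-12,
    max_iter: int = 1000,
) -> Structure:
    """Minimize the restraint residual over fractional coordinates, cell fixed.

    Only atoms that appear in at least one restraint move, and within those
    only coordinate components not flagged as fixed.  The net translation of
    the restrained atoms is removed afterwards (their centroid is preserved)
    to fix the translational gauge, unless fixed components already pin it.

    This reproduces the *mechanism* of an alternating cell/coordinate
    refinement; it is not a stand-in for refinement against diffraction data,
    which additionally anchors coordinates to observed intensities.
    """
    cell = cell if cell is not None else structure.cell
    obj0 = residual(structure, cell, form=form)  # validates restraints exist
    pairs = np.array([(r.i, r.j) for r in structure.restraints], dtype=int)
    targets = np.array([r.target for r in structure.restraints])
    sigmas = np.array([r.sigma for r in structure.restraints])
    G = cell.metric_tensor()

    restrained = sorted(set(pairs[:, 0]) | set(pairs[:, 1]))
    # free variable map: (atom index, component) per scalar variable
    varmap = [
        (ai, k)
        for ai in restrained
        for k in range(3)
        if not structure.atoms[ai].fixed[k]
    ]
    if not varmap:
        return structure

    frac0 = np.array([a.frac for a in structure.atoms], dtype=float)

    def unpack(v):
        frac = frac0.copy()
        for val, (ai, k) in zip(v, varmap):
            frac[ai, k] = val
        return frac

    def fun(v):
        frac = unpack(v)
        dx = frac[pairs[:, 0]] - frac[pairs[:, 1]]
        d2 = np.einsum("ki,ij,kj->k", dx, G, dx)
        gdx = dx @ G  # (n,3): G Δx per restraint
        if form == "squared":
            f = float(np.sum((d2 - targets**2) ** 2 / sigmas**2))
            pref = 2.0 * (d2 - targets**2) / sigmas**2  # d f / d (d²)
        else:
            d = np.sqrt(np.maximum(d2, 0.0))
            f = float(np.sum((d - targets) ** 2 / sigmas**2))
            safe = np.where(d > 0.0, d, 1.0)
            pref = np.where(d > 0.0, (d - targets) / (sigmas**2 * safe), 0.0)
        grad_atoms = np.zeros_like(frac0)
        np.add.at(grad_atoms, pairs[:, 0], (2.0 * pref)[:, None] * gdx)
        np.add.at(grad_atoms, pairs[:, 1], -(2.0 * pref)[:, None] * gdx)
        g = np.array([grad_atoms[ai, k] for ai, k in varmap])
        return f, g

    v0 = np.array([frac0[ai, k] for ai, k in varmap])
    res = scipy.optimize.minimize(
        fun,
        v0,
        jac=True,
        method="L-BFGS-B",
        options={"gtol": gtol, "ftol": 1e-16, "maxiter": max_iter},
    )
    frac = unpack(res.x)

    any_fixed = any(
        structure.atoms[ai].fixed[k] for ai in restrained for k in range(3)
    )
    if not any_fixed:
        shift = frac0[restrained].mean(axis=0) - frac[restrained].mean(axis=0)
        frac[restrained] += shift

    new_atoms = list(structure.atoms)
    moved = False
    for ai in restrained:
        if not np.array_equal(frac[ai], frac0[ai]):
            new_atoms[ai] = structure.atoms[ai].moved(frac[ai])
            moved = True
    if not moved:
        return structure
    out = structure.with_atoms(new_atoms)
    # only accept the move if it did not worsen the residual (it cannot, but
    # guard against pathological line-search exits)
    if residual(out, cell, form=form).total > obj0.total:
        return structure
    return out


# ---------------------------------------------------------------------------
# refiner hooks


class RefinerError(RuntimeError):
    """An external coordinate-refinement step failed."""


class ExternalRefiner:
    """Invoke an external refinement program through a command template.

    The template must contain ``{input}`` and ``{output}`` placeholders for
    the RES file paths, e.g. ``"myrefine {input} {output}"``.  A nonzero exit
    status or a missing/unparseable output file raises :class:`RefinerError`.
    The parsed output structure is returned; if the program writes a line
    ``REM SCORE <value>`` the value is reported as the refiner score (used by
    the combined mode).
    """

    def __init__(self, command_template: str, workdir: Optional[str] = None):
        if "{input}" not in command_template or "{output}" not in command_template:
            raise ValueError(
                "command template must contain {input} and {output} placeholders"
            )
        self.command_template = command_template
        self.workdir = workdir

    def __call__(self, structure: Structure) -> tuple[Structure, Optional[float]]:
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            in_path = os.path.join(tmp, "in.res")
            out_path = os.path.join(tmp, "out.res")
            with open(in_path, "w") as fh:
                fh.write(write_res(structure, comment=False))
            cmd = self.command_template.format(input=in_path, output=out_path)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RefinerError(
                    f"refiner exited with status {proc.returncode}: "
                    f"{proc.stderr.strip()[:500]}"
                )
            if not os.path.exists(out_path):
                raise RefinerError(f"refiner produced no output file {out_path}")
            with open(out_path) as fh:
                text = fh.read()
            try:
                refined = parse_res(text)
            except Exception as exc:
                raise RefinerError(f"refiner output unparseable: {exc}") from exc
            score = None
            for line in text.splitlines():
                tokens = line.split()
                if len(tokens) >= 3 and tokens[0].upper() == "REM" \
                        and tokens[1].upper() == "SCORE":
                    try:
                        score = float(tokens[2])
                    except ValueError:
                        pass
            return refined, score


def _as_refiner(refiner) -> Optional[Callable]:
    if refiner is None:
        return None
    if refiner == "internal":
        return lambda s: (regularize_coordinates(s), None)
    if isinstance(refiner, str):
        return ExternalRefiner(refiner)
    if callable(refiner):
        return refiner
    raise ValueError(f"unusable refiner hook {refiner!r}")


class IterativeCellRefiner(BaseEstimator):
    """Alternate cell optimization with a coordinate refinement step.

    Parameters
    ----------
    system, form:
        As for the drivers.
    driver:
        ``"bfgs"``, ``"hillclimb"``, or a driver estimator instance (cloned
        per iteration).
    refiner:
        ``None`` (single-shot cell optimization), ``"internal"`` (built-in
        restraints-only coordinate regularizer), a command-template string
        for an external program (see :class:`ExternalRefiner`), or a callable
        ``structure -> structure`` / ``structure -> (structure, score)``.
    max_iter:
        Hard cap on alternations (default 25).
    length_tol, angle_tol:
        Convergence thresholds on the cell change between successive
        iterations (Å and degrees).
    keep_dir:
        If set, the RES file after each iteration is written there.

    Attributes (after ``fit``)
    --------------------------
    cell_, structure_ (final model), trace_, converged_, termination_reason_,
    n_iter_.
    """

    def __init__(self, system="triclinic", driver="bfgs", refiner=None,
                 form="squared", max_iter=25, length_tol=1e-4,
                 angle_tol=1e-3, keep_dir=None):
        self.system = system
        self.driver = driver
        self.refiner = refiner
        self.form = form
        self.max_iter = max_iter
        self.length_tol = length_tol
        self.angle_tol = angle_tol
        self.keep_dir = keep_dir

    def _make_driver(self):
        if isinstance(self.driver, str):
            if self.driver == "bfgs":
                return BFGSCellOptimizer(system=self.system, form=self.form)
            if self.driver == "hillclimb":
                return HillClimbCellOptimizer(system=self.system, form=self.form)
            raise ValueError(f"unknown driver {self.driver!r}")
        return clone(self.driver).set_params(system=self.system)

    def fit(self, structure: Structure, y=None):
        system = get_system(self.system)
        system.check(structure.cell)
        refiner = _as_refiner(self.refiner)
        current = structure
        trace = OptimizationTrace()
        converged = False
        reason = MAX_ITERATIONS
        n_done = 0
        for it in range(1, int(self.max_iter) + 1):
            prev_cell = current.cell
            drv = self._make_driver().fit(current)
            obj_before = residual(current, prev_cell, form=self.form).total
            rec = _record(
                current, drv.cell_, it, self.form,
                objective_before_cell_step=obj_before,
                driver_termination=drv.termination_reason_,
            )
            current = current.with_cell(drv.cell_)
            n_done = it
            if refiner is not None:
                try:
                    out = refiner(current)
                except RefinerError as exc:
                    warnings.warn(f"refiner failed at iteration {it}: {exc}")
                    trace.iterations.append(rec)
                    reason = REFINER_ERROR
                    break
                if isinstance(out, tuple):
                    current, rec.refiner_score = out
                else:
                    current = out
            trace.iterations.append(rec)
            if self.keep_dir is not None:
                path = os.path.join(self.keep_dir, f"iter_{it:02d}.res")
                with open(path, "w") as fh:
                    fh.write(write_res(current, comment=False))
            if refiner is None:
                converged = drv.converged_
                reason = drv.termination_reason_
                break
            da = np.abs(
                np.array(drv.cell_.as_tuple()[:3]) - np.array(prev_cell.as_tuple()[:3])
            )
            dang = np.abs(
                np.array(drv.cell_.as_tuple()[3:]) - np.array(prev_cell.as_tuple()[3:])
            )
            if da.max() < self.length_tol and dang.max() < self.angle_tol:
                converged = True
                reason = CELL_TOLERANCE
                break
        trace.converged = converged
        trace.termination_reason = reason
        self.cell_ = current.cell
        self.structure_ = current
        self.trace_ = trace
        self.converged_ = converged
        self.termination_reason_ = reason
        self.n_iter_ = n_done
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers


def optimize_cell_bfgs(structure: Structure, system="triclinic", step=0.01,
                       grad_tol=1e-6, form="squared",
                       max_iter=500) -> tuple[UnitCell, OptimizationTrace]:
    est = BFGSCellOptimizer(system=system, step=step, grad_tol=grad_tol,
                            form=form, max_iter=max_iter).fit(structure)
    return est.cell_, est.trace_


def optimize_cell_hillclimb(structure: Structure, system="triclinic",
                            initial_step=0.1, abort_cycles=10,
                            criterion="mean_abs_dev", form="squared",
                            ) -> tuple[UnitCell, OptimizationTrace]:
    est = HillClimbCellOptimizer(
        system=system, initial_step=initial_step, abort_cycles=abort_cycles,
        criterion=criterion, form=form).fit(structure)
    return est.cell_, est.trace_


def iterate(structure: Structure, system="triclinic", driver="bfgs",
            refiner_hook=None, max_iter=25, **kwargs) -> OptimizationTrace:
    est = IterativeCellRefiner(system=system, driver=driver,
                               refiner=refiner_hook, max_iter=max_iter,
                               **kwargs).fit(structure)
    return est.trace_
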