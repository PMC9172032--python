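import os
import sys

import numpy as np
import pytest

from latticefit import (
    BFGSCellOptimizer,
    CellConstraintError,
    FixtureSpec,
    HillClimbCellOptimizer,
    IterativeCellRefiner,
    UnitCell,
    generate_fixture,
    get_system,
    optimize_cell_bfgs,
    optimize_cell_hillclimb,
    parse_res,
    regularize_coordinates,
    residual,
)

from conftest import ALL_SYSTEMS, TRUE_CELLS, single_restraint_res


def perturbed_fixture(system, amp=0.05, **kwargs):
    spec = FixtureSpec(
        system=system,
        true_cell=TRUE_CELLS[system],
        molecule="tetrahedral",
        cell_perturbation=amp,
        **kwargs,
    )
    return generate_fixture(spec)


class TestBFGS:
    def test_cubic_closed_form_from_any_positive_start(self):
        for start in (1.0, 5.0, 14.0, 50.0, 200.0):
            s = parse_res(single_restraint_res(start, t=0.1, target=1.54))
            cell, trace = optimize_cell_bfgs(s, "cubic")
            assert cell.a == pytest.approx(15.4, abs=1e-8)
            assert trace.converged

    def test_fixed_point_at_true_cell(self):
        s, true_cell, _ = perturbed_fixture("orthorhombic", amp=0.0)
        cell, trace = optimize_cell_bfgs(s, "orthorhombic")
        assert cell.as_tuple() == true_cell.as_tuple()
        assert trace.termination_reason == "gradient_tolerance"

    def test_orthorhombic_recovery(self):
        s, true_cell, _ = perturbed_fixture("orthorhombic", amp=0.05)
        cell, _ = optimize_cell_bfgs(s, "orthorhombic")
        for got, want in zip(cell.as_tuple()[:3], true_cell.as_tuple()[:3]):
            assert got == pytest.approx(want, abs=1e-3)

    def test_trace_objective_never_increases_overall(self):
        s, _, _ = perturbed_fixture("triclinic", amp=0.04)
        _, trace = optimize_cell_bfgs(s, "triclinic")
        assert trace.iterations[-1].objective <= trace.iterations[0].objective

    def test_nonconforming_start_rejected(self):
        s = parse_res(single_restraint_res(14.0))
        bad = s.with_cell(UnitCell(14.0, 14.0, 14.1))
        with pytest.raises(CellConstraintError):
            BFGSCellOptimizer(system="cubic").fit(bad)

    def test_sklearn_params_roundtrip(self):
        est = BFGSCellOptimizer(system="cubic", grad_tol=1e-8)
        assert est.get_params()["grad_tol"] == 1e-8
        est.set_params(grad_tol=1e-7)
        assert est.grad_tol == 1e-7


class TestHillClimb:
    def test_hand_simulated_step_schedule(self):
        # one free parameter offset −0.35 from its optimum, initial step 0.1:
        # three accepted +0.1 moves, then a halving closes the last 0.05
        s = parse_res(single_restraint_res(15.05, t=0.1, target=1.54))
        cell, trace = optimize_cell_hillclimb(s, "cubic")
        accepted = [
            (r.meta["sign"], r.meta["step"]) for r in trace.iterations[1:]
        ]
        assert accepted == [(1, 0.1), (1, 0.1), (1, 0.1), (1, 0.05)]
        assert cell.a == pytest.approx(15.4, abs=1e-10)
        assert trace.termination_reason == "no_improvement"

    def test_start_at_optimum_accepts_nothing(self):
        s = parse_res(single_restraint_res(15.4, t=0.1, target=1.54))
        est = HillClimbCellOptimizer(system="cubic").fit(s)
        assert len(est.trace_.iterations) == 1  # only the starting record
        assert est.cell_.a == 15.4
        assert est.n_iter_ == est.abort_cycles  # pure halving rounds

    def test_largest_improvement_wins_the_round(self):
        # two restraints: moving a by −0.1 gains more than moving b by −0.1
        text = (
            "CELL 0.0251 10.3 20.1 30.0 90 90 90\nSFAC C\n"
            "DFIX 1.5 A1 A2\nDFIX 1.5 A1 A3\n"
            "A1 1 0 0 0\nA2 1 0.15 0 0\nA3 1 0 0.075 0\nEND\n"
        )
        s = parse_res(text)
        est = HillClimbCellOptimizer(system="orthorhombic").fit(s)
        first = est.trace_.iterations[1].meta
        assert (first["parameter"], first["sign"]) == ("a", -1)

    def test_accepted_scores_strictly_decrease(self):
        s, _, _ = perturbed_fixture("orthorhombic", amp=0.04)
        _, trace = optimize_cell_hillclimb(s, "orthorhombic")
        devs = [r.weighted_mean_abs_dev for r in trace.iterations]
        assert all(b < a for a, b in zip(devs, devs[1:]))

    def test_agrees_with_bfgs_on_well_conditioned_fixture(self):
        s, _, _ = perturbed_fixture("orthorhombic", amp=0.03)
        bcell, _ = optimize_cell_bfgs(s, "orthorhombic")
        # common criterion so both drivers minimize the same function
        hcell, _ = optimize_cell_hillclimb(s, "orthorhombic", criterion="objective")
        for bv, hv in zip(bcell.as_tuple()[:3], hcell.as_tuple()[:3]):
            assert hv == pytest.approx(bv, abs=5e-3)
        for bv, hv in zip(bcell.as_tuple()[3:], hcell.as_tuple()[3:]):
            assert hv == pytest.approx(bv, abs=5e-2)


class TestConstraintPreservation:
    @pytest.mark.parametrize("driver", ["bfgs", "hillclimb"])
    @pytest.mark.parametrize(
        "system", [s for s in ALL_SYSTEMS if s != "triclinic"]
    )
    def test_fixed_angles_and_ties_exact_after_optimization(self, system, driver):
        s, _, _ = perturbed_fixture(system, amp=0.04)
        if driver == "bfgs":
            cell, _ = optimize_cell_bfgs(s, system)
        else:
            cell, _ = optimize_cell_hillclimb(s, system)
        sys_obj = get_system(system)
        for p, v in sys_obj.fixed:
            assert getattr(cell, p) == v  # bitwise
        for group in sys_obj.groups:
            values = {getattr(cell, p) for p in group}
            assert len(values) == 1  # tied lengths exactly equal

    def test_p1_relaxation_recovers_right_angles(self):
        # a true orthorhombic fixture optimized with all six parameters free
        spec = FixtureSpec(
            system="triclinic",
            true_cell=TRUE_CELLS["orthorhombic"],
            molecule="tetrahedral",
            cell_perturbation=[0.05, -0.04, 0.05, 0.01, -0.01, 0.02],
        )
        s, true_cell, _ = generate_fixture(spec)
        cell, _ = optimize_cell_bfgs(s, "triclinic")
        for angle in cell.as_tuple()[3:]:
            assert angle == pytest.approx(90.0, abs=0.05)
        for got, want in zip(cell.as_tuple()[:3], true_cell.as_tuple()[:3]):
            assert got == pytest.approx(want, abs=1e-3)


class TestDegeneracy:
    def test_planar_molecule_leaves_c_at_start(self):
        # hexagon in the a–b plane: no restraint spans c, so c is invisible
        spec = FixtureSpec(
            system="orthorhombic",
            true_cell=TRUE_CELLS["orthorhombic"],
            molecule="hexagon_planar",
            cell_perturbation=0.05,
        )
        s, true_cell, manifest = generate_fixture(spec)
        assert manifest["observable"] == {"a": True, "b": True, "c": False}
        start_c = s.cell.c
        cell, _ = optimize_cell_bfgs(s, "orthorhombic")
        assert cell.a == pytest.approx(true_cell.a, abs=1e-3)
        assert cell.b == pytest.approx(true_cell.b, abs=1e-3)
        assert cell.c == pytest.approx(start_c, abs=1e-8)


class TestRegularizeCoordinates:
    def test_satisfied_structure_unchanged(self):
        s, true_cell, _ = perturbed_fixture("orthorhombic", amp=0.0)
        out = regularize_coordinates(s, true_cell)
        assert out is s

    def test_displaced_atom_recovered_when_others_fixed(self):
        spec = FixtureSpec(
            system="orthorhombic", true_cell=TRUE_CELLS["orthorhombic"],
            molecule="tetrahedral",
        )
        s, true_cell, _ = generate_fixture(spec)
        atoms = list(s.atoms)
        # pin every atom except the first, displace the first by 0.05 Å along a
        for i in range(1, len(atoms)):
            atoms[i] = atoms[i].__class__(**{**atoms[i].__dict__,
                                             "fixed": (True, True, True)})
        original = atoms[0].frac.copy()
        atoms[0] = atoms[0].moved(original + np.array([0.05 / true_cell.a, 0, 0]))
        displaced = s.with_atoms(atoms)
        out = regularize_coordinates(displaced, true_cell)
        residual_shift = true_cell.distance(out.atoms[0].frac, original)
        assert residual_shift < 1e-4

    def test_geometry_restored_for_free_molecule(self):
        s, true_cell, _ = perturbed_fixture("orthorhombic", amp=0.0)
        atoms = list(s.atoms)
        atoms[0] = atoms[0].moved(atoms[0].frac + np.array([0.004, -0.002, 0.003]))
        out = regularize_coordinates(s.with_atoms(atoms), true_cell)
        obj = residual(out, true_cell)
        assert np.max(np.abs(obj.deviations)) < 1e-6

    def test_unrestrained_atom_untouched(self):
        text = (
            "CELL 0.0251 10 10 10 90 90 90\nSFAC C O\n"
            "DFIX 1.5 C1 C2\n"
            "C1 1 0 0 0\nC2 1 0.16 0 0\nO1 2 0.7 0.7 0.7\nEND\n"
        )
        s = parse_res(text)
        out = regularize_coordinates(s)
        assert out.atoms[2] is s.atoms[2]  # bit-identical passthrough


class TestIterate:
    def test_absent_refiner_equals_single_driver_run(self):
        s, _, _ = perturbed_fixture("orthorhombic", amp=0.05)
        single, _ = optimize_cell_bfgs(s, "orthorhombic")
        est = IterativeCellRefiner(system="orthorhombic", refiner=None).fit(s)
        assert est.n_iter_ == 1
        assert est.cell_.as_tuple() == single.as_tuple()

    def test_internal_regularizer_joint_recovery(self):
        s, true_cell, _ = perturbed_fixture(
            "orthorhombic", amp=0.05, coordinate_noise_sd=0.02, seed=7
        )
        est = IterativeCellRefiner(system="orthorhombic", refiner="internal").fit(s)
        assert est.converged_
        assert est.n_iter_ < 25
        for got, want in zip(est.cell_.as_tuple()[:3], true_cell.as_tuple()[:3]):
            assert got == pytest.approx(want, abs=1e-3)

    def test_adversarial_hook_hits_iteration_cap(self):
        s, _, _ = perturbed_fixture("orthorhombic", amp=0.05)
        rng = np.random.default_rng(0)

        def jitter(structure):
            atoms = [
                a.moved(a.frac + rng.normal(0, 2e-3, 3)) for a in structure.atoms
            ]
            return structure.with_atoms(atoms)

        est = IterativeCellRefiner(
            system="orthorhombic", refiner=jitter, length_tol=1e-12
        ).fit(s)
        assert est.n_iter_ == 25
        assert est.termination_reason_ == "max_iterations"
        # each cell half-step never increases the objective at fixed coords
        for rec in est.trace_.iterations:
            assert rec.objective <= rec.meta["objective_before_cell_step"] + 1e-12

    def test_external_refiner_roundtrip(self, tmp_path):
        # external hook: copies input to output (an identity "refiner")
        script = tmp_path / "refine.py"
        script.write_text(
            "import shutil, sys\n"
            "shutil.copy(sys.argv[1], sys.argv[2])\n"
            "open(sys.argv[2], 'a').write('REM SCORE 0.25\\n')\n"
        )
        s, true_cell, _ = perturbed_fixture("orthorhombic", amp=0.05)
        est = IterativeCellRefiner(
            system="orthorhombic",
            refiner=f"{sys.executable} {script} {{input}} {{output}}",
        ).fit(s)
        assert est.converged_
        assert est.trace_.iterations[0].refiner_score == 0.25
        for got, want in zip(est.cell_.as_tuple()[:3], true_cell.as_tuple()[:3]):
            assert got == pytest.approx(want, abs=1e-3)

    def test_failing_external_refiner_reported_not_swallowed(self):
        s, _, _ = perturbed_fixture("orthorhombic", amp=0.05)
        est = IterativeCellRefiner(
            system="orthorhombic",
            refiner=f"{sys.executable} -c 'raise SystemExit(3)' {{input}} {{output}}",
        )
        with pytest.warns(UserWarning, match="refiner failed"):
            est.fit(s)
        assert est.termination_reason_ == "refiner_error"
        assert not est.converged_
        assert len(est.trace_.iterations) == 1  # partial trace retained

    def test_kept_res_files_written(self, tmp_path):
        s, _, _ = perturbed_fixture("orthorhombic", amp=0.05)
        IterativeCellRefiner(
            system="orthorhombic", refiner="internal", keep_dir=str(tmp_path)
        ).fit(s)
        assert (tmp_path / "iter_01.res").exists()

    def test_trace_csv_columns(self, tmp_path):
        s, _, _ = perturbed_fixture("orthorhombic", amp=0.05)
        est = IterativeCellRefiner(system="orthorhombic", refiner="internal").fit(s)
        path = tmp_path / "trace.csv"
        est.trace_.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == [
            "iteration", "a", "b", "c", "alpha", "beta", "gamma",
            "objective", "mean_abs_dev", "refiner_score",
        ]
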