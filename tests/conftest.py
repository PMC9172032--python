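import numpy as np
import pytest

from latticefit import FixtureSpec, UnitCell, generate_fixture, get_system

#: a realistic triclinic cell used throughout (a previously published
#: electron-diffraction MOF model's original cell)
VIE1_CELL = UnitCell(12.136, 13.173, 33.346, 83.130, 84.435, 77.633)

#: orthorhombic cell of a published pharmaceutical electron-diffraction model
OSELTAMIVIR_CELL = UnitCell(23.380, 23.660, 7.250, 90.0, 90.0, 90.0)

#: one conforming true cell per crystal system
TRUE_CELLS = {
    "triclinic": UnitCell(9.0, 11.0, 13.0, 80.0, 95.0, 105.0),
    "monoclinic": UnitCell(9.0, 11.0, 13.0, 90.0, 100.0, 90.0),
    "orthorhombic": UnitCell(10.0, 20.0, 30.0),
    "hexagonal": UnitCell(10.0, 10.0, 14.0, 90.0, 90.0, 120.0),
    "tetragonal": UnitCell(10.0, 10.0, 14.0),
    "cubic": UnitCell(12.0, 12.0, 12.0),
}

ALL_SYSTEMS = tuple(TRUE_CELLS)


def single_restraint_res(a0: float, t: float = 0.1, target: float = 1.54,
                         sigma: float | None = None) -> str:
    """Cubic cell with one bond restraint between (0,0,0) and (t,0,0):
    the objective has the closed-form minimizer a = target / t."""
    sig = f" {sigma}" if sigma is not None else ""
    return (
        "TITL single restraint\n"
        f"CELL 0.02510 {a0} {a0} {a0} 90 90 90\n"
        "SFAC C\n"
        f"DFIX {target}{sig} C1 C2\n"
        "C1 1 0 0 0\n"
        f"C2 1 {t} 0 0\n"
        "END\n"
    )


def random_cell(system_name: str, rng: np.random.Generator) -> UnitCell:
    """A random cell conforming to the given crystal system."""
    system = get_system(system_name)
    while True:
        free = []
        for group in system.groups:
            if group[0] in ("a", "b", "c"):
                free.append(rng.uniform(6.0, 25.0))
            else:
                free.append(rng.uniform(75.0, 110.0))
        try:
            return system.to_cell(free)
        except Exception:
            continue  # rare invalid triclinic angle combination; redraw


def random_fixture(system_name: str, rng: np.random.Generator,
                   perturbation_scale: float = 0.05):
    """A tetrahedral-molecule fixture with a random conforming true cell and
    random signed perturbations on the free parameters."""
    system = get_system(system_name)
    cell = random_cell(system_name, rng)
    amp = rng.uniform(-perturbation_scale, perturbation_scale,
                      size=system.free_parameter_count)
    spec = FixtureSpec(
        system=system_name,
        true_cell=cell,
        molecule="tetrahedral",
        cell_perturbation=amp,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return generate_fixture(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
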