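# latticefit

Restraint-based optimization of crystallographic unit-cell parameters for
small-molecule structure models, aimed at electron diffraction (MicroED /
3D ED) work.

## The problem

In electron diffraction the wavelength is very short (0.0251 Å at 200 keV),
so the diffraction angles are small and the unit-cell parameters are strongly
correlated with the (hard-to-calibrate) detector distance. The resulting
cells routinely carry systematic errors an order of magnitude larger than in
X-ray work — and since bond lengths and angles are computed *through* the
cell, the model stereochemistry inherits the error.

Organic molecules, however, have highly conserved bond distances. `latticefit`
exploits this: it holds the fractional coordinates **x** of a model fixed,
recomputes every restrained inter-atomic distance under a trial cell via the
cell metric tensor *G* (*d*² = Δ**x**ᵀ *G* Δ**x**), and adjusts the cell to
minimize the weighted discrepancy against idealized 1,2 (DFIX) and 1,3 (DANG)
distance restraints:

```
T(a, b, c, α, β, γ) = Σ_R (1/σ_R²) · (d_R² − Δ_R²)²
```

where Δ_R and σ_R are the restraint target and weight (defaults 0.02 Å for
DFIX, 0.04 Å for DANG). The analytic gradient follows by the chain rule
through ∂G/∂τ for each cell parameter τ. Optimization respects the lattice
constraints of the declared crystal system — from triclinic (6 free
parameters) down to cubic (1) — and can be relaxed to all-six-free to
*validate* a crystal-system assignment. Two drivers are provided: BFGS with
the analytic gradient, and a multi-level hill climb (±0.1 Å/° steps, best
single modification per round, step halving, abort after ten improvement-free
rounds). An alternation loop interleaves cell optimization with a coordinate
refinement step — an external refinement program via a command template, or a
built-in restraints-only coordinate regularizer — capped at 25 iterations.

Input and output are SHELX RES/INS files, with RESI residue scoping,
multi-pair DFIX/DANG lines and `+filename` restraint includes.

## Worked example

Generate a synthetic fixture whose ground truth is known — a tetrahedral
molecule in a true orthorhombic cell (10, 20, 30) Å, with every free cell
parameter perturbed by +5 % — then recover the true cell:

```python
from latticefit import FixtureSpec, UnitCell, write_fixture
write_fixture(FixtureSpec(system="orthorhombic", true_cell=UnitCell(10, 20, 30),
                          cell_perturbation=0.05), "example.res")
```

```sh
$ latticefit example.res -xo -o example_opt.res --trace-csv trace.csv --deviations dev.csv
optimized cell: (9.999999999938336, 20.000000000008907, 29.9999999999544, 90.0, 90.0, 90.0)
termination: gradient_tolerance (converged)
wrote example_opt.res
```

The starting cell was (10.5, 21.0, 31.5); the optimizer returns the
generating cell to ~1e-10 Å and exits 0 on convergence. `trace.csv` logs the
cell, objective and weighted mean |d − Δ| per iteration (the data behind
convergence plots):

```
iteration,a,b,c,alpha,beta,gamma,objective,mean_abs_dev,refiner_score
0,10.5,21.0,31.5,90.0,90.0,90.0,2166.716270436672,0.09788877434122997,
1,9.634285714285715,20.56714285714286,31.21142857142857,90.0,90.0,90.0,277.6053979109131,0.024521510343592068,
2,10.06954837095443,19.74947350379787,30.524153095937912,90.0,90.0,90.0,36.79223837819537,0.009863442332495349,
```

and `dev.csv` reports each restraint's signed deviation d − Δ in Å, readable
as plain geometry deviations. The same machinery is available as
scikit-learn-style estimators:

```python
from latticefit import BFGSCellOptimizer, parse_res
est = BFGSCellOptimizer(system="orthorhombic").fit(parse_res(open("example.res").read()))
est.cell_       # UnitCell(a=10.0…, b=20.0…, c=30.0…, 90, 90, 90)
est.trace_      # per-iteration OptimizationTrace
```

Crystal-system flags: `-xa` triclinic, `-xm` monoclinic, `-xo` orthorhombic,
`-xh` hexagonal, `-xt` tetragonal, `-xc` cubic. Use `--iterate
--refiner 'cmd {input} {output}'` to alternate with an external refinement
program, or `--refiner internal` for the built-in coordinate regularizer.

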