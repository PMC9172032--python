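# Methods

## Model

A unit cell (a, b, c in Å; α, β, γ in degrees) defines the metric tensor

```
G = [ a²        ab·cosγ   ac·cosβ ]
    [ ab·cosγ   b²        bc·cosα ]
    [ ac·cosβ   bc·cosα   c²      ]
```

so that for two atoms with fractional coordinates x₁, x₂ the squared
distance is d² = (x₁−x₂)ᵀ G (x₁−x₂). Every distance in the package goes
through G, which makes all results independent of the orthogonalization
convention; the convention (a along the first Cartesian axis, b in the first
coordinate plane, M upper-triangular with G = MᵀM) only matters for exported
Cartesian/PDB coordinates. Angles are degrees at every public interface and
radians only inside trigonometric evaluation. Restrained pairs are taken at
their literal coordinates — no minimum-image wrapping — matching SHELX
semantics where restrained pairs are listed explicitly within the model.

### Objective

For restraints R with target Δ_R and weight σ_R the primary target function
is

```
T = Σ_R (1/σ_R²) (d_R² − Δ_R²)²
```

It compares *squared* distances: this avoids the modulus, is smooth
everywhere, and along any one-parameter cell family attains its minimum at
the same cell as the conventional least-squares form
T_ls = Σ (1/σ²)(d − Δ)², which is selectable via `form="least_squares"`
(the coincidence of minimizers is asserted in the test suite). The
"inverse variation" weight is read as 1/σ² for both squared objectives.
The hill-climb driver instead scores candidate cells by the weighted mean
absolute deviation Σ (1/σ)|d − Δ| / Σ (1/σ) — an interpretable Å-scale
criterion with weights 1/σ. Deviation reports always show the signed d − Δ
in Å, never squared quantities.

The gradient with respect to a cell parameter τ is

```
∂T/∂τ = Σ_R (2/σ_R²) (d_R² − Δ_R²) · Δxᵀ (∂G/∂τ) Δx
```

with the ∂G/∂τ entries read off the metric tensor (angle derivatives carry a
π/180 factor so the public gradient is per degree). Crystal-system
constraints act as a linear map: fixed angles are dropped, tied parameters
(a = b, or a = b = c) accumulate their partials into one free variable.

### Crystal systems

| system | free variables | constraints |
|---|---|---|
| triclinic | a, b, c, α, β, γ (6) | none |
| monoclinic | a, b, c, β (4) | α = γ = 90° |
| orthorhombic | a, b, c (3) | α = β = γ = 90° |
| hexagonal | a, c (2) | a = b, α = β = 90°, γ = 120° |
| tetragonal | a, c (2) | a = b, α = β = γ = 90° |
| cubic | a (1) | a = b = c, α = β = γ = 90° |

Monoclinic deliberately has **four** free variables: the constraints
α = γ = 90° (unique axis b) leave a, b, c and β free, even though some
summaries quote three. Trigonal/rhombohedral lattices are handled in the
hexagonal setting. Fixed angles are held *bitwise* at 90°/120° throughout
optimization (they are never part of the optimization vector), and tied
lengths are one variable, so they remain exactly equal. A cell that violates
its declared system is rejected up front; the user either fixes the cell or
relaxes to triclinic — relaxing a correct higher-symmetry structure to
triclinic recovers the constrained angles to well under 0.05°, which is a
useful crystal-system validation.

## Drivers

**BFGS** (default): scipy's BFGS with the analytic gradient, terminating at
gradient infinity-norm < 1e-6. The `step` parameter (default 0.01) scales
the initial inverse Hessian. Only a local minimum is guaranteed; the
objective is quartic in the cell parameters and multimodal in principle,
but in practice starting cells are within a few percent of the answer.
If the line search stalls, the best conforming cell seen is returned with
`termination_reason="step_exhausted"` rather than raising.

**Hill climb**: from the starting cell, each round evaluates ±step on every
free parameter (initial step 0.1 Å for lengths and 0.1° for angles, one
shared step schedule), and accepts only the single proposal with the largest
improvement of the fitting criterion; all other improving proposals are
discarded. A round with no strict improvement halves the step. The search
aborts after ten consecutive improvement-free rounds; a halving counts as
such a round, and any accepted modification resets the counter (the
alternative — never resetting — would abort prematurely on long descents).
Ties break deterministically: parameter order a, b, c, α, β, γ, then "+"
before "−". There is no randomness in either driver.

**Alternation** (`IterativeCellRefiner`): repeat {optimize cell at fixed
coordinates; refine coordinates at fixed cell} until the cell change between
successive iterations falls below 1e-4 Å on lengths and 1e-3° on angles, or
25 iterations are reached. The coordinate step is pluggable:

* an **external refinement program**, invoked through a shell command
  template with `{input}`/`{output}` RES-file placeholders. This is the
  production setup: a data-driven refiner (e.g. a SHELX-style least-squares
  program) supplies coordinates refined against diffraction data with the
  new cell. A nonzero exit or unparseable output stops the iteration with a
  partial trace and `termination_reason="refiner_error"` — reported, never
  swallowed. If the program writes `REM SCORE <v>`, the score is recorded
  per iteration (and enables score-driven combined-mode workflows).
* the **internal coordinate regularizer**: minimizes the same restraint
  objective over the fractional coordinates of restrained atoms (L-BFGS-B,
  analytic coordinate gradient), cell fixed. Atoms in no restraint are
  untouched, SHELX-fixed coordinate components never move, and the net
  translation of the restrained atoms is removed afterwards (centroid
  preserved) to fix the translational gauge. **This reproduces the
  mechanism of the alternation, not data-driven refinement**: it pulls
  coordinates onto the restraint geometry only, so passing tests with it
  demonstrate the optimizer and the plumbing, not refinement against
  intensities.
* nothing: single-shot cell optimization.

Convergence tolerances (1e-4 Å / 1e-3° cell change, 1e-6 gradient norm) are
set one order below the precision the method can meaningfully claim, and are
exposed as parameters.

## SHELX I/O

The parser reads the instruction subset the optimizer needs — CELL
(wavelength + six parameters), SFAC, RESI scoping, DFIX/DANG (optional
sigma; defaults 0.02/0.04 Å; a line with 2k atom names yields k restraints
sharing Δ and σ), `+filename` includes, atom records — and preserves every
other line verbatim. Instruction names match on their first four characters,
case-insensitive; trailing `=` joins continuation lines. A coordinate v with
5 ≤ v < 15 is decoded as fixed at v − 10; other free-variable arithmetic and
symmetry-equivalent restraint references (`$n`) are rejected with explicit
errors rather than mis-read. An unqualified restraint atom reference inside
a RESI scope resolves within that residue first, then globally, and a
globally ambiguous name is an error (qualify with `_<residue>`): SHELX
itself does not document this case, so the package makes the safe choice
explicit. Writing reproduces the source byte-for-byte except the CELL line
(reformatted with ≥4 length / ≥3 angle decimals, widened automatically to an
exact round-trip representation) and any atom record whose coordinates were
changed in memory; `parse(write(S)) == S` holds exactly and is
property-tested.

## Synthetic fixtures

The generator places a known molecule (planar hexagon, tetrahedral fragment,
zigzag chain, or custom coordinates) in a known true cell, derives DFIX
restraints for bonded pairs (distance-cutoff bonding, default 1.8 Å) and
DANG restraints for 1,3 pairs, perturbs the cell multiplicatively on the
free parameters only, and emits RES text plus a JSON manifest (true cell,
perturbed cell, seed, noise levels, per-parameter observability flags).
Restraint targets are computed from the *emitted* decimal-formatted
coordinates through the same metric-tensor distance as the objective, so a
zero-noise fixture has residual exactly zero at the true cell up to one
floating-point ulp (≲1e-18 after squaring); tests assert that bound.
Optional independent Gaussian noise can be added to restraint targets and/or
Cartesian coordinates; all randomness is seeded and a given (spec, seed)
pair is byte-reproducible.

What the fixtures do **not** emulate: diffraction intensities, thermal
motion, disorder, chemically curated restraint dictionaries, or correlated
experimental error. Recovery results on fixtures therefore demonstrate the
optimizer's correctness and conditioning, not end-to-end refinement quality
on real data.

### Observability and the flat-molecule degeneracy

A cell parameter is recoverable only if some restraint vector has a
component along it. A planar molecule lying in the a–b plane has Δx₃ = 0
for every restraint, so ∂T/∂c ≡ 0: the optimizer leaves c exactly at its
starting value, and the manifest flags c as unobservable. The same applies
to α and β in a triclinic setting. This is a property of the problem, not a
defect of the optimizer, and it is asserted as expected behaviour in the
tests.

### Expected recovery precision under noise

With Gaussian noise of standard deviation σ_n on the restraint targets, the
recoverable per-axis *relative* scale precision is bounded by Fisher
information: each restraint contributes sensitivity ∂d/∂f_axis = X_axis²/d
(X_axis = Cartesian extent along the axis). For the 5-atom tetrahedral
fixture (10 restraints) at σ_n = 0.01 Å this bound is ≈0.4 % per axis for a
three-parameter system — i.e. the *absolute* error in Å grows linearly with
the axis length (≈0.04 Å on a 10 Å axis, ≈0.12 Å on a 30 Å axis), and the
measured median recovery error matches this scaling. Fewer free parameters
(cubic: one) pool all restraints and do proportionally better (≈0.01 Å at
12 Å). Any absolute accuracy target for noisy recovery must therefore be
read relative to the cell size and the number of restraints.

## Design choices and limitations

* The displayed objective uses squared-distance differences; the
  conventional (d − Δ)² form is one switch away and shares its minimizers.
  Which convention an external program uses only matters for non-uniform σ,
  and then only for the weighting, not the zero-noise optimum.
* The hill-climb criterion (weighted mean |d − Δ|) differs from the BFGS
  objective by design; `criterion="objective"` forces a common criterion
  when the two drivers must be compared head-to-head.
* Restraints other than DFIX/DANG (SADI, FLAT, CHIV, …) pass through
  unchanged and do not enter the objective. EQIV/symmetry-expanded
  restraints and general SHELX free-variable coordinate arithmetic are
  rejected explicitly.
* No global optimization, no standard uncertainties on the optimized cell,
  no refinement of displacement parameters.
* Inorganic or disordered structures with genuinely variable bond lengths
  violate the premise that restraint targets are accurate; cell optimization
  against such restraints can then be misleading. Whether the restraints
  span all cell directions (packing, molecular shape) must be judged per
  structure — the manifest's observability flags automate that judgement
  for synthetic cases only.
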