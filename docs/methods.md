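# Methods

## The model class

`fluxvar` works on constraint-based (stoichiometric) metabolic models: a
sparse stoichiometry matrix **N** (m metabolites × r reactions), flux
bounds α_i ≤ v_i ≤ β_i per reaction (mmol gDW⁻¹ h⁻¹; the biomass flux in
h⁻¹), and a designated biomass reaction taken from the model objective.
The feasible set is the polytope {v : N·v = 0, α ≤ v ≤ β}.  Reactions are
classified totally into three groups:

* **growth** — the biomass pseudo-reaction (exactly one per model);
* **exchange** — reactions with a single nonzero stoichiometric column
  entry (uptakes, secretions, demands/sinks).  Whether non-biomass
  demands count as "external" is a genuinely open convention; the
  single-entry rule treats them as exchanges, which matches standard
  reconstruction practice and keeps the rule purely structural.
  ATP-maintenance reactions involve several metabolites and therefore
  remain internal without special-casing;
* **internal** — everything else.

Sign convention: fluxes are stored BiGG-signed (exchange uptake is a
negative flux), while every user-facing number — media, scan grids, CLI
`--fix` values on exchanges, reported uptakes — is a positive uptake
magnitude.  The conversion happens exactly once, at the medium/CLI/report
boundary.

## Linear programs

All computations reduce to LPs over the polytope above:

* **FBA** — maximize (or minimize) one flux, by default biomass.
* **FVA** — per-reaction minimum and maximum flux (two LPs per reaction)
  under a constraint set, giving an interval [j_i^min, j_i^max].
* **linear MoMA** — minimize the Manhattan distance Σ_i |v_i − v_i^ref|
  to a reference flux vector, via split deviation variables
  (v_i = v_i^ref + d_i⁺ − d_i⁻, d ≥ 0, minimize Σ(d⁺+d⁻)); the sum runs
  over all r reactions on signed fluxes.
* **single-flux minimization** — for exchanges, performed on the uptake
  magnitude and reported as a positive uptake, clipped at zero when the
  flux can leave the uptake regime.

The backend is HiGHS dual simplex via `scipy.optimize.linprog`
(`method="highs-ds"`), behind a small solver contract
(`StoichiometricLP`) so another backend can be dropped in.  The
constraint matrix is assembled once per model and only objectives and
bounds change between solves.  The solver and the variable order (the
model's reaction order) are pinned, so the vertex returned for a
degenerate optimum is deterministic run to run; outputs record a hash of
the chosen exchange vertex because optimal exchange patterns are
degenerate in general.

Fixing a reaction means lb = ub = value exactly, with no optimality
slack: growth is fixed at exactly its LP maximum, which is safe because
the fixed values are produced by the same solver and tolerance stack
that re-solves under them.  Tolerances: mass-balance residual and bound
slack 1e-9 (solver defaults), fix-validation slack 1e-6, zero-width
threshold 1e-9.

## The Δ and Σ measures

Flexibility under a condition is measured against a fixed reference
condition.  With V_i^min/V_i^max the reference FVA interval of internal
reaction i and j_i^min/j_i^max the interval under the condition,

    Δ = (1/|A|) Σ_{i∈A} (j_i^max − j_i^min) / (V_i^max − V_i^min)

averaged over the **admissible set** A of internal reactions.  Δ = 1 at
the reference by construction, and 0 ≤ Δ < 1 whenever the condition's
feasible set is nested inside the reference's.  Δ is deliberately not
clamped: conditions looser than the reference can exceed 1.

Two kinds of internal reaction are excluded from A:

1. **Zero reference width.**  The ratio is 0/0; blocked or permanently
   pinned reactions carry no variability information.  This is the only
   division-safe reading of the formula; the admissible count is
   reported so the effective r is visible.
2. **Cap-limited ranges** (default, switchable with
   `include_cap_limited=True`).  Genome-scale reconstructions stand in
   for "unbounded" with ±1000 placeholder bounds; reactions sitting on
   thermodynamically unconstrained cycles get reference FVA ranges that
   touch those caps (endpoint magnitude ≥ cap·(1−1e-4), where the cap is
   the model's largest bound magnitude).  Such ranges measure the
   placeholder value, not stoichiometry or medium, and whether they
   shrink under a condition says nothing about metabolism, so they are
   excluded.  On iJO1366 this removes 78 of 1588 nonzero-width internal
   reactions and is what makes the anaerobic total variability land at
   ≈ 0.21 rather than ≈ 0.24; it is equivalent to treating the
   placeholder bounds as infinite, under which those FVA subproblems
   would be unbounded and could never enter the average.

Δ is computed over net fluxes of reversible reactions as modeled; no
forward/backward splitting.

The companion measure Σ — the variability of the summed internal flux —
is the ratio of the summed FVA widths over the same admissible set:
Σ = Σ_i (j_i^max − j_i^min) / Σ_i (V_i^max − V_i^min).  It is an opt-in
robustness companion (`with_sigma=True`), never a substitute for Δ.
Note that this per-reaction-sum form is not the same number as the
spread of the aggregate flux Σv_i optimized directly (the sum of maxima
exceeds the maximum of the sum); the per-reaction form is the one the
Δ/Σ framework defines, and it comes free from the FVA already computed
for Δ.

## The three-way decomposition

For a condition (a set of exchange fixes and/or bound overrides on the
medium-conditioned model):

1. maximize growth → v_gro^max and one optimal flux vertex;
2. Δ_int: FVA with growth and all remaining exchanges fixed at that
   vertex;
3. Δ_int+ext: FVA with only growth fixed;
4. Δ_tot: FVA with neither fixed;
5. Δ_ext = Δ_int+ext − Δ_int, Δ_gro = Δ_tot − Δ_int+ext.

Δ_tot = Δ_int + Δ_ext + Δ_gro holds exactly by construction.  Exchanges
fixed by the condition itself (a scanned uptake, a coordinated carbon
source) stay fixed in all three FVAs, so Δ_ext measures only the
variation the condition leaves free.  Because the optimal exchange
pattern is degenerate, Δ_int and Δ_ext individually depend on the vertex
chosen; their sum and Δ_gro do not (asserted on toys by permuting the
variable order).  Steady state also makes fixing the exchanges alone
equivalent to fixing exchanges and growth together whenever the growth
reaction is the only biomass drain.

## Scans and coordination

* **Uptake scans** fix one exchange's uptake along a strictly increasing
  grid and decompose at each point.  The reference ranges are computed
  once per scan from the base medium, never per point; by default that
  is the aerobic reference even for anaerobic conditions, so anaerobic
  totals are commensurable with the aerobic Δ = 1.  A scanned uptake may
  exceed the medium's own limit — the scan widens the bound on purpose.
  Infeasible points are flagged rows, not failures, unless the whole
  grid is infeasible.  Default grids: 20 points on (0, 10] for glucose,
  (0, 40] for oxygen, (0, 20] for ammonia; density is configuration, not
  dogma.
* **Carbon–nitrogen coordination** is a lexicographic two-stage LP: fix
  the nitrogen-source uptake, maximize growth, then minimize the
  carbon-source uptake with growth fixed at that maximum.  In
  coordinated scans the carbon uptake is pinned at that minimum, which
  collapses internal and external variability to zero on the
  two-substrate toy (exactly, asserted) and is reported—not asserted—for
  genome-scale models.
* **Growth-bound scans** constrain growth to [0, f·v_max] (upper bound),
  [f·v_max, v_max] (lower bound), exactly f·v_max (both bounds), or
  indirectly via a glucose grid with growth free, and record Δ_tot.  The
  near-identity of the lower-bound and both-bounds curves seen at genome
  scale is an empirical report, not an invariant — the branched toy
  shows they can differ.

## Reorganization

Adaptation between glucose-uptake states is modeled with linear MoMA
from the FBA optimum at uptake 10.  The reorganization statistic counts
fluxes whose magnitude increases to more than 2× or falls below 0.1× the
initial value; the asymmetry reflects that total flux scales roughly
with uptake, biasing changes downward.  Reactions with initial magnitude
below 1e-6 are excluded from the counts (no meaningful fold change from
a zero baseline); `count_new_as_up=True` opts into counting appearances,
and `n_eligible` is always reported so the exclusion is visible.  Counts
are taken over all r reactions.  Because the initial optimum is
degenerate, counts can differ between solvers; the chosen vertex is
recorded in the run manifest.

## Synthetic networks and the oracle

Three deterministic presets stand in for genome-scale models at desk
scale: a chain (uptake-pinned single path), a branched network (one
internal degree of freedom between two routes), and a two-substrate
network (1 C + 1 N per unit growth, with carbon- and nitrogen-overflow
secretion routes so the uptakes decouple unless coordinated).  Internal
and secretion caps are 50, far above any uptake-limited flux, so toy FVA
ranges are never cap-limited.  A seedable random parallel-route
generator exists only for fuzzing LP invariants, never for golden
values.

The `brute_force_ranges` oracle verifies FVA without an LP solver: it
solves the equality system (balance + fixes) for a particular solution
and null-space basis, picks pivot reactions spanning the null space by
QR column pivoting, grid-searches the pivots over their bounds at a
given resolution, and reports empirical per-reaction extrema over the
feasible grid — an inner approximation within one grid step.  It refuses
more than three degrees of freedom.  Toy polytopes have their vertices
on the grid, so agreement in tests is essentially exact.

What the toys do not emulate: realistic biomass composition, cofactor
coupling, thermodynamic loops, and the sheer degeneracy of genome-scale
optima.  Passing toy tests therefore validates the machinery and the
identities, not medium-specific genome-scale numbers — those are checked
directly on the iJO1366 reconstruction (read from the installed cobra
distribution's data directory) under the packaged glucose minimal
medium.

## Problem sizes and runtime choices

Genome-scale checks compute the reference FVA once over the ~2250
internal reactions (~4500 LPs, about three minutes) and reuse it; the
anaerobic total needs one more FVA over the ~1500 admissible reactions.
Desk-scale tests run in seconds.  The two-substrate oracle uses a 0.25
grid resolution (three degrees of freedom); the others use 0.05.

## Known limitations

* A single biomass objective is assumed (ambiguous objectives are
  rejected); alternative objectives are supported per call via
  `objective_reaction`.
* No gene–protein–reaction rules, knockouts, thermodynamic (loopless)
  constraints, quadratic MoMA, flux sampling, or polytope volumes.
* The glucose-minimal medium shipped in `fluxvar/data/` mirrors the BiGG
  iJO1366 defaults; other reconstructions need their own medium YAML.
* Cap-limited exclusion keys on the model's largest bound magnitude; a
  model that uses its largest bound as a *real* physiological limit on a
  variable internal reaction would need an explicit `cap=` override.
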