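"""Deterministic toy networks with desk-computable answers, and an
LP-independent brute-force oracle for FVA ranges.

Presets (all unit stoichiometry, no randomness):

* ``chain`` (TOY1): exchange -> stem -> biomass; a single path whose flux
  is pinned by the uptake limit.
* ``branched`` (TOY2): exchange -> stem -> {direct route, route via an
  intermediate} -> biomass; 4 internal reactions and one internal degree
  of freedom (the split between the two routes).
* ``two_substrate`` (TOY3): a carbon-like and a nitrogen-like source, a
  biomass reaction consuming 1 C-unit + 1 N-unit per unit growth, and
  overflow routes secreting excess carbon and excess nitrogen, so the two
  uptakes decouple unless coordinated.

An optional maintenance demand (an internal reaction with a positive lower
bound consuming the first assimilated metabolite, draining to a secreted
waste product) emulates non-growth ATP expenditure.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .lp import EPS_BOUND, BoundSpec, FixSpec, FluxRanges, InfeasibleError
from .model import MetabolicModel, ModelError, build_model

#: generous finite cap for toy internal/secretion fluxes (well above any
#: uptake-limited flux, small enough for the grid oracle to enumerate)
TOY_CAP = 50.0

PRESETS = ("chain", "branched", "two_substrate")


def make_toy(
    preset: str,
    uptake_limit: float = 10.0,
    maintenance: float = 0.0,
    n_limit: float = 20.0,
) -> MetabolicModel:
    """Build a toy preset; see the module docstring for the topologies."""
    if preset not in PRESETS:
        raise ModelError(f"unknown toy preset {preset!r}")
    if uptake_limit < 0 or maintenance < 0 or n_limit < 0:
        raise ModelError("toy parameters must be non-negative")

    if preset == "chain":
        metabolites = ["A", "B"]
        reactions = [
            ("EX_A", {"A": -1.0}, -uptake_limit, 0.0),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, TOY_CAP),
            ("GRO", {"B": -1.0}, 0.0, TOY_CAP),
        ]
        maint_met = "B"
    elif preset == "branched":
        metabolites = ["A", "B", "C", "D"]
        reactions = [
            ("EX_A", {"A": -1.0}, -uptake_limit, 0.0),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, TOY_CAP),
            ("R2", {"B": -1.0, "C": 1.0}, 0.0, TOY_CAP),
            ("R3", {"B": -1.0, "D": 1.0}, 0.0, TOY_CAP),
            ("R4", {"D": -1.0, "C": 1.0}, 0.0, TOY_CAP),
            ("GRO", {"C": -1.0}, 0.0, TOY_CAP),
        ]
        maint_met = "B"
    else:  # two_substrate
        metabolites = ["C", "N", "P", "Ov", "Nw"]
        reactions = [
            ("EX_C", {"C": -1.0}, -uptake_limit, 0.0),
            ("EX_N", {"N": -1.0}, -n_limit, 0.0),
            ("T1", {"C": -1.0, "P": 1.0}, 0.0, TOY_CAP),
            ("OF", {"C": -1.0, "Ov": 1.0}, 0.0, TOY_CAP),
            ("EX_Ov", {"Ov": -1.0}, 0.0, TOY_CAP),
            ("NF", {"N": -1.0, "Nw": 1.0}, 0.0, TOY_CAP),
            ("EX_Nw", {"Nw": -1.0}, 0.0, TOY_CAP),
            ("GRO", {"P": -1.0, "N": -1.0}, 0.0, TOY_CAP),
        ]
        maint_met = "C"

    if maintenance > 0:
        metabolites = list(metabolites) + ["W"]
        reactions = reactions + [
            ("NGAM", {maint_met: -1.0, "W": 1.0}, maintenance, TOY_CAP),
            ("EX_W", {"W": -1.0}, 0.0, TOY_CAP),
        ]
    return build_model(f"toy_{preset}", metabolites, reactions, biomass="GRO")


def random_branched_network(
    rng: np.random.Generator, n_branches: int | None = None
) -> MetabolicModel:
    """A seedable random parallel-route network for fuzzing LP invariants.

    Never used for golden values: topology is a single substrate feeding
    2-5 parallel routes into biomass, with random finite bounds, so the
    model is always feasible (the zero flux is admissible).
    """
    k = int(n_branches or rng.integers(2, 6))
    metabolites = ["A", "B"]
    uptake = float(rng.uniform(2.0, 15.0))
    reactions = [("EX_A", {"A": -1.0}, -uptake, 0.0)]
    for i in range(k):  # parallel A -> B routes: k - 1 internal freedoms
        ub = float(rng.uniform(1.0, 20.0))
        reactions.append((f"B{i}", {"A": -1.0, "B": 1.0}, 0.0, ub))
    reactions.append(("GRO", {"B": -1.0}, 0.0, TOY_CAP))
    return build_model("random_branched", metabolites, reactions, biomass="GRO")


def brute_force_ranges(
    model: MetabolicModel,
    resolution: float = 0.05,
    fixes: FixSpec | None = None,
    bound_overrides: BoundSpec | None = None,
    max_dof: int = 3,
    chunk: int = 200_000,
) -> FluxRanges:
    """LP-free FVA oracle: enumerate the bounded steady-state polytope.

    The equality system (mass balance plus any fixed reactions) is solved
    for a particular solution and a null-space basis; a set of pivot
    reactions spanning the null space is grid-searched over its flux
    bounds at ``resolution``, and feasible combinations give empirical
    per-reaction minima/maxima (an inner approximation within one grid
    step of the truth).  Refuses models with more than ``max_dof`` free
    dimensions rather than approximating badly.
    """
    fixes = dict(fixes or {})
    bound_overrides = dict(bound_overrides or {})
    r = model.n_reactions
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for rid, (lo, hi) in bound_overrides.items():
        j = model.index(rid)
        lb[j], ub[j] = lo, hi
    for rid, val in fixes.items():
        j = model.index(rid)
        lb[j] = ub[j] = val

    # stack mass balance with fixed-reaction equality rows
    N = model.stoichiometry.toarray()
    fixed_idx = np.nonzero(ub - lb <= EPS_BOUND)[0]
    rows = [N]
    rhs = [np.zeros(N.shape[0])]
    if fixed_idx.size:
        E = np.zeros((fixed_idx.size, r))
        E[np.arange(fixed_idx.size), fixed_idx] = 1.0
        rows.append(E)
        rhs.append((lb[fixed_idx] + ub[fixed_idx]) / 2.0)
    M = np.vstack(rows)
    d_rhs = np.concatenate(rhs)

    v0, residues, *_ = np.linalg.lstsq(M, d_rhs, rcond=None)
    if np.abs(M @ v0 - d_rhs).max() > 1e-8:
        raise InfeasibleError("equality system is inconsistent")
    Z = linalg.null_space(M)
    dof = Z.shape[1]
    if dof > max_dof:
        raise ModelError(
            f"too many degrees of freedom for the brute-force oracle "
            f"({dof} > {max_dof})"
        )

    tol = 1e-9
    if dof == 0:
        if np.any(v0 < lb - 1e-7) or np.any(v0 > ub + 1e-7):
            raise InfeasibleError("point solution violates bounds")
        frame = pd.DataFrame(
            {"minimum": v0, "maximum": v0}, index=model.reaction_ids
        )
        return FluxRanges(frame, fixes, bound_overrides)

    # pivot reactions: rows of Z forming an invertible dof x dof block
    _, _, piv = linalg.qr(Z.T, pivoting=True)
    pivots = piv[:dof]
    B = Z[pivots, :]
    Binv = np.linalg.inv(B)

    grids = []
    for j in pivots:
        if not (np.isfinite(lb[j]) and np.isfinite(ub[j])):
            raise ModelError(
                f"pivot reaction {model.reaction_ids[j]!r} has non-finite bounds"
            )
        n_steps = max(1, int(np.ceil((ub[j] - lb[j]) / resolution)))
        grids.append(np.linspace(lb[j], ub[j], n_steps + 1))

    mins = np.full(r, np.inf)
    maxs = np.full(r, -np.inf)
    any_feasible = False
    dims = tuple(len(g) for g in grids)
    total = int(np.prod(dims))
    # evaluate the grid in chunks to bound memory
    for start in range(0, total, chunk):
        flat = np.arange(start, min(start + chunk, total))
        idx = np.unravel_index(flat, dims)
        P = np.stack([grids[k][idx[k]] for k in range(dof)])  # dof x n
        T = Binv @ (P - v0[pivots, None])
        V = v0[:, None] + Z @ T  # r x n
        feas = np.all(V >= lb[:, None] - tol, axis=0) & np.all(
            V <= ub[:, None] + tol, axis=0
        )
        if feas.any():
            any_feasible = True
            Vf = V[:, feas]
            mins = np.minimum(mins, Vf.min(axis=1))
            maxs = np.maximum(maxs, Vf.max(axis=1))
    if not any_feasible:
        raise InfeasibleError("no feasible grid point found")
    frame = pd.DataFrame({"minimum": mins, "maximum": maxs}, index=model.reaction_ids)
    return FluxRanges(frame, fixes, bound_overrides)
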