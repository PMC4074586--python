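"""Linear programs over a metabolic model: FBA, FVA, linear MoMA.

All problems share the constraint set ``N v = 0``, ``alpha <= v <= beta``.
A :class:`FixSpec` is a mapping ``{reaction_id: value}`` pinning fluxes
(lb = ub = value); fixed values must lie within the reaction's original
bounds up to a small tolerance.

The solver contract is a plain function of ``(c, A_eq, lb, ub, sense)``;
the default backend is HiGHS dual simplex through
:func:`scipy.optimize.linprog`, which is deterministic for a fixed
variable order (the model's reaction order), so the optimal vertex
returned for degenerate problems is reproducible run-to-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError, ReactionClass

EPS_BALANCE = 1e-9  # mass-balance residual tolerance
EPS_BOUND = 1e-6  # bound / fix validation tolerance
EPS_WIDTH = 1e-9  # range width considered zero

FixSpec = Mapping[str, float]
BoundSpec = Mapping[str, tuple[float, float]]


class InfeasibleError(RuntimeError):
    """The LP constraint set admits no solution."""


class UnboundedError(RuntimeError):
    """The LP objective is unbounded over the feasible set."""


@dataclass
class FluxVector:
    """One steady-state flux distribution with its provenance."""

    fluxes: pd.Series
    provenance: str = "user"

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])

    @property
    def values(self) -> np.ndarray:
        return self.fluxes.to_numpy()


@dataclass
class FluxRanges:
    """Per-reaction FVA intervals plus the constraint set that produced them."""

    frame: pd.DataFrame  # columns: minimum, maximum
    fixes: dict = field(default_factory=dict)
    bound_overrides: dict = field(default_factory=dict)

    @property
    def widths(self) -> pd.Series:
        w = self.frame["maximum"] - self.frame["minimum"]
        return w.clip(lower=0.0)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.frame.index)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        row = self.frame.loc[rid]
        return float(row["minimum"]), float(row["maximum"])


def _scipy_highs_backend(c, A_eq, lb, ub, sense):
    res = linprog(
        sense * np.asarray(c, dtype=float),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs-ds",
    )
    return res


Backend = Callable[..., object]


class StoichiometricLP:
    """Reusable LP over one model: the constraint matrix is assembled once
    and only objectives / bounds change between solves."""

    def __init__(self, model: MetabolicModel, backend: Backend | None = None):
        self.model = model
        self.A = sparse.csr_matrix(model.stoichiometry)
        self.backend = backend or _scipy_highs_backend

    def _bounds(
        self,
        fixes: FixSpec | None,
        bound_overrides: BoundSpec | None,
        validate_fixes: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        lb = self.model.lower_bounds.copy()
        ub = self.model.upper_bounds.copy()
        if bound_overrides:
            for rid, (lo, hi) in bound_overrides.items():
                j = self.model.index(rid)
                if lo > hi + EPS_BOUND:
                    raise ModelError(f"bound override for {rid!r} has lb > ub")
                lb[j], ub[j] = lo, hi
        if fixes:
            for rid, val in fixes.items():
                j = self.model.index(rid)
                if validate_fixes and not (
                    lb[j] - EPS_BOUND <= val <= ub[j] + EPS_BOUND
                ):
                    raise ModelError(
                        f"fix {rid}={val} lies outside the reaction's bounds "
                        f"[{lb[j]}, {ub[j]}]"
                    )
                lb[j] = ub[j] = val
        return lb, ub

    def solve(
        self,
        c: np.ndarray,
        sense: int,
        fixes: FixSpec | None = None,
        bound_overrides: BoundSpec | None = None,
    ):
        """sense = -1 maximizes, +1 minimizes.  Returns the linprog result."""
        lb, ub = self._bounds(fixes, bound_overrides)
        res = self.backend(c, self.A, lb, ub, sense)
        if res.status == 2:
            raise InfeasibleError("infeasible")
        if res.status == 3:
            raise UnboundedError("unbounded")
        if res.status != 0:
            raise RuntimeError(f"LP solver failure: {res.message}")
        return res


def _objective_vector(model: MetabolicModel, reaction_id: str) -> np.ndarray:
    c = np.zeros(model.n_reactions)
    c[model.index(reaction_id)] = 1.0
    return c


def solve_fba(
    model: MetabolicModel,
    objective_reaction: str | None = None,
    sense: str = "max",
    fixes: FixSpec | None = None,
    bound_overrides: BoundSpec | None = None,
    lp: StoichiometricLP | None = None,
) -> tuple[float, FluxVector]:
    """Optimize one flux (the biomass reaction by default) under the
    steady-state constraint set; returns ``(objective_value, flux_vector)``.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    objective_reaction = objective_reaction or model.biomass_reaction
    lp = lp or StoichiometricLP(model)
    c = _objective_vector(model, objective_reaction)
    res = lp.solve(c, -1 if sense == "max" else +1, fixes, bound_overrides)
    value = float(res.x[model.index(objective_reaction)])
    fluxes = pd.Series(res.x, index=model.reaction_ids)
    return value, FluxVector(fluxes, provenance="fba")


def solve_fva(
    model: MetabolicModel,
    reactions: Sequence[str] | None = None,
    fixes: FixSpec | None = None,
    bound_overrides: BoundSpec | None = None,
    lp: StoichiometricLP | None = None,
) -> FluxRanges:
    """Min and max flux of each requested reaction under the constraint set
    (two LPs per reaction); results are independent of iteration order.
    """
    reactions = list(reactions) if reactions is not None else list(model.reaction_ids)
    lp = lp or StoichiometricLP(model)
    # fail before iterating if the constraint set itself is infeasible
    lp.solve(np.zeros(model.n_reactions), +1, fixes, bound_overrides)
    mins = np.empty(len(reactions))
    maxs = np.empty(len(reactions))
    c = np.zeros(model.n_reactions)
    for k, rid in enumerate(reactions):
        j = model.index(rid)
        c[j] = 1.0
        mins[k] = lp.solve(c, +1, fixes, bound_overrides).x[j]
        maxs[k] = lp.solve(c, -1, fixes, bound_overrides).x[j]
        c[j] = 0.0
    frame = pd.DataFrame({"minimum": mins, "maximum": maxs}, index=reactions)
    return FluxRanges(frame, dict(fixes or {}), dict(bound_overrides or {}))


def solve_moma(
    model: MetabolicModel,
    v_ref: FluxVector | pd.Series | np.ndarray,
    fixes: FixSpec | None = None,
    bound_overrides: BoundSpec | None = None,
) -> tuple[float, FluxVector]:
    """Linear MoMA: minimize the Manhattan distance sum_i |v_i - v_i_ref|
    subject to the (possibly re-bounded) FBA constraints.

    Implemented with split deviation variables
    ``v_i = v_i_ref + d_i_plus - d_i_minus``, ``d >= 0``, minimizing
    ``sum(d_plus + d_minus)``.
    """
    if isinstance(v_ref, FluxVector):
        ref = v_ref.fluxes.reindex(model.reaction_ids).to_numpy()
    elif isinstance(v_ref, pd.Series):
        ref = v_ref.reindex(model.reaction_ids).to_numpy()
    else:
        ref = np.asarray(v_ref, dtype=float)
    if ref.shape != (model.n_reactions,) or np.isnan(ref).any():
        raise ModelError("reference flux vector does not cover the model's reactions")

    r = model.n_reactions
    base = StoichiometricLP(model)
    lb, ub = base._bounds(fixes, bound_overrides)

    # variables: [v (r), d_plus (r), d_minus (r)]
    A_bal = sparse.hstack([model.stoichiometry, sparse.csr_matrix((model.n_metabolites, 2 * r))])
    eye = sparse.identity(r, format="csr")
    A_dev = sparse.hstack([eye, -eye, eye])  # v - d+ + d- = ref
    A_eq = sparse.vstack([A_bal, A_dev], format="csr")
    b_eq = np.concatenate([np.zeros(model.n_metabolites), ref])
    full_lb = np.concatenate([lb, np.zeros(2 * r)])
    full_ub = np.concatenate([ub, np.full(2 * r, np.inf)])
    c = np.concatenate([np.zeros(r), np.ones(2 * r)])

    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([full_lb, full_ub]),
        method="highs-ds",
    )
    if res.status == 2:
        raise InfeasibleError("infeasible")
    if res.status != 0:
        raise RuntimeError(f"MoMA LP failure: {res.message}")
    fluxes = pd.Series(res.x[:r], index=model.reaction_ids)
    distance = float(np.abs(fluxes.to_numpy() - ref).sum())
    return distance, FluxVector(fluxes, provenance="moma")


def minimize_flux(
    model: MetabolicModel,
    reaction_id: str,
    fixes: FixSpec | None = None,
    bound_overrides: BoundSpec | None = None,
    lp: StoichiometricLP | None = None,
) -> float:
    """Minimum attainable value of a single flux.

    For exchange reactions the minimization is performed on the uptake
    magnitude and reported as a positive uptake (clipped at zero when the
    flux can leave the uptake regime entirely).
    """
    lp = lp or StoichiometricLP(model)
    j = model.index(reaction_id)
    cls = model.reaction_classes[reaction_id]
    c = np.zeros(model.n_reactions)
    if cls is ReactionClass.EXCHANGE:
        # uptake magnitude = sign(coeff) * flux; minimize it
        sign = 1.0 if model._exchange_coeff(reaction_id) > 0 else -1.0
        c[j] = sign
        res = lp.solve(c, +1, fixes, bound_overrides)
        return max(0.0, float(sign * res.x[j]))
    c[j] = 1.0
    res = lp.solve(c, +1, fixes, bound_overrides)
    return float(res.x[j])


def check_steady_state(model: MetabolicModel, fluxes: FluxVector, tol: float = 1e-6) -> bool:
    """True when N v = 0 and the bounds hold within ``tol``."""
    v = fluxes.fluxes.reindex(model.reaction_ids).to_numpy()
    residual = np.abs(model.stoichiometry @ v).max() if model.n_metabolites else 0.0
    in_bounds = bool(
        np.all(v >= model.lower_bounds - tol) and np.all(v <= model.upper_bounds + tol)
    )
    return bool(residual <= tol) and in_bounds
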