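"""Condition sweeps: uptake scans, carbon-nitrogen coordination, and
growth-bound scans.

All scans condition the model on a base medium once, compute the reference
FVA ranges once from that medium (never per grid point), and then evaluate
the variability decomposition along a grid.  Grids and uptake values are
positive uptake magnitudes; conversion to signed exchange fluxes happens
at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lp import (
    FluxRanges,
    InfeasibleError,
    StoichiometricLP,
    minimize_flux,
    solve_fba,
    solve_fva,
)
from .model import MediumSpec, MetabolicModel, ModelError, ReactionClass, apply_medium
from .variability import (
    ReferenceState,
    VariabilityComponents,
    compute_reference_ranges,
    decompose_variability,
    delta_measure,
)

GROWTH_SCAN_MODES = ("glucose_limited", "upper_bound", "lower_bound", "both_bounds")


@dataclass
class CoordinationResult:
    """Two-stage optimum for one fixed nitrogen-source uptake."""

    v_n: float  # fixed nitrogen (ammonia-like) uptake
    vgro_max: float  # maximum growth at that nitrogen uptake
    v_c_min: float  # minimum carbon (glucose-like) uptake sustaining it


@dataclass
class UptakeScanResult:
    exchange_id: str
    grid: np.ndarray
    components: list[VariabilityComponents | None]
    coordinated: bool = False
    coordination: list[CoordinationResult | None] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (g, comp) in enumerate(zip(self.grid, self.components)):
            row = {"uptake": g}
            if comp is None:
                row["feasible"] = False
            else:
                row.update(comp.as_dict())
            if self.coordinated and self.coordination:
                coord = self.coordination[k]
                row["v_c_min"] = coord.v_c_min if coord is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class GrowthScanResult:
    mode: str
    fractions: np.ndarray
    delta_tot: np.ndarray
    vgro: np.ndarray
    feasible: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "vgro": self.vgro,
                "delta_tot": self.delta_tot,
                "feasible": self.feasible,
            }
        )


def _as_exchange(model: MetabolicModel, rid: str) -> str:
    if model.reaction_classes.get(rid) is not ReactionClass.EXCHANGE:
        raise ModelError(f"{rid!r} is not an exchange reaction")
    return rid


def coordinate_carbon_nitrogen(
    model: MetabolicModel,
    medium: MediumSpec | None,
    v_n: float,
    n_exchange: str,
    c_exchange: str,
    lp: StoichiometricLP | None = None,
) -> CoordinationResult:
    """Lexicographic two-stage LP implementing carbon-nitrogen coordination.

    Stage 1 fixes the nitrogen-source uptake at ``v_n`` and maximizes
    growth; stage 2 minimizes the carbon-source uptake with growth fixed at
    the stage-1 optimum.  The carbon uptake is thereby pinned to the
    minimum value sustaining the maximum growth attainable at ``v_n``.
    """
    if v_n < 0:
        raise ModelError("nitrogen uptake must be non-negative")
    if medium is not None:
        model = apply_medium(model, medium)
        lp = None
    _as_exchange(model, n_exchange)
    _as_exchange(model, c_exchange)
    lp = lp or StoichiometricLP(model)
    fixes = {n_exchange: model.uptake_flux(n_exchange, v_n)}
    vgro_max, _ = solve_fba(model, sense="max", fixes=fixes, lp=lp)
    fixes[model.biomass_reaction] = vgro_max
    v_c_min = minimize_flux(model, c_exchange, fixes=fixes, lp=lp)
    return CoordinationResult(v_n=v_n, vgro_max=vgro_max, v_c_min=v_c_min)


def scan_uptake(
    model: MetabolicModel,
    medium: MediumSpec | None,
    exchange_id: str,
    grid: Sequence[float],
    coordinate_cn: bool = False,
    c_exchange: str = "EX_glc__D_e",
    n_exchange: str = "EX_nh4_e",
    reference: ReferenceState | None = None,
    with_sigma: bool = False,
) -> UptakeScanResult:
    """Decompose flux variability along a grid of fixed uptake values.

    Each grid value pins the scanned exchange (lb = ub in the uptake
    orientation); with ``coordinate_cn`` and the nitrogen source scanned,
    the carbon source is additionally pinned at the coordinated minimum.
    Grid points may exceed the medium's own uptake limit by design (the
    scan overrides the bound).  Infeasible points are flagged, not fatal,
    unless every point is infeasible.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ModelError("scan grid must be strictly increasing")
    if np.any(grid < 0):
        raise ModelError("uptake grid values must be non-negative")
    if medium is not None:
        model = apply_medium(model, medium)
    _as_exchange(model, exchange_id)
    lp = StoichiometricLP(model)
    if reference is None:
        reference = compute_reference_ranges(model, lp=lp)

    components: list[VariabilityComponents | None] = []
    coordination: list[CoordinationResult | None] = []
    j = model.index(exchange_id)
    for g in grid:
        signed = model.uptake_flux(exchange_id, g)
        # a scanned uptake may exceed the medium bound: widen it on purpose
        lo = min(model.lower_bounds[j], signed)
        hi = max(model.upper_bounds[j], signed)
        bounds = {exchange_id: (lo, hi)}
        fixes = {exchange_id: signed}
        coord = None
        try:
            if coordinate_cn and exchange_id == n_exchange:
                coord = coordinate_carbon_nitrogen(
                    model, None, g, n_exchange=n_exchange, c_exchange=c_exchange, lp=lp
                )
                fixes[c_exchange] = model.uptake_flux(c_exchange, coord.v_c_min)
            comp = decompose_variability(
                model,
                reference,
                fixes=fixes,
                bound_overrides=bounds,
                with_sigma=with_sigma,
                lp=lp,
            )
        except InfeasibleError:
            comp = None
        components.append(comp)
        coordination.append(coord)
    if grid.size and all(c is None for c in components):
        raise InfeasibleError("every grid point is infeasible")
    return UptakeScanResult(
        exchange_id=exchange_id,
        grid=grid,
        components=components,
        coordinated=coordinate_cn,
        coordination=coordination,
    )


def scan_growth_bounds(
    model: MetabolicModel,
    medium: MediumSpec | None,
    mode: str,
    fractions: Sequence[float] | None = None,
    glucose_grid: Sequence[float] | None = None,
    glucose_exchange: str = "EX_glc__D_e",
    reference: ReferenceState | None = None,
) -> GrowthScanResult:
    """Total variability as a function of how growth is constrained.

    Modes (f = fraction of the reference maximum growth):

    * ``upper_bound``   -- growth in [0, f * vgro_max], exchanges free;
    * ``lower_bound``   -- growth in [f * vgro_max, vgro_max];
    * ``both_bounds``   -- growth fixed at f * vgro_max;
    * ``glucose_limited`` -- glucose uptake fixed along ``glucose_grid``
      (growth free); the realized fraction vgro_max(g)/vgro_max is the
      x-coordinate.
    """
    if mode not in GROWTH_SCAN_MODES:
        raise ModelError(f"unknown growth-scan mode {mode!r}")
    if medium is not None:
        model = apply_medium(model, medium)
    lp = StoichiometricLP(model)
    if reference is None:
        reference = compute_reference_ranges(model, lp=lp)
    vgro_max, _ = solve_fba(model, sense="max", lp=lp)
    growth = model.biomass_reaction

    if mode == "glucose_limited":
        if glucose_grid is None:
            raise ModelError("glucose_limited mode needs a glucose grid")
        points = [("glc", float(g)) for g in glucose_grid]
    else:
        if fractions is None:
            raise ModelError(f"mode {mode!r} needs growth fractions")
        fr = np.asarray(list(fractions), dtype=float)
        if np.any((fr < 0) | (fr > 1)):
            raise ModelError("growth fractions must lie in [0, 1]")
        points = [("f", float(f)) for f in fr]

    out_f, out_d, out_v, out_ok = [], [], [], []
    for kind, val in points:
        try:
            if kind == "glc":
                signed = model.uptake_flux(glucose_exchange, val)
                j = model.index(glucose_exchange)
                bounds = {
                    glucose_exchange: (
                        min(model.lower_bounds[j], signed),
                        max(model.upper_bounds[j], signed),
                    )
                }
                fixes = {glucose_exchange: signed}
                v_at, _ = solve_fba(
                    model, sense="max", fixes=fixes, bound_overrides=bounds, lp=lp
                )
                ranges = solve_fva(
                    model,
                    reactions=reference.admissible,
                    fixes=fixes,
                    bound_overrides=bounds,
                    lp=lp,
                )
                frac = v_at / vgro_max if vgro_max else np.nan
            else:
                f = val
                target = f * vgro_max
                if mode == "upper_bound":
                    gb = (0.0, target)
                elif mode == "lower_bound":
                    gb = (target, vgro_max)
                else:  # both_bounds
                    gb = (target, target)
                ranges = solve_fva(
                    model,
                    reactions=reference.admissible,
                    bound_overrides={growth: gb},
                    lp=lp,
                )
                v_at, frac = target, f
            out_d.append(delta_measure(ranges, reference))
            out_ok.append(True)
        except InfeasibleError:
            out_d.append(np.nan)
            out_ok.append(False)
            v_at = np.nan
            frac = val if kind == "f" else np.nan
        out_f.append(frac)
        out_v.append(v_at)
    return GrowthScanResult(
        mode=mode,
        fractions=np.asarray(out_f),
        delta_tot=np.asarray(out_d),
        vgro=np.asarray(out_v),
        feasible=np.asarray(out_ok, dtype=bool),
    )


def default_grid(lo: float, hi: float, n: int = 20) -> np.ndarray:
    """n evenly spaced points on (lo, hi], endpoints included at the top."""
    return np.linspace(lo, hi, n + 1)[1:]
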