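"""Network reorganization under minimal metabolic adjustment.

An adaptation from a reference state (FBA optimum at glucose uptake 10) to
a lower glucose uptake is modeled with linear MoMA: the final flux state is
the feasible vector of the final condition closest, in Manhattan distance,
to the reference.  The degree of reorganization is the number of fluxes
that change by a large factor: increase to more than ``up_factor`` times
(default 2x) or decrease below ``down_factor`` times (default one tenth of)
their initial magnitude.  The asymmetric default interval reflects that
total flux scales roughly with glucose uptake, making decreases the more
likely direction when uptake falls.

Comparisons are on absolute flux values; reactions whose initial magnitude
is below ``eps_zero`` are excluded from the counts (a zero baseline has no
meaningful fold change) unless ``count_new_as_up`` is set, in which case a
flux appearing from (near) zero above ``eps_zero`` counts as an increase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lp import FluxVector, InfeasibleError, StoichiometricLP, solve_fba, solve_moma
from .model import MediumSpec, MetabolicModel, apply_medium

EPS_ZERO = 1e-6

GROWTH_MODES = ("free", "fixed_max")


@dataclass
class ChangeCounts:
    n_up: int
    n_down: int
    n_eligible: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


@dataclass
class AdaptationResult:
    grid: np.ndarray
    growth_mode: str
    distances: np.ndarray
    counts: list[ChangeCounts | None]
    vgro: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, d, c, v in zip(self.grid, self.distances, self.counts, self.vgro):
            row = {"glucose": g, "vgro": v, "moma_distance": d}
            if c is None:
                row["feasible"] = False
            else:
                row.update(
                    feasible=True,
                    n_up=c.n_up,
                    n_down=c.n_down,
                    n_total=c.n_total,
                    n_eligible=c.n_eligible,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def count_flux_changes(
    v_init,
    v_final,
    up_factor: float = 2.0,
    down_factor: float = 0.1,
    eps_zero: float = EPS_ZERO,
    count_new_as_up: bool = False,
) -> ChangeCounts:
    """Count large flux changes between two states of equal length."""
    vi = np.abs(np.asarray(v_init, dtype=float))
    vf = np.abs(np.asarray(v_final, dtype=float))
    if vi.shape != vf.shape:
        raise ValueError("flux vectors differ in length")
    if up_factor <= 0 or down_factor <= 0:
        raise ValueError("fold-change factors must be positive")
    eligible = vi >= eps_zero
    n_up = int(np.sum(eligible & (vf > up_factor * vi)))
    n_down = int(np.sum(eligible & (vf < down_factor * vi)))
    if count_new_as_up:
        n_up += int(np.sum(~eligible & (vf > eps_zero)))
    return ChangeCounts(n_up=n_up, n_down=n_down, n_eligible=int(eligible.sum()))


def adapt_moma_scan(
    model: MetabolicModel,
    medium: MediumSpec | None,
    glucose_grid: Sequence[float],
    growth_mode: str = "free",
    glucose_exchange: str = "EX_glc__D_e",
    initial_uptake: float = 10.0,
    v_ref: FluxVector | None = None,
    up_factor: float = 2.0,
    down_factor: float = 0.1,
    eps_zero: float = EPS_ZERO,
) -> AdaptationResult:
    """MoMA adaptation from the optimal-growth state at ``initial_uptake``
    to each glucose uptake on the grid.

    With ``growth_mode='fixed_max'`` the growth rate is additionally
    pinned at the FBA maximum of the final condition, so only internal and
    external variability are available for the adjustment; with ``'free'``
    growth variability is available too and the distance can only be
    smaller.  A caller-supplied ``v_ref`` overrides the initial FBA vertex
    (the optimum is degenerate in general).
    """
    if growth_mode not in GROWTH_MODES:
        raise ValueError(f"unknown growth mode {growth_mode!r}")
    if medium is not None:
        model = apply_medium(model, medium)
    lp = StoichiometricLP(model)
    if v_ref is None:
        signed0 = model.uptake_flux(glucose_exchange, initial_uptake)
        _, v_ref = solve_fba(
            model, sense="max", fixes={glucose_exchange: signed0}, lp=lp
        )
    ref_values = v_ref.fluxes.reindex(model.reaction_ids).to_numpy()

    grid = np.asarray(list(glucose_grid), dtype=float)
    distances = np.full(grid.shape, np.nan)
    vgros = np.full(grid.shape, np.nan)
    counts: list[ChangeCounts | None] = []
    for k, g in enumerate(grid):
        fixes = {glucose_exchange: model.uptake_flux(glucose_exchange, g)}
        try:
            if growth_mode == "fixed_max":
                vmax, _ = solve_fba(model, sense="max", fixes=fixes, lp=lp)
                fixes[model.biomass_reaction] = vmax
            dist, v_final = solve_moma(model, v_ref, fixes=fixes)
        except InfeasibleError:
            counts.append(None)
            continue
        distances[k] = dist
        vgros[k] = v_final[model.biomass_reaction]
        counts.append(
            count_flux_changes(
                ref_values,
                v_final.values,
                up_factor=up_factor,
                down_factor=down_factor,
                eps_zero=eps_zero,
            )
        )
    return AdaptationResult(
        grid=grid,
        growth_mode=growth_mode,
        distances=distances,
        counts=counts,
        vgro=vgros,
    )
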