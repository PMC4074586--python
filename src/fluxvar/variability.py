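"""The delta and sigma flux-variability measures and their decomposition.

Metabolic flexibility under a condition is compared against a fixed
reference condition (a glucose minimal medium for the E. coli runs).
With ``V_i^min/V_i^max`` the reference FVA interval of internal reaction
``i`` and ``j_i^min/j_i^max`` the interval under the condition of
interest,

    delta = (1 / |A|) * sum_{i in A} (j_i^max - j_i^min) / (V_i^max - V_i^min)

where ``A`` is the *admissible* internal set.  Two kinds of internal
reaction are excluded from ``A``:

* reactions with zero reference width (the ratio is 0/0 — blocked or
  always-pinned reactions carry no variability information);
* by default, reactions whose reference interval reaches the model's
  artificial bound cap (``|v|`` at the +-1000 placeholder bounds used by
  genome-scale reconstructions).  Such ranges are set by the placeholder
  caps on thermodynamically unconstrained (loop-carrying) cycles, not by
  stoichiometry and medium, so their "variability" is an artifact of the
  cap value.  Pass ``include_cap_limited=True`` to keep them.

The companion measure sigma is the variability of the summed internal
flux: ``sigma = sum_i (j_i^max - j_i^min) / sum_i (V_i^max - V_i^min)``
over the same admissible set.

Total variability splits additively into internal, external and growth
components obtained by successively releasing constraints from the
optimal-growth state: delta_int fixes growth and all exchanges at one
optimal-growth vertex, delta_int+ext fixes growth only, delta_tot fixes
neither; then delta_ext = delta_int+ext - delta_int and delta_gro =
delta_tot - delta_int+ext, so delta_tot = delta_int + delta_ext +
delta_gro by construction.  The optimal exchange pattern is degenerate in
general: different vertices can shift delta_int vs delta_ext individually,
but delta_int+ext and delta_gro are invariant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lp import (
    EPS_WIDTH,
    BoundSpec,
    FixSpec,
    FluxRanges,
    StoichiometricLP,
    solve_fba,
    solve_fva,
)
from .model import MediumSpec, MetabolicModel, apply_medium


class EmptyAdmissibleSetError(ValueError):
    """The reference condition has no variable internal reactions."""


@dataclass
class ReferenceState:
    """Reference FVA ranges over the internal reactions, with the admissible
    set (internal reactions whose reference width exceeds ``EPS_WIDTH`` and,
    by default, whose range is not capped by the placeholder bounds)."""

    ranges: FluxRanges
    admissible: list[str]
    cap_excluded: list[str]
    medium_name: str = "as-loaded"

    @property
    def widths(self) -> pd.Series:
        return self.ranges.widths

    @property
    def admissible_count(self) -> int:
        return len(self.admissible)


@dataclass
class VariabilityComponents:
    """The (delta_int, delta_ext, delta_gro, delta_tot) tuple for one
    condition, with optional sigma analogues and the fixes actually used
    (recording the degenerate-optimum choice)."""

    delta_int: float
    delta_ext: float
    delta_gro: float
    delta_tot: float
    vgro_max: float
    admissible_count: int
    sigma_int: float | None = None
    sigma_ext: float | None = None
    sigma_gro: float | None = None
    sigma_tot: float | None = None
    condition: dict = field(default_factory=dict)
    ext_vertex_hash: str = ""
    feasible: bool = True

    def as_dict(self) -> dict:
        out = {
            "feasible": self.feasible,
            "vgro_max": self.vgro_max,
            "delta_int": self.delta_int,
            "delta_ext": self.delta_ext,
            "delta_gro": self.delta_gro,
            "delta_tot": self.delta_tot,
            "admissible_count": self.admissible_count,
        }
        if self.sigma_tot is not None:
            out.update(
                sigma_int=self.sigma_int,
                sigma_ext=self.sigma_ext,
                sigma_gro=self.sigma_gro,
                sigma_tot=self.sigma_tot,
            )
        return out


def compute_reference_ranges(
    model: MetabolicModel,
    medium: MediumSpec | None = None,
    include_cap_limited: bool = False,
    cap: float | None = None,
    lp: StoichiometricLP | None = None,
) -> ReferenceState:
    """Full FVA of the internal reactions with nothing fixed under the
    reference medium; records the admissible set."""
    if medium is not None:
        model = apply_medium(model, medium)
        lp = None  # bounds changed; any supplied LP wrapper is stale
    internal = model.internal_ids
    ranges = solve_fva(model, reactions=internal, lp=lp)
    widths = ranges.widths
    cap = model.bound_cap if cap is None else cap
    cap_threshold = cap * (1.0 - 1e-4)
    capped = (
        (ranges.frame["maximum"] >= cap_threshold)
        | (ranges.frame["minimum"] <= -cap_threshold)
    )
    admissible, cap_excluded = [], []
    for rid in internal:
        if widths[rid] <= EPS_WIDTH:
            continue
        if capped[rid] and not include_cap_limited:
            cap_excluded.append(rid)
        else:
            admissible.append(rid)
    return ReferenceState(
        ranges=ranges,
        admissible=admissible,
        cap_excluded=cap_excluded,
        medium_name=medium.name if medium is not None else "as-loaded",
    )


def _ratio_table(ranges: FluxRanges, reference: ReferenceState) -> pd.DataFrame:
    if not reference.admissible:
        raise EmptyAdmissibleSetError("reference has no variable internal reactions")
    missing = [r for r in reference.admissible if r not in ranges.frame.index]
    if missing:
        raise ValueError(
            f"ranges do not cover the admissible set (missing {missing[:5]} ...)"
        )
    q = ranges.widths.loc[reference.admissible]
    v = reference.widths.loc[reference.admissible]
    return pd.DataFrame({"query": q, "reference": v})


def delta_measure(ranges: FluxRanges, reference: ReferenceState) -> float:
    """Average, over the admissible internal reactions, of the condition's
    FVA width relative to the reference width.  Not clamped: conditions
    looser than the reference may exceed 1."""
    t = _ratio_table(ranges, reference)
    return float((t["query"] / t["reference"]).mean())


def sigma_measure(ranges: FluxRanges, reference: ReferenceState) -> float:
    """Variability of the summed internal flux relative to reference:
    ratio of the summed FVA widths over the admissible internal set."""
    t = _ratio_table(ranges, reference)
    denom = float(t["reference"].sum())
    if denom <= EPS_WIDTH:
        raise EmptyAdmissibleSetError("zero reference spread for sigma")
    return float(t["query"].sum() / denom)


def decompose_variability(
    model: MetabolicModel,
    reference: ReferenceState,
    fixes: FixSpec | None = None,
    bound_overrides: BoundSpec | None = None,
    objective_reaction: str | None = None,
    with_sigma: bool = False,
    lp: StoichiometricLP | None = None,
) -> VariabilityComponents:
    """Three-way decomposition of flux variability for one condition.

    The condition is a set of fixes and/or bound overrides on the
    (already medium-conditioned) model used to build ``reference``.
    Exchanges fixed by the condition itself stay fixed throughout; the
    optimal-growth exchange pattern covers only the remaining exchanges.
    """
    fixes = dict(fixes or {})
    bound_overrides = dict(bound_overrides or {})
    lp = lp or StoichiometricLP(model)
    growth = model.biomass_reaction

    vgro_max, v_opt = solve_fba(
        model,
        objective_reaction=objective_reaction,
        sense="max",
        fixes=fixes,
        bound_overrides=bound_overrides,
        lp=lp,
    )
    ext_fixes = {
        rid: float(v_opt[rid]) for rid in model.exchange_ids if rid not in fixes
    }
    vertex_hash = hashlib.sha256(
        np.array(sorted(ext_fixes.items()), dtype=object).tobytes()
        if ext_fixes
        else b""
    ).hexdigest()[:16]

    def fva_with(extra: FixSpec) -> FluxRanges:
        merged = {**fixes, **extra}
        return solve_fva(
            model,
            reactions=reference.admissible,
            fixes=merged,
            bound_overrides=bound_overrides,
            lp=lp,
        )

    ranges_int = fva_with({growth: vgro_max, **ext_fixes})
    ranges_int_ext = fva_with({growth: vgro_max})
    ranges_tot = fva_with({})

    d_int = delta_measure(ranges_int, reference)
    d_int_ext = delta_measure(ranges_int_ext, reference)
    d_tot = delta_measure(ranges_tot, reference)

    sigmas = {}
    if with_sigma:
        s_int = sigma_measure(ranges_int, reference)
        s_int_ext = sigma_measure(ranges_int_ext, reference)
        s_tot = sigma_measure(ranges_tot, reference)
        sigmas = dict(
            sigma_int=s_int,
            sigma_ext=s_int_ext - s_int,
            sigma_gro=s_tot - s_int_ext,
            sigma_tot=s_tot,
        )

    return VariabilityComponents(
        delta_int=d_int,
        delta_ext=d_int_ext - d_int,
        delta_gro=d_tot - d_int_ext,
        delta_tot=d_tot,
        vgro_max=vgro_max,
        admissible_count=reference.admissible_count,
        condition={"fixes": dict(fixes), "bounds": dict(bound_overrides)},
        ext_vertex_hash=vertex_hash,
        **sigmas,
    )


def components_frame(rows: Sequence[VariabilityComponents], index=None) -> pd.DataFrame:
    """Tabulate a sequence of decompositions (one row per condition)."""
    return pd.DataFrame([r.as_dict() for r in rows], index=index)
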