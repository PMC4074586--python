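"""Core metabolic-model container, reaction classification, and media.

A genome-scale reconstruction is held as a sparse stoichiometry matrix
``N`` (m metabolites x r reactions) with per-reaction flux bounds
``alpha_i <= v_i <= beta_i`` (mmol gDW^-1 h^-1; the biomass flux is the
growth rate in h^-1).  Every reaction belongs to exactly one of three
classes:

* ``growth`` -- the biomass pseudo-reaction (exactly one per model);
* ``exchange`` -- boundary reactions with a single nonzero stoichiometric
  entry (uptakes, secretions, sinks/demands);
* ``internal`` -- everything else, including ATP-maintenance reactions,
  which involve several metabolites and therefore stay internal under the
  single-entry rule.

Sign convention: internally, fluxes are stored BiGG-signed (an exchange
written ``A ->`` carries negative flux during uptake).  All user-facing
uptake quantities are positive magnitudes; :meth:`MetabolicModel.uptake_flux`
and :meth:`MetabolicModel.uptake_rate` convert exactly once at that
boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import sparse

#: Conventional magnitude standing in for an unbounded flux (BiGG usage).
UNBOUNDED = 1000.0

_EPS_BOUND = 1e-9


class ModelError(ValueError):
    """Raised for structurally invalid models or media."""


class ReactionClass(str, enum.Enum):
    INTERNAL = "internal"
    EXCHANGE = "exchange"
    GROWTH = "growth"


@dataclass
class MetabolicModel:
    """Stoichiometric model: identifiers, sparse N, bounds, biomass reaction."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: sparse.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    biomass_reaction: str
    model_id: str = "model"
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)
    _classes: dict[str, ReactionClass] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.stoichiometry = sparse.csc_matrix(self.stoichiometry)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise ModelError(f"unknown reaction id: {reaction_id!r}") from None

    def validate(self) -> None:
        m, r = self.stoichiometry.shape
        if m != self.n_metabolites or r != self.n_reactions:
            raise ModelError(
                f"stoichiometry shape {(m, r)} does not match "
                f"{self.n_metabolites} metabolites x {self.n_reactions} reactions"
            )
        if len(self._rxn_index) != r:
            raise ModelError("duplicate reaction ids")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds + _EPS_BOUND)[0]
        if bad.size:
            names = [self.reaction_ids[i] for i in bad[:5]]
            raise ModelError(f"lower bound exceeds upper bound for {names}")
        if self.biomass_reaction not in self._rxn_index:
            raise ModelError(
                f"biomass reaction {self.biomass_reaction!r} is not in the model"
            )

    # -- classification ----------------------------------------------------
    @property
    def reaction_classes(self) -> dict[str, ReactionClass]:
        if self._classes is None:
            self._classes = classify_reactions(self, self.biomass_reaction)
        return self._classes

    def reactions_of_class(self, cls: ReactionClass) -> list[str]:
        return [r for r, c in self.reaction_classes.items() if c is cls]

    @property
    def exchange_ids(self) -> list[str]:
        return self.reactions_of_class(ReactionClass.EXCHANGE)

    @property
    def internal_ids(self) -> list[str]:
        return self.reactions_of_class(ReactionClass.INTERNAL)

    # -- sign convention ---------------------------------------------------
    def _exchange_coeff(self, reaction_id: str) -> float:
        j = self.index(reaction_id)
        col = self.stoichiometry.getcol(j)
        if col.nnz != 1:
            raise ModelError(f"{reaction_id!r} is not an exchange reaction")
        return float(col.data[0])

    def uptake_flux(self, reaction_id: str, uptake: float) -> float:
        """Signed flux corresponding to a positive uptake magnitude."""
        return math.copysign(1.0, self._exchange_coeff(reaction_id)) * uptake

    def uptake_rate(self, reaction_id: str, flux: float) -> float:
        """Positive-uptake-magnitude reading of a signed exchange flux.

        Negative values mean net secretion.
        """
        return math.copysign(1.0, self._exchange_coeff(reaction_id)) * flux

    # -- copies ------------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            stoichiometry=self.stoichiometry.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            biomass_reaction=self.biomass_reaction,
            model_id=self.model_id,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """A copy with ``{reaction_id: (lb, ub)}`` overrides applied."""
        out = self.copy()
        for rid, (lb, ub) in bounds.items():
            j = out.index(rid)
            out.lower_bounds[j] = lb
            out.upper_bounds[j] = ub
        out.validate()
        return out

    @property
    def bound_cap(self) -> float:
        """Largest finite bound magnitude (the model's 'infinity' stand-in)."""
        mags = np.concatenate([np.abs(self.lower_bounds), np.abs(self.upper_bounds)])
        mags = mags[np.isfinite(mags)]
        return float(mags.max()) if mags.size else UNBOUNDED


def classify_reactions(
    model: MetabolicModel, biomass_id: str
) -> dict[str, ReactionClass]:
    """Total classification: biomass -> growth, single-entry columns ->
    exchange, everything else internal."""
    if biomass_id not in model._rxn_index:
        raise ModelError(f"biomass reaction {biomass_id!r} is not in the model")
    nnz_per_col = np.diff(sparse.csc_matrix(model.stoichiometry).indptr)
    out: dict[str, ReactionClass] = {}
    for j, rid in enumerate(model.reaction_ids):
        if rid == biomass_id:
            out[rid] = ReactionClass.GROWTH
        elif nnz_per_col[j] == 1:
            out[rid] = ReactionClass.EXCHANGE
        else:
            out[rid] = ReactionClass.INTERNAL
    return out


@dataclass(frozen=True)
class MediumSpec:
    """Exchange-reaction uptake/secretion limits, positive magnitudes.

    ``exchanges`` maps exchange-reaction id to ``(uptake_limit,
    secretion_limit)``; ``None`` for a secretion limit means unbounded.
    Exchanges absent from the map are closed for uptake and left free for
    secretion.  ``aerobic`` toggles the oxygen exchange: when False its
    uptake limit is forced to zero regardless of the listed value.
    """

    exchanges: Mapping[str, tuple[float, float | None]]
    name: str = "medium"
    aerobic: bool = True
    oxygen_exchange: str = "EX_o2_e"

    def __post_init__(self) -> None:
        for rid, (up, sec) in self.exchanges.items():
            if up < 0 or (sec is not None and sec < 0):
                raise ModelError(f"negative limit for {rid!r} in medium {self.name!r}")

    def with_aerobic(self, aerobic: bool) -> "MediumSpec":
        return replace(self, aerobic=aerobic)

    @classmethod
    def from_yaml(cls, path) -> "MediumSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        exchanges = {}
        for rid, entry in (doc.get("exchanges") or {}).items():
            if isinstance(entry, (int, float)):
                uptake, secretion = float(entry), None
            else:
                uptake = float(entry.get("uptake", 0.0))
                sec = entry.get("secretion", "unbounded")
                secretion = None if sec in (None, "unbounded") else float(sec)
            exchanges[rid] = (uptake, secretion)
        return cls(
            exchanges=exchanges,
            name=doc.get("name", "medium"),
            aerobic=bool(doc.get("aerobic", True)),
            oxygen_exchange=doc.get("oxygen_exchange", "EX_o2_e"),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "aerobic": self.aerobic,
            "oxygen_exchange": self.oxygen_exchange,
            "exchanges": {
                rid: {
                    "uptake": up,
                    "secretion": "unbounded" if sec is None else sec,
                }
                for rid, (up, sec) in self.exchanges.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Condition a model on a medium; returns a new model, input unchanged.

    Listed exchanges get their uptake-direction bound set to the uptake
    limit and the secretion-direction bound to the secretion limit
    (``UNBOUNDED`` when unlimited); unlisted exchanges are closed for
    uptake and unbounded for secretion.  Idempotent for a fixed medium.
    """
    out = model.copy()
    exchange_set = set(out.exchange_ids)
    for rid in medium.exchanges:
        if rid not in out._rxn_index:
            raise ModelError(f"medium lists unknown reaction {rid!r}")
        if rid not in exchange_set:
            raise ModelError(f"medium lists non-exchange reaction {rid!r}")

    for rid in exchange_set:
        uptake, secretion = medium.exchanges.get(rid, (0.0, None))
        if not medium.aerobic and rid == medium.oxygen_exchange:
            uptake = 0.0
        sec_mag = UNBOUNDED if secretion is None else secretion
        j = out.index(rid)
        if out._exchange_coeff(rid) < 0:  # uptake = negative flux
            out.lower_bounds[j] = -uptake
            out.upper_bounds[j] = sec_mag
        else:  # uptake = positive flux
            out.upper_bounds[j] = uptake
            out.lower_bounds[j] = -sec_mag
    out.validate()
    return out


def build_model(
    model_id: str,
    metabolites: Iterable[str],
    reactions: list[tuple[str, dict[str, float], float, float]],
    biomass: str,
) -> MetabolicModel:
    """Assemble a model from ``(id, {metabolite: coeff}, lb, ub)`` rows."""
    met_ids = list(metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    rids, lbs, ubs = [], [], []
    for j, (rid, stoich, lb, ub) in enumerate(reactions):
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for met, coeff in stoich.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rids))
    )
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        stoichiometry=S,
        lower_bounds=np.array(lbs, dtype=float),
        upper_bounds=np.array(ubs, dtype=float),
        biomass_reaction=biomass,
        model_id=model_id,
    )
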