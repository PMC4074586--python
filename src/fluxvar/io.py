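"""Reading and writing constraint-based models.

Supported dialects: BiGG-style JSON and SBML Level 3 (+ FBC v2).  The
biomass reaction is taken from the model objective; an objective with more
than one nonzero coefficient is rejected as ambiguous.  ``.gz`` files are
decompressed transparently.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
from lxml import etree

from .model import MetabolicModel, ModelError, build_model

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model, auto-detecting BiGG JSON vs SBML-FBC from the suffix.

    ``format`` may be ``"bigg-json"`` or ``"sbml-fbc"`` to force a dialect.
    """
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        format = "bigg-json" if stem.endswith(".json") else "sbml-fbc"
    if format == "bigg-json":
        return read_bigg_json(path)
    if format == "sbml-fbc":
        return read_sbml_fbc(path)
    raise ModelError(f"unknown model format {format!r}")


def _pick_biomass(candidates: list[str]) -> str:
    if not candidates:
        raise ModelError("model declares no objective reaction")
    if len(candidates) > 1:
        raise ModelError(
            "ambiguous objective: more than one nonzero coefficient "
            f"({', '.join(sorted(candidates))})"
        )
    return candidates[0]


def read_bigg_json(path) -> MetabolicModel:
    with _open_text(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelError(f"could not parse {path} as JSON: {exc}") from exc
    try:
        metabolites = [m["id"] for m in doc["metabolites"]]
        raw_reactions = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelError(f"{path} is not a BiGG-style model document") from exc

    reactions = []
    objective = []
    for rxn in raw_reactions:
        rid = rxn["id"]
        if "lower_bound" not in rxn or "upper_bound" not in rxn:
            raise ModelError(f"reaction {rid!r} is missing flux bounds")
        reactions.append(
            (
                rid,
                {m: float(c) for m, c in rxn.get("metabolites", {}).items()},
                float(rxn["lower_bound"]),
                float(rxn["upper_bound"]),
            )
        )
        if float(rxn.get("objective_coefficient", 0.0)) != 0.0:
            objective.append(rid)
    biomass = _pick_biomass(objective)
    return build_model(doc.get("id", "model"), metabolites, reactions, biomass)


def _strip_sbml_prefix(sid: str, prefix: str) -> str:
    # SBML ids conventionally prepend R_/M_ to reaction/species names
    return sid[len(prefix):] if sid and sid.startswith(prefix) else sid


def read_sbml_fbc(path) -> MetabolicModel:
    with _open_text(path) as fh:
        try:
            tree = etree.parse(fh)
        except etree.XMLSyntaxError as exc:
            raise ModelError(f"could not parse {path} as SBML: {exc}") from exc
    root = tree.getroot()
    model = root.find(f"{{{_SBML_NS}}}model")
    if model is None:
        raise ModelError(f"{path} has no <model> element")

    def findall(parent, *names):
        node = parent
        for name in names[:-1]:
            node = node.find(f"{{{_SBML_NS}}}{name}")
            if node is None:
                return []
        return node.findall(f"{{{_SBML_NS}}}{names[-1]}")

    # global flux-bound parameters
    parameters = {
        p.get("id"): float(p.get("value"))
        for p in findall(model, "listOfParameters", "parameter")
    }

    # species; boundary-condition species are outside the balanced system
    metabolites: list[str] = []
    boundary: set[str] = set()
    for sp in findall(model, "listOfSpecies", "species"):
        sid = sp.get("id")
        if sp.get("boundaryCondition") == "true":
            boundary.add(sid)
        else:
            metabolites.append(_strip_sbml_prefix(sid, "M_"))

    reactions = []
    for rxn in findall(model, "listOfReactions", "reaction"):
        rid = _strip_sbml_prefix(rxn.get("id"), "R_")
        stoich: dict[str, float] = {}
        for tag, sign in (("listOfReactants", -1.0), ("listOfProducts", 1.0)):
            for ref in findall(rxn, tag, "speciesReference"):
                sid = ref.get("species")
                if sid in boundary:
                    continue
                met = _strip_sbml_prefix(sid, "M_")
                coeff = sign * float(ref.get("stoichiometry", "1"))
                stoich[met] = stoich.get(met, 0.0) + coeff
        lb_ref = rxn.get(f"{{{_FBC_NS}}}lowerFluxBound")
        ub_ref = rxn.get(f"{{{_FBC_NS}}}upperFluxBound")
        if lb_ref is None or ub_ref is None:
            raise ModelError(f"reaction {rid!r} is missing fbc flux bounds")
        try:
            lb, ub = parameters[lb_ref], parameters[ub_ref]
        except KeyError as exc:
            raise ModelError(f"undefined bound parameter for {rid!r}") from exc
        reactions.append((rid, stoich, lb, ub))

    objective = []
    fbc_objectives = model.find(f"{{{_FBC_NS}}}listOfObjectives")
    if fbc_objectives is not None:
        active = fbc_objectives.get(f"{{{_FBC_NS}}}activeObjective")
        for obj in fbc_objectives.findall(f"{{{_FBC_NS}}}objective"):
            if active and obj.get(f"{{{_FBC_NS}}}id") != active:
                continue
            flux_objs = obj.find(f"{{{_FBC_NS}}}listOfFluxObjectives")
            if flux_objs is None:
                continue
            for fo in flux_objs.findall(f"{{{_FBC_NS}}}fluxObjective"):
                if float(fo.get(f"{{{_FBC_NS}}}coefficient", "0")) != 0.0:
                    objective.append(
                        _strip_sbml_prefix(fo.get(f"{{{_FBC_NS}}}reaction"), "R_")
                    )
    biomass = _pick_biomass(objective)
    return build_model(model.get("id", "model"), metabolites, reactions, biomass)


def write_bigg_json(model: MetabolicModel, path) -> None:
    """Serialize to BiGG-style JSON; re-reading reproduces N, bounds and
    classes exactly (floats round-trip via repr)."""
    S = model.stoichiometry.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j)
        mets = {
            model.metabolite_ids[i]: float(v)
            for i, v in zip(col.indices, col.data)
        }
        reactions.append(
            {
                "id": rid,
                "metabolites": mets,
                "lower_bound": _as_json_float(model.lower_bounds[j]),
                "upper_bound": _as_json_float(model.upper_bounds[j]),
                "objective_coefficient": 1.0 if rid == model.biomass_reaction else 0.0,
            }
        )
    doc = {
        "id": model.model_id,
        "metabolites": [{"id": m} for m in model.metabolite_ids],
        "reactions": reactions,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _as_json_float(x: float) -> float:
    # JSON has no Infinity; fall back to the conventional +-1e6 sentinel
    if np.isposinf(x):
        return 1e6
    if np.isneginf(x):
        return -1e6
    return float(x)
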