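"""Model and expression-table I/O.

Two on-disk model dialects are supported:

* **SBML** (Level 3 + FBC: flux bounds, objective, gene associations),
  read and written through cobrapy/libSBML.  Only the subset needed for
  constraint-based analysis is preserved; groups and rich annotations are
  ignored.
* A **tabular reaction-list dialect**: a reactions TSV (textual equations
  with ``[compartment]`` suffixes and ``-->``/``<=>`` arrows) plus a
  metabolite-list TSV carrying names, elemental formulas and tags.

Gene-expression input is a TSV of ``gene_id`` plus one nonnegative TPM
column per replicate.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .model_core import (
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    met_base_id,
    met_compartment,
)

__all__ = [
    "ExpressionTable",
    "read_sbml",
    "write_sbml",
    "read_model_table",
    "write_model_table",
    "read_expression_table",
    "write_expression_table",
    "parse_equation",
    "format_equation",
]

DEFAULT_BOUND = 1000.0  # conventional "unbounded" flux magnitude


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Per-gene TPM values across replicates (``data``: gene x replicate)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValueError("expression table needs at least one replicate column")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if (self.data.values < 0).any():
            raise ValueError("negative TPM values are not permitted")

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    @property
    def replicates(self) -> List[str]:
        return list(self.data.columns)


def read_expression_table(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene_id column plus >=1 replicate columns")
    df = df.set_index(df.columns[0])
    df = df.astype(float)
    return ExpressionTable(df)


def write_expression_table(table: ExpressionTable, path) -> None:
    out = table.data.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# tabular reaction-list dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->")

REACTION_COLUMNS = [
    "reaction_id",
    "name",
    "equation",
    "lower_bound",
    "upper_bound",
    "gene_association",
    "subsystem",
    "kind",
    "objective_coefficient",
]

METABOLITE_COLUMNS = ["metabolite_id", "name", "formula", "compartment", "tags"]


def parse_equation(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"2 atp[h] + h2o[h] <=> adp[h] + pi[h]"``.

    Returns (stoichiometry, reversible).  Either side may be empty
    (exchange reactions touch a single metabolite).
    """
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ValueError(f"equation {equation!r}: no '-->' or '<=>' arrow")
    lhs, rhs = equation.split(arrow, 1)
    stoich: Dict[str, float] = {}

    def _add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s+\+\s+", side):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$", term)
            if m is None:
                raise ValueError(f"equation {equation!r}: cannot parse term {term!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    _add(lhs, -1.0)
    _add(rhs, +1.0)
    if not stoich:
        raise ValueError(f"equation {equation!r}: no metabolites")
    return stoich, arrow == "<=>"


def format_equation(rxn: Reaction) -> str:
    def _side(items):
        parts = []
        for mid, coeff in items:
            c = abs(coeff)
            parts.append(mid if c == 1.0 else f"{c:.17g} {mid}")
        return " + ".join(parts)

    lhs = _side((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    rhs = _side((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{lhs} {arrow} {rhs}".strip()


def _infer_kind(rxn_id: str, name: str, stoich: Dict[str, float]) -> str:
    label = f"{rxn_id} {name}".lower()
    if "biomass" in label:
        return "biomass"
    if len(stoich) == 1:
        return "exchange"
    probe = Reaction(id="_probe", stoichiometry=dict(stoich))
    if probe.is_one_to_one_transport():
        return "transport"
    return "internal"


def _metabolites_path_for(reactions_path) -> Path:
    p = Path(reactions_path)
    if ".reactions." in p.name:
        return p.with_name(p.name.replace(".reactions.", ".metabolites."))
    return p.with_name(p.stem + ".metabolites" + p.suffix)


def read_model_table(path, metabolites_path=None) -> MetabolicModel:
    """Read a model from the tabular dialect.

    ``path`` is the reactions TSV; the metabolite list is looked for at
    ``metabolites_path`` or, by convention, alongside with ``.metabolites.``
    in place of ``.reactions.``.
    """
    path = Path(path)
    if metabolites_path is None:
        metabolites_path = _metabolites_path_for(path)
    model = MetabolicModel(id=path.name.split(".")[0])

    mdf = pd.read_csv(metabolites_path, sep="\t", dtype=str).fillna("")
    for _, row in mdf.iterrows():
        tags = {t for t in str(row.get("tags", "")).split("|") if t}
        model.add_metabolite(
            Metabolite(
                id=row["metabolite_id"],
                name=row.get("name", ""),
                formula=row.get("formula", ""),
                compartment_id=row.get("compartment", ""),
                tags=tags,
            )
        )

    rdf = pd.read_csv(path, sep="\t")
    for lineno, row in enumerate(rdf.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            stoich, reversible = parse_equation(str(row["equation"]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        ub = row.get("upper_bound")
        lb = row.get("lower_bound")
        ub = DEFAULT_BOUND if ub is None or pd.isna(ub) else float(ub)
        lb = (-ub if reversible else 0.0) if lb is None or pd.isna(lb) else float(lb)
        gene = row.get("gene_association")
        gene = "" if gene is None or pd.isna(gene) else str(gene)
        name = row.get("name")
        name = "" if name is None or pd.isna(name) else str(name)
        subsystem = row.get("subsystem")
        subsystem = "" if subsystem is None or pd.isna(subsystem) else str(subsystem)
        kind = row.get("kind")
        if kind is None or pd.isna(kind) or not str(kind):
            kind = _infer_kind(str(row["reaction_id"]), name, stoich)
        try:
            model.add_reaction(
                Reaction(
                    id=str(row["reaction_id"]),
                    name=name,
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gene_association=gene,
                    kind=str(kind),
                    subsystem=subsystem,
                )
            )
        except ModelIntegrityError as exc:
            raise ModelIntegrityError(f"{path}:{lineno}: {exc}") from exc
        obj = row.get("objective_coefficient")
        if obj is not None and not pd.isna(obj) and float(obj) != 0.0:
            model.objective[str(row["reaction_id"])] = float(obj)
    model.validate()
    return model


def write_model_table(model: MetabolicModel, path, metabolites_path=None) -> None:
    path = Path(path)
    if metabolites_path is None:
        metabolites_path = _metabolites_path_for(path)
    mrows = [
        {
            "metabolite_id": m.id,
            "name": m.name,
            "formula": m.formula,
            "compartment": m.compartment_id,
            "tags": "|".join(sorted(m.tags)),
        }
        for m in model.metabolites.values()
    ]
    pd.DataFrame(mrows, columns=METABOLITE_COLUMNS).to_csv(
        metabolites_path, sep="\t", index=False
    )
    rrows = []
    for rxn in model.reactions.values():
        rrows.append(
            {
                "reaction_id": rxn.id,
                "name": rxn.name,
                "equation": format_equation(rxn),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "gene_association": rxn.gene_association,
                "subsystem": rxn.subsystem,
                "kind": rxn.kind,
                "objective_coefficient": model.objective.get(rxn.id, 0.0),
            }
        )
    pd.DataFrame(rrows, columns=REACTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# SBML (via cobrapy / libSBML)
# ---------------------------------------------------------------------------

def _sbml_met_id(met_id: str) -> str:
    base, comp = met_base_id(met_id), met_compartment(met_id)
    safe = re.sub(r"\W", "_", base)
    return f"{safe}__{comp}" if comp else safe


def _internal_met_id(cobra_met) -> str:
    mid, comp = cobra_met.id, cobra_met.compartment or ""
    if comp and mid.endswith(f"__{comp}"):
        mid = mid[: -(len(comp) + 2)]
    elif comp and mid.endswith(f"_{comp}"):
        mid = mid[: -(len(comp) + 1)]
    return f"{mid}[{comp}]" if comp else mid


def write_sbml(model: MetabolicModel, path) -> None:
    """Serialize to SBML L3+FBC.  Tags and reaction kinds ride in notes."""
    import cobra

    cmodel = cobra.Model(model.id)
    cmodel.compartments = {c: c for c in model.compartments}
    cmets = {}
    for met in model.metabolites.values():
        cm = cobra.Metabolite(
            _sbml_met_id(met.id),
            name=met.name,
            formula=met.formula or None,
            compartment=met.compartment_id or None,
        )
        if met.tags:
            cm.notes["symbioflux_tags"] = "|".join(sorted(met.tags))
        cmets[met.id] = cm
    cmodel.add_metabolites(list(cmets.values()))

    creactions = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(
            rxn.id,
            name=rxn.name,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        cr.notes["symbioflux_kind"] = rxn.kind
        if rxn.subsystem:
            cr.subsystem = rxn.subsystem
        creactions.append(cr)
    cmodel.add_reactions(creactions)
    for rxn in model.reactions.values():
        cr = cmodel.reactions.get_by_id(rxn.id)
        cr.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gene_association:
            cr.gene_reaction_rule = rxn.gene_association
    if model.objective:
        cmodel.objective = {
            cmodel.reactions.get_by_id(r): c for r, c in model.objective.items()
        }
    else:
        warnings.warn(f"model {model.id}: writing SBML with empty objective")
    cobra.io.write_sbml_model(cmodel, str(path))


def read_sbml(path) -> MetabolicModel:
    """Read an SBML L3+FBC model into a :class:`MetabolicModel`.

    Bounds and objective coefficients are preserved; reaction kinds and
    metabolite tags are restored from notes when present and inferred
    structurally otherwise.
    """
    import cobra
    from cobra.util.solver import linear_reaction_coefficients

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmodel = cobra.io.read_sbml_model(str(path))
    model = MetabolicModel(id=cmodel.id or Path(path).stem)
    model.compartments = list(cmodel.compartments)
    id_map = {}
    for cm in cmodel.metabolites:
        mid = _internal_met_id(cm)
        tags = set()
        note = cm.notes.get("symbioflux_tags")
        if note:
            tags = {t for t in str(note).split("|") if t}
        model.add_metabolite(
            Metabolite(
                id=mid,
                name=cm.name or "",
                formula=cm.formula or "",
                compartment_id=cm.compartment or "",
                tags=tags,
            )
        )
        id_map[cm.id] = mid
    for cr in cmodel.reactions:
        stoich = {id_map[m.id]: c for m, c in cr.metabolites.items()}
        kind = cr.notes.get("symbioflux_kind") or _infer_kind(cr.id, cr.name or "", stoich)
        model.add_reaction(
            Reaction(
                id=cr.id,
                name=cr.name or "",
                stoichiometry=stoich,
                lower_bound=cr.lower_bound,
                upper_bound=cr.upper_bound,
                gene_association=cr.gene_reaction_rule or "",
                kind=str(kind),
                subsystem=cr.subsystem or "",
            )
        )
    coeffs = linear_reaction_coefficients(cmodel)
    model.objective = {r.id: float(c) for r, c in coeffs.items() if c}
    if not model.objective:
        warnings.warn(f"{path}: SBML model has no objective")
    model.validate()
    return model
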