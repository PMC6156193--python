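"""Core data model for compartmentalized metabolic networks.

A :class:`MetabolicModel` is the in-memory representation shared by every
stage of the pipeline: metabolites carry Hill-style elemental formulas (the
basis of the nitrogen budgeting), reactions carry flux bounds in
mmol gDW⁻¹ h⁻¹ and an optional boolean gene association, and the model
assembles into the stoichiometric matrix ``S`` consumed by the linear
programs.

Conventions
-----------
* Metabolite ids are suffixed with their compartment in square brackets,
  e.g. ``"gln[h]"`` for glutamine in the host compartment.  The suffix is
  the single source of truth for provenance after models are merged.
* Stoichiometric coefficients are signed: negative = consumed,
  positive = produced.
* Pseudo-metabolites (biomass aggregates) carry an empty formula and are
  excluded from elemental budgets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "FormulaError",
    "ModelIntegrityError",
    "parse_formula",
    "element_count",
    "build_matrix",
    "check_mass_balance",
    "met_base_id",
    "met_compartment",
]

#: labels a metabolite may carry; drives medium exclusion and report classes
METABOLITE_TAGS = {"mineral", "cofactor", "eaa", "b_vitamin", "central_carbon", "other"}

#: reaction roles within a model
REACTION_KINDS = {"internal", "transport", "exchange", "biomass", "objective"}


class FormulaError(ValueError):
    """Raised for malformed elemental formulas or missing formulas."""


class ModelIntegrityError(ValueError):
    """Raised when a model violates referential integrity."""


_ELEMENT_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-style elemental formula into element -> count.

    The grammar is deliberately small: a sequence of element symbols (one
    capital letter optionally followed by one lowercase letter) each with an
    optional positive integer count (absent count = 1).  No charges, isotopes
    or parentheses -- elemental budgeting only needs atom counts.

    >>> parse_formula("C5H10N2O3")
    {'C': 5, 'H': 10, 'N': 2, 'O': 3}
    """
    if not formula:
        raise FormulaError("empty formula")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _ELEMENT_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected character "
                f"{formula[pos]!r} at position {pos}"
            )
        element, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(
                f"malformed formula {formula!r}: nonpositive count at position {pos}"
            )
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``id`` embeds the compartment suffix (``"glc[e]"``); ``formula`` may be
    empty only for abstract biomass/pseudo-metabolites.
    """

    id: str
    name: str = ""
    formula: str = ""
    compartment_id: str = ""
    tags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = self.tags - METABOLITE_TAGS
        if bad:
            raise ValueError(f"unknown metabolite tags {sorted(bad)} on {self.id}")
        if not self.compartment_id:
            self.compartment_id = met_compartment(self.id) or ""

    @property
    def base_id(self) -> str:
        """Species identity with the compartment suffix stripped."""
        return met_base_id(self.id)

    def elements(self) -> Dict[str, int]:
        if not self.formula:
            raise FormulaError(f"metabolite {self.id!r} has no formula")
        return parse_formula(self.formula)


def met_base_id(met_id: str) -> str:
    """``"gln[h]" -> "gln"``; ids without a suffix pass through."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id[: met_id.rindex("[")]
    return met_id


def met_compartment(met_id: str) -> Optional[str]:
    """``"gln[h]" -> "h"``; ``None`` when no suffix is present."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id[met_id.rindex("[") + 1 : -1]
    return None


def element_count(met: Metabolite, element: str) -> int:
    """Atoms of ``element`` per molecule of ``met`` (0 if absent).

    A metabolite without a formula raises :class:`FormulaError` rather than
    silently counting 0 -- budgets must not quietly drop species.
    """
    return met.elements().get(element, 0)


@dataclass
class Reaction:
    """A bounded reaction; ``stoichiometry`` maps metabolite id -> coefficient."""

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_association: str = ""
    kind: str = "internal"
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r} on {self.id}")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def compartments(self) -> Set[str]:
        comps = set()
        for mid in self.stoichiometry:
            c = met_compartment(mid)
            if c is not None:
                comps.add(c)
        return comps

    def is_one_to_one_transport(self) -> bool:
        """True when the reaction moves one species 1:1 between two compartments."""
        if len(self.stoichiometry) != 2:
            return False
        (m1, c1), (m2, c2) = self.stoichiometry.items()
        if met_base_id(m1) != met_base_id(m2):
            return False
        if len({met_compartment(m1), met_compartment(m2)}) != 2:
            return False
        return np.isclose(c1, -c2) and abs(c1) > 0


@dataclass
class MetabolicModel:
    """A (possibly multi-compartment) metabolic network."""

    id: str
    compartments: List[str] = field(default_factory=list)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective: Dict[str, float] = field(default_factory=dict)
    genes: Set[str] = field(default_factory=set)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        if met.compartment_id and met.compartment_id not in self.compartments:
            self.compartments.append(met.compartment_id)
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelIntegrityError(
                f"reaction {rxn.id} references unknown metabolites: {missing}"
            )
        self.reactions[rxn.id] = rxn
        self.genes.update(_genes_of(rxn.gene_association))

    # -- reported counts -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        """Referential integrity: reactions and objective refer to known ids."""
        for rxn in self.reactions.values():
            missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
            if missing:
                raise ModelIntegrityError(
                    f"reaction {rxn.id} references unknown metabolites: {missing}"
                )
        dangling = [r for r in self.objective if r not in self.reactions]
        if dangling:
            raise ModelIntegrityError(f"objective references unknown reactions: {dangling}")

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]


def _genes_of(gene_association: str) -> Set[str]:
    if not gene_association:
        return set()
    tokens = re.split(r"[()\s]+", gene_association)
    return {t for t in tokens if t and t.lower() not in {"and", "or"}}


@dataclass
class StoichiometricMatrix:
    """``S`` with explicit row (metabolite) and column (reaction) orderings."""

    metabolite_ids: List[str]
    reaction_ids: List[str]
    matrix: sparse.csc_matrix

    @property
    def shape(self):
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def column(self, reaction_id: str) -> Dict[str, float]:
        """Reconstruct one reaction's stoichiometry from its column."""
        j = self.reaction_ids.index(reaction_id)
        col = self.matrix.getcol(j).tocoo()
        return {self.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}


def build_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble the stoichiometric matrix in declared id order.

    Ordering follows insertion order of the model's collections so that the
    LP stage is deterministic.
    """
    model.validate()
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows: List[int] = []
    cols: List[int] = []
    data: List[float] = []
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coeff))
    mat = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return StoichiometricMatrix(met_ids, rxn_ids, mat)


def check_mass_balance(
    reaction: Reaction, model: MetabolicModel
) -> Optional[Dict[str, float]]:
    """Elemental imbalance of a reaction: element -> sum(coeff * atom count).

    Balanced reactions return all-zero maps.  Exchange/biomass reactions and
    reactions touching formula-less metabolites are not checkable and return
    ``None`` ("unchecked") rather than a fake zero.
    """
    if reaction.kind in {"exchange", "biomass", "objective"}:
        return None
    imbalance: Dict[str, float] = {}
    for mid, coeff in reaction.stoichiometry.items():
        met = model.metabolites[mid]
        if not met.formula:
            return None
        for element, n in met.elements().items():
            imbalance[element] = imbalance.get(element, 0.0) + coeff * n
    return {e: v for e, v in imbalance.items()}


def mass_balance_report(model: MetabolicModel, atol: float = 1e-9):
    """(unbalanced, unchecked) reaction id lists for a whole model."""
    unbalanced: List[str] = []
    unchecked: List[str] = []
    for rxn in model.reactions.values():
        result = check_mass_balance(rxn, model)
        if result is None:
            unchecked.append(rxn.id)
        elif any(abs(v) > atol for v in result.values()):
            unbalanced.append(rxn.id)
    return unbalanced, unchecked
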