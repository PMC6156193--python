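"""Metabolite exchange classification and cross-feeding detection.

Given an optimal flux solution for the integrated model, these routines
recover what each compartment imports and exports (net, thresholded),
which host-derived metabolites the two symbionts share, which metabolites
pass exclusively between the symbionts (cross-feeding), and how the
essential-amino-acid (EAA) release is split between the symbionts and
consumed by the host.

Accounting is *net* per (metabolite species, compartment): opposing
transport fluxes for the same species are summed before thresholding, so a
species relayed through a compartment with no net consumption does not
appear in that compartment's profile.  That is exactly the property used to
recognize symbiont-to-symbiont cross-feeding in a topology where all
transport passes through the host interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .integration import MultiCompartmentModel
from .model_core import Metabolite, met_base_id
from .optimization import FluxSolution

__all__ = [
    "ExchangeProfile",
    "CrossFeedRecord",
    "EAAReleaseReport",
    "classify_exchanges",
    "shared_unique_sets",
    "detect_cross_feeding",
    "eaa_release_accounting",
]

EXCHANGE_THRESHOLD = 1e-6          # mmol gDW-1 h-1 (paper's significance cutoff)
DEFAULT_EXEMPT_TAGS = frozenset({"mineral", "cofactor"})


@dataclass
class ExchangeProfile:
    """Net imports/exports of one compartment (fluxes positive)."""

    compartment: str
    imports: Dict[str, float] = field(default_factory=dict)
    exports: Dict[str, float] = field(default_factory=dict)
    #: species kept despite sub-threshold flux because of an exempt tag
    exempt_flagged: Set[str] = field(default_factory=set)
    #: metabolite class (tag) -> count, per direction
    import_counts_by_class: Dict[str, int] = field(default_factory=dict)
    export_counts_by_class: Dict[str, int] = field(default_factory=dict)

    @property
    def n_imports(self) -> int:
        return len(self.imports)

    @property
    def n_exports(self) -> int:
        return len(self.exports)

    def n_imports_nonexempt(self) -> int:
        return len([m for m in self.imports if m not in self.exempt_flagged])


def _species_tags(model: MultiCompartmentModel) -> Dict[str, Set[str]]:
    tags: Dict[str, Set[str]] = {}
    for met in model.metabolites.values():
        tags.setdefault(met.base_id, set()).update(met.tags)
    return tags


def _class_of(tags: Set[str]) -> str:
    for label in ("eaa", "b_vitamin", "central_carbon", "mineral", "cofactor"):
        if label in tags:
            return label
    return "other"


def classify_exchanges(
    model: MultiCompartmentModel,
    sol: FluxSolution,
    threshold: float = EXCHANGE_THRESHOLD,
    exempt_tags: Iterable[str] = DEFAULT_EXEMPT_TAGS,
    compartments: Optional[Sequence[str]] = None,
) -> Dict[str, ExchangeProfile]:
    """Net transport flux per (species, compartment), thresholded.

    A species is an import (export) for a compartment when its summed
    transport flux into (out of) that compartment exceeds ``threshold``.
    Mineral/cofactor-tagged species are retained regardless of magnitude
    (they are required in small quantities) and flagged as exempt.
    """
    if not sol.optimal:
        raise ValueError("classify_exchanges requires an optimal solution")
    exempt_tags = set(exempt_tags)
    if compartments is None:
        compartments = [model.host_compartment] + list(model.symbiont_compartments)
    species_tags = _species_tags(model)

    net: Dict[str, Dict[str, float]] = {c: {} for c in compartments}
    for (base, donor, recipient), rid in model.transport_registry.items():
        v = sol.flux.get(rid, 0.0)
        for comp, sign in ((recipient, +1.0), (donor, -1.0)):
            if comp in net:
                net[comp][base] = net[comp].get(base, 0.0) + sign * v

    profiles: Dict[str, ExchangeProfile] = {}
    for comp in compartments:
        prof = ExchangeProfile(compartment=comp)
        for base, flux in sorted(net[comp].items()):
            tags = species_tags.get(base, set())
            exempt = bool(tags & exempt_tags)
            if abs(flux) > threshold or (exempt and abs(flux) > 1e-12):
                if abs(flux) <= threshold:
                    prof.exempt_flagged.add(base)
                target = prof.imports if flux > 0 else prof.exports
                target[base] = abs(flux)
        for direction, counts in (
            (prof.imports, prof.import_counts_by_class),
            (prof.exports, prof.export_counts_by_class),
        ):
            for base in direction:
                label = _class_of(species_tags.get(base, set()))
                counts[label] = counts.get(label, 0) + 1
        profiles[comp] = prof
    return profiles


def shared_unique_sets(
    profA: ExchangeProfile, profB: ExchangeProfile, side: str = "imports"
) -> Tuple[Set[str], Set[str], Set[str]]:
    """Set algebra on two profiles: (shared, unique to A, unique to B)."""
    if side not in {"imports", "exports"}:
        raise ValueError(f"side must be 'imports' or 'exports', got {side!r}")
    a = set(getattr(profA, side))
    b = set(getattr(profB, side))
    return a & b, a - b, b - a


@dataclass
class CrossFeedRecord:
    """A metabolite made by one symbiont and consumed only by the other."""

    metabolite: str
    donor: str
    recipient: str
    flux: float
    annotation: str = ""


def detect_cross_feeding(
    profiles: Dict[str, ExchangeProfile],
    host_compartment: str,
    symbiont_compartments: Sequence[str],
    threshold: float = EXCHANGE_THRESHOLD,
) -> List[CrossFeedRecord]:
    """Metabolites transferred exclusively between the symbionts.

    ``m`` is cross-fed X -> Y when m is exported by symbiont X, imported by
    symbiont Y, and the host neither consumes nor produces it on net (the
    host may relay it: with net accounting a pure relay leaves the host
    profile empty for that species).
    """
    host = profiles[host_compartment]
    host_touched = {
        m for m, f in list(host.imports.items()) + list(host.exports.items())
        if f > threshold
    }
    records: List[CrossFeedRecord] = []
    for donor in symbiont_compartments:
        for recipient in symbiont_compartments:
            if donor == recipient:
                continue
            for met, out_flux in profiles[donor].exports.items():
                in_flux = profiles[recipient].imports.get(met)
                if in_flux is None or out_flux <= threshold or in_flux <= threshold:
                    continue
                if met in host_touched:
                    continue
                records.append(
                    CrossFeedRecord(
                        metabolite=met,
                        donor=donor,
                        recipient=recipient,
                        flux=min(out_flux, in_flux),
                    )
                )
    records.sort(key=lambda r: (r.donor, r.recipient, r.metabolite))
    return records


@dataclass
class EAAReleaseReport:
    """EAA release by symbiont, with shares and host sink fractions."""

    per_symbiont: Dict[str, Dict[str, float]]
    total_flux: float
    shares: Dict[str, Optional[float]]
    host_sink_fraction: Dict[str, Optional[float]]

    def symbiont_total(self, compartment: str) -> float:
        return sum(self.per_symbiont.get(compartment, {}).values())


def eaa_release_accounting(
    profiles: Dict[str, ExchangeProfile],
    host_compartment: str,
    symbiont_compartments: Sequence[str],
    eaa_list: Iterable[str],
) -> EAAReleaseReport:
    """Account for symbiont EAA release and its host consumption.

    Shares are each symbiont's exported-EAA subtotal over the combined
    release; the host sink fraction for an EAA is the host's import of it
    over the total release of that EAA.  With zero total release the shares
    are undefined (``None``), not zero.
    """
    eaa_set = set(eaa_list)
    per_symbiont: Dict[str, Dict[str, float]] = {}
    release_by_eaa: Dict[str, float] = {}
    for comp in symbiont_compartments:
        exported = {
            m: f for m, f in profiles[comp].exports.items() if m in eaa_set
        }
        per_symbiont[comp] = exported
        for m, f in exported.items():
            release_by_eaa[m] = release_by_eaa.get(m, 0.0) + f
    total = sum(release_by_eaa.values())
    if total > 0:
        shares: Dict[str, Optional[float]] = {
            comp: sum(per_symbiont[comp].values()) / total
            for comp in symbiont_compartments
        }
    else:
        shares = {comp: None for comp in symbiont_compartments}
    host_imports = profiles[host_compartment].imports
    sink: Dict[str, Optional[float]] = {}
    for m, released in release_by_eaa.items():
        sink[m] = (host_imports.get(m, 0.0) / released) if released > 0 else None
    return EAAReleaseReport(
        per_symbiont=per_symbiont,
        total_flux=total,
        shares=shares,
        host_sink_fraction=sink,
    )
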