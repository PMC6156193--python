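"""End-to-end pipeline orchestration and report emission.

``run_pipeline`` executes the full analysis in method order — load (or
generate) models, optional expression-derived host bounds, integration,
medium, biomass floors, FBA, FVA, exchange classification, shared/unique
sets, cross-feeding, EAA accounting, nitrogen ledgers, maintenance costs —
and returns a result bundle that ``emit_report`` serializes to TSV/JSON
with stable column orders and fixed precision, so identical inputs yield
byte-identical outputs.  Every report embeds the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .budget_analysis import (
    DEFAULT_CAPPED_NUTRIENTS,
    MaintenanceCostReport,
    maintenance_cost,
    nitrogen_ledger,
)
from .exchange_analysis import (
    EXCHANGE_THRESHOLD,
    classify_exchanges,
    detect_cross_feeding,
    eaa_release_accounting,
    shared_unique_sets,
)
from .integration import (
    DEFAULT_BIOMASS_FLOOR,
    MediumSpec,
    MultiCompartmentModel,
    TransportEntry,
    apply_expression_bounds,
    apply_medium,
    build_multicompartment,
    fix_symbiont_biomass,
    normalize_expression,
)
from .model_io import read_expression_table, read_model_table, read_sbml
from .optimization import (
    flux_range_summary,
    fraction_transports_below,
    solve_fba,
    solve_fva,
    transport_flux_variation,
)
from .synthetic_data import ToySymbiosisSpec, generate_toy_symbiosis

logger = logging.getLogger("symbioflux")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "emit_report",
    "read_transport_table",
    "read_medium_spec",
    "load_model",
]


def load_model(path):
    """Dispatch on extension: ``.xml``/``.sbml`` -> SBML, else tabular TSV."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"model file not found: {p}")
    if p.suffix.lower() in {".xml", ".sbml"}:
        return read_sbml(p)
    return read_model_table(p)


def read_transport_table(path) -> List[TransportEntry]:
    """TSV with columns metabolite, donor, recipient, reversible."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples(index=False):
        rev = getattr(row, "reversible", True)
        if isinstance(rev, str):
            rev = rev.strip().lower() in {"1", "true", "yes"}
        entries.append(TransportEntry(str(row.metabolite), str(row.donor),
                                      str(row.recipient), bool(rev)))
    return entries


def read_medium_spec(path) -> MediumSpec:
    """YAML: ``uptake_caps`` mapping plus optional scalar caps."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return MediumSpec(
        uptake_caps=dict(raw.get("uptake_caps", {})),
        default_uptake_cap=float(raw.get("default_uptake_cap", 100.0)),
        o2_cap=float(raw.get("o2_cap", 20.0)),
        o2_id=str(raw.get("o2_id", "o2")),
        excluded_tags=set(raw.get("excluded_tags", ["eaa"])),
    )


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; fully serialized for provenance."""

    #: three organism model paths (host, primary, coprimary) ...
    model_paths: Optional[Tuple[str, str, str]] = None
    #: ... or one already-integrated model
    integrated_model_path: Optional[str] = None
    #: ... or a generated toy symbiosis
    toy: bool = False
    transport_path: Optional[str] = None
    medium_path: Optional[str] = None
    expression_path: Optional[str] = None
    exchange_threshold: float = EXCHANGE_THRESHOLD
    fva_range_threshold: float = 1.0
    transport_variation_percent: float = 1.0
    biomass_floor: float = DEFAULT_BIOMASS_FLOOR
    capped_nutrients: Tuple[str, ...] = DEFAULT_CAPPED_NUTRIENTS
    stabilize_fluxes: bool = False
    out_dir: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Computed artifacts of one run, ready for reporting."""

    config: PipelineConfig
    model: MultiCompartmentModel
    solution: object
    fva: object
    range_summary: object
    transport_variation: Dict[str, Optional[float]]
    transport_fraction_below: float
    profiles: Dict[str, object]
    shared_imports: Tuple[set, set, set]
    cross_feeds: List[object]
    eaa_report: object
    ledgers: Dict[str, object]
    maintenance: Dict[str, MaintenanceCostReport]
    expected: Optional[object] = None


def _build_model(config: PipelineConfig) -> Tuple[MultiCompartmentModel, Optional[object], List[str]]:
    if config.toy:
        bundle = generate_toy_symbiosis(ToySymbiosisSpec(seed=config.seed))
        model = bundle.integrate()
        return model, bundle, [n for n in bundle.eaa_names]
    if config.integrated_model_path:
        model = load_model(config.integrated_model_path)
        if not isinstance(model, MultiCompartmentModel):
            model = _promote_integrated(model)
        return model, None, _tagged_eaas(model)
    if not config.model_paths:
        raise ValueError("config must set toy, integrated_model_path or model_paths")
    host = load_model(config.model_paths[0])
    symA = load_model(config.model_paths[1])
    symB = load_model(config.model_paths[2])
    if config.expression_path:
        table = read_expression_table(config.expression_path)
        host = apply_expression_bounds(host, normalize_expression(table))
        logger.info("applied expression bounds from %s", config.expression_path)
    if not config.transport_path:
        raise ValueError("three-model mode requires transport_path")
    transports = read_transport_table(config.transport_path)
    model = build_multicompartment(host, symA, symB, transports)
    if config.medium_path:
        apply_medium(model, read_medium_spec(config.medium_path))
    fix_symbiont_biomass(model, config.biomass_floor)
    return model, None, _tagged_eaas(model)


def _tagged_eaas(model) -> List[str]:
    return sorted({m.base_id for m in model.metabolites.values() if "eaa" in m.tags})


def _promote_integrated(model) -> MultiCompartmentModel:
    """Wrap a plain integrated model, inferring roles from reaction structure.

    The external compartment is the one exchange reactions touch; the host
    is the compartment carrying the objective (falling back to the one
    adjacent to the external compartment); the remaining compartments are
    the symbionts.
    """
    from .model_core import met_base_id, met_compartment

    mcm = MultiCompartmentModel(
        id=model.id,
        compartments=list(model.compartments),
        metabolites=model.metabolites,
        reactions=model.reactions,
        objective=model.objective,
        genes=model.genes,
    )
    external_candidates = set()
    for rxn in model.reactions.values():
        if rxn.kind == "transport" and rxn.is_one_to_one_transport():
            items = sorted(rxn.stoichiometry.items(), key=lambda kv: kv[1])
            donor_mid, recipient_mid = items[0][0], items[1][0]
            mcm.transport_registry[
                (met_base_id(donor_mid), met_compartment(donor_mid),
                 met_compartment(recipient_mid))
            ] = rxn.id
        if rxn.kind == "biomass":
            comps = rxn.compartments()
            if len(comps) == 1:
                mcm.biomass_reactions[comps.pop()] = rxn.id
        if rxn.kind == "exchange" and len(rxn.stoichiometry) == 1:
            comp = met_compartment(next(iter(rxn.stoichiometry)))
            if comp:
                external_candidates.add(comp)
    if len(external_candidates) == 1:
        mcm.external_compartment = external_candidates.pop()
    host = None
    for rid in model.objective:
        comps = model.reactions[rid].compartments() - {mcm.external_compartment}
        if len(comps) == 1:
            host = comps.pop()
            break
    if host is None:
        for (_, donor, recipient) in mcm.transport_registry:
            if donor == mcm.external_compartment:
                host = recipient
                break
            if recipient == mcm.external_compartment:
                host = donor
                break
    mcm.host_compartment = host or ""
    mcm.symbiont_compartments = sorted(
        c for c in mcm.compartments
        if c not in {mcm.external_compartment, mcm.host_compartment}
    )
    return mcm


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every analysis stage; failures halt with the stage name."""
    stage = "load/integrate"
    try:
        model, bundle, eaa_list = _build_model(config)
        logger.info("model %s: %d reactions, %d metabolites",
                    model.id, model.n_reactions, model.n_metabolites)

        stage = "fba"
        sol = solve_fba(model, stabilize=config.stabilize_fluxes)
        if not sol.optimal:
            raise RuntimeError(f"FBA not optimal: status={sol.status}")
        logger.info("FBA objective = %.6g", sol.objective_value)

        stage = "fva"
        fva = solve_fva(model)
        summary = flux_range_summary(fva, threshold=config.fva_range_threshold)
        transports = model.transport_reaction_ids()
        variation = transport_flux_variation(fva, sol, transports)
        frac_below = fraction_transports_below(
            variation, percent=config.transport_variation_percent
        )

        stage = "exchanges"
        profiles = classify_exchanges(model, sol, threshold=config.exchange_threshold)
        sa, sb = model.symbiont_compartments
        shared = shared_unique_sets(profiles[sa], profiles[sb], side="imports")

        stage = "cross_feeding"
        cross = detect_cross_feeding(
            profiles, model.host_compartment, model.symbiont_compartments,
            threshold=config.exchange_threshold,
        )

        stage = "eaa_accounting"
        eaa_report = eaa_release_accounting(
            profiles, model.host_compartment, model.symbiont_compartments, eaa_list
        )

        stage = "nitrogen_ledger"
        ledgers = {
            comp: nitrogen_ledger(model, profiles[comp], sol)
            for comp in model.symbiont_compartments
        }

        stage = "maintenance_cost"
        maintenance = {
            comp: maintenance_cost(model, comp, config.capped_nutrients)
            for comp in model.symbiont_compartments
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        config=config,
        model=model,
        solution=sol,
        fva=fva,
        range_summary=summary,
        transport_variation=variation,
        transport_fraction_below=frac_below,
        profiles=profiles,
        shared_imports=shared,
        cross_feeds=cross,
        eaa_report=eaa_report,
        ledgers=ledgers,
        maintenance=maintenance,
        expected=bundle.expected if bundle is not None else None,
    )
    if config.out_dir:
        emit_report(result, config.out_dir)
    return result


# ---------------------------------------------------------------------------
# report emission
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def result_summary(result: PipelineResult) -> Dict:
    """The JSON-facing summary of one run."""
    sa, sb = result.model.symbiont_compartments
    shared, uniq_a, uniq_b = result.shared_imports
    return {
        "version": __version__,
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "model_id": result.model.id,
        "n_reactions": result.model.n_reactions,
        "n_metabolites": result.model.n_metabolites,
        "objective_value": result.solution.objective_value,
        "fva_fraction_below_threshold": result.range_summary.fraction_below,
        "transport_fraction_below_percent": result.transport_fraction_below,
        "symbiont_import_counts": {
            c: result.profiles[c].n_imports for c in (sa, sb)
        },
        "shared_import_count": len(shared),
        "unique_import_counts": {sa: len(uniq_a), sb: len(uniq_b)},
        "cross_feed_count": len(result.cross_feeds),
        "cross_feeds": [
            {"metabolite": r.metabolite, "donor": r.donor,
             "recipient": r.recipient, "flux": round(r.flux, 9)}
            for r in result.cross_feeds
        ],
        "eaa_total_release": result.eaa_report.total_flux,
        "eaa_shares": {
            c: (None if s is None else round(s, 9))
            for c, s in result.eaa_report.shares.items()
        },
        "nitrogen": {
            c: {
                "n_in": led.n_in,
                "n_out_eaa": led.n_out_eaa,
                "n_out_other": led.n_out_other,
                "n_biomass": led.n_biomass,
                "efficiency": led.efficiency,
            }
            for c, led in result.ledgers.items()
        },
        "maintenance_costs": {
            c: {
                "host_growth_full": rep.host_growth_full,
                "host_growth_symbiont_off": rep.host_growth_symbiont_off,
                "cost_absolute": rep.cost_absolute,
                "cost_relative": rep.cost_relative,
                "status_off": rep.status_off,
            }
            for c, rep in result.maintenance.items()
        },
    }


def emit_report(result: PipelineResult, out_dir, formats: Sequence[str] = ("tsv", "json")) -> List[Path]:
    """Write the report bundle; deterministic bytes for identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    if "json" in formats:
        path = out / "report.json"
        payload = result_summary(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=_fmt) + "\n")
        written.append(path)
        cfg = out / "config.json"
        cfg.write_text(json.dumps(result.config.to_dict(), indent=2, sort_keys=True) + "\n")
        written.append(cfg)

    if "tsv" in formats:
        rows = []
        for rid in result.model.reactions:
            lo, hi = result.fva.ranges[rid]
            var = result.transport_variation.get(rid)
            rows.append({
                "reaction": rid,
                "flux": _fmt(result.solution.flux[rid]),
                "min": _fmt(lo),
                "max": _fmt(hi),
                "range": _fmt(hi - lo),
                "percent_variation": _fmt(var),
            })
        path = out / "fluxes.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)

        rows = []
        for comp in sorted(result.profiles):
            prof = result.profiles[comp]
            for direction, table in (("import", prof.imports), ("export", prof.exports)):
                for met in sorted(table):
                    rows.append({
                        "compartment": comp,
                        "direction": direction,
                        "metabolite": met,
                        "flux": _fmt(table[met]),
                        "exempt": met in prof.exempt_flagged,
                    })
        path = out / "exchanges.tsv"
        pd.DataFrame(rows, columns=["compartment", "direction", "metabolite",
                                    "flux", "exempt"]).to_csv(path, sep="\t", index=False)
        written.append(path)

        rows = [{"metabolite": r.metabolite, "donor": r.donor,
                 "recipient": r.recipient, "flux": _fmt(r.flux)}
                for r in result.cross_feeds]
        path = out / "cross_feeds.tsv"
        pd.DataFrame(rows, columns=["metabolite", "donor", "recipient", "flux"]
                     ).to_csv(path, sep="\t", index=False)
        written.append(path)

        rows = []
        for comp in sorted(result.ledgers):
            led = result.ledgers[comp]
            for direction, detail in (("import", led.import_detail),
                                      ("export", led.export_detail)):
                for met in sorted(detail):
                    flux, n, nflux = detail[met]
                    rows.append({
                        "compartment": comp, "direction": direction,
                        "metabolite": met, "flux": _fmt(flux),
                        "n_count": n, "n_flux": _fmt(nflux),
                    })
        path = out / "nitrogen_ledger.tsv"
        pd.DataFrame(rows, columns=["compartment", "direction", "metabolite",
                                    "flux", "n_count", "n_flux"]
                     ).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
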