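# Methods

## The model and its assumptions

The package analyzes a community metabolic model with four compartments:
an insect host bacteriocyte (`h`), a primary symbiont (`sA`), a coprimary
symbiont (`sB`), and the external medium (`e`, standing in for hemolymph).
Each organism is a genome-scale metabolic model — metabolites with
Hill-notation elemental formulas, reactions with flux bounds in
mmol gDW⁻¹ h⁻¹, optional boolean gene associations — and the community is
their union plus 1:1 transport reactions and export-positive exchange
reactions on the external compartment.

Standing assumptions:

- **Steady state.** All analyses are FBA/FVA solutions of
  `max cᵀv s.t. S·v = 0, lb ≤ v ≤ ub`; no kinetics, no regulation beyond
  the expression-derived bounds.
- **Cost-free transport.** Transport reactions move one species 1:1
  between two compartments with no ATP or proton stoichiometry. This is a
  parsimony choice in the absence of annotated transporters; it tends to
  understate the true cost of exchange, so maintenance costs are lower
  bounds in that respect.
- **Equal symbiont loads.** Both symbiont biomass reactions carry the same
  growth floor (default 0.01 mmol gDW⁻¹ h⁻¹) since relative symbiont
  abundances are not separately constrained.
- **Exchange convention.** Exchange reactions are written export-positive
  (`met[e] → ∅`); uptake is a negative flux and reported uptake magnitudes
  are |lb|-side values.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| O₂ uptake cap | 20 | mmol gDW⁻¹ h⁻¹ | aerobic ceiling on the medium |
| nutrient uptake cap | 100 | mmol gDW⁻¹ h⁻¹ | generic cap per medium nutrient |
| symbiont biomass floor | 0.01 | mmol gDW⁻¹ h⁻¹ | enforced symbiont growth |
| B-vitamin objective coefficient | 5·10⁻⁵ | mmol gDW⁻¹ | vitamins are required in trace amounts; applied per vitamin |
| default host bound | 10 | mmol gDW⁻¹ h⁻¹ | reactions with no transcript match |
| exchange threshold | 10⁻⁶ | mmol gDW⁻¹ h⁻¹ | below this, transport flux is noise, except minerals/cofactors which are kept and flagged |
| FVA range threshold | 1 | mmol gDW⁻¹ h⁻¹ | "tightly pinned" cutoff for the range summary |
| transport variation threshold | 1 | % of optimal flux | "tightly pinned" cutoff for transports |

Amino acids are never allowed as nutrients: medium application closes
uptake on every exchange whose metabolite carries the `eaa` tag.

## Expression-derived host bounds

TPM tables are normalized in two steps: zero-TPM genes first receive each
replicate's lowest nonzero TPM (they exist but fall below quantification),
then each gene's mean is divided by the lowest nonzero mean and rounded to
an integer level, so the weakest expressed transcript sits at level 1.
Rounding is half-up; "round to nearest" is ambiguous at .5 and one rule had
to be fixed for reproducibility.

Levels map to bounds through the gene-protein-reaction rules with
**OR = sum** (isozymes add capacity) and **AND = min** (a complex is
limited by its scarcest subunit); the resulting capacity is the upper bound
(and its negative the lower bound for reversible reactions), i.e. the
expression level is taken directly as a flux capacity on the same
mmol gDW⁻¹ h⁻¹ scale as the default bound of 10. Genes missing from the
table evaluate to 0 inside a rule that matches at least one measured gene;
a rule matching no genes at all falls back to the default bound. These
GPR conventions are this package's declared choice — the mapping is not
uniquely fixed by the biology.

## Numerical choices

- LP solver: scipy's HiGHS, deterministic for a fixed reaction ordering
  (insertion order of the model's collections).
- Feasibility tolerance 10⁻⁹; FVA pins the objective as
  `cᵀv ≥ opt − max(10⁻⁹, 10⁻⁶·|opt|)` — strict equality is numerically
  brittle, so FVA ranges may widen by up to that slack.
- Degenerate optima: plain FBA reports whatever vertex HiGHS returns
  (reproducible but arbitrary among alternate optima). The optional
  stabilized mode re-solves for minimum total |v| at the pinned optimum,
  making per-reaction fluxes unique in practice; it is off by default so
  that default results reflect plain FBA.
- Infeasible or unbounded problems are reported as a status, not an
  exception; a missing elemental formula on a transported metabolite is an
  error (not a silent zero) because it would corrupt the nitrogen budget.
- Exchange classification is *net* per (species, compartment): opposing
  transports are summed before thresholding, so marginal two-way traffic
  is not double-counted, and a species relayed through the host with zero
  net host consumption is attributed to the symbiont→symbiont route. This
  is precisely how cross-feeding is recognized in a topology where all
  transport passes the host interface.

## The synthetic study system

`generate_toy_symbiosis` emulates the structure of the real symbioses with
a network small enough to solve by hand: the host builds a nitrogen-carrying
precursor (C₃H₇NO₂) from glucose and ammonia, ships it to both symbionts,
and grows on the EAAs they return. The primary symbiont covers 7 EAAs, the
coprimary 3 — matching the 7–8 / 2–3 partition in the real systems — plus a
B vitamin at coefficient 5·10⁻⁵. The coprimary symbiont wastes a fraction
*f* = 0.3 of its precursor as overflow ammonia (and a deaminated C₃H₄O₂
byproduct), giving it a designed nitrogen-recycling efficiency of
1/(1+f) ≈ 0.77 before biomass retention; one intermediate is optionally
cross-fed from primary to coprimary through the host. Glucose (cap 10,
scaled down from the generic 100 so that uptake rather than enzyme capacity
limits growth) is the designed bottleneck under the default EAA-capacity
interval (2.5–4.0); the sweep interval (1.0–4.0) lets individual pathway
capacities bind instead, exercising the min-over-bottlenecks optimum.

Because every pathway is a linear chain hanging off the objective, the
generator computes the optimum, the full exchange table, the nitrogen
ledgers and the maintenance costs by closed-form arithmetic — never by
linear programming — so the expectations are an independent oracle for the
solver stack. When glucose binds strictly, every flux in the network is
uniquely determined, which is what makes exact table-level assertions
possible; when another bottleneck binds, only the objective value (and the
cross-feed structure and ledger closure, which are degeneracy-robust) are
asserted.

What the toy does *not* emulate: branched and looping pathway topology,
cofactor and energy metabolism, realistic metabolite multiplicities, and
competition between symbionts for multiple shared inputs. Passing the
property suite therefore demonstrates that the machinery (integration, LP,
classification, budgeting) is correct, not that any particular biological
number is right; the deposited genome-scale models remain the benchmark
for the published values, and the corresponding tests run only when those
SBML files are provided under `data/deposited/`.

Maintenance costs on the toy have an exact reference: with glucose binding
and biomass drains `b·floor`, host growth is `μ = (2·G − b·ΣF)/P` (P =
precursor demand per unit growth), so switching one symbiont's biomass off
recovers exactly `b·floor/P` — the value the LP must reproduce.

## Design decisions that were genuinely open

- **Transport reversibility** defaults to reversible (direction resolved by
  the LP) when a transport table does not say otherwise; the toy generator
  declares directions explicitly to keep its optimum closed-form.
- **Host-relay cross-feeding**: a metabolite routed symbiont→host→symbiont
  counts as cross-fed when the host's net consumption is below the
  exchange threshold.
- **Efficiency denominator**: total N import flux including exempt-tagged
  (mineral/cofactor) species that carry formulas — the ledger covers all
  assimilated nitrogen, not only bulk nutrients.
- **Relative maintenance cost** is reported against full-model host growth;
  both absolute (flux) and relative (fraction) values are emitted.
- **Vitamin coefficient** is applied per vitamin, not summed over vitamins.
- The nitrogen ledger takes the realized biomass flux from the solution
  and the biomass reaction's own stoichiometry as the biomass composition;
  a static composition spec alone cannot close the balance.

## Problem sizes and limitations

The test suite and the acceptance script run entirely on generated
networks of ~45–50 reactions; FVA there is 2n ≈ 100 LPs and the brute-force
vertex-enumeration oracle is limited to ≤ 8 reactions, where exhaustive
enumeration is exact. These sizes were chosen so every expected value is
hand-checkable; the pipeline itself is routinely applied to
genome-scale inputs (hundreds of reactions) through the same interfaces.
Known limitations: no loopless FVA or thermodynamic constraints, no charge
or proton bookkeeping, no automated transporter inference, and SBML support
covers the L3+FBC subset (bounds, objective, gene associations) only.
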