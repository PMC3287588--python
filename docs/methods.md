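# Methods

## Scope and model form

phycoflux implements constraint-based analysis of a compartmentalized
metabolic network. A model is a set of metabolites, each bound to one of
five compartments (cytosol `_c`, plastid `_p`, mitochondrion `_m`,
microbody `_x`, extracellular `_e`; the suffix convention is ours — the
same chemical in two compartments is two species), and a set of reactions
with signed stoichiometry, reversibility-consistent flux bounds, a boolean
gene association, a kind (`enzymatic`, `transport`, `exchange`,
`biomass_drain`, `non_enzymatic_gap`) and a compartment-evidence label.
Flux balance analysis solves `max/min c·v s.t. S v = 0, lb ≤ v ≤ ub` with
HiGHS (simplex) through `scipy.optimize.linprog`; solver feasibility
tolerance is 1e-9, and reported solutions are checked against
`max|S v| ≤ 1e-6 · max(1, max|v|)`.

**Alternate optima.** The scalar objective is the contract of every
operation. Reported flux vectors additionally minimize Σ|v| at the fixed
optimum (a second LP over split positive/negative parts). This
parsimonious resolution makes flux vectors — and therefore flux
comparisons and direction tables — deterministic and reproducible; it is
the standard choice where the underlying biology does not dictate a
particular member of the optimal face.

## Curation pipeline

Raw reaction tables are gene-centric and compartment-free. The pipeline
applies, in order: synonym merging (non-canonical compound labels are
rewritten to canonical ids, coefficients summed, fully cancelling species
dropped; reactions that become stoichiometrically identical are collapsed
with their gene associations OR-combined — the union of catalysts is the
conservative reading); polymer rewriting (degenerate
`P(n) + X -> P(n+1)` elongations become monomer-unit accumulation, with
the monomer coefficient given by the index-weighted sum, and generic
R-group species are rejected outright); compartment assignment with
precedence literature > homolog > cytosol-by-default, where several
literature claims duplicate the reaction into one copy per compartment
(this is how plastidic and cytosolic glycolysis coexist); and manual
transporter/exchange addition from curated tables, with intercellular
(cytosol↔extracellular) and inter-organelle transporters counted
separately. Evidence is applied per reaction; the pipeline is idempotent.

## Elemental audit conventions

Every internal (non-exchange, non-drain) reaction in the shipped network
balances for every element under these documented conventions: reduced
nicotinamide cofactors carry the transferred hydrogens (neutral free-acid
formulas, NADH = NAD + H2), reduced ferredoxin carries one hydrogen
(`HFe2S2` vs `Fe2S2`), the photon is massless, and protonation states are
not tracked (charge balance is out of scope). Reactions with any
missing formula report `unknown`, never `unbalanced`.

## The synthetic algal core network

The fixture is built through the curation pipeline itself from embedded
raw tables, so reconstruction and simulation are exercised end-to-end. It
is deliberately lumped: GAPDH carries the phosphoglycerate-kinase step,
Calvin-cycle regeneration is one pseudo-reaction with exact carbon/ATP
accounting, the oxidative pentose phosphate pathway is a single
full-oxidation reaction, AMP and palmitate synthesis are single balanced
lumps. What matters for its purpose — testing flux routing and LP
correctness — is the pathway topology and the energy/redox economy, not
enzyme-level detail.

Energetic constants (documented assumptions, not literature values):

* **Linear electron flow (LEF)**: 8 photons split 2 H2O → O2 + 4 reduced
  ferredoxin + 3 ATP.
* **Cyclic electron flow (CEF)**: 1 photon per ATP (ferredoxin cycles
  catalytically and is omitted from the lumped stoichiometry). CEF is the
  photon-cheapest ATP source, which is why resource-minimal solutions
  engage it whenever ATP demand outruns LEF co-production.
* **Oxidative phosphorylation**: P/O = 2 for NADH (1 ATP at complex I,
  1 at complexes III/IV), 1 for ubiquinol-level electrons (succinate and
  glycolate dehydrogenase).
* **Maintenance**: 30 mmol ATP/gDW growth-associated, 0.2 mmol/gDW/h
  non-growth-associated (the maintenance reaction is also the ATP
  overflow valve).

Biomass is starch 2.2, glutamate 2.2, AMP 0.35, palmitate 0.15 mmol/gDW
(identical across conditions). The composition was chosen so that (i) the
ATP:NADPH demand ratio exceeds the 3:2 that LEF co-produces — giving
cyclic electron flow a role in light-grown wild types — and (ii) biomass
is slightly more oxidized than acetate, so dark biosynthesis has a small
electron surplus to dispose of.

Deliberate structural choices, made where a naive network lets the LP do
non-biological things:

* The plastid NAD-GAPDH is irreversible (glycolytic); the reductive
  plastid step is strictly NADPH-dependent. Otherwise the solver runs a
  NADH-powered Calvin cycle in the dark as an electron sink — in the cell
  this is prevented by thioredoxin-mediated dark inactivation, which bare
  stoichiometry cannot express. The cytosolic GAPDH remains reversible
  and carries gluconeogenesis.
* There is no plastidic PEP or pyruvate importer; carbon enters the
  plastid through the canonical glucose-6-phosphate and triose-phosphate
  translocators. Plastidic pyruvate therefore comes only from plastid
  glycolysis, keeping GAPDH and pyruvate kinase on the dark-H2 route.
* Ferredoxin-NADP+ reductase is irreversible toward NADPH, so reduced
  ferredoxin in the dark can only come from pyruvate:ferredoxin
  oxidoreductase.
* Acetate enters metabolism only through acetyl-CoA synthetase (cytosol
  and microbody); the microbody route feeds the glyoxylate cycle, whose
  net product (succinate) must transit the cytosol into the
  mitochondrion.

## Trophic conditions and the H2 studies

The three conditions apply the minimal constraint sets given in the
README table. "–" closes the uptake bound only; CO2 secretion stays open
in the dark (respiration must vent CO2). Fixed growth is an equality
(lb = ub). Photon supply under "free flux" is the conventional
effectively-unbounded box (1000).

Two dark-specific parameters define the heterotrophic study conditions:

* **O2 uptake cap 2.0 mmol/gDW/h.** Dark growth on acetate in this
  network is respiration-dependent (acetate catabolism has no net
  substrate-level ATP), and growth at 0.035 h⁻¹ requires about
  1.8 mmol O2/gDW/h; the cap is set just above that, so growth is
  feasible but respiratory capacity — not acetate supply — bounds ATP
  regeneration during H2 maximization.
* **Acetate allowance 1.25.** At the *exact* substrate-minimal uptake
  every resource is binding and the maximum H2 is zero by LP duality; the
  dark H2 study therefore fixes acetate at 1.25× the Optimization-1
  minimum, the low end of a supply sweep. All fourteen numbered steps of
  the dark route (acetate uptake and transport, acetyl-CoA synthetase,
  isocitrate lyase, malate synthase, two succinate transporters, PEP
  carboxykinase, phosphoglucomutase, starch synthase, plastid GAPDH,
  plastid pyruvate kinase, PFR1, hydrogenase) carry positive flux in the
  resulting optimum.

**Knockout comparisons.** A plain H2 maximization never uses cyclic
electron flow, so knocking it out would change nothing — the LP sees no
value in a pathway that makes ATP without reductant when the objective is
reductant disposal. The study therefore holds the knockout targets at
their *wild-type operating flux* (taken from the parsimonious
Optimization-1 solution) in the baseline producer run, and at zero in the
knockout run. This renders "wild-type photosystem operation vs. mutant"
as two LPs differing only in that constraint, and blocking cyclic flow
then strictly increases the H2 maximum at fixed growth.

**Illumination.** Light-condition producer runs cap photon uptake at
2.5× the wild-type minimal demand ("moderate constant illumination").
The choice matters and is documented rather than hidden: far below ~1.5×
the toy network's knockout becomes ATP-starved (its only
reductant-to-ATP route is a malate-valve shuttle at P/O 2), and far above
it the cyclic-flow share of photons becomes negligible; 2.5× sits in the
regime where light is neither starving nor saturating. The resulting
~1.5-fold increase is a property of this small network; on a
genome-scale model the same protocol produces much larger factors, and
only the direction is asserted by the tests.

**Direction tables** classify per-pathway summed |flux| of the producer
against the wild type at a 20 % threshold (reference magnitudes floored
at 1e-6). On this fixture linear electron flow and hydrogenase increase
and cyclic electron flow decreases, as expected; the mitochondrial TCA
cycle stays roughly flat rather than decreasing, because at fixed growth
the toy's respiratory ATP remains indispensable — a known limitation of
the small network, reported but not asserted.

## Photorespiration contrast

RuBisCO oxygenation is forced (lower bound 0.05 on the oxygenation
branch) and photons are minimized autotrophically. With algal defaults,
phosphoglycolate is salvaged to glycolate and then either oxidized by the
mitochondrial, ubiquinone-linked glycolate dehydrogenase (no H2O2 is ever
formed, so no catalase exists in the network) or secreted. The
plant-style variant (peroxisomal glycolate oxidase + catalase + lumped
glycerate recycling) instead recovers the carbon into 3-phosphoglycerate.
The two behaviours are switchable fixture options and both are asserted;
with both paths priced, recycling is the photon-cheaper strategy —
consistent with why plants evolved it — while the algal network trades
carbon for respiratory electrons or simply exports glycolate.

## Gap analysis

Producibility screening maximizes each biomass-component drain (combined
biomass off, other drains off) under a condition's bounds; rates above
1e-6 count as producible. Dead-end detection is structural and iterated
to a fixpoint: a multi-species reaction can carry steady flux only if
every metabolite it touches is touched by another active reaction, which
correctly marks an isolated reversible pair as dead in both directions
without flagging cofactor pools. Breakpoint tracing walks backward from a
blocked component (breadth-first, sorted, cycle-safe, depth cap 25),
testing each frontier metabolite with a producibility LP. Causes are
classified in precedence order: `missing_transporter` (a
sibling-compartment pool is producible but unlinked — the most specific
evidence); `irreversibility_conflict` (a locked reaction would make the
species producible if relaxed, verified by LP, not just by sign
pattern); `no_producer`; otherwise recursion into the producing
reactions' substrates (`blocked_precursor` if the depth cap is reached).
A missing-transporter breakpoint does not stop the walk — the root cause
may sit deeper on the producing branch, and both are reported.

## What the fixture does and does not show

The synthetic network reproduces the qualitative systems biology —
which pathways carry flux under which trophic condition, how electron
flow reroutes under perturbation, how gaps manifest and are traced. It
does not emulate genome-scale redundancy (most metabolites have a single
producer, which is why seeded deletions are cleanly traceable), real
photon/biomass yields, nitrogen-source variation, charge balance, or
kinetic/regulatory effects (dark inactivation had to be imposed
structurally, see above). Passing tests therefore certify the machinery
and the direction of the predictions, not quantitative rates on real
organisms.

## Numerical and problem-size choices

All shipped analyses are desk-scale: the fixture has ~100 internal
reactions (59 enzymatic, 42 transport) plus exchanges and drains; the gap-recovery experiment uses 50 single-deletion fixtures;
the brute-force LP oracle enumerates vertices of networks with ≤8
reactions (3^n tight-set assignments). The full test suite and the
acceptance script each run in well under a minute on one CPU. Default
bounds are ±1000 (reversible) and [0, 1000] (irreversible); producibility
threshold 1e-6; flux-change threshold 20 % with a 1e-6 floor; LP
tolerances as above. Ties in the parsimonious LP are resolved by the
deterministic simplex pivot order of HiGHS; identical inputs give
bit-identical outputs.
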