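"""Synthetic compartmentalized algal core network.

:func:`generate_core_network` builds a curated, elementally balanced toy
model of green-algal primary metabolism spanning cytosol, plastid,
mitochondrion, microbody and the extracellular space.  It contains the
pathways whose interplay drives the package's flux predictions:

* photosynthetic light reactions — linear electron flow (water-splitting,
  ferredoxin reduction, ATP co-synthesis) and cyclic electron flow around
  photosystem I (ATP only);
* the Calvin cycle with explicit RuBisCO carboxylation and oxygenation and
  phosphoglycolate salvage;
* algal photorespiration (mitochondrial glycolate dehydrogenase feeding the
  ubiquinone pool, or glycolate secretion) with an optional plant-style
  variant (peroxisomal glycolate oxidase + catalase + glycerate recycling)
  for contrast experiments;
* acetate assimilation via acetyl-CoA synthetase and the microbody
  glyoxylate cycle, gluconeogenesis through PEP carboxykinase to plastidic
  starch;
* plastidic glycolysis with GAPDH and pyruvate kinase feeding
  pyruvate:ferredoxin oxidoreductase (PFR1) and the ferredoxin hydrogenase —
  the dark route to H2;
* TCA cycle and oxidative phosphorylation; cytosolic fermentative drains
  (formate, ethanol, lactate);
* biomass drains (starch, glutamate, AMP, palmitate) plus a combined biomass
  equation with growth-associated ATP maintenance.

The network is deliberately lumped (e.g. GAPDH carries the phosphoglycerate
kinase step; Calvin-cycle regeneration is one pseudo-reaction with correct
carbon/ATP accounting) — the fixture exists to exercise flux routing and LP
correctness, not genome-scale fidelity.  All internal reactions balance
elementally under the conventions documented in the formula table (reduced
cofactors carry the transferred hydrogens; ferredoxin carries one).

Energetic constants (documented assumptions, exposed as module attributes):

* ``LEF``: 8 photons split 2 H2O, reduce 4 ferredoxin and co-synthesize
  3 ATP (evolving 1 O2);
* ``CEF``: 1 photon per ATP — cyclic flow is the photon-cheapest ATP source,
  which is why resource-minimal solutions engage it;
* oxidative phosphorylation: P/O of 2 for NADH (1 at complex I, 1 at
  complexes III/IV), 1 for ubiquinol-level electrons.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    BiomassComposition,
    CompartmentalizedModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    add_biomass_equation,
    parse_reaction_equation,
)
from .reconstruction import (
    EvidenceRecord,
    TransporterEntry,
    add_exchanges,
    add_transporters,
    assign_compartments,
)

__all__ = [
    "FixtureOptions",
    "generate_core_network",
    "seed_gaps",
    "fixture_hash",
    "export_tables",
    "BIOMASS_COEFFICIENTS",
    "GROWTH_ATP_MAINTENANCE",
    "ACETATE_UPTAKE_MAX",
    "DARK_H2_PATH",
    "CEF_REACTION",
    "HYDROGENASE",
]

# -- documented fixture constants -------------------------------------------

#: photons per linear-electron-flow turnover (2 H2O -> O2 + 4 Fd_red + 3 ATP)
PHOTONS_PER_LEF = 8
#: photons per ATP through cyclic electron flow around PSI
CEF_PHOTONS_PER_ATP = 1
#: biomass composition, mmol precursor per gDW (identical across conditions)
BIOMASS_COEFFICIENTS = {
    "DM_starch_p": 2.2,   # storage carbohydrate, glucose units
    "DM_glu_c": 2.2,      # proteinogenic amino acid proxy (glutamate)
    "DM_amp_c": 0.35,     # nucleotide proxy (AMP)
    "DM_hdca_p": 0.15,    # fatty acid proxy (palmitate)
}
#: growth-associated ATP maintenance, mmol ATP per gDW
GROWTH_ATP_MAINTENANCE = 30.0
#: default acetate uptake capacity, mmol gDW^-1 h^-1
ACETATE_UPTAKE_MAX = 1.5

#: id of the cyclic-electron-flow reaction (the in-silico *Stm6* target)
CEF_REACTION = "CEF_p"
HYDROGENASE = "HYDA_p"

#: the numbered dark-H2 route: acetate assimilation -> glyoxylate cycle ->
#: gluconeogenesis -> starch, plus plastid glycolysis -> PFR1 -> hydrogenase
DARK_H2_PATH = (
    "T_ac_ec",       # (1)  acetate uptake/assimilation at the membrane
    "T_ac_cx",       # (2,4) acetate transport to the microbody
    "ACS_x",         # (3,5) acetyl-CoA synthetase
    "ICL_x",         #      isocitrate lyase (glyoxylate cycle)
    "MALS_x",        #      malate synthase (glyoxylate cycle)
    "T_succ_xc",     # (6)  succinate export from the microbody
    "T_succ_cm",     # (7)  succinate import into the mitochondrion
    "PEPCK_c",       # (8)  PEP carboxykinase (gluconeogenesis)
    "PGM_p",         # (9)  phosphoglucomutase (starch synthesis)
    "STARCHS_p",     # (10) starch synthase / branching
    "GAPDH_p",       # (11) plastidic glyceraldehyde-3-P dehydrogenase
    "PYK_p",         # (12) plastidic pyruvate kinase
    "PFR1_p",        # (13) pyruvate:ferredoxin oxidoreductase
    "HYDA_p",        # (14) ferredoxin hydrogenase
)


@dataclass(frozen=True)
class FixtureOptions:
    """Switches selecting fixture variants.

    Defaults reproduce the canonical algal fixture exactly; the core network
    is seed-independent (``random_seed`` only matters for gap seeding).
    """

    include_cyclic_electron_flow: bool = True
    include_glycolate_dehydrogenase: bool = True
    include_plant_style_photorespiration: bool = False
    include_glycolate_secretion: bool = True
    include_fermentation: bool = True
    random_seed: int = 0


# ---------------------------------------------------------------------------
# species tables (suffix-free; compartments are assigned by the pipeline)
# ---------------------------------------------------------------------------

#: Hill-notation formulas.  Conventions: reduced nicotinamide cofactors carry
#: the transferred H2 (neutral free-acid formulas), reduced ferredoxin carries
#: one hydrogen, the photon is massless.
FORMULAS: Dict[str, str] = {
    "photon": "",
    "co2": "CO2",
    "o2": "O2",
    "h2o": "H2O",
    "h2": "H2",
    "h2o2": "H2O2",
    "nh3": "H3N",
    "pi": "H3O4P",
    "ppi": "H4O7P2",
    "atp": "C10H16N5O13P3",
    "adp": "C10H15N5O10P2",
    "amp": "C10H14N5O7P",
    "nad": "C21H27N7O14P2",
    "nadh": "C21H29N7O14P2",
    "nadp": "C21H28N7O17P3",
    "nadph": "C21H30N7O17P3",
    "q": "C49H74O4",
    "qh2": "C49H76O4",
    "fdxox": "Fe2S2",
    "fdxrd": "HFe2S2",
    "coa": "C21H36N7O16P3S",
    "accoa": "C23H38N7O17P3S",
    "g6p": "C6H13O9P",
    "g1p": "C6H13O9P",
    "f6p": "C6H13O9P",
    "fbp": "C6H14O12P2",
    "gap": "C3H7O6P",
    "pg3": "C3H7O7P",
    "pep": "C3H5O6P",
    "pyr": "C3H4O3",
    "rubp": "C5H12O11P2",
    "pglyc": "C2H5O6P",
    "glyclt": "C2H4O3",
    "glx": "C2H2O3",
    "glyct": "C3H6O4",
    "ac": "C2H4O2",
    "cit": "C6H8O7",
    "icit": "C6H8O7",
    "akg": "C5H6O5",
    "succ": "C4H6O4",
    "fum": "C4H4O4",
    "mal": "C4H6O5",
    "oaa": "C4H4O5",
    "glu": "C5H9NO4",
    "starch": "C6H10O5",
    "adpglc": "C16H25N5O15P2",
    "hdca": "C16H32O2",
    "for": "CH2O2",
    "etoh": "C2H6O",
    "lac": "C3H6O3",
}

NAMES: Dict[str, str] = {
    "photon": "photon (photosynthetically active)",
    "co2": "carbon dioxide", "o2": "oxygen", "h2o": "water", "h2": "hydrogen",
    "h2o2": "hydrogen peroxide", "nh3": "ammonia", "pi": "orthophosphate",
    "ppi": "pyrophosphate", "atp": "ATP", "adp": "ADP", "amp": "AMP",
    "nad": "NAD+", "nadh": "NADH", "nadp": "NADP+", "nadph": "NADPH",
    "q": "ubiquinone", "qh2": "ubiquinol",
    "fdxox": "ferredoxin (oxidized)", "fdxrd": "ferredoxin (reduced)",
    "coa": "coenzyme A", "accoa": "acetyl-CoA",
    "g6p": "D-glucose 6-phosphate", "g1p": "D-glucose 1-phosphate",
    "f6p": "D-fructose 6-phosphate", "fbp": "D-fructose 1,6-bisphosphate",
    "gap": "glyceraldehyde 3-phosphate", "pg3": "3-phosphoglycerate",
    "pep": "phosphoenolpyruvate", "pyr": "pyruvate",
    "rubp": "ribulose 1,5-bisphosphate", "pglyc": "2-phosphoglycolate",
    "glyclt": "glycolate", "glx": "glyoxylate", "glyct": "glycerate",
    "ac": "acetate", "cit": "citrate", "icit": "isocitrate",
    "akg": "2-oxoglutarate", "succ": "succinate", "fum": "fumarate",
    "mal": "malate", "oaa": "oxaloacetate", "glu": "L-glutamate",
    "starch": "starch (glucose unit)", "adpglc": "ADP-glucose",
    "hdca": "palmitate", "for": "formate", "etoh": "ethanol", "lac": "lactate",
}


# raw reaction spec: (id, name, equation, genes, subsystem,
#                     [(compartment, source, citation), ...])
_RawRxn = Tuple[str, str, str, str, str, List[Tuple[str, str, str]]]


def _core_reactions(opts: FixtureOptions) -> List[_RawRxn]:
    P = [("plastid", "literature", "plastid-localized, biochemical evidence")]
    M = [("mitochondrion", "literature", "mitochondrial, biochemical evidence")]
    Mh = [("mitochondrion", "homolog", "mitochondrial homolog localization")]
    X = [("microbody", "literature", "microbody-localized, biochemical evidence")]
    C = [("cytosol", "literature", "cytosolic, biochemical evidence")]
    Ch = [("cytosol", "homolog", "cytosolic homolog localization")]
    NONE: List[Tuple[str, str, str]] = []  # -> cytosol by default

    rxns: List[_RawRxn] = [
        # --- photosynthetic light reactions (plastid) ---
        ("LEF", "linear electron flow (PSII+PSI, water splitting)",
         "4 fdxox + 8 photon + 3 adp + 3 pi --> o2 + 4 fdxrd + 3 atp + h2o",
         "psbA and psaB and petA", "linear electron flow", P),
        ("FNR", "ferredoxin-NADP+ reductase",
         "2 fdxrd + nadp --> 2 fdxox + nadph",
         "fnr1", "ferredoxin-NADP+ reductase", P),
        ("HYDA", "ferredoxin hydrogenase",
         "2 fdxrd --> 2 fdxox + h2",
         "hydA1 or hydA2", "hydrogenase", P),
        ("PFR1", "pyruvate:ferredoxin oxidoreductase",
         "pyr + coa + 2 fdxox --> accoa + co2 + 2 fdxrd",
         "pfr1", "pyruvate ferredoxin oxidoreductase", P),
        # --- Calvin cycle & photorespiration source (plastid) ---
        ("RBPC", "RuBisCO (carboxylation)",
         "rubp + co2 + h2o --> 2 pg3",
         "rbcL and rbcS", "Calvin cycle", P),
        ("RBPO", "RuBisCO (oxygenation)",
         "rubp + o2 --> pg3 + pglyc",
         "rbcL and rbcS", "photorespiration", P),
        ("PGP", "phosphoglycolate phosphatase",
         "pglyc + h2o --> glyclt + pi",
         "pgp1", "photorespiration", P),
        ("GAPDHN", "NADPH-glyceraldehyde-3-P dehydrogenase (reductive, with PGK)",
         "pg3 + atp + nadph --> gap + adp + pi + nadp",
         "gap1", "Calvin cycle", P),
        ("RUBPREG", "Calvin-cycle regeneration (lumped, with phosphoribulokinase)",
         "5 gap + 3 atp + 2 h2o --> 3 rubp + 3 adp + 2 pi",
         "prk1 and tkl1", "Calvin cycle", P),
        # --- starch synthesis (plastid) ---
        ("PGM", "phosphoglucomutase",
         "g6p <=> g1p", "gpm1", "starch synthesis", P),
        ("AGPASE", "ADP-glucose pyrophosphorylase",
         "g1p + atp --> adpglc + ppi", "sta1 and sta6", "starch synthesis", P),
        ("STARCHS", "starch synthase / 1,4-alpha-glucan branching enzyme",
         "adpglc --> starch + adp", "sta2 and sbe1", "starch synthesis", P),
        ("PPA", "inorganic pyrophosphatase",
         "ppi + h2o --> 2 pi", "ppa1", "starch synthesis", P),
        # --- fatty acid & pentose phosphate (plastid) ---
        ("FAS160", "palmitate synthesis (lumped)",
         "8 accoa + 14 nadph + 7 atp + h2o --> hdca + 8 coa + 14 nadp + 7 adp + 7 pi",
         "fas1 and fas2", "fatty acid synthesis", P),
        ("OPP", "oxidative pentose phosphate pathway (lumped, full oxidation)",
         "g6p + 12 nadp + 7 h2o --> 6 co2 + 12 nadph + pi",
         "zwf1 and gnd1", "pentose phosphate pathway", P),
        ("PTAACK", "phosphotransacetylase + acetate kinase (lumped)",
         "accoa + adp + pi --> ac + atp + coa",
         "pat2 and ack2", "fermentation", P),
        # --- glycolysis / gluconeogenesis (plastidic and cytosolic copies) ---
        ("PGI", "phosphoglucose isomerase", "g6p <=> f6p",
         "pgi1", "glycolysis", P + C),
        ("PFK", "phosphofructokinase", "f6p + atp --> fbp + adp",
         "pfk1", "glycolysis", P + C),
        ("FBA", "fructose-bisphosphate aldolase (with triose-P isomerase)",
         "fbp <=> 2 gap", "fba1 or fba2", "glycolysis", P + C),
        ("FBP", "fructose-1,6-bisphosphatase", "fbp + h2o --> f6p + pi",
         "fbp1", "gluconeogenesis", P + C),
        # the plastid NAD-GAPDH is glycolytic-only: the reductive (Calvin)
        # direction in the plastid is strictly NADPH-dependent (GAPDHN above),
        # while the cytosolic copy is reversible and carries gluconeogenesis
        ("GAPDH", "glyceraldehyde-3-P dehydrogenase (with phosphoglycerate kinase)",
         "gap + nad + adp + pi --> pg3 + nadh + atp",
         "gap3", "glycolysis", P),
        ("GAPDHC", "glyceraldehyde-3-P dehydrogenase, cytosolic (with PGK)",
         "gap + nad + adp + pi <=> pg3 + nadh + atp",
         "gap3", "glycolysis", Ch),
        ("ENO", "phosphoglycerate mutase + enolase", "pg3 <=> pep + h2o",
         "eno1", "glycolysis", P + C),
        ("PYK", "pyruvate kinase", "pep + adp --> pyr + atp",
         "pyk1", "glycolysis", P + C),
        # --- cytosolic carbon handling ---
        ("PEPCK", "PEP carboxykinase", "oaa + atp --> pep + co2 + adp",
         "pck1", "gluconeogenesis", C),
        ("PPC", "PEP carboxylase", "pep + co2 + h2o --> oaa + pi",
         "ppc1", "anaplerosis", Ch),
        ("GDH", "glutamate dehydrogenase (aminating)",
         "akg + nh3 + nadh --> glu + nad + h2o",
         "gdh1", "amino acid synthesis", Ch),
        ("AMPS", "AMP synthesis (lumped purine pathway)",
         "2 g6p + 5 nh3 + 4 atp + 9 nad + h2o --> amp + 2 co2 + 4 adp + 5 pi + 9 nadh",
         "pur1 and pur2", "nucleotide synthesis", Ch),
        # --- acetate assimilation (cytosol + microbody) ---
        ("ACS", "acetyl-CoA synthetase (lumped, 2 ATP equivalents)",
         "ac + coa + 2 atp + h2o --> accoa + 2 adp + 2 pi",
         "acs1 or acs2", "acetate assimilation", C + X),
        # --- glyoxylate cycle (microbody) & shared TCA steps ---
        ("CS", "citrate synthase", "oaa + accoa + h2o --> cit + coa",
         "cis1", "glyoxylate cycle", X + M),
        ("ACO", "aconitase", "cit <=> icit",
         "aco1", "glyoxylate cycle", X + M),
        ("ICL", "isocitrate lyase", "icit --> succ + glx",
         "icl1", "glyoxylate cycle", X),
        ("MALS", "malate synthase", "glx + accoa + h2o --> mal + coa",
         "mas1", "glyoxylate cycle", X),
        ("MDH", "malate dehydrogenase", "mal + nad <=> oaa + nadh",
         "mdh1", "TCA cycle", C + M + [("plastid", "literature",
                                        "plastidic NAD-MDH (malate valve)")]),
        # --- TCA cycle & oxidative phosphorylation (mitochondrion) ---
        ("PDH", "pyruvate dehydrogenase", "pyr + coa + nad --> accoa + co2 + nadh",
         "pdh1 and pdh2", "pyruvate oxidation", Mh),
        ("IDH", "isocitrate dehydrogenase", "icit + nad --> akg + co2 + nadh",
         "idh1", "TCA cycle", Mh),
        ("OGDH", "2-oxoglutarate dehydrogenase + succinyl-CoA synthetase (lumped)",
         "akg + nad + adp + pi --> succ + co2 + nadh + atp",
         "ogd1 and scs1", "TCA cycle", Mh),
        ("SDH", "succinate dehydrogenase", "succ + q --> fum + qh2",
         "sdh1 and sdh2", "TCA cycle", M),
        ("FUM", "fumarase", "fum + h2o <=> mal",
         "fum1", "TCA cycle", Mh),
        ("CPLX1", "NADH:ubiquinone oxidoreductase (proton-pumping, lumped ATP yield)",
         "nadh + q + adp + pi --> nad + qh2 + atp + h2o",
         "nuo1 and nuo2", "oxidative phosphorylation", M),
        ("CPLX34", "ubiquinol oxidase (complexes III+IV, lumped ATP yield)",
         "qh2 + 0.5 o2 + adp + pi --> q + 2 h2o + atp",
         "cox1 and cyb1", "oxidative phosphorylation", M),
        # --- maintenance ---
        ("ATPM", "non-growth-associated ATP maintenance",
         "atp + h2o --> adp + pi", "", "maintenance", NONE),
    ]
    if opts.include_cyclic_electron_flow:
        rxns.append(
            ("CEF", "cyclic electron flow around PSI (lumped; ferredoxin catalytic)",
             "photon + adp + pi --> atp + h2o",
             "pgr5 and pgrl1", "cyclic electron flow", P))
    if opts.include_glycolate_dehydrogenase:
        rxns.append(
            ("GLYDH", "glycolate dehydrogenase (ubiquinone-linked, no H2O2)",
             "glyclt + q --> glx + qh2",
             "gyd1", "photorespiration", M))
        rxns.append(
            ("GLXOX", "glyoxylate oxidation to CO2 (lumped)",
             "glx + 2 nad + h2o --> 2 co2 + 2 nadh",
             "gxo1", "photorespiration", Mh))
    if opts.include_plant_style_photorespiration:
        rxns.append(
            ("GOX", "glycolate oxidase (plant-type, H2O2-producing)",
             "glyclt + o2 --> glx + h2o2",
             "gox1", "photorespiration (plant-type)",
             [("microbody", "homolog", "peroxisomal in plants")]))
        rxns.append(
            ("CAT", "catalase", "2 h2o2 --> 2 h2o + o2",
             "cat1", "photorespiration (plant-type)",
             [("microbody", "homolog", "peroxisomal in plants")]))
        rxns.append(
            ("GLYRED", "glyoxylate-to-glycerate recycling (lumped)",
             "2 glx + nadh --> glyct + co2 + nad",
             "hpr1", "photorespiration (plant-type)", Ch))
        rxns.append(
            ("GLYCK", "glycerate kinase", "glyct + atp --> pg3 + adp",
             "glk1", "photorespiration (plant-type)", Ch))
    if opts.include_fermentation:
        rxns.append(
            ("PFL", "pyruvate formate-lyase", "pyr + coa --> accoa + for",
             "pfl1", "fermentation", NONE))
        rxns.append(
            ("ALDADH", "acetaldehyde/alcohol dehydrogenase (lumped)",
             "accoa + 2 nadh --> etoh + coa + 2 nad",
             "adh1", "fermentation", NONE))
        rxns.append(
            ("LDH", "D-lactate dehydrogenase", "pyr + nadh --> lac + nad",
             "ldh1", "fermentation", NONE))
    return rxns


def _transporters(opts: FixtureOptions) -> List[TransporterEntry]:
    T = TransporterEntry
    e, c, p, m, x = ("extracellular", "cytosol", "plastid",
                     "mitochondrion", "microbody")
    entries = [
        # intercellular
        T("photon", e, p, reversible=False),
        T("co2", e, c), T("o2", e, c), T("h2o", e, c),
        T("nh3", e, c, reversible=False), T("pi", e, c, reversible=False),
        T("ac", e, c),
        T("h2", c, e, reversible=False),
        # plastid envelope
        T("gap", c, p, cotransport="pi"), T("g6p", c, p, cotransport="pi"),
        T("atp", c, p, cotransport="adp"), T("pi", c, p),
        T("co2", c, p), T("o2", c, p), T("h2o", c, p),
        T("h2", p, c, reversible=False),
        T("mal", c, p), T("oaa", c, p),
        T("ac", p, c, reversible=False),
        T("glyclt", p, c, reversible=False),
        # mitochondrial membrane
        T("pyr", c, m), T("atp", m, c, cotransport="adp"), T("pi", c, m),
        T("co2", m, c), T("o2", c, m), T("h2o", c, m),
        T("mal", c, m), T("oaa", m, c), T("akg", m, c),
        T("succ", c, m, reversible=False),
        # microbody membrane
        T("ac", c, x, reversible=False),
        T("atp", c, x, cotransport="adp"), T("pi", x, c), T("h2o", c, x),
        T("mal", x, c, reversible=False), T("oaa", c, x, reversible=False),
        T("succ", x, c, reversible=False),
    ]
    if opts.include_glycolate_secretion:
        entries.append(T("glyclt", c, e, reversible=False))
    if opts.include_glycolate_dehydrogenase:
        entries.append(T("glyclt", c, m, reversible=False))
    if opts.include_plant_style_photorespiration:
        entries.append(T("glyclt", c, x, reversible=False))
        entries.append(T("o2", c, x))
        entries.append(T("glx", x, c, reversible=False))
    if opts.include_fermentation:
        entries.append(T("for", c, e, reversible=False))
        entries.append(T("etoh", c, e, reversible=False))
        entries.append(T("lac", c, e, reversible=False))
    return entries


def _exchanges(opts: FixtureOptions) -> Dict[str, Tuple[float, float]]:
    ex = {
        "photon": (-1000.0, 0.0),
        "co2": (-1000.0, 1000.0),
        "o2": (-1000.0, 1000.0),
        "h2o": (-1000.0, 1000.0),
        "nh3": (-1000.0, 0.0),
        "pi": (-1000.0, 0.0),
        "ac": (-ACETATE_UPTAKE_MAX, 1000.0),
        "h2": (0.0, 1000.0),
    }
    if opts.include_glycolate_secretion:
        ex["glyclt"] = (0.0, 1000.0)
    if opts.include_fermentation:
        ex["for"] = (0.0, 1000.0)
        ex["etoh"] = (0.0, 1000.0)
        ex["lac"] = (0.0, 1000.0)
    return ex


def generate_core_network(
    options: Optional[FixtureOptions] = None,
) -> CompartmentalizedModel:
    """Build the canonical algal core network (deterministic)."""
    opts = options or FixtureOptions()
    raw: List[Reaction] = []
    evidence: List[EvidenceRecord] = []
    for rid, name, equation, genes, subsystem, ev in _core_reactions(opts):
        stoich, reversible = parse_reaction_equation(equation)
        raw.append(
            Reaction(
                id=rid, name=name, stoichiometry=stoich, reversible=reversible,
                gene_association=genes, subsystem=subsystem,
            )
        )
        for comp, source, citation in ev:
            evidence.append(EvidenceRecord(rid, comp, source, citation))

    placed = assign_compartments(raw, evidence)
    model = CompartmentalizedModel(id="algal_core", name="algal core network")
    # create compartmentalized metabolites referenced by the placed reactions
    needed: Dict[str, str] = {}
    from .core import SUFFIX_COMPARTMENT

    for rxn in placed:
        for mid in rxn.stoichiometry:
            base, suffix = mid.rsplit("_", 1)
            needed[mid] = SUFFIX_COMPARTMENT[suffix]
    for mid in sorted(needed):
        base = mid.rsplit("_", 1)[0]
        model.add_metabolite(
            Metabolite(
                id=mid, compartment=needed[mid], name=NAMES.get(base, base),
                formula=FORMULAS.get(base),
                is_boundary=needed[mid] == "extracellular",
            )
        )
    # compartment copies of shared enzymes play different pathway roles
    subsystem_overrides = {
        "CS_m": "TCA cycle",
        "ACO_m": "TCA cycle",
        "MDH_m": "TCA cycle",
        "MDH_c": "malate shuttle",
        "MDH_p": "malate valve",
    }
    from dataclasses import replace as _replace

    for rxn in placed:
        if rxn.id in subsystem_overrides:
            rxn = _replace(rxn, subsystem=subsystem_overrides[rxn.id])
        model.add_reaction(rxn)

    model, _counts = add_transporters(
        model, _transporters(opts), formula_table=FORMULAS, names=NAMES
    )
    model = add_exchanges(model, _exchanges(opts), formula_table=FORMULAS, names=NAMES)

    # biomass drains (one per component) + combined biomass equation
    drains = {
        "DM_starch_p": "starch_p",
        "DM_glu_c": "glu_c",
        "DM_amp_c": "amp_c",
        "DM_hdca_p": "hdca_p",
    }
    for drain_id, mid in sorted(drains.items()):
        model.add_reaction(
            Reaction(
                id=drain_id,
                name=f"{model.metabolites[mid].name} biomass drain",
                stoichiometry={mid: -1.0},
                reversible=False,
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="biomass_drain",
                subsystem="biomass",
            )
        )
    model.biomass_components = sorted(drains)
    composition = BiomassComposition(
        condition="default",
        coefficients=BIOMASS_COEFFICIENTS,
        atp_maintenance=GROWTH_ATP_MAINTENANCE,
    )
    model = add_biomass_equation(model, composition, reaction_id="BIOMASS")
    model.validate()
    return model


def seed_gaps(
    model: CompartmentalizedModel, n: int, seed: int
) -> Tuple[CompartmentalizedModel, List[str]]:
    """Delete ``n`` internal reactions to create gaps with known ground truth.

    Deterministic for a given seed.  Deletion prefers sole producers (the
    unique reaction able to produce some metabolite), so the created gaps are
    detectable by producibility screening.  Exchange, transport, biomass and
    maintenance reactions are never deleted.
    """
    candidates = [
        rid
        for rid in model.reaction_ids
        if model.reactions[rid].kind in ("enzymatic", "transport")
        and rid != "ATPM_c"
    ]
    if n >= len(candidates):
        raise ValueError(f"cannot seed {n} gaps: only {len(candidates)} candidates")
    # which reactions are sole structural producers of some metabolite?
    producers: Dict[str, List[str]] = {}
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        for mid, coeff in rxn.stoichiometry.items():
            can_produce = (coeff > 0 and rxn.upper_bound > 0) or (
                coeff < 0 and rxn.lower_bound < 0
            )
            if can_produce:
                producers.setdefault(mid, []).append(rid)
    sole = sorted(
        {rids[0] for rids in producers.values() if len(rids) == 1}
        & set(candidates)
    )
    rng = np.random.default_rng(seed)
    if len(sole) >= n:
        chosen = sorted(rng.choice(sole, size=n, replace=False).tolist())
    else:
        rest = sorted(set(candidates) - set(sole))
        extra = rng.choice(rest, size=n - len(sole), replace=False).tolist()
        chosen = sorted(sole + extra)
    gapped = model.copy()
    for rid in chosen:
        gapped.remove_reaction(rid)
    return gapped, chosen


def fixture_hash(model: CompartmentalizedModel) -> str:
    """Stable content hash of a model (sorted canonical serialization)."""
    h = hashlib.sha256()
    for mid in model.metabolite_ids:
        met = model.metabolites[mid]
        h.update(
            f"M|{met.id}|{met.compartment}|{met.formula}|{int(met.is_boundary)}\n".encode()
        )
    for rid in model.reaction_ids:
        r = model.reactions[rid]
        stoich = ";".join(f"{k}:{v:.12g}" for k, v in sorted(r.stoichiometry.items()))
        h.update(
            f"R|{r.id}|{stoich}|{int(r.reversible)}|{r.lower_bound:.12g}|"
            f"{r.upper_bound:.12g}|{r.gene_association}|{r.kind}|"
            f"{r.compartment_evidence}\n".encode()
        )
    return h.hexdigest()


def export_tables(
    model: CompartmentalizedModel,
    directory: Path,
    options: Optional[FixtureOptions] = None,
) -> Dict[str, Path]:
    """Write the fixture as tab-delimited curation tables plus SBML.

    Emits both the *compartmentalized* reaction table (``reactions.tsv``,
    with suffixed ids) and the *raw* gene-centric inputs
    (``raw_reactions.tsv``, ``evidence.tsv``, ``transporters.tsv``,
    ``exchanges.tsv``) from which the reconstruction pipeline can rebuild
    the model end-to-end, and the formula table used by the elemental
    audit.
    """
    from .core import format_reaction_equation
    from .reconstruction import write_reaction_table
    from .sbml_io import write_sbml

    opts = options or FixtureOptions()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["reactions"] = directory / "reactions.tsv"
    write_reaction_table(model, paths["reactions"])
    paths["sbml"] = directory / "model.xml"
    write_sbml(model, paths["sbml"])
    formula_rows = [
        {"metabolite_id": mid, "formula": model.metabolites[mid].formula or ""}
        for mid in model.metabolite_ids
    ]
    paths["formulas"] = directory / "formulas.tsv"
    pd.DataFrame(formula_rows).to_csv(paths["formulas"], sep="\t", index=False)

    raw_rows, ev_rows = [], []
    for rid, name, equation, genes, subsystem, ev in _core_reactions(opts):
        raw_rows.append(
            {"reaction_id": rid, "name": name, "equation": equation,
             "gene_association": genes, "kind": "enzymatic", "evidence": "",
             "subsystem": subsystem}
        )
        for comp, source, citation in ev:
            ev_rows.append(
                {"enzyme_or_reaction_id": rid, "compartment": comp,
                 "source": source, "citation": citation}
            )
    paths["raw_reactions"] = directory / "raw_reactions.tsv"
    pd.DataFrame(raw_rows).to_csv(paths["raw_reactions"], sep="\t", index=False)
    paths["evidence"] = directory / "evidence.tsv"
    pd.DataFrame(ev_rows).to_csv(paths["evidence"], sep="\t", index=False)

    t_rows = [
        {"species_id": t.species, "compartment_a": t.compartment_a,
         "compartment_b": t.compartment_b, "reversible": t.reversible,
         "cotransport": t.cotransport}
        for t in _transporters(opts)
    ]
    paths["transporters"] = directory / "transporters.tsv"
    pd.DataFrame(t_rows).to_csv(paths["transporters"], sep="\t", index=False)

    x_rows = [
        {"species_id": sp, "lower_bound": lb, "upper_bound": ub}
        for sp, (lb, ub) in sorted(_exchanges(opts).items())
    ]
    paths["exchanges"] = directory / "exchanges.tsv"
    pd.DataFrame(x_rows).to_csv(paths["exchanges"], sep="\t", index=False)
    return paths


def formula_table_for(model: CompartmentalizedModel) -> Dict[str, Optional[str]]:
    """Metabolite-id -> formula map for the elemental audit."""
    return {mid: model.metabolites[mid].formula for mid in model.metabolite_ids}
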