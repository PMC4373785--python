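"""Core model of human brain energy metabolism, with measured study data.

The network covers glycolysis, the pentose phosphate pathway (PPP), the
citric acid cycle, the malate-aspartate and glycerol-phosphate shuttles,
the glutamate/GABA shunt and oxidative phosphorylation: 71 reactions over
89 metabolites with Recon-1 style identifiers, in three compartments
(c cytosol, m mitochondrial matrix, e extracellular).

Extracellular species and the cytosolic currency pools (atp/adp/pi/h and
nadp/nadph) are treated as unbalanced externals: the cytosolic ATP surplus
is the quantity the analysis maximizes, and NADPH-consuming biosynthesis is
outside the network.  Proton bookkeeping across the inner mitochondrial
membrane is explicit (complex I/III/IV pumping, ATP synthase, the
proton-coupled pyruvate, phosphate and glutamate carriers and the
aspartate/glutamate exchanger), so the P/O ratio is a property of the
network rather than a parameter.

Measured cerebral exchange rates (whole brain, mmol/min): glucose uptake
0.284 +/- 0.058, lactate uptake -0.013 +/- 0.032, pyruvate uptake
-0.003 +/- 0.004 (negative = release).  The pentose phosphate pathway
carries 6.9% of glycolysis and the GABA shunt 32% of glucose oxidation;
both are imposed by fixing glucose-6-phosphate dehydrogenase and glutamate
decarboxylase to the corresponding fractions of glucose uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fba import FluxVector, LinearInverseModel, ObjectiveSpec, build_lim
from .lsei import FoldChangeTable
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "BrainStudyData",
    "build_brain_model",
    "derive_fraction_constraints",
    "atp_objective",
    "fixed_exchange_fluxes",
    "brain_fba_lim",
    "brain_ensemble_lim",
    "synthetic_fold_changes",
]

# Reaction table: (id, name, reversible, {species: coeff}, pathway, gene association)
# fmt: off
BRAIN_REACTIONS = [
    # glycolysis and plasma-membrane transport
    ("R_GLCt1r", "glucose transport (uniport)", True,
     {"M_glc_DASH_D_e": -1, "M_glc_DASH_D_c": 1}, "transport", "SLC2A1 or SLC2A3"),
    ("R_HEX1", "hexokinase", False,
     {"M_glc_DASH_D_c": -1, "M_atp_c": -1, "M_adp_c": 1, "M_g6p_c": 1, "M_h_c": 1},
     "glycolysis", "HK1 or HK2"),
    ("R_PGI", "glucose-6-phosphate isomerase", True,
     {"M_g6p_c": -1, "M_f6p_c": 1}, "glycolysis", "GPI"),
    ("R_PFK", "phosphofructokinase", False,
     {"M_f6p_c": -1, "M_atp_c": -1, "M_adp_c": 1, "M_fdp_c": 1, "M_h_c": 1},
     "glycolysis", "PFKM or PFKL or PFKP"),
    ("R_FBA", "fructose-bisphosphate aldolase", True,
     {"M_fdp_c": -1, "M_dhap_c": 1, "M_g3p_c": 1}, "glycolysis", "ALDOA or ALDOC"),
    ("R_TPI", "triose-phosphate isomerase", True,
     {"M_dhap_c": -1, "M_g3p_c": 1}, "glycolysis", "TPI1"),
    ("R_GAPD", "glyceraldehyde-3-phosphate dehydrogenase", True,
     {"M_g3p_c": -1, "M_nad_c": -1, "M_pi_c": -1, "M_13dpg_c": 1, "M_h_c": 1,
      "M_nadh_c": 1}, "glycolysis", "GAPDH"),
    ("R_PGK", "phosphoglycerate kinase", True,
     {"M_3pg_c": -1, "M_atp_c": -1, "M_13dpg_c": 1, "M_adp_c": 1},
     "glycolysis", "PGK1"),
    ("R_PGM", "phosphoglycerate mutase", True,
     {"M_2pg_c": -1, "M_3pg_c": 1}, "glycolysis", "PGAM1"),
    ("R_ENO", "enolase", True,
     {"M_2pg_c": -1, "M_h2o_c": 1, "M_pep_c": 1}, "glycolysis", "ENO1 or ENO2"),
    ("R_PYK", "pyruvate kinase", False,
     {"M_adp_c": -1, "M_h_c": -1, "M_pep_c": -1, "M_atp_c": 1, "M_pyr_c": 1},
     "glycolysis", "PKM"),
    ("R_LDH_L", "L-lactate dehydrogenase", True,
     {"M_lac_DASH_L_c": -1, "M_nad_c": -1, "M_h_c": 1, "M_nadh_c": 1, "M_pyr_c": 1},
     "glycolysis", "LDHA or LDHB"),
    ("R_L_DASH_LACt2r", "L-lactate transport (proton symport)", True,
     {"M_h_e": -1, "M_lac_DASH_L_e": -1, "M_h_c": 1, "M_lac_DASH_L_c": 1},
     "transport", "SLC16A1"),
    ("R_PYRt2r", "pyruvate transport (proton symport)", True,
     {"M_h_e": -1, "M_pyr_e": -1, "M_h_c": 1, "M_pyr_c": 1},
     "transport", "SLC16A1"),
    # pentose phosphate pathway
    ("R_G6PDH2r", "glucose-6-phosphate dehydrogenase", True,
     {"M_g6p_c": -1, "M_nadp_c": -1, "M_6pgl_c": 1, "M_h_c": 1, "M_nadph_c": 1},
     "ppp", "G6PD"),
    ("R_PGL", "6-phosphogluconolactonase", False,
     {"M_6pgl_c": -1, "M_h2o_c": -1, "M_6pgc_c": 1, "M_h_c": 1}, "ppp", "PGLS"),
    ("R_GND", "phosphogluconate dehydrogenase", False,
     {"M_6pgc_c": -1, "M_nadp_c": -1, "M_co2_c": 1, "M_nadph_c": 1,
      "M_ru5p_DASH_D_c": 1}, "ppp", "PGD"),
    ("R_RPI", "ribose-5-phosphate isomerase", True,
     {"M_r5p_c": -1, "M_ru5p_DASH_D_c": 1}, "ppp", "RPIA"),
    ("R_RPE", "ribulose-5-phosphate 3-epimerase", True,
     {"M_ru5p_DASH_D_c": -1, "M_xu5p_DASH_D_c": 1}, "ppp", "RPE"),
    ("R_TKT1", "transketolase 1", True,
     {"M_r5p_c": -1, "M_xu5p_DASH_D_c": -1, "M_g3p_c": 1, "M_s7p_c": 1},
     "ppp", "TKT"),
    ("R_TALA", "transaldolase", True,
     {"M_g3p_c": -1, "M_s7p_c": -1, "M_e4p_c": 1, "M_f6p_c": 1}, "ppp", "TALDO1"),
    ("R_TKT2", "transketolase 2", True,
     {"M_e4p_c": -1, "M_xu5p_DASH_D_c": -1, "M_f6p_c": 1, "M_g3p_c": 1},
     "ppp", "TKT"),
    # pyruvate entry and citric acid cycle
    ("R_PYRt2m", "mitochondrial pyruvate carrier (proton symport)", False,
     {"M_h_c": -1, "M_pyr_c": -1, "M_h_m": 1, "M_pyr_m": 1},
     "transport", "MPC1 and MPC2"),
    ("R_PDHm", "pyruvate dehydrogenase", False,
     {"M_coa_m": -1, "M_nad_m": -1, "M_pyr_m": -1, "M_accoa_m": 1, "M_co2_m": 1,
      "M_nadh_m": 1}, "tca", "PDHA1 and PDHB and DLAT and DLD"),
    ("R_CSm", "citrate synthase", False,
     {"M_accoa_m": -1, "M_h2o_m": -1, "M_oaa_m": -1, "M_cit_m": 1, "M_coa_m": 1,
      "M_h_m": 1}, "tca", "CS"),
    ("R_ACONTm", "aconitase (mitochondrial)", True,
     {"M_cit_m": -1, "M_icit_m": 1}, "tca", "ACO2"),
    ("R_ICDHxm", "isocitrate dehydrogenase (NAD)", False,
     {"M_icit_m": -1, "M_nad_m": -1, "M_akg_m": 1, "M_co2_m": 1, "M_nadh_m": 1},
     "tca", "IDH3A and IDH3B and IDH3G"),
    ("R_AKGDm", "alpha-ketoglutarate dehydrogenase", False,
     {"M_akg_m": -1, "M_coa_m": -1, "M_nad_m": -1, "M_co2_m": 1, "M_nadh_m": 1,
      "M_succoa_m": 1}, "tca", "OGDH and DLST and DLD"),
    ("R_SUCOAS1m", "succinyl-CoA synthetase (GDP)", True,
     {"M_gdp_m": -1, "M_pi_m": -1, "M_succoa_m": -1, "M_coa_m": 1, "M_gtp_m": 1,
      "M_succ_m": 1}, "tca", "SUCLG1 and SUCLG2"),
    ("R_SUCD1m", "succinate dehydrogenase", True,
     {"M_q10_m": -1, "M_succ_m": -1, "M_fum_m": 1, "M_q10h2_m": 1},
     "tca", "SDHA and SDHB and SDHC and SDHD"),
    ("R_FUMm", "fumarase (mitochondrial)", True,
     {"M_fum_m": -1, "M_h2o_m": -1, "M_mal_DASH_L_m": 1}, "tca", "FH"),
    ("R_MDHm", "malate dehydrogenase (mitochondrial)", True,
     {"M_mal_DASH_L_m": -1, "M_nad_m": -1, "M_h_m": 1, "M_nadh_m": 1,
      "M_oaa_m": 1}, "tca", "MDH2"),
    ("R_NDPK1m", "nucleoside-diphosphate kinase (mitochondrial)", True,
     {"M_atp_m": -1, "M_gdp_m": -1, "M_adp_m": 1, "M_gtp_m": 1}, "tca", "NME4"),
    # oxidative phosphorylation
    ("R_NADH2_DASH_u10m", "NADH dehydrogenase (complex I)", False,
     {"M_h_m": -5, "M_nadh_m": -1, "M_q10_m": -1, "M_h_c": 4, "M_nad_m": 1,
      "M_q10h2_m": 1}, "oxphos", "NDUFS1 and NDUFS2 and NDUFV1"),
    ("R_CYOR_DASH_u10m", "ubiquinol-cytochrome c reductase (complex III)", False,
     {"M_ficytC_m": -2, "M_h_m": -2, "M_q10h2_m": -1, "M_focytC_m": 2, "M_h_c": 4,
      "M_q10_m": 1}, "oxphos", "UQCRC1 and UQCRC2 and CYC1"),
    ("R_CYOOm2", "cytochrome c oxidase (complex IV)", False,
     {"M_focytC_m": -4, "M_h_m": -8, "M_o2_m": -1, "M_ficytC_m": 4, "M_h_c": 4,
      "M_h2o_m": 2}, "oxphos", "COX4I1 and COX5A and COX6C"),
    ("R_ATPS4m", "ATP synthase (F0/F1)", False,
     {"M_adp_m": -1, "M_h_c": -4, "M_pi_m": -1, "M_atp_m": 1, "M_h2o_m": 1,
      "M_h_m": 3}, "oxphos", "ATP5F1A and ATP5F1B and ATP5F1C"),
    ("R_ATPtm", "ADP/ATP translocase", True,
     {"M_adp_c": -1, "M_atp_m": -1, "M_adp_m": 1, "M_atp_c": 1},
     "transport", "SLC25A4 or SLC25A5"),
    ("R_PIt2m", "phosphate carrier (proton symport)", True,
     {"M_h_c": -1, "M_pi_c": -1, "M_h_m": 1, "M_pi_m": 1},
     "transport", "SLC25A3"),
    # malate-aspartate shuttle
    ("R_MDH", "malate dehydrogenase (cytosolic)", True,
     {"M_mal_DASH_L_c": -1, "M_nad_c": -1, "M_h_c": 1, "M_nadh_c": 1,
      "M_oaa_c": 1}, "malate_aspartate_shuttle", "MDH1"),
    ("R_ASPTA", "aspartate transaminase (cytosolic)", True,
     {"M_akg_c": -1, "M_asp_DASH_L_c": -1, "M_glu_DASH_L_c": 1, "M_oaa_c": 1},
     "malate_aspartate_shuttle", "GOT1"),
    ("R_ASPTAm", "aspartate transaminase (mitochondrial)", True,
     {"M_akg_m": -1, "M_asp_DASH_L_m": -1, "M_glu_DASH_L_m": 1, "M_oaa_m": 1},
     "malate_aspartate_shuttle", "GOT2"),
    ("R_AKGMAL", "alpha-ketoglutarate/malate antiport", True,
     {"M_akg_m": -1, "M_mal_DASH_L_c": -1, "M_akg_c": 1, "M_mal_DASH_L_m": 1},
     "malate_aspartate_shuttle", "SLC25A11"),
    ("R_ASPGLUm", "aspartate/glutamate exchanger (proton-coupled)", False,
     {"M_asp_DASH_L_m": -1, "M_glu_DASH_L_c": -1, "M_h_c": -1, "M_asp_DASH_L_c": 1,
      "M_glu_DASH_L_m": 1, "M_h_m": 1}, "malate_aspartate_shuttle",
     "SLC25A12 or SLC25A13"),
    # glutamate and GABA shunt
    ("R_GLUDC", "glutamate decarboxylase", False,
     {"M_glu_DASH_L_c": -1, "M_h_c": -1, "M_4abut_c": 1, "M_co2_c": 1},
     "gaba_shunt", "GAD1 or GAD2"),
    ("R_ABTA", "4-aminobutyrate transaminase", True,
     {"M_4abut_c": -1, "M_akg_c": -1, "M_glu_DASH_L_c": 1, "M_sucsal_c": 1},
     "gaba_shunt", "ABAT"),
    ("R_SSALx", "succinate-semialdehyde dehydrogenase", False,
     {"M_h2o_c": -1, "M_nad_c": -1, "M_sucsal_c": -1, "M_h_c": 2, "M_nadh_c": 1,
      "M_succ_c": 1}, "gaba_shunt", "ALDH5A1"),
    ("R_GLUDym", "glutamate dehydrogenase (NAD)", True,
     {"M_glu_DASH_L_m": -1, "M_h2o_m": -1, "M_nad_m": -1, "M_akg_m": 1, "M_h_m": 1,
      "M_nadh_m": 1, "M_nh4_m": 1}, "gaba_shunt", "GLUD1"),
    ("R_GLNS", "glutamine synthetase", False,
     {"M_atp_c": -1, "M_glu_DASH_L_c": -1, "M_nh4_c": -1, "M_adp_c": 1,
      "M_gln_DASH_L_c": 1, "M_h_c": 1, "M_pi_c": 1}, "gaba_shunt", "GLUL"),
    ("R_GLUt2m", "mitochondrial glutamate carrier (proton symport)", True,
     {"M_glu_DASH_L_c": -1, "M_h_c": -1, "M_glu_DASH_L_m": 1, "M_h_m": 1},
     "transport", "SLC25A18 or SLC25A22"),
    ("R_SUCCtm", "mitochondrial dicarboxylate carrier (succinate)", True,
     {"M_succ_c": -1, "M_succ_m": 1}, "transport", "SLC25A10"),
    ("R_AKGtm", "oxoglutarate efflux carrier", False,
     {"M_akg_m": -1, "M_akg_c": 1}, "transport", "SLC25A21"),
    # glycerol-phosphate shuttle
    ("R_G3PD1", "glycerol-3-phosphate dehydrogenase (NAD, cytosolic)", True,
     {"M_glyc3p_c": -1, "M_nad_c": -1, "M_dhap_c": 1, "M_h_c": 1, "M_nadh_c": 1},
     "glycerol_phosphate_shuttle", "GPD1"),
    ("R_G3PD2m", "glycerol-3-phosphate dehydrogenase (FAD, mitochondrial)", False,
     {"M_glyc3p_c": -1, "M_q10_m": -1, "M_dhap_c": 1, "M_q10h2_m": 1},
     "glycerol_phosphate_shuttle", "GPD2"),
    # gas and water transport
    ("R_O2t", "oxygen transport (diffusion)", True,
     {"M_o2_e": -1, "M_o2_c": 1}, "transport", None),
    ("R_O2tm", "oxygen transport, mitochondrial", True,
     {"M_o2_c": -1, "M_o2_m": 1}, "transport", None),
    ("R_CO2t", "CO2 transport (diffusion)", True,
     {"M_co2_e": -1, "M_co2_c": 1}, "transport", None),
    ("R_CO2tm", "CO2 transport, mitochondrial", True,
     {"M_co2_c": -1, "M_co2_m": 1}, "transport", None),
    ("R_H2Ot", "water transport", True,
     {"M_h2o_e": -1, "M_h2o_c": 1}, "transport", "AQP4"),
    ("R_H2Otm", "water transport, mitochondrial", True,
     {"M_h2o_c": -1, "M_h2o_m": 1}, "transport", None),
    # peripheral core reactions
    ("R_CITtam", "citrate/malate antiport", True,
     {"M_cit_m": -1, "M_mal_DASH_L_c": -1, "M_cit_c": 1, "M_mal_DASH_L_m": 1},
     "transport", "SLC25A1"),
    ("R_ACONT", "aconitase (cytosolic)", True,
     {"M_cit_c": -1, "M_icit_c": 1}, "tca", "ACO1"),
    ("R_ME1m", "malic enzyme (NAD, mitochondrial)", False,
     {"M_mal_DASH_L_m": -1, "M_nad_m": -1, "M_co2_m": 1, "M_nadh_m": 1,
      "M_pyr_m": 1}, "tca", "ME2"),
    ("R_ME2m", "malic enzyme (NADP, mitochondrial)", False,
     {"M_mal_DASH_L_m": -1, "M_nadp_m": -1, "M_co2_m": 1, "M_nadph_m": 1,
      "M_pyr_m": 1}, "tca", "ME3"),
    ("R_CK", "creatine kinase", True,
     {"M_atp_c": -1, "M_creat_c": -1, "M_adp_c": 1, "M_pcreat_c": 1, "M_h_c": 1},
     "energy_buffering", "CKB"),
    ("R_ADK1", "adenylate kinase", True,
     {"M_amp_c": -1, "M_atp_c": -1, "M_adp_c": 2}, "energy_buffering", "AK1"),
    ("R_HCO3E", "carbonic anhydrase", True,
     {"M_co2_c": -1, "M_h2o_c": -1, "M_h_c": 1, "M_hco3_c": 1}, "transport", "CA2"),
    ("R_GLCP", "glycogen phosphorylase", False,
     {"M_glygn2_c": -1, "M_pi_c": -1, "M_g1p_c": 1}, "glycogen", "PYGB"),
    ("R_PGMT", "phosphoglucomutase", True,
     {"M_g1p_c": -1, "M_g6p_c": 1}, "glycogen", "PGM1"),
    ("R_PPA", "inorganic pyrophosphatase", False,
     {"M_h2o_c": -1, "M_ppi_c": -1, "M_h_c": 1, "M_pi_c": 2},
     "energy_buffering", "PPA1"),
    ("R_FUM", "fumarase (cytosolic)", True,
     {"M_fum_c": -1, "M_h2o_c": -1, "M_mal_DASH_L_c": 1}, "tca", "FH"),
]
# fmt: on

#: species that are not balanced to zero: the extracellular pool and the
#: cytosolic currency metabolites
EXTERNAL_SPECIES = frozenset({
    "M_glc_DASH_D_e", "M_lac_DASH_L_e", "M_pyr_e", "M_h_e", "M_o2_e",
    "M_co2_e", "M_h2o_e",
    "M_atp_c", "M_adp_c", "M_pi_c", "M_h_c", "M_nadp_c", "M_nadph_c",
})


@dataclass(frozen=True)
class BrainStudyData:
    """Measured cerebral exchange rates and pathway fractions (whole brain).

    Uptakes are medians +/- standard deviation in mmol/min; negative uptake
    means release.  ``ppp_fraction`` is the share of glycolysis routed
    through the pentose phosphate pathway; ``gaba_fraction`` the share of
    glucose oxidation through the GABA shunt.
    """

    glucose_uptake: tuple[float, float] = (0.284, 0.058)
    lactate_uptake: tuple[float, float] = (-0.013, 0.032)
    pyruvate_uptake: tuple[float, float] = (-0.003, 0.004)
    ppp_fraction: float = 0.069
    gaba_fraction: float = 0.32
    brain_mass_kg: float = 1.4

    def __post_init__(self):
        for label, (_, sd) in (("glucose", self.glucose_uptake),
                               ("lactate", self.lactate_uptake),
                               ("pyruvate", self.pyruvate_uptake)):
            if sd < 0:
                raise ValueError(f"{label} sd must be >= 0")
        for label, frac in (("ppp_fraction", self.ppp_fraction),
                            ("gaba_fraction", self.gaba_fraction)):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{label} must be in (0, 1)")


def build_brain_model() -> MetabolicModel:
    """Construct the 71-reaction / 89-metabolite brain core model."""
    species = sorted({m for _, _, _, st, _, _ in BRAIN_REACTIONS for m in st})
    metabolites = [
        Metabolite(
            id=s,
            name=s[2:].replace("_DASH_", "-"),
            compartment=s.rsplit("_", 1)[-1],
            is_boundary=s in EXTERNAL_SPECIES,
        )
        for s in species
    ]
    reactions = []
    annotations: dict[str, list[str]] = {}
    for rid, name, rev, stoich, pathway, gpr in BRAIN_REACTIONS:
        reactions.append(
            Reaction(id=rid, name=name, stoichiometry=dict(stoich),
                     reversible=rev, gene_association=gpr)
        )
        annotations.setdefault(pathway, []).append(rid)
    return MetabolicModel(metabolites=metabolites, reactions=reactions,
                          annotations=annotations, id="brain_core_metabolism")


def derive_fraction_constraints(data: BrainStudyData) -> tuple[float, float]:
    """Fraction-of-glucose-uptake constraints, rounded to 3 decimals.

    Returns (g6pd_flux, gad_flux): glucose-6-phosphate dehydrogenase carries
    the PPP fraction of glucose uptake, glutamate decarboxylase the GABA
    fraction.
    """
    glc = data.glucose_uptake[0]
    return (round(glc * data.ppp_fraction, 3), round(glc * data.gaba_fraction, 3))


def atp_objective() -> ObjectiveSpec:
    """Net ATP production: synthase plus glycolytic ATP balance.

    ATP synthase and pyruvate kinase produce ATP (+); hexokinase and
    phosphofructokinase consume it (-).  The phosphoglycerate-kinase and
    mitochondrial nucleoside-diphosphate-kinase reactions are written in the
    ATP-consuming direction, so ATP production corresponds to negative flux
    and they enter with weight -1.
    """
    return ObjectiveSpec(
        {"R_ATPS4m": 1.0, "R_NDPK1m": -1.0, "R_HEX1": -1.0, "R_PFK": -1.0,
         "R_PGK": -1.0, "R_PYK": 1.0},
        sense="maximize",
    )


def fixed_exchange_fluxes(data: BrainStudyData | None = None) -> dict[str, float]:
    """Equality constraints for the FBA run: measured exchanges plus the
    fraction-derived G6PD and GAD fluxes."""
    data = data or BrainStudyData()
    g6pd, gad = derive_fraction_constraints(data)
    return {
        "R_GLCt1r": data.glucose_uptake[0],
        "R_L_DASH_LACt2r": data.lactate_uptake[0],
        "R_PYRt2r": data.pyruvate_uptake[0],
        "R_G6PDH2r": g6pd,
        "R_GLUDC": gad,
    }


def brain_fba_lim(data: BrainStudyData | None = None) -> LinearInverseModel:
    """Constraint system for the healthy-brain FBA (all exchanges fixed)."""
    return build_lim(build_brain_model(), fixed_fluxes=fixed_exchange_fluxes(data))


def brain_ensemble_lim(data: BrainStudyData | None = None) -> LinearInverseModel:
    """Constraint system for ensemble sampling.

    Exchange fluxes become approximate equalities with their measurement
    standard deviations; the fraction-derived G6PD/GAD fluxes stay fixed and
    the glycerol-3-phosphate dehydrogenase flux is additionally fixed to
    zero to suppress the thermodynamically implausible reversal of the
    malate-aspartate shuttle via the glycerol-phosphate shuttle.
    """
    data = data or BrainStudyData()
    g6pd, gad = derive_fraction_constraints(data)
    return build_lim(
        build_brain_model(),
        fixed_fluxes={"R_G6PDH2r": g6pd, "R_GLUDC": gad, "R_G3PD2m": 0.0},
        measured_fluxes={
            "R_GLCt1r": data.glucose_uptake,
            "R_L_DASH_LACt2r": data.lactate_uptake,
            "R_PYRt2r": data.pyruvate_uptake,
        },
    )


def synthetic_fold_changes(
    model: MetabolicModel,
    pathway_effects: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FoldChangeTable:
    """Generate a synthetic per-gene log2 fold-change table.

    Emulates microarray-derived disease-vs-control contrasts in which a
    pathway shows many small, largely congruent expression shifts: every
    gene associated with a reaction of pathway p draws
    log2 fc ~ Normal(effect_p, noise_sd); genes outside the listed pathways
    draw from Normal(0, noise_sd).  A gene appearing in several listed
    pathways gets the mean of their effects.  Deterministic under ``seed``.
    """
    from .model import extract_gene_associations

    unknown = [p for p in pathway_effects if p not in model.annotations]
    if unknown:
        raise KeyError(f"unknown pathways: {unknown}")
    assoc = extract_gene_associations(model)
    gene_effects: dict[str, list[float]] = {}
    for rid, genes in assoc.items():
        for g in genes:
            gene_effects.setdefault(g, [])
    for pathway, effect in pathway_effects.items():
        members = set(model.annotations[pathway])
        for rid, genes in assoc.items():
            if rid in members:
                for g in genes:
                    gene_effects[g].append(float(effect))
    rng = np.random.default_rng(seed)
    entries = {}
    for g in sorted(gene_effects):
        mean = float(np.mean(gene_effects[g])) if gene_effects[g] else 0.0
        entries[g] = mean + noise_sd * rng.standard_normal()
    return FoldChangeTable(entries, source_scale="log2")
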