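# Engineered butanol / butanol-precursor pathway definitions.
#
# Every reaction is written in BiGG nomenclature against the reduced E. coli
# core model (77 reactions, 63 metabolites).  All equations are elementally
# and charge balanced; products leave through dedicated irreversible export
# and sink reactions that drain the target out of the network.
#
# The declared `atp` and `nadph_pool` coefficients are the net sums of the
# respective stoichiometric coefficients over all introduced reactions
# (acetyl-CoA through to the final target); they are validated at build time.

metabolites:
  aacoa_c:    {name: Acetoacetyl-CoA,          formula: C25H36N7O18P3S, charge: -4, compartment: c}
  3hbcoa_c:   {name: (S)-3-Hydroxybutyryl-CoA, formula: C25H38N7O18P3S, charge: -4, compartment: c}
  b2coa_c:    {name: Crotonyl-CoA,             formula: C25H36N7O17P3S, charge: -4, compartment: c}
  btcoa_c:    {name: Butyryl-CoA,              formula: C25H38N7O17P3S, charge: -4, compartment: c}
  btal_c:     {name: Butyraldehyde,            formula: C4H8O,   charge: 0,  compartment: c}
  btal_e:     {name: Butyraldehyde (ext),      formula: C4H8O,   charge: 0,  compartment: e}
  btoh_c:     {name: 1-Butanol,                formula: C4H10O,  charge: 0,  compartment: c}
  btoh_e:     {name: 1-Butanol (ext),          formula: C4H10O,  charge: 0,  compartment: e}
  malcoa_c:   {name: Malonyl-CoA,              formula: C24H33N7O19P3S, charge: -5, compartment: c}
  hco3_c:     {name: Bicarbonate,              formula: CHO3,    charge: -1, compartment: c}
  but_c:      {name: Butyrate,                 formula: C4H7O2,  charge: -1, compartment: c}
  but_e:      {name: Butyrate (ext),           formula: C4H7O2,  charge: -1, compartment: e}
  b2ac_c:     {name: Crotonate,                formula: C4H5O2,  charge: -1, compartment: c}
  b2ac_e:     {name: Crotonate (ext),          formula: C4H5O2,  charge: -1, compartment: e}
  ppi_c:      {name: Diphosphate,              formula: HO7P2,   charge: -3, compartment: c}
  ACP_c:      {name: Acyl carrier protein,     formula: C11H21N2O7PRS,  charge: -1, compartment: c}
  acACP_c:    {name: Acetyl-ACP,               formula: C13H23N2O8PRS,  charge: -1, compartment: c}
  malACP_c:   {name: Malonyl-ACP,              formula: C14H22N2O10PRS, charge: -2, compartment: c}
  actACP_c:   {name: Acetoacetyl-ACP,          formula: C15H25N2O9PRS,  charge: -1, compartment: c}
  3haACP_c:   {name: 3-Hydroxybutyryl-ACP,     formula: C15H27N2O9PRS,  charge: -1, compartment: c}
  but2eACP_c: {name: But-2-enoyl-ACP,          formula: C15H25N2O8PRS,  charge: -1, compartment: c}
  butACP_c:   {name: Butyryl-ACP,              formula: C15H27N2O8PRS,  charge: -1, compartment: c}

reactions:
  ATOB:      {name: Acetyl-CoA acetyltransferase (AtoB),        equation: "2 accoa_c --> aacoa_c + coa_c"}
  HCO3E:     {name: Carbonic anhydrase,                         equation: "co2_c + h2o_c <=> h_c + hco3_c"}
  ACCOAC:    {name: Acetyl-CoA carboxylase,                     equation: "accoa_c + atp_c + hco3_c --> adp_c + h_c + malcoa_c + pi_c"}
  NPHT7:     {name: Acetoacetyl-CoA synthase (NphT7),           equation: "accoa_c + h_c + malcoa_c --> aacoa_c + co2_c + coa_c"}
  HBD:       {name: 3-Hydroxybutyryl-CoA dehydrogenase,         equation: "aacoa_c + h_c + nadh_c --> 3hbcoa_c + nad_c"}
  CROTZ:     {name: Crotonase,                                  equation: "3hbcoa_c --> b2coa_c + h2o_c"}
  TER:       {name: Trans-enoyl-CoA reductase,                  equation: "b2coa_c + h_c + nadh_c --> btcoa_c + nad_c"}
  BTCOARX:   {name: Butyryl-CoA reductase (AdhE2 N-domain),     equation: "btcoa_c + h_c + nadh_c --> btal_c + coa_c + nad_c"}
  ALCD4:     {name: Butyraldehyde reductase (AdhE2 C-domain),   equation: "btal_c + h_c + nadh_c --> btoh_c + nad_c"}
  TESB:      {name: Butyryl-CoA thioesterase,                   equation: "btcoa_c + h2o_c --> but_c + coa_c + h_c"}
  CAR:       {name: Carboxylic acid reductase (PPi lumped),     equation: "but_c + atp_c + h2o_c + nadph_c --> btal_c + amp_c + nadp_c + 2 pi_c"}
  CARP:      {name: Carboxylic acid reductase,                  equation: "but_c + atp_c + h_c + nadph_c --> btal_c + amp_c + nadp_c + ppi_c"}
  PPA:       {name: Inorganic pyrophosphatase,                  equation: "h2o_c + ppi_c --> h_c + 2 pi_c"}
  TESC:      {name: Crotonyl-CoA thioesterase,                  equation: "b2coa_c + h2o_c --> b2ac_c + coa_c + h_c"}
  MCOATA:    {name: Malonyl-CoA-ACP transacylase (FabD),        equation: "ACP_c + malcoa_c <=> coa_c + malACP_c"}
  ACOATA:    {name: Acetyl-CoA-ACP transacylase,                equation: "ACP_c + accoa_c <=> acACP_c + coa_c"}
  KAS:       {name: 3-Oxoacyl-ACP synthase,                     equation: "acACP_c + h_c + malACP_c --> ACP_c + actACP_c + co2_c"}
  KAR:       {name: 3-Oxoacyl-ACP reductase (FabG),             equation: "actACP_c + h_c + nadph_c --> 3haACP_c + nadp_c"}
  HAD:       {name: 3-Hydroxyacyl-ACP dehydratase,              equation: "3haACP_c --> but2eACP_c + h2o_c"}
  EAR:       {name: Enoyl-ACP reductase (FabI),                 equation: "but2eACP_c + h_c + nadh_c --> butACP_c + nad_c"}
  TESA:      {name: Butyryl-ACP thioesterase,                   equation: "butACP_c + h2o_c --> ACP_c + but_c + h_c"}
  BTOHt:     {name: Butanol export,                             equation: "btoh_c --> btoh_e"}
  BTALt:     {name: Butyraldehyde export,                       equation: "btal_c --> btal_e"}
  BTACt:     {name: Butyrate export,                            equation: "but_c --> but_e"}
  CROACt:    {name: Crotonate export,                           equation: "b2ac_c --> b2ac_e"}
  BTOH_sink: {name: Butanol sink,                               equation: "btoh_e --> "}
  BTAL_sink: {name: Butyraldehyde sink,                         equation: "btal_e --> "}
  BTAC_sink: {name: Butyrate sink,                              equation: "but_e --> "}
  CROAC_sink: {name: Crotonate sink,                            equation: "b2ac_e --> "}

pathways:
  BuOH-0:
    description: AtoB + CP + AdhE2
    reactions: [ATOB, HBD, CROTZ, TER, BTCOARX, ALCD4, BTOHt, BTOH_sink]
    target_metabolite: btoh_e
    sink: BTOH_sink
    atp: 0
    nadph_pool: -4
  BuOH-1:
    description: NphT7 + CP + AdhE2
    reactions: [HCO3E, ACCOAC, NPHT7, HBD, CROTZ, TER, BTCOARX, ALCD4, BTOHt, BTOH_sink]
    target_metabolite: btoh_e
    sink: BTOH_sink
    atp: -1
    nadph_pool: -4
  tpcBuOH:
    description: AtoB + CP + TPC7
    reactions: [ATOB, HBD, CROTZ, TER, TESB, CAR, ALCD4, BTOHt, BTOH_sink]
    target_metabolite: btoh_e
    sink: BTOH_sink
    atp: -1
    nadph_pool: -4
  BuOH-2:
    description: NphT7 + CP + TPC7
    reactions: [HCO3E, ACCOAC, NPHT7, HBD, CROTZ, TER, TESB, CAR, ALCD4, BTOHt, BTOH_sink]
    target_metabolite: btoh_e
    sink: BTOH_sink
    atp: -2
    nadph_pool: -4
  fasBuOH:
    description: Butyryl-ACP route (FAS)
    reactions: [HCO3E, ACCOAC, MCOATA, ACOATA, KAS, KAR, HAD, EAR, TESA, CARP, PPA, ALCD4, BTOHt, BTOH_sink]
    target_metabolite: btoh_e
    sink: BTOH_sink
    atp: -2
    nadph_pool: -4
  CROT:
    description: AtoB + CP (crotonate)
    reactions: [ATOB, HBD, CROTZ, TESC, CROACt, CROAC_sink]
    target_metabolite: b2ac_e
    sink: CROAC_sink
    atp: 0
    nadph_pool: -1
  BUTYR:
    description: AtoB + CP (butyrate)
    reactions: [ATOB, HBD, CROTZ, TER, TESB, BTACt, BTAC_sink]
    target_metabolite: but_e
    sink: BTAC_sink
    atp: 0
    nadph_pool: -2
  BUTAL:
    description: AtoB + CP (butyraldehyde)
    reactions: [ATOB, HBD, CROTZ, TER, BTCOARX, BTALt, BTAL_sink]
    target_metabolite: btal_e
    sink: BTAL_sink
    atp: 0
    nadph_pool: -3
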