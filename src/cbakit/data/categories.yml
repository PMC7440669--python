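# Default category rules for the co-factor balance assessment.
#
# Classification is id-based: target reactions are filled in per variant from
# its pathway definition, the biomass reaction collects growth-associated
# consumption, and the waste lists below collect (i) ATP-hydrolysing
# maintenance/recycling reactions, (ii) ATP formed on the acetate overflow
# branch, (iii) dehydrogenases that make NAD(P)H while releasing CO2 and
# (iv) fermentative NAD(P)H re-oxidation.  Ids missing from a given model are
# skipped with a warning.

cofactors:
  ATP: [atp_c]
  NAD(P)H: [nadh_c, nadph_c]

split_cofactors:
  NADH: [nadh_c]
  NADPH: [nadph_c]

biomass: [Biomass_Ecoli_core]

waste:
  ATP: [ATPM, ADK1, ACKr]
  NAD(P)H: [GND, PDH, AKGDH, ICDHyr, LDH_D, ALCD2x, ACALD, ADHEr]

# Oxidative pentose-phosphate dehydrogenases, used for the PPP share of total
# NAD(P)H production.
ppp_production: [G6PDH2r, GND]
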