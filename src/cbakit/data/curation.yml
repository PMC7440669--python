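# Futile-cycle curation settings.
#
# Each candidate names the reaction that is capped when the cycle appears
# (the member that does not itself burn the co-factor, or that is inactive in
# the wild type) together with the partner reactions that close the loop.
# Detection compares the engineered flux against the wild-type flux envelope
# [min(0, v_wt), max(0, v_wt)] widened by `threshold` (mmol gDW-1 hr-1).

atpm_cap: 7.6
threshold: 1.0

candidates:
  - {cap: FBP,     partners: [PFK],         cofactor: ATP}
  - {cap: PPCK,    partners: [PPC],         cofactor: ATP}
  - {cap: PPS,     partners: [PYK],         cofactor: ATP}
  - {cap: ME1,     partners: [PPC, MDH],    cofactor: "NAD(P)H"}
  - {cap: ME2,     partners: [PPC, MDH],    cofactor: "NAD(P)H"}
  - {cap: NADTRHD, partners: [THD2],        cofactor: "NAD(P)H"}
  - {cap: THD2,    partners: [NADTRHD],     cofactor: "NAD(P)H"}
  - {cap: FRD7,    partners: [SUCDi],       cofactor: "NAD(P)H"}
  - {cap: ATPS4r,  partners: [],            cofactor: ATP}
  - {cap: GLUN,    partners: [GLNS],        cofactor: ATP}
  - {cap: GLUSy,   partners: [GLNS, GLUDy], cofactor: "NAD(P)H"}
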