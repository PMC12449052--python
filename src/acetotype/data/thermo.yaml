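# Reaction definitions and standard transformed Gibbs energies (kJ/mol,
# 25 degC, pH 7) for the competing ruminal H2 sinks. Values follow classic
# anaerobe bioenergetics tables (Thauer, Jungermann & Decker 1977 and
# descendants); edit to substitute your own constant set. The reducing
# equivalent token "[H]" is one proton plus one electron and enters reaction
# quotients as half an H2 unless a carrier model is configured.
constant_set: thauer1977_class
reactions:
  glucose_fermentation:
    # classic fermentation of glucose to two acetate; water is an explicit
    # reactant so the equation balances elementally
    stoich: {glucose: -1, H2O: -2, acetate: 2, CO2: 2, "[H]": 8}
    dG0_prime: -216.0
  wl_acetogenesis:
    # the Wood-Ljungdahl sink: two CO2 reduced to one acetate with 8 [H]
    stoich: {CO2: -2, "[H]": -8, acetate: 1, H2O: 2}
    dG0_prime: -94.9
  hydrogenotrophic_methanogenesis:
    stoich: {CO2: -1, "[H]": -8, CH4: 1, H2O: 2}
    dG0_prime: -131.0
conditions:
  temperature_K: 312.65        # 39.5 degC, rumen incubation temperature
  R_kJ_per_mol_K: 0.008314462618
  henry_h2_M_per_atm: 7.8e-4   # headspace <-> dissolved H2 conversion
  activities:                  # default molar activities, rumen-like
    glucose: 1.0e-5
    acetate: 0.06
    CO2: 0.02
    CH4: 1.0e-3
    formate: 1.0e-5
    H2: 1.0e-6
    H2O: 1.0
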