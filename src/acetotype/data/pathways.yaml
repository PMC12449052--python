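# Gene sets used for pathway-completeness fractions. These follow standard
# KEGG module composition for the three fermentative glucose-degradation
# routes; edit freely to match your annotation source's symbol set.
glycolysis_em: [glk, pgi, pfkA, fba, tpiA, gap, pgk, gpmA, eno, pyk]
pentose_phosphate: [zwf, pgl, gnd, rpe, rpiA, tktA, talB]
entner_doudoroff: [zwf, pgl, edd, eda]
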