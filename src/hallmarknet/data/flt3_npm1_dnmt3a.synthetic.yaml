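# Companion configuration for the synthetic FLT3-NPM1-DNMT3A module.
name: flt3_npm1_dnmt3a
description: >
  Synthetic reconstruction of the FLT3/NPM1/DNMT3A AML co-mutation module:
  21 protein nodes wired to the three hallmark phenotypes. Built from
  canonical AML signaling biology; not a transcription of any published
  rule table.
drivers: [FLT3, NPM1, DNMT3A]
# Boolean-gate overrides (experimentally known AND constraints). None are
# asserted for this synthetic module.
overrides: {}
# Wild-type initial condition: source nodes constitutively expressed in
# healthy hematopoietic cells start active; the FLT3 receptor starts
# inactive (no ligand). Source nodes hold their initial value.
initial_state:
  NPM1: 1
  DNMT3A: 1
  FLT3: 0
# The genotype sweep of the module's co-mutation pattern.
sweep_genes:
  - [FLT3, GOF]
  - [NPM1, LOF]
  - [DNMT3A, LOF]
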