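{
 "table4_aspartate.succinate_k_d": "Succinate K_D is printed as 2.E-04 in the analog table (consistent with its printed sensitivity 3.7) but as 2.E-3 in the misclassification table; the fixture carries the analog-table value and both tables are transcribed as printed.",
 "table4_aspartate.oxaloacetate_n_nh2": "The N_NH2 cell for oxaloacetate is blank in the printed table; stored as 0 (the compound has no amino group).",
 "table4_aspartate.label": "Class labels are not printed in the analog table; attractant := K_D present (the printed table lists K_D exactly for its 13 attractants).",
 "functional_group_counts": "The running text gives hydroxyl n=10 / carboxyl n=5 while the figure caption gives carboxyl 10 / hydroxyl 5; the two sources are swapped and the discrepancy is left unresolved. No per-compound attribution fixture is packaged.",
 "q_minus_attractant_mean": "The running text prints the attractant q- mean as '300 +/- 31 kJ/mol' (sign dropped); the summary table prints -300 +/- 31, which the fixture carries."
}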