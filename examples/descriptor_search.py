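"""Exhaustive descriptor-subset search on a synthetic compound table.

Simulates 38 attractants and 15 non-attractants whose seven descriptors
follow the published class means/SDs, evaluates all 127 descriptor subsets
with ridge logistic regression under 5x repeated stratified 10-fold CV, and
prints the AUC ranking plus the frequency of each descriptor among the top
10 models. A frequency of 1.0 means the descriptor appears in every top
model — the study's criterion for the most informative descriptor.
"""

from chemoqsar import DescriptorSynthConfig, run_search, simulate_descriptor_table

table = simulate_descriptor_table(DescriptorSynthConfig(seed=42))
print(f"simulated {len(table)} compounds "
      f"({table.n_attractant} attractants / {table.n_non_attractant} non-attractants)")

report = run_search(table, list(table.descriptor_names), base_seed=42)
print(f"\nevaluated {len(report.results)} candidate models; top five by mean AUC:")
for res in report.results[:5]:
    print(f"  AUC {res.auc_mean:.3f} +/- {res.auc_sd:.3f}  "
          f"accuracy {res.cv_accuracy_mean:.1%}  {{{', '.join(res.descriptors)}}}")

print("\ndescriptor frequency in the top 10 models:")
for name, f in sorted(report.frequencies.items(), key=lambda kv: -kv[1]):
    print(f"  {name:>8}: {f:.2f}")
print("\n(q- carries the largest planted group separation, Cohen's d ~ 0.96,"
      "\n so it appears in every top-ranked subset)")
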