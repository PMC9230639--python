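"""Binomial over-representation of an upregulated-protein list.

The reference list is every protein detected in the experiment; expected
hits for a set are n*K/N and fold enrichment is observed/expected. Terms
with near-identical membership can be merged (single-linkage, Jaccard 0.5).
"""
from concordia import (binomial_ora, default_scenario, generate_cohort,
                       merge_redundant_terms, protein_de)

transcripts, proteins, design, sets = generate_cohort(default_scenario(seed=1))
de_p = protein_de(proteins, design)

up = list(de_p.index[de_p.direction == "up"])
reference = list(de_p.index)
rows = binomial_ora(up, reference, sets, correct_fdr=True)
print(f"hit list n={len(up)} of N={len(reference)} detected proteins\n")
show = rows.sort_values("p_value")[
    ["term", "K", "k", "expected", "fold_enrichment", "p_value", "fdr"]]
print(show.round(4).to_string(index=False))
print("\nfold_enrichment > 1 means the set is over-represented among "
      "upregulated proteins; complexes I-IV should lead.")
merged = merge_redundant_terms(rows)
print(f"after merging redundant terms: {len(rows)} -> {len(merged)} rows")
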