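"""Generate a synthetic paired transcript/protein cohort.

The default scenario plants the study-shaped structure: respiratory
complexes I-IV with transcripts down (0.8x) but proteins up (2.0x),
Complex V and the ribosome down in both omes, immune/sphingolipid sets up
in both, plus a null background.
"""
import numpy as np
from concordia import default_scenario, generate_cohort

transcripts, proteins, design, sets = generate_cohort(default_scenario(seed=1))

print(f"transcripts : {transcripts.n_features} genes x {transcripts.n_samples} samples")
print(f"proteins    : {proteins.n_features} proteins x {proteins.n_samples} samples")
print(f"cohorts     : {len(design.case_samples)} case / {len(design.control_samples)} control")
print(f"gene sets   : {[s.name for s in sets]}")
missing = proteins.values.isna().to_numpy().mean()
print(f"protein missingness: {missing:.1%} of cells (intensity-dependent, "
      "so dim proteins vanish more often)")
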