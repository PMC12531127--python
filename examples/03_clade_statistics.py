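"""Clade-level comparison of targeting-peptide features.

Samples species-mean features for a separated ("eudicot-like",
separation_delta=3) and an overlapping ("algal", delta=0) clade, runs the
one-way ANOVA with Bonferroni-corrected pairwise Welch tests, and shows
the subsampling robustness of the key mTP-vs-pTP comparison.
"""

import numpy as np
import pandas as pd

from tpdiverge import anova_bonferroni, subsample_robustness, violin_table
from tpdiverge.synthetic import sample_protein_table, sample_species_summaries

rng = np.random.default_rng(2)
summaries = pd.concat(
    [sample_species_summaries("eudicot_like", 10, 40, 3.0, rng),
     sample_species_summaries("algal", 10, 40, 0.0, rng)],
    ignore_index=True,
)

print(violin_table(summaries, "charge").to_string(index=False))
comp = anova_bonferroni(summaries, "charge")
print(f"\none-way ANOVA across {len(comp.groups)} clade x organelle groups: "
      f"F = {comp.anova_F:.1f}, p = {comp.anova_p:.3g}")
pw = comp.pairwise
within = pw[pw.group1.str.split("/").str[0] == pw.group2.str.split("/").str[0]]
print(within.to_string(index=False))

table = pd.concat(
    [sample_protein_table("eudicot_like", 8, 120, 3.0, rng),
     sample_protein_table("algal", 8, 120, 0.0, rng)],
    ignore_index=True,
)
sub = subsample_robustness(
    table, [(("eudicot_like", "plastid"), ("eudicot_like", "mito"))],
    n_range=(100, 100), N_range=(6, 6), reps=50, seed=3,
)
frac = sub[sub.trait == "phospho"].significant.mean()
print(f"\nsubsampling 100 proteins x 6 species, 50 replicates: "
      f"pTP-vs-mTP phospho difference significant in {frac:.0%} of replicates")
print(
    "\nIn the separated clade the mito/plastid contrast survives Bonferroni"
    "\ncorrection and aggressive subsampling; in the overlapping clade the"
    "\nsame contrast stays non-significant."
)
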