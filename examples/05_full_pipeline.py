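"""The whole chain in one call: simulate -> rbbh -> infer -> features ->
summarize -> stats -> MAD+ASR, with every intermediate persisted as TSV.

Equivalent to `tpdiverge run-all --seed 42 --out tpdiverge_demo` on the
command line.
"""

import pandas as pd

from tpdiverge.config import CladeConfig, RunConfig
from tpdiverge.pipeline import run_pipeline

config = RunConfig(
    outdir="scratch_pipeline_demo",
    seed=42,
    clades=[
        CladeConfig(name="eudicot_like", n_species=5, separation_delta=3.0,
                    mutation_rate=0.02),
        CladeConfig(name="algal", n_species=5, separation_delta=0.0,
                    mutation_rate=0.02),
    ],
)
manifest = run_pipeline(config)
for stage, count in sorted(manifest["record_counts"].items()):
    print(f"{stage:40s} {count}")

comps = pd.read_csv(f"{config.outdir}/comparisons.tsv", sep="\t")
key = comps[(comps.group1 == "eudicot_like/mito")
            & (comps.group2 == "eudicot_like/plastid")]
print("\nmTP vs pTP within the separated clade:")
print(key[["trait", "t", "p_adj", "significant"]].to_string(index=False))
print(
    "\nRe-running with the same config reproduces byte-identical outputs;"
    "\nthe manifest records the config hash and per-stage record counts."
)
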