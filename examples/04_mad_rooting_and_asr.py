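"""MAD rooting and Brownian-motion ancestral state reconstruction.

Simulates a species tree and a continuous trait (think: species-mean mTP
net charge) under Brownian motion, unroots the tree, re-roots it by
minimal ancestral deviation, and reconstructs ancestral states with 95%
confidence intervals.
"""

import numpy as np

from tpdiverge import (
    asr_bm,
    asr_table,
    mad_root,
    random_ultrametric_tree,
    simulate_species_traits,
)
from tpdiverge.trees import deroot

rng = np.random.default_rng(5)
tree = random_ultrametric_tree([f"sp{i:02d}" for i in range(8)], rng)
traits = simulate_species_traits(tree, sigma2=1.0, root_state=3.0, seed=6)

res = mad_root(deroot(tree))
print(f"MAD root deviation score: {res.score:.4f} "
      "(root-mean-square relative deviation of ancestor-tip distances)")

params, estimates = asr_bm(res.tree, traits)
print(f"fitted BM rate sigma^2 = {params.sigma2:.3f}, "
      f"root state = {params.root_state:.3f} (true root was 3.0)")
print(asr_table(estimates).to_string(index=False, float_format="%.3f"))
print(
    "\nInternal rows are ancestor estimates with variances; tip rows carry"
    "\nthe observations (variance 0).  The true simulated root lies inside"
    "\nthe root node's 95% interval in ~95% of runs."
)
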