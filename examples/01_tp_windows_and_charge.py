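"""Window statistics and charge-editing of an N-terminal targeting peptide.

Builds a synthetic mitochondrial-style 20-residue window whose +4 net
charge is carried by two arginines and two lysines, then applies the
charge-editing substitutions used to probe whether charge (not residue
identity) drives targeting.
"""

from tpdiverge import TPWindow, compute_features, net_charge, substitute_charge

window = TPWindow("demo_mTP", "MFSRAKLAVSGAKPLRWGQA")
feats = compute_features(window)
print(f"window          {window.residues}")
print(f"net charge      {feats.net_charge:+d}   (K+R minus D+E)")
print(f"phospho (S+T)   {feats.phospho_count}    (phosphorylatable residues)")
print(f"R / K counts    {feats.arg_count} / {feats.lys_count}")

for mode in ("swap_RK", "to_serine", "neutralize", "invert"):
    sub = substitute_charge(window, mode)
    print(f"{mode:>10}  ->  {sub.residues}  charge {net_charge(sub):+d}")

print(
    "\nswap_RK keeps the +4 charge (identity of the basic residue does not"
    "\nmatter); to_serine removes it and adds four phosphorylatable serines"
    "\n— the edit that rediverts a mitochondrial reporter to the plastid."
)
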