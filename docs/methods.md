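# Methods

This note documents the models and conventions implemented in
`tpdiverge`, the parameters that matter, what the synthetic data do and
do not emulate, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis in one paragraph

Targeting peptides are summarised by two integer statistics of the
N-terminal window (default W = 20 residues, initiator Met included):
**net charge** `(#K + #R) − (#D + #E)` and **phosphorylatable count**
`#S + #T`. Organelle proteomes of non-model species are inferred by
transferring labels from an experimentally annotated seed species via
reciprocal best hits. Species × organelle means of the two statistics are
the unit of every downstream analysis: clade-level hypothesis tests,
subsampling robustness, divergence-vs-proteome-size correlation, and
continuous-trait ancestral state reconstruction on a rooted species tree.

## Sequence similarity and RBBH

* Local alignment: Smith–Waterman under BLOSUM62 with affine gaps; a gap
  of length k costs `open + k·extend` (BLAST convention), defaults 11/1.
  Residues outside the matrix alphabet are mapped to X, whose BLOSUM62
  row is the mismatch floor.
* E-values follow the Karlin–Altschul form `E = K·m·n·exp(−λS)` with
  constants fixed at the gapped BLOSUM62-11/1 values λ = 0.267,
  K = 0.041, independent of any database size. They exist only to
  threshold hits. A published cutoff written "10e−6" is ambiguous
  (literally 1e−5); the default here is the stricter 1e−6 and both are
  selectable.
* Best hit = maximum-score hit passing the cutoff; ties break to the
  lexicographically smallest subject id (documented, deterministic). A
  pair is emitted iff the best-hit relation holds in both directions.
  Self-comparisons and within-species (paralog) hits never participate.
* Global identity (used for comparing paralogous proteins such as the
  two outer-membrane purple acid phosphatases): Needleman–Wunsch under
  the same scoring; identity = identical aligned positions / alignment
  length, gap columns included in the denominator.

## Label transfer

A target protein is called iff it has ≥ 1 RBBH partner in the seed set.
Resolution when partners disagree is not dictated by the transfer idea
itself, so it is a configurable decision: any dual-labelled partner →
`dual`; partners in both single-organelle sets → `dual` by default
(rationale: dual targeting is treated throughout as the intermediate
class), or the protein is dropped with `conflict="drop"`. With several
seed species, RBBH to at least one suffices (union semantics, favouring
recall). Every call records its seed evidence ids.

## Window statistics

* Charge alphabet is {K, R: +1; D, E: −1} at face value — no pKa/pH
  model — because the analysis works with integer charges and histidine
  is not counted as basic in this context.
* Sequences shorter than W are analysed over their full length and
  flagged `short`, not dropped.
* Nonstandard residues (X, B, Z, U, …) contribute 0 to both statistics
  and are logged.
* The initiator methionine is counted inside positions 1..W; a
  `strip_met` flag removes it first for users whose annotations include
  it inconsistently.
* The R-vs-K usage profile keeps windows with charge **strictly** above
  the threshold (default +3); under that filter R + K > 0, so the
  arginine fraction R/(R+K) is always defined.
* Charge-editing substitutions: `neutralize` (K/R/D/E→A), `invert`
  (K/R→D; a documented choice that flips the basic contribution),
  `to_serine` (K/R→S), `swap_RK` (R↔K). They operate position-wise, so
  they commute with window extraction.

## Clade statistics

* "Multiple ANOVA with Bonferroni correction" is realised as a one-way
  ANOVA per trait across all (clade × organelle) groups with ≥ 2
  species, followed by all pairwise Welch (unequal-variance) t-tests
  with `p_adj = min(1, p·m)`, m = number of pairs; the comparison family
  and group order are emitted with the results. Dual-targeted summaries
  form a third group and are never pooled.
* Degenerate input (all group values identical) flags the ANOVA as
  undefined rather than erroring; zero-variance Welch comparisons fall
  back to their limit values (t = 0, p = 1 for equal means).
* Subsampling draws n proteins per (species, organelle) and N species
  per clade uniformly without replacement, with n and N drawn per
  replicate from inclusive ranges; each named comparison is re-tested on
  the subsample (both traits, Bonferroni across the family). Fully
  deterministic under the seed; requests exceeding availability raise.
* Divergence vs proteome size: per species, `pTP − mTP` mean phospho and
  `mTP − pTP` mean charge (both positive when destinations separate),
  each correlated with total proteome size by Pearson and Spearman;
  constant inputs are flagged instead of reporting spurious
  coefficients.
* Violin-plot quantities (median, quartiles, range per clade ×
  organelle) are emitted as a tidy table; rendering is left to the user.

## MAD rooting

For a candidate root ρ on a branch, each tip pair (b, c) whose path
crosses ρ implies ρ as its ancestor; under a strict clock ρ would be the
path midpoint, and the pair's relative deviation is
`|2·d(ρ,c)/d(b,c) − 1|`. The branch score is the root-mean-square of the
deviations over all root-straddling pairs, minimised in closed form over
the position (an ordinary least-squares problem clipped to the branch);
the tree is rooted at the global minimiser. This package scores
straddling pairs only — same-side pairs, whose ancestors are fixed
interior nodes, are deliberately excluded from the objective; on
clock-like trees both variants recover the original root, which is the
property the pipeline relies on. Ties between branches break to the
earliest branch in a preorder enumeration of the input. The objective is
invariant under uniform branch-length scaling. Requires ≥ 3 tips and an
unrooted input.

Note one subtlety: in a near-degenerate 3-tip tree with branch lengths
(1, 1, ε), the least-squares optimum does *not* sit at the midpoint of
the long path — the pair involving the short-branch tip pulls the root
toward one of the long branches (to 0.6 of the way in the ε → 0 limit).
The dense-grid oracle in the test suite pins the implemented objective
rather than that midpoint intuition.

## Brownian-motion ancestral state reconstruction

Tip covariance is σ²·S with S the shared-path-length matrix of the
rooted tree. The root state is the GLS mean `(1'S⁻¹x)/(1'S⁻¹1)`; σ² is
maximum likelihood with divisor n (REML with n−1 by flag — the REML
convention is what R's phytools `fastAnc` uses for its variances, and
the cross-check test matches it exactly). Internal nodes use the
re-rooting identity: the estimate at a node equals the GLS root estimate
of the tree re-rooted there, with variance `σ²/(1'S_a⁻¹1)`; the
re-rooted shared-path matrix is obtained purely from path lengths,
`S_a[i,j] = (d(a,i) + d(a,j) − d(i,j))/2`, so no tree surgery is needed.
Tips carry their observations with zero variance. CIs are mean ±
1.96·√var. Zero-length branches are inflated to a configurable epsilon
(default 1e−8 × tree height) before inversion. Estimates are invariant
to tip-label permutation and to uniform branch rescaling (σ² scales
inversely). Ancestor values are compared between clades with Welch's
unequal-variance t-test; the "ancestor of a clade" is taken to be the
root of that clade's MAD-rooted tree.

## Synthetic data: what it emulates, and what it does not

The generator plants known truth for every downstream stage:

* **Species trees**: random ultrametric trees from coalescent-style
  pairwise joins (waiting time exponential with mean 1/#lineages), so
  heights are of order log n and default branch lengths of order 0.1–1.
* **Ortholog families**: one member per species; an ancestral mature
  domain (default 80 residues — long enough for unambiguous RBBH at
  desk scale) evolves along the tree with per-site substitution
  probability `1 − exp(−μ·t)`, substitutions uniform over the 19 other
  residues. The default μ = 0.05 yields a few percent divergence across
  a clade, comfortably inside the RBBH decision boundary.
* **TP windows**: drawn i.i.d. per protein from a destination-specific
  amino-acid composition. Starting from a uniform background (expected
  charge 0, expected phospho 2 per 20 residues), `separation_delta`
  moves δ/20 of probability mass into K/R (mito) or S/T (plastid),
  planting an expected charge gap (mito − plastid) and phospho gap
  (plastid − mito) of exactly δ. Dual is the 50/50 per-residue mixture,
  so its means sit halfway. δ = 0 is the "algal" regime (destinations
  statistically indistinguishable); δ ≈ 3 gives the clean
  "eudicot-like" separation. Windows are fixed at W = 20 because only
  the first 20 residues are analysed; this is not a claim about real TP
  lengths, which vary widely.
* **Seeds**: the first species is the designated "experimental" species;
  its true labels are the seed annotations (mirroring the single
  well-annotated model species per clade).
* **ASR traits**: species-mean traits for reconstruction tests evolve
  under Brownian motion separately from the window machinery, keeping
  the two testing surfaces independently controllable.
* A **trait-level fast path** samples per-protein (charge, phospho)
  pairs directly as multinomial functionals of the composition models —
  statistically identical to scoring drawn windows, and what the
  power/type-I simulations use so that 1,000-replicate runs stay cheap.

Not emulated: realistic substitution models (no rate heterogeneity, no
indels), codon structure, hydrophobicity or secondary structure of TPs,
phylogenetic signal within TP windows, paralogy/gene loss, or annotation
errors in seed proteomes. Passing tests therefore demonstrate that the
pipeline's inference and statistics are correct and calibrated under its
stated model — not that real proteomes satisfy that model.

## Problem sizes and determinism

Simulation-based checks use desk-scale sizes chosen once: clades of
4–10 species with 12–120 families per destination; 500 replicates for
ASR calibration on a 32-tip tree; 1,000/200 replicates for type-I/power;
subsampling at n = 100 proteins and N = 6 species, the low end of what
clade-scale data supply. All randomness flows through seeded
`numpy.random.Generator` instances; a pipeline re-run with the same
config is byte-identical, and the run manifest records the config hash,
seed, and per-stage record counts (and deliberately no timestamps).

## Known limitations

* The straddling-pairs-only MAD objective can differ from the full
  published objective on strongly non-clock trees; both agree on
  clock-like data.
* E-value constants are fixed rather than length-corrected, so absolute
  E-values are approximate; only their use as a threshold is meaningful.
* The ANOVA/Bonferroni family is one defensible reading of "multiple
  ANOVA with Bonferroni correction"; the comparison family is therefore
  configurable and always logged.
* ML σ² is biased low by factor (n−1)/n, making CIs slightly
  anti-conservative at small n; the REML flag removes this at the cost
  of departing from the default convention.
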