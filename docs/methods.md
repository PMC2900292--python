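# Methods

## What the pipeline models

16S rRNA surveys rest on a chain of analysis choices: align the sequences,
compute pairwise distances, cluster into OTUs or build a tree, then summarize
alpha and beta diversity. Each link has free parameters that the literature
treats as interchangeable — which aligner, how to score gaps, whether to mask
hypervariable columns, which sub-region was sequenced. ssudiv implements the
whole chain so that the effect of changing any one link can be isolated and
measured, with regression through the origin as the common currency: two
distance configurations are compared pair-by-pair, and the deviation of the
slope `Σxy/Σx²` from 1 reads directly as genetic diversity gained or lost.

## Distance calculators

All distances are uncorrected mismatch fractions `m/p`. Correction for
multiple substitutions is deliberately absent: corrected values are undefined
for the large distances that short hypervariable reads routinely produce, and
the comparisons of interest are between calculators, not against a
substitution model. Values are stored rounded half-up to 4 decimals.

Gap handling is the experimental variable:

| policy | positions `p` | differences `m` |
|---|---|---|
| ignore_gap | base-vs-base columns | base mismatches |
| each_gap | base-vs-base + single-gap columns | mismatches + every single-gap column |
| one_gap | base-vs-base + one per gap run | mismatches + one per gap run |

Conventions that the definitions leave open, fixed here:

- Both-gap columns carry no information and are excluded in every mode; they
  do not terminate a one_gap run.
- A one_gap "run" is a maximal stretch of single-gap columns with the gap in
  the same row; if the gapped row switches, a second event is counted.
- Terminal gaps (columns before the first or after the last residue of either
  row) are excluded by default; `penalize_terminal_gaps=True` restores them.
  Alignments of partial reads would otherwise be dominated by length
  differences.
- `N` against anything is never a difference but does count as a position, so
  ambiguity lowers rather than inflates distance.

The ordering `ignore ≤ one ≤ each` holds for every pair: the three modes
compute `(m+t)/(p+t)` with `t` = 0, number of gap runs, number of gap
columns, and `(m+t)/(p+t)` is non-decreasing in `t` whenever `m ≤ p`.

The kmer distance uses 7-base words on the unaligned sequences:
`d = 1 − Σ_w min(c_a(w), c_b(w)) / (L_min − k + 1)`. Normalizing by the
shorter sequence's word count keeps identical sequences at 0 and word-disjoint
sequences at 1; a profile dot-product normalization would have been equally
defensible but is not scale-free in length.

## Clustering and trees

Furthest/nearest/average neighbor are complete/single/UPGMA linkage,
implemented directly so the tie-break is specified: among equally distant
cluster pairs, the pair whose (lexicographically smallest member id) labels
sort first merges. Average linkage is UPGMA — the unweighted mean over all
cross-cluster sequence pairs, equivalently the cluster-size-weighted mean of
merged distances. Merge heights are the raw 4-decimal distances, so richness
curves report exactly the cutoffs the data can describe; on 60-base gap-free
reads adjacent observable cutoffs are 1/60 ≈ 0.0167 apart, which is the
stair-step granularity short-read richness curves show.

Neighbor joining is the canonical Saitou–Nei algorithm (Studier–Keppler
Q-criterion), no relaxed heuristic, lexicographic tie-breaks. It reproduces
any additive matrix exactly, topology and branch lengths. Negative branch
estimates — possible on non-additive input — are clamped to zero so that
phylogenetic diversity (total branch length) and UniFrac stay non-negative.
Trees are `skbio.TreeNode` objects; newick I/O goes through scikit-bio.

## Beta diversity

All four metrics are reported as similarities in [0, 1]. Jaccard uses OTU
incidence; Morisita-Horn uses relative abundances and is scale-invariant per
community. UniFrac walks the branches of the (midpoint-rooted, when unrooted
input is given) tree: unweighted similarity is the fraction of branch length
whose subtree contains leaves of both communities; weighted similarity is
`1 − Σ l_b|a_b − b_b| / Σ l_b(a_b + b_b)` with `a_b, b_b` the fractions of
each community's sequences below branch `b`. The denominator bounds the
distance by 1 (since `|a−b| ≤ a+b`); other normalizations (e.g. by
abundance-weighted root-to-tip depth) differ by a constant factor per tree
and would not change any ordering the pipeline reports.

## Mock communities

The two-community simulation fixes the true overlap and lets sampling do the
rest. Given a furthest-neighbor partition at cutoff 0.05: shuffle the OTUs,
assign `floor(0.10·n)` (min 1) exclusively to each community, split the
remaining shared OTUs into halves, and draw each sequence of a shared OTU
into community 1 with p = 0.375 (first half) or 0.625 (second half); an odd
shared count puts the extra OTU in the 0.625 half. With every OTU deeply
sampled the design values are Jaccard 0.80 (8 of 10 OTU groups shared) and
Morisita-Horn exactly 0.60 (closed form: with u exclusive OTUs per side and
4u shared per half at size N, `2·Σxy = 3.75uN²` against `λ·XY = 6.25uN²`).
Shallow sampling loses rare OTUs from one side and biases both indices
downward — which is itself a finding the simulation reproduces. 100
replicates by default; replicate seeds spawn deterministically from the
design seed so the identical 100 partitions can be reused across every
calculator, alignment, region and metric.

## Synthetic worlds

The generator emulates a curated full-length collection, not real rRNA:

- **Tree.** Pure-birth (Yule) topology, ultrametric, scaled so root-to-tip
  length equals `tree_depth` expected substitutions/site (default 0.10,
  giving pairwise distances up to ~0.2 in conserved regions — the range where
  OTU cutoffs of 0.03–0.10 are meaningful).
- **Substitution.** Jukes-Cantor per site: change probability
  `(3/4)(1 − e^{−4rt/3})` on a branch of length `t`. Since downstream
  distances are uncorrected counts, a richer model would only add parameters
  nothing downstream can see.
- **Region structure.** A layout of conserved and variable blocks (default
  120/60/120/60/120 columns); variable blocks evolve `rate_multiplier`×
  faster (default 4).
- **Indels.** Per branch, each variable-region column starts a deletion with
  probability `indel_rate·t`; run lengths are geometric with mean 2, clipped
  at the block boundary. Indels are presence/absence against a fixed column
  universe — a deletion on one lineage is observationally an insertion on the
  rest — so the truth alignment keeps exact positional homology. The first
  leaf is exempt from indels and serves as the gap-free coordinate reference,
  the role E. coli numbering plays for real alignments.
- **Perturbations.** `shuffle_variable` re-draws which positions within each
  variable block hold a row's residues (residue order preserved);
  `unalign_variable` left-justifies them. Both move gaps only and leave
  conserved columns untouched, emulating aligners that handle conserved stems
  well but fail in variable loops. Their intensities are not calibrated to
  any real aligner — no quantitative model of that gap exists — so pipeline
  claims are directional (slope above/below 1), not magnitudes.

What the generator does *not* model: secondary structure and covarying
sites, chimeras, sequencing error, compositional bias. Passing tests
therefore demonstrate correctness of the calculators and the direction of the
alignment/masking/region effects, not magnitudes transferable to real data.

## Statistical harness

Through-origin regression restricts to pairs with reference distance < 0.10
(beyond that, saturation of fast regions breaks linearity) and reports the
squared Pearson product-moment correlation of the retained pairs — not the
through-origin coefficient of determination, which has no comparable
interpretation. Pairs are matched by unordered sequence-id pair; pairs
undefined under either configuration are dropped. Replicated beta metrics go
through a balanced two-way fixed-effects ANOVA (statsmodels, type-II sums of
squares; with factor cells balanced by construction, type II equals type I
on the factor terms) and Tukey HSD at α = 0.05 within each OTU cutoff or
UniFrac variant.

## Problem sizes and determinism

The test suite and the reproduction script run everything at desk scale by
design: synthetic worlds of 6–20 taxa and a few hundred columns,
direction-of-effect claims averaged over 20 seeds, and the mock-community
recovery at 1,000 OTUs × 100 sequences × 100 replicates (the design values
are properties of the partitioning procedure, not of sequence content, so no
sequences are needed there). Every stochastic component takes a single
integer seed; identical (config, seed) pairs are byte-identical, and derived
seeds stay below 2³¹.

## Known limitations

- Average-linkage is UPGMA; the WPGMA variant is not offered.
- Needleman-Wunsch penalizes terminal gaps (no free end-gaps option yet);
  scoring defaults (+1/−1, gap open −2, extend −1) are conventions, exposed
  as configuration.
- The agglomerative clustering is quadratic-space/cubic-time and intended
  for the desk-scale matrices the rest of the pipeline produces.
- UniFrac values depend on the rooting convention (midpoint here) for
  unrooted input; comparisons across rootings are not meaningful.
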