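# ssudiv

Tools for asking how much the *analysis choices* in 16S rRNA gene surveys —
multiple-alignment quality, the treatment of gaps when computing pairwise
distances, conserved-column (Lane-style) mask filtering, and the choice of
hypervariable sub-region (V1–V9) — change the answers those surveys give:
OTU richness, Faith's phylogenetic diversity, and the Jaccard, Morisita-Horn
and UniFrac comparisons between communities.

The package is aimed at microbial ecologists and method developers who want
these sensitivity analyses reproducible and testable at desk scale. Because
the original full-length curated reference collections cannot be bundled, a
synthetic-data module generates phylogenetically structured gapped alignments
with known truth — slow conserved blocks, fast hypervariable blocks, indels
concentrated where alignment is hard, and systematically degraded alignment
variants — so every downstream stage runs against data whose right answer is
known.

## The core quantities

**Gap-aware uncorrected distances.** For two aligned rows, with `p` compared
positions and `m` mismatching bases, the distance is `d = m/p` (no multiple-
substitution correction), stored at 4-decimal precision. The three gap
policies differ in what enters `p` and `m`:

- *ignore gap* — columns containing a gap are skipped;
- *each gap* — every base-vs-gap column is one difference over one position
  (a gap of length *n* is *n* mutations);
- *one gap* — a maximal run of base-vs-gap columns is a single difference
  over a single position (an indel of any length is one mutation).

For every pair, `ignore ≤ one ≤ each`. A 7-base kmer distance
`1 − Σ_w min(c_a(w), c_b(w)) / (L_min − 6)` covers the alignment-free case.

**OTUs and richness.** Agglomerative clustering of the distance matrix —
furthest (complete), nearest (single) or average (UPGMA) neighbor — yields a
merge schedule; the richness curve reports the OTU count at every cutoff the
data can describe.

**Phylogeny.** Canonical Saitou–Nei neighbor joining, with Faith's
phylogenetic diversity as the total branch length of the tree.

**Beta diversity.** From a two-community OTU table: Jaccard
`|shared| / |either|`, Morisita–Horn
`2Σx_iy_i / ((Σx_i²/X² + Σy_i²/Y²)XY)`, and unweighted / weighted UniFrac
reported as similarities (1 − distance).

**Comparison statistic.** Two distance configurations are compared by
regression through the origin, `slope = Σxy/Σx²`, over pairs whose reference
distance is below 0.10; slope > 1 means the comparison configuration reads
more genetic diversity than the reference. Replicated beta metrics are
compared by balanced two-way ANOVA with Tukey HSD.

## Worked example

```python
from ssudiv import (SyntheticWorldConfig, generate_world, perturb_alignment,
                    distance_matrix, regress_origin)
from ssudiv.compare import matched_pairs

world = generate_world(SyntheticWorldConfig(n_taxa=20, seed=1))
faithful = distance_matrix(world.truth_alignment, "one_gap")
degraded = distance_matrix(perturb_alignment(world, "shuffle_variable", seed=2), "one_gap")
x, y = matched_pairs(faithful, degraded)
fit = regress_origin(x, y)
print(f"slope {fit.slope_through_origin:.3f}  r2 {fit.pearson_r2:.3f}  n {fit.n_pairs_used}")
```

This prints

```
slope 1.041  r2 0.965  n 44
```

meaning that on this world, scrambling residue placement inside the
hypervariable regions (mimicking an aligner that fails there) inflates
apparent genetic diversity by ~4% over the 44 sequence pairs with faithful
distance < 0.10, while still correlating tightly (r² ≈ 0.97) with the true
distances; heavier perturbation or faster variable regions push the slope
higher.

The same objects drive the rest of the pipeline: `cluster`/`richness_curve`
for OTUs, `neighbor_joining`/`phylogenetic_diversity` for trees, and
`mocksim.run_replicates` for replicated two-community beta-diversity
simulations. A `ssudiv` command-line entry point wraps the common steps
(`screen`, `region`, `mask`, `dist`, `cluster`, `tree`, `pd`, `mocksim`).

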