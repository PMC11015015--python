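# tumorgeo

Phylogeography of spatial intra-tumor heterogeneity (sITH) from
multi-sector tumor data.

Solid tumors are sampled as *sectors*: bulk tissue punches a few
millimetres across, each with known (x, y) coordinates on a tumor slice,
each yielding somatic mutation calls, expression profiles and clone
compositions. `tumorgeo` asks how that molecular variation is organized in
space:

- **Isolation by distance (IBD).** Are physically distant sectors more
  dissimilar? Ordinary least squares of pairwise dissimilarity on pairwise
  physical distance over all n(n−1)/2 sector pairs, with an optional
  Mantel permutation p-value that respects the non-independence of pairs.
  Four distance families: genetic (Hamming count or branch-mutation
  proportion, i.e. Jaccard distance, between mutation sets), transcriptomic
  (1 − Spearman ρ over the top-3000 genes by median absolute deviation),
  clonal (Euclidean distance between clone-proportion vectors, √Σ(pᵢ−qᵢ)²),
  and physical (mm).
- **Local spatial autocorrelation.** Per-sector local Geary's C,
  Cᵢ = (2n²/ΣᵢΣⱼD²ᵢⱼ) Σⱼ wᵢⱼ D²ᵢⱼ with inverse-distance weights
  wᵢⱼ = 1/dist(i,j), tested by permuting genetic identities over the fixed
  sector positions.
- **Spatial blocks.** A maximum-parsimony (or neighbor-joining) sector
  tree is cut into k connected pieces (every way of removing k−1 edges,
  k = 2–5); each partition is scored with a distance-based
  Calinski-Harabasz index, CH = [SS_between (N−K)] / [SS_within (K−1)]
  where dispersion is the mean sum of pairwise patristic distances, and
  the k maximizing CH is chosen. Blocks are typically spatially
  contiguous regions of the slice.
- **Regional diversity maps.** θ_R on a 2-mm grid: the mean pairwise
  branch-proportion distance among sectors within a circular neighborhood
  (diameter = median inter-sector distance). Two-block tumors show a
  ridge of elevated θ_R along the block interface.
- **Neutrality tests.** The Sackin index S (sum of leaf depths) of the
  sector tree against a Monte-Carlo Yule (equal-fitness) null, one-sided
  toward imbalance; exact binomial tests of clonal asymmetry (are derived
  blocks larger than ancestral ones?); and the genome instability index
  GII = fraction of the genome with |log₂(CN/2)| > 0.2.

Because matched sequencing data cannot ship with the package, a
first-class synthetic-tumor generator (`tumorgeo.simulate`) provides
ground-truth test beds: 2-D Eden boundary growth (restricted cell mixing
→ IBD), an optional selectively advantaged subclone with a punctuated
mutation burst (→ two spatially segregated genetic blocks), honeycomb
sector sampling, binomial read sampling of VAFs, and clone-linked
expression. A `mixed` mode severs all lineage–location links and serves
as the negative control.

## Worked example

```python
import tumorgeo as tg

# a synthetic patient with two coexisting clones
cfg = tg.two_block_config(rng_seed=7)
pop, sectors, members, vaf, clones, expr = tg.simulate_patient(cfg)

m = tg.binarize_and_filter(vaf, present_threshold=0.05)  # call presence
fit = tg.ibd_fit(tg.physical_distance(sectors), tg.genetic_distance(m),
                 mantel_permutations=999, rng_seed=1)
print(f"IBD: slope={fit.slope:.2f} r={fit.pearson_r:.2f} "
      f"mantel_p={fit.mantel_p:.4f}")

tree = tg.build_parsimony_tree(m).tree
blocks = tg.find_spatial_blocks(tree)
print(f"chosen k={blocks.chosen_k}, CH by k: "
      f"{ {k: round(v, 1) for k, v in blocks.ch_by_k.items()} }")
print(f"contiguity={tg.block_contiguity(blocks, sectors):.2f}")

res = tg.sackin_yule_test(tree.root_at_midpoint(), n_sim=9999, rng_seed=2)
print(f"Sackin S={res.s} (n={res.n_leaves} sectors), Yule p={res.p_value:.4f}")
```

Output:

```
IBD: slope=6.29 r=0.61 mantel_p=0.0010
chosen k=2, CH by k: {2: 49.0, 3: 27.7, 4: 21.0, 5: 17.6}
contiguity=0.96
Sackin S=138 (n=24 sectors), Yule p=0.3083
```

Read: genetic dissimilarity grows with physical distance (r = 0.61,
Mantel p = 0.001 — strong IBD). The CH index peaks sharply at k = 2 and
the two blocks are almost perfectly spatially contiguous — they are the
two clones' territories (13 vs 11 sectors; mean driver cell fraction
0.002 in one block, 0.75 in the other). The Sackin test does *not*
reject neutrality here (p ≈ 0.31), and rightly so: in this particular
tumor the two clones occupy comparable areas, so the tree is not
especially imbalanced — tree-shape tests flag selection only when the
derived clone's territory is disproportionately large, which is what
`clonal_asymmetry` quantifies directly on the block sizes.

The same analyses run from the shell: `tumorgeo simulate`, `tumorgeo
ibd`, `tumorgeo blocks`, `tumorgeo geary`, `tumorgeo theta`, `tumorgeo
sackin`, `tumorgeo gii`, or `tumorgeo all` for the whole pipeline plus a
reproducibility manifest. See `tumorgeo --help`.

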