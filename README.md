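# poprep

Multivariate analysis of how a neural population represents visual
objects, built around fully synthetic data with planted structure.  The
package provides:

- **`poprep.stimgen`** — procedural generation of a grayscale object
  stimulus set (default: 213 images — 94 twin pairs, 5 cars, 5 faces,
  5 silhouettes, 5 textures, 1 blank, 4 low-contrast variants of one
  object) on a uniform mid-gray background.
- **`poprep.neurogen`** — a spiking population simulator whose tuning is
  driven by image properties (with optional planted semantic gain),
  Poisson trial noise, and a responsiveness screen (one-sided Welch t-test
  against background, p < 0.005).
- **`poprep.imgprops`** — the four low-level image properties (luminance,
  contrast, area, aspect ratio) and the eight extreme-value categories.
- **`poprep.shapefeat`** — a reduced hierarchical shape-feature model
  (Gabor S1 → max-pool C1 → template-match S2 → global-max C2) and k-means
  shape categories.
- **`poprep.popspace`** — per-neuron normalization, Pearson similarity /
  dissimilarity matrices, PCA with property correlations, average-linkage
  hierarchical clustering with a top-branch chi-square test, k-means with
  BIC/AIC model selection, a k = 2 segregation permutation test, and a
  face-selectivity index.
- **`poprep.dmst`** — bounded-depth minimum-spanning-forest clustering:
  max-sum message passing with reinforcement (plus local search and a
  short annealing refinement), an exact subset-DP solver for small
  instances, a parameter stability scan, and a consensus forest with
  per-link stability weights.
- **`poprep.overlapstat`** — cluster–category overlap scores (averaged
  ratios for partitions; best connected-subtree intersection-over-union
  for forests, via Dinkelbach iteration on a tree DP) with object-level
  and twin-set-level permutation nulls and Holm–Bonferroni correction.
- **`poprep.flddecode`** — binary Fisher-discriminant decoding of category
  membership from resampled pseudo-population spike-count vectors with
  leave-two-objects-out cross-validation, label-shuffle nulls, and exact
  constraint-based category pruning (maximum independent set with seeded
  noise to sample alternate maximal solutions).
- **`poprep.pipeline_cli`** — end-to-end orchestration with per-stage
  derived seeds.

## CLI

```sh
poprep all --seed 1 --outdir out/           # full pipeline, default config
poprep simulate --config run.yaml           # single stage
poprep overlap --seed 2 --outdir out/       # simulate+categories+cluster+overlap
```

Configuration is YAML or JSON; see `poprep.pipeline_cli.RunConfig` for the
schema.  Artifacts (trial tables, property tables, similarity matrices,
Newick dendrograms, forest edge lists, overlap and decoding tables, and a
machine-readable `report.json`) are written to the output directory.
Identical config + seed gives identical outputs.

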