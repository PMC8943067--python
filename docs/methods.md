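# Methods

## The CMP model

A sample is an ordered panel of M binary marker channels on a common pixel
grid. The combinatorial molecular phenotype (CMP) of a pixel is the length-M
bitstring of marker presence, leftmost character = marker 0 (instrument
convention: the first marker imaged — typically cellular autofluorescence —
is marker #0). The all-zero pattern is background, never a phenotype; a
15-pixel border (matching the excluded periphery of 2048×2048 acquisitions)
is likewise always background. All downstream statistics operate on
multisets of CMP bitstrings:

- **CMP tables** rank distinct CMPs by pixel count; rank 0 is the most
  abundant. Frequencies are raw pixel counts — whole-image abundance depends
  on how many cells the field happens to contain, so normalization is left
  to consumers that can control for it. Ties in count are broken by
  ascending lexicographic bitstring. The paper-scale analyses use the top
  N = 54 rows; marker-specific ("lead protein") tables are the subsequence
  of the full ranking whose CMPs contain a given marker, keeping the parent
  rank as annotation.
- **Conservation** within a 3-replicate group: a CMP is 3-of-3 conserved
  when its exact bitstring occurs in all three samples' top-54 lists, and
  2-of-3 conserved when it occurs in exactly two. The three reported 2-of-3
  numbers are the counts of the three pairwise comparisons (#1v#2, #1v#3,
  #2v#3) restricted to exactly-two-sample CMPs; their mean (sum/3, kept as
  an exact rational) is the per-sample rate entering the summary. The
  "Common" row intersects the two groups' conserved sets (present in ≥2 of
  3 samples by default; 3-of-3-only available as a flag). Group totals
  across the All + per-marker columns are compared by a two-sided Wilcoxon
  rank-sum test — reproducing the published design; note the caveat that
  the 13 column totals are not independent replicates (pseudo-replication).
- **Cell profiles**: a cell's CMPs are ranked within the cell, the top 20
  kept, and k_m counts how many of them contain marker m; f_m = k_m /
  (CMPs actually used). Cells with fewer than 20 distinct CMPs use all of
  them — normalizing by the number used keeps f comparable across cell
  sizes. Profiles depend only on the within-cell ranking, so they are
  invariant to uniform pixel-count scaling.
- **Clustering and scoring**: cells are clustered on their f vectors by
  agglomerative clustering (default Ward linkage, Euclidean distance — a
  standard choice for compact profile clusters; linkage, metric and k are
  configurable, with k user-chosen from the dendrogram as in the source
  studies: 7 for the 12-marker set, 12 for the 7-marker comparison). A
  cluster is scored against a two-level factor by the reference level's
  share p: "predominantly reference" when p ≥ 2/3, "predominantly other"
  when p ≤ 1/3, else "mixed". The thresholds are exact rationals, not
  rounded percentages: the published 12-cluster tally classifies a 2-of-6
  (33.3%) cluster as predominantly-other, which only the ≤ 1/3 reading
  reproduces. Association between factor and cluster membership is
  Cramér's V = sqrt(χ²/(n·(min(r,c)−1))) with Pearson χ² and no continuity
  correction; for 2×2 tables V = |φ|.
- **Marker contrasts**: group marker means are arithmetic means of f_m.
  Pairwise contrasts use the two-sided Wilcoxon rank-sum test (robust for
  bounded fractions; a t-test would presume normality these fractions do
  not have), with Benjamini–Hochberg adjustment applied jointly across the
  full contrast × marker family. The default design is the six contrasts
  {treatment within each sex and overall, sex within each treatment and
  overall} × 7 markers = 42 tests; the published analysis names the count
  but not the contrast list, so the set is configurable.

The rank-sum test uses the exact null distribution when both samples have
n ≤ 25 and the pooled values are tie-free, otherwise the normal
approximation with tie correction; the method used is reported alongside
the statistic (the rank sum W of the first sample).

## Preprocessing chain

`register → subtract → binarize → merge`, mirroring the acquisition
software's stages without reproducing its file dialects:

- **Registration** is integer translation only (serial imaging of a fixed
  slide drifts by translation; no rotation/scale). The search is exhaustive
  within ±shift_max, scored by Pearson correlation over the overlap region.
  Zero-mean normalisation matters: with a constant illumination base a raw
  dot product grows with overlap area and always elects the zero shift.
  Ties are broken toward the smallest L1 shift, then lexicographically, so
  a featureless image registers at (0, 0). An optional Gaussian pre-smooth
  of the score images is available for data whose channels share only
  cell-scale structure. The default reference channel is the last one:
  panels conventionally end with a diffuse whole-cell stain (F-actin),
  which carries the strongest shared structure. A channel whose marker is
  essentially absent from the field contains no alignment information; its
  estimated shift is then arbitrary — a real identifiability limit, not an
  implementation artifact (its content is equally arbitrary, so downstream
  effect is nil).
- **Background subtraction** is pixel-wise `max(signal − postbleach, 0)`.
- **Binarization** defaults to per-channel Otsu (parameter-free; the
  original instrument's thresholds are not published), with fixed and
  quantile overrides for reproducible reanalysis. The mask is strictly
  `> threshold`, so threshold 0 excludes exact zeros under the quantile
  policy. A constant channel has no Otsu threshold and yields an all-false
  mask with a warning.
- **Merge** packs the ordered masks into per-pixel integer codes (bit m =
  marker m) and forces the margin border to background.

## The synthetic cohort generator

No raw images are deposited with the source study, so the generator stands
in for them: it emulates fields of sparse, round, non-touching
macrophage-like cells with full ground truth (per-pixel marker matrix,
label mask, per-cell CMP multisets) retained for oracle tests.

- Cells are hard disks (uniform radius in `cell_radius_range`), placed by
  rejection sampling fully inside margin + shift slack, non-overlapping;
  placement failure after bounded retries raises `PackingError`.
- Each cell draws a **phenotype** — a per-marker expression probability
  vector — from a library, with prevalence weights per (treatment, sex)
  group. Pixel-level marker presence is independent Bernoulli given the
  phenotype, so each cell yields a *distribution* of CMPs; this is what
  makes a top-20-per-cell summary meaningful. Marker 0 additionally gets
  Poisson-count punctate granules (radius 1–2 px), emulating granular
  autofluorescence; the last marker is diffuse (high probability in every
  phenotype), emulating F-actin.
- Grayscale rendering: `base (10) + amplitude (200) × presence + N(0,
  noise_sd)`, clipped at 0, 16-bit; the post-bleach background is
  `bleach_residual × clean signal` plus fresh noise. With `noise_sd = 0`
  and `bleach_residual = 0` the chain recovers truth exactly — the basis of
  the oracle-equivalence tests.
- Channels other than the last are mis-registered by a uniform integer
  shift up to `shift_max` (signal and its matched background share the
  shift); truth stays in the anchor frame.
- Cohorts derive per-sample seeds as `seed + sample index`, so any sample
  regenerates in isolation; identical (config, seed) reruns are
  bit-identical.

What the generator does **not** emulate: optics (PSF, illumination fields),
spectral autofluorescence, cell-shape variety, touching cells, spatially
correlated within-cell texture. Consequently, passing oracle tests shows
the *computational chain* is faithful, not that the statistics would behave
identically on real morphology; in particular real binarization thresholds
are a judgment call the Otsu default only approximates.

## Study-condition presets

Three canned configurations define the simulation conditions the property
tests exercise; sizes are test-scale by design (fields 96–160 px, 6–12
cells per field, 7–8 markers) — large enough for stable statistics, small
enough for a laptop-speed suite.

- `treatment_diversity_conditions`: five phenotypes sharing one base
  expression pattern, four being ±0.35 perturbations of four mid-range
  markers; Vehicle draws from the first two (weights .7/.3), the treated
  group uniformly from all five; 3 samples per group. Both groups express
  every marker at similar marginal rates, but the treated group's CMP
  ranking is flatter and varies more between replicates — so the
  low-diversity group accumulates more 3-of-3/2-of-3 matches. The effect
  is on the order of one to two CMPs per summary column and is asserted in
  aggregate over seeded replicates.
- `sex_linked_conditions`: a 2×2 (treatment × sex) cohort where only sex
  drives phenotype weights; clustering cell profiles should associate with
  sex, not treatment (Cramér's V comparison, ≥90% of 50 seeded replicates).
- `phenotype_recovery_conditions`: three well-separated planted phenotypes;
  Ward clustering at k = 3 must recover them (ARI ≥ 0.8; in practice 1.0).

The source study gives no pixel-level effect sizes, so these probabilities
and weights are free parameters of the generator chosen once as plausible
for well-separated macrophage phenotypes; they are documented config, not
estimates of the study.

## Numerical and design notes

- Exact rational arithmetic where integer semantics matter: 2-of-3 means
  (`Fraction`), scoring thresholds (1/3, 2/3). Percentages are computed in
  float and rendered to 1 decimal.
- The bundled 12-cluster treatment table's printed row totals disagree with
  the sum of its printed per-cluster cells by a few cells; the per-cluster
  cells are internally consistent with the published scoring totals and
  Cramér's V, so they are treated as authoritative.
- Deterministic ordering throughout: compile ordering fixes every top-N
  cut; SciPy's agglomerative clustering is deterministic given input order;
  cluster ids are relabelled 1..k contiguously in order of first
  appearance.
- Degenerate inputs are errors, not silent zeros: empty cell multisets,
  zero-margin contingency tables, non-binary factors for scoring, k > n.
- Panel reduction recomputes CMPs from re-merged channels rather than
  projecting bitstrings: a pixel whose only markers are dropped must become
  background in the reduced space, which projection would miscount.

## Known limitations

- Registration is translation-only and integer-valued; sub-pixel drift,
  rotation and illumination gradients are out of scope.
- Conservation generalizes beyond 3-replicate groups only behind an
  explicit flag, since "2-of-3" semantics are tied to three pairwise
  comparisons.
- The rank-sum comparison of conservation totals inherits the published
  design's pseudo-replication (columns share CMPs); its p-value should be
  read as descriptive.
- The scoring rule assumes a two-level factor; multi-level factors need a
  reference dichotomy first.
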