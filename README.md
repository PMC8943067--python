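# toponome

Combinatorial molecular phenotype (CMP) analysis for multiplexed
immunofluorescence imaging.

Serial stain–image–photobleach microscopy (toponome imaging) localizes a
panel of protein markers on the same specimen, one marker per cycle. After
alignment, post-bleach background subtraction and per-channel binarization,
every pixel carries a binary presence/absence pattern over the whole panel —
its **CMP**, written as a bitstring such as `000000001000` with marker 0
leftmost. CMPs turn a stack of grayscale channels into a combinatorial
phenotype map: ranked CMP frequency tables describe whole images, per-cell
top-20 CMP summaries describe single cells, and simple set and contingency
statistics compare samples, treatment groups and sexes. The package was
built for studies of alveolar macrophages (e.g. surfactant-protein-A
knockout mice rescued with exogenous SP-A1), but nothing in it is specific
to that system beyond the defaults.

It provides, as a library plus a `toponome` command-line tool:

- **`toponome.synthetic`** — a cohort simulator with planted ground truth:
  fields of sparse round cells, per-cell phenotypes (per-marker Bernoulli
  expression probabilities), punctate autofluorescence on marker 0, diffuse
  F-actin on the last marker, matched post-bleach backgrounds, integer
  mis-registration, and group/sex effects on phenotype prevalence.
- **`toponome.image_prep`** — the preprocessing chain: integer-translation
  registration, `max(signal − bleach, 0)` subtraction, binarization
  (Otsu / fixed / quantile), and channel merge into a per-pixel CMP image
  with a 15-px excluded border.
- **`toponome.catalog`** — ranked CMP frequency tables (rank 0 = most
  abundant), top-N cuts (N = 54 by convention), and marker-specific
  ("lead protein") subtables.
- **`toponome.conservation`** — cross-sample conserved CMPs: 3-of-3
  (present in every replicate's top-54) and 2-of-3 (pairwise-only) counts,
  group summaries, and a Wilcoxon rank-sum comparison of column totals.
- **`toponome.single_cell`** — per-cell pixel extraction, the top-20-CMP
  marker profile k_m / f_m ("how many of this cell's 20 most abundant CMPs
  contain marker m"), and panel reduction by re-merging channel subsets.
- **`toponome.clustering`** — Ward hierarchical clustering of cell
  profiles, cluster composition tables, the 2/3–1/3 predominance scoring
  rule, Cramér's V association, group marker means and FDR-adjusted
  pairwise rank-sum contrasts.
- **`toponome.pipeline` / CLI** — end-to-end orchestration with a run
  manifest and figure/table reports.

## Worked example: scoring published cluster compositions

The 2/3–1/3 rule labels a cluster "predominantly X" when level X makes up
at least 2/3 of its cells, "predominantly Y" at 1/3 or less, and "mixed" in
between (exact rational comparison, so a 2-of-6 cluster is predominantly-Y).
Applied to the bundled 7-cluster treatment composition of 103 cells:

```python
>>> from toponome import score_clusters, cramers_v
>>> from toponome.datasets import (female_study_composition,
...     sex_comparison_composition, treatment_comparison_composition)
>>> sc = score_clusters(female_study_composition(), "Vehicle")
>>> print(sc.summary.round(1))
                            n_clusters  n_cells  percent
label
predominantly Vehicle                3       51     49.5
predominantly SP-A1 rescue           2       27     26.2
mixed                                2       25     24.3
```

Clusters 3, 5 and 7 (23, 20 and 8 cells at Vehicle fractions 1.0, 0.70 and
0.75) are predominantly Vehicle; together they hold 51 of the 103 cells.
On the pooled two-sex cohort's 12-cluster tables, the association of
cluster membership with each factor:

```python
>>> print(f"V(sex) = {cramers_v(sex_comparison_composition()):.2f}")
V(sex) = 0.75
>>> print(f"V(treatment) = {cramers_v(treatment_comparison_composition()):.2f}")
V(treatment) = 0.39
```

i.e. these clusters track sex much more strongly than treatment.

A full synthetic run (simulate → prep → tabulate → conserve → cells →
cluster → score → assoc, with every artifact written and a manifest):

```sh
toponome run --seed 7 --out runs/demo
toponome report --run-dir runs/demo
```

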