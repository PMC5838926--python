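# toxpi

Weighted multi-criteria prioritization of entities — chemicals, clinical
subjects, any set of instances measured on heterogeneous metrics — as
scriptable, reproducible analytics: the ToxPi (Toxicological Prioritization
Index) scoring scheme with bootstrap confidence intervals,
profile-similarity clustering, and deterministic vector-graphic rendering
of the radial slice profiles.

## Who this is for

Risk assessors and cheminformaticians who need a transparent
weight-of-evidence ranking: many assay readouts and descriptors per
chemical, grouped by expert judgment into a handful of evidence domains,
combined into a single comparable score — with the contribution of every
domain kept visible, and the whole analysis runnable from a shell script or
a notebook instead of a GUI.

## The model

Metrics are apportioned into ordered, named **slices**. Slice *i* carries a
positive weight *wᵢ*, a display color, and a monotone scaling transform
(`linear`, `linear_inverted`, `log10`, `log10_inverted`, `sqrt`; logs take a
fixed +1 offset, inverted variants score *small* raw values high). For
entity *j*:

1. every retained (non-missing, nonnegative) metric value is transformed;
2. the raw slice value *rᵢⱼ* is the **mean of the transformed non-missing
   components** (0, with missingness 1, if all components are absent);
3. slice scores are rescaled by the column maximum,
   *sᵢⱼ = rᵢⱼ / maxⱼ rᵢⱼ*, so every informative slice attains 1 somewhere;
4. the overall score is the weight-normalised average

   *ToxPiⱼ = Σᵢ (wᵢ / Σₖ wₖ) · sᵢⱼ*  ∈ [0, 1],

   comparable across models; rank 1 is the highest score, ties break by
   entity id.

Missing cells are the literal token `NA`; strictly negative inputs are
converted to missing on import (zero is retained). Per-entity uncertainty
comes from bootstrapping each slice's component set (expanded-percentile
intervals; see `docs/methods.md`). Profile similarity is clustered on the
slice-score vectors with Euclidean distance, via six classic agglomerative
linkages (single, complete, average, McQuitty, centroid, Ward) or
multi-start Hartigan–Wong k-means displayed on PCA coordinates.

In the rendered profile, a slice's angular width is its weight share
(2π·wᵢ/Σw), its arc radius is its score, a lighter band marks the
confidence interval, and the inner circle darkens with the fraction of
missing components.

## Worked example

Generate a synthetic 25-entity dataset with the classic published model
structure — four equally-weighted slices of 8 cardiophysiology, 3
cardiotoxicity, 5 hepatotoxicity, and 2 physico-chemical metrics — then
score it under its stored model with 95% bootstrap intervals:

```sh
toxpi simulate --kind uvcb_model --seed 0 --out uvcb.csv
toxpi score --input uvcb.csv --recreate-from uvcb.csv \
    --boot 1000 --seed 42 --out run
```

`run/results.csv` holds one row per entity
(`id,class,overall_score,rank,cluster,<slices...>` plus `_lo/_hi` interval
columns). The top of the ranking:

```
id       overall  rank  slice scores (Cardiophysiology, Cardiotox, Hepatotox, PhysChem)
UVCB-13  0.6844      1  [1.000, 0.606, 0.132, 1.000]
UVCB-03  0.6597      2  [0.700, 0.632, 0.952, 0.355]
UVCB-24  0.6565      3  [0.456, 1.000, 0.266, 0.903]
```

UVCB-13 and UVCB-03 have nearly the same overall score for different
reasons — the first is driven by cardiophysiology and physico-chemical
evidence, the second by hepatotoxicity — exactly the situation the profile
view and the clustering are meant to expose:

```sh
toxpi cluster --input uvcb.csv --recreate-from uvcb.csv \
    --method ward --k 3 --layout circular --auto-color-depth 2 --out clus
toxpi render --input uvcb.csv --recreate-from uvcb.csv \
    --boot 1000 --seed 42 --out figs
```

which writes `clus/dendrogram.svg` (circular, three auto-colored main
branches, cluster labels joined into `clus/results_clustered.csv`, Newick
export alongside) and `figs/profiles.svg` / `figs/rank_plot.svg`. Every
output directory gets a `manifest.json` with the exact configuration and
per-file SHA-256 digests; `toxpi rerun <manifest>` reproduces the outputs
byte-for-byte. SVG output is byte-deterministic; `--format png` rasterizes
the same geometry.

The same pipeline is available as a library (`toxpi.read_table`,
`toxpi.score`, `toxpi.bootstrap_ci`, `toxpi.linkage`, `toxpi.kmeans`,
`toxpi.render_profiles`, ...).

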