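# Methods

## Problem setting

Each glioma case contributes one whole-slide image labeled only with its
subtype — astrocytoma (A), oligodendroglioma (O), or glioblastoma (G) — and
optionally a 3-entry class-probability vector from an MRI-based classifier.
No lesion outlines exist, so patch-level supervision is inexact by
construction: a slide labeled G also contains stroma, blood, infiltration
zones, and background. The pipeline addresses this with three mechanisms:
cheap intensity filters that bias sampling toward cellular tissue,
prototype distillation that discards non-representative patches, and an
explicit irrelevant category (I) whose votes are excluded from the case
decision.

## Patch sampling

Patches (default 224 px, the conventional CNN input size; the source
magnification is whatever the supplied image has) are drawn uniformly
without replacement over all in-bounds top-left origins, then screened:

| rule | statistic | accept when | screens out |
|---|---|---|---|
| 1a | mean over all pixels and channels | in [50, 150] (inclusive) | blank background, over-dark smears |
| 1b | std of each RGB channel | > 20 | low-contrast, non-cellular areas |
| 2 | max − min of per-channel means | < 100 | saturated marker ink |

The pooled-channel reading of rule 1a and the channel-mean-spread reading
of rule 2 are deliberate interpretations: grayscale conversion is never
performed, and channel-mean imbalance is exactly the signature of a colored
pen marker on an H&E slide. Sampling retries until 300 acceptances
(default) or `max_attempts = 50 × n_patches`; `allow_partial` downgrades a
shortfall from an error to a warning. Every accepted patch inherits the
case label.

## Embedding

The feature extractor is a contract, not a model: any deterministic
tile → fixed-length-vector map. The shipped default is a handcrafted
56-dimensional descriptor — three 16-bin channel histograms (L1-normalized),
channel means and standard deviations (scaled 1/255), and
gradient-magnitude mean and standard deviation (scaled 1/255). It is
training-free, fast, and separates the synthetic texture classes by a
within-minus-between cosine-similarity margin of ≈ 0.15. Externally
computed CNN features plug in through a delimited file keyed by tile id
(`file:<path>`); nothing in the package trains a network. All similarity
arithmetic is double precision with exact pairwise computation.

## Prototype selection

Per category with m patch features and similarity matrix S:

* threshold `s_t` = mean of the m(m−1)/2 distinct pairwise similarities;
* density `ρ_i` = count of j ≠ i with `s_ij > s_t` (strict). A signed-sum
  variant (`Σ sign(s_ij − s_t)`) is available behind a flag; it is an
  affine function of the count and produces the same ranking;
* priority order: ρ descending, original index ascending. The index
  tie-break makes δ well defined for tied densities at the cost of
  permutation equivariance only up to tie order;
* diversity `δ_i` = minimum distance `d = 1 − s` to any strictly
  higher-priority patch; the head of the ranking takes the maximum of the
  other δ (and is always accepted), the density-peaks convention that keeps
  the most typical patch selectable;
* selection walks the priority order accepting patches with
  `δ > mean(δ)` (default; a fixed threshold is configurable) until
  k = 100 prototypes are collected.

Distance is `1 − s` rather than an angular distance — monotone equivalent
and cheaper. With a homogeneous candidate pool (patches from a single
texture), δ concentrates near zero with a few large outliers, the mean gate
is then stringent, and fewer than k prototypes may emerge; this is the
intended behavior of a mean-based threshold, not a failure mode — the
selected few are the cluster modes. Heterogeneous pools (several hundred
independently rendered tiles per category) comfortably fill the 100-slot
budget.

Expert review is consumed from a file (exclude / reassign-to-category rows)
and conserves counts; reassignment may create the irrelevant category I. An
`auto_review` helper flags weakly cohesive prototypes (mean within-category
similarity below a percentile) for fully automatic runs; δ and ρ are not
recomputed after review.

## Inference and fusion

A query patch gets the category with the highest mean cosine similarity
over that category's prototypes; ties fall to the fixed order A, O, G, I.
Case aggregation counts votes over all four categories, drops I, normalizes
the rest to a distribution over {A, O, G}, and takes the argmax (same tie
order) with the maximum as the confidence index. When every patch votes I
the case abstains (confidence 0).

Fusion keeps the WSI label when confidence ≥ `C_t` (default 0.6) and adopts
the MRI argmax otherwise — strictly-below semantics, so confidence exactly
0.6 keeps the WSI label. Abstention always defers to MRI; a missing MRI
vector for a low-confidence case keeps the WSI label with a warning. MRI
probability vectors are validated to sum to 1 within 1e-3, a tolerance
chosen so vectors printed at four decimals remain admissible.

## Metrics

Micro-F1 for single-label multiclass equals overall accuracy (diagonal of
the confusion matrix over total). Cohen's κ uses marginal-product chance
agreement; the degenerate single-class full-agreement case returns 1.
Balanced accuracy averages per-class recall over classes that actually
occur in the truth. The summary "average" is the unweighted mean of the
three. All three are cross-checked in the test suite against scikit-learn
to 1e-12 on random instances; scikit-learn is not a runtime dependency.

## Synthetic fixtures

The generator renders what the filters and the embedding need to be
exercised, nothing more: A = dense dark irregular nuclei on pink,
G = the same field plus pale necrotic blobs, O = "fried egg" cells (bright
halo, dark rim, central nucleus), I = small dark-red discs on pale stroma
(passes the filters but is none of the three subtypes), plus pure-white
blank and saturated-green marker textures that must fail the filters.
Default recipes are calibrated so per-channel means stay within ≈ [84, 149]
and minimum channel std above ≈ 22 across seeds — comfortably inside the
filter envelope — and so the three subtypes separate in the default
embedding. Densities are in nuclei per 1000 px², noise is additive Gaussian
on the 8-bit scale.

What the fixtures do **not** emulate: real H&E stain variation, scanner
artifacts, pyramidal resolution levels, nuclear texture, or the actual
morphological ambiguity between A and O. Passing tests therefore
demonstrate the correctness of the machinery (sampling, selection, voting,
fusion, metrics) under controlled separability, not clinical performance.

Slides are composed of non-overlapping rectangular regions on a white
background; the default per-case layout is one large subtype region
(≈ 57% of a 1024² slide), an irrelevant-tissue region (≈ 9%), and a small
marker blob. The simulated MRI arm places probability mass
`concentration` (default 0.8) on a peak label that equals the truth with
probability `accuracy`, the remainder spread evenly. Every per-case
quantity is drawn from a counter-split seed stream (`SeedSequence([seed,
k])` style), so case k is bit-reproducible independently of the cohort
size; consequently class balance is a per-case sampling probability, not an
exact apportionment.

## Pipeline and problem sizes

The `run-all` flow trains on a simulated split with `n_train_per_class`
slides per class (default 2; patches pooled per category), builds I
prototypes from 300 generated distractor tiles, and evaluates on
`n_cases` slides (default 12). The shipped test suite and the acceptance
script use 512–1024 px slides, 300 patches per slide at 224 px, 100-slot
prototype budgets, and a 30-case evaluation cohort — sizes chosen so a full
run completes in minutes on a single CPU while still exercising every
stated default. Stage outputs are plain CSV/JSON written atomically, with a
per-stage manifest (config hash, seed, input digests) for provenance.

## Known limitations

* The default embedding is intensity-based; on real slides it would conflate
  stain variation with class signal — swap in CNN features via the file
  adapter for any serious application.
* Prototype counts under the mean-δ gate depend strongly on candidate-pool
  heterogeneity (see above).
* The fusion rule trusts the WSI arm's confidence calibration; an
  over-confident wrong WSI prediction is never corrected, which mirrors the
  method's design stance that pathology has priority.
* Class balance in generated cohorts is stochastic per case; small cohorts
  can be noticeably imbalanced.
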