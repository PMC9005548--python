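# gliomavote

Weakly supervised glioma subtype classification from whole-slide images
(WSI), with confidence-gated fusion against an mpMRI class-probability
vector.

Adult diffuse gliomas fall into three clinically distinct groups —
lower-grade astrocytoma (**A**), oligodendroglioma (**O**), and glioblastoma
(**G**) — but a digitized slide usually carries only a case-level diagnosis,
with no annotation of which tissue regions are diagnostic. `gliomavote`
implements a prototype-voting pipeline built for exactly this weak-label
setting, aimed at researchers in computational pathology who want a fully
reproducible, dependency-light reference implementation they can test end to
end on synthetic slides and then point at real data through a pluggable
feature-embedding contract.

## Method

1. **Patch sampling.** 300 patches per slide are drawn uniformly at random
   and kept only if (i) the mean intensity over all pixels and channels lies
   in [50, 150], (ii) every RGB channel's standard deviation exceeds 20, and
   (iii) the spread of the per-channel means stays below 100 (rejects pen
   markers). Each kept patch inherits the case label.
2. **Embedding.** Patches map to feature vectors `G(x)` through any
   deterministic embedding; pairwise affinity is cosine similarity
   `s_ij = G(x_i)ᵀG(x_j) / (‖G(x_i)‖‖G(x_j)‖)`.
3. **Prototype selection.** Per category, with `s_t` the mean pairwise
   similarity: density `ρ_i = #{j ≠ i : s_ij > s_t}` and diversity
   `δ_i = min_{j earlier in density order} (1 − s_ij)` (the densest patch
   takes the maximum of the other δ). Walking the density ranking, patches
   with `δ` above the mean-δ threshold are kept until 100 prototypes are
   selected. An expert-review file can drop prototypes or move them to the
   irrelevant category **I**.
4. **Inference.** Each patch is assigned to the category (A/O/G/I) with the
   highest mean cosine similarity to its prototypes; the case label is the
   majority vote with I excluded, and the normalized vote distribution's
   maximum is the **confidence index**.
5. **Label agreement.** The WSI label is kept when the confidence index is
   at least `C_t = 0.6`; below that the mpMRI probability vector's argmax is
   adopted instead.
6. **Metrics.** Micro-F1 (= overall accuracy), Cohen's κ
   `(p_o − p_e)/(1 − p_e)`, and balanced accuracy (mean per-class recall).

A synthetic-fixture module renders class-separable cartoon histology (dense
dark nuclei for A, necrotic blobs for G, "fried egg" cells for O, a
blood-rich distractor for I, blank background, marker ink) plus simulated
MRI vectors of controllable accuracy, so the whole pipeline is testable
without any external data.

## Worked example

```bash
gliomavote run-all --workdir runs/demo --seed 123 --n-cases 6 --mri-accuracy 0.7
```

simulates 6 evaluation cases plus a small training split, runs every stage,
and ends with (abridged):

```json
{
  "select-prototypes": {"n_prototypes_A": 59, "n_prototypes_O": 87,
                        "n_prototypes_G": 100, "n_prototypes_I": 100},
  "fuse": {"n_overridden": 0},
  "evaluate": {"micro_f1": 1.0, "kappa": 1.0, "balanced_accuracy": 1.0,
               "average": 1.0,
               "confusion": [[1, 0, 0], [0, 0, 0], [0, 0, 5]]}
}
```

The mean-diversity gate fills the 100-prototype budget where the training
pool is heterogeneous enough (G, I) and keeps fewer where patches are
near-duplicates (A, O); distractor patches land in category I and are
ignored by the vote. Case labels are drawn per case, so a 6-case cohort can
be imbalanced (here 1 A, 5 G). Every case is classified correctly at high
confidence, so no MRI override fires.
Intermediate artifacts (`patches/patches_*.csv`, `features/*.csv`,
`prototypes/prototypes.json`, `predictions.csv`, `final_predictions.csv`,
`metrics.json`) are plain delimited/JSON files, each with a stage manifest
recording the config hash and seed. The library API mirrors the CLI
(`sample_patches`, `build_prototype_set`, `classify_patches`,
`aggregate_case`, `fuse`, `evaluate`); see `docs/methods.md` for the model
details and design choices.

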