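# Methods

This note records the model implemented by `pollenomics`, the meaning
and default of every parameter, what the synthetic generator emulates,
and the numerical choices that affect results.

## Experimental design assumed

Three pollen developmental stages (tetrad, post-meiotic, mature) × two
conditions (control CO, heat stress HS). Transcripts are measured by a
3'-tag counting protocol in 2 replicates per group; proteins by
label-free LC-MS/MS (MaxQuant `proteinGroups` output) in 3 replicates
per group. An intensity of 0 encodes "not detected" at the protein
level; contaminant (`CON__`) and reverse-decoy (`REV__`) entries are
dropped during parsing.

## Quantification and detection

* **TPM.** `TPM = count / aligned_total × 10⁶`. Tag counting yields one
  tag per transcript regardless of length, so no length normalisation
  is applied. Columns therefore sum to at most 10⁶ (exactly 10⁶ when
  every aligned tag is assigned to a gene).
* **Detection threshold** (`tpm_threshold`, default 5; derived when
  control genes are supplied). Plastid light-harvesting genes are not
  expressed in pollen, so any signal on them measures sporophytic
  contamination plus noise. The threshold is the smallest integer
  strictly above the maximum control-gene TPM
  (`derive_detection_threshold`); individual TPM cells below it are set
  to zero. This is the only place where measured values are zeroed.
* **Replicate rule** (`transcript_min_replicates=2` of 2,
  `protein_min_replicates=2` of 3). A gene/protein is *detected* in a
  stage × condition group when at least that many replicates are
  non-zero. Requiring all transcript replicates but tolerating one
  protein dropout reflects the higher technical missingness of
  label-free proteomics.
* **Averaging.** Replicate means ignore zeros (mean over positive
  replicates; 0 when all are zero), because a zero encodes
  "not measured / below threshold", not an abundance of zero.
  Averaged values are deliberately **not** re-masked by the detection
  flags: detection gates which entities enter each analysis, while the
  values themselves retain every above-threshold measurement. Masking
  averages would push entities detected under only one condition onto
  the exact corners of the (CO, HS) simplex and distort the
  heat-stress clustering.
* **Ungrouping.** Protein-group intensities are assigned to every
  mapped member protein's gene; when several rows map to one gene the
  maximum per library is kept (a shared peptide set bounds each
  member's abundance from above). Unmapped members are reported and
  excluded.

## Developmental clustering

* Profiles are per-entity stage vectors under CO, normalised to sum to
  1 (all-zero rows are dropped); only entities detected in at least one
  CO stage enter.
* `FomKMeans` (a scikit-learn estimator) runs Lloyd k-means `n_runs=25`
  times from initial centroids drawn uniformly from the data points
  and keeps the run with the lowest **clustering variance**: the
  unweighted mean over clusters of the mean per-sample within-cluster
  population variance. Ties keep the earliest run; final centroids are
  recomputed as exact member means. Singleton clusters contribute zero
  variance. Lloyd iterations are delegated to
  `sklearn.cluster.KMeans(n_init=1)`; its empty-cluster repair
  (reassigning the farthest point) stands in for re-seeding empty
  clusters manually.
* Default `k_dev = 15` for developmental profiles. A leave-one-sample-
  out **figure of merit** (fit each k on all samples but one, score the
  root-mean-square deviation of the held-out sample from its cluster
  centroid, averaged over held-out samples) is reported per k; the
  suggested k is the largest one whose FOM improves on its predecessor
  by more than 10% (relative) — a "last substantial gain" reading of
  the elbow.

## Translation-mode calling

* A cluster is **stage-increased** when its centroid places at least
  `increase_threshold` (default 2/3) of the profile mass in one stage.
  The bound t guarantees a worst-case fold of `t/(1−t)` over every
  other stage — exactly 2-fold at t = 2/3 (`implied_min_fold`).
* For each stage-increased set (either level), the overlap row against
  the other level's clusters — computed on genes detected at both
  levels — is min–max scaled; partner clusters with scaled overlap
  **strictly** above `mode_threshold = 0.5` are accepted. The partner's
  dominant stage (centroid argmax) decides the mode: same stage →
  *direct*; protein one stage after the transcript → *delayed*
  (recorded at the transcript's stage); protein earlier than the
  transcript → no call. *Delayed* is impossible for the final stage.
  Both trace directions (transcript→protein and protein→transcript)
  are unioned; when a gene receives both a direct and a delayed call at
  one stage, the larger scaled overlap wins and exact ties are dropped.
  Degenerate overlap rows (all counts equal) yield no calls.

## Heat-stress response

* Per stage and level, entities detected under at least one condition
  are represented by the fractions `(CO, HS) / (CO + HS)` of their
  averaged abundances and clustered with `k_hs = 7` (same restart
  selection). Clusters are ranked by centroid HS fraction (stable
  sort); rank 1 → *down*, rank k → *up*, middle ranks → *stable*.
  k must be ≥ 3 so all three categories exist.
* A degree-≤ 4 polynomial is least-squares fitted to the percentage of
  entities per rank — a reporting aid describing the shape of the
  distribution, never a basis for calls.
* Pseudocounted `log₂(HS/CO)` ratios (pseudocount 1 TPM for
  transcripts; the smallest positive CO intensity for proteins) are
  attached as a diagnostic cross-check of the rank-based categories.

## Annotation summaries

* KOG categories R and S (poorly characterised) are excluded; a gene
  carrying several informative categories counts once in each, so
  percentages may exceed 100% in total. Categories below the 5%
  display cutoff are flagged, not removed.
* Family summaries (Hsp100/90/70/60/40/sHsp/Hsp10, Hsf) report per
  stage the fractions of members called down/stable/up/undetected with
  the annotated family size as denominator (fractions sum to 1). At
  the protein level a member also needs a detected transcript at that
  stage; a protein call without transcript evidence is counted as
  undetected.

## Synthetic generator

Defaults in `SimConfig` are the study conditions, fixed before any
outcome was inspected:

* ~3000 genes; 16 control genes at an expected 1 TPM (below threshold);
  100 direct and 100 delayed genes per applicable stage; 40/40 HS
  up/down transcripts and 50/50 HS up/down proteins per stage; the
  remainder background.
* Transcript counts are negative-binomial with `var = μ + 0.05 μ²`
  around class-implied means at a library depth of 2 × 10⁶; base TPM is
  log-normal (median 60, log-sd 0.8, floor 20). Protein intensities
  are log-normal (multiplicative noise sd 0.4) with 5% per-replicate
  dropout encoded as 0.
* Background genes follow stage-detection masks — transcript
  probabilities (0.95, 0.80, 0.60) and protein probabilities
  (0.50, 0.65, 0.80) across stages — reproducing the shrinking
  transcriptome / growing proteome pattern. Some background proteins
  are paired into two-member protein groups to exercise ungrouping.
* Planted effects: stage fold 6 (lognormal jitter, log-sd 0.2) at the
  planted stage (protein one stage later for delayed genes); HS fold 8
  multiplying (dividing) the affected level at the planted stage.

What the generator does **not** emulate: transcript-length effects
(irrelevant to tag counting), shared-peptide ambiguity beyond
two-member groups, stage-correlated replicate batch effects, and
compositional coupling between genes (each gene is drawn
independently).

## Numerical choices

* All randomness flows from a single integer seed; child seeds are
  drawn from `numpy.random.default_rng(seed)` below 2³¹, so runs are
  bit-reproducible.
* The restart-selection criterion (clustering variance) differs from
  the SSE objective Lloyd minimises. On structured profile data the
  selected run almost always attains the exhaustive-partition variance
  optimum (verified against a brute-force oracle on small instances);
  on structureless noise the variance optimum may isolate singletons
  and need not be a Lloyd fixed point, so no restart count can reach
  it. The guarantee is therefore stated for clustered data only.
* Min–max scaling of an overlap row is undefined when all counts are
  equal; such rows are flagged degenerate and produce no calls rather
  than an arbitrary winner.
* PCA diagnostics standardise genes (zero mean, unit variance,
  constant genes removed) and treat libraries as observations.

## Limitations

* Detection is binary per group; borderline genes near the threshold
  flip with small count changes, and the 2-of-n replicate rules are
  heuristics, not error-rate-controlled tests.
* Rank-based regulation categories guarantee at least one *down* and
  one *up* cluster per stage even if no biological response exists;
  the log₂ diagnostic should accompany any interpretation.
* Mode calls describe cluster-level coupling; an individual gene's
  call inherits its clusters' behaviour and is only as sharp as the
  clustering.
* The polynomial distribution curve is descriptive; its coefficients
  have no inferential meaning.
* Recovery figures quoted in the README are properties of the
  synthetic generator's noise model, not claims about any real
  dataset.
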