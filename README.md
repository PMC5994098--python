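# pollenomics

Transcriptome–proteome coupling analysis of developing pollen under
control and heat-stress conditions.

Pollen development runs through three sampled stages — tetrad,
post-meiotic and mature — during which the transcriptome shrinks while
the proteome grows. Because much of the mature pollen proteome is
translated from transcripts made at earlier stages, transcript and
protein abundance for the same gene often peak at different stages.
This package quantifies that decoupling: it normalises 3'-tag RNA-seq
counts and label-free protein intensities, clusters developmental
expression profiles, matches transcript clusters to protein clusters to
call **direct** (same-stage) versus **delayed** (protein one stage
later) translation, and classifies each gene's heat-stress response as
up-, down- or stably regulated. A synthetic data generator with planted
ground truth makes the whole pipeline testable end to end.

## The model

1. **Quantification.** Tag counts are scaled to tags per million (TPM =
   count / aligned total × 10⁶; 3'-tag protocols yield one tag per
   transcript, so there is no length term). A detection threshold is
   derived from plastid light-harvesting control genes — sporophytic
   contamination markers that should not be expressed in pollen — as the
   smallest integer TPM strictly above their maximum. TPM values below
   the threshold are set to zero. A gene counts as *detected* in a
   stage/condition group when at least 2 of 2 transcript replicates (2 of
   3 protein replicates) are non-zero; replicate averages ignore zeros.
   MaxQuant `proteinGroups` tables are parsed directly; protein groups
   are ungrouped to gene level, collapsing duplicates by maximum.
2. **Developmental clustering.** Per-gene stage profiles under control
   conditions are normalised to fractions summing to 1 and clustered
   with k-means (default k = 15) restarted 25 times; the run with the
   lowest clustering variance (mean over clusters of the mean per-stage
   within-cluster variance) is kept. A leave-one-sample-out figure of
   merit suggests k.
3. **Translation modes.** Clusters whose centroid places ≥ 2/3 of
   abundance in one stage are *stage-increased* (this bound analytically
   guarantees a ≥ 2-fold increase over every other stage). For each
   stage-increased set, overlaps with the other level's clusters are
   min–max scaled per row; partner clusters with scaled overlap
   strictly above 0.5 yield calls — *direct* when the partner's dominant
   stage matches, *delayed* when the protein peaks one stage later.
4. **Heat-stress response.** Per stage and level, (CO, HS) abundance
   fractions are clustered (k = 7); clusters ranked by HS fraction give
   *down* (rank 1), *up* (rank k) and *stable* (middle) categories,
   cross-checked with pseudocounted log₂ HS/CO ratios.
5. **Reporting.** KOG functional-category distributions (excluding the
   uninformative R and S categories) and per-family regulation summaries
   for the Hsp/Hsf chaperone families.

See [docs/methods.md](docs/methods.md) for parameter defaults,
numerical choices and limitations.

## Worked example

Simulate a study-scale dataset (~3000 genes, planted translation modes
and heat-stress responses), run the full pipeline and score the calls
against the planted truth:

```python
import pollenomics as pk

cfg = pk.SimConfig(seed=1)               # ~3000 genes, study-like defaults
recovery, result, dataset = pk.end_to_end_recovery(cfg, seed=11)

print("detection threshold:", result.threshold, "TPM")
print("dually detected genes:", len(result.dual_genes))
print("transcripts detected per stage (CO):",
      {s: int(result.tr_flags[(s, "CO")].sum()) for s in pk.STAGES})
print("proteins detected per stage (CO):",
      {s: int(result.pr_flags[(s, "CO")].sum()) for s in pk.STAGES})
print("translation-mode calls:", result.summary["mode_call_counts"])
print(recovery.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

Output:

```text
detection threshold: 4.0 TPM
dually detected genes: 1446
transcripts detected per stage (CO): {'tetrad': 2905, 'post_meiotic': 2577, 'mature': 2240}
proteins detected per stage (CO): {'tetrad': 1123, 'post_meiotic': 1220, 'mature': 1324}
translation-mode calls: {'mature:direct': 97, 'post_meiotic:delayed': 98, 'post_meiotic:direct': 100, 'tetrad:delayed': 100, 'tetrad:direct': 100}
   call      level  n_true  n_called  sensitivity  precision
 direct       both     300       297        0.987      0.997
delayed       both     200       198        0.990      1.000
  hs_up transcript     120       120        1.000      1.000
  hs_up    protein     150       150        1.000      1.000
hs_down transcript     120       119        0.992      1.000
hs_down    protein     150       154        1.000      0.974
```

The detection trends mirror the biology the generator emulates: the
transcriptome shrinks (2905 → 2240 genes) while the proteome grows
(1123 → 1324) from tetrads to mature pollen, and direct/delayed
translation calls recover the planted truth with ≥ 0.98 sensitivity and
precision.

The same run from the command line:

```bash
pollenomics simulate --seed 1 --out simdata
pollenomics run-all --indir simdata --out results --seed 11
```

writes `clusters_developmental.tsv`, `overlap_matrix.tsv`,
`translation_modes.tsv`, `hs_regulation.tsv`,
`hs_cluster_distribution.tsv`, `functional_distribution.tsv`,
`family_regulation.tsv` and a machine-readable `summary.json` into
`results/`. `pollenomics quantify` stops after detection filtering;
`pollenomics --help` lists all subcommands.

## Layout

| Module | Contents |
| --- | --- |
| `pollenomics.quantification` | TPM, detection threshold and flags, replicate averaging, protein ungrouping |
| `pollenomics.clustering` | `FomKMeans` estimator, clustering variance, figure of merit |
| `pollenomics.translation` | stage-increased sets, overlap scaling, direct/delayed calls |
| `pollenomics.hs_response` | condition profiles, cluster ranking, regulation categories |
| `pollenomics.annotation` | KOG distributions, family regulation summaries |
| `pollenomics.simulate` | synthetic generator with planted ground truth |
| `pollenomics.pipeline` | end-to-end orchestration and file outputs |
| `pollenomics.io` | TSV / MaxQuant `proteinGroups` readers and writers |
| `pollenomics.cli` | `pollenomics` command-line interface |
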