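# dsrnascan

Editing-agnostic detection of double-stranded RNA (dsRNA) regions from
long-read RNA-seq alignments.

## The problem

Endogenous dsRNAs — typically hairpins formed by inverted repeats — are
ligands of innate-immune sensors such as MDA5, and their identification
matters for understanding autoinflammation, ADAR biology and disease.
The standard computational proxy is the *editing-enriched region* (EER):
a cluster of known A-to-I editing sites marks a duplex that ADAR has
visited. EER-based catalogs miss dsRNAs that happen to be unedited in the
sample at hand.

`dsrnascan` exploits an orthogonal signal that requires no editing at all.
During cDNA synthesis, reverse transcriptase occasionally jumps across a
stable hairpin in its template (intramolecular template switching), leaving
an intron-like internal deletion in the read. In spliced long-read
alignments these artifacts appear as reference skips (`~` items in the
minimap2 `cs` tag, `N` operations in the CIGAR) — but with a signature that
differs from real splicing: they occur in a small fraction of the molecules
of a locus, their boundaries wander from read to read, and they are not tied
to splice-site motifs.

## The method

For every 2500-nt genomic window with at least 6 overlapping reads and at
least 1 internally skipping read, 38 features are computed:

* `skip_ratio` — skipping reads / total reads (low for RT artifacts, often
  high and bimodally distributed for spliced loci);
* `len_skip` — mean skipped length (nt);
* `group_num`, `std_start`, `std_end` — skip boundaries are clustered so
  that each cluster's extremes lie within 100 nt of its median; the number
  of clusters and the mean within-cluster standard deviation quantify
  boundary consistency (exactly 0 for clean splicing);
* `gc_skip` — mean GC fraction of the skipped reference segment;
* `bp_start_AA … bp_end_TT` — frequencies of the 16 boundary dinucleotides
  at each end of the skipped segment (GT…AG for true introns).

A random forest (gini splits, 100 trees, `min_samples_leaf` 4, 20 % of
features per split, bootstrapped, unlimited depth) is trained on
EER-derived, RNAfold-verified positive regions versus randomly sampled
read-supported control windows, balanced 1:1. Genome-wide discovery scores
every candidate window, keeps probability > 0.5, removes windows overlapping
the curated positives, folds the survivors with ViennaRNA and splits them by
structure: a *novel long dsRNA* needs a duplex stem of ≥ 200 bp with ≤ 20 %
internal mismatches and an adjusted MFE (MFE / length × 100) ≤ −35 kcal/mol
per 100 nt; anything else is a generally *structured RNA*. A pooled per-region
editing index, G/(A+G) over catalog sites covered by more than three reads,
annotates how edited each discovery is.

A fully seeded synthetic-data module generates genomes with planted
hairpin and splice loci, pre-aligned SAM reads carrying both `cs` and CIGAR
encodings, and clustered editing catalogs, so the entire pipeline is testable
at desk scale without downloads.

## Worked example

```python
from dsrnascan import TrainingSet, ModelConfig, cross_validate, train_model, permutation_importance
from dsrnascan.synthetic_data import SimulationConfig, simulate_corpus, labeled_window_table

corpus = simulate_corpus(SimulationConfig(n_dsrna_loci=40, n_splice_loci=40, seed=11))
table = labeled_window_table(corpus)          # 38 features + label per locus window
ts = TrainingSet(table)
report = cross_validate(ts, k=20, seed=11)
print(f"windows: {len(table)}  (label 1 = dsRNA: {(table.label==1).sum()}, "
      f"label 0 = splice: {(table.label==0).sum()})")
print(f"20-fold CV accuracy: {report.mean_accuracy:.3f}   "
      f"ROC AUC: {report.roc_auc:.3f}   AUPRC: {report.auprc:.3f}")

heldout = labeled_window_table(
    simulate_corpus(SimulationConfig(n_dsrna_loci=40, n_splice_loci=40, seed=1011)))
model = train_model(ts, ModelConfig(random_seed=11))
for name, score in permutation_importance(model, TrainingSet(heldout), seed=11).ranked()[:3]:
    print(f"  {name:12s} contribution {score:+.3f}")
```

prints

```
windows: 69  (label 1 = dsRNA: 33, label 0 = splice: 36)
20-fold CV accuracy: 0.833   ROC AUC: 0.941   AUPRC: 0.938
  skip_ratio   contribution +0.169
  std_end      contribution +0.110
  std_start    contribution +0.106
```

69 of the 80 planted loci yield analysable windows (the rest draw no
skipping read and are removed by the candidate filter). The forest
separates artifact from splice windows with ~0.83 accuracy at this corpus
size (~0.89 at 100+100 loci), and permuting the skipping ratio costs the
model the most held-out R² — the artifact-frequency signal, not the splice
motifs, carries the prediction.

The same steps are available from the shell:

```bash
dsrnascan simulate --n-dsrna 40 --n-splice 40 --seed 11 --out-dir corpus
dsrnascan extract-features --bam corpus/reads.sam --fasta corpus/genome.fa --out features.tsv
dsrnascan train --features labeled.tsv --model model.joblib
dsrnascan predict --bam corpus/reads.sam --fasta corpus/genome.fa \
    --model model.joblib --out-dir discoveries
dsrnascan editing-index --bam corpus/reads.bam --sites corpus/sites.tsv \
    --region chr1:2500-5000
```

## Layout

| module | role |
| --- | --- |
| `dsrnascan.alignment_io` | cs/CIGAR skip parsing, window read indexing, editing catalogs |
| `dsrnascan.feature_extraction` | the 38 per-window features, boundary clustering |
| `dsrnascan.eer_annotation` | editing-enriched regions → merged → structure-verified positives |
| `dsrnascan.structure_curation` | RNAfold adapter, adjusted MFE, duplex-stem metrics, classification |
| `dsrnascan.classifier` | training-set curation, the random forest, CV, permutation importance |
| `dsrnascan.discovery_pipeline` | sliding-window scan, scoring, exclusion, folding, editing index, export |
| `dsrnascan.synthetic_data` | seeded corpus generator with planted ground truth |
| `dsrnascan.cli` | `dsrnascan` command-line entry points |

See `docs/methods.md` for the model, parameter and design details.
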