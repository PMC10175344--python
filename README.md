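# methclass

Methylation-array class discovery and copy-number profiling for mixed
Illumina 450K/850K tumor cohorts.

Genome-wide DNA methylation is the reference tool for classifying brain
tumors — including the low-grade epilepsy-associated tumors (LEAT) such
as ganglioglioma — into *methylation classes* that can carry prognostic
information histology misses.  `methclass` implements the full analysis
such a study needs once arrays from two platform generations have to be
analysed jointly:

1. **Virtual array** — intersect the probe sets of 450K and 850K
   matrices into one combined matrix.
2. **Stratified quantile normalization** — per probe-type stratum and
   channel, map every sample onto the cross-sample mean quantile
   distribution.
3. **Probe filtering** — drop probes on sex chromosomes, overlapping
   SNPs, cross-reactive or not uniquely matching.
4. **Class discovery** — beta values β = M/(M+U+100) are embedded with
   UMAP (`init="random"`, `min_dist=0`, `spread=3`) and clusters
   confirmed with HDBSCAN (`min_samples=4`, `min_cluster_size=4`);
   clusters are matched to published reference labels by majority vote,
   and clusters without labeled members are reported **NOVEL**.
5. **Copy-number calling** — per sample, total log2 intensity
   log₂(M+U+1) is regressed (OLS + intercept) on copy-neutral reference
   samples; median-centered residuals are binned (median per genomic
   bin), segmented by circular binary segmentation with a seeded
   permutation test, and thresholded at |log2 ratio| ≥ 0.15 into
   gain/neutral/loss.
6. **Cohort summary tracks** — per discovered class and genomic bin,
   the percentage of samples called gained/lost, the group-level view
   that separates CNV-rich classes from flat-profile classes.
7. **Outcome statistics** — 2×2 chi-square (with optional Yates
   correction) of class membership against postsurgical seizure freedom.

A fully specified synthetic-cohort generator (mixed array designs,
class-specific methylation signatures, chromosome-arm CNV events,
copy-neutral controls) makes every stage testable without downloads.

## Worked example

Run the packaged demonstration cohort (five planted methylation classes,
one of them unlabeled and CNV-rich with an adverse-outcome profile, plus
eight copy-neutral controls):

```python
from methclass import PipelineConfig, run_pipeline, demo_config, CNVParams

config = PipelineConfig(
    seed=1,
    outdir="demo_run",
    simulation=demo_config(seed=1),
    cnv=CNVParams(target_bin_size=2_000_000),  # synthetic genome is sparse
)
report = run_pipeline(config)
print(report["clusters"]["mapping"])
print("ARI vs truth:", report["ari_vs_truth"])
print("novel track:", report["tracks"]["NOVEL"])
print("outcome:", {k: round(v, 3) for k, v in report["outcome"].items()
                   if isinstance(v, float)})
```

prints (seed 1):

```
{'0': 'LGG-GG', '1': 'LGG-DNT', '2': 'LGG-PXA', '3': 'LGG-MYB', '4': 'NOVEL'}
ARI vs truth: 1.0
novel track: {'n_samples': 21, 'max_pct_gain': 47.61904761904762, 'max_pct_loss': 52.38095238095238, 'mean_pct_altered': 23.492063492063487}
outcome: {'chi2': 3.853, 'p': 0.05, 'chi2_yates': 2.859, 'p_yates': 0.091, 'seizure_free_pct_novel': 47.619, 'seizure_free_pct_rest': 72.0}
```

Reading this: the four labeled reference classes are recovered and
mapped back to their names; the fifth cluster contains no labeled
samples and is flagged NOVEL (adjusted Rand index 1.0 against the
planted truth).  Its summary track shows up to ~48% of samples gained /
~52% lost per bin — the planted arm events at their penetrances — while
the reference-class tracks stay flat.  Seizure freedom in the novel
class (10/21) is lower than in the remaining classes (36/50); the
chi-square on that 2×2 table is printed with and without Yates
correction.  All artifacts (clusters.tsv, segments.seg, calls.tsv,
per-group `track_*.tsv`, UMAP and summary figures, report.json) are
written under `demo_run/`.

The same pipeline is scriptable from a shell:

```bash
methclass simulate --seed 1 --out cohort/
methclass run --config pipeline.yaml
methclass stats --yates 5 8 19 6
```

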