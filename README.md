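# circsync

Cross-tissue temporal-coordination analysis of circadian gene expression.

## The problem

Multi-tissue circadian studies profile gene expression in many organs over a
24-h cycle (e.g. 22 tissues sampled every 2 h, 2 replicates per time point,
under *ad libitum* (ALF) vs time-restricted feeding (TRF)). The scientific
question is not whether individual genes are rhythmic within one organ, but
how tightly expression rhythms are *aligned* — among genes within a tissue,
between tissue pairs, and for a single gene across the whole body. `circsync`
implements that analysis for computational biologists working with such
time-course matrices:

- **Intra-tissue coordination** — all-pairs Pearson correlation matrices of
  gene profiles over the cycle; synchronization strength as the matrix mean
  |r|; the count of significantly correlated pairs at an unadjusted
  two-tailed α (default 0.05); complete-linkage ordering on 1 − r; unpaired
  t-tests contrasting feeding conditions.
- **Inter-tissue coordination** — cross-tissue correlation matrices (all gene
  pairs, or each gene against itself), pair-level summaries, per-tissue
  summed strength Σ|r|, relative ALF→TRF changes, and a network edge table.
- **Whole-body synchronization score** — for gene *g* over tissues
  *s = 1..T*,

      S_g = Σ_{A<B} r(x_gA, x_gB),    max S_g = C(T, 2)  (= 231 at T = 22)

  with signs preserved so anti-phase tissues lower the score. A "clock-like"
  threshold is calibrated on a benchmark panel of core clock genes: scores
  are sorted descending and the threshold is placed at the first pronounced
  decline (largest gap, first gap above 3× the median gap, or a manual
  value). Genes above the threshold form the globally synchronized set,
  clustered into temporal waves by complete linkage on 1 − r at a fixed
  dendrogram height (default 1.0, the r = 0 boundary).
- **Pathway-term enrichment** — MitoCarta-style hierarchical term paths are
  reduced to per-gene term multisets; clusters are ranked by term frequency
  and term ratio (cluster count / universe count), excluding the broad
  "Metabolism" category, top 5 reported per metric.
- **Amplitude statistics** — peak-to-trough range of the replicate-averaged
  waveform on *unscaled* values, ratios/log2 ratios between conditions, and
  one-sample/unpaired t-test utilities.
- **Synthetic data** — a generator of cosine-rhythm multi-tissue datasets
  with known ground truth (aligned / scattered / benchmark genes, per-tissue
  phase jitter that differs by condition), so every stage is testable without
  external data.

## Worked example

```python
import numpy as np
from circsync import (SimulationConfig, generate_dataset, designate_benchmarks,
                      score_table, calibrate_threshold, global_set, overlap_sets)

cfg = SimulationConfig(seed=1)          # 22 tissues x 500 genes, ALF vs TRF
dataset, truth = generate_dataset(cfg)
panel = designate_benchmarks(truth, cfg)

tables = {c: score_table(dataset, c) for c in ("ALF", "TRF")}
cal = calibrate_threshold({g: tables["ALF"].scores[g] for g in panel})
sets = {c: global_set(t, cal.threshold) for c, t in tables.items()}
ov = overlap_sets(sets["ALF"], sets["TRF"])
print(f"threshold {cal.threshold:.1f}; "
      f"ALF {len(sets['ALF'])} vs TRF {len(sets['TRF'])} globally synchronized; "
      f"shared {ov.n_shared}")
```

prints

```
threshold 96.0; ALF 12 vs TRF 50 globally synchronized; shared 12
```

The benchmark-calibrated threshold (96.0 here, on a 0–231 score scale) admits
only the 12 benchmark clock-like genes under the loosely phase-dispersed ALF
condition, while the tightly entrained TRF condition lifts all 50 planted
aligned genes above the same bar — the coordination gain the score is
designed to expose — and every ALF gene is shared with TRF.

The same pipeline runs from the shell:

```
circsync run-all --seed 1 --out-dir run1
```

writing per-stage TSV/JSON outputs (`intra/summaries.tsv`,
`inter/edges_ALF.tsv`, `global/scores_TRF.tsv`, `global/overlap.json`,
`pathways/top_terms_TRF.tsv`, `amplitude/comparison.json`, …) and a
`manifest.json` recording all parameters; identical seeds reproduce the run
byte-for-byte.

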