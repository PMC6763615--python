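# phosphoprofiler

Analysis pipeline for duplicate-spotted phospho-protein antibody arrays
(Proteome Profiler-style RTK and MAPK membranes), aimed at labs that use
these membranes to screen tumour samples for activated — i.e.
phosphorylated — kinases as candidate drug targets.

A membrane carries capture antibodies spotted in duplicate (49 receptor
tyrosine kinases on the RTK array; 26 downstream signalling molecules,
9 of them MAPKs, on the MAPK array), plus three positive-reference
duplicate pairs and one PBS-only negative-control pair. The package
covers the full path from a scanned membrane image to cohort-level
statistics:

* **Densitometry** — per-spot integrated density (exact pixel-center disc
  sums), global background estimation (negative-control spots or corner
  patches), background subtraction with a zero floor, duplicate
  averaging and duplicate-CV QC.
* **Profile views** — absolute density *v*, percent of maximum
  (100·*v*/max *v*), percent of total (100·*v*/Σ*v*), and
  reference-normalized (*v*/mean reference density); all four are
  rank-isomorphic, and the reference view cancels exposure differences
  between membranes.
* **Activation calling** — two binary cut-off schemes from the antibody
  array literature: log2 values above mean + SD of the membrane's own
  distribution, and signals above 3× the highest negative control;
  plus a four-level ordinal grading of %max (cuts at 10/50/80).
* **IHC concordance** — cross-table, exact agreement and Kendall τ-b
  (exact permutation p for n ≤ 10) between array %max values and ordinal
  immunohistochemistry scores (–, +, ++, +++).
* **Serial samples** — per-interval log2 fold changes of
  reference-normalized profiles across timepoints, flagging analytes
  with sustained decreases (e.g. under kinase-inhibitor therapy).
* **Cohort clustering** — log2 transform, per-sample median centering,
  per-analyte z-scoring, Welch-test filtering between two diagnostic
  groups (unadjusted p < α), then hierarchical clustering of both axes
  with Ward linkage over correlation distances (1 − Pearson r), heights
  in the ward.D2 convention, and heatmap export clipped to [−3, 3].
* **Synthetic data** — because patient membranes are not public, a
  first-class simulator generates lognormal two-group cohorts with
  planted log2 effects, rendered 16-bit membrane images (background
  plane, gradient, pixel noise, duplicate jitter, optional saturation),
  serial series and matched ordinal IHC scores, all deterministic under
  a seed.

## Worked example

Simulate a membrane, quantify it and rank the most phosphorylated
targets:

```sh
phosphoprofiler simulate --seed 11 --n-samples 2 --group-sizes 1,1 --out demo/sim
phosphoprofiler quantify --image demo/sim/membrane_S01.tiff --out demo/quant
```

```
          absolute     pct_max  pct_total  ref_norm
analyte
DDR2     4407182.5  100.000000  26.946196  1.993822
IGF-1R   1828750.0   41.494765  11.181261  0.827332
EphA10   1388707.0   31.510086   8.490770  0.628255
FGFR4    1047244.0   23.762211   6.403012  0.473776
EphA1     564710.5   12.813413   3.452727  0.255477
EphB4     508128.0   11.529543   3.106773  0.229879
```

Each row is one analyte's averaged, background-subtracted duplicate
density on the four scales: DDR2 is the most phosphorylated target on
this membrane (by construction of the seed), reading exactly 100 %max,
carrying ~27% of the membrane's total signal and about 2× the
positive-reference intensity. Calling activation on the same profile:

```sh
phosphoprofiler call --profile demo/quant/profile.csv --out demo/calls
# 6 of 49 analytes activated (mean+SD threshold 18.890 log2 units)
```

Cluster a simulated 12-sample cohort (5 + 7 in two diagnostic groups,
planted log2 effect 3):

```sh
phosphoprofiler simulate --no-render --seed 11 --out demo/cohort
phosphoprofiler cluster --cohort demo/cohort/cohort.csv --out demo/clust
# 13 analytes pass p<0.05; clustered 13 analytes x 12 samples
```

`demo/clust/` then holds the clipped z-score matrix (`heatmap.csv`),
dendrograms as Newick (`rows.nwk`, `cols.nwk`), per-analyte p-values and
the k=2 sample partition, which for this seed reproduces the two planted
groups exactly.

The same operations are available as a library
(`phosphoprofiler.quantify_membrane`, `cluster_cohort`, …); see
`docs/methods.md` for the model and parameter conventions.

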