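# riftkin

Genome-wide RNA decay kinetics from rifampicin-chase time courses.

Rifampicin blocks initiation of new bacterial transcripts, so the signal
decline after treatment measures RNA degradation alone. Chase experiments in
the marine cyanobacterium *Prochlorococcus* MED4 (triplicate cultures sampled
at 0, 2.5, 5, 10, 20, 40 and 60 minutes) revealed transcripts with some of the
shortest half-lives known, and — for polycistronic messages and long genes —
decay that starts later and runs slower with increasing distance from the
transcriptional start. `riftkin` implements the estimators behind those
findings as a tested, reusable pipeline for anyone analysing
transcription-arrest time courses:

* **Half-life, twofold decay-step method.** An exponential is fit between the
  first timepoint and the earliest later timepoint with a ≥ 2-fold decrease;
  its time-per-twofold is the half-life *t*<sub>1/2</sub>. Series that never
  halve fall back to an all-point fit (possibly negative for rising signals)
  and are flagged stable.
* **Decay rate, relative two-phase model.** Decline is measured relative to
  the last timepoint of maximal expression *t*<sub>on</sub>; two successive
  exponentials are fit to log2 signal, one from *t*<sub>on</sub> to a
  breakpoint *x* and one from *x* to the end, with *x* chosen over all sampled
  timepoints to minimize the pooled MSE of the logged data. The first phase's
  time-per-twofold is the decay rate, so delayed-onset transcripts get a rate
  that reflects degradation speed, not onset lag.
* **Operon analysis.** Strand-aware distances to the operon's first start
  codon, Spearman correlation of distance versus stability, operon validation
  against the expression data, and type I (plateau, then decline) versus
  type II (transient distal rise, then decline) profile classification.
* **Polymerase elongation rate.** For genes ≥ 2 kb tiled by probes every
  80 nt, the velocity *v* = *s*/*t* (nt/s) from each probe's distance *s* and
  half-life lag *t* relative to the first probe.
* **Soft clustering + enrichment.** Fuzzy c-means (fuzzifier *m* = 2) on
  standardized decay profiles, hypergeometric category enrichment with
  Bonferroni correction, and cluster-number selection by enrichment.
* **Synthetic chase generator.** Seeded fixtures (gene-, operon- and
  probe-level) with known kinetic ground truth — exponential and two-phase
  decay, delayed onsets growing with distance, distal transient rises,
  multiplicative replicate noise, signal saturation — so every stage is
  testable without external data.

## Worked example: one delayed-onset transcript

```python
from riftkin import ChaseDesign, DecayModel
from riftkin.synthetic import TrueKinetics, simulate_gene

design = ChaseDesign(seed=7, noise_sigma=0.0, replicates=3)
gene = TrueKinetics("PMM_demo", E0=900.0, onset_delay=10.0,
                    fast_half_life=4.0, slow_half_life=4.0, phase_break=30.0)
series = simulate_gene(gene, design)
results = DecayModel(design.times, series.to_numpy(), gene_id="PMM_demo").fit()
print(results.summary())
```

```
Decay kinetics: PMM_demo
============================================
half-life (twofold)          8.00 min  (se 0.00)
decay rate (two-phase)        4.0 min  (se 0.00)
decay onset t_on             10.0 min
phase breakpoint             20.0 min
stable (> 60 min)          False
points used                     7
```

The transcript sits at full signal for 10 minutes before decaying with a true
half-life of 4 minutes. The twofold method, anchored at *t* = 0, absorbs the
onset lag and reports 8.0 min; the two-phase model detects the onset at
10 min and recovers the post-onset rate of 4.0 min exactly. The gap between
the two columns is the signature of delayed decay — the pattern shown by
distal operon genes.

## Worked example: a genome-scale run

```bash
riftkin simulate --out demo --seed 42 --n-genes 300 --n-operons 20
riftkin run --expression demo/expression.tsv --annotation demo/annotation.tsv \
            --seed 42 --n-clusters 8 --out demo/run
riftkin report --out demo/run --expression demo/expression.tsv
```

```
riftkin run report
========================================
genes analysed:        300
median half-life:      3.2 min
median decay rate:     3.2 min
80% of half-lives in:  1.0-10.7 min
stable fraction:       2.0%
operons retained:      18/20 (type I 13, type II 5)
distance vs half-life: Spearman r = 0.89, P <= 1e-16 (n = 91)
warning: probes stage skipped: no probe table
```

Half-life medians and the central-80% interval summarize the genome; operons
are validated (weak expression or inconsistent member profiles are excluded
with logged reasons), typed I/II, and the distance-to-start versus half-life
correlation quantifies the 5'→3' stability gradient. `manifest.json` records
config, input digests and output digests; two runs with the same seed are
byte-identical.

A GEO series-matrix file can be passed anywhere an expression TSV is
accepted (detected by its `!series_matrix_table_begin` sentinel), which is
how deposited chase experiments are analysed with the same pipeline.

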