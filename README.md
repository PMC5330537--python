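# parsbias

Analysis pipeline for studying how RNA secondary structure drives
sequencing bias, built around transcriptome-wide structure probing
(PARS — Parallel Analysis of RNA Structure).

## The problem

Illumina-style sequencing under-represents GC-rich regions, and the usual
suspects (PCR amplification, adapter ligation) all interact with one
GC-correlated molecular property: RNA secondary structure.  Dual-nuclease
probing makes that property measurable at nucleotide resolution.  RNase V1
cleaves double-stranded RNA and RNase S1 single-stranded RNA, each leaving
a 5' phosphate that is captured by adapter ligation — so the 5' end of an
aligned read marks a cleavage site, and the balance of V1 versus S1 read
starts at a position reports its folded state.

The per-position **PARS score** is the log ratio of read-start counts,

```
score_i = log2( V1_i / S1_i )
```

positive where the position is double-stranded, negative where it is
single-stranded.  A position is *high quality* when all three libraries
(V1, S1, and an ordinary RNA-seq control) have data there and
|score| >= 3; genes with at least 80% high-quality positions are retained.
On the retained genes the package runs the downstream battery:

* **depth vs. structure** — Pearson correlation of PARS score with control
  read starts, per gene;
* **depth vs. GC** — pooled, within GC strata (<40%, 35–60%, >60%), and
  per-strain ordinary least squares of normalized depth on gene GC;
* **structure prevalence vs. GC** — percent double-stranded per gene
  against gene GC;
* **structure vs. read starts** — binomial logistic regression
  `P(paired) = logistic(b0 + b1 * read_starts)`, with predicted-probability
  curves and pointwise Wald intervals; `exp(b1)` is the odds multiplier
  per additional read start;
* **PARS vs. thermodynamic folds** — agreement with externally computed
  dot-bracket structures (score/indicator correlation plus a 2×2 Fisher
  exact test).

A synthetic-data generator emulates the whole protocol for three bacterial
"strains" of low/medium/high GC (32%, 48.5%, 73%), with known pairing
states, Poisson cleavage counts, an off-target cleavage rate calibrated so
about 7% of V1/S1 peaks are shared, and a control library depressed at
structured positions and in GC-rich genes — so every stage of the pipeline
can be validated against ground truth without any download.

## Worked example

```python
from parsbias import SimConfig, simulate_study, predict_curve

configs = [
    SimConfig(target_gc=gc, n_transcripts=60, seed=1000 + i, strain_id=sid)
    for i, (sid, gc) in enumerate(
        [("lowgc", 0.32), ("midgc", 0.485), ("highgc", 0.73)]
    )
]
truths, results = simulate_study(configs)

print(results.retained_counts)
for c in results.depth_gc:
    print(f"depth~GC [{c.stratum}] r={c.r:.3f} p={c.p_value:.3g} n={c.n}")
pc = results.pctds_gc
print(f"pctds~GC r={pc.r:.3f} p={pc.p_value:.3g}")
fit = results.pooled_logit
print(f"pooled logit beta1={fit.beta1:.4f} (se {fit.se1:.4f}) n={fit.n}")
curve = predict_curve(fit)
```

prints

```
{'highgc': 60, 'lowgc': 60, 'midgc': 60}
depth~GC [pooled] r=-0.114 p=0.126 n=180
depth~GC [low] r=-0.579 p=1.27e-06 n=60
depth~GC [medium] r=-0.230 p=0.063 n=66
depth~GC [high] r=-0.881 p=1.71e-20 n=60
pctds~GC r=0.991 p=2.82e-157
pooled logit beta1=-0.5991 (se 0.0039) n=96643
```

All 180 simulated genes clear the 80% retention filter at this probing
depth.  The high-GC stratum shows the strong inverse depth–GC correlation
(r = −0.88), structure prevalence tracks GC almost perfectly by
construction (r = 0.99), and the pooled logistic coefficient is negative:
each extra control read start multiplies the odds that the position is
structured by `exp(−0.60) ≈ 0.55`.  The curve object tabulates the
predicted structure probability with its 95% interval across the observed
read-start range (e.g. p̂ = 0.87 at 10 read starts, 0.02 at 20).

## Command line

`parsbias` exposes the stages as subcommands: `simulate`, `tally` (SAM/BAM
→ counts TSV), `score`, `filter`, `gcbias`, `logit`, `compare-fold`,
`all` (YAML-config-driven full chain) and `selftest` (simulate → analyze →
assert the recovery invariants).  All file interfaces are plain text:
FASTA, SAM/BAM, GFF3/BED, 4-column count TSV, dot-bracket, bedGraph, YAML.

```
parsbias selftest --seed 1
parsbias simulate --target-gc 0.73 --out sim/
parsbias score --counts sim/sim.counts.tsv --out sim/profiles.tsv
```

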