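# Methods

## Scoring model

The measurement model follows the dual-nuclease probing logic: RNase V1
cleaves double-stranded RNA, RNase S1 single-stranded RNA, and each
cleavage leaves a 5' phosphate captured by adapter ligation, so the 5'
end of an aligned read marks a cleavage site.  The per-position PARS
score is `log2((V1_i + c) / (S1_i + c))` with pseudocount `c = 0` by
default; with `c = 0` the score is undefined wherever either probing
count is zero.  Log base 2 is the convention of the original PARS method
and is configurable (`ParsParams.log_base`); the quality threshold is
applied on whatever scale the chosen base produces.

Positional quality is a hard 0/1 rule: flag 0 wherever any of the three
libraries (V1, S1, control) has a zero count — this absent-data rule is
applied to the raw counts and is never softened by a pseudocount — and
otherwise flag 1 iff |score| >= 3, boundary inclusive.  Genes with at
least 80% flagged positions (boundary inclusive) are retained.  Structure
calls use only the sign of the score on flagged positions; the magnitude
gate already lives in the flag, so no second call threshold exists.
"Absent" is interpreted as a zero count in the merged track.

## Read-start tallying

The biological 5' end is the alignment start after soft-clipping
(clipped bases are an alignment artifact, not part of the ligated end):
the leftmost reference position for + strand genes, the rightmost for −
strand genes, mirrored into transcript coordinates.  Replicates merge by
summation.  Only primary, non-duplicate, non-supplementary alignments
with MAPQ >= 10 count, and by default only read 1 of a pair (the mate
ligation captures the 5' phosphate on one end; counting both mates is
available via `count_read2=True`).  Internal coordinates are 0-based
half-open; all files are 1-based.  Input SAM/BAM is streamed
sequentially, so no sort order is required.

## Bias battery

Depth is normalized per strain — each gene's mean control start count
divided by the strain-wide mean per position — because library size is
strain-specific and depths are only ever compared across genes; the
length-weighted mean of normalized depths is 1 by construction.  Gene GC
is computed over unambiguous A/C/G/T only.  The GC strata default to
low < 40%, medium 35–60% (closed), high > 60%; the low/medium overlap is
kept deliberately, and strata are arbitrary labeled intervals so
non-overlapping schemes are one argument away.  Pearson correlations use
the product-moment statistic with the two-sided p from the t transform on
n − 2 df; per-strain fits are ordinary least squares of normalized depth
on GC.  p-values are reported raw; Benjamini–Hochberg adjustment across
the per-gene battery is available (`bias.bh_adjust`) but off by default,
since the battery reports distributions of unadjusted p-values.

## Logistic model

`P(paired) = logistic(b0 + b1 * read_starts)` is fit by IRLS (relative
tolerance 1e-8, at most 100 iterations) on the called positions only;
unknown calls are excluded, not imputed.  The predictor is the raw count,
so a one-unit increase means one read start and `exp(b1)` is the odds
multiplier.  With a single continuous predictor, complete separation is
exactly non-overlap of the two classes' predictor ranges; it is detected
up front and returned as a non-converged fit with a diagnostic.
Predicted-probability curves are evaluated on the integer grid from 0 to
the observed maximum; the 95% (configurable) pointwise interval is the
normal-approximation interval on the linear predictor, using the full
coefficient covariance, mapped through the logistic — hence always inside
[0, 1].  Both a pooled fit across retained genes and a per-gene battery
are produced; genes violating fit preconditions are flagged in the output
table rather than dropped.

## Fold comparison

Dot-bracket structures are validated with a bracket stack; pseudoknot
brackets `[] {} <>` are accepted and treated as paired.  Agreement with
the experimental calls is reported both ways a reader might mean it:
Pearson correlation of PARS score with the folded-state indicator over
quality-1 positions, and the paired/single 2×2 contingency table with a
two-sided Fisher exact p.

## The synthetic-data generator

The generator emulates the probing protocol on three strains of low,
medium and high GC (32%, 48.5%, 73%), with per-strain defaults:

| parameter | default | meaning |
|---|---|---|
| `n_transcripts` | 60 | genes per strain |
| `length_range` | 300–900 nt | transcript lengths, uniform |
| `gc_window` | 51 nt | centered window for local GC, truncated at ends |
| `struct_gc_intercept`, `struct_gc_slope` | −2, 4 | `P(paired_i) = logistic(−2 + 4·localGC_i)` |
| `lambda_v1`, `lambda_s1` | 100 | mean on-target cleavage start count |
| `nonspecific_rate` | 0.022 | off-target cleavage rate relative to on-target |
| `control_depth0` | 20 | baseline control start count per position |
| `gamma_struct` | 0.7 | control start-rate penalty at paired positions |
| `gamma_gc` | 1.5 | per-gene depth penalty per unit GC above 0.5 |
| `peak_threshold` | 5 | count defining a "peak" for the shared-peak statistic |

Sequences are i.i.d. with P(G or C) = target GC; pairing states are
independent given local GC (the analyses use only the binary state, so
base-pair partner topology is not modeled); cleavage and control counts
are Poisson.  The control rate is
`control_depth0 · exp(−gamma_struct·paired) · exp(−gamma_gc·max(0, geneGC−0.5))`
— the structure penalty is per position, the GC penalty gene-level and
one-sided, active only above 50% GC.  The fragment-end ligation-failure
mechanism is collapsed into the per-position start-rate penalty; no
fragment-length or read-level (FASTQ) simulation is attempted, and no
thermodynamic folding is performed.

The off-target rate is calibrated so that about 7% of peak positions
(count >= 5 in either probing track) are peaks in both.  Under the
Poisson model the expected shared-peak fraction depends on the rates only
through the products `lambda·rate`, and `calibrate_nonspecific_rate`
solves for the rate by bisection on the analytic Poisson survival
expression; at the default lambdas the solution is ~0.0218, and the
shipped default of 0.022 gives an expected shared fraction of 0.0725.
The probing intensity `lambda = 100` was chosen together with that rate:
the expected on-target score is `log2(1/0.022) ≈ 5.5`, comfortably above
the quality threshold of 3, which is what makes an 80%-retention
experiment feasible at all — at `log2(1/rate)` near 3 the typical
position sits on the threshold and essentially no gene is retained.
Mean counts of ~100 per position correspond to a deep probing library
concentrated on a modest transcriptome, which is the regime the retained
high-confidence genes of such an assay occupy.

What the generator does **not** emulate: expression-level variation
across genes (real retention filtering is dominated by lowly expressed
genes; simulated retention is therefore near-total), sequence-specific
nuclease preferences, dynamic or alternative structures (the shared-peak
rate stands in for all off-target signal), positional autocorrelation of
pairing, and library-size differences between V1 and S1.  Passing tests
therefore demonstrate the correctness of the statistical machinery and
the recoverability of the generative couplings — not that real probing
data meet these idealizations.

## Numerical and design choices

* Poisson counts everywhere: every moment has a closed form, so tests can
  use analytic oracles rather than tuned tolerances.
* Problem sizes: the study-level checks use three strains × 60 genes
  (~10^5 positions), sign-recovery uses 100 replicates of ~5400 positions,
  coverage 500 replicates of 1000 positions, and the noise calibration a
  ~10^6-position simulation — sizes at which every directional and
  calibration property is far from its decision boundary.
* Determinism: a single `numpy` Generator seeded from the config drives
  each simulated strain in a fixed order; identical configs give
  bit-identical sequences, states and counts, and identical output files.
* Degenerate inputs: zero-length genes, all-unknown genes, single-class
  logistic responses, constant-GC designs and zero-variance correlations
  all raise explicit errors (or return flagged non-computable results
  where the battery must continue past a bad gene).
* The three-strain GC assignment follows the strain descriptions used
  throughout (low 32%, medium 48.5%, high 73%).

## Known limitations

* The quality rule conflates "no data" with "count zero"; at low depth
  this censors genuinely single-stranded (V1-silent) positions and is the
  main reason real assays retain few genes.
* Wald intervals on the logistic curve are first-order; near-separation
  they undercover, which the separation flag only partially mitigates.
* `pct_double_stranded` conditions on called positions; when quality
  flags are sparse it estimates structure prevalence among confidently
  called sites, not among all sites.
* The per-strain depth normalization assumes genes within a strain share
  one library; mixing libraries within a strain would need per-library
  normalization first.
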