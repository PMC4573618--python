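# Methods

This note documents the models, numerical choices and synthetic benchmark
behind `dhstf`, at the level of detail a maintainer or reviewer needs to
judge what a passing test suite does and does not demonstrate.

## 1. Motif scoring

A PWM is stored as an L × 4 nonnegative count matrix (A, C, G, T order).
Counts are converted to log2-odds weights against a background composition
b with an additive pseudocount p:

    w[l, β] = log2( (n[l, β] + p·b[β]) / (N_l + p) / b[β] ),   N_l = Σ_β n[l, β]

Defaults: uniform background (0.25 each) and p = 1.0. The source material
for this method names only "similarity scores" without defining them;
log2-odds with a pseudocount is the field-standard, reproducible choice and
both background and pseudocount are exposed as parameters so a MATCH-style
rescaled score could be layered on top if ever needed.

The binding affinity of a PWM for a sequence is the maximum summed weight
over all length-L windows on **both strands** (TF binding is
strand-agnostic; the reverse complement of the sequence is scanned with the
same weights). The ambiguity code N contributes weight 0, i.e. scores as
the background expectation — neutral rather than disqualifying. A sequence
shorter than the motif has no valid window; in the affinity matrix that
(PWM, DHS) entry is treated as absent.

### Top-K thresholding

Per PWM, all DHS max scores are ranked and the threshold ts is the K-th
highest (reference setting K = 5000 genome-wide; the synthetic benchmark
uses K = 100 of 400 DHS as the desk-scale analogue). Scores below ts are
zeroed; scores equal to ts are **all** retained, so ties make the column
slightly denser than K rather than arbitrarily dropping sites — a
deterministic, input-order-independent rule. With fewer than K scored
sites, ts falls back to the minimum score (nothing is discarded).

## 2. Regulatory regions and the indicator matrix

Coordinates are BED convention (0-based, half-open) throughout. The
regulatory region of a gene is [tss − 1000, tss + 500) on the + strand and
the mirror image on the − strand, clipped at the chromosome origin. When an
annotation lists several transcripts per gene, the most upstream TSS is
used: the model is per-gene, so exactly one window per gene is wanted.

C[i, j] = 1 when DHS j overlaps the window of gene i. *Any* overlap counts
by default — DHS sites routinely straddle window edges, and requiring full
containment would drop exactly the promoter-spanning sites the method
relies on. Full containment is available as `overlap_mode="contained"`.
Overlap queries run on an interval tree; tests check equivalence with an
all-pairs brute-force oracle.

## 3. Expression preprocessing

Input is a log2-scale features × samples matrix with a sample→condition
map. The pipeline:

1. **Quantile normalisation** within each condition's replicates: each
   column is mapped onto the mean of the sorted columns; tied values
   receive the mean of the quantile values they span. The operation is
   idempotent on tie-free data; with ties, the averaged values perturb a
   second-pass reference at the last decimal, which is why the idempotence
   test uses continuous data.
2. **Scaling normalisation** of treatment onto control: one additive log2
   shift equating 2%-trimmed means. Only the location of the distribution
   moves; within-sample differences are untouched.
3. **Differential selection**: Welch's two-sample, two-sided t-test per
   feature (unequal variances; the replicate design is 2 vs 3, so assuming
   equal variances would be unfounded), keeping features with raw
   p < 0.05 and linear fold change strictly greater than 2 (on log2 data,
   |g| > 1 with g = mean(treatment) − mean(control)). A feature with zero
   variance in both groups gets p = 1 and is excluded with a log message.
   No multiple-testing correction is applied by default, matching the
   method's raw-p selection; a Benjamini–Hochberg switch exists (`fdr=True`).

Platform detection calls ("reliably detected" filters) are array-specific
and not reproducible from a bare matrix; a minimum-expression floor
(default log2 value 4.0, i.e. features whose maximum never reaches ~16
units are dropped) stands in for them. Probe→gene annotation collapsing is
out of scope: one feature is one gene here.

## 4. The subset-regression scorer

With A = C·D (genes × PWMs) and Z the DE-gene log-ratio vector, each
iteration samples n_t = 5 distinct PWM columns uniformly at random, solves
the least-squares problem min ‖Z − A_s x‖², and updates every sampled PWM:

    TFCV_i += 1 / max(Err, ε)²,   TFL_i += x_i,   Err = ‖Z − A_s x‖²

Design and numerical choices:

- **Increment convention.** Each of the n_t sampled PWMs receives the full
  1/Err² (no division by n_t). Any constant factor cancels in the ranking,
  which is the scientific output.
- **Rank deficiency.** Collinear or zero subset columns make the literal
  normal-equations inverse undefined; the minimum-norm least-squares
  solution (pseudoinverse semantics, relative singular-value cutoff 1e-10)
  is used instead. The residual — the only quantity entering TFCV — is
  identical for every least-squares solution.
- **ε clamp.** On noise-free synthetic data Err can reach exact 0; the
  default ε = 1e-12 bounds the weight and each clamp is logged.
- **Fast path.** `run_monte_carlo` precomputes AᵀA and AᵀZ once and solves
  the n_t × n_t normal equations with a batched pseudoinverse, evaluating
  residuals against the actual subset columns; `fit_subset` solves A_s
  directly via LAPACK least squares. Tests pin both to each other and to an
  independent pseudoinverse oracle (1e-8 relative).
- **Sampling and determinism.** Subsets are uniform without replacement
  (the n_t smallest of n i.i.d. uniform keys), independent across
  iterations; one seed drives the whole run and reruns are bitwise
  identical, independent of the internal chunk size.
- **Exhaustive mode.** `run_exhaustive` enumerates every subset once; the
  Monte-Carlo accumulator converges to n_iter/C(n, n_t) times it, and a
  test checks agreement within 3 exact standard errors (computed from the
  first two moments of the per-iteration increment by enumeration).

The default iteration count is 1e6 (a library parameter; the reference
setting of 1e8 is reachable by configuration — at roughly 40k iterations/s
on one core, plan hours accordingly). Rankings on the benchmark problems
stabilise well below 1e6. TFCV ties (improbable with continuous scores) are
broken lexicographically by PWM id, making reports deterministic.

`compare_thresholds` computes pairwise Pearson correlations of TFCV
profiles across runs (e.g. top-K variants); a constant profile has
undefined correlation and is reported as NaN off the diagonal.

## 5. Synthetic benchmark

`SyntheticSpec` defaults define the benchmark study:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 500 kb, uniform composition | smallest layout that keeps windows, DHS and intergenic space non-trivial |
| genes | 150, non-overlapping slots, random strand | same order as a focused DE gene set |
| DHS | 400 sites × 200 bp, non-overlapping; 40% placed inside regulatory windows (round-robin, so every gene gets one) | DHS length matches typical accessible-site width; the in-window fraction leaves a majority of distal/background sites |
| PWMs | 50, lengths 8–12; planted motifs 90% majority base per position, decoys Dirichlet(2)-flat | sharp planted motifs make embedded consensus sites near-maximal without making decoys trivial to reject |
| planted effects | (+0.12, +0.10, −0.10) on PWMs 1–3, 25 target genes each | yields per-gene signals of roughly ±1.5–3 log2 units through the affinity scale — strong but realistic DE |
| expression | 2 treatment + 3 control replicates, baseline N(8, 1), replicate SD 0.15 (mean-centred), noise SD = 25% of the signal SD | replicate structure mirrors the reference design; mean-centring makes the noise-free group difference exactly the model signal |
| top-K | 100 of 400 | desk-scale analogue of 5000 genome-wide |

The generator embeds each planted PWM's consensus verbatim into the
in-window DHS of its target genes (collision-checked), recomputes the true
thresholded affinities of the planted PWMs from the final sequences, and
wires the treatment−control difference through the linear model. The truth
tables list every planted (gene, PWM, DHS, position) and effect. All
randomness flows from one seed through named generator streams (genome,
layout, motifs, embedding, expression), so fixtures are byte-reproducible.

What the benchmark does **not** emulate: realistic chromatin-accessibility
landscapes, motif clustering and co-occurrence, probe-level array noise,
batch effects, or correlated PWM families (the real TRANSFAC library
contains many near-duplicate matrices whose TFCV scores will be strongly
coupled — as visible in the reference results, where one TF family
dominates the top ranks). Passing the recovery test therefore shows the
estimator works when the model assumptions hold at realistic noise, not
that every real-data confounder is handled.

## 6. Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 20 PWMs × 200 sequences for
scanning-oracle equivalence; 100 random 30 × 5 least-squares instances; 6
PWMs/15 subsets at 150k iterations for Monte-Carlo convergence; 20
independent datasets (150 genes, 400 DHS, 50 PWMs, 200k iterations) for
planted recovery; 50 datasets for null rank-uniformity; and 5 datasets plus
four top-K variants (25/50/75/100) in the acceptance script. These sizes
keep a full run in the minutes range on a single core while leaving each
statistical check adequately powered.

## 7. Known limitations

- The score of a retained affinity entry is stored as-is; a legitimately
  zero or negative top-K score is indistinguishable from "absent" in the
  sparse matrix. With informative motifs top-K scores are comfortably
  positive, but pathological flat PWMs could blur this boundary.
- TFCV has no significance calibration (no p-values); it is a ranking
  statistic only.
- The 197→181 probe-to-gene reduction of the reference analysis depends on
  unavailable annotation rules and is not reproduced; the detection floor
  and DE filters are the exposed equivalents.
- Quantile normalisation is exactly idempotent only on tie-free data (see
  §3).
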