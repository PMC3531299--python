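# Methods

This note records the statistical models behind `ecref`, the defaults
and why they hold, the design choices that were genuinely open, and what
the synthetic-data tests do and do not establish about real data.

## Data model and pre-processing

A measurement is a quantification cycle Cq for one well: one (sample,
card, assay, replicate well) combination. Expression is taken
proportional to 2^−Cq (unit amplification efficiency assumed; no
Pfaffl-style efficiency correction), so log2 relative expression is
y = −Cq and every log-scale computation is done directly on Cq
differences, avoiding exponentiation round trips. Cq values are assumed
already threshold/baseline-corrected upstream; no amplification-curve
processing is implemented.

**Ceiling imputation.** Cq values above the detection ceiling (default
32 cycles, the TLDA platform recommendation) are set to the ceiling.
Undetermined wells — no threshold crossing — are treated the same way:
a non-amplifying well means expression at or below the detection limit,
and imputing to the ceiling is the conservative reading consistent with
the ceiling rule for weak signals. Each imputed well is logged.

**Replicate collapse.** Technical replicates are collapsed per card by
the arithmetic mean of Cq, which is the geometric mean on the expression
scale — the standard qPCR convention. Genes assayed on both cards are
never merged across cards: the replicate ANOVA (below) shows card-level
offsets are real, so each card is analysed as an independent panel.

## Replicate QC

Intra-card spread is summarized per gene as the mean over samples of the
per-sample replicate SD and range. Inter-card variation is tested by
classical one-way fixed-effects ANOVA (pooled within-level variance, no
Welch correction). The default factor is the *replicate instance* — each
physical (card, well) position is one level whose observations are that
well's Cq across samples; `factor_mode="card"` pools wells within card,
and with two cards is algebraically a pooled two-sample t-test (F = t²).

Two caveats are deliberate properties of this design rather than bugs:

* Sample-to-sample biological variance enters the *within*-level
  variance of the one-way layout (samples are not modelled as blocks),
  so the test has power against card offsets only for genes whose
  biological noise is small relative to the offset. Mixed-effects or
  repeated-measures layouts are out of scope.
* For the same reason, when levels share sample effects the observations
  are positively correlated across levels and the test is conservative;
  the null p-value is uniform exactly when all wells are independent
  draws from one normal, which is how the null calibration simulations
  are constructed.

## Three-criterion candidate filter

On the collapsed per-card matrix, for each gene: mean/min/max Cq over
all samples, CV = sample SD / mean × 100 (computed on the Cq scale,
n−1 denominator), Welch unequal-variance two-sample t-test between the
case group and the pooled control group (each sorted population is one
observation), and a signed fold change FC from group-mean Cq values:
r = 2^(Cq̄_control − Cq̄_case), reported as r if r ≥ 1 else −1/r, so
|FC| ≥ 1 by construction.

Status assignment:

* **fail** if mean Cq > 25 (too weakly expressed), or if p < 0.05 *and*
  |FC| ≥ 1.5 (differentially expressed), or if CV ≥ 10.
* **warn** if all hard criteria pass but |FC| ≥ 1.5: a gene over- or
  under-expressed by 1.5-fold that misses significance (easily the case
  with a 4-sample control group) is kept for stability ranking but
  excluded from the final recommendation.
* **pass** otherwise.

Boundary semantics follow the printed thresholds: mean Cq exactly 25
passes (≤ 25), CV exactly 10 fails (< 10 required), |FC| exactly 1.5
counts as exceeding the threshold. Raw p-values are used — no
multiple-testing correction — because the filter is a per-gene screen
whose differential criterion is deliberately anti-conservative for the
screening purpose: a reference gene wrongly discarded costs little, one
wrongly kept costs a lot. Welch rather than pooled variance is the
default because the two groups differ in size and plausibly in variance;
a pooled option exists.

Candidates sharing any cytoband (multi-valued, slash-separated locations
are expanded) are flagged — not removed — because clustered miRNAs
transcribed as one polycistron are co-regulated and would reinforce each
other in both rankings. Exclusion is left to the user.

## geNorm

For genes j, k the pairwise variation V_jk is the SD (n−1) across
samples of the log2 expression ratio, equal to the SD of per-sample Cq
differences Cq_k − Cq_j. Stability M_j is the mean of V_jk over all
other candidates. Ranking proceeds by stepwise elimination of the gene
with the highest M, recomputing M each round, until two genes remain;
these cannot be separated (their two-gene M values are equal by
definition) and share rank 1. Ties in the maximal M are broken by input
order and logged. Both the full-set M and the M at the round of
elimination are reported, since published tables are ambiguous about
which variant they print; the stepwise ranking is the default. The
V_{n/n+1} optimal-number-of-genes analysis is not implemented.

All outputs are invariant to adding a constant to any single gene's Cq
(shifts cancel in the ratio SDs) — verified by property test.

## NormFinder-style model-based stability

Model: y_igj = α_ig + β_gj + ε_igj with Var(ε_igj) = σ²_ig, where β_gj
is a sample loading common to all genes (the quantity normalization
removes) and α_ig carries the gene's group-specific level. G ≥ 2 groups,
k ≥ 3 genes, n_g ≥ 2 samples per group.

1. **Residuals.** Within each group, double-centring over genes and
   samples: r_igj = y_igj − ȳ_ig· − ȳ_·gj + ȳ_··g. Gene effects and
   sample loadings are absorbed exactly (property-tested).
2. **Intra-group variance.** With u_ig = Σ_j r²_igj/(n_g−1), the
   additive model gives E[u_ig] = (1 − 2/k)σ²_ig + S_g/k² where
   S_g = Σ_i σ²_ig. Hence Ŝ_g = (k/(k−1)) Σ_i u_ig is unbiased for S_g
   and σ̂²_ig = (u_ig − Ŝ_g/k²)·k/(k−2), truncated at 0 (truncation is
   logged; it matters at n_g = 4). The correction constants are
   validated by simulation (mean estimate within [0.037, 0.043] at true
   0.04), not assumed.
3. **Group differences.** d_ig is the gene's group-mean deviation,
   centred over genes within group and over groups within gene with
   equal group weights (rows and columns of d sum to zero; for G = 2,
   d_i1 = −d_i2). The between-gene variance of true differences is
   estimated by the moment γ̂² = max(0, Σ d²_ig/((k−1)(G−1)) −
   mean(σ̂²_ig/n_g)), and each difference is shrunk,
   d̃_ig = d_ig · γ̂²/(γ̂² + σ̂²_ig/n_g) (0 when γ̂² = 0).
4. **Stability.** ρ_i = (1/G) Σ_g [ |d̃_ig| + √v_ig ] with
   v_ig = (σ̂²_ig/n_g)·γ̂²/(γ̂² + σ̂²_ig/n_g): the magnitude of the
   shrunken inter-group bias plus its standard error. Lower is more
   stable. A two-gene normalizer averages the pair's log2 expression, so
   its differences and variances average:
   pair stability = (1/G) Σ_g [ |(d̃_ig + d̃_i'g)/2| + √((v_ig+v_i'g)/4) ].
   The best pair is searched over the top-m ranked singles (default:
   all) and reported only when it is at least as stable as the best
   single gene — this inequality is not a theorem under the estimator,
   so it is enforced as a reporting rule rather than assumed.

Bit-compatibility with the original spreadsheet add-in is not claimed;
the contract is simulation-based recovery (unbiased σ̂², Spearman ≥ 0.8
between designed and estimated instability at study-sized groups) plus
the model's exact invariances (gene relabelling, within-group sample
permutation, sample-loading shifts change nothing).

**Degenerate regime.** When the surviving candidates are genuinely
uniform between groups, γ̂² truncates to zero with substantial
probability, all d̃ and v collapse, and every gene ties at ρ = 0. This
is the estimator's honest statement that no inter-group variation is
detectable; ranking then degenerates to input order and intra-group
variance no longer discriminates. The geNorm ranking, which has no such
degeneracy, is reported alongside for exactly this reason.

## Quantification and normalizer impact

ΔCq = Cq_target − Cq_EC per sample; relative expression 2^−ΔCq; log2
relative expression −ΔCq. Multi-gene normalizers are summarized by the
arithmetic mean of Cq (geometric mean of expression). Group-level log2
fold change is the case mean minus the control mean of log2 relative
expression; by default the control mean is taken per cell line first and
then across lines (`per_line_average`), so unequal per-line sample
counts do not tilt the pooled control value; `per_sample` is available
for sensitivity analysis.

For a single-gene normalizer the exact identity

log2FC_normalized(t) = log2FC_raw(t) − log2FC_raw(EC)

holds on the Cq scale (tested to 1e−12). This identity *is* the
sign-flip mechanism: any control over-expressed in the case group by
more than the target's own effect drives the normalized fold change
negative. The impact table computes one log2 FC per (target, normalizer
set) and flags targets whose direction differs across sets.

## Synthetic data generator

Per well: Cq = baseline + group_effect·[case] + card_offset +
N(0, gene_noise_sd) per sample + N(0, replicate_noise_sd) per well,
censored at the ceiling. Gaussian noise on the Cq (log-expression) scale
is the standard qPCR error model. A negative group effect means fewer
cycles — higher expression — in cases; the true log2 fold change is the
negated effect. The seed fully determines the output bytes.

The `paper-like` preset is a desk-scale stand-in (~60 genes; the
full-size study had 668 assays) for a two-card design with 9 tumour
samples and 4 control samples generated as 2 cell lines × 2 sorted
subtypes. Designed characters, with magnitudes taken from the kind of
values such studies report:

* uniform sn/snoRNA and miRNA controls (effects ~0, noise SD 0.8–1.45,
  i.e. CV ≈ 3–7% at their baselines), replicate-heavy where the real
  cards are;
* a weakly over-expressed control (−1.24 cycles ≈ 2.4-fold) that misses
  significance at n = 9 vs 4 — the `warn` archetype;
* a moderately inflated control (−1.87 cycles ≈ 3.7-fold, noisy enough
  to fail the CV criterion);
* a massively inflated control: −8.96 cycles = −log2(498), ≈ 500-fold
  up in cases, with within-group noise SD 1.2 (its CV is dominated by
  the group split itself);
* a card-offset gene (+0.5 cycles on card B, 4 wells per card,
  biological noise 0.1) that the replicate ANOVA must flag, and a
  zero-biological-noise companion that calibrates the false-flag rate
  (the one-way null holds exactly only when wells are independent);
* three strongly over-expressed targets (−4.0/−4.5/−5.0 cycles, 16–32
  fold, noise SD 0.9). These margins make the sign structure of the
  normalizer-impact comparison a deterministic consequence of the
  design: the worst-case separation is ≈ 4σ of the fold-change sampling
  noise, so positive fold changes under uniform normalizers and
  negative under the inflated control occur in every simulated study;
* null filler genes on a deterministic grid of baselines (17–28) and
  noise SDs (0.8–2.0), some of which legitimately fail the CV screen.

What the simulations do **not** model: amplification-curve chemistry,
Megaplex RT/pre-amplification efficiency differences (only their net
additive Cq offsets), probe-specific efficiencies, correlated biological
co-regulation between genes (each gene's noise is independent), and
missing-well mechanisms. Passing tests therefore establish the
statistical machinery — estimator correctness, calibration, invariances,
determinism — not biological validity of any particular ranking on real
tissue.

## Numerical and reporting conventions

* Welch t degenerate inputs: both groups constant and equal → p = 1;
  constant and unequal → p = 0 (logged).
* One-way ANOVA with all observations identical → F = 0, p = 1; distinct
  level means with zero within-level variance → F = ∞, p = 0.
* Negative variance moment estimates truncate at 0 (logged).
* geNorm ties break by input order (logged); NormFinder ranking uses a
  stable sort, so exact ties keep input order.
* All TSV output uses fixed `%.10g` float formatting; reruns with the
  same seed and config are byte-identical (tested).
* Problem sizes used by the test-suite simulations (e.g. 2000
  unbiasedness replicates, 200 rank-recovery studies, 100 preset seeds,
  1000/2000-gene null panels) were chosen to put Monte-Carlo error well
  inside the asserted bounds at desk-scale runtimes.

## Known limitations

* The recommendation rule (best NormFinder pair among pass-status genes,
  geNorm top pair reported alongside) is a convention; no formal
  combination of the two rankings is attempted.
* The replicate ANOVA's one-way layout is conservative for genes with
  appreciable biological variance (see above); a blocked design would
  have more power but a different null.
* CV is computed on the Cq scale, as is conventional for this screen;
  it is scale-dependent and not comparable across genes with very
  different baselines.
* With fewer than 3 surviving candidates on a card, stability ranking
  is skipped (the intra-group variance is not identifiable at k < 3).
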