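# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `codonstab`.

## Half-life model and fitting

During continuous metabolic labeling, the labeled abundance of a transcript
approaches its steady-state level as

  y(t) = y_eq · (1 − e^{k t}),   k ≤ 0 (1/h),   HL = ln 2 / |k|.

Inputs are CDS read counts at labeled time points (default grid 1, 2, 4, 8,
12, 24 h). Before fitting:

* **Spike normalization.** Each sample's counts are divided by the sum of
  its labeled fly (`spike_dmel|*`) spike-in rows, making time points
  comparable. The unlabeled yeast spike (`spike_scer|*`) is carried as rows
  but unused downstream (QC-only by design). A zero fly-spike total is an
  error naming the sample.
* **Expression filter** on raw counts: keep a transcript iff it has ≥1 read
  at every labeled time point and ≥5 reads at some time point. The filter
  runs on human-transcript rows only (spike rows excluded); together with
  the filter, normalized values are strictly positive, which the 1/y
  weights require. The fitter additionally rejects series containing
  non-positive values rather than imputing.

The weighted least-squares objective is Σ_t (y_t − y_eq(1 − e^{k t}))² / y_t,
minimized with scipy's trust-region reflective solver under box constraints
y_eq ∈ [0, ∞), k ∈ (−∞, 0], starting at y_eq = max(y), k = −0.5, with an
analytic Jacobian. Numerical choices: xtol = ftol = gtol = 1e-12 and at most
200 function evaluations. The tight tolerance is needed for the noise-free
recovery guarantee (relative half-life error ≤ 1e-6 across HL ∈ [0.25, 100]
h); at 1e-8 the solver stops near 5e-6. Solver identity is not part of the
contract — correctness is defined by a grid-search oracle test: on noisy
fixture series the returned optimum's weighted SSE never exceeds the minimum
over a dense 400×400 (y_eq, k) grid by more than 1e-6.

**Non-convergence** is solver failure or a fitted rate at the k = 0 bound
(k ≥ −1e-9); such fits report NA half-lives. k is recorded with the
non-positive sign convention and HL = ln 2/|k|. Half-lives are reported
uncapped; values above 100 h carry a long-lived flag. Replicate half-lives
are combined by the arithmetic mean of non-NA values.

Properties guaranteed by tests: scale equivariance (scaling y scales y_eq
and leaves k unchanged), monotonicity in |k| on noise-free data, and the
grid-oracle bound above.

### Precision limits under count noise

With a single replicate, six time points, and Poisson counting noise at
~200 expected steady-state counts per transcript, the Fisher information of
the bounded-growth model bounds the achievable precision: median relative
half-life error ≈ 8–9% at the best-conditioned half-lives (2–4 h), ~13% at
8 h, and 26–42% at 16–24 h, where even the last time point is only half
saturated. Integrated over half-lives log-uniform in [0.5, 24] h the floor
is ~11%, and the fitter achieves it to within a few percent (oracle-weighted
and unweighted fits do no better). Sub-10% median error at this depth
requires replicates, deeper counts, or later time points.

## Reporter classification

Steady-state libraries are normalized to library size by scaling each
sample by (mean library total / its total), keeping values on a read-count
scale so the absolute threshold stays meaningful. For a cell line, a
transcript is "orfeome" iff it is in the line's pool and its normalized
count strictly exceeds both 3× the paired line's value and 4 reads; pool
members failing either threshold are "excluded"; transcripts in neither
pool are "endogenous". Transcripts present only in the *paired* line's pool
are also "excluded" from the endogenous set (their reads may be
reporter-derived); this choice is recorded in the output. Both thresholds
are strict inequalities, with boundary cases (9 vs 3 at 3×; exactly 4
reads) covered by tests.

## Codon statistics

Codon frequencies are fractions of codons counted in the CDS; stop codons
are counted in the denominator but excluded from CSC output. Using
fractions rather than raw counts avoids confounding CSC with ORF length.
Frameshift controls remove, from a CDS of length n, 1-based positions
{1, n−2, n−1} (+1) or {1, 2, n−1} (+2) and re-chunk the remaining n−3
nucleotides into codons.

CSC(c) is the Spearman correlation (average ranks for ties; NA half-lives
dropped pairwise) between codon c's frequency and half-life across
transcripts, computed as a Pearson correlation of ranked columns and
cross-checked in tests against independent per-codon `scipy.stats.spearmanr`
calls. Codons with zero frequency variance yield NA with a warning.
AASC(aa) is the arithmetic mean of the member codons' CSCs (NA omitted) —
an identity tested exactly. Fisher's r-to-z comparison of two correlations
uses the standard independent-samples formula
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with a two-sided normal
p-value.

A permutation null band (`csc_null_band`) is provided for calibration:
half-lives are permuted across transcripts and per-codon CSC quantiles
recorded; under a zero-effect simulation ~5% of CSCs fall outside the
central 95% band (tested at ≤10%, the two-sigma binomial reading of ~5%
over 61 codons).

## Pause scores

Footprint reads are 28–30 nt, in CDS coordinates (0-based 5' offset; a
transcriptome SAM with RNAME=transcript converts as five_prime_pos=POS−1).
The A/P/E sites are read positions 17–19/14–16/11–13 (1-based), so the
three site codons of one read are consecutive CDS codons (i, i−1, i−2). A
read contributes to a site table iff that site starts at a multiple of 3
and lies fully inside the CDS; since the three offsets are congruent mod 3,
in-frame acceptance is site-independent, making the "evaluate in-frame at
the site under consideration" choice consequence-free (tested). Reads from
terminating ribosomes may overhang the CDS 3' end — the reader does not
reject 3' overhang, only the site placement is constrained — which is what
lets stop codons appear in the A site at all with 28–30 nt reads.

The null expected frequency of a codon is Σ_g w_g f_g(c), with f_g the
gene's CDS codon frequency (stop codons counted: they are part of f_g, and
the choice is covered by a test) and w_g the gene's share of in-frame
A-site-accepted reads; one consistent weighting serves all three site
tables. Pause score = observed/expected frequency; expected 0 yields NA;
amino-acid scores are arithmetic means of member codon scores. Tertile
grouping sorts codons by descending score (slow/neutral/fast) into
near-equal groups (61 → 21/20/20), ties and the all-equal case broken
lexicographically, so grouping is order-invariant and deterministic.

**Edge exclusion.** With fixed offsets, the first six codons of every ORF
(the 5' end would be negative) and, for fully-contained reads, the last few
codons can never host an A-site read, while they still count in f_g. This
start/stop deficit is a structural property of the method, most visible for
ATG in short ORFs. The uniform-dwell calibration therefore uses ORFs of
300–500 codons (typical human lengths), where the excluded positions are
<2% and observed/expected deviations reduce to multinomial sampling error
for all codons except ATG: every non-ATG codon sits at random positions, so
position exclusion thins it proportionally and cancels in the ratio, but
the initiator ATG counts in the null while never being sampleable, leaving
a residual deficit of roughly 1/(1 + L·u_ATG) that can exceed 10% when
ATG's elongation usage u_ATG is low. The same bias is expected in real
libraries analyzed with fixed offsets.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
all latent quantities emitted for recovery testing. Defaults are the
study's conditions; every stage draws from its own generator seeded by
(seed, stage), so identical seeds give identical outputs.

* **Sequences.** Per-transcript codon usage is a Dirichlet perturbation of
  a global usage (concentration κ = 40), giving codon-frequency variation
  across transcripts — the variation that makes stability coefficients
  estimable. CDSs are ATG + i.i.d. sense codons + one stop; lengths uniform
  in 100–300 codons (300–500 for the pause-score calibration, above).
* **Decay.** log k_i = α + β·Σ_c f_i(c) w_c + ε_i, with stability weights
  w_c ~ N(0,1), ε ~ N(0, 0.35), and α = log(ln2/8) (median half-life 8 h,
  endogenous-like). Positive w_c stabilizes, so β < 0; setting `codon_r2`
  calibrates |β| so the codon term explains that fraction of var(log k)
  (0.5 gives Spearman ≈ −0.7 between the codon score and log k). The
  linear-in-frequencies coupling is the minimal generative model that makes
  CSC recovery well-posed; no effect size is claimed for real human cells —
  β/`codon_r2` are simulation parameters.
* **Counts.** Expected labeled count is y_eq·(1 − e^{−kt}) with
  y_eq = depth × human share × abundance (abundance lognormal, sd 1,
  normalized). Fly and yeast spikes each take 10% of depth (the 10% w/w
  spike mass of the protocol), split over 8 constant-expectation rows.
  Noise is Poisson or off; the noise-free mode emits exact expected values
  (fractional) for recovery benchmarks, while on-disk count tables are
  integers.
* **Footprints.** The A-site codon is sampled ∝ abundance_g × dwell(codon),
  dwell multipliers log-uniform in [0.5, 2] via a Gaussian copula that can
  couple them to the stability weights (`dwell_stability_coupling`); read
  length uniform on {28, 29, 30}; the 5' end is 3i − 16. Reads stay inside
  the CDS by default; `allow_stop_site=True` permits 3' overhang so
  terminating ribosomes (optionally dwell-inflated via `stop_pause`) put
  stop codons in the A site.
* **Classification plant.** Two-line steady-state tables with pool members
  planted as pass / fold-fail / min-fail, plus three deterministic boundary
  transcripts exactly at the 3× and 4-read thresholds; library totals are
  equalized with a filler row so normalization is the identity and the
  planted arithmetic is exact.

What the generator does **not** emulate: UTR- or RBP-mediated regulation,
biotinylation/enrichment efficiency, positional (5'-ramp) ribosome-density
structure, multi-isoform genes, di-codon effects, alignment artifacts, or
overdispersed counts. Passing recovery tests therefore demonstrates
estimator correctness under the assumed model, not robustness to everything
real libraries contain.

## ORF features

Windowed structure uses 100-nt windows starting every 3 nt; the per-CDS
score is the minimum window energy. The default energy is a deterministic
surrogate: minus the maximum number of nested complementary base pairs
(Watson-Crick + G:U wobble, minimum hairpin loop 3 nt) from a
Nussinov-style dynamic program (numba-compiled). The energy function is an
injection point: `rnafold_energy` adapts ViennaRNA's RNAfold (thermodynamic
MFE) to the same contract, and tests target the windowing/min logic, not
folding thermodynamics. miRNA sites use the 7mer-m8 rule (exact reverse
complement of the seed, miRNA positions 2–8); the seed list is
configuration, not a built-in claim about which families matter. The ARE
rule defaults to ≥1 occurrence of the AUUUA pentamer and is configurable;
neither default is presented as the original study's (unstated) definition.

## Shared statistics

KS and rank tests wrap scipy with exact small-sample p-values where its
'auto' mode provides them (signed-rank: n ≤ 25 without ties/zeros;
Mann-Whitney: n ≤ 8 without ties; KS: n₁·n₂ ≤ 10⁴) and tie-corrected normal
approximations otherwise. Identical paired samples return statistic 0,
p = 1 rather than erroring. Variance comparisons use the ratio of variances
of median-centered log2 half-lives with a two-sided F-test p-value; the
method string records the choice (the comparison the original analysis used
is unnamed, and the log2 scale matches how stability densities are usually
displayed; median-centering removes location without touching spread).
Even-length medians follow the mean-of-middle-two convention. Type-I
calibration of all three tests is verified by simulation (5% ± 2% at
α = 0.05, 1000 replicates).

## Problem sizes

The test suite and the acceptance script run at the study's own scales:
200 noise-free and 2000 Poisson-noise transcripts for half-life recovery,
50 fixture series against a 400×400 grid oracle, 500 transcripts for CSC
recovery, 10⁵ footprint reads over 100 transcripts for pause-score
recovery, 400 transcripts and 400 permutations for null calibration, and
1000 replicates per test for type-I calibration. The full suite completes
in well under a minute on one CPU.
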