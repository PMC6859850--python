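# codonstab

Tools for isolating the effect of the coding region on mRNA stability in
human cells, built around a parallel-reporter (ORFeome-style) experimental
design: thousands of ORFs expressed from a common vector with invariant
UTRs, so that differences in transcript stability can only come from the
coding sequence itself.

The package implements the computational arm of that design:

* **Half-life estimation** from approach-to-equilibrium 4SU metabolic
  labeling. During continuous labeling the labeled abundance of a transcript
  follows bounded growth, *y*(*t*) = *y*<sub>eq</sub>·(1 − e^(*kt*)) with
  decay constant *k* ≤ 0, and the half-life is HL = ln 2 / |*k*|. Counts are
  normalized per sample to labeled *D. melanogaster* spike-in reads, filtered
  (≥1 read at every time point, ≥5 reads at some time point), and fit by
  weighted (1/*y*) nonlinear least squares with box constraints.
* **Reporter classification**: a transcript counts as reporter-derived
  ("orfeome") in a cell line only if it is in that line's infected pool and
  its library-size-normalized steady-state count is >3× the paired line's
  and >4 reads; otherwise it is "excluded", and transcripts in neither pool
  are "endogenous".
* **Codon stability coefficients (CSC)**: per codon, the Spearman
  correlation between the codon's frequency in each CDS and the transcript's
  half-life; amino-acid stabilization coefficients (AASC) are the mean CSC
  over synonymous codons; +1/+2 frameshift controls test that the signal is
  reading-frame dependent.
* **Ribosome dwell-time (pause) scores** from 28–30 nt footprint reads: the
  A/P/E sites occupy read positions 17–19, 14–16, 11–13, and a codon's pause
  score is its observed in-frame site frequency divided by its
  abundance-weighted expected frequency across the translated pool. High
  scores mark slowly decoded codons.
* **ORF covariates** (length, windowed secondary structure with a pluggable
  energy function, miRNA 7mer-m8 seed sites, AU-rich elements) and the
  shared statistics (KS, rank tests, Fisher r-to-z, variance ratios of
  median-centered log2 half-lives) used to compare them against stability.
* **A synthetic-data generator** that plants known codon→decay couplings and
  known codon dwell times, so every estimator above can be validated against
  ground truth.

## Worked example

Run the full synthetic study — simulate, fit, classify, score — with one
command:

```bash
codonstab all --outdir study --seed 3
```

which prints the recovery checks computed from the run's own ground truth:

```json
{
  "halflife_median_rel_err_lt_10pct": true,
  "classification_exact": true,
  "pause_recovery_ge_0.95": true,
  "csc_recovery_ge_0.8": true,
  "frameshift_gap_ge_0.3": true
}
```

and writes `study/report.json` with the underlying numbers. For this seed:
the median relative half-life error over 500 Poisson-noise transcripts is
4.6%; the estimated CSCs recover the planted codon weights at Spearman 0.82
while the +1/+2 frameshifted CSCs drop to −0.04/−0.11 (the signal is
frame-dependent, as it should be for a translation-driven effect); A-site
pause scores recover the planted dwell multipliers at Spearman 0.99 while
P-/E-site scores sit near 0.15/0.07 (the A site carries the dwell signal);
and the planted classification design is reproduced with zero label errors.

Individual stages are available as subcommands (`simulate`,
`fit-halflives`, `classify`, `csc`, `pausescore`, `features`, `compare`);
see `codonstab <cmd> --help`. All of it is also importable:

```python
from codonstab import fit_bounded_growth
fit = fit_bounded_growth([1, 2, 4, 8, 12, 24],
                         [17.3, 33.0, 58.8, 100.1, 129.3, 175.0])
print(round(fit.half_life, 2))   # 7.76 (hours)
```

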