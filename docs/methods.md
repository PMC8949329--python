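# Methods

## The measurement problem

Tumor mutational burden (TMB) is defined over the whole exome (~30 Mb), but
clinical assays count mutations on targeted panels of roughly 0.2–5 Mb and
divide by the panel footprint. The panel count is therefore a small random
sample of the exome-wide mutation process, and the reported TMB carries
sampling error that is large exactly where it matters clinically — near the
10 mut/Mb threshold used for checkpoint-inhibitor eligibility.

## Sampling model

Assume mutations are independent and identically distributed across
sequenced bases. For a panel of M megabases, the number of bases is
n = round(M × 10⁶) and the observed mutation count is

    k ~ Binomial(n, p),   p = t × 10⁻⁶,

where t is the true exome-wide TMB in mut/Mb. Given a user's target TMB we
first choose the integer count k that a real assay would have produced:
the k minimizing |k/M − t|, with an exact tie resolved toward the larger
count (the choice favourable to treatment eligibility; it must be fixed
somehow and is tested). The likelihood of each candidate t is the binomial
PMF of that k, evaluated on a uniform grid of true TMB values — by default
0–200 mut/Mb in steps of 0.1 (2001 points) — and normalized to sum to one.
Both grid bound and step are configurable; the bound must be at least ten
steps and a multiple of the step.

This i.i.d. assumption deliberately ignores mutational signatures, hotspot
enrichment of panel content, variant-allele-fraction cutoffs and
germline/somatic misclassification; the model isolates pure sampling error
and should be read as a lower bound on real assay uncertainty.

## Priors and the Bayes update

Histology matters: melanomas typically have high TMB, renal cell carcinomas
low. A histology-specific prior is estimated from a cohort table of
(histology, TMB) records by a Gaussian kernel density evaluated at the grid
points. The default bandwidth is the normal-reference rule
h = 1.06 · sd · n^(−1/5) (in mut/Mb) on that histology's values and can be
overridden; prior-sensitive outputs depend on this choice, and a
zero-variance cohort requires an explicit bandwidth. Kernel mass leaking
below 0 (or beyond the grid maximum) is simply discarded by renormalizing
on the grid — no boundary reflection; with bandwidths of a few mut/Mb this
slightly flattens the prior near 0 and is documented as a deliberate
simplification. Each grid mass is floored at 10⁻¹² before the final
renormalization so that the posterior never loses support where the
likelihood lives; the perturbation is far below reporting precision.
Histologies with fewer than 5 records fall back to a flat prior with a
warning. The posterior is the point-wise product of prior and likelihood,
renormalized; a flat prior reproduces the likelihood exactly.

## Summaries

All summaries are exact sums over the grid — no Monte Carlo — so results
are deterministic and reproducible:

- **Central interval** (default level 0.90): equal-tailed on the discrete
  grid; the bounds are the smallest grid values at which the cumulative
  mass first reaches (1−level)/2 and (1+level)/2. Discretization places
  each bound within one grid step of the continuous quantile.
- **Threshold probability** (default threshold 10 mut/Mb): the summed mass
  at grid points strictly greater than the threshold. A grid point
  numerically equal to the threshold (tolerance 10⁻⁹) counts as
  not-greater. Because the strict sum excludes the entire 0.1-wide cell
  centred at the threshold, its exact continuous counterpart is
  P(T > threshold + step/2); the gamma–Poisson closed form
  P(T > c) = P(Poisson(cM) ≤ k), valid under a flat prior, is used at that
  cell edge as the independent oracle in the tests (agreement within
  2 × 10⁻³ for k ≤ 50, panels 0.2–5 Mb). Comparing the strict sum against
  the closed form at the threshold itself instead would show the half-cell
  offset, up to ~0.014 when the posterior peaks exactly at the threshold.
- **Percentile range**: the interval bounds mapped through the histology's
  *empirical* cohort CDF (midpoint convention for ties), not through the
  smoothed KDE — the raw quantiles are what a decile table displays.
  Deciles are linear-interpolation (type-7) quantiles and need ≥ 10
  records.
- **Sampling mode**: seeded i.i.d. draws from the grid masses are provided
  for parity with Monte-Carlo implementations of these summaries; they add
  only binomial noise around the exact sums and are never the canonical
  path.

## Synthetic cohorts

Real pan-cancer immunotherapy cohorts are accession-gated, so tests and
examples use a deterministic generator: per histology, TMB values are drawn
log-normally (log-location, log-spread per histology), reproducing the
strictly positive support and heavy right tail of observed TMB data, capped
at the grid maximum and rounded to 4 decimals. Two presets fix the study
conditions: *melanoma-like* (log-location ln 15) and *rcc-like*
(log-location ln 2.5), both with log-spread 1.0 — a realistic ~1 log-unit
dispersion — and 2000 samples each. What the generator does **not** emulate:
multimodality (e.g. mismatch-repair-deficient subpopulations), zero
inflation from panels that detect no mutations, and inter-assay calibration
differences. Tests passing on these cohorts therefore demonstrate the
machinery (prior ordering, washout with panel size), not the exact
probabilities a specific clinical cohort would give; with synthetic presets
only orderings are asserted, never the cohort-specific percentages.

## Numerical choices and problem sizes

- Grid comparisons (threshold, bound checks) use a 10⁻⁹ absolute tolerance,
  far below any sensible grid step and far above float rounding.
- Distributions validate to ∑p = 1 within 10⁻¹²; construction from raw
  weights renormalizes twice to absorb division rounding.
- Degenerate inputs: target TMB 0 yields count 0 and a likelihood peaked at
  0; disjoint prior/likelihood support raises rather than returning an
  all-zero posterior; a reported TMB above the grid maximum raises with the
  bound named.
- The coverage check simulates 2000 one-megabase assays at true TMB 12 and
  verifies the 90% flat-prior interval covers the truth 88–94% of the time;
  2000 replicates keep the binomial standard error of the coverage estimate
  near 0.7 points while the whole check runs in well under a second thanks
  to caching per distinct count.

## Known limitations

Only sampling error is modelled; every other error source listed above is
out of scope. The KDE prior inherits the bandwidth sensitivity of any
kernel estimate, especially for small or highly skewed histologies. The
equal-tailed interval is not the highest-posterior-density interval and can
be conservative for strongly skewed posteriors at very small panels.
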