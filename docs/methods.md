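# Methods

## The model

For each COG functional category *c* (one-letter classes A–Z) and each
organism *i*, the category abundance is modelled as a power law of the
organism's total number of functional annotations:

    y_ic = k_c * x_i^beta_c,        x_i = sum over categories of y_ic

Taking base-10 logarithms makes this linear, so the scaling exponent
`beta_c` is the ordinary-least-squares slope of log10 y against log10 x and
the normalization constant is `10**intercept`. Exponents near 1 mean a
category grows proportionally with the annotation total (isometric
scaling); exponents below 1 mean progressive dilution, above 1 progressive
enrichment. Exponents are invariant to the logarithm base; intercepts are
reported in log10 units.

Counting semantics: a protein annotated with several categories at once
(for example "KT") is split and counted once in each category, and each
split letter contributes 1 to the organism's total. Duplicate letters in a
single record each count. By construction, the per-organism total is
exactly the row sum of the count matrix, and this invariant is enforced
whenever a matrix is built or read.

## Fitting

`ols_fit` uses `scipy.stats.linregress` on the log-transformed data. The
95% confidence intervals on slope and intercept are half-widths,
`t_{0.975, n-2}` times the standard error; both the half-width and the raw
standard error are emitted in every table. Organisms with a zero count in
the category being fitted are dropped by default (their logarithm is
undefined) and the number of dropped points is reported; a `pseudocount`
policy (log10(count+1)) is available as a sensitivity option. Cells with
fewer than 3 usable points are reported as NA with a reason rather than
fitted.

### Binning

OLS can be dominated by the best-sampled range of x. `bin_points` divides
the log10 x axis into equal-width bins (20 by default), replaces each
non-empty bin by (mean log10 x in bin, mean log10 y in bin), and refits.
Using the within-bin mean of x — rather than the bin midpoint — keeps
exactly collinear data collinear after binning, so a perfect line fits
identically with or without binning. On well-sampled single-law synthetic
data the binned and unbinned slopes agree to well within twice the
unbinned CI.

## Breakpoints

The segmented model is a continuous two-segment line in log-log space,

    y = b0 + b1*x + b2*max(x - psi, 0)

with slope `b1` below the breakpoint `psi` and `b1 + b2` above; the upper
intercept is derived from continuity, never free. `segmented_fit`
estimates `psi` by Muggeo's iterative linearization (the working covariate
`-1{x>psi}` yields a correction `gamma/b2` to the current breakpoint, with
step-halving when a step would increase the RSS), started from the best
basins of a coarse scan of the RSS profile at up to 120 quantiles of x.
Both segments must hold at least `min_segment` points (default
`max(10, 5% of n)`), which prevents degenerate end segments. If no start
converges, the best scanned position is returned with a logged warning.

`grid_oracle` is an exhaustive reference implementation used to validate
the iterative fit: for every gap between consecutive distinct x values it
evaluates the constrained fit at the gap midpoint and at the intersection
of the two sides' unconstrained regression lines when that intersection
falls inside the gap (for fixed segment membership the continuous model's
optimum is exactly that intersection). Ties are broken toward the
smallest breakpoint. On randomized instances the iterative fit matches
the oracle's RSS within 1%.

Model selection follows an RSS-reduction rule: the breakpoint model is
adopted when `rss_segmented / rss_single <= 0.95`, i.e. a 5% decrease in
the residual sum of squares. A numerically perfect single line (RSS at
float-rounding scale, below `1e-12 * n`) never selects a breakpoint. The
threshold is configurable; lowering it can only move selections from
single toward segmented.

Reported per-segment slopes and CIs come from independent per-side OLS
refits (the same procedure as the single-line fits); the joint continuous
model's slopes are emitted alongside. The breakpoint's own confidence
half-width derives from the linearization standard error
`se(gamma)/|b2|` and is flagged `muggeo_se` in outputs, as no standard
closed form exists. Breakpoint positions are reported both in log10 units
and as the percentile of organisms lying below the break. One breakpoint
is supported; multi-breakpoint and mixture structure (e.g. post-break
clusters) are out of scope.

## Z-statistics

To quantify how far a phylum's exponent deviates from its domain's, the
package computes

    z = (beta_phylum - beta_domain) / denominator

with two denominator conventions, emitted side by side:

* `as_printed` — `sqrt(err_p^2 - err_d^2)`: undefined (NA, with a reason)
  when the phylum error does not exceed the domain error;
* `sum_of_squares` — `sqrt(err_p^2 + err_d^2)`: always defined when either
  error is positive, and the form used for calibration checks.

"Error" is the slope's 95% CI half-width for both fits. `z` is exactly 0
when the slopes are equal. Categories in the z-table are ordered by the
spread (max − min) of their defined z values, so the most heterogeneous
categories come first. No formal test is attached to z; under phyla
subsampled from a single generating law, |z| ≤ 2 in ≥ 90% of cells under
the sum-of-squares convention.

## Shuffle null

The null permutes the multiset of all split category letters across the
data set and re-deals them to the same (organism, protein) slots with each
record's letter count preserved. Per-organism totals and global
per-category totals are conserved exactly — only the association between
categories and organisms is destroyed. Refitting shuffled data drives
every category's slope toward a common value near 1 (each organism's
expected shuffled count is its total times the category's global
frequency), so the across-category spread of null slopes collapses
relative to the observed spread. Unfittable permutations are recorded as
NA and disclosed, never dropped. A record-level shuffle (permuting whole
category strings) is available as an option.

## Phylogenetic distance

Phylum-level distances are mean patristic (branch-path) distances over all
tip pairs spanning two phyla, computed with dendropy. Exponent divergence
between phyla is `|beta_p - beta_q|` or the quotient `max/min` (NA for
opposite-signed slopes). The association between the distance and
divergence matrices is a plain Pearson or Spearman correlation over
upper-triangle pairs; because pairs share phyla they are not independent,
which is disclosed in the output rather than corrected. An optional
Mantel permutation test is provided, off by default.

## Synthetic data

The generator draws each organism's target total T log-uniformly over a
configured range, computes each category's mean log10 count from its law
(single or breakpoint, with optional per-phylum exponent offsets), adds
Gaussian noise on the log10 scale (log-normal scatter on counts), and
rounds to the nearest non-negative integer. Rounded-to-zero entries are
kept as zeros so downstream zero handling is exercised. The matrix total
is the realized row sum — exactly as for parsed data — while the drawn T
is returned in the truth record. Because fits regress categories against
the row-sum total, specs whose categories are minor components should name
a `filler_category` (conventionally "S", the poorly characterized
catch-all class) which receives `max(round(T) − other counts, 0)`, so the
realized total tracks T and each category's exponent is identifiable.
Breakpoint laws are continuous at the break, matching the fitted model.

`simulate_tree` builds a random coalescent-style ultrametric tree over
phyla. At coupling 1, exponent offsets are the first principal coordinate
(classical MDS) of the tree's patristic distance matrix, scaled to a
target standard deviation (0.2 by default — the size of exponent
heterogeneity the phylum analyses are meant to detect); at coupling 0,
offsets are independent normal draws; intermediate couplings mix the two.
An exact monotone map from a tree metric to scalar offsets does not exist
in general, so coupling 1 yields a strong but not perfect rank
correlation (≈0.9 at 20 phyla) between distance and |Δoffset|.

What the generator does not emulate: real annotation pipelines' variable
fraction of unannotated proteins, correlated noise between categories,
gene copy number, multi-letter annotation records (simulated records are
single letters), or phylogenetic autocorrelation of totals. Passing tests
demonstrate parameter recovery and calibration under the stated model,
not robustness to those real-data features.

## Problem sizes and numerical choices

Calibration-style checks use 100 replicates of n = 500 organisms (CI
coverage, false-breakpoint control), 50 replicates of n = 1000 (breakpoint
recovery), 20-phylum trees for the distance analyses, and a 160-organism
matrix for the shuffle null — sizes at which the sampling error of the
measured rates is small relative to the asserted margins. Seeds for every
stochastic stage derive deterministically from a master seed and the stage
name; reruns are byte-identical. Grid ties in the oracle prefer the
smallest breakpoint; degenerate designs (constant x) and under-sized cells
raise typed errors that surface as NA rows in tables.

## Known limitations

* One breakpoint per category; no mixture or per-phylum breakpoints.
* The breakpoint CI is a linearization approximation.
* The quotient divergence is undefined across sign changes and is reported
  NA there.
* The Z-score's printed-form denominator can be undefined; both
  conventions are reported and neither is asserted as canonical.
* Correlations over phylum pairs are pseudo-replicated; only the optional
  Mantel test accounts for it.
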