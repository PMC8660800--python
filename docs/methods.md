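# Methods

## First-order decay fits

All half-lives derive from one shared routine: ordinary least squares of
natural-log abundance on time (closed-form normal equations), with
`t1/2 = ln 2 / (−slope)` for negative slopes and `+inf` otherwise. Fitting
`y = a·e^(b·t)` on the log scale rather than by nonlinear least squares
weights relative (multiplicative) error equally across the chase, which
matches how counting and densitometry noise behave; a nonlinear option
exists in the targeted module (`fit_first_order(..., method="nls")`) but is
off by default. The transcriptome-wide and targeted modules call the same
code path, so their fits agree exactly on identical inputs.

Zero or negative observations have no logarithm. They are dropped (with a
per-gene tally) and at least three positive points at two or more distinct
times must survive, else the fit is marked failed; no pseudocount is added,
because a pseudocount biases the slope of exactly the fast-decaying genes
the chase is designed to measure, and the downstream reliability filter
already removes sparse genes.

R² is 1 − SS_res/SS_tot and is undefined (NaN) for a constant response;
such genes fail the reliability filter through their non-negative slope.

## Spike-in normalization

Each sample's counts are divided by that sample's summed spike-in counts.
Because the spike-in mass per sample is fixed while cellular mRNA decays,
this ratio tracks absolute per-cell abundance. The exported normalized
matrix is, by default, rescaled by the median spike-in sum across samples
purely for readability; the pipeline's internal fits use the raw ratio
(scale = 1). That choice makes every reported slope, R² and half-life
*bit-exactly* invariant to rescaling any sample's counts: integer counts
scaled by a constant change numerator and denominator by the same exact
factor, and IEEE correctly-rounded division then returns the identical
quotient — whereas a data-dependent global scale (the median spike sum)
would shift all log values by a non-representable constant and perturb
slopes in the last bits.

## Reliability filtering

A gene is retained iff, in **every** condition, its fit succeeded, the slope
is negative (finite positive half-life) and R² is **strictly** greater than
the threshold (default 0.5). Spike-in features are always excluded, and
genes with all-zero counts are reported as "not quantified", distinct from
"filtered". Replicates are pooled into a single regression per condition by
default (one R², more degrees of freedom); per-replicate fits with averaged
half-lives are available (`pooling="per_replicate"`).

Filtering on R² preferentially removes slow decayers (their signal over a
6 h chase is comparable to the noise), so the retained-set median half-life
sits a few percent below the population median. This is a property of the
method, not of the implementation, and affects any chase analysis with a
fit-quality filter.

## Chase simulation

`simulate_chase` draws per-gene true half-lives log-normal (default median
4.9 h, log-sd 0.5 — a realistic transcriptome-wide spread of roughly
2–12 h for the central 90%), time-zero abundances log-normal (log-sd 1),
and a constant spike-in pool scaled to a configurable fraction (default 5%)
of the time-zero library. Per condition, every gene's decay rate is
multiplied by a global factor (a globally destabilized line) and optionally
by gene-set-specific factors (e.g. an IEG-like labile subset); gene-set
membership is either a deterministic index range or an explicit index list
recorded in the truth table. At each timepoint the molar pool shrinks and
reads are allocated proportionally at fixed expected depth (default 5·10⁶),
so the spike-in *fraction* of the library grows during the chase exactly as
in the real assay.

Gene counts are negative-binomial with a shared size parameter (default
50, i.e. ~14% biological CV at high depth) — the standard bulk RNA-seq
noise model with one knob. Spike-in counts are Poisson around their
expectations: a pipetted spike-in mix has no biological replicate
variability, and giving spike-ins the gene-level overdispersion would
inject a sample-wide ~5% noise through the normalization denominator that
shifts entire conditions coherently — an artifact of the wrong noise
assignment, not a feature of the assay. Library depth is fixed (not
random) so the normalization-invariance property is exact in expectation.

The default timepoints are 0/2/4/6 h with two replicates (chase designs of
three points at 0/3/6 h are equally supported).

What the generator does **not** emulate: read-level artifacts (mapping,
positional/length bias), correlated gene–gene noise beyond the shared
library allocation, transcriptional leakage under actinomycin D, biphasic
or delayed decay. Recovery results on synthetic data therefore demonstrate
correctness of the estimator under first-order kinetics, not robustness to
those real-data violations.

## Paired decay statistics

Condition pairs are compared with the Wilcoxon signed-rank test on per-gene
half-life pairs, two-sided; zero differences are dropped before ranking
(Wilcoxon's original treatment). The null is exact for ≤25 usable pairs
(scipy's enumeration, validated in the tests against a full 2ⁿ
sign-assignment oracle) and a normal approximation with continuity
correction above. An unpaired Mann-Whitney option exists for sensitivity
analysis. Raw p values are reported; Benjamini-Hochberg adjustment across
bins or subgroups is available but off by default.

Binning uses half-open intervals (lo, hi] on the **reference** condition's
half-life with default edges 0/3/6/9/12/∞ h. Note a caveat the package
deliberately surfaces rather than hides: binning on a noisy estimate
induces regression-to-the-mean inside extreme bins (genes enter the top bin
partly because their reference estimate erred high), so within-bin ratios
of *any* alternative condition against the reference drift from 1 even
under no true effect. The bias is identical for all alternative conditions,
so effects confined to particular bins should be read as one alternative
condition relative to another (e.g. partial rescue vs full rescue), which
is how the acceptance suite asserts the rescue pattern.

## Deadenylation kinetics

Calibration interpolates tail length piecewise-linearly between marker
bands and never extrapolates (positions outside the marker range clamp to
the endpoints); denaturing-PAGE mobility is only locally linear in length,
so no global functional form is assumed even though the bundled simulator
happens to generate a linear ladder. Background is a rolling-minimum
baseline (window defaults to a fifth of the scan) subtracted and clamped at
zero — robust to lane-wide offsets with a single parameter. The most
abundant intermediate is the global background-subtracted argmax within the
calibrated region, with exact ties broken toward the longer tail (the
earlier intermediate): deterministic, and conservative in that it can only
underestimate the rate. Tail lengths are reported in adenosines by
subtracting the 7-nt body of the standard substrate.

The rate regression uses points up to and including the first lane at ≤1 A
remaining; later lanes sit on the plateau of a fully deadenylated substrate
and only flatten the slope. Fold-inhibition is the ratio of apparent rates
with a delta-method standard error; a test rate of zero is reported as a
lower bound (reference rate / SE of the test rate), never as infinity.

## AP-MS and SILAC

Missing LFQ intensities are treated as absent — no imputation — because the
exclusivity criterion is presence/absence logic and imputed control values
would fabricate exactly the evidence the criterion needs to be missing.
The presence filter counts bait replicates by default ("at least 3 of 4");
a scope option counts across all runs instead. The one-sample t test runs
on log2 ratios against 0 (the log-scale reading of "control set to 1",
appropriate for log-symmetric ratio noise) and reports the mean ratio back
on the linear scale. Zero-variance replicate ratios return a p floored at
the smallest positive float with a warning, rather than failing; a single
replicate yields a mean with undefined p.

## Problem sizes and tolerances

The test and acceptance suites run entirely on synthetic data at the scale
of the simulated designs above: 2000-gene chases (two- and four-condition),
four-lane gel assays, 200–300-protein AP-MS tables, and 10⁴-draw null
calibrations — sizes chosen so the full suite completes in well under a
minute while leaving the statistical assertions comfortable margins.
Recovery tolerances (median half-lives within 10%, deadenylation rates
within 5%, fold-inhibition within 10%) reflect the generators' default
noise levels; exactness claims (normalization invariance, half-life
arithmetic, exact-test agreement) are asserted to machine precision or bit
identity.

## Known limitations

- First-order kinetics only; no biphasic, delayed, or age-dependent decay.
- Isoform-level half-lives are out of scope (gene-level counts in).
- Gel profiles are consumed as 1-D line scans; lane segmentation from gel
  images, per-intermediate deconvolution and enzyme kinetics (K_m,
  processivity) are not modeled.
- The Wilcoxon test treats genes as independent; residual sample-level
  normalization noise correlates genes within a condition, so extremely
  small p values on transcriptome-wide comparisons overstate certainty —
  as they do in any gene-level paired analysis of this design.
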