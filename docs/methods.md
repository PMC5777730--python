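# Methods

## The assay and the analysis model

A peptide kinome array carries up to 1,024 substrate peptides, each spotted
in triplicate on a rectangular grid. One hybridization of one lysate to one
chip yields one per-spot density table; a two-condition experiment (e.g.
chemosensitive vs chemoresistant cells) compares one or more chips per
condition. The analysis treats the triplicate spots of a substrate on one
chip as technical replicates of one phosphorylation reaction.

### Spot quantification

Quantification is fixed-grid: the caller supplies the grid geometry
(origin, pitch, spot radius, all in pixels, 0-based (row, col) order).
Per spot,

    intensity = sum(pixels in disc) − median(annulus) × disc_area,

clipped at 0. Disc membership is pixel center within Euclidean distance
≤ radius of the spot center; the background annulus spans radius + 2 px to
radius + 6 px. The median background resists bleed-over from neighboring
spots. There is no automatic grid registration, flat-field correction or
saturation model — the quantification stage exists to make the pipeline
runnable from images, not to reproduce any particular array software's
segmentation.

### Reliability filter

Two indexes per substrate per chip:

* SD/A = sample standard deviation (n − 1 denominator) / arithmetic mean —
  the replicate coefficient of variation;
* A/M = arithmetic mean / median — sensitive to a single outlier replicate
  dragging the mean away from the (robust) median.

Defaults: a substrate passes a chip iff SD/A < 0.20 **and**
0.80 < A/M < 1.20, with strict inequalities at every boundary (so the
worked boundary case SD/A = 0.20 exactly fails); a substrate that fails on
any chip of the experiment is rejected outright. Both the thresholds and
the strictness are configurable because the inclusive/exclusive status of
the published cut-offs is a convention choice; strict is the default
reading of "< 20%" and "80% < A/M < 120%". The n − 1 standard deviation is
the conventional estimator for triplicates; the cut-off is a selected
operating point, not a distributional quantile, so the estimator choice
only shifts the effective stringency slightly.

Degenerate inputs (mean ≤ 0 or median = 0, non-finite values, fewer than
two replicates) make the indexes undefined; such substrates are
auto-rejected with reason `degenerate`. Rejection reasons (`sd_fail`,
`am_low`, `am_high`, `degenerate`) are recorded per chip for audit.

### Differential calling

For each QC-passing substrate, FC = median(experimental replicates) /
median(control replicates). Medians match the median-intensity fold-change
convention of array scatter plots; the significance test runs on the raw
replicate values, since with a single chip per condition the triplicates
are the only replication available to a t-test. The test is Welch's
two-sample t (unequal variances) with Welch–Satterthwaite degrees of
freedom, two-tailed. Classes with defaults alpha = 0.05, fc_up = 1.5,
fc_down = 0.75:

* `up`: FC > fc_up and p < alpha
* `down`: FC < fc_down and p < alpha
* `unchanged`: p < alpha but FC within [fc_down, fc_up]
* `not_significant`: p ≥ alpha

Zero-variance conventions: if both groups have zero variance, p = 1 when
the means are equal and p = 0 otherwise (t = ±inf, df undefined). A zero
control median leaves FC undefined; the substrate is excluded and reported
with reason `zero_median`.

The test runs on linear intensities by default; a `log_transform` flag
tests log-intensities instead for users who prefer variance stabilization.
No multiple-testing correction is applied by default (the calling
convention is raw p < 0.05); Benjamini–Hochberg q-values can be added as an
extra, clearly optional column (`bh_qvalues`). The volcano export carries
log2 FC, −log10 p, the class, the kinase annotation, and reference lines at
FC ∈ {0.5, 1, 2}.

### Network export

Substrates called up/down are mapped to the kinase putatively responsible
via the annotation column of the layout file — a local table, never a live
database query, so results are reproducible without pinned database
versions. One deduplicated directed edge per (kinase, substrate) pair,
typed by the substrate's class and weighted by |log2 FC| (weights support
downstream filtering; classical kinome-network figures are unweighted).
Selected substrates without annotation are reported as orphans. The
per-kinase summary counts up/down targets and mean |log2 FC|, sorted by
total targets descending with alphabetical tie-break.

### Pharmacology

**IC50.** "Logarithmic trend line" estimation: ordinary least squares of
mean viability (% of drug-free control) on log10(concentration), then
IC50 = 10^((50 − a)/b). This is the spreadsheet log-trendline estimator; a
four-parameter logistic fit is available as an alternative and recovers a
logistic midpoint essentially exactly, whereas the trend line approximates
it (within ~5% for a symmetric 2-decade design). A flat or rising trend
(b ≥ 0) raises an undefined-IC50 error; a solution outside the tested
concentration range is flagged `extrapolated` (or raises, per config).
Viability normalization is the caller's responsibility.

**Sensitization.** Welch t-test (two-tailed) between viability replicates
of drug-alone and inhibitor-pretreatment arms; `sensitized` requires both a
lower pretreatment mean and p < alpha (default 0.05).

**Apoptosis quadrants.** Events are classified against user-supplied
(annexin-V, 7-AAD) gates with strict positivity (signal > gate): live =
double negative, early apoptosis = annexin+/7-AAD−, late apoptosis = double
positive, non-apoptotic death = annexin−/7-AAD+. Counts always partition
the events; percentages are undefined for an empty table.

## Synthetic data: what it emulates and what it does not

The generator's defaults define the standard study conditions used by the
tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_substrates | 1024 | substrates per chip |
| n_replicates | 3 | spots per substrate |
| n_chips_per_condition | 1 | triplicates within chip are the replication |
| baseline | 1000 (a.u.) | control spot density |
| noise_cv | 0.10 | CV of multiplicative log-normal spot noise |
| planted effects | 50 up at FC 3.0, 50 down at FC 1/3 | true differential substrates |
| n_unreliable | 10 | substrates planted to fail QC |

Spot noise is multiplicative log-normal with mean exactly 1 (sigma² =
ln(1 + CV²), mu = −sigma²/2): phospho-imager densities are positive and
right-skewed, and a 10% CV is a realistic technical-replicate spread for a
well-behaved spotted array. Unreliable substrates are planted by replacing
one replicate with a 5× outlier, which deterministically gives SD/A ≈ 0.99
and A/M ≈ 2.33 — both hard failures. Flow clusters sit at fixed offsets
from the gates (negative 0.7 below, positive 2.0 above, sd 0.1), so
classification is unambiguous by construction. Dose–response curves follow
a logistic in log-concentration with midpoint IC50 and additive truncated
Gaussian replicate noise.

Real arrays additionally show spatial gradients, saturated and merged
spots, chip-to-chip intensity scale differences, and correlated noise
between neighboring spots; none of these are modelled, and the pipeline
applies no inter-chip normalization. Passing the synthetic recovery tests
therefore demonstrates the correctness of the statistics and plumbing, not
robustness to those artifacts.

With the standard conditions, the recovery run typically rejects ~3–4% of
null substrates at QC (triplicate CV occasionally exceeds 0.2 by chance),
recovers 96–98% of planted effects in the correct direction, colors ~0% of
nulls, and rejects 100% of planted-unreliable substrates. Under a global
null the Welch test on log-normal triplicates flags ~3–4% of substrates at
alpha = 0.05 — slightly conservative, as expected for t-tests on skewed
data at n = 3.

## Numerical and design choices

* Fold changes and classes change discontinuously at the thresholds; all
  comparisons are strict by default and configurable.
* Median of an even replicate count is the mean of the two central values.
* Rendering distributes a spot's intensity uniformly over its disc so the
  integrated excess equals the intensity exactly; the TIFF writer scales to
  16-bit (peak at 60,000 counts by default), introducing ≤ ~0.1%
  quantization error in recovered ratios.
* Determinism: every generator takes an explicit seed (numpy
  `default_rng`); a fixed seed gives bit-identical outputs, and the
  pipeline manifest records config + seed so runs are regenerable.
* Problem sizes in the test suite and acceptance script (1,024-substrate
  recovery, 10,000-substrate null calibration, 16-substrate image round
  trip, 25 noisy dose–response curves, 10,000 flow events) were chosen to
  give stable statistics while keeping a full run to a few seconds.

## Known limitations

* No automatic grid detection; mis-specified geometry is an error, not a
  recovery problem.
* No inter-chip normalization or batch correction; multi-chip designs
  assume comparable intensity scales.
* The log-trendline IC50 is a biased estimator of a logistic midpoint when
  the tested range is asymmetric around it; prefer the 4PL alternative for
  accurate midpoints.
* Kinase annotations are taken at face value from the layout file; the
  package asserts nothing about their biological correctness.
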