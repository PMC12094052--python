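# Methods

## Problem and pipeline

Dairy cows differ consistently in how they allocate time to eating and
ruminating across the day; these circadian behaviour patterns are stable
individual traits. `rumiclust` classifies cows into a low-rumination (LR)
and a high-rumination (HR) cluster from hourly collar records of rumination
time (RT, s/h) and eating time (ET, s/h), and then compares enteric-gas,
intake, milk and efficiency phenotypes between the clusters. The pipeline
is: DIM filter → series preprocessing → pairwise multivariate DTW →
agglomerative clustering → principal-coordinates ordination → blocked
extreme-cow selection → daily phenotype derivation → mixed models, an
additive circadian model, and binned correlations.

## DTW distance

The distance between two cows is *dependent* multivariate DTW: a single
warping path is shared by the RT and ET dimensions, the local cost of
aligning hour *i* of cow A with hour *j* of cow B is the squared Euclidean
distance between the (RT, ET) 2-vectors, the accumulated cost obeys
`D[i,j] = c(i,j) + min(D[i-1,j], D[i,j-1], D[i-1,j-1])` with boundary at
(1,1), and the reported distance is the square root of the terminal cell.
Choices and rationale:

* **No normalisation by default.** RT and ET share units (s/h) and scale;
  level differences between cows are part of the signal. A `normalize`
  flag (per-cow, per-dimension z-scoring) is provided for users who want
  shape-only comparison.
* **Unbounded window by default**; a Sakoe–Chiba radius (in hours) is
  available for speed. The radius must cover the length difference of the
  two series or a configuration error is raised. Shrinking the radius can
  only increase the distance (tested).
* **One concatenated multi-day series per cow**, not per-day averages: the
  alignment is over the whole monitored span, so day-to-day drift is part
  of the comparison.
* **Gap policy.** Within a cow's record, runs of at most `max_gap_hours`
  (default 3) missing hours are filled by linear interpolation per
  dimension; any day touched by a longer run is dropped whole. A cow left
  with fewer than 2 usable hours raises an error naming the cow.

The dynamic programme is a numba-compiled kernel (pure-Python fallback if
numba is unavailable). Tests pin the implementation to an exhaustive
enumeration of all monotone warping paths for short series, and to hand-
computed DP tables.

## Clustering, ordination, selection

* **Agglomerative clustering** uses scipy's linkage on the condensed DTW
  matrix. Average linkage is the default (the agnes default); complete and
  single are options. The flat cut removes the k−1 highest merges; cluster
  labels 1..k are assigned by decreasing size, ties by smallest member
  index, so output is deterministic.
* **Agglomerative coefficient**: mean over leaves of `1 − m(i)/h_max`,
  where `m(i)` is the height of the leaf's first merge and `h_max` the
  final merge height; 0 for structureless (all-equal) matrices.
* **Ordination.** The upstream object is a distance matrix, not a feature
  table, so the "PCA plot" is realised as principal coordinates analysis
  (classical MDS): eigendecomposition of the double-centred −D²/2, top two
  axes scaled by the square roots of their eigenvalues. Negative
  eigenvalues (DTW distances are not exactly Euclidean) are reported but
  their axes excluded; variance fractions are taken over the positive
  spectrum. Cross-checked against scikit-bio's implementation in tests.
* **Selection.** The by-eye cohort pick is replaced by a reproducible rule:
  within each cluster rank cows by |axis-1 coordinate| (most extreme
  first); walk down cluster 1 and greedily match each cow to an unused
  cluster-2 cow, requiring equal parity when any is available, then
  minimising |ΔDIM|/sd(DIM) + |ΔMY|/sd(MY); ties resolve to the more
  extreme cow, then the smaller id. A cluster smaller than the requested
  size raises a shortfall error naming the cluster (or flags it with
  `strict=False`). Reproducibility was deliberately preferred over
  fidelity to a manual step.
* **LR/HR naming.** Numeric cluster labels are mapped to LR/HR by mean
  hourly RT (lower → LR), rather than by cluster index.

## Phenotype statistics

**Daily table.** `rt_min`/`et_min` are the day's summed sensor seconds/60;
the daily gas rate is the mean of that cow-day's hourly records; DMI,
refusal DM and MY come from the production table. CH4/DMI, CH4/MY and feed
efficiency MY/DMI are computed per cow-day and then modelled — the LS mean
of a ratio is *not* the ratio of LS means, and the suite asserts the
difference on skewed data. Feed efficiency is isolated in one place so it
can be redefined. Rows missing a denominator keep their other responses.

**Mixed models.** Each response is fit with statsmodels' MixedLM: cluster
fixed effect, cow random intercept, REML. LS means are the fitted cluster
means; the cluster p-value uses a t statistic with between-within
denominator df (n_cows − 2), mirroring the default of the mixed-model
software family commonly used for such designs. If the REML fit
degenerates (e.g. zero residual variance in noiseless worked examples) the
result is recomputed by the exact balanced-case estimator — OLS on cow
means with the same df — and flagged `singular=True` with cow variance 0.

**Additive circadian model.** Behaviour is modelled as
cluster + f(hour) + g(date) + cow intercept, where f is built on a Fourier
basis (4 harmonics, period 24) so the fitted curve is *exactly* periodic
(hour 0 = hour 24), g is a cubic P-spline (≤6 basis functions,
second-difference penalty), and cow intercepts are ridge-penalized — the
penalized-least-squares analogue of a random intercept. The three
smoothing parameters are chosen jointly by GCV on a log grid; grids run
from smoothest to wiggliest so exact GCV ties (e.g. a constant response)
resolve to the smoothest fit. Reported smooth edf is 1 + tr(hat block),
counting the absorbed constant level, so a penalized-away smooth reports
edf → 1. This hand-rolled model is used because no installed GAM
implementation combines a period-24 cyclic constraint with a grouped
random intercept. Harmonic k carries penalty weight k²; the Wald p-value
for the cluster effect uses a sandwich covariance and n_cows − 2 df.

**Binned correlations.** Hours are grouped into twelve 2-h bins anchored
at 00:00. Within each bin, behaviour and gas rate are averaged per cow
(default; per cow-day available, since the proper unit is not obvious a
priori), and Pearson r with its two-sided t-based p is computed across
cows, collectively and separately for LR and HR. Bins with (numerically)
zero variance report a missing r. No multiplicity correction is applied;
all 12 bins are reported with n.

## Synthetic herd generator

The generator states a world resembling a free-stall research herd: TMR
delivered once daily at 10:00, milkings at 04:00 and 15:00, a ~10% refusal
target on offered feed, a GreenFeed-style gas record and a collar-style
hourly behaviour record.

* **Circadian profiles.** Expected behaviour in hour h is
  `daily_mean · 24 · w[h] / Σw` for 24 nonnegative weights. Default ET
  weights peak in hours 10–12 (post-feeding) and 16–18 (post-milking);
  default RT weights are elevated 20:00–05:00 and dip while cows are at
  the bunk — the inverse RT/ET pattern. The weights are the package's own
  choice; only the qualitative shape is constrained by observation.
* **Cows.** Each cow gets a stable offset ("fingerprint") per trait, drawn
  from N(0, cow_sd); hourly values add truncated Gaussian noise
  (`hour_noise_sd`, default 150 s) and are clipped to [0, 3600] and to the
  joint 3600 s/h budget, removing any excess from the smaller component
  first. Parity is uniform on {1,2,3}; DIM uniform on 1–150.
* **Two groups.** Defaults: LR ruminates 1,099 and eats 718 s/h, 430 g/d
  CH4, 20.9 kg/d DMI, 35.1 kg/d MY (CO2 14,252, H2 3.84 g/d); HR 1,296 and
  852 s/h, 404 g/d CH4, 24.6 kg/d DMI, 40.6 kg/d MY (CO2 15,498, H2
  3.54 g/d); 50/50 split, rounding remainder to the largest (first-listed
  on ties) group. Between-cow SDs for emissions/production derive from the
  reported per-cluster SEMs scaled by √10 cows (CH4 19 g/d, CO2 600 g/d,
  H2 0.4 g/d, DMI 0.9 kg/d, MY 1.5 kg/d); behaviour fingerprint SDs
  (RT 60, ET 45 s/h) are set small relative to the group gaps because the
  design assumes distinct, repeatable clusters. A second preset
  (`experimental_period_groups`) restates behaviour and milk on the
  daily scale of the 3-week measurement period (RT 400 vs 494 min/d,
  ET 175 vs 261 min/d, MY 35.1 vs 40.6 kg/d) for worked examples of the
  daily-scale gaps.
* **Emissions.** Daily CH4 = group mean + cow offset +
  `dmi_ch4_slope` (default 15 g CH4 per kg DMI deviation) × that day's DMI
  deviation + day noise (default 40 g/d), distributed over 24 hourly
  records by a diurnal weight rising after feeding and after the afternoon
  milking (`diurnal_ch4_amplitude`, default 0.2), so the mean of the
  hourly rates equals the daily value exactly. CO2 and H2 have group mean
  + cow offset + day noise. n_days defaults to 21 (a 3-week measurement
  campaign).

**What the generator does not emulate:** visit-level spot-sampling
sparsity and airflow of a real GreenFeed (gas records are complete and
hourly), diet/weather/health perturbations, estrus, lactation-stage trends
within the window, or sensor misclassification between eating and
rumination. A green recovery test therefore establishes that the pipeline
recovers the structure *this* world encodes, not field performance on a
commercial herd.

## Determinism and numerics

Everything downstream of the RNG seed is deterministic: a rerun with the
same config is byte-identical for all artifacts, tie-breaks are by
smallest label/index everywhere, and the distance matrix CSV round-trips
at 12 significant digits. Degenerate inputs have defined behaviour:
all-equal distance matrices give agglomerative coefficient 0; constant
responses give flat smooths with edf → 1 and a two-sided p of 1; noiseless
mixed-model designs fall back to the exact balanced estimator.

## Known limitations

* The additive circadian model's GCV grid is coarse (6×6×4 points); it
  selects smoothness robustly but not finely, and its cluster-effect
  inference is Wald-type rather than exact REML.
* The between-within df approximation is anti-conservative when clusters
  are very unbalanced; a Satterthwaite option is not implemented.
* Extreme-cow selection assumes k = 2.
* PCoA axes beyond the first two are discarded; with strongly
  non-Euclidean DTW matrices the 2-D embedding can understate distances.
* At the generator's *full* default fingerprint SDs the two groups' offset
  distributions overlap slightly (~2% of cows ambiguous), so perfect
  cluster recovery at every seed is only guaranteed in worlds with
  distinct groups (e.g. halved fingerprint SDs, as used in the recovery
  acceptance test).
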