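# Methods

This note documents the models, algorithms and numerical choices behind
`maldikd`, in the order the pipeline runs them.

## Data model

A **spectrum** is one replicate acquisition: paired arrays of m/z
(Daltons, strictly increasing) and intensity.  A **dataset** groups
replicates into samples and samples into labelled conditions.  Matching
reduces spectra to peak lists, samples to consensus spectra, and the
dataset to a samples × m/z **peak matrix** — the single container all
downstream analyses consume, in binary (presence/absence) or intensity
mode.

Unsorted input m/z values are sorted (with a warning) rather than
rejected; exact duplicate m/z values are merged by summing intensities.
Only MS1 scans of mzML/mzXML files are considered; the profile/centroid
flag is recorded as metadata but not enforced.

## Preprocessing

**Smoothing.**  Moving average (unweighted mean over a
2·*h*+1 window, shrunk at the edges) or Savitzky-Golay (local
least-squares polynomial of order *k* over the same window).  Defaults:
Savitzky-Golay, half-window 5, order 3.  The window is deliberately
narrow: on 1 Da grids MALDI peaks are only a few grid steps wide
(σ ≈ 3 Da), and a wide polynomial window rings around sharp peaks.
That ringing is not cosmetic — the negative undershoot propagates
through the morphological baseline's erosion step and produces a
systematically low baseline (hence spurious residual "peaks") for over
a hundred Daltons around every tall peak.

**Baseline.**  Four estimators of the chemical-noise offset (largest at
low m/z, decaying roughly exponentially with mass):

* *top-hat* (default): morphological opening (erosion then dilation)
  with a flat structuring element of 2·75+1 grid points;
* *SNIP*: iterative clipping y ← min(y, (y₍ᵢ₋w₎+y₍ᵢ₊w₎)/2) for
  w = 1..100 on the log-log-sqrt (LLS) compressed signal, inverted
  afterwards;
* *convex hull*: the lower convex hull of the point set, linearly
  interpolated;
* *median*: a moving median with the same half-window as top-hat.

Corrected intensity is max(0, y − baseline).  Clipping at zero is a
deliberate choice: negative intensities would break TIC/median
normalization downstream.  The opening cannot follow the steepest part
of the exponential decay within the first structuring-element width of
the spectrum edge, so a residual of a few intensity units survives
there; consequences for detection are bounded by the noise floor below.

**Normalization.**  TIC (divide by the intensity sum; sum becomes 1),
median (divide by the median intensity), or PQN (TIC-normalize, build
the point-wise median reference over the batch, divide each spectrum by
the median of its point-wise quotients against the reference).  PQN is
defined only for batches sharing one m/z grid; resampling onto a common
grid is out of scope, and unequal grids raise a parameter error.

**Peak detection.**

* *SNR detector* (default): a point is a peak if (a) it is the maximum
  of the sliding window of 2·10+1 points around it and a strict local
  maximum, and (b) its intensity is at least 8× the local noise.  Noise
  is 1.4826 × the median absolute deviation in a 2·100+1-point window,
  floored at half the spectrum-wide MAD — without the floor, stretches
  zeroed by baseline clipping have local MAD 0 and infinite SNR.  The
  window-maximum criterion (rather than a bare 3-point local maximum)
  is what keeps flank wiggles of broad peaks from being reported as
  separate peaks.  The threshold of 8 sits well below the SNR of any
  plausible analyte peak (planted peaks in the generator have SNR ≳ 40
  after smoothing) and well above the maxima of smoothed, correlated
  noise (≈ 3–4× MAD); with correlated noise a threshold of 2–3 admits
  hundreds of noise maxima per spectrum, which measurably degrades
  detector precision even though POP filtering would remove most of
  them later.
* *CWT detector*: Mexican-hat continuous wavelet transform over scales
  1..64 with ridge-line linking (scipy's `find_peaks_cwt`; minimum
  ridge length 10, ridge SNR ≥ 3).  It runs on raw spectra without
  explicit smoothing or baseline correction.

Both detectors, at these defaults, recover planted peaks on the
generator's default spectra with mean recall and precision ≥ 0.95 at a
±2-grid-step match tolerance (the per-seed floor is ≈ 0.91, set by the
0–2 unavoidable low-m/z edge artifacts described above).

**Intensity scaling.**  Optional per-spectrum min-max scaling of peak
intensities to [0, 1] (required for the red/green heat-map convention).
A zero-range peak list (single peak, or all equal) maps to all ones:
downstream use is presence-oriented, and "present at the only observed
level" is best encoded as fully present.

## Peak matching and consensus

**Forward matcher.**  All peaks are pooled and visited from minimum to
maximum m/z.  A peak joins the *last-created* cluster iff its m/z is
within tolerance of that cluster's mean m/z (the mean is recomputed
after every insertion); otherwise it starts a new cluster.  No cluster
may hold two peaks of one spectrum: on a conflict the member whose
retention minimizes the cluster's mean absolute deviation from its
center is kept and the displaced peak seeds a new cluster, which
becomes the active one.  (A literal "minimize the resulting mean m/z"
rule is available as `conflict="min_center"`.)  Tolerance may be
absolute (Da) or relative (ppm); defaults 0.3 Da intra-sample, 500 ppm
inter-sample.

**Binning matcher.**  Pooled, sorted peaks are recursively split at the
largest relative gap until every bin lies within (relative) tolerance of
its mean and holds at most one peak per spectrum.  If all internal gaps
are zero but a spectrum is duplicated, the bin is halved — a guard that
guarantees termination on pathological all-identical inputs.

**Consensus spectra.**  Intra-sample matching across a sample's
replicates yields one entry per cluster: the cluster-center m/z, the
mean member intensity (the mean is symmetric in the replicates and
stable), and POP = 100 · members / replicates.  Entries with POP below
the threshold (default 50%, comparison `>=`) are dropped.  A
single-replicate sample passes through with POP 100.

**Peak matrix.**  Inter-sample matching across consensus spectra
defines the m/z axis (cluster centers); a sample's cell is 1 (binary)
or its contributed intensity (intensity mode) iff it has a member in
the column's cluster.

## Quality control

Replicate-level QC tabulates peak count, m/z range and intensity
range/mean per spectrum.  Sample-level QC tabulates, per sample, the
number of aligned masses, the count of entries at each attainable POP
level, and the count/percentage of entries at POP ≥ t for
t ∈ {20, 40, 60, 80, 100}.  Outliers are flagged by Tukey fences:
beyond Q1 − 1.5·IQR / Q3 + 1.5·IQR ("outlier") or beyond 3·IQR
("extreme"), with quartiles by linear interpolation (numpy default).
Sample-level fences are computed per count category, globally and
within each condition (conditions with fewer than 4 samples are
skipped).  Fewer than 4 units yields tables only — fences on 3 points
are noise.  Flagging is advisory; nothing is excluded automatically.

## Biomarker discovery

Test selection follows the design-size rule (inclusive boundary):
≤ 1000 samples → Fisher's exact (2 conditions) or randomization (> 2);
> 1000 → Yates' chi-square (2) or chi-square (> 2).

* Fisher: two-sided, the sum of hypergeometric probabilities of all
  tables with the observed margins whose probability does not exceed
  the observed one (scipy implementation; validated in the tests
  against an exact `Fraction`-based enumeration).
* Chi-square: Pearson Σ(O−E)²/E with (r−1)(c−1) df; Yates reduces
  |O−E| by 0.5 before squaring.
* Randomization: the statistic is the Pearson chi-square of the
  conditions × {present, absent} table (the natural two-sided choice
  for a C×2 table, and identical to the chi-square tests' statistic so
  the two regimes measure the same departure).  The presence vector is
  permuted B times (default 10 000) against fixed labels — equivalent
  to permuting labels — with the add-one estimator
  p = (1 + hits)/(1 + B), which cannot return 0 and is never smaller
  than 1/(B+1).  Permutations are vectorized (argsort of a B×n uniform
  matrix), which keeps a 60-column matrix at B = 10 000 under a second.
* BH-FDR: step-up q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1, mapped back to
  input order.

Columns that are constant (present everywhere or nowhere) carry no
association evidence; on the chi-square path their degenerate margins
are mapped to p = 1 rather than an error, matching what the exact tests
return.  The output table is sorted by q, then p, then m/z
(deterministic tie-break).

Intra-label analysis is a filter, not a test: keep columns with
presence rate ≥ `min_presence_target` inside the target sample set and
≤ `max_presence_rest` outside (defaults 100 and 0 — strictly present
in, absent out).

## PCA and clustering

PCA mean-centers columns (covariance PCA; an optional flag standardizes)
and eigen-decomposes via SVD with the unbiased (n−1) normalization, so
the eigenvalue sum equals the total column variance and retained
variances sum to 1.  Binary matrices are analyzed as 0/1 numerics.
Component signs are fixed by making each loading vector's
largest-magnitude entry positive — scores are then reproducible across
runs and platforms.  The top-3 scores are exported for 3-D plotting;
the full eigenvalue spectrum is retained.

Hierarchical clustering is bottom-up agglomerative with Euclidean or
Hamming (count of differing positions, binary vectors only) distances
and single/complete/average linkage; average linkage is the unweighted
mean over all inter-cluster leaf pairs.  The default metric follows the
matrix mode (Hamming for binary, Euclidean for intensity).  Merge ties
are broken by the smallest (min-leaf-index) pair, making the merge
sequence fully deterministic — the property the brute-force oracle test
relies on.  Both axes (samples and m/z) are clustered the same way.
Exports: the matrix reordered to both trees' leaf orders as TSV, each
dendrogram as Newick with branch length = parent height − child height,
and optionally a Java TreeView CDT/GTR/ATR triplet.  A biomarker m/z
list can restrict the matrix columns (tolerance window match) before
clustering.

## Biclustering

The binary matrix is encoded for the requested pattern: presence
(identity), absence (complement), or presence/absence (the matrix
concatenated horizontally with its complement, so an all-1 block in the
widened matrix is a constant-in-one-direction pattern).  Rows are
samples or peaks per the mode flag (transpose).

*Bimax* returns **every** inclusion-maximal all-1 submatrix meeting the
minimum dimensions.  Maximal all-1 submatrices are exactly the closed
(row-set, column-set) pairs of the binary relation, and are enumerated
by a canonical close-by-one search over columns — each maximal
bicluster is visited exactly once, so no duplicate-elimination pass is
needed; output is sorted by row set then column set.

*BiBit* seeds a bicluster from each row pair's bitwise AND; if the seed
is wide enough, every row whose AND with the seed leaves it unchanged
joins.  Each seed is the closed column set of its row pair, so every
BiBit bicluster is one of Bimax's maximal biclusters — BiBit returns a
(generally much smaller) subset at a fraction of the cost, which the
containment and cardinality tests assert.

Class-biclusters: with labelled samples, keep biclusters whose
sample-axis purity (largest label share) reaches `min_purity` (default
1.0 — one condition per bicluster), annotated with the majority label
(ties broken lexicographically).

## Classification

The harness assigns samples to stratified (default) or plain k-fold CV,
or a stratified percentage split, using the scheme's seed; held-out
predictions and per-class scores are pooled, and every statistic
derives from the pooled confusion matrix: accuracy = trace/total;
Cohen's kappa = (p₀ − pₑ)/(1 − pₑ) with pₑ from the marginal products
(if pₑ = 1, kappa is 1 when agreement is perfect and 0 otherwise);
per-class precision/recall, reported as undefined (`None`) for classes
never predicted / never present.  ROC per condition is one-vs-rest by a
threshold sweep over distinct scores (ties traverse one diagonal
segment) with trapezoidal AUC.  Classifier adapters (naive Bayes, k-NN,
decision tree, random forest, SVM, majority dummy) wrap scikit-learn
estimators; scores come from `predict_proba` where available, else
`decision_function`.  There is no internal feature selection — combine
with the biomarker export and `restrict_to_peaks` instead.

## Synthetic data generator

Each spectrum is built on a regular grid (default 1000–12 000 Da,
1 Da steps) as

&nbsp;&nbsp;&nbsp;&nbsp;y(m) = A·exp(−(m − m₀)/τ) + Σₖ hₖ·exp(−(m − cₖ)²/2σ²) + ε

with baseline amplitude A = 60 and decay τ = 2000 Da (chemical noise
largest at low mass), peak width σ = 3 Da, per-peak base heights drawn
uniformly from [50, 150], and white noise ε ~ N(0, 1).  The default
design is 5 conditions × 5 samples × 3 replicates with 30 peaks shared
by all conditions and 5 biomarkers private to each condition, positions
drawn with ≥ 20 Da mutual separation and a 60 Da edge margin.
Replicate variation: per-replicate m/z jitter N(0, 0.5 Da),
multiplicative lognormal height variation (σ = 0.2), and independent
peak dropout with probability 0.1.  Everything derives from one seed;
identical seeds give byte-identical datasets.

What the generator does **not** emulate: isotope envelopes, adduct and
matrix-cluster ions, detector saturation, mass-dependent resolution,
chemical noise correlated between replicates, and m/z calibration drift
(warping).  Passing tests therefore demonstrate correctness of the
algorithms under a clean additive model, not robustness to every
instrumental artifact; in particular, real data with calibration drift
would need wider matching tolerances or external alignment, which is
out of scope.

The end-to-end recovery check runs the default pipeline with absolute
2 Da matching windows at both matching stages: with a 1 Da grid and
0.5 Da replicate jitter, detected positions of one analyte differ by
1–2 grid steps between replicates, and planted peaks are ≥ 20 Da apart,
so a 2 Da window captures replicate scatter with a 10× margin against
collisions.  (The generic ppm default is kept for the matching API
itself, where instrument-style relative tolerances are the norm.)
Scoring counts a planted biomarker as recovered if a q < 0.05 m/z lies
within 3 Da.  At the default conditions this yields biomarker recall
and precision ≥ 0.9 (typically 1.0) across seeds, and a q < 0.05
false-positive fraction of 0 when nothing is planted.

## Problem sizes in the test suite

The suite favors many small randomized instances over few large ones:
matcher oracles run on pools of ≤ 12 peaks (1000 instances), Fisher on
all margins ≤ 12, clustering oracles on ≤ 7 leaves, Bimax oracles on
≤ 8×8 matrices, and the full-pipeline checks on the generator's default
75-spectrum design over 10 seeds — sizes at which the independent
brute-force references are exact and fast, and the whole suite runs in
about a minute.

## Known limitations

* PQN requires grid-aligned batches; no resampling or warping.
* The top-hat baseline leaves a small residual within one
  structuring-element width of the spectrum edges (steep baseline
  region); peaks reported there deserve skepticism.
* Bimax's output can be exponential in matrix size; it is intended for
  sample-scale matrices (tens of rows).  BiBit is the scalable choice.
* The randomization p-value is bounded below by 1/(B+1); q-values near
  that floor are resolution-limited.
* No protein identification, isotope-aware matching, or intensity-based
  differential abundance — the tests here are presence/absence only.
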