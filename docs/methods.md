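# Methods

This note documents the models, defaults and numerical choices behind
`kipquant`, and what the synthetic-data generators do and do not emulate.

## PRM quantification

**Peak boundaries.** Interactive chromatogram review adjusts integration
ranges by hand; a library needs a deterministic rule. The boundary of a
co-eluting transition group is the contiguous region around the apex of the
summed, 3-point-smoothed trace where intensity stays at or above a fraction
(`boundary_frac`, default 0.05) of the apex, clipped to the scheduling
window. For a Gaussian peak of width σ this gives a window of
±σ·√(2 ln 20) ≈ ±2.45σ, which retains erf(√(ln 20)) ≈ 98.6% of the analytic
area. `quantify_peptides` therefore divides integrated areas by that
closed-form retained fraction (`tail_correction=True` by default), so
Gaussian-like peaks are recovered essentially unbiased; the correction is
exact only for Gaussian shapes, which the panel-design shape rules are
there to enforce. All-zero trace groups are reported as "no peak", distinct
from an error.

**Integration** is the trapezoidal rule over the in-boundary samples, in
minutes × intensity. It is additive over partitions of the boundary and
stable (≤ 1%) under 2× resampling.

**Concordance filter.** A transition is excluded when its in-boundary
profile has Pearson r < `min_correlation` (default 0.8) against the
reference profile — the precursor trace when available, otherwise the
pointwise median of all transitions — or when its apex lies more than
`max_apex_shift` (default 2) sampling intervals from the reference apex
(reason codes `low_concordance`, `apex_shift`). Of the survivors, the six
largest integrated areas are summed into the peptide area ("strongest" is
ranked by area, not apex height; ties break on fragment label for
determinism). Fewer than six concordant transitions are all used; fewer
than two skip the filter with a warning.

**Rollup and normalisation.** Gene value = sum of its peptides' areas per
sample; a gene with no detected peptide is *missing*, never zero, because
non-identification is absence of evidence. Peptides mapping to several
genes are an error at this stage — the panel rules exclude shared peptides
upstream. Median normalisation rescales each sample so its median equals
the global median of per-sample medians (preserving overall scale rather
than forcing 1.0), then takes log2. `log_transform` offers plain log2
without normalisation: median normalisation assumes most genes unchanged
across samples, which is indefensible when a third of a targeted panel is
genuinely differential — the planted-cohort analyses therefore use plain
log2.

**iBAQ** divides intensity by the count of distinct fully tryptic peptides
of 7–30 residues (cleavage after K/R except before P, zero missed
cleavages). The bounds are the field's usual observability convention and
are configurable.

**CV** is the sample standard deviation (n−1) over the mean on linear-scale
replicate values; a zero mean yields a missing CV.

## Panel design

Hard exclusions (ion score < 20, modified fraction > 10%, missed cleavage,
subpeptide of a miscleaved form, sequence shared across gene products) are
all evaluated on every record and reasons accumulate, making the verdict
order-independent. Soft rules (shared with mouse, not covering all
isoforms) only deprioritise: such peptides fill shortlist slots only when
fewer clean candidates exist than the shortlist holds (up to 6, ranked by
PSM count). `is_subpeptide_of_miscleaved` is consumed as a precomputed
boolean from the archive rather than re-derived from raw search output.

Response curves are judged on three axes with numeric thresholds chosen to
quantify qualitative criteria ("narrow symmetrical peaks, proportional
response, no interfering peaks"); none of the three is a measured constant,
and all are configurable:

* linearity: R² of the zero-intercept fit area = b·input, computed against
  the mean-model total sum of squares so saturating curves score ≪ 1
  (threshold 0.95);
* symmetry: left/right half-area ratio at the apex within [0.67, 1.5];
* interference: any in-window local maximum outside the boundary exceeding
  20% of the apex.

The final panel keeps the top 2–4 passing peptides per gene by (R², PSM
count); genes with no passing peptide land in a shortfall report.

## IS-PRM acquisition model

The simulator replays the triggered-acquisition event loop over recorded
survey scans: precursors matching an inclusion entry within ±3 ppm (and an
intensity ≥ 1e5, at most 70 per cycle) get a heavy MS2; a light MS2 at the
heavy m/z + mass offset fires only when ≥ 4 of the entry's listed product
ions are found (product tolerance 10 ppm — the precursor tolerance is an
instrument-documented setting, the product tolerance is our configurable
default). Once fired, a target is not re-isolated until its precursor
leaves the survey selection (`once_per_elution=True`), giving one
quantitative light scan per elution. Scan scheduling is event-driven with
no AGC/injection-time physics. Labels are SILAC-style
(+8.014199 Da on K, +10.008269 Da on R); with the label on the C-terminus,
every singly charged y ion shifts by the full label mass, which is how
light product targets are derived from the heavy list. TIC normalisation is
plain value/TIC (invariant to joint rescaling of signal and TIC); a
rescale-to-mean-TIC option restores raw-intensity magnitudes at the cost of
that invariance.

## Downstream statistics

Technical replicates are averaged on the log2 scale; genes observed in
fewer than 10 biological samples are dropped before testing. The subtype
contrast is a two-sided two-sample t-test per gene — pooled-variance
Student's for the PDX-style contrast, Welch's for patient cohorts where
equal variances are not credible — with pairwise-complete values and ≥ 2
observations per group (otherwise "untested", not an error). Zero-variance
identical groups are guarded to p = 1 with undefined direction. BH
adjustment runs across all tested genes (statsmodels implementation,
cross-checked against a brute-force step-up oracle in the tests); the
significance flag uses the *uncorrected* p < 0.05 convention used for
panel-level counts, with adjusted p reported alongside.

Hierarchical clustering uses 1 − Pearson distance between samples with
average linkage (linkage/distance are open choices; these are the
defaults); k-means runs on per-gene z-scored values with 10 restarts and a
fixed seed. Missing values are imputed to the per-gene minimum for distance
computation only, encoding "absent ≈ low".

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their spec (same seed → identical
output) and return planted truth sufficient for downstream recovery checks.

* **Chromatograms**: Gaussian peaks (σ = 0.05 min, 0.01 min sampling, 4 min
  scheduled window) scaled so the analytic area equals the planted area,
  plus i.i.d. additive noise clipped at zero and optional offset
  interference Gaussians. Real chromatography adds tailing, baseline drift
  and correlated noise; passing the noiseless-recovery checks therefore
  bounds algorithmic bias, not real-data accuracy.
* **Dilution series**: linear genes scale ∝ input; saturating genes follow
  input/(input + K), emulating the binding-site saturation of highly
  abundant kinases.
* **Depletion**: constant per-round binding fraction f (default 0.7), so
  round k binds A·f·(1−f)^k — the simplest model consistent with round-wise
  recovery percentages; no kinetics, no carrier effects. Base abundances
  are LogNormal(meanlog 14, sdlog 2.5) (≈ 3–4 decades of dynamic range) and
  the detection floor is 7e4, the order of the survey intensity threshold;
  with ~300 kinases these conditions put round-1/round-2 identification
  retention near 84%/59% and abundance retention near 30%/9%.
* **Cohorts**: a gene's biological value is constant within subtype;
  replicates multiply it by mean-one lognormal noise at the stated CV
  (default 10%, which reproduces the observed ~9–10% replicate CV). There
  is no between-sample biological variance within subtype and missingness
  is completely at random — both simplifications mean the power estimates
  are upper bounds for real cohorts.
* **IS-PRM streams**: true targets emit their full 6-ion product set,
  decoys only 3 (so the n ≥ 4 rule can never fire on them); light twins
  appear only for endogenous-present targets. Precursor m/z jitter is
  Gaussian in ppm.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use: 5–50 cohort seeds
(8 vs 8 samples × 2 replicates, 100 kinases, 36 planted at |log2FC| = 2) for
recovery, 100–200 null matrices for calibration, 300-kinase depletion runs,
20-target acquisition streams, 80 peptides × 18 replicates for precision,
and 10–20 seeds for clustering recovery — sizes at which every stochastic
summary is stable to well inside its asserted tolerance. Numerical
comparisons use relative tolerances stated per check (0.5% noiseless area
recovery, 1% integration vs analytic area, 1e-9 for closed-form identities).

## Known limitations

* No cross-run retention-time alignment, match-between-runs or isotope
  pattern scoring; each sample is quantified independently.
* The gene rollup is a simplified sum over proteotypic peptides, not a
  parsimony-based grouper; shared peptides must be excluded at design time.
* The acquisition simulator models decision logic, not ion physics:
  injection time, AGC and resolution are treated as documentation.
* Saturation flagging uses lack-of-fit to proportionality, which cannot
  separate binding-site saturation from detector non-linearity.
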