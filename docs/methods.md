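# Methods

## Scope

`lisca` quantifies *when* cell-death-related events happen in individual
cells imaged on micropatterned single-cell arrays, and how those event
times relate across markers.  The pipeline runs in four stages:

1. **simulate** — generate a synthetic cohort with planted pathway
   labels, event cascades, traces and (optionally) image stacks;
2. **extract** — integrate background-corrected fluorescence inside an
   ROI grid into per-cell traces;
3. **fit** — fit phenomenological marker models by maximum likelihood,
   reject no-event traces, extract event times and ROS production
   rates;
4. **correlate** — summarize event-time distributions and pairwise
   event-order structure.

## Trace models

Two parametric families cover the marker panel.  Early markers
(LysoTracker → LMP, TMRM → MOMP, CellROX → OxBurst) rise or plateau and
then collapse:

    f(t) = s(t) · (a0 + a1·t + a2·t²) + (1 − s(t)) · c,
    s(t) = 1 / (1 + exp((t − t_b)/τ_b))

Late markers (Caspase 3/7, pSIVA, PI/Toto-3) switch on sharply and
decay smoothly (bleaching and dye degradation absorbed into λ):

    g(t) = B + A · σ(t) · exp(−λ · max(0, t − t_h)),
    σ(t) = 1 / (1 + exp(−(t − t_h)/τ_o))

The logistic-step forms are a design choice: the literature for this
assay specifies only the qualitative shape (a step multiplied by an
algebraic or exponential function).  Logistic steps reproduce every
observed trace feature, have analytic tangents (needed by the onset
definition) and sharp-step limits, and make every event definition
computable in closed form for testing.  The pre-breakdown polynomial is
capped at degree 2; plateau markers such as TMRM are the special case
a1 = a2 = 0 rather than a separate family.  The post-breakdown floor
`c ≥ 0` is retained as a free parameter.

## Event definitions

* **Breakdown time** (early markers): the deviation
  Δ(t) = P(t) − f(t) of the fit from its own pre-breakdown polynomial
  is evaluated on a uniform 1-min grid over the fit domain;
  t_breakdown is the earliest grid time with Δ(t) > κ·η (default
  κ = 3).  Note that by this definition t_breakdown precedes the step
  centre t_b by roughly τ_b·ln((P − c)/(κη)); the same definition is
  therefore applied to planted true parameters when measuring recovery,
  so the systematic part cancels.
* **Onset time** (late markers): the earliest time at which the fit
  reaches halfway between baseline B and its maximum over the fit
  domain (bracketed on the 1-min grid, refined by Brent root finding);
  the tangent there (analytic derivative, right-sided at the λ-kink)
  is intersected with the horizontal baseline.  For a pure sigmoid
  (λ = 0) this gives exactly t_onset = t_h − 2·τ_o.  The earliest
  half-maximum crossing is used because λ > 0 creates a second,
  descending crossing.
* **ROS production rate**: slope of the line through the first two
  points of the fitted CellROX model evaluated at 1-min resolution from
  the start of the fit domain, in a.u. h⁻¹.
* The administration-to-first-frame delay is added to accepted event
  times exactly once; the event set carries a guard flag and a second
  application raises.

## Fitting and quality control

Noise is modelled as i.i.d. Gaussian with constant variance, under
which maximum likelihood is least squares; the flat noise bands seen in
this kind of trace data support homoscedasticity.  The optimizer
(`scipy.optimize.least_squares`, TRF, tolerances 1e-14) runs from 8
deterministic starts — breakdown/onset candidates at the steepest
observed intensity change plus span quantiles, each paired with two
step-width initializations — and keeps the best SSE solution.  On
reduced two-parameter problems the result matches an exhaustive 0.01 h
grid search (tested), and on noiseless traces it recovers planted
parameters to < 1e-3 h.

The noise level η is the robust residual scale 1.4826 × median
absolute residual, insensitive to the event region.  A trace is
rejected when (in order): the optimizer failed; the fitted model's
dynamic range is below k_amp·η (default k_amp = 5); or the event model
does not beat the nested no-event model (polynomial-only for early,
constant for late) by at least ΔBIC = 10.  η is floored at 1e-6 a.u.
when forming thresholds so that noiseless traces remain well defined.
These thresholds are configurable; they are this package's defaults,
not values claimed from any reference implementation.

## Population statistics

Event-time histograms are summarized by maximum-likelihood log-normal
fits (μ = mean ln t, σ = uncorrected sd ln t); the distribution maximum
is exp(μ − σ²).  Pairs of markers are inner-joined per cell over
accepted events only.

**Mean shift.** Clusters in the (t₁, t₂) plane are found by mean-shift
ascent: every point iterates the window mean of its in-radius
neighbours (uniform kernel, radius = bandwidth) until the step falls
below 1e-4 h or 500 iterations; converged positions closer than
bandwidth/2 merge into one mode, and clusters below 5% of the points
dissolve into the nearest surviving mode.  The procedure is
deterministic.  The uniform kernel was chosen over a Gaussian kernel of
the same scale deliberately: at the default 2 h bandwidth a Gaussian
kernel smooths the density so strongly that two pathways whose delays
differ by ~5 h (3.5 h perpendicular to the diagonal) merge into a
single mode, whereas the uniform window of radius 2 h resolves them.
The bandwidth is a required analysis parameter (default 2 h, fixed for
reproducibility); a Silverman rule-of-thumb helper is provided as a
starting point only.

**Asymmetric one-sigma ellipses.** Each cluster is summarized by its
mean centre and the principal components of the 1/n-normalized sample
covariance (so axis lengths equal RMS displacements exactly).  The
major axis may have different lengths on its positive and negative
sides: each side's length is the RMS of that side's strictly positive
(negative) projections; points with exactly zero projection count for
neither side, and an empty side inherits the other side's length so
that no axis degenerates to zero.  The first direction is oriented
toward the diagonal (non-negative component along (1,1)/√2).  The
signed delay Δt is the difference of the cluster-centre coordinates
(t₂ − t₁) — the natural estimator given the ellipse construction; the
output metadata records this definition, since "average delay" could
also be read as a median or a mean of per-cell differences.

The diagonal partition reports the fractions of pairs above, below and
within a tolerance band of the coincidence diagonal.  Pearson
correlation (with a zero-variance guard) links ROS production rates to
event times.  No causal claims follow from any of these summaries.

## Synthetic cohorts: what is emulated, what is not

The generator plants the statistical structure the analysis assumes:

* each cell draws a pathway label (e.g. lysosomal LMP→MOMP→OxBurst vs.
  mitochondrial MOMP→OxBurst→LMP) from configured fractions — a
  two-component mixture with opposite marker order models bimodal
  populations, rather than a heavy-tailed single law;
* the anchor (first) event time is log-normal, multiplied by a
  cell-level latent scale factor that induces the diagonal-elongated
  correlation of real event-time scatter;
* downstream events add |mean delay + Gaussian jitter|, so the
  cascade order holds by construction (anchor-plus-positive-increments,
  not independent marginals — planted clusters then lie strictly on one
  side of the diagonal, as observed cohorts do);
* traces are the marker models at the planted event times sampled every
  10 min over 30 h plus i.i.d. Gaussian noise, matching the fitting
  likelihood;
* image rendering places each cell's trace as a pixel-integrated
  Gaussian blob (sd = site/7, > 99.9% of flux inside the ROI) at its
  site centre on a 30 µm / 90 µm-pitch square lattice, plus a constant
  or linearly tilted background and optional pixel noise; 16-bit TIFF
  output.

Defaults the assay literature does not pin down were chosen once as
realistic values and are free parameters of the configuration:
amplitudes of order 10²–10³ a.u. of integrated fluorescence; noise
20–50 a.u.; breakdown widths τ_b ≈ 0.25–0.3 h; onset widths
τ_o ≈ 0.12–0.15 h (a "sharp" onset completes within 2–4 frames at
10-min sampling — at SNR 10 the intrinsic MLE uncertainty of the onset
time grows with τ_o, and a broad rise ≥ 0.3 h would carry > 5 min
statistical error by itself); ROS-rate law log-normal with median
80 a.u. h⁻¹.  The planted-cluster benchmark cohort uses an anchor
log-sd of 0.12 (≈ 1.2 h at a 10 h median) so that each pathway forms
one coherent cluster below the 2 h analysis bandwidth.

Not emulated (and therefore not demonstrated by passing tests): cell
migration or detachment, multi-cell site occupancy, spatially varying
background or flat-field structure, photobleaching beyond the
late-marker exponential, heteroscedastic or Poisson photon noise, and
day-to-day or marker-interference variability.  Results on real
microscopy data additionally depend on the semi-automated occupancy QC,
which is an input table here by design.

## Numerical choices and degenerate inputs

* Half-open, 0-based, row-major pixel rectangles everywhere.
* Background estimate: per-frame scalar median of out-of-ROI pixels
  (robust to sparse bright cells); negative pixels clamp to 0 after
  subtraction because integrated intensities feed positive-amplitude
  models.  Whether a per-frame scalar or a spatially varying correction
  is more faithful to any given acquisition is data-dependent; a
  spatially varying estimator is a possible extension.
* Traces shorter than 12 samples yield a rejection record; non-finite
  intensities raise.
* Event grids are uniform at 1-min resolution; breakdown times are
  reported on the grid, onset times are refined by root finding to
  1e-12.
* Collinear point sets raise in the ellipse construction; fewer than 5
  points raise in mean shift; fewer than 3 positive times raise in the
  log-normal fit.
* All generators and the fit multistart are seeded; identical
  configuration + seed reproduce byte-identical CSV outputs, which the
  run manifest verifies by checksum.

## Validation problem sizes

The packaged validation experiments (also run by
`scripts/acceptance.py`) use: 100 random parameter sets for the onset
closed form; 200 + 200 noisy traces at SNR 10 for event recovery;
200 pure-noise traces for null rejection; n = 300 cohorts for cluster
and delay recovery; n = 10⁴ draws for log-normal recovery and n = 5000
for correlation recovery; and a 64-site grid for the full
image-to-correlation pipeline.  These sizes give the statistical
resolution the tolerances require while keeping a full run in the
minutes range on one CPU.

## Known limitations

* The breakdown time is definition-dependent (threshold multiple κ and
  η estimator); absolute values shift systematically with κ although
  comparisons using a fixed κ are consistent.
* The onset tangent construction assumes the fitted maximum is reached
  within the observation window; onsets too close to the horizon are
  rejected rather than extrapolated.
* Mean-shift cluster counts depend on the bandwidth; it must be chosen
  with the expected delay scale in mind (the default 2 h resolves
  delays of a few hours).
* The latent-scale factor is a single multiplicative cell-level degree
  of freedom; real cohorts may correlate through richer mechanisms.
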