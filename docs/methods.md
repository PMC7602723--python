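# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Compositional framework

HPLC peak relative abundances carry only relative information, so every
statistic operates in Aitchison geometry: closure to proportions, clr/ilr
log-ratio transforms, and Euclidean distance between clr images. The ilr
basis is the Helmert-type orthonormal contrast matrix in peak-index order;
any orthonormal basis yields identical distances (tested), the fixed
default merely makes coordinates reproducible.

**Zero replacement.** Multiplicative replacement with a configurable
δ (default 6.5 × 10⁻⁴ = 0.65 × the 0.1% minor-peak reporting threshold):
zeros become δ and nonzero parts in a row with Z zeros are scaled by
(1 − Zδ), preserving within-row ratios. A deterministic, closed-form rule
was preferred over Bayesian-multiplicative imputation, whose prior choices
add a tuning surface without changing any downstream decision at these
magnitudes. δ must stay below the smallest positive entry; the default
sits safely below the 0.1% reporting floor.

**Juvenile baseline.** The reference composition is the *closed
component-wise geometric mean* of the three earliest samples — the Fréchet
mean under the Aitchison metric, hence consistent with the distances
measured from it. An arithmetic-mean option exists
(`baseline_distance_series(..., mean="arithmetic")`) for comparison.
Averaging three early samples, rather than trusting a single first sample,
buffers the reference against one noisy chromatogram. Distance series are
scaled per individual by their own mean ("mean-scaled"), so trajectory
parameters are comparable across snakes with different overall magnitudes
of change; raw distances are retained for plotting and the hormone
regression. If all samples are identical the mean distance is zero and the
scaled series is returned as zeros rather than NaN.

**Minor-peak filter.** Peaks averaging < 0.1% relative abundance across an
individual's samples are dropped as integration noise and rows re-closed.
The filter is applied per peak on the mean across samples — a peak is an
entity of the individual's chromatogram set, and per-sample filtering
would fragment the peak set over time.

## PERMANOVA with a continuous predictor

The ontogeny test regresses the ilr coordinates on [1, predictor] and
partitions sums of squares; because ilr coordinates are Euclidean this is
exactly the Gower-centered distance-matrix formulation (the dual route is
implemented and the equality tested to 1e-6). Significance comes from
permuting the predictor: p = (#{F_perm ≥ F_obs} + 1)/(B + 1) with
B = 10,000 by default, giving the familiar 1/10001 ≈ 9.9 × 10⁻⁵ floor when
no permutation matches the observed statistic. For n ≤ 7 all n! orderings
are enumerated and the exact tail proportion is reported without the +1
correction (seed-independent). Rows are permuted freely — the design has a
single continuous covariate and no blocking structure. The time-vs-size
comparison runs the identical test with day and with SVL on the same
sample subset (samples lacking SVL dropped from both) and prefers the
higher R²; affinely related predictors tie exactly.

## Trajectory models, AICc and tempo

Candidate models for the scaled distance series d(t):

| model    | form                        | k (incl. σ²) |
|----------|-----------------------------|--------------|
| constant | c                           | 2            |
| linear   | a·t + b                     | 3            |
| sigmoid  | A / (1 + exp((t₀ − t)/s))   | 4            |

The logistic has a zero left asymptote because distance from the juvenile
baseline starts near zero by construction; a free-baseline 4-parameter
variant is available (`free_baseline=True`). Fitting is bounded nonlinear
least squares (scipy's trust-region reflective) — a Levenberg–Marquardt-
style least-squares fit, with bounds because positivity of A and s is part
of the model's meaning. Initialization is multi-start: A₀ = max d, t₀ at
the first crossing of A₀/2, and s₀ ∈ {span/50, span/20, span/8, span/3};
the lowest-RSS start wins. The extra small start matters for switches
faster than the sampling cadence. The sigmoid's p-value is a single
extra-sum-of-squares F-test against the constant model (one p per curve,
rather than three parameter-wise t-tests). Non-convergence from every
start raises a convergence signal and the caller falls back to linear.

Models compete on AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1) (Gaussian
likelihood, constants dropped consistently); plain AIC is not exposed
because at these n the correction always matters. RSS is floored at 1e-12
so noiseless test fixtures keep a finite criterion.

**Tempo.** The speed of a sigmoid shift is summarized as the days needed
to cover 90% of the asymptotic change at the maximum (inflection-point)
rate A/(4s): tempo = 0.9A/(A/4s) = 3.6·s, which cancels A and is invariant
to rescaling the distance axis. The alternative reading — the curve's own
5%→95% transit time, 2·ln(19)·s ≈ 5.89·s — is selectable
(`tempo_formula="curve_span"`); the default matches "days to shift at the
maximum estimated rate of change". Against a 244-day active season
(April through November), tempo < 244 ⇒ **discrete**, otherwise gradual.

**Classification rule** (α = 0.05, decisive ΔAICc = 2):

1. best (lowest-AICc) model not significant → `no_shift`;
2. sigmoid AICc strictly lower → `sigmoid_discrete` / `sigmoid_gradual`
   by the tempo rule;
3. linear lower but by ≤ 2, with a converged sigmoid → `linear_gradual`
   reported with the competitive sigmoid's tempo (a linear-best series can
   still imply a fast transition);
4. linear decisively better, or sigmoid unfit → `linear_gradual` with
   tempo equal to the sampling span.

## Per-peak scan

Each peak's clr coordinate is centered on its own juvenile reference (mean
of the three earliest samples — the same construction as the whole-venom
baseline) and run through the identical competition, with the logistic
amplitude free in sign since a peak's relative abundance can fall as well
as rise. Without the centering, the zero-asymptote logistic cannot
represent a peak sitting at, say, −1.4 clr units as a juvenile. No
multiple-testing correction is applied by default (per-peak significance
is reported at raw α, the convention for descriptive peak panels);
Benjamini–Hochberg (`mtc="bh"`) demotes non-surviving peaks to `no_shift`.
Closure means a genuine shift in one peak drags bystander peaks with it —
anti-correlated, often equally significant shifts in unmanipulated peaks
are an expected property of compositional data, not a false-positive
pathology. Recovery tests therefore assert that planted peaks are detected
with the planted mode, not that detections are exclusive; the null
false-positive rate (no planted shifts) is what is bounded (≤ 10% at
α = 0.05).

## Venom space

Peaks are called per individual, so cross-individual comparison first sums
abundances into eleven fixed retention-time windows, half-open [lo, hi)
with the last closed at 125 min — the printed window ranges share their
endpoints, so a deterministic boundary rule is required and 20.0 min
belongs to R2. Binned rows are re-closed; empty windows go through the
standard zero replacement before clr. Ordination is Kruskal non-metric MDS
(SMACOF majorization with isotonic regression, primary treatment of ties),
best of 20 random starts, coordinates centered; stress-1 is recomputed
from the returned configuration. Configurations are identifiable only up
to rotation/reflection and only as tightly as the dissimilarity ranks
constrain them, so reproducibility across input reorderings is asserted
via Procrustes residual at n large enough for the ranks to pin the shape.

## Hormone and diet companions

Testosterone: duplicate reads averaged, non-detects (or values below) set
to the assay's lower limit of detection, 0.001 ng/mL — substitution is
idempotent — then ln-transformed, since concentrations vary
multiplicatively. The venom association is OLS of *raw* Aitchison distance
from baseline on ln-T, matched by collection day (an exact-day match by
default; a day-window for jittered schedules). The collinearity guard
refuses a joint body-size + testosterone model when |Pearson r| > 0.7,
where a regression could no longer attribute variance between the two.

Diet: snout–vent lengths are binned into four *equal-width* quarters of
the observed range (not data quantiles — the published class edges
512–782 / 783–1053 mm for a 512–1595 mm range force the equal-width,
integer-width convention width = (max − min + 1)/4). Adjacent classes are
contrasted with Pearson chi-square on the 2 × C table, no continuity
correction, empty-in-both-classes categories dropped from the df; expected
cells < 5 are flagged, zero-total classes skipped. The statistic scales
with total count at fixed proportions — tests document this rather than
pretending scale invariance.

## Simulator

`simulate_snake` draws, per individual: per-peak latent log-abundance
trajectories (constant, linear drift, or logistic switch), additive
Gaussian noise *in clr space* (the geometry every downstream statistic
uses), and softmax re-closure, so simulated rows are exact simplex points.
Body growth is von Bertalanffy (defaults L∞ = 110 cm, L0 = 35 cm,
k = 0.0015/day — a neonate-to-adult rise over ~3 years — with 1 cm
measurement noise, mimicking the observer error of measuring a live
snake). Testosterone is lognormal around a baseline of 0.5 ng/mL with a
size-linked rise (2 ln-units neonate→asymptote), an annual sinusoid
(±0.5 ln-units) and 0.3 ln-units of noise. Sampling cadence defaults to
61 days (bimonthly) over 1220 days. Diet records draw SVL uniformly over
a configured range and prey from the owning quartile's multinomial.

What the simulator does **not** emulate: chromatographic integration
error structure (noise is homoscedastic in clr space), peak retention-time
drift, missed samples/irregular cadence (available only by configuring
intervals), individual variation in t₀ linked to growth realization, and
correlated shifts across peaks beyond what closure induces. Passing tests
therefore demonstrate that the statistical machinery recovers known
structure under the stated noise model — not that real chromatograms meet
that model.

**End-to-end recovery.** Through the full pipeline (composition → baseline
distances → model competition) a planted logistic with scale 40 d recovers
`sigmoid_discrete` and scale 150 d recovers `sigmoid_gradual`, each ≥ 90%
of replicates at clr noise σ = 0.02. A planted *linear* drift yields a
distance trajectory that is linear only beyond the baseline window — the
norm and the three-sample reference bend its early segment — so linear and
shallow-sigmoid fits describe it equally well and the AICc winner is close
to a coin flip. Correct recovery for that class is therefore defined as
any gradual, non-discrete call; the sharp 3-class separation (linear vs.
shallow vs. steep logistic, each ≥ 90%) is asserted on directly simulated
distance series, where the generating class is well defined. Problem
sizes: recovery runs use ~15 samples spanning 1200 days, 15–20 peaks, and
~200 replicate snakes per grid; the null false-positive bound uses 40
replicate snakes of 10 peaks.

## Degenerate inputs and tie-breaks

All-zero abundance rows, constant predictors, non-orthonormal ilr bases,
δ above the smallest positive part, non-symmetric distance matrices and
sub-minimal sample counts raise typed errors (`venomshift.errors`).
Exactly constant response series short-circuit to a flat fit with p = 1
rather than propagating 0/0. Equal R² in the time-vs-size comparison
(within 1e-9) is reported as a tie rather than an arbitrary preference.
AICc ties (exactly equal) fall to the linear branch, which then reports
the sigmoid-derived tempo when the sigmoid is within the decisive margin.

## Known limitations

- Per-snake mean-scaling makes trajectory parameters comparable across
  individuals but means asymptote estimates are in units of each snake's
  own average change.
- Tempo is undefined for linear-preferred series except as the sampling
  span, which is a lower bound on the true completion time, not an
  estimate of it.
- With sampling cadence coarser than the logistic scale, s is weakly
  identified from the transition region; the multi-start keeps the fit
  honest but confidence in s (hence tempo) degrades.
- The PERMANOVA assumes exchangeability of samples under the null;
  serial autocorrelation within an individual would inflate significance,
  a caveat shared by the underlying design.
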