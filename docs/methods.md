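# Methods

This note documents the models, numerical choices and simulator design
behind `phytonirs`, and what the package's validation does and does not
demonstrate.

## Calibration model

Each hormone gets its own PLS1 model (four independent calibrations, not a
single multi-response PLS2 fit): the study design calibrates each analyte
against its own standard-solution series, and separate models keep the
factor counts and preprocessing choices independent per analyte.

NIPALS extracts one latent factor at a time from the column-centered
spectral matrix X (no autoscaling — all columns are absorbance in the same
units, and variance-scaling would inflate baseline channels) and the
centered concentration vector y:

    w ∝ Xᵀy,  ‖w‖ = 1        (weight: covariance direction)
    t = X w                   (score)
    p = Xᵀt / tᵀt             (X loading)
    q = yᵀt / tᵀt             (y loading)
    X ← X − t pᵀ,  y ← y − q t

For a single response the weight iteration is stationary after one pass;
the iterative guard (tolerance 1e-12, 500 iterations) only matters for
numerically degenerate input. Factor extraction stops early when the
deflated X or the remaining y-covariance falls below 1e-20 of its original
sum of squares — exactly low-rank (noise-free) data otherwise yields
garbage factors with enormous loadings. The folded coefficient vector
B = W(PᵀW)⁻¹q reproduces the sequential factor expansion to 1e-10; this
identity is asserted at fit time.

Predictions are ŷ = (X_new − x̄)B + ȳ with x̄, ȳ frozen from training. A
zero-factor model is legal and predicts ȳ.

Per-factor explained X-variance is ‖t_a p_aᵀ‖²_F / ‖X_c‖²_F; because scores
are mutually orthogonal these contributions add and cannot exceed 100%.

## Preprocessing

Order is fixed: window restriction first, then the transform, so each
(window, treatment) pair is one self-contained candidate.

* **MSC** regresses each spectrum on a reference (ordinary least squares
  over channels) and returns (x − a)/b. The reference is the mean of the
  calibration standards for the analyte being modeled and is stored inside
  the saved model: external validation and unknown prediction never refit
  it (a leakage guard in the test suite asserts the frozen path is used).
  A fitted |b| < 1e-12 is an error, not a silent pass-through.
* **Savitzky–Golay first derivative** uses a 13-point window and quadratic
  polynomial by default (the window length is the study's stated choice;
  quadratic is the standard chemometric order for first derivatives; both
  are configurable). Derivatives are taken with respect to wavenumber on
  the ascending grid (coefficients divided by the 2 cm⁻¹ step). Edges are
  truncated to the valid convolution region — 6 points per side — rather
  than padded: padding fabricates data exactly where scatter artefacts are
  worst.

## Split, cross-validation, metrics, selection

* 70/30 split, stratified by concentration: standards are sorted by
  concentration, cut into as many contiguous blocks as test samples, and
  one non-extreme sample per block is drawn (seeded). The global minimum
  and maximum concentrations always stay in training so prediction never
  extrapolates the calibration range. 70% of 65 is rounded half-up to
  46 train / 19 test.
* RMSECV uses seeded k-fold (k = min(10, n)) by default; leave-one-out is
  available and k = n reproduces it exactly. All preprocessing statistics
  (MSC reference, centering) are refit inside each fold. Factor counts
  1..7 share one NIPALS fit per fold (PLS factors are nested); the count
  with minimal RMSECV wins, ties going to fewer factors. The cap of 7
  mirrors the largest factor count the candidate grids consider.
* RMSEC/RMSEP are plain root-mean-square errors on the training and
  held-out sets; R² is 1 − SSres/SStot and may be negative — a model that
  predicts the external set worse than its mean.
* Selection over candidates: drop candidates with prediction R² ≤ 0
  (validity filter — a tiny RMSEP is meaningless if the model tracks the
  test set worse than a constant), then minimal RMSEP, ties by fewer
  factors, then by smaller RMSEC. If nothing survives the filter the
  overall-minimum-RMSEP candidate is returned with a warning. The
  threshold is configurable; 0 is the default because it is the weakest
  filter that rejects anti-correlated models.

The published candidate table that ships in `phytonirs.data` labels its
columns unambiguously (`rmsec` = calibration error, `rmsecv` =
cross-validation error, `rmsep` = external prediction error); the source
table's own header conflates the first two, and its cross-validation
column was not printed, so `rmsecv` is NaN there.

## Units

Tissue content (µg g⁻¹ fresh weight) = c(µM) × M(g mol⁻¹) × V(L) / m(g).
Defaults: molar masses IAA 175.18, GA₃ 346.37, SA 138.12, kinetin 215.21
g/mol; extract volume 10 mL; tissue mass 1.0 g. The extraction volume is
not a measured constant of the emulated protocol — it is a prominent,
configurable assumption, and every profile report carries the context
used. Negative concentration predictions are flagged, not clipped
(clipping is opt-in), so extrapolation artefacts stay visible.

## Population statistics

ANOVA and Tukey HSD accept either raw replicate vectors or published-style
summaries (mean, SE, n); summaries reconstruct within-group sums of
squares via sd² = n·SE², which is algebraically identical to the raw
computation. Tukey uses the studentized-range distribution directly
(Tukey–Kramer standard error for unequal n); with two groups q = t√2
recovers the pooled t-test p-value exactly. The populations are treated as
independent groups of distinct trees (a repeated-measures design would
require the same trees measured repeatedly, which the data do not
support).

Bray–Curtis dissimilarity Σ|u−v| / Σ(u+v) is computed on raw profiles —
it is designed for nonnegative abundance-like data and the hormone
profiles are used unstandardized; range-scaling is available as a flag at
the matrix level. nMDS minimizes Kruskal stress-1 by SMACOF majorization
with isotonic regression of embedded distances on dissimilarity ranks
(primary tie treatment via stable rank ordering), initialized from
classical scaling plus seeded Gaussian restarts (8 by default, best
restart returned); convergence at stress change < 1e-8 or 300 iterations.
Stress is invariant to rotation, translation and uniform scaling of the
configuration, and to monotone rescaling of the input dissimilarities.

## Synthetic data: what it emulates and how it was designed

The simulator emulates the study design: 65 log-spaced standard
concentrations from 0.1 to 250 µM per hormone (260 standards total; the
levels span 3.4 decades, so log spacing is the natural choice; linear is
available), and 13-population extract panels with 3 replicates, each
spectrum a Beer–Lambert sum of Gaussian bands plus a fixed-level matrix
interferent and an instrument-noise realization

    x → b·x + a + tilt·(ν−ν₀)/range + ε,   b lognormal.

Band centers follow the published assignments (IAA: 4150, 4500, 5200,
5900, 7100, 9100; GA: 4500, 4700, 5200, 7150; SA: 4150, 5000, 5200, 7100;
kinetin: 4400, 5100, 6700, 8800 cm⁻¹). Widths and amplitudes are package
constants, and they were designed — by an explicit cross-talk analysis,
not trial and error — around one hard requirement: four *single-analyte*
calibrations must quantify a *four-analyte mixture* to within a few
percent. That requirement is what the whole pipeline claims to do, and it
constrains the spectral geometry sharply:

* Each hormone's dominant band (4 × 10⁻³ AU/µM, ≈1 AU at the 250 µM top
  standard) is a combination band unique to it — IAA N–H 4500, GA R–OH
  4700, SA O–H 5000, kinetin C–N 5100 cm⁻¹ — with σ = 15 cm⁻¹ so that
  even the 100 cm⁻¹ SA/kinetin neighbors overlap by < 0.01%. Bands shared
  between hormones are weak (2 × 10⁻⁵), overtone secondaries moderate
  (2–3 × 10⁻⁴, σ = 120 cm⁻¹).
* The matrix interferent consists of broad bands at 7800 and 9500–10000
  cm⁻¹ — spectral zones free of analyte absorption. A single-analyte PLS
  model must estimate each sample's multiplicative scatter factor from
  somewhere; a stable background feature gives it a *clean* channel. When
  the interferent instead overlaps the analytical region (as a solvent
  background realistically might), the models develop negative
  compensation weights across that region and misread every co-extracted
  hormone — closed-loop errors of tens to hundreds of percent, measured
  during design. The same analysis showed that MSC, when the background
  dominates the spectrum, wins calibration handily yet carries a
  scale-invariant mixture bias of ≈ −40%: its per-spectrum affine fit
  treats the other hormones' bands as scatter.
* Default noise is multiplicative scatter (lognormal σ = 0.005) plus
  detector white noise (σ = 0.004 AU). Additive offset and baseline tilt
  default to zero: absorption-mode measurements are referenced against a
  solvent background, which cancels additive terms — and, numerically, any
  appreciable offset/tilt noise drives the models to estimate a diffuse
  baseline from all ~3000 channels, a conduit through which mixture
  partners leak into every prediction. Both fields remain in the noise
  model for robustness studies.

Under these defaults the closed loop (simulate → calibrate → select →
predict → convert) recovers the published POP13 tissue contents to within
5% for all four hormones across seeds, and the recovered 13-population
panel preserves the qualitative patterns: kinetin lowest everywhere,
POP13 maximal for every hormone, POP13 and POP2 the two most dissimilar
profiles by average Bray–Curtis distance.

**What the simulator does not emulate.** Real leaf-extract NIR spectra
have overlapping analyte bands, solvent features inside the analytical
region, wavelength-dependent scatter and baseline curvature. The design
analysis above shows that the single-analyte-calibration design is *not*
robust to those features — that is a finding about the study design, not
an implementation artefact. Passing closed-loop tests therefore
demonstrate that the pipeline is correct and self-consistent under
favorable spectral geometry; they do not certify the underlying assay
against strongly overlapping real-world matrices. Within the simulation,
the selected pre-treatment is usually the untreated full spectrum
(occasionally the derivative); the published pattern in which derivatives
win for IAA/GA is reproduced from the published metrics table itself, not
re-derived from simulated spectra.

## Numerical choices and degenerate inputs

* Grids must be strictly ascending and uniform to 1e-6 relative; files
  written descending are flipped on read. Windows are closed intervals on
  exact grid points — no interpolation, mismatched grids are rejected
  rather than resampled.
* NIPALS: tolerance 1e-12 / 500 iterations; rank-exhausted extraction
  stops early and records the achieved factor count.
* k-fold CV caps the factor count at what the smallest fold can support.
* Tukey with zero pooled variance: identical means give p = 1, different
  means p = 0 rather than NaN.
* nMDS ties in the isotonic fit use the stable (primary) rank ordering;
  duplicated objects embed to coincident points.
* Single-replicate populations get SE = 0 plus an explicit flag rather
  than NaN.

## Problem sizes

The default validation runs at the full study scale — 3001-point spectra,
260 standards, six candidates × four hormones with 10-fold CV, and a
39-spectrum unknown panel; the complete closed loop takes a few seconds,
so no reduced-scale shortcuts are needed anywhere in the test suite.
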