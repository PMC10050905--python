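# Methods

## Model

A processed 2D-¹H,¹³C-HSQC spectrum is represented as a real intensity
matrix on calibrated ppm axes (rows = ¹³C, columns = ¹H, both descending).
Within a search window centred on a resonance's library shifts, every ¹H
column is modelled as a nonnegative linear mixture of K latent ¹³C source
traces plus independent noise, **Y = W S**.  Three physical assumptions
justify the decomposition: signals at different ¹H shifts belong to
chemically distinct CH pairs and are statistically independent; metabolite
signals superpose additively; and absorption-mode intensities are
nonnegative with zero baseline.  FastICA (log-cosh contrast, tolerance
1e-5, at most 500 fixed-point iterations, seeded) recovers S up to sign
and scale; each source is re-oriented so its dominant extremum is positive,
its baseline (median) is restored to zero — ICA centres its output, but an
absorption trace has a zero baseline — and scaled to unit maximum.

Multiplets are simulated to first order: an isotopomer labelling subset
{J₁…J_q} of the one-bond coupling partners produces 2^q sticks at all sign
combinations of ± s·J_k/2 (s = apparent-J scaling), each dressed with a
Lorentzian and the total normalised to unit area so that regression
coefficients are proportional to signal integrals.  The weak-coupling
approximation is quantified against exact two-spin diagonalisation in the
test suite: the roof-effect intensity error is J/√(Δν²+J²) — about 5 % at
a shift separation of 20 J, 1 % at 100 J, and < 1 % for typical one-bond
¹³C pairs at high field (≥ 150 J).  The closest pair in the shipped
library (glutamate C3–C4, ≈ 38 J at 201 MHz) carries ≈ 2.6 % roof error,
well below the noise level of real spectra; strong-coupling (second-order)
simulation is out of scope.

## Identification and quantification

Candidate identification searches every nonempty subset of the p simulated
components (default all sizes 1..p; 15 subsets for p = 4).  Each subset's
equal-intensity pattern is cross-correlated with the peak-filtered source
trace; the best-correlating lags (default the top 15, plus the
library-centred position) are evaluated by a nonnegative least-squares fit
of the source on the subset's component traces, yielding a coefficient of
determination ρ.  Evaluating only the top cross-correlation lags keeps the
subset × centre search cheap; setting `align_candidates=None` evaluates
every grid offset.  ρ is divided by (ε + Δppm²), where Δppm is the
Euclidean distance from the library shifts with the ¹³C axis compressed by
Γ_adjusted = 20·(γ_H/γ_C) ≈ 79.5 (the ratio of the search widths,
3.0/0.15, times the gyromagnetic ratio), so equally good fits resolve
toward the library position.  ε (default 1e-4 ppm²) guards the Δppm = 0
case; the adjusted score ranks candidates and is never reported as ρ.
Ties break toward smaller Δppm, then smaller subsets.

Peak filtering zeroes local maxima below 50 % of a source's global maximum
(together with their flanks out to the surrounding minima), protecting the
identification score from noise spikes and neighbouring resonances.

Quantification fits the *experimental* ¹³C column — not the ICA trace — at
the ¹H position found by a one-column hill climb on the fit ρ (no sub-grid
interpolation: the data resolution bounds meaningful precision).  The
design matrix holds all 2^n simulated components at the assigned centre;
NNLS coefficients normalised to unit sum are the reported fractions.  The
fit and its ρ are evaluated on the multiplet footprint — the span of the
outermost sticks padded by six linewidths (≈ 95 % of a Lorentzian line's
area) — rather than the full ±3 ppm column: baseline noise over the
~1000-point window would otherwise dominate the total sum of squares and
suppress ρ even for perfect fits.  ρ is clamped to [0, 100]; a constant
observed trace and an all-zero fit both score 0.  Trust thresholds: ρ ≥ 80
trustworthy, 70 < ρ < 80 borderline, ρ ≤ 70 not trustworthy (boundary
values classified per those inequalities); a resonance with no acceptable
candidate is reported not_found with ρ = 0.

Diastereotopic CH₂ protons are analysed as independent entries sharing the
carbon shift and couplings; they legitimately select the same ¹³C
multiplet.  No cross-metabolite disambiguation is attempted — a collision
(e.g. glutamate/glutamine) surfaces as a large Δppm in the report.

## Apparent-J scaling detection

Acquisition schemes multiply the observed splittings by an integer factor
s ∈ {1, 2, 4, 8}.  The detector re-runs alignment for a set of reference
resonances under each candidate and picks the candidate with the highest
mean adjusted score, falling back to the file/config value when no
candidate reaches ρ = 50.  During detection the peak-retention threshold
is relaxed to 0.15: when a singlet isotopomer dominates, the 50 % filter
would remove the very satellite lines whose spacing distinguishes the
candidates.  Detection of s = 8 is unreliable when weak multiplets are
present (widely spaced single lines mimic narrow patterns near the library
shift) — consistent with that acquisition regime being outside the
recommended operating range.

## Synthetic data

The generator forward-simulates what the analysis consumes: each entry
contributes a separable 2D peak — Gaussian ¹H profile (FWHM 0.02 ppm,
typical after apodisation) × fraction-weighted sum of its Lorentzian ¹³C
component traces — at library shifts perturbed uniformly within stated
ranges (defaults ±0.05 ppm ¹H, ±0.5 ppm ¹³C, emulating pH/matrix drift),
plus white Gaussian noise scaled so that max intensity / σ equals the
requested peak SNR.  Axis defaults mimic a zero-filled high-field
acquisition: ≈ 0.0076 ppm/point in ¹H and ≈ 0.0057 ppm/point in ¹³C.  The
¹³C linewidth default is 4.5 Hz (FWHM): processed high-field carbon lines
including apodisation broadening; appreciably narrower lines would be
under-sampled on an acquisition-realistic carbon grid (≈ 4.7 Hz/point
before zero-filling).  What the generator does *not* emulate: ¹H multiplet
structure, t₁ noise, baseline/phase distortions, solvent ridges, spectral
artefacts of non-uniform sampling (reduced sampling is represented purely
as reduced SNR), and strong-coupling effects.  Passing tests therefore
demonstrate correct recovery under ideal lineshapes and white noise, not
robustness to processing artefacts.

The benchmark suite spans the three study axes — full-quality replicates,
scalings {1, 2, 4, 8}, and degraded SNR — with a machine-readable truth
table, reproducible from a single seed.

## Numerical choices and study conditions

* ICA component count: smallest K explaining ≥ 99.5 % of noise-corrected
  variance.  Raw explained variance keeps growing with the noise floor
  (every noise direction carries equal variance), so eigenvalues are
  floor-corrected (floor = median of the trailing half of the spectrum)
  and those inside the noise band (< 2.5× floor, a conservative
  Marchenko–Pastur edge) are discarded; cap 10.  A noiseless rank-k region
  yields exactly k.
* Degenerate (noiseless, rank-deficient) regions make FastICA's
  unit-variance whitening divide by zero; the principal components, which
  are already the independent sources in that case, are used instead.
* Hill climbing treats improvements below 1e-9 (percentage points of ρ) as
  floating-point flatness and stops, so exactly flat profiles terminate.
* Stochastic validation runs the full pipeline on single-resonance spectra
  at peak SNR 20 with random simplex fractions and shift perturbations; at
  these conditions mean ρ ≈ 93 with mean |fraction error| ≈ 0.02 and
  assignments within one ¹H column / well under 0.1 ppm ¹³C.  Weak
  multiplets (intensity spread over four lines) bound ρ from above at
  fixed peak SNR; this mirrors the behaviour of real congested spectra.
* Source-separation oracles run in the signal-dominant regime (SNR 500):
  a window-wide cosine against the true trace saturates near 0.9 at SNR 20
  from accumulated baseline noise alone — irrespective of separation
  quality (cross-talk between sources stays below 2 %) — so low-noise
  conditions are required for the cosine to measure separation rather than
  the noise floor.  Noise robustness is covered by the end-to-end SNR-20
  checks instead.

## Known limitations

* Library shift values are compiled from public references; absolute
  agreement with any particular spectrometer database is not guaranteed,
  and analyses adapt only within the ±0.15/±3.0 ppm windows.
* Long-range ¹³C/¹³C couplings are parsed but excluded from enumeration by
  default (`include_long_range` enables them).
* Quantification uses a single ¹H column; very broad ¹H lines would leave
  signal on neighbouring columns unused.
* The NMRPipe and UCSF readers cover real-valued frequency-domain 2D data
  (the processed spectra this tool consumes), not complex or time-domain
  files.
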