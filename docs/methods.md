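# Methods

`camvitals` estimates four vital signs — pulse rate (PR), respiratory rate
(RR), percutaneous arterial oxygen saturation (SpO2) and tissue oxygen
saturation (StO2) — from RGB video of skin, by first inverting each frame
into skin chromophore concentrations and then reading the vitals off the
hemoglobin time series. This note records the models, the defaults and the
reasoning behind the design choices.

## Forward model: light transport in two-layer skin

Diffuse reflectance spectra (400–700 nm, 10 nm steps) are produced by a
Monte Carlo random walk in a plane-parallel skin model:

* **Epidermis** — 0.06 mm thick; absorption = bloodless baseline +
  `Cm` × melanosome absorption (power-law fit 6.6·10¹¹·λ⁻³·³³ cm⁻¹).
  `Cm` is the melanosome volume fraction.
* **Dermis** — semi-infinite (truncated at 10 mm, beyond which escaping
  weight is counted as transmitted; at the most transparent red
  wavelengths this truncation changes total reflectance by well under a
  percent); absorption = baseline + `CHbO`/`CHbR` × whole-blood
  absorption per unit blood volume fraction (150 g/L hemoglobin,
  molar extinction from the bundled table).
* **Scattering** — a single "typical skin" reduced-scattering spectrum
  μs′(λ) = 4.6·(λ/500 nm)⁻¹·³ mm⁻¹ in both layers; refractive index 1.4
  against air.

The tissue geometry and optical constants are stand-ins assembled from
standard skin-optics literature; they are deliberately configurable
(`SkinModel`) because real skin varies by site and subject, and because any
self-consistent forward model supports the closed-loop analysis below.

Transport details: implicit capture (photon weight decays by the
single-scattering albedo at each interaction), probabilistic Fresnel
reflection at index-mismatched boundaries, survival roulette below weight
10⁻⁴ with survival chance 0.1, per-wavelength independence, and a
deterministic counter-based RNG so every run is bit-reproducible for a
given seed. Crossed-polarizer acquisition is represented by omitting the
specular term: photons launch just below the surface with unit weight, and
the reported reflectance is the diffuse fraction of the light entering the
tissue. Energy (reflected + transmitted + absorbed weight = launched
weight) is asserted to 10⁻⁶ on every run, with the roulette ledger folded
into the absorbed tally so the identity holds exactly in expectation.

**Similarity-reduced scattering.** By default the walk uses isotropic
scattering with μs = μs′ (g = 0). By the similarity relation this
reproduces the diffuse reflectance of the anisotropic (g = 0.9,
Henyey–Greenstein) medium — we measured agreement within ~2 % over the
visible band except in the strongly absorbing Soret region, where the
model's absolute accuracy is limited by the two-layer idealization anyway —
at roughly a tenth of the compute. Setting `SkinModel(g=0.9)` restores the
full anisotropic walk (μs is always derived as μs′/(1−g)).

A scattering-only variant ("white" survey) records the per-layer path
lengths of escaping photons once per wavelength; reflectance for any
hemoglobin concentrations then evaluates analytically as
E[w·exp(−μa·L_dermis)]. The synthetic renderer uses this to produce long
videos without rerunning the transport, and because all frames share one
photon ensemble the frame-to-frame reflectance changes are smooth, as for
a real deterministic tissue.

## Colorimetry and camera calibration (M1)

Reflectance spectra map to CIE 1931 2° XYZ under a working illuminant by a
10 nm Riemann sum, normalized so a perfect reflector has Y = 100. The
default illuminant is D65; the illuminant used by a given camera system is
a config item, and the synthetic camera uses the same SPD for generation
and analysis so the loop is closed.

Camera RGB is assumed linear (the hardware this models reports 8 bits per
channel with no gamma), and is mapped to XYZ by a single affine transform
(1, R, G, B) → (X, Y, Z) — the 3×4 matrix **M1** — fitted by ordinary
least squares per output channel on a 24-patch color-checker table. Fit
residuals are reported per patch; a rank check rejects degenerate
(e.g. all-gray) tables.

## Inverse mapping (M2)

The estimator is a quadratic multiple regression per chromophore on the
feature vector (1, X, Y, Z, X², Y², Z², XY, XZ, YZ); the three coefficient
vectors form the 10×3 matrix **M2**. It is trained on 300 simulated
(state, XYZ) pairs with states Latin-hypercube sampled over

* Cm ∈ [1, 10] % (melanosome volume fraction),
* CHbT ∈ [0.2, 2] % (blood volume fraction),
* StO2 ∈ [0, 100] %,

sampling in (Cm, CHbT, StO2) space so blood volume and oxygenation are
independently stratified. Predictors are not standardized, so the fitted
coefficients slot directly into M2 in the feature order above. R² is
reported in-sample on the 300 training spectra. With 10⁴ photons per
wavelength the second-order fit reaches R² ≈ 0.98/0.97/0.93 for
Cm/CHbO/CHbR and the first-order fit ≈ 0.86/0.80/0.71 (the exact third
digit moves with the seed).

Negative concentration predictions are preserved in the raw maps and
counted, and clamped to zero only when deriving StO2 = 100·CHbO/CHbT
(flagged undefined where CHbT ≤ 0). Silently clamping the raw output would
hide calibration drift; the count is diagnostic.

The polynomial is least accurate near the edges of the training ranges —
in particular the estimated StO2 is biased several points low as true StO2
approaches 100 % (where CHbR → 0). Physiological tissue saturations sit
in the interior of the range, where held-out recovery is good.

## Vital-sign extraction

The ROI-mean CHbO/CHbR/CHbT series (frame rate 15 Hz in the modeled
system) is band-pass filtered by two linear-phase windowed-sinc (Hamming)
FIR filters:

* **cardiac**: 0.75–3 Hz (45–180 beats/min), 151 taps at 15 Hz,
* **respiratory**: 0.05–0.5 Hz (3–30 breaths/min), 2001 taps.

Design cut-offs are widened by half the transition width so the nominal
band edges sit near unity gain, and the tap mean is removed so DC gain is
exactly zero. The respiratory filter is long because holding 20 dB of
attenuation at half the 0.05 Hz cut-off requires a ~0.025 Hz transition;
at 15 Hz that is ≈2000 taps (133 s of signal). Offline processing applies
the filter forward–backward (zero phase); streaming mode filters causally
and shifts timestamps by the group delay. Samples within half a filter
length of either end are flagged invalid. The cardiac low edge is 0.75 Hz
(one widely used alternative is 0.7 Hz; both are config). If a user
configures overlapping bands the pipeline warns and proceeds — slow pulse
and fast respiration genuinely overlap, and silently proceeding would be
worse.

Peaks of the filtered CHbT signal are local maxima above 0.3× a rolling
amplitude envelope, separated by at least the band-appropriate minimum
(60/180 s cardiac, 60/30 s respiratory), with parabolic sub-sample
refinement so inter-peak intervals are not quantized to the frame grid
(at 15 Hz the grid alone would quantize 72 bpm to 75). A rate is 60 /
median inter-peak interval within a window — the median resists single
missed or spurious beats — and is flagged missing with fewer than two
peaks, never fabricated.

Per beat, the pulse amplitude on each hemoglobin channel is the value at
the cardiac peak minus the channel minimum over the preceding half
inter-beat interval; φ is the median over beats of PA_HbO/PA_HbR. SpO2
comes from the exponential calibration SpO2(φ) = A·exp(−φ/B) + C with
A < 0, B > 0, fitted by bounded nonlinear least squares to (φ, reference
SpO2) pairs — at least 5 pairs spanning ≥ 1.0 in φ, since a narrower span
cannot constrain an exponential. The calibration is empirical by design:
the mapping from true pulse oxygenation to measured φ passes through the
quadratic inversion, whose local Jacobian rescales the ratio, and the
fitted curve absorbs exactly that distortion (which is why the calibration
must be fitted on φ values *measured by this pipeline*, not on nominal
ones). StO2 needs no calibration: it is the ROI-mean 100·CHbO/CHbT of the
raw (unfiltered) maps, averaged per window.

Windowing: PR, φ and SpO2 use a 20 s window sliding by 1 s (≥ 2 cycles of
the slowest cardiac component); RR uses 60 s sliding by 5 s; each cardiac
window reports the RR of the nearest respiratory window. PR outside
45–180 bpm or RR outside 3–30 rpm is flagged out-of-range.

## Pipeline and flat-field correction

Frames are divided per pixel and channel by the illumination estimate
(white-diffuser frame / 0.99), which removes the vignette and the
illuminant color in one step — the diffuser serves both flat-field and
white-balance duty — and makes everything downstream invariant to global
illumination scaling. Near-zero diffuser pixels are masked; frames with
more than half the ROI flagged are marked low-quality. A scale-preserving
`mean` mode is available when absolute intensities matter. The ROI
defaults to a centered 300×300 square (clipped to the frame) and is split
into four quadrants to report across-quadrant standard deviations (sample
SD, n−1) as a spatial-variability diagnostic. Coordinates are 0-based
(row, col) with half-open extents. "Streaming" means the causal-filter
contract above, not a GUI.

## Synthetic data

The generator provides ground-truthed inputs for every stage:

* **Scenario** — 9 min at 15 Hz by default, mirroring a normoxia →
  4 min hypoxia → recovery protocol: SpO2 falls 99 → 87 %, StO2
  88 → 77 %, PR rises 72 → 80 bpm, RR eases 15 → 13.5 rpm, with 60 s
  cosine ramps. Baseline tissue: Cm = 4 %, CHbT = 1 % blood volume.
  The normal-tissue StO2 of 88 % reflects that the optically sampled pool
  mixes arterial with capillary/venous blood (venous saturation
  ~70–75 %), so tissue saturation must sit well below arterial SpO2.
* **Signals** — the baseline pool follows the StO2 trajectory and carries
  a multiplicative respiratory modulation (depth 2.5 % of CHbT,
  saturation-preserving); a zero-mean arterial pulse (depth 5 % of CHbT)
  rides on top with an asymmetric systolic waveform (narrow upstroke +
  dicrotic bump) so peak detection faces realistic shapes. The pulse is
  split between CHbO and CHbR so per-beat amplitudes satisfy
  PA_HbO/PA_HbR = φ(SpO2), using an exponential coupling that spans
  φ ≈ 1–4 over SpO2 ≈ 86–100 % (steep below φ = 2, nearly flat above 3).
* **Rendering** — white-survey reflectance → XYZ → a linear synthetic
  camera (XYZ→sRGB-primary mixing, white-normalized) with quadratic
  vignette, Gaussian sensor noise (SD 1 LSB) and 8-bit quantization, plus
  a matching diffuser frame and a 24-patch checker table for M1.
* **Reference traces** — truth + bias + seeded noise at a device-typical
  1 Hz, for exercising the Bland–Altman machinery.

What the generator does **not** emulate: head motion, facial structure and
specular highlights, exposure/white-balance drift, melanin heterogeneity
within the ROI, and camera nonlinearity. Passing closed-loop tests
therefore demonstrates the correctness and internal consistency of the
algorithm chain — not field accuracy on human faces, which depends on
exactly the artifacts excluded here.

## Evaluation statistics

Bland–Altman bias is mean(estimate − reference); precision is the sample
SD (n−1) of the differences; limits of agreement are bias ± 2·SD. RMSE
and Pearson r (with a t-distribution two-sided p) complete the set.
Estimate and reference series are aligned by nearest-neighbour matching
within half an estimation window; unmatched rows are dropped and counted.

## Numerical choices and limitations

* Photon budgets: 10⁴ photons/wavelength reproduces the regression R²
  ladder (the residual is dominated by model nonlinearity, not shot
  noise); 10⁵ is recommended for production M2 matrices. Reported
  per-wavelength standard errors let users trade speed against noise.
* The closed-loop analyses run at a reduced 96×96 frame size; since every
  pixel in a rendered frame shares the frame's chromophore state, frame
  size only changes the ROI averaging of sensor noise.
* Monte Carlo training noise and the emulator's photon ensemble each
  leave a small static offset in estimated concentrations (sub-point in
  StO2 at the default budgets).
* StO2 from a three-band color camera is a relative, model-dependent
  quantity; different scattering assumptions shift its absolute scale.
* φ is measured on band-passed signals; its absolute scale is
  calibration-absorbed (see above), and only its monotone relation to
  SpO2 is load-bearing.
* Bilirubin is not modeled; melanin outside the 1–10 % training range
  (very dark skin) degrades the inversion, a known limitation of the
  approach.
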