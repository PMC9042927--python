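# Methods

## Signal model and conventions

The intrinsic signal is the relative change of re-emitted light,
ΔR/R = (R(t) − B)/B, against a baseline B that is either the session mean
(Fourier analyses), a pre-stimulus window mean (trial analyses), or the
trial maximum.  Because in-vivo ΔR/R is permille-scale, the baseline
variants are interchangeable to first order; `Movie` containers enforce a
|ΔR/R| < 0.2 sanity bound to catch unit errors.  Invalid pixels (zero or
negative baseline, saturated chamber edges) are NaN-masked and the mask
propagates through every downstream map rather than raising.

Pixel coordinates are (row, col), 0-based; time is seconds from session
start with frame timestamps at frame centers.  **Phase is stored as time
in cycle (seconds in [0, T)), never radians**, fixed by the convention
that a noise-free, polarity-compensated cosine peaking at cycle time t₀
reads out phase t₀.  Amplitudes are normalized 2|c|/N so a unit cosine has
amplitude 1 and spectral amplitudes compare directly to trace excursions.

Signal polarity — whether activity raises or lowers backscattered
intensity — is wavelength-dependent through the HbO/HbR absorptivity
balance: −1 at 470, 530 and 850 nm, +1 at 625 and 730 nm, +1-but-ambiguous
at 590 nm.  Polarity is compensated by sign multiplication before any
phase is interpreted (a flipped sign shifts phase by exactly T/2).

Two deliberately *different* dispersion conventions coexist because the
analysis chain they belong to defines them so: `sem_trace` implements the
biased (÷n) SEM formula verbatim (so n = 1 gives SEM 0), whereas the Welch
t statistic uses sample (n−1) standard deviations.  Both are documented
here rather than silently "fixed".

## Stimulus schedules

Schedules are timing objects that double as synthesis ground truth and
decoding references.  The standard designs: the three-modality
parcellation session (periods 22 / 19.8 / 18 s × 18 / 20 / 22 cycles =
396 s, air-puff and noise trains centered in their cycles, dot-speed ramp
peaking mid-cycle); the tonotopy trial (2.7 s silence + 73 × 0.2 s
semitone pips + 2.7 s silence = 20 s, 440 Hz to 28,160 Hz, upward and
downward); retinotopy sweeps (20 s cycles; polar angle at 0.05 rounds/s
starting at 12 o'clock, eccentricity cosine-modulated between the
5–15° periphery and the 0–5° center); somatotopy (23 / 19 s × 19 / 23 =
437 s).  Session configs assert at construction that every cycle period
divides the session duration, making each stimulus frequency an exact
spectral bin.  Polar angle is measured in degrees clockwise from
12 o'clock as seen by the subject — the numeric convention is ours, since
published maps define it only pictorially.

## Synthetic data

The generator plants, per pixel and channel, a preferred stimulus time s,
an amplitude A (ΔR/R), and a shared hemodynamic delay δ, and renders
polarity · A · kernel((t − s − δ) mod T) plus i.i.d. Gaussian noise of
stated permille sd per frame.  Defaults follow the study conditions:
5 fps saved rate, 530 nm (polarity −1), amplitudes ~1‰, delays in the
physiologic 2.0–5.7 s range, 20-cycle sessions.  The default kernel is a
pure cosine at the channel frequency — matching the cosine-fit analysis
and making spectral recovery exact — with a raised-cosine bump option for
transient-response realism (its fundamental amplitude is attenuated
relative to A; the phase readout is preserved).  Noise is Gaussian at the
ΔR/R level rather than Poisson at the photon level: after 4×4×16 binning
the shot-noise floor is well approximated as a Gaussian relative sd, and
`shot_noise_floor` exposes the 1/√(N·reps) closed form with the photon
budget as an explicit input (it depends on unpublished sensor constants).
What passing tests on this generator do *not* show: robustness to
vascular artifacts, breathing/heartbeat periodicities, motion, or skull
inhomogeneity — none of which are emulated.

## Delay mapping

Combining a session with its time-reversed twin gives
δ₀ = ((φ_f + φ_r) mod T)/2 ∈ [0, T/2); the model admits the pair
{δ₀, δ₀ + T/2}.  The default disambiguation keeps the candidate in the
physiologic window [0, T/2) — for T ≈ 20 s this spans [0, 10) s, far above
any plausible hemodynamic delay — and an optional acceptance range
(2.0–5.7 s, endpoints inclusive; the source notation gives no open/closed
indication) acts as a stronger disambiguator.  Candidate pixels for delay
summaries are the top 10% by mean amplitude, ties broken by row-major
pixel order for determinism.

## Rendering

Tuning maps render in HSV: hue = cyclic tuning phase (wheel zero and
direction configurable; default phase 0 → red through the rainbow),
saturation = value = amplitude clipped at the 99th percentile of valid
pixels (per-subject percentile overrides are a `RenderSpec` parameter).
Tonotopy validity blanks pixels tuned outside the tone window or with
out-of-range delays.  The retinotopy composite packs polar angle into hue,
eccentricity into saturation (center-preferring → white), and motion
amplitude into value.  RGB summaries mask each channel by phase within its
most-intense-stimulus window ± 1 s tolerance.  Landscape assembly uses
least-squares affine transforms from ≥3 non-collinear landmark pairs
(bilinear resampling for scalar planes, nearest-neighbor for masks);
iso-t contours come from marching squares.  Hemisphere mirroring is an
explicit rendering flag, never applied silently to data.

## Photon transport and the resolution estimate

The medium is a 10 mm cube of three layers — skull 0.5 mm (n 1.56), gray
matter 1.3 mm, white matter 8.2 mm (n 1.37) — with absorption, scattering
and anisotropy per tissue and wavelength from the packaged table.  A note
on that table: the skull-scattering power law 1533.01·λ^−0.65 mm⁻¹ is
labeled "reduced" in the source literature yet reproduces the table's
plain μ_s column (typical bone μ_s, with g = 0.92 carried separately);
the table is treated as authoritative μ_s.  The same inconsistency makes
the quoted ~0.4 mm green-light depolarization distance differ from
1/μ_s′ = 0.48 mm computed from the table; we compute, and document, the
latter.

Transport is absorption-free: step lengths sampled from μ_s,
Henyey–Greenstein deflection with the layer's g, Snell refraction with
unpolarized Fresnel reflectance and total internal reflection at the
skull–air (1.56→1.0) and skull–gray (1.56→1.37) interfaces, launch at the
top-face center uniformly over the NA = 0.03 cone (refracted into the
skull, entry reflections rejected probabilistically), collection of
top-face exits whose angle stays within the NA cone (reciprocity with
wide-field epi-illumination through the imaging objective).  The
exit-angle test defaults to the *medium* frame — the direction sine just
inside the surface, the convention of voxel transport engines that record
detected-photon directions before refraction — with the in-air camera
cone (a factor n_skull narrower internally) as an option; the sensitivity
profile is insensitive to the choice, which mainly sets the collected
fraction (~2.4× higher in the medium frame).  Side and
bottom faces terminate trajectories.  Photons are killed beyond a
cumulative path of 300 mm by default; every launched photon ends as
exactly one of collected / escaped / terminated.  Each photon owns a
counter-based splitmix64 stream keyed by (seed, photon index), so runs are
bit-reproducible and collected photons can be replayed exactly — the
engine's two-pass design traces all photons first, then replays only the
collected ones to accumulate per-voxel gray-matter path lengths.

Absorption enters post hoc through Beer's law, W = exp(−Σᵢ μ_a(i)·x(i)).
The sensitivity profile raises gray-matter absorption by 10% in single
0.033 mm voxel columns and re-evaluates each stored photon's weight as an
exact exponential difference, ΔR(v) = Σ_p W_p·(1 − e^(−0.1·μ_a·x_v)) —
a linearized shortcut is never used, and tests verify equality with full
re-computation of the weight formula.

**Estimators.**  The per-voxel ΔR along the lateral center row of the
gray-matter grid is the defining estimator (`estimator="row"`; the x and
y center rows are averaged — equal in expectation by the 90° symmetry of
the geometry).  Its per-voxel statistics converge only at ~10⁹-photon
budgets; at the desk scale used here (10⁷ launched photons, ~6,000
collected) peak noise biases its half-max crossing low.  Because the
sensitivity field is exactly rotationally symmetric in expectation
(axisymmetric launch cone, symmetric cube), the default
`estimator="radial"` pools all voxels at equal lateral radius: each
photon's gray path is binned by radius and converted to the mean path
through one voxel of that annulus before the same exponential
re-weighting.  This measures the same per-voxel expectation with far
lower variance.  Even so, the raw half-max crossing remains
noise-limited — the innermost annuli shrink in area and the Beer weights
are heavy-tailed — so the radial FWHM is read off a variance-weighted fit
of a two-component stretched-exponential mixture,
a₁·e^(−(r/ℓ₁)^β₁) + a₂·e^(−(r/ℓ₂)^β₂), which accommodates the profile's
cusp-like core and broad tail; per-bin standard errors come from the
per-photon contribution second moments, and the raw interpolated crossing
is the fallback if the fit fails.  On pooled 4×10⁷-photon reference runs
the raw crossing gives 0.59 mm and the fit is unbiased against it to
within ~0.03 mm, with seed-to-seed spread ~±0.06 mm at 5×10⁶ photons.
σ is always the raw profile-weighted standard deviation of lateral
offset; the row estimator's FWHM is always the raw interpolated crossing.

**Problem sizes.**  The packaged acceptance run launches 1.5×10⁷ photons
with the path cap at 60 mm — at the green-light absorption
(μ_a = 0.638 mm⁻¹ in gray and white) any trajectory with a 60 mm tissue
path carries weight < e⁻³⁰, so the cap changes the profile negligibly
while bounding the longest random walks.  Under these conditions the
green-light profile has FWHM ≈ 0.6 mm; the full-scale (10⁹-photon, GPU)
estimate of the same quantity is 0.63 mm, and an empirical through-window
comparison brackets 0.60–0.70 mm.  The residual difference is within the
Monte-Carlo spread at the reduced budget plus engine-level model-choice
differences (boundary handling, launch/collection conventions).

The depth-tolerance closed form h ≥ D·n/(2·NA) (0.30 mm blur, n = 1,
NA = 0.03 → 5.0 mm) and the blood-based brain absorption
μ_a = f_blood·[Hb]·(0.25·ε_HbR + 0.75·ε_HbO) (3% blood volume, 2 mM
hemoglobin, base-10 extinctions in cm⁻¹/M converted to natural-log mm⁻¹)
live alongside the transport code.

## Resolution comparison of two maps

To ask how much a diffusing layer blurs a cortical map, the
higher-resolution map is convolved in the complex plane
(amplitude·e^(i·2π·phase/T), so phase disagreement cancels amplitude) with
the simulated sensitivity profile radially rescaled to a target FWHM, and
regressed against the lower-resolution map: amplitude through the origin
(uncentered r², the through-origin convention), tuning on the octave
scale (log₂(f/440)) with intercept.  Fits are iteratively reweighted
(Tukey bisquare) by default — the robust option of the original
analysis — with plain least squares as the tested oracle path, since the
original robust tuning constants are unpublished.  Target scales at or
below the pixel pitch are unresolvable on the lattice and return the map
unchanged (delta kernel).  The scan across scales reports the r²-maximizing
scale for amplitude and tuning separately; candidate pixels must clear
0.2‰ (low-resolution) and 1.5‰ (high-resolution) amplitude and carry valid
tunings in both maps.

## Known limitations

- The synthetic generator omits vascular/motion artifacts (above), so
  pipeline performance on real recordings will be worse than the planted
  round trips suggest.
- The transport engine models unpolarized photons; polarization-resolved
  visitation-depth analyses are out of scope (only the mean-free-path
  unit conversions are provided).
- The desk-scale Monte Carlo budget leaves a few-percent Monte-Carlo error
  on the resolution FWHM; the row estimator at this budget is
  noise-limited by design and kept for exactness checks.
- Motion correction is an optional external pre-step (rigid registration);
  the package assumes registered movies.
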