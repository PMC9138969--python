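# Methods

`envconn` implements a resting-state hdEEG network-connectivity pipeline —
sensor cleaning, a spherical-head eLORETA inverse, frequency-resolved
orthogonalized power-envelope correlation aggregated over six canonical
resting-state networks — together with scoring of a bimanual
motor-sequence-learning task and the group statistics that relate the two.
Because raw cohort recordings of this kind are rarely shareable, the package
ships a synthetic-data generator with exact ground truth, and every stage is
validated against it.

## Signal model and synthetic data

Each cortical source is a sum over the five canonical bands (delta 1–4,
theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz) of a narrowband carrier
multiplied by a slowly varying amplitude envelope:

    s_i(t) = Σ_b  exp(g_ib(t)) · c_ib(t) / ‖·‖

* **Carriers** `c_ib` are band-pass white noise, realized by frequency-domain
  shaping (a frequency-sampling FIR design with 1 Hz raised-cosine edge
  tapers), normalized to unit variance.
* **Log envelopes** `g_ib` are Gaussian processes low-passed at 0.5 Hz
  (4th-order Butterworth applied forward-backward at an internal 8 Hz
  envelope rate, cubic-spline interpolated to the signal rate) and scaled to
  a log-amplitude standard deviation of 0.5, i.e. an amplitude coefficient
  of variation of about 0.5 — envelopes wax and wane by factors of ~2–3, as
  band-limited resting envelopes do.
* **Coupling.** A coupling specification (pair, band, ρ) prescribes the
  Pearson correlation between the latent log envelopes of two sources in one
  band. All ground truth and all downstream measures are on the log scale,
  where `log exp(g) = g`: the latent Gaussian correlation equals the target
  exactly, so no Monte-Carlo calibration table is required. Correlations are
  injected by a Cholesky factor applied to the white envelope innovations
  before filtering (identical filters preserve instantaneous correlation).
* **Sensor model.** Sources are assigned fixed unit orientation vectors —
  drawn once per *subject* (`orientation_seed`), because orientation is an
  anatomical property shared between that subject's sessions — and projected
  through the spherical leadfield with a dipole moment of 20 nA·m; white
  sensor noise (default 1 µV), an ocular artifact (episodic raised-cosine
  blink pulses, frontal-weighted topography) and a muscular artifact
  (burst-modulated 30–80 Hz noise, edge-weighted topography) are added, and
  flagged bad channels are overwritten (flat: zeros; noisy: 20× the typical
  channel amplitude). The artifacts are deliberately non-Gaussian: that is
  both what real blinks/EMG look like and what makes them identifiable by
  ICA; Gaussian band-limited processes would be statistically invisible to a
  fixed-point ICA.
* **Keypress logs** follow the 6-element cyclic sequence 4-7-3-8-2-6 in
  blocks of 60 presses. Inter-key intervals are lognormal with block-level
  mean `mu_b = mu_inf + (mu0 − mu_inf)·exp(−(b−1)/tau)` (defaults: mu0 0.5 s,
  mu_inf 0.2 s, tau 4 blocks, CV 0.25); each press is replaced with
  probability `error_prob` (default 0.02) by a uniformly random wrong key.

What the generator does **not** emulate: 1/f background spectra, sleep
grapho-elements, event-related dynamics during practice, or non-stationary
artifact loads. Passing tests therefore demonstrate the correctness of the
computational chain under the stated signal model, not performance on real
recordings.

## Preprocessing

Bad channels are flagged by three configurable rules: a robust (median/MAD)
z-score of the **log** channel variance above 4 — variance is
multiplicatively distributed across a scalp topography, and robust scaling
prevents an extreme channel from masking itself; variance below 1e−3 of the
median (flat); or correlation below 0.2 with the mean of the six nearest
channels, where channels already failing the variance rules are excluded
from neighbour sets so that one noisy electrode cannot drag down its
region. Flagged channels are rebuilt by inverse-distance weighting over the
six nearest good channels (weights ∝ 1/d, normalized). Filtering is a
zero-phase linear-phase FIR band-pass (1–80 Hz, Hamming design, transition
width 25 % of the band edge), applied as a centred convolution on
per-channel demeaned, reflect-padded data so DC rejection is exact at the
edges; the average reference is then subtracted per sample. Artifact
attenuation fits FastICA (deflation variant — it converges
component-by-component and is robust to near-Gaussian trailing components;
`n_components = min(channels − 1, 40)`, seeded) and zeroes components whose
absolute correlation with an EOG proxy channel exceeds 0.7 (ocular) or whose
30–80 Hz share of spectral power exceeds 60 % (muscular), before remixing.

## Forward model and inverse

The head is three concentric spheres (brain/skull/scalp radii 80/85/92 mm,
conductivities 0.33/0.0042/0.33 S/m). Dipole potentials are a truncated
Legendre series (60 terms; the per-degree radial coefficients solve the 5×5
interface-continuity system with an insulating scalp, radii pre-scaled by
the scalp radius for conditioning). The series was verified against the
closed-form infinite-medium dipole potential and the homogeneous-sphere
solution, and 60 terms agree with 200 to better than 0.1 % over the source
grid. Geometry lives in a sphere-centred frame obtained by translating MNI
coordinates by (0, −25, 8) mm, an approximate best-fit scalp-sphere centre
under which all 21 ROI seeds lie inside the brain shell with margin;
electrodes are projected radially onto the scalp sphere.

The inverse is eLORETA: iterate `M ← (K W⁻¹ Kᵀ + α H)⁺`,
`W_j ← sqrtm(K_jᵀ M K_j)` with H the average-reference centering operator
and `α = alpha_frac · mean diag(K W⁻¹ Kᵀ)` (defaults: alpha_frac 0.05,
tolerance 1e−6 on the per-node relative Frobenius change of W, 100
iterations; non-convergence is recorded in the diagnostics, not raised).
The defining property — exact localization of noiseless point sources — is
tested on ~790-node grids. ROI time courses are the first principal
component of the stacked 3-orientation moments of all grid nodes within
6 mm of the ROI centre (the centre snaps to the nearest node on coarse
grids; the pipeline's template grid appends the 21 ROI centres as explicit
nodes), sign-aligned with the stack mean.

## Connectivity

ROI courses are decomposed with a 1 s Hann STFT at 50 % hop (1 Hz bins,
full frames only). For ROIs X, Y and bin f, the orthogonalized log-power
envelope correlation is

    Y⊥X(t,f) = Im( Y·conj(X) / |X| )
    r_XY(f)  = Pearson( log|X|², log|Y⊥X|² ),   r = (r_XY + r_YX)/2

with frames of zero magnitude or vanishing orthogonalized power dropped
pairwise (an entirely collinear pair — pure zero-lag leakage — yields a NaN
sentinel rather than a spurious value). Correlations are Fisher
z-transformed and averaged over half-open bands [lo, hi), so 8 Hz belongs
to alpha and 13 Hz to beta. A vectorized single-precision path computes all
pairs at once and is verified against the per-pair double-precision path.

**Attenuation is intrinsic to this estimator.** A 1 Hz bin of a 1 s frame
has two degrees of freedom, so `log|X|²` carries χ² noise of variance
ψ′(1) ≈ 1.64 around the log envelope, and the orthogonalized series
additionally carries log-sin² phase noise (variance ≈ π²/2). With latent
log-power envelope variance v the per-bin correlation is approximately
ρ·v/√((v+1.64)(v+6.5)) ≈ 0.2·ρ at the generator's v = 1. Measured band
z-values of ~0.05–0.2 for strong coupling are therefore expected — and are
the magnitude range this estimator produces on real resting hdEEG — while
rank order across pairs is preserved (the recovery tests assert ranking).
Orthogonalization removes zero-lag mixing exactly: leakage tests assert
|band z| < 0.1 under arbitrary real mixtures of a single source.

## Network aggregation and statistics

Within-network connectivity is the mean z over the ROI pairs inside a
network (DMN/DAN/VAN/LANG/MOT/VIS with 4/4/2/2/5/4 seeds → 6/6/1/1/10/6
pairs); between-network connectivity averages all cross pairs; sentinels are
excluded and counted. Session effects use the two-level repeated-measures
ANOVA, reported as F(1, n−1) = t² of the paired t with the sign of
mean(post − pre). Brain–behavior relations are Pearson correlations with
two-tailed p from the t-transform, listwise deletion per analysis cell.
BH-FDR is applied per band over two declared families: the six
motor-involving pairs of interest and all 21 pairs. All tests are
two-tailed.

The power utility integrates the exact sampling density of the Pearson
correlation under bivariate normality (Hotelling's form with a ₂F₁ factor,
evaluated in log space) over the two-sided rejection region defined by the
null t-transform, with adaptive quadrature (absolute tolerance 1e−10). At
the null it reproduces α to 1e−4; it matches Monte Carlo within sampling
error; and it reproduces the printed design values: power 96.1 % at
(ρ = 0.87, n = 10) and (ρ = 0.83, n = 12), α = 0.05.

## Behavioral scoring

A transition is a consecutive press pair; it is correct when both presses
match the expected cyclic sequence position, tracked by a pointer that
advances after *every* press (a wrong press is treated as a substitution,
so scoring resynchronizes at the next element). Block speed is the mean
inter-press interval over correct transitions; accuracy is 100 × correct /
total transitions (59 in a full block). Online gains contrast training
blocks 1–4 with 13–16; offline gains contrast the fatigue-free test blocks
17–20 with retest blocks 1–4; both are literal first-minus-last
differences, so positive speed gains and negative accuracy gains mean
improvement. One-sample two-tailed t tests assess gains against zero; the
block effect uses a one-way repeated-measures ANOVA with sphericity
assumed, F(b−1, (b−1)(n−1)).

## Study driver and problem sizes

`run_pipeline` simulates a cohort (default 20 subjects, two 5-minute
resting sessions at 250 Hz, 32-sensor Fibonacci montage, 12 mm source grid
plus the 21 ROI nodes), runs every stage, and emits per-subject network
matrices, behavioral summaries, a session-effect report and brain–behavior
correlations with online/offline speed gains, plus a manifest keyed by a
configuration hash; reruns are byte-identical. Per-subject seeds and the
subject-level orientation seed derive from the master seed.

The replicate suites in the test battery (null calibration and
planted-effect recovery, 20 replicates of a 20-subject cohort each) run the
same pipeline at reduced problem size — 60 s sessions at 200 Hz on a 13 mm
grid — chosen so a full battery completes on a single CPU in minutes; the
estimator-attenuation analysis above applies unchanged at these sizes. The
null-calibration check compares the cohort-level false-positive fraction
against 0.05 using the dispersion across replicates, since p-values within
a cohort are correlated through shared ROIs and bands.

## Known limitations

* The spherical three-shell head and template geometry replace individual
  FEM head models; absolute source amplitudes and localization away from
  the sphere's validity region are not meaningful.
* The per-bin envelope estimator is attenuated (see above); its output is
  comparable across pairs, sessions and subjects, not an unbiased estimate
  of the latent envelope correlation. Detecting a latent coupling *change*
  of Δz = 0.1 at the network level consequently requires far more data than
  a 20-subject cohort of short sessions provides; the corresponding
  planted-effect ranking test documents this sensitivity limit.
* eLORETA cross-talk between the 21 ROIs is substantial at 32–128 sensors;
  orthogonalization protects against false positives from it but further
  attenuates genuine coupling.
* No phase-based metrics, dynamic connectivity, cluster statistics or
  mixed-effects models.
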