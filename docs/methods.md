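# Methods

This note documents the models implemented in `megmyelin`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## Forward model

The field of a current dipole inside a homogeneous spherical conductor
is computed from the standard closed-form sphere solution.  A realistic
single-shell model fitted to an individual head surface would differ
quantitatively, but the two properties the downstream analysis relies on
— insensitivity to radial moments and exact linearity in the moment —
are shared, and the sphere solution is verifiable against an independent
construction: outside any spherically symmetric conductor the radial
field component equals that of the free-space current dipole, so a
spherical-harmonic expansion of the radial component determines the full
exterior field.  The test suite checks agreement to better than 0.1%
relative RMS (observed ~1e-10).

Units: geometry in mm (RAS, conductor centre at the origin; the
synthetic "MNI" frame is the world frame, i.e. identity registration),
moments in nAm, fields in tesla; conversion to SI happens at the module
boundary.  Axial gradiometers are modelled as a two-point difference
with a configurable 50 mm baseline.  Conductor radius defaults to 90 mm.

## Variational-Bayes dipole fitting

Two dipoles are fitted simultaneously to a single-time-point topography
y (N channels) under the generative model

    y = G(ρ) m + ε,  ε ~ N(0, λ⁻¹ I),
    ρ ~ N(ρ₀, σρ² I)  (σρ = 10 mm, bilateral auditory means),
    m ~ N(0, σm² I)   (σm = 100 nAm, all three directions per dipole),
    λ ~ Gamma(1e-6, 1e-6).

The mean-field posterior q(ρ)q(m)q(λ) (Gaussian, Gaussian, Gamma)
ascends the free energy

    F = ⟨log p(y|ρ,m,λ)⟩ − KL(q(m)‖p(m)) − KL(q(ρ)‖p(ρ)) − KL(q(λ)‖p(λ)),

with the expected likelihood evaluated under a first-order linearisation
of G(ρ)m around the posterior means (Jacobian by central differences,
0.05 mm step).  Given locations, the moment update is the exact
conditional Gaussian; the location mean moves by damped Gauss–Newton
steps — a step is shrunk (halved, down to 2⁻¹²) and finally rejected if
the fully re-evaluated F would decrease — so the recorded F trace is
non-decreasing by construction (asserted to 1e-8 per iteration).
Convergence at |ΔF| < 1e-6 nats or 200 iterations.  Ten restarts by
default: the first initialises at the prior location means, the rest
draw from the location prior; the highest final F wins, and a fixed seed
makes the winner reproducible.  Internally fields are scaled to
femtotesla so every quantity is O(1)–O(100) in double precision.

Because the radial moment direction is magnetically silent in a sphere,
its posterior variance stays near the prior (numerical leadfield rank 2).
The scalar dipole magnitude is therefore the norm of the posterior
moment mean projected onto the plane spanned by the two eigenvectors of
the moment covariance with the smallest eigenvalues (the most precise
directions).  Eigenvalues are ordered ascending; eigenvector signs are
fixed by making the first nonzero component positive, which makes the
degenerate isotropic case deterministic.

Sensor noise is assumed i.i.d. across channels (identity covariance up
to the inferred precision); no channel calibration or noise whitening is
modelled.

## Evoked chain

Trials whose worst-channel peak-to-peak amplitude exceeds 5 × 10⁻¹² T
are rejected (all channels are screened).  Averages are low-pass
filtered with a 4th-order Butterworth applied forward–backward (zero
phase; only the cutoff, 20 Hz, is externally constrained — order and
zero-phase application are this package's choices, recorded in the
evoked provenance).  Baseline correction subtracts the per-channel mean
over the 100 ms immediately preceding the noise-to-pitch transition.
The fitted time point is the maximum of global field power (RMS over
channels) in a post-transition window; "peak" is not otherwise defined
for a 275-channel topography, and GFP is the conventional scalar.  Flat
windows tie-break to the earliest sample with a warning.

## Quantitative maps and ROIs

R2\* is estimated per voxel by ordinary least squares of log signal on
echo time (8 echoes, 2.39–18.91 ms, 2.36 ms spacing); voxels with any
non-positive sample are flagged invalid rather than clipped.  R1 and MT
estimation involve acquisition-specific corrections and are out of
scope: those maps are inputs.

Smoothing uses a separable Gaussian kernel specified as FWHM
(σ = FWHM/2.3548 per axis, converted to voxels through the affine
scales); sheared/oblique affines are rejected rather than silently
resampled.  Tissue masks threshold probability volumes with strict
inequality (GM > 0.2, WM > 0.8); the inequality convention is a package
choice.  Sphere ROIs include a voxel iff its centre lies within the
radius (no partial-volume weighting).  ROI values are arithmetic means
over ROI ∧ GM voxels, and the pipeline order is fixed as smooth → mask →
average; ROI averages are taken from smoothed maps.

## Rank statistics

Spearman's ρ is the Pearson correlation of midranks.  The omnibus
statistic sums the 18 (map, ROI) coefficients; its null distribution
shuffles the moment column against the myelin rows (equivalent to
re-assigning hemisphere labels), sampling orderings uniformly with
replacement, with an exhaustive-enumeration mode for n ≤ 8 used by the
oracle tests.  The Monte-Carlo p-value uses the add-one convention
p = (1 + #{null ≥ observed})/(1 + n_perm), so p is never zero; the
one-tailed direction is "greater" (a positive structure–function
association is the hypothesis).  All ten hemisphere labels are permuted
independently; within-subject-pair shuffling is not implemented.  Cells
with zero rank variance abort in strict mode (default) or contribute 0
with a warning in lenient mode.

The repeated-measures ANOVA uses the classical within-subject
decomposition (hemispheres as blocks; no sphericity correction), with
Bonferroni-corrected alphas 0.05/3 per map and 0.05/15 for the pairwise
post-hoc paired t-tests.  The implementation is cross-checked against
statsmodels' AnovaRM in the tests.

## Bayesian GLMs and families

Each model regresses the ten moments on an intercept plus one myelin
regressor, with w ~ N(0, α⁻¹I), noise precision λ, and broad
Gamma(1e-6, 1e-6) hyperpriors on both precisions; closed-form mean-field
updates run to |ΔF| < 1e-6 nats (max 200 iterations).  With the
precisions pinned the model is conjugate and the converged F equals the
exact log marginal likelihood (tested to 1e-6 nats).

**Regressor scaling.**  Myelin regressors are standardised (centred and
unit variance), not merely centred.  The map types carry different units
and ranges (MT ~0.85 p.u., R1 ~0.63 s⁻¹, R2\* ~19 s⁻¹); with a shared
weight prior, raw-scale regressors make the complexity penalty depend on
those units, so evidence would rank scale rather than fit.
Standardising makes the 18 evidences comparable; the dependent variable
stays in nAm and the intercept absorbs its mean.

A log-evidence difference of 3 nats corresponds to posterior odds
exp(3) ≈ 20.09 under equal priors — "about 20 to 1".

The spatial-extent comparison fits three regressors of increasing
extent: TE1.2 alone; the whole koniocortex TE1 as a voxel-count-weighted
mean of TE1.0/TE1.1/TE1.2 (equal weights when counts are unavailable);
and the GM-masked whole-hemisphere mean.  Log Bayes factors are reported
relative to the worst model (normalised to zero).

Family comparison places a uniform prior over the complete 18-model grid
(equivalently, hierarchically uniform 1/3-per-map and 1/6-per-ROI
priors, identical because the grid is complete), computes model
posteriors ∝ exp(F) with log-sum-exp stabilisation, and sums members
within each ROI family (6) and each map family (3).  Each model uses a
single regressor; multi-regressor designs per model are not implemented.

## Synthetic-data generator

The generator's defaults are the study conditions: 10 hemispheres,
moments spanning 3.01–71.34 nAm, grey-matter map means MT 0.8521 p.u.,
R1 0.628 s⁻¹, R2\* 19.0 s⁻¹ (white matter 1.6855 / 0.944 / 20.0), 250
trials per subject, 3.5 s epochs (−0.75 to 2.75 s) at 600 Hz with the
pitch transition at 0.8 s, and a default target association of 0.42 —
the mean of the 18-cell reference correlation table (7.5637/18).

**Association model.**  A latent standard-normal hemisphere factor z
drives the moment through a strictly monotone map (probit-uniform onto
the moment range).  Each (map, ROI) myelin cell is
baseline + sd·(ρ_p z + √(1−ρ_p²) ε) with ρ_p = 2 sin(π ρ_s/6), the
latent Pearson value for which the population Spearman equals the
requested ρ_s; monotone marginal transforms leave Spearman untouched, so
the target is exact in population (and exactly ±1 at ρ_s = ±1).
`assoc_cells` restricts the shared factor to chosen cells for
planted-association recovery tests.  Per-ROI baselines impose the
inter-areal ordering TE1.1, TE1.0 > TE1.2 > TE3; cell noise sd is 3% of
the grey-matter mean.

**Evoked fields.**  The signal is the forward field of the two dipoles
times a Gaussian temporal bump of 40 ms sd peaking 147.7 ms after the
transition (the activation shape is otherwise unconstrained).  SNR is
defined on the trial average at the peak sample,
SNR = mean_ch(s_peak²)/(σ²/n_trials), because no standard definition is
imposed by the protocol; this makes the averaged SNR independent of the
trial count.  Note that this is *broadband* SNR: the 20 Hz zero-phase
low-pass in the evoked chain removes the large majority of white-noise
power at 600 Hz sampling, so a 10 dB broadband topography yields ~99%
explainable variance after filtering — which is why two-dipole fits at
"realistic" 10 dB exceed the 95%-variance-explained benchmark.

**Volumes.**  A 64³ grid at 3 mm (world frame shared with the MEG
geometry) holds a white-matter core (r < 60 mm, probability 0.95) and a
grey-matter ribbon (60–66 mm, probability 0.9); six disjoint 5 mm
spherical ROIs sit on the ribbon mid-surface, two of them along the
auditory prior directions.  Quantitative maps take their GM mean in the
ribbon (modulated by the per-ROI baseline offsets), WM means in the
core, a small positive background elsewhere, and 0.5% multiplicative
noise.  The anatomy is deliberately schematic: no gyrification, no
partial-volume structure, no registration error.

**What passing tests do not show.**  The generator emulates the
*structure* of the analysis inputs, not the physics of real data: no
correlated sensor noise or environmental artifacts, no head-model
mismatch (data and fit share the sphere), no co-registration error, no
inter-subject anatomical variability, and record-level myelin values are
distributional stand-ins (only distributional targets are available).
Recovery results therefore demonstrate the correctness and calibration
of the chain, not its field performance.

## Problem sizes

Defaults used by the shipped tests and scripts: the acceptance script
fits 10 replicate subjects (275 channels, 16 trials each, 3 restarts);
the recovery test runs 50 two-dipole fits; pipeline demos use 6–20
trials and 1–3 restarts, and permutation tests 200–5000 samples.  These
sizes were chosen so the whole suite runs comfortably on a single CPU
while keeping every statistical check adequately powered.

## Known limitations

- Homogeneous-sphere forward model only; no realistic single-shell or
  BEM surfaces, no EEG.
- The VB-ECD free energy uses a first-order linearisation for the
  location factor; location covariances are Laplace-style curvature
  estimates.
- Fixed two-dipole model; no model comparison over dipole counts.
- No segmentation, spatial normalisation, or partial-volume correction;
  tissue probabilities and atlases are inputs (or synthetic).
- No parametric p-values for the summed statistic and no FDR control
  (Bonferroni and permutation FWE only, by design).
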