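# megmyelin

Linking MEG source strength to cortical myeloarchitecture: a tested
implementation of the inference chain from evoked magnetic field
topographies to spatially specific structure–function statements.

## The scientific problem

Evoked MEG responses are generated by post-synaptic currents in aligned
cortical pyramidal cells; quantitative MRI multi-parameter maps (MPMs) —
magnetization-transfer saturation (MT, p.u.), longitudinal relaxation
rate (R1, s⁻¹) and apparent transverse relaxation rate (R2\*, s⁻¹) — are
indirect markers of the local myelin (and hence pyramidal-cell) density.
If structure predicts function, hemispheres with higher myelin-sensitive
values in the relevant auditory areas should show larger equivalent
current dipole (ECD) moments for the pitch-onset evoked response, and
that relationship should be spatially specific to the auditory cortex
rather than a property of the whole hemisphere.

The package implements every stage needed to test this on data with
known ground truth:

1. **Forward model** — analytic field of a current dipole in a
   homogeneous spherical conductor (radially silent, linear in the
   moment), for magnetometer and axial-gradiometer arrays.
2. **Evoked chain** — 5 pT peak-to-peak artifact rejection, trial
   averaging, zero-phase 20 Hz low-pass, 100 ms pre-transition baseline
   correction, global-field-power peak detection.
3. **VB-ECD** — variational-Bayes fitting of two dipoles to the peak
   topography under Gaussian location priors (bilateral auditory means,
   sd 10 mm) and moment priors (0 ± 100 nAm, all three directions).  The
   free energy F = ⟨log likelihood⟩ − KL(q‖prior) approximates the log
   model evidence; the scalar moment magnitude is the posterior mean
   projected onto the plane of the two most precise moment directions.
4. **Quantitative maps** — voxel-wise log-linear R2\* estimation from
   8-echo decays, 3 mm FWHM Gaussian smoothing, grey-matter (p > 0.2) and
   white-matter (p > 0.8) masks, atlas/spherical ROIs, GM-masked ROI
   means (fixed order: smooth → mask → average).
5. **Omnibus statistic** — the 3 maps × 6 ROIs Spearman correlations
   between hemisphere dipole moments and ROI myelin estimates, summed:
   S = Σₘ Σᵣ ρₘᵣ.  Significance by permuting the ten hemisphere labels
   (5000 permutations, one-tailed).
6. **Bayesian GLMs** — per-(map, ROI) models mᵢ = β₀ + β₁ xᵢ + εᵢ with
   variational log evidence; spatial-extent comparison (TE1.2 vs whole
   koniocortex TE1 vs whole hemisphere) and family comparison over the
   18-model grid with uniform 1/3 (maps) and 1/6 (ROIs) priors.
7. **Synthetic data** — a latent-Gaussian-copula generator that plants a
   chosen population Spearman association between moments and myelin,
   evoked epochs from known dipoles at controlled SNR, and NIfTI volumes
   with tissue probabilities and a labelled ROI atlas, all with stored
   ground truth.

## Worked example

`examples/04_correlation_permutation.py` plants a rank association of
0.42 across all cells for ten hemispheres and calibrates the summed
statistic against its permutation null:

```
Spearman correlations (moments vs myelin), 10 hemispheres:
     TE1.0  TE1.1  TE1.2    TE3   Patt   Post
MT   0.806  0.770  0.055  0.721  0.321  0.285
R1   0.661  0.758  0.564  0.370  0.333  0.430
R2*  0.067  0.382  0.103  0.418  0.927  0.491

summed r = 8.4606  (18 cells)
permutation null: mean +0.026, sd 2.954 (5000 label permutations)
one-tailed p = 0.0002
```

The 18 coefficients sum to 8.46; under label permutation the sum is
centred on zero with a spread of ~3, so the observed value sits far in
the upper tail and the association is detected.  The other examples
cover the forward model, a full two-dipole fit (variance explained
≈ 99% at 10 dB broadband SNR after the 20 Hz low-pass), R2\*/ROI
extraction, evidence-based spatial specificity, and the end-to-end
pipeline (`megmyelin run-all` on the command line does the same from a
YAML config).

## Layout

- `src/megmyelin/` — library modules (`forward`, `preprocess`, `vbecd`,
  `qmri`, `stats`, `bayesglm`, `synthgen`, `pipeline`, `io`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, numerical choices, limits
- `tests/` — pytest suite (unit, property and end-of-pipeline checks)
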