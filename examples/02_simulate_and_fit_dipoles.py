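"""Simulate a pitch-onset evoked field and refit its two dipoles.

Generates epoched sensor data from two tangential dipoles near the
bilateral auditory priors at 10 dB trial-averaged SNR, runs the evoked
chain (5 pT artifact rejection, averaging, 20 Hz zero-phase low-pass,
100 ms baseline correction), finds the global-field-power peak and fits
the two-dipole variational-Bayes model there.
"""

import numpy as np

from megmyelin import ConductorModel, fit_vb_ecd, make_sensor_array, moment_magnitude
from megmyelin.preprocess import (
    average_epochs,
    baseline_correct,
    find_peak_latency,
    lowpass,
    reject_artifacts,
)
from megmyelin.reference import TRANSITION_S
from megmyelin.synthgen import SimulationConfig, simulate_evoked_epochs, simulate_hemisphere_records

cfg = SimulationConfig(seed=7, snr_db=10.0, n_trials=16)
_, truth = simulate_hemisphere_records(cfg)
array = make_sensor_array(275)
conductor = ConductorModel()

epochs, _ = simulate_evoked_epochs(truth, array, cfg)
kept = reject_artifacts(epochs)
evoked = baseline_correct(lowpass(average_epochs(kept)))
latency, idx = find_peak_latency(evoked, (TRANSITION_S, TRANSITION_S + 0.4))

post = fit_vb_ecd(evoked.data[:, idx], array, conductor, n_restarts=3, seed=7)

print(f"peak latency: {(latency - TRANSITION_S) * 1e3:.1f} ms after the pitch transition")
print(f"variance explained: {post.variance_explained * 100:.2f}%")
print(f"free energy: {post.free_energy:.1f} nats")
for d, side in enumerate(("left", "right")):
    err = np.linalg.norm(post.location_mean_mm[d] - truth.dipole_locations_mm[d])
    mag = moment_magnitude(post, d)
    true_mag = np.linalg.norm(truth.dipole_moments_nAm[d])
    print(
        f"{side}: fitted {np.round(post.location_mean_mm[d], 1)} mm "
        f"(error {err:.1f} mm), magnitude {mag:.1f} nAm (truth {true_mag:.1f})"
    )
print()
print("The fit should explain >95% of the sensor variance and recover both")
print("locations to a few millimetres and both magnitudes to a few nAm.")
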