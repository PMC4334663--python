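"""Quantitative-map handling: R2* fitting and GM-masked ROI averages.

First recovers R2* from a synthetic 8-echo decay by the log-linear fit,
then builds a synthetic head volume (grey-matter ribbon, white-matter
core, six labelled ROIs) and extracts smoothed, grey-matter-masked ROI
means for the three quantitative maps.
"""

import numpy as np

from megmyelin import fit_r2star, make_synthetic_volumes
from megmyelin.qmri import extract_roi_table
from megmyelin.reference import ECHO_TIMES_S, ROI_LABELS
from megmyelin.synthgen import SimulationConfig, make_multiecho_signal

# --- R2* from a noisy multi-echo decay --------------------------------
signal = make_multiecho_signal(100.0, 19.0, noise_sd=1.0, seed=0)
r2s, amp, valid = fit_r2star(signal[:, None], ECHO_TIMES_S)
print(f"true R2* = 19.0 1/s, fitted = {r2s[0]:.2f} 1/s "
      f"(log-linear fit over {len(ECHO_TIMES_S)} echoes, 1% noise)")

# --- ROI extraction from synthetic volumes ----------------------------
vols = make_synthetic_volumes(SimulationConfig(seed=0))
table = extract_roi_table(vols["maps"], vols["gm_prob"], vols["rois"],
                          vols["atlas"], fwhm_mm=3.0)
print("\nGM-masked ROI means after 3 mm FWHM smoothing:")
print(f"{'ROI':8s}" + "".join(f"{m:>10s}" for m in ("MT", "R1", "R2*")))
for roi in ROI_LABELS:
    row = "".join(f"{table[(m, roi)]:10.3f}" for m in ("MT", "R1", "R2*"))
    print(f"{roi:8s}{row}")
print()
print("Koniocortex core ROIs (TE1.0, TE1.1) show the highest myelin-")
print("sensitive values, the transition zone TE1.2 sits lower, TE3 lowest —")
print("the inter-areal ordering the generator builds in.")
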