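"""Reference values for the auditory structure-function analysis.

Constants used throughout the package: the bilateral auditory dipole
location priors (MNI mm), the published 3 x 6 Spearman correlation table
between pitch-onset dipole moments and quantitative-map myelin estimates
over ten hemispheres, grey/white-matter means of the three quantitative
maps, and the multi-echo acquisition grid used for R2* estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Quantitative map types: magnetization-transfer saturation (p.u.),
#: longitudinal relaxation rate R1 (1/s), apparent transverse relaxation
#: rate R2* (1/s).  All three are indirect myelin markers.
MAP_TYPES = ("MT", "R1", "R2*")

#: Auditory regions of interest: cytoarchitectonic koniocortex sub-areas
#: TE1.0/TE1.1/TE1.2 on Heschl's gyrus, secondary auditory cortex TE3,
#: and two 5 mm spherical ROIs centred on the dipole location priors
#: (Patt) and on the mean fitted posterior locations (Post).
ROI_LABELS = ("TE1.0", "TE1.1", "TE1.2", "TE3", "Patt", "Post")

#: Bilateral dipole location priors in MNI mm (fMRI pitch contrast).
PRIOR_LOCATIONS_MM = {
    "left": np.array([-55.3, -12.9, 1.5]),
    "right": np.array([57.2, -8.8, -1.3]),
}

#: Mean fitted posterior dipole locations in MNI mm.
POSTERIOR_LOCATIONS_MM = {
    "left": np.array([-54.3, -30.0, -6.1]),
    "right": np.array([56.9, -28.6, -13.3]),
}

#: Location prior standard deviation (mm, per cardinal direction).
LOCATION_PRIOR_SD_MM = 10.0
#: Moment prior standard deviation (nAm, per cardinal direction).
MOMENT_PRIOR_SD_NAM = 100.0

#: Grey-matter means of the quantitative maps (MT in p.u., R1 and R2* in 1/s).
GM_MAP_MEANS = {"MT": 0.8521, "R1": 0.628, "R2*": 19.0}
#: White-matter means of the quantitative maps.
WM_MAP_MEANS = {"MT": 1.6855, "R1": 0.944, "R2*": 20.0}

#: Range of fitted dipole moment magnitudes over ten hemispheres (nAm).
MOMENT_RANGE_NAM = (3.01, 71.34)

#: 8 equidistant gradient-echo times, 2.39 to 18.91 ms (seconds).
ECHO_TIMES_S = np.arange(8) * 2.36e-3 + 2.39e-3

#: Published Spearman correlations between dipole moments and myelin
#: estimates for the five-subject auditory dataset (10 hemispheres),
#: one coefficient per (map, ROI) pair.  Their sum is the observed
#: summed-rank statistic of that dataset.
REFERENCE_CORRELATIONS = pd.DataFrame(
    [
        [0.3818, 0.3212, 0.5273, 0.1394, 0.3091, 0.4424],
        [0.5030, 0.4303, 0.6000, 0.4424, 0.4909, 0.2970],
        [0.3576, 0.5152, 0.3818, 0.3091, 0.5879, 0.5273],
    ],
    index=list(MAP_TYPES),
    columns=list(ROI_LABELS),
)

#: Artifact rejection threshold on peak-to-peak sensor amplitude (tesla).
ARTIFACT_THRESHOLD_T = 5e-12
#: Evoked low-pass cutoff (Hz) and baseline window length (s).
LOWPASS_HZ = 20.0
BASELINE_S = 0.100
#: Epoch timing: 3.5 s epochs from -0.75 s to +2.75 s around stimulus
#: onset at 600 Hz; the noise-to-regular-interval-noise transition that
#: elicits the pitch-onset response occurs 0.8 s after stimulus onset.
EPOCH_TSPAN_S = (-0.75, 2.75)
SFREQ_HZ = 600.0
TRANSITION_S = 0.8
#: Mean pitch-onset response peak latency after the transition (s).
PEAK_LATENCY_S = 0.1477
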