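"""Synthetic inputs for the full structure-function pipeline.

Everything the analysis consumes can be generated here with known ground
truth: sensor helmets, epoched evoked fields from two tangential
dipoles, quantitative volumes with tissue probabilities and a labelled
ROI atlas, multi-echo decay signals, and per-hemisphere record tables
with a controlled monotone association between dipole moments and
myelin estimates.

The moment-myelin association uses a latent Gaussian copula: a standard
normal hemisphere factor drives the moment through a strictly monotone
map, and each (map, ROI) myelin cell mixes that factor with independent
noise at a latent Pearson correlation of 2 sin(pi rho_s / 6), the value
for which the population Spearman correlation equals the requested
rho_s.  Any strictly monotone marginal transform leaves the Spearman
correlation untouched, so the target holds exactly in population.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import ndtr

from .forward import ConductorModel, GeometryError, SensorArray, dipole_field
from .preprocess import EpochSet
from .qmri import QuantitativeMap, ROIDefinition
from .reference import (
    ECHO_TIMES_S,
    EPOCH_TSPAN_S,
    GM_MAP_MEANS,
    MAP_TYPES,
    MOMENT_RANGE_NAM,
    PEAK_LATENCY_S,
    PRIOR_LOCATIONS_MM,
    ROI_LABELS,
    SFREQ_HZ,
    TRANSITION_S,
    WM_MAP_MEANS,
)
from .stats import HemisphereRecord


class ConfigError(ValueError):
    pass


#: Per-ROI myelin baselines as fractional offsets from the grey-matter
#: map mean; koniocortex core (TE1.1, TE1.0) above the lateral
#: transition zone TE1.2, which is above secondary cortex TE3.
ROI_BASELINE_OFFSET = {
    "TE1.0": 0.06,
    "TE1.1": 0.07,
    "TE1.2": 0.01,
    "TE3": -0.04,
    "Patt": 0.02,
    "Post": 0.03,
    "global": 0.0,
}


@dataclass
class SimulationConfig:
    """All tunable knobs of the generator; the seed fixes every draw."""

    seed: int = 0
    n_hemispheres: int = 10
    association_rho: float = 0.42
    snr_db: float = 10.0
    n_trials: int = 250
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 3.0
    map_means: dict = dc_field(default_factory=lambda: dict(GM_MAP_MEANS))
    wm_means: dict = dc_field(default_factory=lambda: dict(WM_MAP_MEANS))
    moment_range_nAm: tuple[float, float] = MOMENT_RANGE_NAM
    myelin_noise_frac: float = 0.03  # per-cell myelin sd as fraction of GM mean
    assoc_cells: list[tuple[str, str]] | None = None  # None -> association in all cells
    max_voxels: int = 2**24

    def __post_init__(self):
        if self.n_hemispheres < 4:
            raise ConfigError("need at least 4 hemispheres")
        if not -1.0 <= self.association_rho <= 1.0:
            raise ConfigError("association_rho must lie in [-1, 1]")
        if np.isnan(self.snr_db):
            raise ConfigError("snr_db must not be NaN")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be positive")
        if any(g <= 0 for g in self.grid_shape) or self.voxel_size_mm <= 0:
            raise ConfigError("grid shape and voxel size must be positive")
        lo, hi = self.moment_range_nAm
        if not 0 <= lo < hi:
            raise ConfigError("moment range must be increasing and non-negative")


@dataclass
class GroundTruth:
    """Everything needed to score recovery, stored with each dataset."""

    dipole_locations_mm: np.ndarray  # (n_hemispheres, 3)
    dipole_moments_nAm: np.ndarray  # (n_hemispheres, 3) tangential vectors
    roi_myelin: dict  # (hemisphere_id, map, roi) -> value
    hemisphere_ids: list[str]
    moment_magnitudes_nAm: np.ndarray


def make_sensor_array(
    n_channels: int,
    helmet_radius_mm: float = 120.0,
    theta_max_rad: float = 2.0,
    baseline_mm: float | None = 50.0,
) -> SensorArray:
    """Quasi-uniform helmet on an upper spherical cap (Fibonacci lattice).

    Channels are axial gradiometers by default (two-point difference
    with a 50 mm baseline); pass ``baseline_mm=None`` for magnetometers.
    Orientations are radial unit vectors.  Deterministic for fixed
    inputs.
    """
    if n_channels < 16:
        raise ConfigError("need at least 16 channels")
    if not 0 < theta_max_rad <= np.pi:
        raise ConfigError("theta_max_rad must lie in (0, pi]")
    i = np.arange(n_channels)
    # cos(theta) uniform on [cos(theta_max), 1] -> equal-area rings
    z = 1.0 - (1.0 - np.cos(theta_max_rad)) * (i + 0.5) / n_channels
    theta = np.arccos(z)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    ori = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    return SensorArray(
        positions_mm=helmet_radius_mm * ori,
        orientations=ori,
        baseline_mm=baseline_mm,
        name=f"synthetic cap ({n_channels} ch, R={helmet_radius_mm:g} mm)",
    )


def _tangential_unit(direction_rng, location):
    """A unit vector orthogonal to the (radial) location direction."""
    radial = location / np.linalg.norm(location)
    v = direction_rng.normal(size=3)
    v -= (v @ radial) * radial
    n = np.linalg.norm(v)
    while n < 1e-9:  # pragma: no cover - essentially impossible
        v = direction_rng.normal(size=3)
        v -= (v @ radial) * radial
        n = np.linalg.norm(v)
    return v / n


def simulate_hemisphere_records(cfg: SimulationConfig):
    """Hemisphere records with a controlled moment-myelin association.

    Returns (records, ground_truth).  Records carry one myelin value per
    (map, ROI) for the six auditory ROIs plus a per-map ``global``
    (whole-hemisphere) value.  With ``assoc_cells`` set, only those
    (map, ROI) cells share the latent factor; all others are independent
    of the moment.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_hemispheres
    rho_s = cfg.association_rho
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)

    z_mom = rng.normal(size=n)
    lo, hi = cfg.moment_range_nAm
    moments = lo + (hi - lo) * ndtr(z_mom)  # strictly monotone in the factor

    hemi_ids = [f"S{i // 2 + 1}-{'L' if i % 2 == 0 else 'R'}" for i in range(n)]
    rois = list(ROI_LABELS) + ["global"]
    assoc = (
        {(m, r) for m in MAP_TYPES for r in rois}
        if cfg.assoc_cells is None
        else set(cfg.assoc_cells)
    )
    records, truth_myelin = [], {}
    cell_values = {}
    for m in MAP_TYPES:
        gm_mean = cfg.map_means[m]
        sd = cfg.myelin_noise_frac * gm_mean
        for r in rois:
            eps = rng.normal(size=n)
            if (m, r) in assoc:
                z = rho_p * z_mom + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
            else:
                z = eps
            cell_values[(m, r)] = gm_mean * (1.0 + ROI_BASELINE_OFFSET[r]) + sd * z

    # dipole geometry: jittered auditory locations with tangential moments
    locs = np.empty((n, 3))
    mvecs = np.empty((n, 3))
    for i in range(n):
        base = PRIOR_LOCATIONS_MM["left" if i % 2 == 0 else "right"]
        locs[i] = base + rng.normal(0.0, 3.0, size=3)
        mvecs[i] = moments[i] * _tangential_unit(rng, locs[i])

    for i, hid in enumerate(hemi_ids):
        myelin = {}
        for (m, r), vals in cell_values.items():
            myelin[(m, r)] = float(vals[i])
            truth_myelin[(hid, m, r)] = float(vals[i])
        records.append(HemisphereRecord(hid, float(moments[i]), myelin))

    truth = GroundTruth(
        dipole_locations_mm=locs,
        dipole_moments_nAm=mvecs,
        roi_myelin=truth_myelin,
        hemisphere_ids=hemi_ids,
        moment_magnitudes_nAm=moments,
    )
    return records, truth


def activation_waveform(times_s: np.ndarray, transition_s: float = TRANSITION_S,
                        latency_s: float = PEAK_LATENCY_S, sd_s: float = 0.040) -> np.ndarray:
    """Smooth temporal activation: unit-peak Gaussian bump centred
    ``latency_s`` after the noise-to-pitch transition (40 ms sd)."""
    return np.exp(-0.5 * ((times_s - (transition_s + latency_s)) / sd_s) ** 2)


def simulate_evoked_epochs(
    truth: GroundTruth,
    array: SensorArray,
    cfg: SimulationConfig,
    conductor: ConductorModel | None = None,
    hemispheres: tuple[int, int] = (0, 1),
    seed: int | None = None,
):
    """Epoched sensor data from the two dipoles of one synthetic subject.

    The noiseless signal is the forward field of the two dipoles times a
    Gaussian temporal bump peaking ~150 ms after the transition.
    I.i.d. Gaussian sensor noise is scaled so the *trial-averaged* SNR at
    the peak sample equals ``cfg.snr_db``:
    SNR = mean_ch(signal_peak^2) / (sigma^2 / n_trials).
    Returns (epochs, clean) with ``clean`` the noiseless channels x
    samples signal.
    """
    if conductor is None:
        conductor = ConductorModel()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t0, t1 = EPOCH_TSPAN_S
    n_samp = int(round((t1 - t0) * SFREQ_HZ))
    times = t0 + np.arange(n_samp) / SFREQ_HZ

    topo = np.zeros(array.n_channels)
    for h in hemispheres:
        loc = truth.dipole_locations_mm[h]
        if np.linalg.norm(loc - conductor.centre_mm) >= conductor.radius_mm:
            raise GeometryError(f"dipole {h} lies outside the conductor")
        topo += dipole_field(loc, truth.dipole_moments_nAm[h], conductor, array)
    act = activation_waveform(times)
    clean = topo[:, None] * act[None, :]

    peak = int(np.argmax(act))
    sig_p2 = float(np.mean(clean[:, peak] ** 2))
    if np.isinf(cfg.snr_db):
        sigma = 0.0
    else:
        snr_lin = 10.0 ** (cfg.snr_db / 10.0)
        sigma = np.sqrt(cfg.n_trials * sig_p2 / snr_lin) if sig_p2 > 0 else 0.0
    if sig_p2 == 0 and not np.isinf(cfg.snr_db):
        # all-noise epochs: fall back to unit-variance sensor noise
        sigma = 1e-13
    data = clean[None] + rng.normal(0.0, sigma, size=(cfg.n_trials, array.n_channels, n_samp))
    epochs = EpochSet(data=data, sfreq_hz=SFREQ_HZ, t0_s=t0, transition_s=TRANSITION_S)
    return epochs, clean


def make_multiecho_signal(
    s0: float,
    r2star_per_s: float,
    echo_times_s: np.ndarray = ECHO_TIMES_S,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Mono-exponential multi-echo decay with additive Gaussian noise."""
    te = np.asarray(echo_times_s, float)
    if np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ConfigError("echo times must be positive and strictly increasing")
    if r2star_per_s < 0:
        raise ConfigError("R2* must be non-negative")
    signal = s0 * np.exp(-r2star_per_s * te)
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd, te.size)
    return signal


def _atlas_centres_mm(shell_radius_mm: float) -> dict[str, np.ndarray]:
    """Six disjoint ROI centre points on the cortical-ribbon mid surface."""
    uL = PRIOR_LOCATIONS_MM["left"] / np.linalg.norm(PRIOR_LOCATIONS_MM["left"])
    uR = PRIOR_LOCATIONS_MM["right"] / np.linalg.norm(PRIOR_LOCATIONS_MM["right"])
    dirs = {
        "TE1.0": uL,
        "TE1.1": uR,
        "TE1.2": np.array([0.0, 1.0, 0.3]),
        "TE3": np.array([0.0, -1.0, 0.3]),
        "Patt": np.array([0.7, 0.5, 0.6]),
        "Post": np.array([-0.7, 0.5, 0.6]),
    }
    return {k: shell_radius_mm * v / np.linalg.norm(v) for k, v in dirs.items()}


def make_synthetic_volumes(cfg: SimulationConfig):
    """Quantitative maps, tissue probabilities and a labelled ROI atlas.

    Geometry: a grey-matter spherical shell (probability ~0.9) around a
    white-matter core (~0.95) on a world grid centred at the origin
    (identity "MNI" registration).  Quantitative maps take their
    grey-matter mean inside the ribbon (modulated per-ROI by the same
    baseline offsets as the record generator) and white-matter means in
    the core.  Six disjoint 5 mm spherical ROIs sit on the ribbon.

    Returns a dict with keys ``maps`` (map type -> QuantitativeMap),
    ``gm_prob``, ``wm_prob``, ``atlas`` (int array), ``rois``
    (list of ROIDefinition, atlas-based), ``affine``.
    """
    shape = tuple(cfg.grid_shape)
    if min(shape) < 32:
        raise ConfigError("grid must be at least 32 voxels per axis")
    if int(np.prod(shape)) > cfg.max_voxels:
        raise ConfigError(f"voxel budget exceeded ({np.prod(shape)} > {cfg.max_voxels})")
    vs = cfg.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.array(shape) - 1) / 2.0

    idx = np.indices(shape, dtype=float)
    world = affine[:3, :3] @ idx.reshape(3, -1) + affine[:3, 3:4]
    r = np.linalg.norm(world, axis=0).reshape(shape)

    wm_radius, gm_outer = 60.0, 66.0
    core = r < wm_radius
    shell = (r >= wm_radius) & (r < gm_outer)

    gm_prob = np.full(shape, 0.01)
    gm_prob[shell] = 0.9
    gm_prob[core] = 0.05
    wm_prob = np.full(shape, 0.0)
    wm_prob[core] = 0.95
    wm_prob[shell] = 0.05

    centres = _atlas_centres_mm((wm_radius + gm_outer) / 2.0)
    atlas = np.zeros(shape, dtype=np.int16)
    world3 = world.reshape(3, *shape)
    for lab, roi in enumerate(ROI_LABELS, start=1):
        d2 = np.sum((world3 - centres[roi][:, None, None, None]) ** 2, axis=0)
        atlas[(d2 <= 5.0**2)] = lab

    rng = np.random.default_rng(cfg.seed + 1)
    maps = {}
    for m in MAP_TYPES:
        gm_val, wm_val = cfg.map_means[m], cfg.wm_means[m]
        vol = np.full(shape, 0.05 * gm_val)  # positive background
        vol[shell] = gm_val
        vol[core] = wm_val
        for lab, roi in enumerate(ROI_LABELS, start=1):
            sel = (atlas == lab) & shell
            vol[sel] = gm_val * (1.0 + ROI_BASELINE_OFFSET[roi])
        vol = vol * (1.0 + rng.normal(0.0, 0.005, size=shape))
        maps[m] = QuantitativeMap(np.abs(vol), m, affine)

    rois = [
        ROIDefinition(label=roi, atlas_label=lab)
        for lab, roi in enumerate(ROI_LABELS, start=1)
    ]
    return {
        "maps": maps,
        "gm_prob": QuantitativeMap(gm_prob, "GM-probability", affine),
        "wm_prob": QuantitativeMap(wm_prob, "WM-probability", affine),
        "atlas": atlas,
        "rois": rois,
        "affine": affine,
    }
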