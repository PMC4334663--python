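"""Generator contracts: geometry, association control, volumes, decays,
and determinism."""

import numpy as np
import pytest

from megmyelin import (
    SimulationConfig,
    correlation_table,
    fit_r2star,
    make_multiecho_signal,
    make_sensor_array,
    make_synthetic_volumes,
    simulate_evoked_epochs,
    simulate_hemisphere_records,
    spearman,
)
from megmyelin.reference import ECHO_TIMES_S, GM_MAP_MEANS, MAP_TYPES, ROI_LABELS
from megmyelin.synthgen import ConfigError


class TestSensorArray:
    def test_full_helmet_unit_orientations(self):
        arr = make_sensor_array(275, 120.0)
        assert arr.n_channels == 275
        assert np.allclose(np.linalg.norm(arr.orientations, axis=1), 1.0)

    def test_minimal_array_on_the_sphere(self):
        arr = make_sensor_array(16, 120.0)
        assert np.allclose(np.linalg.norm(arr.positions_mm, axis=1), 120.0)

    def test_quasi_uniform_spacing(self):
        """Nearest-neighbour spacing within a factor two of the ideal
        hexagonal cap packing, by brute-force pairwise distances."""
        arr = make_sensor_array(64, 110.0)
        pos = arr.positions_mm
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        cap_area = 2 * np.pi * 110.0**2 * (1 - np.cos(2.0))
        ideal = np.sqrt(cap_area / 64 * 2 / np.sqrt(3))
        assert nn.min() > ideal / 2
        assert nn.max() < ideal * 2

    def test_too_few_channels_rejected(self):
        with pytest.raises(ConfigError):
            make_sensor_array(8, 120.0)

    def test_deterministic(self):
        a = make_sensor_array(64, 110.0)
        b = make_sensor_array(64, 110.0)
        assert np.array_equal(a.positions_mm, b.positions_mm)


class TestEvokedEpochs:
    def setup_method(self):
        self.cfg = SimulationConfig(seed=0, n_trials=16, snr_db=10.0)
        _, self.truth = simulate_hemisphere_records(self.cfg)
        self.arr = make_sensor_array(32, baseline_mm=None)

    def test_infinite_snr_average_equals_clean_signal(self):
        cfg = SimulationConfig(seed=0, n_trials=4, snr_db=np.inf)
        _, truth = simulate_hemisphere_records(cfg)
        ep, clean = simulate_evoked_epochs(truth, self.arr, cfg)
        assert np.array_equal(ep.data.mean(axis=0), clean)

    def test_zero_moments_give_pure_noise_at_documented_level(self):
        cfg = SimulationConfig(seed=1, n_trials=8)
        _, truth = simulate_hemisphere_records(cfg)
        truth.dipole_moments_nAm[:] = 0.0
        ep, clean = simulate_evoked_epochs(truth, self.arr, cfg)
        assert np.all(clean == 0)
        assert ep.data.var() == pytest.approx((1e-13) ** 2, rel=0.05)

    def test_trial_averaged_snr_within_one_db(self):
        ep, clean = simulate_evoked_epochs(self.truth, self.arr, self.cfg)
        noise = ep.data.mean(axis=0) - clean
        peak = int(np.argmax(clean.std(axis=0)))
        snr_db = 10 * np.log10(np.mean(clean[:, peak] ** 2) / noise.var())
        assert snr_db == pytest.approx(10.0, abs=1.0)

    def test_epoch_timing_matches_protocol(self):
        ep, _ = simulate_evoked_epochs(self.truth, self.arr, self.cfg)
        assert ep.sfreq_hz == 600.0
        assert ep.data.shape == (16, 32, 2100)
        assert ep.times[0] == pytest.approx(-0.75)
        assert ep.transition_s == pytest.approx(0.8)

    def test_dipole_outside_conductor_rejected(self):
        self.truth.dipole_locations_mm[0] = [150.0, 0.0, 0.0]
        from megmyelin import GeometryError

        with pytest.raises(GeometryError):
            simulate_evoked_epochs(self.truth, self.arr, self.cfg)


class TestHemisphereRecords:
    def test_independent_records_have_zero_mean_association(self):
        """rho = 0: the mean Spearman coefficient over 1000 seeded
        replicates stays within +/-0.05 of zero."""
        means = []
        for s in range(1000):
            cfg = SimulationConfig(seed=s, association_rho=0.0)
            recs, _ = simulate_hemisphere_records(cfg)
            table = correlation_table(recs)
            means.append(np.mean(list(table.r.values())))
        assert abs(np.mean(means)) < 0.05

    def test_perfect_association_is_exact(self):
        cfg = SimulationConfig(seed=2, association_rho=1.0)
        recs, _ = simulate_hemisphere_records(cfg)
        table = correlation_table(recs)
        assert all(v == pytest.approx(1.0) for v in table.r.values())

    def test_intermediate_association_at_large_n(self):
        cfg = SimulationConfig(seed=3, association_rho=0.6, n_hemispheres=200)
        recs, _ = simulate_hemisphere_records(cfg)
        mom = [r.moment_nAm for r in recs]
        vals = [r.myelin[("R1", "TE1.2")] for r in recs]
        assert spearman(mom, vals) == pytest.approx(0.6, abs=0.1)

    def test_moments_within_configured_range(self):
        recs, truth = simulate_hemisphere_records(SimulationConfig(seed=4))
        lo, hi = 3.01, 71.34
        assert all(lo <= r.moment_nAm <= hi for r in recs)
        # tangential magnitude of the truth vectors equals the record moment
        for i, r in enumerate(recs):
            assert np.linalg.norm(truth.dipole_moments_nAm[i]) == pytest.approx(
                r.moment_nAm
            )

    def test_roi_baseline_ordering(self):
        """Core koniocortex above the lateral transition zone above TE3 for
        the MT and R1 maps (population ordering of cell means)."""
        cfg = SimulationConfig(seed=5, n_hemispheres=400, association_rho=0.0)
        recs, _ = simulate_hemisphere_records(cfg)
        for m in ("MT", "R1"):
            mean = {
                roi: np.mean([r.myelin[(m, roi)] for r in recs])
                for roi in ("TE1.0", "TE1.1", "TE1.2", "TE3")
            }
            assert mean["TE1.1"] > mean["TE1.2"] > mean["TE3"]
            assert mean["TE1.0"] > mean["TE1.2"]

    def test_ground_truth_travels_with_records(self):
        recs, truth = simulate_hemisphere_records(SimulationConfig(seed=6))
        for r in recs:
            for (m, roi), v in r.myelin.items():
                assert truth.roi_myelin[(r.hemisphere_id, m, roi)] == v

    def test_determinism(self):
        a, _ = simulate_hemisphere_records(SimulationConfig(seed=7))
        b, _ = simulate_hemisphere_records(SimulationConfig(seed=7))
        assert all(
            x.moment_nAm == y.moment_nAm and x.myelin == y.myelin
            for x, y in zip(a, b)
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_hemispheres=3)
        with pytest.raises(ConfigError):
            SimulationConfig(association_rho=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(snr_db=float("nan"))


@pytest.fixture(scope="module")
def vols():
    return make_synthetic_volumes(SimulationConfig(seed=0))


class TestVolumes:
    def test_probabilities_in_unit_interval(self, vols):
        for key in ("gm_prob", "wm_prob"):
            v = vols[key].values
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_pure_gm_mean_matches_map_means(self, vols):
        shell = vols["gm_prob"].values > 0.2
        pure = shell & (vols["atlas"] == 0)
        assert vols["maps"]["R1"].values[pure].mean() == pytest.approx(0.628, abs=0.01)
        assert vols["maps"]["MT"].values[pure].mean() == pytest.approx(0.8521, abs=0.02)
        assert vols["maps"]["R2*"].values[pure].mean() == pytest.approx(19.0, abs=0.2)

    def test_atlas_labels_disjoint_by_exhaustive_scan(self, vols):
        atlas = vols["atlas"]
        labels = [lab for lab in np.unique(atlas) if lab != 0]
        assert sorted(labels) == [1, 2, 3, 4, 5, 6]
        total = sum(int((atlas == lab).sum()) for lab in labels)
        assert total == int((atlas > 0).sum())  # no voxel carries two labels
        for lab in labels:
            assert (atlas == lab).sum() > 0

    def test_maps_positive(self, vols):
        for m in MAP_TYPES:
            assert vols["maps"][m].values.min() > 0

    def test_voxel_budget_enforced(self):
        cfg = SimulationConfig(seed=0, grid_shape=(512, 512, 512))
        with pytest.raises(ConfigError):
            make_synthetic_volumes(cfg)

    def test_small_grid_rejected(self):
        with pytest.raises(ConfigError):
            make_synthetic_volumes(SimulationConfig(seed=0, grid_shape=(16, 32, 32)))


class TestMultiEcho:
    def test_noiseless_closed_form(self):
        sig = make_multiecho_signal(100.0, 19.0)
        assert sig[0] == pytest.approx(100.0 * np.exp(-19.0 * 0.00239))
        assert len(sig) == 8

    def test_no_decay_is_constant(self):
        assert np.allclose(make_multiecho_signal(55.0, 0.0), 55.0)

    def test_monte_carlo_recovery(self):
        """500 noisy decays at 1% noise: the fitted R2* recovers the truth
        within 1.5/s."""
        ests = []
        for s in range(500):
            sig = make_multiecho_signal(100.0, 19.0, noise_sd=1.0, seed=s)
            if np.any(sig <= 0):
                continue
            r2s, _, _ = fit_r2star(sig[:, None], ECHO_TIMES_S)
            ests.append(r2s[0])
        assert np.mean(ests) == pytest.approx(19.0, abs=1.5)

    def test_bad_echo_grid_rejected(self):
        with pytest.raises(ConfigError):
            make_multiecho_signal(1.0, 1.0, np.array([0.004, 0.002]))
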