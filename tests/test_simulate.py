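import numpy as np
import pytest

from gensmr.geometry import StateSpace, TrapArray, make_clustered_design
from gensmr.model import Parameters
from gensmr.simulate import (
    default_live_traps,
    simulate_dataset,
    simulate_marking,
    simulate_population,
    simulate_resighting,
    simulate_telemetry,
    simulate_transience,
)

SS = StateSpace(0.0, 100.0, 0.0, 100.0)


class TestPopulation:
    def test_fixed_n_exact_density(self):
        t = simulate_population(SS, n=100, rng=0)
        assert t.n == 100
        assert t.density_per_100km2 == pytest.approx(1.0)
        assert np.all(SS.contains(t.s_m))

    def test_all_male_when_p_sex_zero(self):
        t = simulate_population(SS, n=50, p_sex=0.0, rng=1)
        assert np.all(t.sex == 0)

    def test_female_fraction_matches_bernoulli_expectation(self):
        """Mean female fraction over replicates ~ p_sex (binomial MC check)."""
        p = 0.33
        fracs = [
            simulate_population(SS, n=1000, p_sex=p, rng=seed).sex.mean()
            for seed in range(60)
        ]
        se = np.sqrt(p * (1 - p) / 1000 / len(fracs))
        assert np.mean(fracs) == pytest.approx(p, abs=4 * se)

    def test_density_and_n_mutually_exclusive(self):
        with pytest.raises(ValueError):
            simulate_population(SS, density_per_100km2=1.0, n=10)
        with pytest.raises(ValueError):
            simulate_population(SS)


class TestMarking:
    live = TrapArray("live", [[50.0, 50.0], [60.0, 50.0]], np.full((2, 1), 20.0))

    def test_zero_rate_marks_nobody(self):
        t = simulate_population(SS, n=200, rng=2)
        y = simulate_marking(t, self.live, 0.0, 5.0, rng=3)
        assert y.sum() == 0
        assert t.marked.sum() == 0

    def test_capture_probability_at_zero_distance(self):
        """At d = 0 the per trap-day capture probability is 1 - e^-lam0."""
        t = simulate_population(SS, n=4000, rng=4)
        t.s_m[:] = [50.0, 50.0]  # everyone on the first trap
        live1 = TrapArray("live", [[50.0, 50.0]], np.full((1, 1), 1.0))
        y = simulate_marking(t, live1, 0.05, 5.0, rng=5)
        p = 1 - np.exp(-0.05)
        se = np.sqrt(p * (1 - p) / 4000)
        assert y.mean() == pytest.approx(p, abs=4 * se)

    def test_target_cap(self):
        t = simulate_population(SS, n=500, rng=6)
        simulate_marking(t, self.live, 0.5, 10.0, rng=7, target_n_marked=5)
        assert t.marked.sum() == 5


class TestTransience:
    def test_zero_scale_identity(self):
        t = simulate_population(SS, n=30, rng=8)
        s_r = simulate_transience(t, 0.0, SS, rng=9)
        np.testing.assert_array_equal(s_r, t.s_m)

    def test_small_scale_displacement_sd(self):
        """Far from edges, per-axis displacement sd ~ sigma_t."""
        t = simulate_population(SS, n=4000, rng=10)
        t.s_m[:] = [50.0, 50.0]
        s_r = simulate_transience(t, 2.0, SS, rng=11)
        disp = s_r - t.s_m
        assert disp.std(axis=0) == pytest.approx([2.0, 2.0], rel=0.1)
        assert abs(disp.mean()) < 0.15

    def test_corner_truncation_pushes_inward(self):
        t = simulate_population(SS, n=2000, rng=12)
        t.s_m[:] = [0.0, 0.0]
        s_r = simulate_transience(t, 5.0, SS, rng=13)
        assert np.all(SS.contains(s_r))
        assert s_r.mean(axis=0).min() > 0.5  # pushed toward the interior


class TestResighting:
    cams = TrapArray("camera", [[48.0, 50.0], [52.0, 50.0]], np.ones((2, 10)))

    def _marked_pop(self, n=300, seed=14):
        t = simulate_population(SS, n=n, rng=seed)
        t.marked[:3] = True
        return t

    def test_zero_rate_empty(self):
        t = self._marked_pop()
        y, u = simulate_resighting(t, self.cams, 0.0, 5.0, rng=15)
        assert y.sum() == 0 and len(u) == 0

    def test_known_sex_fraction(self):
        t = self._marked_pop(n=800, seed=16)
        _, u = simulate_resighting(t, self.cams, 0.3, 8.0, p_sex_observed=0.52, rng=17)
        assert len(u) > 200
        frac = (u["obs_sex"] >= 0).mean()
        se = np.sqrt(0.52 * 0.48 / len(u))
        assert frac == pytest.approx(0.52, abs=4 * se)

    def test_observed_sex_matches_truth_when_known(self):
        t = self._marked_pop(n=400, seed=18)
        _, u = simulate_resighting(t, self.cams, 0.2, 8.0, p_sex_observed=1.0, rng=19)
        known = u[u["obs_sex"] >= 0]
        assert np.array_equal(
            known["obs_sex"].to_numpy(), t.sex[known["true_individual"]]
        )

    def test_premarking_detections_are_unmarked_records(self):
        """A marked individual's detections on occasions before its marking
        occasion come out as identity-free records, never known counts."""
        t = self._marked_pop(n=50, seed=20)
        t.s_r[t.marked_indices] = [50.0, 50.0]
        m = np.ones((3, 10), dtype=int)
        m[:, :4] = 0  # all three marked only from occasion 5
        y, u = simulate_resighting(t, self.cams, 0.5, 5.0, m_matrix=m, rng=21)
        assert y[:, :, :4].sum() == 0
        assert (u["occasion"] <= 4).sum() > 0

    def test_dead_occasions_produce_nothing(self):
        t = self._marked_pop(n=30, seed=22)
        t.s_r[t.marked_indices] = [50.0, 50.0]
        m = np.ones((3, 10), dtype=int)
        m[0, :] = 2
        y, u = simulate_resighting(t, self.cams, 1.0, 5.0, m_matrix=m, rng=23)
        assert y[0].sum() == 0
        dead_idx = t.marked_indices[0]
        assert (u["true_individual"] == dead_idx).sum() == 0


class TestTelemetry:
    def test_complete_occasions(self):
        t = simulate_population(SS, n=10, rng=24)
        t.marked[:4] = True
        tel = simulate_telemetry(t, 5.0, 17, missingness=0.0, rng=25)
        assert len(tel) == 4
        assert all(len(x) == 17 for x in tel)

    def test_location_moments(self):
        """Sample mean near the activity center, per-axis sd near sigma_d."""
        t = simulate_population(SS, n=2, rng=26)
        t.marked[:] = True
        t.s_r[:] = [40.0, 60.0]
        tel = simulate_telemetry(t, 3.0, 4000, missingness=0.0, rng=27)
        xy = tel[0][:, 1:]
        assert xy.mean(axis=0) == pytest.approx([40.0, 60.0], abs=0.25)
        assert xy.std(axis=0) == pytest.approx([3.0, 3.0], rel=0.05)

    def test_missingness_thins(self):
        t = simulate_population(SS, n=5, rng=28)
        t.marked[:] = True
        tel = simulate_telemetry(t, 5.0, 400, missingness=0.25, rng=29)
        counts = np.array([len(x) for x in tel])
        assert counts.mean() == pytest.approx(300, rel=0.1)


class TestFullPipeline:
    def test_dataset_consistency(self):
        data, truth = simulate_dataset(seed=42)
        n_m = truth.marked.sum()
        assert data.n_marked == n_m
        assert data.y_mark.shape[0] == n_m
        assert len(data.telemetry) == n_m
        # marking counts bounded by exposure
        assert np.all(data.y_mark <= data.exposure.E_M)
        # unmarked records come from unmarked (or pre-marking) individuals
        marked_set = set(truth.marked_indices)
        overlap = set(data.unmarked["true_individual"]) & marked_set
        assert not overlap  # default: everyone marked from occasion 1

    def test_reproducible(self):
        d1, t1 = simulate_dataset(seed=7)
        d2, t2 = simulate_dataset(seed=7)
        assert t1.n == t2.n
        np.testing.assert_array_equal(d1.y_resight_marked, d2.y_resight_marked)
        assert d1.unmarked.equals(d2.unmarked)

    def test_realized_statistics_near_expectations(self):
        """Averages over seeds stay near large-carnivore survey magnitudes:
        tens of marked-animal captures are not expected (order 10 marked of
        ~130 animals) and total camera detections of order 10^2."""
        marked, records = [], []
        for seed in range(8):
            data, truth = simulate_dataset(seed=seed)
            marked.append(truth.marked.sum())
            records.append(len(data.unmarked) + int(data.y_resight_marked.sum()))
        assert 4 <= np.mean(marked) <= 30
        assert 30 <= np.mean(records) <= 250

    def test_live_traps_cluster_around_camera_clusters(self):
        """Every default live-trap sits within the stated spread of a camera
        cluster: the marking process is spatially clustered near cameras."""
        cams = make_clustered_design(4, 3, 3, 3.5)
        live = default_live_traps(cams, spread_km=6.0, rng=0)
        centers = cams.coords.reshape(4, 9, 2).mean(axis=1)
        d = np.linalg.norm(
            live.coords[:, None, :] - centers[None, :, :], axis=-1
        ).min(axis=1)
        assert np.all(d <= 6.0 * np.sqrt(2) + 1e-9)
        # traps spread across all clusters, not piled on one
        nearest = np.argmin(
            np.linalg.norm(live.coords[:, None, :] - centers[None, :, :], axis=-1),
            axis=1,
        )
        assert len(set(nearest.tolist())) == 4
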