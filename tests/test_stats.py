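"""Log-normal fits, event pairing, mean shift, ellipses and correlations."""

import numpy as np
import pytest

from lisca.fitting import EventRecord, EventSet, RosRate
from lisca.stats import (
    cluster_ellipse,
    diagonal_partition,
    fit_lognormal,
    mean_shift_cluster,
    pair_events,
    pearson,
    rate_vs_event,
)
from lisca.synthetic import bimodal_pair_config, simulate_cohort


class TestFitLognormal:
    def test_hand_computed_log_moments(self):
        e = np.e
        ln = fit_lognormal([e, e, e**3, e**3])
        assert ln.mu == pytest.approx(2.0)
        assert ln.sigma == pytest.approx(1.0)
        assert ln.mode == pytest.approx(e)

    def test_degenerate_constant_sample(self):
        ln = fit_lognormal([12.0, 12.0, 12.0])
        assert ln.mu == pytest.approx(np.log(12.0))
        assert ln.sigma == 0.0
        assert ln.mode == pytest.approx(12.0)

    def test_mode_below_median(self, rng):
        ln = fit_lognormal(np.exp(rng.normal(2.0, 0.4, size=500)))
        assert ln.mode < ln.median

    @pytest.mark.parametrize("bad", [[1.0, 2.0], [1.0, -2.0, 3.0], [0.0, 1.0, 2.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_lognormal(bad)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 24.0])
    def test_scale_equivariance(self, rng, scale):
        times = np.exp(rng.normal(2.0, 0.5, size=200))
        base = fit_lognormal(times)
        scaled = fit_lognormal(scale * times)
        assert scaled.mu == pytest.approx(base.mu + np.log(scale), abs=1e-9)
        assert scaled.sigma == pytest.approx(base.sigma, abs=1e-9)


def _event_set(marker, records):
    return EventSet(
        records=[
            EventRecord(cid, marker, "breakdown", t, quality)
            for cid, t, quality in records
        ]
    )


class TestPairEvents:
    def test_inner_join_on_cell_id(self):
        e1 = _event_set("LMP", [(1, 5.0, "accepted"), (2, 6.0, "accepted"), (3, 7.0, "accepted")])
        e2 = _event_set("MOMP", [(2, 8.0, "accepted"), (3, 9.0, "accepted"), (4, 10.0, "accepted")])
        pairs = pair_events(e1, e2)
        assert pairs.n == 2
        assert set(pairs.table.cell_id) == {2, 3}

    def test_disjoint_ids_give_empty_pairing(self):
        e1 = _event_set("LMP", [(1, 5.0, "accepted")] + [(10 + i, 5.0, "accepted") for i in range(2)])
        e2 = _event_set("MOMP", [(99, 8.0, "accepted")])
        assert pair_events(e1, e2).n == 0

    def test_rejected_records_excluded(self):
        e1 = _event_set("LMP", [(1, 5.0, "accepted"), (2, 6.0, "rejected:no-breakdown")])
        e2 = _event_set("MOMP", [(1, 8.0, "accepted"), (2, 9.0, "accepted")])
        assert pair_events(e1, e2).n == 1

    def test_duplicate_cell_marker_rejected(self):
        e1 = _event_set("LMP", [(1, 5.0, "accepted"), (1, 6.0, "accepted")])
        e2 = _event_set("MOMP", [(1, 8.0, "accepted")])
        with pytest.raises(ValueError, match="duplicate"):
            pair_events(e1, e2)


class TestMeanShift:
    def test_two_blob_recovery(self, rng):
        pts = np.vstack(
            [
                rng.normal([5.0, 8.0], 0.3, size=(150, 2)),
                rng.normal([12.0, 6.0], 0.3, size=(150, 2)),
            ]
        )
        members, modes = mean_shift_cluster(pts, 1.0)
        assert len(members) == 2
        centers = sorted([tuple(m) for m in modes])
        assert np.allclose(centers[0], (5, 8), atol=0.2)
        assert np.allclose(centers[1], (12, 6), atol=0.2)
        truth = np.array([0] * 150 + [1] * 150)
        correct = sum(
            int(np.unique(truth[idx], return_counts=True)[1].max()) for idx in members
        )
        assert correct >= 0.99 * 300

    def test_identical_points_single_cluster(self):
        pts = np.tile([3.0, 4.0], (10, 1))
        members, modes = mean_shift_cluster(pts, 1.0)
        assert len(members) == 1
        assert np.allclose(modes[0], (3, 4))

    def test_matches_fixed_point_oracle(self, acceptance_module):
        assert acceptance_module.meanshift_oracle_gap(303) <= 1e-3

    def test_matches_reference_flat_kernel_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        pts = np.vstack(
            [
                rng.normal([5.0, 8.0], 0.3, size=(30, 2)),
                rng.normal([12.0, 6.0], 0.3, size=(30, 2)),
            ]
        )
        _, modes = mean_shift_cluster(pts, 1.5)
        ref = sklearn.MeanShift(bandwidth=1.5, bin_seeding=False).fit(pts)
        ref_modes = ref.cluster_centers_
        assert len(modes) == len(ref_modes)
        for m in modes:
            assert np.min(np.linalg.norm(ref_modes - m, axis=1)) < 1e-3

    def test_permutation_invariance_and_translation_equivariance(self, rng):
        pts = np.vstack(
            [
                rng.normal([5.0, 8.0], 0.3, size=(20, 2)),
                rng.normal([12.0, 6.0], 0.3, size=(20, 2)),
            ]
        )
        _, modes = mean_shift_cluster(pts, 1.0)
        perm = rng.permutation(len(pts))
        _, modes_p = mean_shift_cluster(pts[perm], 1.0)
        assert np.allclose(sorted(map(tuple, modes)), sorted(map(tuple, modes_p)))
        _, modes_t = mean_shift_cluster(pts + [2.0, -1.0], 1.0)
        assert np.allclose(
            sorted(map(tuple, modes_t)),
            np.array(sorted(map(tuple, modes))) + [2.0, -1.0],
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            mean_shift_cluster(np.zeros((10, 2)), 0.0)
        with pytest.raises(ValueError, match="at least 5"):
            mean_shift_cluster(np.zeros((3, 2)), 1.0)


class TestClusterEllipse:
    def test_hand_pca_on_symmetric_configuration(self):
        pts = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]]) + [10, 10]
        ell = cluster_ellipse(pts)
        assert ell.center == pytest.approx((10, 10))
        assert abs(ell.major_direction[0]) == pytest.approx(1.0)
        assert ell.l_major_plus == pytest.approx(2.0)
        assert ell.l_major_minus == pytest.approx(2.0)
        assert ell.l_minor == pytest.approx(np.sqrt(0.5))

    def test_mirror_symmetric_cloud_has_equal_major_lengths(self, rng):
        half = rng.normal(0, 1, size=(40, 2)) * [3.0, 0.5]
        pts = np.vstack([half, -half]) + [5, 5]
        ell = cluster_ellipse(pts)
        assert ell.l_major_plus == pytest.approx(ell.l_major_minus, rel=1e-9)

    def test_rotation_equivariance_of_lengths(self, rng):
        pts = rng.normal(0, 1, size=(60, 2)) * [2.0, 0.7]
        theta = 0.4
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        base = cluster_ellipse(pts)
        rot = cluster_ellipse(pts @ R.T)
        assert rot.l_minor == pytest.approx(base.l_minor, abs=1e-9)
        lengths = sorted([base.l_major_plus, base.l_major_minus])
        lengths_r = sorted([rot.l_major_plus, rot.l_major_minus])
        assert lengths == pytest.approx(lengths_r, abs=1e-9)

    def test_delay_sign_and_side(self):
        pts = np.array([[9.0, 13.0], [10.0, 14.0], [11.0, 15.0], [10.0, 15.0], [10.5, 13.0]])
        ell = cluster_ellipse(pts)
        assert ell.delay_h == pytest.approx(ell.center[1] - ell.center[0])
        assert ell.side == "above"

    def test_collinear_points_rejected(self):
        pts = np.array([[i, 2.0 * i] for i in range(5)], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            cluster_ellipse(pts)

    def test_matches_brute_force_rms(self, acceptance_module):
        assert acceptance_module.ellipse_exactness(404) <= 1e-9


class TestDiagonalPartition:
    def test_all_coincident(self):
        fr = diagonal_partition(np.array([[1.0, 1.0], [5.0, 5.0]]), tolerance=0.0)
        assert fr.coincident == 1.0

    def test_symmetric_split(self):
        fr = diagonal_partition(np.array([[1.0, 2.0], [2.0, 1.0]]), tolerance=0.0)
        assert fr.above == 0.5 and fr.below == 0.5

    def test_planted_two_pathway_fraction(self):
        truth = simulate_cohort(bimodal_pair_config(n_cells=300, seed=9))
        pts = np.array(
            [[c.event_times["LMP"], c.event_times["MOMP"]] for c in truth.cells]
        )
        fr = diagonal_partition(pts, tolerance=0.5)
        assert fr.above == pytest.approx(0.70, abs=0.07)
        assert fr.above + fr.below + fr.coincident == pytest.approx(1.0)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=100)
        y = 0.4 * x + rng.normal(size=100)
        base = pearson(x, y)
        assert pearson(3 * x + 7, y) == pytest.approx(base, abs=1e-12)
        assert pearson(x, 0.1 * y - 2) == pytest.approx(base, abs=1e-12)

    def test_bivariate_normal_recovery(self, acceptance_module):
        assert acceptance_module.pcc_recovery(505) == pytest.approx(-0.26, abs=0.04)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRateVsEvent:
    def _rates(self, values):
        return [RosRate(cell_id=i, rate=v, eval_times=(0.0, 1 / 60)) for i, v in enumerate(values)]

    def test_planted_negative_coupling_recovered(self, rng):
        n = 2000
        rates = rng.lognormal(np.log(80), 0.4, size=n)
        t_momp = 20.0 - 0.05 * rates + rng.normal(0, 1.0, size=n)
        expected = pearson(rates, t_momp)
        events = _event_set("MOMP", [(i, t, "accepted") for i, t in enumerate(t_momp)])
        _, pcc = rate_vs_event(self._rates(rates), events)
        assert pcc < 0
        assert pcc == pytest.approx(expected, abs=1e-12)

    def test_constant_rates_zero_variance_error(self):
        events = _event_set("MOMP", [(i, 5.0 + i, "accepted") for i in range(5)])
        with pytest.raises(ValueError, match="variance"):
            rate_vs_event(self._rates([3.0] * 5), events)

    def test_disjoint_ids_rejected(self):
        events = _event_set("MOMP", [(100 + i, 5.0, "accepted") for i in range(5)])
        with pytest.raises(ValueError, match="at least 3"):
            rate_vs_event(self._rates([1.0, 2.0, 3.0]), events)
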