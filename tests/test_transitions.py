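"""Transition counting kernel and coefficient estimators."""

import numpy as np
import pytest

import hbstateflux as hb
from hbstateflux.transitions import forced_sign_regions


def naive_accumulator(labels_row, max_lag=60):
    """Independent run-length-encoding oracle for one voxel's label series.

    Compress into runs; each adjacent run pair (i, f) with both labels
    defined yields one (f, i, dwell-of-earlier-run) count; the final run is
    never counted; a run of the undefined label 0 breaks adjacency.
    """
    runs = []
    for lab in labels_row:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    counts = {}
    for (i_lab, n), (f_lab, _) in zip(runs[:-1], runs[1:]):
        if i_lab > 0 and f_lab > 0:
            counts[(f_lab, i_lab, n)] = counts.get((f_lab, i_lab, n), 0) + 1
    return counts


def acc_of(labels, components=None, **kw):
    return hb.accumulate_transitions(hb.StateSequence(np.asarray(labels)),
                                     components, **kw)


class TestAccumulateTransitions:
    def test_hand_trace(self):
        acc = acc_of([[1, 1, 2, 2, 2, 7]])
        expected = np.zeros((10, 10, 60), dtype=int)
        expected[1, 0, 1] = 1  # 1 -> 2 after dwelling 2 frames
        expected[6, 1, 2] = 1  # 2 -> 7 after dwelling 3 frames
        assert np.array_equal(acc.a_tc, expected)

    def test_constant_sequence_counts_nothing(self):
        assert acc_of([[3] * 10]).n_transitions == 0

    def test_component_increments(self):
        acc = acc_of([[1, 2]], {"O": np.array([[-1.0, 2.0]])})
        assert acc.a_x["O"][1, 0, 0] == pytest.approx(3.0)
        assert acc.pre_sum["O"][1, 0] == pytest.approx(-1.0)
        assert acc.post_sum["O"][1, 0] == pytest.approx(2.0)

    def test_undefined_labels_break_runs(self):
        # 1 -> 0 -> 2: the zero run severs the pair; only 2 -> 3 counts
        acc = acc_of([[1, 1, 0, 2, 3]])
        assert acc.n_transitions == 1
        assert acc.a_tc[2, 1, 0] == 1

    def test_lag_axis_grows_beyond_default(self):
        labels = [[1] * 70 + [2, 3]]
        acc = acc_of(labels)
        assert acc.max_lag >= 70
        assert acc.a_tc[1, 0, 69] == 1

    def test_conservation_total_runs_minus_one(self, rng):
        labels = rng.integers(1, 11, size=(5, 200))
        acc = acc_of(labels)
        n_runs = sum(1 + int(np.sum(row[1:] != row[:-1])) for row in labels)
        assert acc.n_transitions == n_runs - 5

    def test_oracle_equivalence_random(self, rng):
        """Counting kernel equals the run-length-encoding oracle on 1000
        random sequences with undefined labels mixed in."""
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            row = rng.integers(0, 11, size=n)
            acc = acc_of(row[np.newaxis, :])
            oracle = naive_accumulator(row)
            dense = {}
            f, i, lag = np.nonzero(acc.a_tc)
            for a, b, c in zip(f, i, lag):
                dense[(a + 1, b + 1, c + 1)] = int(acc.a_tc[a, b, c])
            assert dense == oracle

    def test_shape_mismatch_and_short_series(self):
        with pytest.raises(ValueError, match="shape"):
            acc_of([[1, 2]], {"O": np.zeros((2, 2))})
        with pytest.raises(ValueError, match="2 frames"):
            acc_of([[1]])

    def test_accumulators_sum(self):
        a = acc_of([[1, 2]], {"O": np.array([[0.0, 1.0]])})
        b = acc_of([[2, 1, 1, 3]], {"O": np.array([[0.0, 1.0, 1.0, 5.0]])})
        total = a + b
        assert total.n_transitions == 3
        assert total.a_x["O"].sum() == pytest.approx(1.0 + 1.0 + 4.0)


class TestProbability:
    def test_hand_trace_probabilities(self):
        P = hb.transition_probability(acc_of([[1, 1, 2, 2, 2, 7]]))
        assert P.values[1, 0] == pytest.approx(50.0)
        assert P.values[6, 1] == pytest.approx(50.0)

    def test_single_transition_is_100(self):
        P = hb.transition_probability(acc_of([[4, 9]]))
        assert P.values[8, 3] == pytest.approx(100.0)

    def test_offdiagonal_sum_exactly_100(self, rng):
        labels = rng.integers(1, 11, size=(4, 300))
        P = hb.transition_probability(acc_of(labels))
        assert np.nansum(P.values) == pytest.approx(100.0, abs=1e-12)

    def test_empty_accumulator_raises(self):
        with pytest.raises(ValueError, match="empty"):
            hb.transition_probability(acc_of([[5, 5, 5]]))


class TestLagAndRate:
    def test_weighted_mean_of_lags(self):
        # one dwell of 2 frames and one of 4 frames for the same pair
        acc = acc_of([[1, 1, 2, 1, 1, 1, 1, 2, 3]])
        assert hb.mean_lag(acc).values[1, 0] == pytest.approx(3.0)

    def test_minimum_dwell_is_one_frame(self):
        tau = hb.mean_lag(acc_of([[1, 2, 1, 2]]))
        assert tau.values[1, 0] == 1.0
        assert np.isnan(tau.values[3, 2])  # unseen pair is missing, not zero

    def test_rate_constant_units(self):
        acc = acc_of([[1, 1, 2, 3]])  # tau(2,1) = 2 frames
        k_frames = hb.rate_constants(acc, in_hz=False)
        k_hz = hb.rate_constants(acc, in_hz=True)
        assert k_frames.values[1, 0] == pytest.approx(0.5)
        assert k_hz.values[1, 0] == pytest.approx(0.5 * 1.8)

    def test_rate_bounded_by_sampling_rate(self, fitted):
        k = fitted.k.offdiag
        assert np.nanmax(k) <= fitted.model.sampling_rate + 1e-12
        assert np.nanmin(k) > 0


class TestFluxAndMass:
    def test_single_transition_flux(self):
        acc = acc_of([[1, 2]], {"O": np.array([[-1.0, 2.0]])})
        assert hb.intrinsic_flux(acc, "O").values[1, 0] == pytest.approx(3.0)

    def test_flux_is_mean_over_transitions(self):
        acc = acc_of([[1, 2, 1, 2]],
                     {"T": np.array([[0.0, 1.0, 0.0, 3.0]])})
        assert hb.intrinsic_flux(acc, "T").values[1, 0] == pytest.approx(2.0)

    def test_forced_sign_regions_hold(self, fitted):
        """Cells where a component goes below-mean -> above-mean must have
        strictly positive flux (and the reverse strictly negative)."""
        for x in hb.COMPONENTS:
            phi = fitted.phi(x).values
            forced = forced_sign_regions(fitted.model.geometry, x)
            pos = (forced == 1) & ~np.isnan(phi)
            neg = (forced == -1) & ~np.isnan(phi)
            assert np.all(phi[pos] > 0)
            assert np.all(phi[neg] < 0)

    def test_mass_is_product(self, fitted):
        m = fitted.mass("T")
        expected = fitted.P.values * fitted.phi("T").values
        np.testing.assert_allclose(m.values, expected)

    def test_mass_sum_identity(self, fitted):
        """sum(m)/100 equals the grand mean component change per transition."""
        m_sum = np.nansum(fitted.mass("D").values) / 100.0
        acc = fitted.accumulator
        grand = acc.a_x["D"].sum() / acc.n_transitions
        assert m_sum == pytest.approx(grand, rel=1e-10)

    def test_weighted_flux_identity(self, fitted):
        """k*phi equals sum A_X / sum n*A_TC cell-wise (frame units)."""
        k = hb.rate_constants(fitted.accumulator, in_hz=False)
        phi = fitted.phi("S")
        kphi, _ = hb.weighted_coefficients(k, phi, fitted.mass("S"))
        acc = fitted.accumulator
        n = np.arange(1, acc.max_lag + 1)
        with np.errstate(invalid="ignore"):
            direct = acc.a_x["S"].sum(axis=2) / (acc.a_tc * n).sum(axis=2)
        mask = ~np.isnan(kphi.values)
        np.testing.assert_allclose(kphi.values[mask], direct[mask], rtol=1e-10)

    def test_weighted_mass_identity(self, fitted):
        """k*m = 100 * k*phi * counts / total counts cell-wise."""
        k = hb.rate_constants(fitted.accumulator, in_hz=False)
        phi, m = fitted.phi("O"), fitted.mass("O")
        kphi, km = hb.weighted_coefficients(k, phi, m)
        counts = fitted.accumulator.counts
        expected = 100.0 * kphi.values * counts / counts.sum()
        mask = ~np.isnan(km.values)
        np.testing.assert_allclose(km.values[mask], expected[mask], rtol=1e-10)


class TestPrePostAmplitudes:
    def test_single_transition_values(self):
        acc = acc_of([[1, 2]], {"O": np.array([[-1.0, 2.0]])})
        pre, post = hb.pre_post_amplitudes(acc, "O")
        assert pre.values[1, 0] == pytest.approx(-1.0)
        assert post.values[1, 0] == pytest.approx(2.0)

    def test_post_minus_pre_equals_flux(self, fitted):
        for x in hb.COMPONENTS:
            pre, post = fitted.pre_post_amplitudes(x)
            phi = fitted.phi(x)
            mask = ~np.isnan(phi.values)
            np.testing.assert_allclose(
                (post.values - pre.values)[mask], phi.values[mask],
                rtol=1e-12, atol=1e-30)

    def test_zero_count_cells_missing(self):
        pre, post = hb.pre_post_amplitudes(
            acc_of([[1, 2]], {"O": np.array([[0.0, 1.0]])}), "O")
        assert np.isnan(pre.values[3, 2]) and np.isnan(post.values[3, 2])


class TestVoltagesAndAsymmetry:
    def test_voltage_quotient(self):
        k = hb.CoefficientMap(np.full((10, 10), 0.5), kind="k")
        P = hb.CoefficientMap(np.full((10, 10), 50.0), kind="P")
        v = hb.ohmic_voltages(k, P)
        assert np.allclose(v.offdiag, 0.01)

    def test_voltage_with_flux(self, fitted):
        v_tc = fitted.voltages()
        v_s = fitted.voltages("S")
        phi = fitted.phi("S")
        mask = ~np.isnan(v_s.values)
        np.testing.assert_allclose(v_s.values[mask],
                                   (v_tc.values * phi.values)[mask])

    def test_zero_probability_is_missing(self):
        k = hb.CoefficientMap(np.ones((10, 10)), kind="k")
        P = hb.CoefficientMap(np.zeros((10, 10)), kind="P")
        assert np.all(np.isnan(hb.ohmic_voltages(k, P).offdiag))

    def test_asymmetry_antisymmetric(self, fitted):
        asym = hb.asymmetry_map(fitted.P).values
        total = asym + asym.T
        assert np.nanmax(np.abs(total)) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetry_values(self):
        y = np.zeros((10, 10))
        y[1, 0], y[0, 1] = 50.0, 30.0
        asym = hb.asymmetry_map(hb.CoefficientMap(y, kind="P"))
        assert asym.values[1, 0] == pytest.approx(20.0)
        assert asym.values[0, 1] == pytest.approx(-20.0)


class TestCoefficientMapIO:
    def test_csv_round_trip(self, fitted, tmp_path):
        path = tmp_path / "k.csv"
        fitted.k.to_csv(path)
        loaded = hb.CoefficientMap.from_csv(path, kind="k")
        np.testing.assert_allclose(loaded.values, fitted.k.values,
                                   rtol=1e-12, equal_nan=True)

    def test_long_format_has_90_rows(self, fitted):
        long = fitted.P.to_long()
        assert len(long) == 90
        assert set(long.columns) == {"from_state", "to_state", "kind",
                                     "component", "value"}
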