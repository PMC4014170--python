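import numpy as np
import pandas as pd
import pytest

from brachyfit.regression import (KernelMatrix, MeasurementSet,
                                  SourceStrengthModel, average_triplets,
                                  average_triplets_kernel, fit_strengths,
                                  predict_internal_dose, ratio_to_stronger)


def _toy_kernel(n_sites=8, seed=0, exposure=24.0):
    rng = np.random.default_rng(seed)
    ids = [f"S{i:03d}c" for i in range(n_sites)]
    vals = pd.DataFrame(
        {"seed1": np.exp(rng.normal(-3, 0.5, n_sites)),
         "seed2": np.exp(rng.normal(-3, 0.5, n_sites))},
        index=pd.Index(ids, name="site_id"))
    return KernelMatrix(vals, vals * 0.0, exposure)


def _meas_from(kernel, a, rel_sigma=0.05):
    dose = kernel.values.to_numpy() @ np.asarray(a)
    return MeasurementSet.from_arrays(kernel.site_ids, dose, rel_sigma * dose,
                                      provenance="synthetic")


class TestAverageTriplets:
    def _triplet_set(self, doses, sigmas=None):
        ids = ["S045m", "S045c", "S045p"]
        sigmas = sigmas if sigmas is not None else [0.1] * 3
        return MeasurementSet.from_arrays(ids, doses, sigmas)

    def test_constant_triplet_passes_through(self):
        out = average_triplets(self._triplet_set([2.0, 2.0, 2.0]))
        assert out.site_ids == ["S045"]
        assert out.dose[0] == pytest.approx(2.0)

    def test_arithmetic_mean_and_standard_error(self):
        out = average_triplets(self._triplet_set([1.0, 2.0, 3.0], [0.3, 0.3, 0.3]))
        assert out.dose[0] == pytest.approx(2.0)
        assert out.sigma[0] == pytest.approx(np.sqrt(3 * 0.3**2) / 3)

    def test_24_surface_records_become_8(self, kernels_mc):
        full = MeasurementSet.from_arrays(
            kernels_mc.site_ids, np.ones(42), np.ones(42) * 0.1)
        out = average_triplets(full)
        surface = [s for s in out.site_ids if s.startswith("S")]
        assert len(surface) == 8
        assert len(out.site_ids) == 8 + 18  # internal rows pass through

    def test_incomplete_triplet_raises(self):
        m = MeasurementSet.from_arrays(["S045m", "S045c"], [1.0, 2.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            average_triplets(m)

    def test_kernel_and_measurement_averaging_agree(self, kernels_mc):
        k_avg = average_triplets_kernel(kernels_mc)
        m = _meas_from(kernels_mc, [0.2, 0.1], rel_sigma=0.1)
        m_avg = average_triplets(m)
        assert set(m_avg.site_ids) == set(k_avg.site_ids)
        # averaging commutes with the noiseless forward model
        np.testing.assert_allclose(
            m_avg.select(k_avg.site_ids).dose,
            k_avg.values.to_numpy() @ [0.2, 0.1], rtol=1e-12)


class TestFitStrengths:
    def test_noiseless_recovery_to_machine_precision(self):
        k = _toy_kernel()
        a_true = np.array([0.253, 0.132])
        res = fit_strengths(_meas_from(k, a_true), k)
        np.testing.assert_allclose(res.params.to_numpy(), a_true, rtol=1e-12)

    def test_single_seed_fit(self):
        k = _toy_kernel()
        k1 = KernelMatrix(k.values[["seed1"]], k.sigma[["seed1"]])
        dose = 0.5 * k1.values.to_numpy()[:, 0]
        m = MeasurementSet.from_arrays(k1.site_ids, dose, 0.05 * dose)
        res = fit_strengths(m, k1)
        assert res.params.iloc[0] == pytest.approx(0.5, rel=1e-12)

    def test_scale_equivariance(self):
        k = _toy_kernel(seed=3)
        m = _meas_from(k, [0.2, 0.1])
        noisy = MeasurementSet.from_arrays(
            m.site_ids, m.dose * (1 + 0.05 * np.sin(np.arange(8))), m.sigma)
        res1 = fit_strengths(noisy, k)
        scaled = MeasurementSet.from_arrays(noisy.site_ids, 3.0 * noisy.dose,
                                            3.0 * noisy.sigma)
        res3 = fit_strengths(scaled, k)
        np.testing.assert_allclose(res3.params, 3.0 * res1.params, rtol=1e-12)

    def test_weighted_and_unweighted_agree_for_uniform_sigma(self):
        k = _toy_kernel(seed=5)
        dose = k.values.to_numpy() @ [0.2, 0.1] + 1e-4
        m = MeasurementSet.from_arrays(k.site_ids, dose, np.full(8, 1e-3))
        rw = fit_strengths(m, k, "inverse_variance")
        ru = fit_strengths(m, k, "none")
        np.testing.assert_allclose(rw.params, ru.params, rtol=1e-10)
        np.testing.assert_allclose(rw.bse, ru.bse, rtol=1e-10)

    def test_mismatched_sites_rejected(self):
        k = _toy_kernel()
        m = MeasurementSet.from_arrays(["X1", "X2"], [1.0, 2.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            SourceStrengthModel(m, k)

    def test_rank_deficient_kernel_rejected(self):
        ids = [f"S{i:03d}c" for i in range(4)]
        col = np.array([1.0, 2.0, 3.0, 4.0])
        vals = pd.DataFrame({"seed1": col, "seed2": 2 * col},
                            index=pd.Index(ids, name="site_id"))
        k = KernelMatrix(vals, vals * 0.0)
        m = MeasurementSet.from_arrays(ids, col, 0.1 * col)
        with pytest.raises(ValueError):
            SourceStrengthModel(m, k)

    def test_negative_strength_warns(self):
        # data generated from a negative coefficient (doses clipped to stay
        # legal) must trip the misfit warning
        k = _toy_kernel(seed=9)
        y = k.values.to_numpy() @ np.array([0.3, -0.5])
        y = np.clip(y, 1e-9, None)
        m = MeasurementSet.from_arrays(k.site_ids, y, np.full(8, 1e-3))
        with pytest.warns(UserWarning):
            fit_strengths(m, k)

    def test_reported_relative_sigma_is_a_few_percent(self, kernels_mc):
        """With ~10% measurement noise on eight azimuths, the strength
        uncertainties land in the few-percent decade, like the experiment."""
        from brachyfit.synthetic import Scenario, generate_measurements
        k_surf = average_triplets_kernel(kernels_mc.select_prefix("S"))
        s = Scenario("t", (0.253, 0.132), (0.253, 0.253))
        m = generate_measurements(s, kernels_mc.select_prefix("S"),
                                  np.random.default_rng(4))
        res = fit_strengths(average_triplets(m), k_surf)
        rel = (res.bse / res.params).to_numpy()
        assert np.all(rel > 0.005) and np.all(rel < 0.15)

    def test_summary_mentions_ratio(self):
        k = _toy_kernel()
        res = fit_strengths(_meas_from(k, [0.253, 0.132]), k)
        text = res.summary()
        assert "ratio to stronger source" in text
        assert "seed1" in text and "seed2" in text


class TestRatioToStronger:
    @pytest.mark.parametrize("a,s,expected", [
        ((0.253, 0.132), (0.008, 0.004), (52, 2)),
        ((0.291, 0.140), (0.003, 0.003), (48, 1)),
        ((0.090, 0.062), (0.003, 0.002), (69, 3)),
    ])
    def test_published_style_rows(self, a, s, expected):
        assert ratio_to_stronger(a, s) == expected

    def test_equal_strengths(self):
        assert ratio_to_stronger((0.1, 0.1), (0.0, 0.0)) == (100, 0)

    def test_order_invariance(self):
        assert ratio_to_stronger((0.132, 0.253), (0.004, 0.008)) == (52, 2)

    def test_zero_strength_rejected(self):
        with pytest.raises(ValueError):
            ratio_to_stronger((0.0, 0.1), (0.01, 0.01))

    def test_single_strength_rejected(self):
        with pytest.raises(ValueError):
            ratio_to_stronger((0.1,), (0.01,))


class TestPredict:
    def test_unit_vector_returns_kernel_column(self):
        import warnings

        k = _toy_kernel()
        m = _meas_from(k, [1.0, 0.0])
        with warnings.catch_warnings():
            # the zero coefficient may come out as a tiny negative number
            warnings.simplefilter("ignore", UserWarning)
            res = fit_strengths(m, k)
        pred = predict_internal_dose(k, res)
        np.testing.assert_allclose(pred.dose, k.values["seed1"], rtol=1e-9)

    def test_linearity(self):
        k = _toy_kernel(seed=2)
        res1 = fit_strengths(_meas_from(k, [0.1, 0.05]), k)
        res2 = fit_strengths(_meas_from(k, [0.2, 0.10]), k)
        p1 = predict_internal_dose(k, res1)
        p2 = predict_internal_dose(k, res2)
        np.testing.assert_allclose(p2.dose, 2 * p1.dose, rtol=1e-9)

    def test_seed_mismatch_rejected(self):
        k = _toy_kernel()
        res = fit_strengths(_meas_from(k, [0.1, 0.05]), k)
        other = KernelMatrix(k.values.rename(columns={"seed2": "zzz"}),
                             k.sigma.rename(columns={"seed2": "zzz"}))
        with pytest.raises(ValueError):
            predict_internal_dose(other, res)


class TestRoundTripIO:
    def test_measurement_csv_round_trip(self, tmp_path):
        m = MeasurementSet.from_arrays(["a", "b"], [1e-3, 2e-3], [1e-4, 2e-4],
                                       exposure_time_h=12.0, provenance="synthetic")
        p = tmp_path / "m.csv"
        m.write_csv(p, ["test: header"])
        back = MeasurementSet.read_csv(p)
        pd.testing.assert_frame_equal(back.data, m.data)
        assert back.exposure_time_h == 12.0
        assert back.provenance == "synthetic"

    def test_kernel_csv_round_trip(self, tmp_path):
        k = _toy_kernel()
        p = tmp_path / "k.csv"
        k.write_csv(p)
        back = KernelMatrix.read_csv(p)
        pd.testing.assert_frame_equal(back.values, k.values, check_names=False)
        assert back.exposure_time_h == k.exposure_time_h
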