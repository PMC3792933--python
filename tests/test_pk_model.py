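import numpy as np
import pytest

from dcespect import pk_model as pk
from dcespect.core import dce_time_vector
from oracles import tofts_numeric

AIF = pk.AifModel(a1=3.0, m1=0.01, a2=1.0, m2=0.001, t_arrival_s=0.0)
TIMES = dce_time_vector()


class TestAifModel:
    def test_zero_before_arrival(self):
        aif = pk.AifModel(3.0, 0.01, 1.0, 0.001, t_arrival_s=30.0)
        t = np.array([0.0, 10.0, 29.9, 30.0, 40.0])
        cp = aif.cp(t)
        assert np.all(cp[:3] == 0.0)
        assert cp[3] == pytest.approx(4.0)
        assert cp[4] > 0

    def test_validation(self):
        with pytest.raises(ValueError):
            pk.AifModel(-1.0, 0.01, 1.0, 0.001)
        with pytest.raises(ValueError):
            pk.AifModel(1.0, 0.0, 1.0, 0.001)

    def test_round_trip_dict(self):
        again = pk.AifModel.from_dict(AIF.to_dict())
        assert again == AIF


class TestFitAif:
    def test_exact_recovery(self):
        cp = AIF.cp(TIMES)
        fit = pk.fit_aif(cp[None, :], TIMES)
        assert fit.a1 == pytest.approx(3.0, rel=1e-4)
        assert fit.m1 == pytest.approx(0.01, rel=1e-4)
        assert fit.a2 == pytest.approx(1.0, rel=1e-4)
        assert fit.m2 == pytest.approx(0.001, rel=1e-4)
        assert fit.m1 > fit.m2

    def test_arrival_estimate(self):
        aif = pk.AifModel(3.0, 0.01, 1.0, 0.001, t_arrival_s=TIMES[7])
        fit = pk.fit_aif(aif.cp(TIMES)[None, :], TIMES)
        assert fit.t_arrival_s == TIMES[7]

    def test_single_exponential_truth(self):
        cp = 2.0 * np.exp(-0.005 * TIMES)
        fit = pk.fit_aif(cp[None, :], TIMES)
        rms = np.sqrt(np.mean((fit.cp(TIMES) - cp) ** 2))
        assert rms < 1e-6

    def test_zero_curve_raises(self):
        with pytest.raises(ValueError):
            pk.fit_aif(np.zeros((3, TIMES.size)), TIMES)

    def test_averages_voxels(self):
        cp = AIF.cp(TIMES)
        fit = pk.fit_aif(np.stack([0.5 * cp, 1.5 * cp]), TIMES)
        assert fit.a1 + fit.a2 == pytest.approx(4.0, rel=1e-3)


class TestToftsForward:
    def test_zero_ktrans(self):
        assert np.all(pk.tofts_forward(0.0, 0.05, AIF, TIMES) == 0.0)

    def test_negative_rates_raise(self):
        with pytest.raises(ValueError):
            pk.tofts_forward(-0.1, 0.05, AIF, TIMES)

    def test_box_aif_closed_form(self):
        # nearly constant plasma input: Ct = ktrans*c0/kep * (1 - exp(-kep t))
        box = pk.AifModel(a1=2.0, m1=1e-9, a2=0.0, m2=1.0, t_arrival_s=0.0)
        kt, kep = 0.01, 0.05
        got = pk.tofts_forward(kt, kep, box, TIMES)
        expect = kt * 2.0 / kep * (1.0 - np.exp(-kep * TIMES))
        assert np.allclose(got, expect, rtol=1e-6)

    def test_kep_to_zero_limit(self):
        # kep -> 0: Ct -> ktrans * integral of Cp
        tiny = pk.tofts_forward(0.01, 1e-12, AIF, TIMES)
        dense = np.linspace(0, TIMES[-1], 20000)
        integral = np.interp(
            TIMES, dense,
            np.concatenate([[0], np.cumsum(
                0.5 * (AIF.cp(dense)[1:] + AIF.cp(dense)[:-1]) * np.diff(dense))]))
        assert np.allclose(tiny, 0.01 * integral, rtol=1e-4)

    def test_kep_equal_decay_rate_limit(self):
        # analytic limit term vs numeric convolution when kep == m1
        got = pk.tofts_forward(0.01, AIF.m1, AIF, TIMES[1:])
        oracle = tofts_numeric(0.01, AIF.m1, AIF, TIMES[1:], oversample=100)
        assert np.allclose(got, oracle, rtol=1e-3)

    @pytest.mark.parametrize("kt", [1e-4, 1e-3, 1e-2, 1e-1])
    @pytest.mark.parametrize("kep", [1e-3, 1e-2, 1e-1, 1.0])
    def test_matches_numeric_convolution(self, kt, kep):
        got = pk.tofts_forward(kt, kep, AIF, TIMES[1:])
        oracle = tofts_numeric(kt, kep, AIF, TIMES[1:], oversample=100)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(got - oracle)) / scale < 1e-4

    def test_vectorized_matches_scalar(self):
        kts = np.array([0.001, 0.01])
        keps = np.array([0.01, 0.1])
        many = pk.tofts_forward(kts, keps, AIF, TIMES)
        for i in range(2):
            one = pk.tofts_forward(kts[i], keps[i], AIF, TIMES)
            assert np.allclose(many[i], one)


class TestFitTofts:
    def test_round_trip(self):
        curve = pk.tofts_forward(0.005, 0.02, AIF, TIMES)
        kt, kep, rss = pk.fit_tofts(curve, AIF, TIMES)
        assert kt == pytest.approx(0.005, rel=1e-3)
        assert kep == pytest.approx(0.02, rel=1e-3)
        assert rss < 1e-12

    def test_zero_curve_returns_origin(self):
        kt, kep, rss = pk.fit_tofts(np.zeros(TIMES.size), AIF, TIMES)
        assert kt == pytest.approx(0.0, abs=1e-6)
        assert rss == pytest.approx(0.0, abs=1e-10)

    def test_map_fit_matches_scalar_fit(self):
        truth = [(0.002, 0.01), (0.008, 0.05), (0.02, 0.2)]
        curves = np.stack([pk.tofts_forward(a, b, AIF, TIMES) for a, b in truth])
        kts, keps, _ = pk.fit_tofts_map(curves, AIF, TIMES)
        for i, (a, b) in enumerate(truth):
            assert kts[i] == pytest.approx(a, rel=1e-3)
            assert keps[i] == pytest.approx(b, rel=1e-3)

    def test_map_fit_handles_nans(self):
        curve = pk.tofts_forward(0.005, 0.02, AIF, TIMES)
        curve[10] = np.nan
        kts, keps, _ = pk.fit_tofts_map(curve[None, :], AIF, TIMES)
        assert kts[0] == pytest.approx(0.005, rel=1e-3)


class TestEnhancementGate:
    def _maps(self):
        kt = np.full((4, 4, 1), 0.01)
        kep = np.full((4, 4, 1), 0.05)
        mask = np.ones((4, 4, 1), dtype=bool)
        return kt, kep, mask

    def test_zero_smax_voxel_gated(self):
        kt, kep, mask = self._maps()
        smax = np.full((4, 4, 1), 100.0)
        smax[0, 0, 0] = 0.0
        kt2, kep2, gated = pk.apply_enhancement_gate(kt, kep, smax, mask, 0.05)
        assert gated[0, 0, 0]
        assert kt2[0, 0, 0] == 0.0 and kep2[0, 0, 0] == 0.0

    def test_all_above_threshold_unchanged(self):
        kt, kep, mask = self._maps()
        smax = np.full((4, 4, 1), 100.0)
        kt2, kep2, gated = pk.apply_enhancement_gate(kt, kep, smax, mask, 0.05)
        assert not gated.any()
        assert np.array_equal(kt2, kt)

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.5, 2.0])
    def test_threshold_range(self, thr):
        kt, kep, mask = self._maps()
        with pytest.raises(ValueError):
            pk.apply_enhancement_gate(kt, kep, np.ones((4, 4, 1)), mask, thr)

    def test_gated_implies_zero(self, rng):
        kt, kep, mask = self._maps()
        smax = rng.uniform(0, 100, (4, 4, 1))
        kt2, kep2, gated = pk.apply_enhancement_gate(kt, kep, smax, mask, 0.3)
        assert np.all(kt2[gated] == 0.0)
        assert np.all(kep2[gated] == 0.0)
        assert np.all(kt2[~gated] == 0.01)
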