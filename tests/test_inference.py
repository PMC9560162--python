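"""PRC inference, Fourier/shift collapse, period modulation, MC fitting."""

import numpy as np
import pytest

from segclock.circstats import StroboscopicMap, wrap_2pi, wrap_pi
from segclock.erica import EricaParams, iterate_strobo, prc_analytic, with_T_osc
from segclock.inference import (
    PRCSamples,
    build_period_modulation,
    collapse_shift,
    fit_erica_mc,
    fit_fourier,
    infer_intrinsic_period,
    pool_prc_samples,
    prc_from_map,
    predict_entrainment_phase,
)

TWO_PI = 2 * np.pi


def map_from_sequence(seq):
    return StroboscopicMap("x", np.column_stack([seq[:-1], seq[1:]]))


class TestPrcFromMap:
    def test_resonant_locked_pair_zero_response(self):
        m = StroboscopicMap("x", np.array([[1.0, 1.0]]))
        s = prc_from_map(m, T_zeit=140.0, T_osc=140.0)
        assert s.dphi[0] == pytest.approx(0.0, abs=1e-12)

    def test_locked_pair_detuning_response(self):
        m = StroboscopicMap("x", np.array([[2.0, 2.0]]))
        s = prc_from_map(m, T_zeit=170.0, T_osc=140.0)
        assert s.dphi[0] == pytest.approx(-1.34640, abs=1e-4)

    def test_roundtrip_inverts_strobo_iteration(self, ref_params):
        """Map inversion recovers the analytic PRC exactly (Eq.2 <-> Eq.3)."""
        seq = iterate_strobo(0.3, 170.0, 12, ref_params)
        s = prc_from_map(map_from_sequence(seq), 170.0, ref_params.T_osc)
        expected = prc_analytic(s.phi, ref_params)
        assert np.max(np.abs(s.dphi - expected)) < 1e-10

    def test_resimulation_reproduces_observed_pairs(self, ref_params):
        """Re-simulating with the inferred point-wise PRC is the identity."""
        seq = iterate_strobo(1.1, 150.0, 15, ref_params)
        m = map_from_sequence(seq)
        s = prc_from_map(m, 150.0, ref_params.T_osc)
        drift = TWO_PI * 150.0 / ref_params.T_osc
        renewed = wrap_2pi(m.phi_old + s.dphi + drift)
        assert np.max(np.abs(wrap_pi(renewed - m.phi_new))) < 1e-10

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            prc_from_map(StroboscopicMap("x", np.empty((0, 2))), 170.0, 140.0)


class TestFitFourier:
    def test_exact_model_class_recovered(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, TWO_PI, 64)
        s = PRCSamples(phi=phi, dphi=-0.3 + 0.2 * np.sin(phi),
                       T_zeit=140.0, T_osc_assumed=140.0)
        f = fit_fourier(s, K=1)
        assert f.a0 == pytest.approx(-0.3, abs=1e-6)
        assert f.b[0] == pytest.approx(0.2, abs=1e-6)
        assert f.a[0] == pytest.approx(0.0, abs=1e-6)

    def test_erica_prc_smooth_enough_at_k5(self, ref_params):
        g = np.linspace(0, TWO_PI, 64, endpoint=False)
        s = PRCSamples(phi=g, dphi=prc_analytic(g, ref_params),
                       T_zeit=140.0, T_osc_assumed=140.0)
        f = fit_fourier(s, K=5)
        assert np.sqrt(f.sse / len(g)) < 0.05

    def test_k0_is_circular_mean(self):
        s = PRCSamples(phi=np.array([0.0, 1.0, 2.0]),
                       dphi=np.array([3.0, -3.0, 0.1]),
                       T_zeit=140.0, T_osc_assumed=140.0)
        f = fit_fourier(s, K=0)
        z = np.mean(np.exp(1j * s.dphi))
        assert f.a0 == pytest.approx(float(np.angle(z)))

    def test_clustered_phases_warn_and_regularize(self):
        rng = np.random.default_rng(1)
        phi = 2.0 + 1e-6 * rng.normal(size=16)
        s = PRCSamples(phi=phi, dphi=np.full(16, -0.5),
                       T_zeit=140.0, T_osc_assumed=140.0)
        with pytest.warns(RuntimeWarning, match="clustered"):
            f = fit_fourier(s, K=3)
        assert np.isfinite(f(2.0))

    def test_too_few_points_rejected(self):
        s = PRCSamples(phi=np.arange(4.0), dphi=np.zeros(4),
                       T_zeit=140.0, T_osc_assumed=140.0)
        with pytest.raises(ValueError, match="points"):
            fit_fourier(s, K=3)


class TestCollapseShift:
    def _samples(self, dphi_fn, T_zeit, n=80, seed=0):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0, TWO_PI, n)
        return PRCSamples(phi=phi, dphi=dphi_fn(phi), T_zeit=T_zeit,
                          T_osc_assumed=140.0)

    def test_identical_prcs_no_shift(self):
        fn = lambda phi: -0.3 + 0.2 * np.sin(phi)
        prcs = [self._samples(fn, 140.0, seed=0),
                self._samples(fn, 160.0, seed=1)]
        shifts, merged = collapse_shift(prcs)
        assert shifts[160.0] == pytest.approx(0.0, abs=1e-2)
        assert len(merged) == 160

    def test_constant_offset_recovered(self):
        fn = lambda phi: -0.3 + 0.2 * np.sin(phi)
        prcs = [self._samples(fn, 140.0, seed=0),
                self._samples(lambda p: fn(p) + 0.5, 170.0, seed=1)]
        shifts, _ = collapse_shift(prcs)
        assert shifts[170.0] == pytest.approx(0.5, abs=1e-2)

    def test_wrong_assumed_period_shift_prediction(self, ref_params,
                                                   ref_modulation):
        """Inverting with a fixed 140-min period shifts each condition by
        2 pi T_zeit (1/140 - 1/T_osc_true)."""
        prcs = []
        rng = np.random.default_rng(3)
        for Tz in (120.0, 140.0, 160.0, 180.0):
            p = with_T_osc(ref_params, float(ref_modulation(Tz)))
            per_map = [
                prc_from_map(map_from_sequence(
                    iterate_strobo(s0, Tz, 10, p)), Tz, 140.0)
                for s0 in rng.uniform(0, TWO_PI, 15)
            ]
            prcs.append(pool_prc_samples(per_map))
        shifts, _ = collapse_shift(prcs)
        # stored shift is what gets subtracted from the condition's points
        for Tz in (120.0, 160.0, 180.0):
            predicted = TWO_PI * Tz * (1 / float(ref_modulation(Tz)) - 1 / 140.0)
            assert shifts[Tz] == pytest.approx(predicted, abs=0.05)

    def test_missing_reference_rejected(self):
        prcs = [self._samples(np.sin, 120.0)]
        with pytest.raises(ValueError, match="reference"):
            collapse_shift(prcs, ref_T_zeit=140.0)


class TestInferIntrinsicPeriod:
    def test_zero_detuning(self):
        assert infer_intrinsic_period(1.0, 140.0, lambda x: 0.0) == \
            pytest.approx(140.0)

    def test_inverts_detuning_example(self):
        T = infer_intrinsic_period(2.0, 170.0, lambda x: -1.34640)
        assert T == pytest.approx(140.0, abs=1e-3)

    def test_positive_response_shortens_period(self):
        T = infer_intrinsic_period(1.0, 120.0, lambda x: 0.5)
        assert T == pytest.approx(TWO_PI * 120.0 / (TWO_PI - 0.5), abs=1e-9)
        assert T == pytest.approx(130.37, abs=0.01)

    def test_fixed_point_roundtrip(self, ref_params):
        """phi_ent of the iterated map + identity returns the true T_osc."""
        for T_osc in (128.0, 140.0, 155.0):
            p = with_T_osc(ref_params, T_osc)
            Tz = T_osc * 1.1
            phi_ent, locked = predict_entrainment_phase(Tz, p)
            assert locked
            T_rec = infer_intrinsic_period(
                phi_ent, Tz, lambda x: float(prc_analytic(float(x), p)))
            assert T_rec == pytest.approx(T_osc, rel=1e-6)

    def test_impossible_response_rejected(self):
        with pytest.raises(ValueError):
            infer_intrinsic_period(1.0, 140.0, lambda x: TWO_PI)


class TestPeriodModulation:
    def test_line_reproduced_and_knots_exact(self):
        pts = [(120.0, 126.0), (140.0, 140.0), (160.0, 150.0), (180.0, 158.0)]
        mod = build_period_modulation(pts)
        for tz, to in pts:
            assert mod(tz) == pytest.approx(to)
        linear = build_period_modulation([(120.0, 130.0), (180.0, 160.0)])
        assert linear(150.0) == pytest.approx(145.0)

    def test_smooth_truth_interpolated_accurately(self):
        tz = np.arange(120.0, 181.0, 10.0)
        truth = lambda T: 140.0 + 0.3 * (T - 140.0)
        mod = build_period_modulation([(t, truth(t)) for t in tz])
        fine = np.linspace(120.0, 180.0, 301)
        assert np.max(np.abs(mod(fine) - truth(fine))) < 0.01

    def test_evaluation_clamped_to_span(self):
        mod = build_period_modulation([(120.0, 126.0), (140.0, 140.0),
                                       (160.0, 150.0), (180.0, 158.0)])
        assert mod(350.0) == pytest.approx(mod(180.0))
        assert mod(50.0) == pytest.approx(mod(120.0))

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_period_modulation([(140.0, 140.0), (140.0, 150.0)])


class TestFitEricaMC:
    def _model_points(self, p, sd, seed, n=120):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0, TWO_PI, n)
        dphi = prc_analytic(phi, p) + sd * rng.normal(size=n)
        return PRCSamples(phi=phi, dphi=wrap_pi(dphi), T_zeit=140.0,
                          T_osc_assumed=140.0)

    def test_noiseless_init_at_truth_stays(self, ref_params):
        s = self._model_points(ref_params, 0.0, 0)
        fit = fit_erica_mc(s, init=ref_params, n_iter=2000, n_restarts=1,
                           seed=0)
        assert fit.sse < 1e-8
        assert fit.params.lam == pytest.approx(0.5, abs=0.05)
        assert fit.params.eps == pytest.approx(0.4, abs=0.02)

    def test_recovery_from_noisy_model_points(self, ref_params):
        """Parameters recovered from the reference configuration + noise."""
        s = self._model_points(ref_params, 0.05, 4, n=200)
        fit = fit_erica_mc(s, n_iter=20000, n_restarts=3, seed=4)
        assert 0.4 <= fit.params.lam <= 0.6
        assert 4.5 <= fit.params.s_star <= 6.7
        assert 0.33 <= fit.params.eps <= 0.47

    def test_ric_degenerate_case_recovered(self):
        p = EricaParams(lam=0.0, s_star=1.0, eps=0.3,
                        kick_dir=(np.cos(np.deg2rad(250.0)),
                                  np.sin(np.deg2rad(250.0))))
        s = self._model_points(p, 0.02, 5, n=150)
        fit = fit_erica_mc(s, n_iter=10000, n_restarts=2, seed=5)
        assert fit.params.lam < 0.1
        assert fit.params.s_star < 1.5

    def test_result_unpacks_as_tuple(self, ref_params):
        s = self._model_points(ref_params, 0.0, 0, n=30)
        params, sse = fit_erica_mc(s, init=ref_params, n_iter=200,
                                   n_restarts=1, seed=0)
        assert isinstance(params, EricaParams)
        assert sse >= 0.0

    def test_too_few_points_rejected(self, ref_params):
        s = self._model_points(ref_params, 0.0, 0, n=3)
        with pytest.raises(ValueError):
            fit_erica_mc(s, n_iter=10, n_restarts=1, seed=0)


class TestFullChainRecovery:
    """Generator -> signal -> strobo -> PRC -> MC fit, at realistic noise.

    The collapsed PRC shape and the kick amplitude are recovered; the
    ellipse eccentricity is the weakest-identified parameter of the family
    (an axis-aligned projection of the kick trades off against it) and is
    not asserted here — at this noise level it is biased low.
    """

    def test_shape_and_kick_recovered_from_noisy_ensembles(self, ref_params,
                                                           ref_modulation):
        from segclock import signal as S
        from segclock.circstats import PulseTrain, build_strobo_map
        from segclock.synthdata import Condition, generate_sample

        prcs = []
        for Tz in (120, 130, 140, 150, 160, 170, 180):
            pulses = PulseTrain(t_first=100.0, T_zeit=float(Tz), strength=0.4,
                                n_pulses=int(1400 // Tz) + 1)
            c = Condition(label=f"d{Tz}", p=ref_params, pulses=pulses,
                          period_drift=ref_modulation, noise_sd=0.1,
                          seed=5 + Tz, n_samples=20)
            per_map = []
            for k in range(20):
                ts, _ = generate_sample(c, k)
                d = S.sinc_detrend(ts, 240.0)
                ph = S.extract_phase(d, method="ridge")
                per_map.append(prc_from_map(
                    build_strobo_map(ph, pulses, advance_to_onset=True),
                    float(Tz), 140.0))
            prcs.append(pool_prc_samples(per_map, n_bins=16))
        fit = fit_erica_mc(prcs, n_iter=20000, n_restarts=3, seed=5,
                           profile_shifts=True)
        g = np.linspace(0, TWO_PI, 360, endpoint=False)
        truth = prc_analytic(g, ref_params)
        fitted = prc_analytic(g, fit.params, eps=fit.params.eps)
        assert np.corrcoef(truth, fitted)[0, 1] > 0.9
        assert abs(fit.params.eps - 0.4) <= 0.3 * 0.4
        assert np.mean(fitted > 0.05) < 0.25  # predominantly non-positive


class TestPredictEntrainmentPhase:
    def test_zero_kick_never_locks_off_resonance(self):
        p = EricaParams(T_osc=140.0)
        phi, locked = predict_entrainment_phase(170.0, p)
        assert not locked

    def test_sinusoidal_prc_stable_branch(self):
        # RIC with a small kick has a near-sine PRC; at zero detuning the
        # stable fixed point is the descending zero crossing
        p = EricaParams(lam=0.0, s_star=1.0, eps=0.05, kick_dir=(0.0, -1.0),
                        T_osc=140.0)
        phi, locked = predict_entrainment_phase(140.0, p)
        assert locked
        d = 1e-4
        slope = (prc_analytic(phi + d, p) - prc_analytic(phi - d, p)) / (2 * d)
        assert slope < 0.0

    def test_phi_ent_monotone_in_T_zeit_with_modulation(self, ref_params,
                                                        ref_modulation):
        ents = []
        for Tz in np.arange(120.0, 181.0, 10.0):
            phi, locked = predict_entrainment_phase(Tz, ref_params,
                                                    mod=ref_modulation)
            assert locked
            ents.append(phi)
        un = np.unwrap(ents)
        assert np.all(np.diff(un) > 0)
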