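import numpy as np
import pytest

from actipoly import rheology
from actipoly.bd_engine import StressSeries
from actipoly.rheology import CorrelationSeries


def _series(sxy, dt=1.0, volume=3.0, **other):
    n = len(sxy)
    z = np.zeros(n)
    return StressSeries(
        time=np.arange(n) * dt,
        sxy=np.asarray(sxy, float),
        sxz=other.get("sxz", z.copy()),
        syz=other.get("syz", z.copy()),
        sxx=other.get("sxx", z.copy()),
        syy=other.get("syy", z.copy()),
        szz=other.get("szz", z.copy()),
        volume=volume,
    )


def _maxwell_corr(G0=2.0, tau=5.0, tmax=500.0, n=400):
    t = np.geomspace(1e-3, tmax, n)
    return CorrelationSeries(
        lags=t, G=G0 * np.exp(-t / tau), counts=np.full(n, 1000),
        volume=1.0, kBT=1.0,
    )


def _ou_series(n, dt, tau, s, seed, volume=3.0):
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau)
    b = s * np.sqrt(1 - a * a)
    x = np.empty(n)
    x[0] = s * rng.standard_normal()
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * rng.standard_normal()
    return x


class TestAccumulateG:
    def test_constant_stress(self):
        ss = _series(np.full(200, 3.0), volume=10.0)
        corr = rheology.accumulate_g(ss, kBT=1.0)
        # G = V c^2 / (3 kBT) at every lag
        assert np.allclose(corr.G, 10.0 * 9.0 / 3.0)

    def test_white_noise(self, rng):
        n = 60_000
        s = 0.7
        ss = _series(
            s * rng.standard_normal(n),
            sxz=s * rng.standard_normal(n),
            syz=s * rng.standard_normal(n),
            volume=5.0,
        )
        corr = rheology.accumulate_g(ss, kBT=1.0)
        # G(0) = V s^2 / kBT; G(t>0) ~ 0
        assert corr.G[0] == pytest.approx(5.0 * s**2, rel=0.03)
        later = corr.G[(corr.lags > 0) & (corr.counts >= 1000)]
        assert np.abs(later).max() < 0.05 * corr.G[0]

    def test_ou_decay_time_recovered(self):
        tau = 0.5
        x = _ou_series(150_000, 0.01, tau, 1.0, seed=2)
        ss = _series(x, dt=0.01, volume=3.0)
        corr = rheology.accumulate_g(ss)
        fit = rheology.fit_plateau_and_tau(corr)
        assert fit.tau_eff == pytest.approx(tau, rel=0.05)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            rheology.accumulate_g(_series([1.0]))

    def test_multiple_tau_matches_brute_force(self):
        """On a smooth synthetic series the pre-averaged estimator agrees with
        the exact FFT autocorrelation to < 2% at every well-sampled lag."""
        n = 10_000
        t = np.arange(n)
        x = (np.sin(2 * np.pi * t / 2.1e4) + 0.5 * np.cos(2 * np.pi * t / 3.3e4)
             + 0.2)
        lags, corr, counts = rheology.multiple_tau_autocorrelation(x)
        bf = rheology.brute_force_autocorrelation(x)
        sel = counts >= 100
        ref = bf[lags[sel].astype(int)]
        assert np.abs(corr[sel] - ref).max() < 0.02 * np.abs(ref).max()


class TestPlateauFit:
    def test_exact_maxwell(self):
        fit = rheology.fit_plateau_and_tau(_maxwell_corr())
        assert fit.G0 == pytest.approx(2.0, abs=1e-6)
        assert fit.tau_eff == pytest.approx(5.0, abs=1e-6)
        assert not fit.no_plateau

    def test_power_law_flags_no_plateau(self):
        t = np.geomspace(1e-2, 100, 200)
        corr = CorrelationSeries(
            lags=t, G=t**-0.5, counts=np.full(200, 1000), volume=1.0, kBT=1.0
        )
        fit = rheology.fit_plateau_and_tau(corr)
        assert fit.no_plateau
        assert fit.midtime_slope == pytest.approx(-0.5, abs=1e-6)

    def test_noisy_maxwell_recovery(self, rng):
        t = np.geomspace(1e-2, 60, 600)
        g = 2.0 * np.exp(-t / 5.0) * (1 + 0.05 * rng.standard_normal(len(t)))
        corr = CorrelationSeries(
            lags=t, G=g, counts=np.full(len(t), 1000), volume=1.0, kBT=1.0
        )
        fit = rheology.fit_plateau_and_tau(corr)
        assert fit.G0 == pytest.approx(2.0, rel=0.03)
        assert fit.tau_eff == pytest.approx(5.0, rel=0.03)

    @pytest.mark.parametrize("G0", [0.02, 2.0, 200.0])
    @pytest.mark.parametrize("tau", [0.5, 5.0, 50.0])
    def test_recovery_across_decades(self, G0, tau, rng):
        t = np.geomspace(tau * 1e-3, tau * 12, 300)
        g = G0 * np.exp(-t / tau) * (1 + 0.05 * rng.standard_normal(len(t)))
        corr = CorrelationSeries(
            lags=t, G=g, counts=np.full(len(t), 1000), volume=1.0, kBT=1.0
        )
        fit = rheology.fit_plateau_and_tau(corr)
        assert fit.G0 == pytest.approx(G0, rel=0.03)
        assert fit.tau_eff == pytest.approx(tau, rel=0.03)

    def test_negative_tail_is_not_an_exception(self):
        t = np.geomspace(0.01, 10, 50)
        g = np.linspace(1.0, -0.5, 50)
        corr = CorrelationSeries(
            lags=t, G=g, counts=np.full(50, 10), volume=1.0, kBT=1.0
        )
        fit = rheology.fit_plateau_and_tau(corr)  # must not raise
        assert isinstance(fit.no_plateau, bool)


class TestGreenKubo:
    def test_trapezoid_example(self):
        corr = CorrelationSeries(
            lags=np.array([0.0, 1.0, 2.0]), G=np.array([2.0, 2.0, 2.0]),
            counts=np.array([3, 3, 3]), volume=1.0, kBT=1.0,
        )
        eta_t, eta_inf, _ = rheology.green_kubo_eta(corr)
        assert eta_t[-1] == pytest.approx(4.0)

    def test_maxwell_integral(self):
        eta_t, eta_inf, diag = rheology.green_kubo_eta(_maxwell_corr())
        assert eta_inf == pytest.approx(10.0, rel=1e-3)

    def test_zero_signal(self):
        corr = CorrelationSeries(
            lags=np.linspace(0, 5, 20), G=np.zeros(20),
            counts=np.full(20, 5), volume=1.0, kBT=1.0,
        )
        eta_t, eta_inf, _ = rheology.green_kubo_eta(corr)
        assert np.all(eta_t == 0) and eta_inf == 0


class TestModuli:
    def test_maxwell_closed_forms(self):
        corr = _maxwell_corr(n=2000)
        om = np.geomspace(0.02, 20, 80)
        gp, gpp, omega_c, diag = rheology.moduli(corr, om)
        gp_th = 2 * (om * 5) ** 2 / (1 + (om * 5) ** 2)
        gpp_th = 2 * om * 5 / (1 + (om * 5) ** 2)
        assert np.abs(gp / gp_th - 1).max() < 0.005
        assert np.abs(gpp / gpp_th - 1).max() < 0.005
        assert omega_c == pytest.approx(0.2, rel=0.01)

    def test_low_frequency_loss_limit(self):
        """G''(w)/w -> eta_inf = G0 tau as w -> 0."""
        corr = _maxwell_corr(n=900)
        om = np.array([1e-3])
        _, gpp, _, _ = rheology.moduli(corr, om)
        assert gpp[0] / om[0] == pytest.approx(10.0, rel=0.01)

    def test_zero_signal(self):
        corr = CorrelationSeries(
            lags=np.linspace(0, 5, 30), G=np.zeros(30),
            counts=np.full(30, 5), volume=1.0, kBT=1.0,
        )
        gp, gpp, omega_c, _ = rheology.moduli(corr, np.geomspace(0.1, 10, 5))
        assert np.all(gp == 0) and np.all(gpp == 0) and omega_c is None

    def test_omega_c_consistent_with_tau_eff(self):
        """The two extractors agree: omega_c * tau_eff is order unity."""
        for tau in (0.5, 5.0, 50.0):
            corr = _maxwell_corr(G0=3.0, tau=tau, tmax=100 * tau, n=900)
            fit = rheology.fit_plateau_and_tau(corr)
            om = np.geomspace(0.02 / tau, 20 / tau, 120)
            _, _, omega_c, _ = rheology.moduli(corr, om)
            assert 0.8 <= omega_c * fit.tau_eff <= 1.2


class TestTauEffPrediction:
    def test_active_branch(self):
        assert rheology.tau_eff_prediction(100.0, 8.0) == pytest.approx(
            1.0 / (1e-6 + 0.08)
        )

    def test_passive_branch(self):
        assert rheology.tau_eff_prediction(100.0, 0.0) == pytest.approx(1e6)

    def test_asymptotically_ballistic(self):
        v = 2.0
        for L in (1e3, 1e5):
            ratio = rheology.tau_eff_prediction(L, v) / (L / v)
            assert ratio < 1.0
        assert rheology.tau_eff_prediction(1e5, v) / (1e5 / v) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rheology.tau_eff_prediction(-1.0, 1.0)
        with pytest.raises(ValueError):
            rheology.tau_eff_prediction(1.0, -1.0)


class TestCollapse:
    def test_point_arithmetic(self):
        curves = [
            dict(t=np.array([1.0]), y=np.array([8.0]), L=100.0, v=8.0, Fp=8.0),
            dict(t=np.array([1.0, 2.0]), y=np.array([8.0, 4.0]), L=100.0,
                 v=8.0, Fp=8.0),
        ]
        rescaled, _ = rheology.rescale_collapse(curves, "stress")
        assert rescaled[0]["x"][0] == pytest.approx(0.08)
        assert rescaled[0]["y"][0] == pytest.approx(0.01)

    def test_identical_curves_score_zero(self):
        t = np.geomspace(0.01, 10, 100)
        y = np.exp(-t)
        curves = [
            dict(t=t, y=y, L=1.0, v=1.0, Fp=1.0),
            dict(t=t.copy(), y=y.copy(), L=1.0, v=1.0, Fp=1.0),
        ]
        _, score = rheology.rescale_collapse(curves, "stress")
        assert score == pytest.approx(0.0, abs=1e-14)

    def test_constructed_activity_scaling_collapses(self):
        """Maxwell curves with G0 ~ Fp L and tau ~ L/v collapse to < 1e-6."""
        curves = []
        for L, Fp in [(100.0, 2.0), (400.0, 5.0), (1000.0, 8.0)]:
            v = Fp  # zeta = 1
            tau = 0.2 * L / v
            t = np.geomspace(1e-3 * tau, 5 * tau, 4000)
            curves.append(
                dict(t=t, y=0.7 * Fp * L * np.exp(-t / tau), L=L, v=v, Fp=Fp)
            )
        _, score = rheology.rescale_collapse(curves, "stress")
        assert score < 1e-6

    def test_viscosity_mode_and_missing_metadata(self):
        t = np.geomspace(0.1, 10, 50)
        good = dict(t=t, y=t, L=10.0, v=1.0, zeta=1.0)
        rescaled, _ = rheology.rescale_collapse([good, dict(good)], "viscosity")
        assert np.allclose(rescaled[0]["y"], t / 100.0)
        with pytest.raises(ValueError, match="metadata"):
            rheology.rescale_collapse([dict(t=t, y=t, L=10.0, v=1.0)],
                                      "viscosity")
        with pytest.raises(ValueError, match="mode"):
            rheology.rescale_collapse([good], "entropy")


class TestSteadyStateDiagnostics:
    def test_isotropy_passes_on_symmetric_noise(self, rng):
        n = 20_000
        ss = _series(
            rng.standard_normal(n),
            sxx=1.0 + 0.1 * rng.standard_normal(n),
            syy=1.0 + 0.1 * rng.standard_normal(n),
            szz=1.0 + 0.1 * rng.standard_normal(n),
        )
        rep = rheology.steady_state_diagnostics(None, ss)
        assert rep["isotropy"]["pass"]

    def test_isotropy_fails_on_constructed_anisotropy(self, rng):
        n = 20_000
        syy = 1.0 + 0.05 * rng.standard_normal(n)
        ss = _series(
            rng.standard_normal(n),
            sxx=2.0 * syy,
            syy=syy,
            szz=syy + 0.05 * rng.standard_normal(n),
        )
        rep = rheology.steady_state_diagnostics(None, ss)
        assert not rep["isotropy"]["pass"]

    def test_shuffled_series_is_stationary(self, rng):
        n = 20_000
        x = _ou_series(n, 0.01, 0.3, 1.0, seed=5)
        rng.shuffle(x)
        ss = _series(rng.standard_normal(n), sxx=x, syy=x.copy(), szz=x.copy())
        rep = rheology.steady_state_diagnostics(None, ss)
        assert rep["stationarity_pressure"]["pass"]
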