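import numpy as np
import pytest
from scipy import integrate

from actipoly import RunSchedule, SimulationParameters, make_fixture, run, step
from actipoly.bd_engine import resolve_steady_state_time
from actipoly.system_model import _config_from_chains


def _free_pair_params(**kw):
    """Two beads with every interaction switched off (free diffusion)."""
    base = dict(N=1, Np=2, eps_wca=0.0, eps_fene=0.0, kappa=0.0)
    base.update(kw)
    return SimulationParameters(**base)


class TestStep:
    def test_zero_temperature_zero_force_freezes(self):
        p = _free_pair_params(kBT=0.0)
        cfg = make_fixture("straight_chain", Np=2, spacing=0.97)
        out = step(cfg, p, np.random.default_rng(0))
        assert np.array_equal(out.positions, cfg.positions)
        assert out.time == pytest.approx(p.dt)

    def test_free_diffusion_msd(self):
        """MSD(t)/t -> 6 D0 for force-free beads (within 3 standard errors)."""
        p = _free_pair_params()
        # many independent free 2-bead "chains" for statistics
        rng = np.random.default_rng(5)
        chains = [rng.uniform(400, 600, size=(2, 3)) for _ in range(150)]
        cfg = _config_from_chains(chains, 1000.0)
        p = _free_pair_params(N=150)
        sch = RunSchedule(n_steps=20_000, sample_stride_stress=20_000,
                          sample_stride_config=20_000)
        res = run(cfg, p, sch, seed=6)
        t = sch.n_steps * p.dt
        disp = res.frames[-1].positions_unwrapped - cfg.positions_unwrapped
        msd = np.mean(np.sum(disp**2, axis=1))
        n = cfg.n_beads
        se = np.sqrt(2.0 / n) * 6 * p.D0 * t  # var of chi^2_3 mean
        assert abs(msd - 6 * p.D0 * t) < 3 * se

    def test_active_advection_speed(self):
        """A straight chain crawls head-ward at exactly v = Fp/zeta.

        At kBT = 0 the chain stays rigidly straight (uniform tangential
        force, internal bond forces cancel), so the center-of-mass velocity
        is deterministic; with noise the short-time rate matches within the
        stochastic error.
        """
        p = SimulationParameters(N=1, Np=10, Fp=8.0, eps_wca=0.0, kBT=0.0)
        cfg = make_fixture("straight_chain", Np=10, spacing=0.97)
        sch = RunSchedule(n_steps=5_000, sample_stride_stress=5_000,
                          sample_stride_config=5_000)
        res = run(cfg, p, sch, seed=3)
        t = sch.n_steps * p.dt
        disp = res.frames[-1].positions_unwrapped - cfg.positions_unwrapped
        com = disp.mean(axis=0)
        assert com[0] == pytest.approx(8.0 * t, rel=1e-9)
        assert abs(com[1]) < 1e-9 and abs(com[2]) < 1e-9
        # noisy variant: short horizon so the chain has not reoriented yet
        p2 = SimulationParameters(N=1, Np=10, Fp=8.0, eps_wca=0.0)
        sch2 = RunSchedule(n_steps=2_000, sample_stride_stress=2_000,
                          sample_stride_config=2_000)
        res2 = run(cfg, p2, sch2, seed=4)
        t2 = sch2.n_steps * p2.dt
        com2 = (res2.frames[-1].positions_unwrapped
                - cfg.positions_unwrapped).mean(axis=0)
        se = np.sqrt(2 * p2.D0 * t2 / cfg.n_beads)
        assert com2[0] == pytest.approx(8.0 * t2, abs=5 * se + 0.1 * 8.0 * t2)


class TestRun:
    def test_steady_state_sampling_onset(self, small_melt):
        p = SimulationParameters(N=6, Np=20, Pe=8.0)
        sst = resolve_steady_state_time(p)
        assert sst == pytest.approx(20 / 8.0)
        sch = RunSchedule(n_steps=30_000, sample_stride_stress=10,
                          sample_stride_config=15_000, steady_state_time=sst)
        res = run(small_melt.copy(), p, sch, seed=8)
        assert len(res.stress) > 0
        assert res.stress.time.min() >= sst

    def test_bit_identical_for_same_seed(self, small_melt, small_params):
        sch = RunSchedule(n_steps=2_000, sample_stride_stress=10,
                          sample_stride_config=1_000)
        a = run(small_melt.copy(), small_params, sch, seed=77)
        b = run(small_melt.copy(), small_params, sch, seed=77)
        assert np.array_equal(a.stress.sxy, b.stress.sxy)
        assert np.array_equal(
            a.frames[-1].positions, b.frames[-1].positions
        )
        c = run(small_melt.copy(), small_params, sch, seed=78)
        assert not np.array_equal(a.stress.sxy, c.stress.sxy)

    def test_phantom_chain_ideal_statistics(self):
        """Phantom chains (WCA off, FENE on, kappa=0) are freely jointed:
        <Ree^2> = (Np-1) <b^2> within 5%.

        Without excluded volume the FENE bond is purely attractive with its
        Boltzmann bond length near 0.3 sigma, so chains start near that
        spacing; the freely-jointed identity uses the mean *squared* bond
        length, the exact closed form for independent bond vectors.
        """
        rng = np.random.default_rng(9)
        Np, nch = 50, 100
        chains = []
        for _ in range(nch):
            steps = rng.normal(size=(Np - 1, 3))
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
            X = np.concatenate([[np.zeros(3)], np.cumsum(0.30 * steps, axis=0)])
            chains.append(X + rng.uniform(300, 700, size=3))
        cfg = _config_from_chains(chains, 1000.0)
        p = SimulationParameters(N=nch, Np=Np, eps_wca=0.0, kappa=0.0, dt=2e-4)
        sch = RunSchedule(n_steps=400_000, sample_stride_stress=400_000,
                          sample_stride_config=15_000)
        res = run(cfg, p, sch, seed=10)
        ree2, b2 = [], []
        for fr in res.frames:
            if fr.time < 20.0:  # ~3 Rouse times of burn-in
                continue
            ree2.append(np.mean(fr.end_to_end_sq()))
            b2.append(np.mean(fr.bond_lengths() ** 2))
        ratio = np.mean(ree2) / ((Np - 1) * np.mean(b2))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_energy_stationary_after_equilibration(self, small_melt, small_params):
        """Mean pair+bond energy shows no drift beyond block noise."""
        sch = RunSchedule(n_steps=60_000, sample_stride_stress=50,
                          sample_stride_config=30_000)
        res = run(small_melt.copy(), small_params, sch, seed=11)
        # discard the first fifth, compare block means of halves
        e = None
        rows = res.stress
        e = rows.sxx + rows.syy + rows.szz  # pressure-like proxy
        e = e[len(e) // 5 :]
        h = len(e) // 2
        blocks1 = e[:h].reshape(4, -1).mean(axis=1)
        blocks2 = e[h:].reshape(4, -1).mean(axis=1)
        se = np.hypot(blocks1.std(ddof=1) / 2, blocks2.std(ddof=1) / 2)
        assert abs(blocks1.mean() - blocks2.mean()) < 4 * se


class TestBondDistribution:
    def test_single_bond_boltzmann(self):
        """A single FENE+WCA bond sampled by BD matches the Boltzmann density
        p(r) ~ r^2 exp(-U(r)/kBT): KS distance < 0.01 against direct
        quadrature of the closed-form density.

        A reduced time step keeps the Euler-Maruyama stationary-distribution
        bias well below the KS tolerance.
        """
        from actipoly import forcefield as ff

        p = SimulationParameters(N=1, Np=2, dt=5e-5)
        cfg = make_fixture("straight_chain", Np=2, spacing=0.97)
        sch = RunSchedule(n_steps=3_000_000, sample_stride_stress=25,
                          sample_stride_config=3_000_000)
        res = run(cfg, p, sch, seed=13)
        # for a 2-bead chain the max-bond diagnostic IS the bond length
        r = res.log["bond_max"]
        r = r[len(r) // 10 :]  # burn-in

        grid = np.linspace(1e-3, p.R0 - 1e-9, 4000)
        u = np.array(
            [ff.fene_energy(x, p.eps_fene, p.R0) + ff.wca_energy(x) for x in grid]
        )
        dens = grid**2 * np.exp(-(u - u.min()))
        cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= cdf[-1]
        sample_cdf = np.interp(np.sort(r), grid, cdf)
        emp = (np.arange(1, len(r) + 1) - 0.5) / len(r)
        ks = np.abs(sample_cdf - emp).max()
        assert ks < 0.01

    def test_dt_robustness_of_bond_statistics(self, small_melt):
        """Doubling dt from 1e-4 to 2e-4 shifts the stationary mean bond
        length by < 0.5%."""
        means = []
        for dt in (1e-4, 2e-4):
            p = SimulationParameters(N=6, Np=20, dt=dt)
            sch = RunSchedule(
                n_steps=int(3.0 / dt), sample_stride_stress=100,
                sample_stride_config=int(3.0 / dt),
            )
            res = run(small_melt.copy(), p, sch, seed=17)
            e = res.log["e_fene"]
            means.append(np.mean(e[len(e) // 3 :]))
        # FENE energy per bond is a stiff monotone proxy for bond length;
        # 0.5% in length is ~2.5% in energy at this curvature
        assert abs(means[1] - means[0]) / means[0] < 0.025
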