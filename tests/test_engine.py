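"""Scheduler, trajectory recording and replicate-management tests."""

import numpy as np
import pytest

from raftsim.engine import (
    ConfigError,
    DomainSpec,
    SimConfig,
    init_state,
    run,
    run_replicates,
    tick,
    window_mean,
)
from raftsim.membrane import MotionParams, Species
from raftsim.reactions import ReactionParams


class TestConfig:
    def test_defaults_match_standard_setup(self):
        cfg = SimConfig()
        assert cfg.n_receptor_monomers == 47
        assert cfg.reactions.k_b == 0.05 and cfg.reactions.k_d == 0.01
        assert cfg.n_steps == 200_000 and cfg.window == 50_000
        assert cfg.replicates == 3
        assert cfg.mono_radius == pytest.approx(0.038 * 30 / 2)
        assert cfg.crowder_radius == pytest.approx(0.05 * 30 / 2)
        assert cfg.domains.occupied_percent == 35.0

    def test_window_larger_than_steps_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_steps=100, window=200)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_receptor_monomers=-1)


class TestInitState:
    def test_default_initial_state(self, rng):
        state = init_state(SimConfig(), rng)
        assert state.n_monomers == 47
        assert state.n_dimers == 0
        assert state.n_inert == 0
        assert len(state.domains.circles) == 1
        assert state.domains.occupied_fraction == pytest.approx(0.35)
        assert not state.has_overlap()

    def test_empty_receptor_state(self, rng, no_domain):
        state = init_state(SimConfig(n_receptor_monomers=0, domains=no_domain),
                           rng)
        assert state.n_molecules == 0

    def test_crowded_packing_feasible(self, rng, no_domain):
        state = init_state(
            SimConfig(n_inert=200, domains=no_domain), rng)
        assert state.n_inert == 200 and state.n_monomers == 47
        assert not state.has_overlap()


class TestTick:
    def test_fixed_point_when_frozen(self, rng, no_domain):
        cfg = SimConfig(
            domains=no_domain,
            motion=MotionParams(d_out=1e-300, d_in=1e-300),
            reactions=ReactionParams(k_b=0.0, k_d=0.0),
            n_receptor_monomers=10, n_steps=10, window=5, seed=2)
        state = init_state(cfg, rng)
        before = state.pos.copy()
        for t in range(5):
            tick(state, cfg, rng, t + 1)
        assert np.allclose(state.pos, before, atol=1e-140)

    def test_zero_binding_rate_never_dimerises(self, rng, no_domain):
        cfg = SimConfig(domains=no_domain,
                        reactions=ReactionParams(k_b=0.0, k_d=0.01),
                        n_receptor_monomers=20, n_steps=50, window=10, seed=3)
        state = init_state(cfg, rng)
        for t in range(50):
            tick(state, cfg, rng, t + 1)
            assert state.n_dimers == 0

    def test_conservation_through_reactions(self, rng, no_domain):
        cfg = SimConfig(domains=no_domain,
                        reactions=ReactionParams(k_b=0.5, k_d=0.2),
                        n_receptor_monomers=20, n_steps=50, window=10, seed=4)
        state = init_state(cfg, rng)
        for t in range(100):
            tick(state, cfg, rng, t + 1)
            assert state.n_molecules == 20


class TestRun:
    def test_zero_steps_yields_initial_record(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, n_steps=0, window=0)
        series = run(cfg)
        assert list(series.step) == [0]
        assert series.fraction_dimeric[0] == 0.0

    def test_bit_reproducibility(self, small_config):
        a = run(small_config, seed=99)
        b = run(small_config, seed=99)
        assert np.array_equal(a.n_dimers, b.n_dimers)
        assert np.array_equal(a.fraction_inside, b.fraction_inside)

    def test_seeds_differ(self, small_config):
        a = run(small_config, seed=1)
        b = run(small_config, seed=2)
        assert not np.array_equal(a.n_dimers, b.n_dimers)

    def test_conservation_recorded(self, small_config):
        series = run(small_config)
        total = series.n_monomers + 2 * series.n_dimers
        assert np.all(total == series.n_total_molecules)

    def test_python_backend_agrees_statistically(self, no_domain):
        """Short crowded runs: the numba kernel and the reference Python
        scheduler land on the same equilibrium within Monte-Carlo noise."""
        cfg = SimConfig(domains=no_domain,
                        reactions=ReactionParams(k_b=0.3, k_d=0.1),
                        n_receptor_monomers=30,
                        n_steps=3_000, window=1_500, thin=10, replicates=2,
                        seed=5)
        fast = run_replicates(cfg, backend="numba")["fraction_dimeric"].mean
        slow = run_replicates(cfg, backend="python")["fraction_dimeric"].mean
        assert fast == pytest.approx(slow, abs=0.08)

    def test_free_diffusion_msd_slope(self, no_domain):
        """Single agent, D=1, half-normal law: the empirical MSD grows
        linearly with lag and its slope matches E[r^2] = D within 5%."""
        cfg = SimConfig(domains=no_domain, n_receptor_monomers=1,
                        reactions=ReactionParams(k_b=0.0, k_d=0.0),
                        n_steps=100_000, window=10, thin=1, seed=8)
        series = run(cfg, track_first=True)
        traj = series.trajectory
        assert traj is not None
        # short lags give thousands of independent blocks, so the 5%
        # band is many standard errors wide; the long lag only checks
        # linearity coarsely (few independent blocks remain)
        for lag, rel in ((1, 0.05), (10, 0.05), (100, 0.08), (1000, 0.25)):
            disp = traj[lag:] - traj[:-lag]
            msd = np.mean(np.sum(disp**2, axis=1))
            assert msd == pytest.approx(1.0 * lag, rel=rel)

    def test_equal_diffusivity_occupancy_matches_area(self, rng):
        """With d_in = d_out a non-reacting receptor spends time inside
        the domain in proportion to its area (35% +/- 2 pp)."""
        cfg = SimConfig(reactions=ReactionParams(k_b=0.0, k_d=0.0),
                        n_receptor_monomers=1, n_steps=200_000,
                        window=150_000, thin=10, seed=9, replicates=3)
        stats = run_replicates(cfg)
        assert stats["fraction_inside"].mean == pytest.approx(0.35, abs=0.02)


class TestWindowMean:
    def make_series(self, values):
        from raftsim.engine import TimeSeries

        n = len(values)
        arr = np.asarray(values, dtype=float)
        return TimeSeries(step=np.arange(n), n_monomers=arr,
                          n_dimers=np.zeros(n), fraction_dimeric=np.zeros(n),
                          fraction_inside=np.zeros(n), n_total_molecules=1,
                          seed=0)

    def test_constant_series(self):
        s = self.make_series([4.0] * 50)
        assert window_mean(s, 20)["n_monomers"] == 4.0

    def test_arithmetic_example(self):
        s = self.make_series(np.arange(101))  # steps 0..100, values 0..100
        assert window_mean(s, 10)["n_monomers"] == pytest.approx(95.5)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            window_mean(self.make_series([1.0, 2.0]), 10)

    def test_thinned_window_mean_close_to_full(self, small_config):
        import dataclasses

        thin1 = run(dataclasses.replace(small_config, thin=1), seed=21)
        full = window_mean(thin1, 1_000)["fraction_dimeric"]
        sub = thin1.fraction_dimeric[thin1.step % 10 == 0]
        steps = thin1.step[thin1.step % 10 == 0]
        thinned = sub[steps > thin1.step[-1] - 1_000].mean()
        assert thinned == pytest.approx(full, abs=0.03)


class TestReplicates:
    def test_single_replicate_sd_not_applicable(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, replicates=1)
        stats = run_replicates(cfg)
        assert stats["fraction_dimeric"].sd is None
        assert stats["fraction_dimeric"].n_replicates == 1

    def test_replicate_stats(self, small_config):
        stats = run_replicates(small_config)
        s = stats["fraction_dimeric"]
        assert s.n_replicates == 2
        reps = stats["_replicates"]["fraction_dimeric"]
        assert s.mean == pytest.approx(np.mean(reps))
        assert s.sd == pytest.approx(np.std(reps, ddof=1))

    def test_stationarity_of_late_windows(self):
        """Window means over ticks (100k,150k] and (150k,200k] agree
        within 3 SD of replicate scatter (equilibration check)."""
        cfg = SimConfig(seed=13, replicates=3)
        m_late, m_mid = [], []
        for s in (13, 14, 15):
            series = run(cfg, seed=s)
            mask_mid = (series.step > 100_000) & (series.step <= 150_000)
            mask_late = series.step > 150_000
            m_mid.append(series.fraction_dimeric[mask_mid].mean())
            m_late.append(series.fraction_dimeric[mask_late].mean())
        diff = abs(np.mean(m_late) - np.mean(m_mid))
        scatter = max(np.std(m_late, ddof=1), np.std(m_mid, ddof=1), 0.005)
        assert diff < 3 * scatter
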