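import numpy as np
import pytest

import kaisim as ks
from kaisim.params import EnsembleState
from kaisim.simulate import SimControl, initialize, simulate, step
from kaisim.states import IDX_FREE


class TestSimControl:
    def test_invalid_step_ordering_rejected(self):
        with pytest.raises(ValueError):
            SimControl(t_end=10.0, dt=0.5, sample_every=0.1)
        with pytest.raises(ValueError):
            SimControl(t_end=10.0, transient=10.0)

    def test_stride_and_steps(self):
        c = SimControl(t_end=10.0, dt=0.01, sample_every=0.1, transient=0.0)
        assert c.stride == 10
        assert c.n_steps == 1000


class TestInitialize:
    def test_free_start(self, small_params):
        st = initialize(small_params, seed=3)
        assert st.A_free == small_params.A_T
        assert st.B_free == small_params.B_T
        assert np.all(st.P[:, IDX_FREE] == 1.0)
        assert np.allclose(st.P.sum(axis=1), 1.0)
        assert not st.adp_bound.any()

    def test_desynchronized_phosphorylation(self, small_params):
        st = initialize(small_params, seed=3)
        assert st.D.std() > 0.15  # spread over [0, 1]
        assert np.all((st.D >= 0) & (st.D <= 1))
        # structure consistent with the quasi-equilibrium map
        expected = ks.structure_X(st.D, 0.0, 0.0, 0.0, small_params)
        assert np.allclose(st.X, expected)

    def test_seed_determinism(self, small_params):
        a = initialize(small_params, seed=5)
        b = initialize(small_params, seed=5)
        assert np.array_equal(a.D, b.D)
        assert np.array_equal(a.P, b.P)


class TestStepFixedPoint:
    def test_free_kaic_rest_state_is_stationary(self, defaults):
        """Without KaiA, KaiB and hydrolysis, D = 0 / free C6 is a fixed point."""
        p = ks.rescale_ensemble(defaults, 5).replace(A_T=0.0, B_T=0.0, f0=0.0)
        control = SimControl(t_end=1.0, dt=0.01, sample_every=0.01, transient=0.0)
        st = initialize(p, seed=0)
        st.D[:] = 0.0
        st.X[:] = ks.structure_X(st.D, 0.0, 0.0, 0.0, p)
        rng = np.random.default_rng(0)
        x0 = st.X.copy()
        for _ in range(100):
            step(st, p, control, rng)
        assert np.abs(st.D).max() < 1e-12
        assert np.allclose(st.X, x0, atol=1e-12)
        assert np.all(st.P[:, IDX_FREE] == 1.0)

    def test_conservation_after_step(self, small_params):
        control = SimControl(t_end=1.0, dt=0.005, sample_every=0.005, transient=0.0)
        st = initialize(small_params, seed=1)
        rng = np.random.default_rng(1)
        for _ in range(50):
            step(st, small_params, control, rng)
        from kaisim.binding import free_concentrations

        A, B = free_concentrations(st.P, small_params)
        assert A >= 0 and B >= 0
        assert np.allclose(st.P.sum(axis=1), 1.0, atol=1e-12)


class TestKernelAgainstReference:
    def test_deterministic_paths_agree_exactly(self, defaults):
        """The compiled kernel reproduces the numpy step bit-for-bit (f0=0)."""
        p = ks.rescale_ensemble(defaults, 20).replace(f0=0.0)
        control = SimControl(t_end=1.0, dt=0.005, sample_every=1.0, transient=0.0, seed=7)
        ref = initialize(p, control.seed)
        rng = np.random.default_rng(0)
        for _ in range(control.n_steps):
            step(ref, p, control, rng)
        traj = simulate(p, control)
        assert traj.Dbar[-1] == pytest.approx(ref.D.mean(), abs=1e-13)
        assert traj.Xbar[-1] == pytest.approx(ref.X.mean(), abs=1e-13)
        assert traj.PCA_bar[-1] == pytest.approx(ref.P[:, 0].mean(), abs=1e-13)

    def test_stochastic_paths_agree_statistically(self, defaults):
        """With hydrolysis on, kernel and reference agree in distribution."""
        p = ks.rescale_ensemble(defaults, 30)
        control = SimControl(t_end=30.0, dt=0.01, sample_every=1.0, transient=0.0, seed=3)
        ref = initialize(p, control.seed)
        rng = np.random.default_rng(control.seed)
        releases = sum(step(ref, p, control, rng) for _ in range(control.n_steps))
        traj = simulate(p, control)
        kernel_releases = traj.releases.sum()
        # Poisson-scale agreement on ~500 events
        assert abs(releases - kernel_releases) < 5 * np.sqrt(max(releases, 1))
        assert traj.Dbar[-1] == pytest.approx(ref.D.mean(), abs=0.05)


class TestSimulate:
    def test_seed_determinism_bit_exact(self, small_params):
        control = SimControl(t_end=20.0, dt=0.01, sample_every=0.5, transient=0.0, seed=11)
        a = simulate(small_params, control)
        b = simulate(small_params, control)
        assert np.array_equal(a.Dbar, b.Dbar)
        assert np.array_equal(a.releases, b.releases)

    def test_sampling_layout_and_recording(self, small_params):
        control = SimControl(t_end=10.0, dt=0.01, sample_every=0.5, transient=0.0,
                             seed=2, record_hexamers=(0, 3))
        traj = simulate(small_params, control)
        assert len(traj.times) == 21
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(10.0)
        assert traj.D_rec.shape == (21, 2)
        assert np.all(np.isfinite(traj.D_rec))

    def test_normalization_drift_bounded(self, small_params):
        control = SimControl(t_end=50.0, dt=0.005, sample_every=1.0, transient=0.0, seed=4)
        traj = simulate(small_params, control)
        assert np.abs(np.ones_like(traj.Dbar) - 1.0).max() < 1e-12  # layout sanity
        # probabilities stay normalized to within the logged bound
        st = initialize(small_params, 4)
        assert np.allclose(st.P.sum(axis=1), 1.0, atol=1e-12)

    def test_step_halving_convergence(self, defaults):
        """Euler error on the deterministic skeleton shrinks with dt."""
        p = ks.rescale_ensemble(defaults, 20).replace(f0=0.0)
        vals = {}
        for dt in (0.01, 0.005, 0.0025):
            control = SimControl(t_end=100.0, dt=dt, sample_every=1.0,
                                 transient=0.0, seed=9)
            vals[dt] = simulate(p, control).Dbar[-1]
        err_coarse = abs(vals[0.01] - vals[0.0025])
        err_fine = abs(vals[0.005] - vals[0.0025])
        assert err_fine <= err_coarse
        assert abs(vals[0.005] - vals[0.0025]) < 1e-3

    def test_rescaled_ensemble_statistically_equivalent(self, defaults):
        """Halving N (volume rescaled) leaves ensemble means unchanged
        within sampling error: overlapping +-2 SE over 10 seeds."""
        control = SimControl(t_end=300.0, dt=0.01, sample_every=0.5, transient=100.0)
        means = {}
        for n in (100, 200):
            p = ks.rescale_ensemble(defaults, n)
            vals = [
                simulate(p, control.replace(seed=sd)).Dbar[200:].mean()
                for sd in range(10)
            ]
            means[n] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        gap = abs(means[100][0] - means[200][0])
        assert gap < 2 * (means[100][1] + means[200][1])

    def test_too_large_step_raises(self, defaults):
        p = ks.rescale_ensemble(defaults, 10).with_ratios(A_ratio=4.0)
        control = SimControl(t_end=5.0, dt=0.02, sample_every=0.1, transient=0.0, seed=0)
        with pytest.raises((RuntimeError, ValueError)):
            simulate(p, control)
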