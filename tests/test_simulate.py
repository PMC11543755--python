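"""Initial conditions, time stepping, conservation and dissipation."""

import hashlib

import numpy as np
import pytest

from llps_gsa.model import ModelParameters, free_energy
from llps_gsa.simulate import (GridSpec, InitialConditionSpec, SolverBlowUp,
                               make_initial_state, simulate, step)


@pytest.fixture
def grid():
    return GridSpec(nx=32, length=2.5)


def conserved_means(state):
    return np.array([
        (state.P + state.K1 + state.K2).mean(),
        (state.R1 + state.K1).mean(),
        (state.R2 + state.K2).mean(),
    ])


class TestInitialConditions:
    def test_equal_ratio_splits_rna_evenly(self, grid):
        spec = InitialConditionSpec(ratio="1:1", P0=0.5, noise_amplitude=0.0,
                                    rna_noise_amplitude=0.0)
        state = make_initial_state(spec, grid)
        assert np.allclose(state.R1, 0.25)
        assert np.allclose(state.R2, 0.25)
        assert np.allclose(state.P, 0.5)

    def test_skewed_ratio(self, grid):
        spec = InitialConditionSpec(ratio="3:1", P0=0.5, noise_amplitude=0.0,
                                    rna_noise_amplitude=0.0)
        state = make_initial_state(spec, grid)
        assert np.allclose(state.R1, 0.375)
        assert np.allclose(state.R2, 0.125)

    def test_no_preformed_complexes(self, grid):
        state = make_initial_state(InitialConditionSpec(seed=3), grid)
        assert not state.K1.any()
        assert not state.K2.any()

    def test_seed_determinism(self, grid):
        a = make_initial_state(InitialConditionSpec(seed=7), grid)
        b = make_initial_state(InitialConditionSpec(seed=7), grid)
        assert np.array_equal(a.P, b.P)
        c = make_initial_state(InitialConditionSpec(seed=8), grid)
        assert not np.array_equal(a.P, c.P)

    def test_white_noise_bounded_by_amplitude(self, grid):
        spec = InitialConditionSpec(P0=0.5, noise_amplitude=0.05,
                                    noise_scale=0.0, seed=1)
        state = make_initial_state(spec, grid)
        assert np.all(np.abs(state.P - 0.5) <= 0.05)

    def test_correlated_noise_keeps_std_and_stays_admissible(self, grid):
        spec = InitialConditionSpec(P0=0.5, noise_amplitude=0.45,
                                    noise_scale=0.08, seed=1)
        state = make_initial_state(spec, grid)
        assert state.P.std() == pytest.approx(0.45 / np.sqrt(3), rel=0.05)
        assert state.P.min() > 0 and state.P.max() < 1
        # RNA fields mirror the protein field pointwise
        assert np.allclose(state.P + state.R1 + state.R2, 1.0, atol=1e-12)

    @pytest.mark.parametrize("bad", [dict(ratio="4:1"), dict(P0=0.0),
                                     dict(noise_amplitude=0.6)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            InitialConditionSpec(**bad)


class TestStep:
    def test_uniform_state_is_fixed_point_without_reactions(self, grid):
        params = ModelParameters(a2=0.0, a4=0.0, epsilon=0.06)
        spec = InitialConditionSpec(P0=0.5, noise_amplitude=0.0,
                                    rna_noise_amplitude=0.0)
        state = make_initial_state(spec, grid)
        state.P[:] = 0.0   # no protein, no reactions, uniform fields
        new = step(state, params, dt=1e-3)
        for name, arr in new.fields().items():
            assert np.allclose(arr, state.fields()[name], atol=1e-13), name

    def test_means_conserved_across_step(self, grid):
        params = ModelParameters(epsilon=0.06)
        state = make_initial_state(InitialConditionSpec(seed=5), grid)
        before = conserved_means(state)
        for _ in range(20):
            state = step(state, params, dt=1e-3)
        after = conserved_means(state)
        assert np.all(np.abs(after - before) / before < 1e-12)

    def test_energy_dissipation_without_reactions(self, grid, rng):
        # pure Cahn-Hilliard/diffusion gradient flow: discrete free energy
        # must not increase
        params = ModelParameters(a1=1e-12, a2=0.0, a3=1e-12, a4=0.0,
                                 epsilon=0.06)
        K1 = 0.25 + 0.02 * rng.standard_normal(grid.shape)
        K2 = 0.25 + 0.02 * rng.standard_normal(grid.shape)
        state = make_initial_state(
            InitialConditionSpec(noise_amplitude=0.0), grid)
        state.K1, state.K2 = K1, K2
        energies = [free_energy(state, params)]
        for _ in range(50):
            state = step(state, params, dt=1e-3)
            energies.append(free_energy(state, params))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-8)

    def test_rejects_nonpositive_dt(self, grid):
        params = ModelParameters()
        state = make_initial_state(InitialConditionSpec(), grid)
        with pytest.raises(ValueError):
            step(state, params, dt=0.0)


class TestSimulate:
    def test_recording_contract(self, grid):
        traj = simulate(ModelParameters(epsilon=0.06),
                        InitialConditionSpec(seed=1), grid, t_cap=5)
        assert list(traj.times) == [0, 1, 2, 3, 4, 5]

    def test_conservation_over_trajectory(self, grid):
        traj = simulate(ModelParameters(epsilon=0.06),
                        InitialConditionSpec(seed=2), grid, t_cap=3)
        base = conserved_means(traj.snapshots[0])
        for snap in traj.snapshots[1:]:
            drift = np.abs(conserved_means(snap) - base) / base
            assert drift.max() < 1e-8

    def test_seed_determinism_bitwise(self, grid):
        def run():
            traj = simulate(ModelParameters(epsilon=0.06),
                            InitialConditionSpec(seed=11), grid, t_cap=2)
            digest = hashlib.sha256()
            for snap in traj.snapshots:
                for arr in snap.fields().values():
                    digest.update(arr.tobytes())
            return digest.hexdigest()

        assert run() == run()

    def test_early_stop_predicate(self, grid):
        calls = []

        def stop(snap):
            calls.append(snap.time)
            return snap.time >= 2

        traj = simulate(ModelParameters(epsilon=0.06),
                        InitialConditionSpec(seed=1), grid, t_cap=10,
                        stop_when=stop)
        assert traj.times[-1] == 2
        assert calls == [0.0, 1.0, 2.0]

    def test_blowup_reports_time(self, grid):
        # explicit reactions with dt * a1 >> 1 overshoot immediately and no
        # halving headroom is given
        bad = ModelParameters(a1=1e6)
        with pytest.raises(SolverBlowUp) as err:
            simulate(bad, InitialConditionSpec(seed=1),
                     GridSpec(nx=8, length=0.1), t_cap=2, dt=0.5,
                     max_halvings=0)
        assert err.value.time is not None

    def test_refinement_consistency(self, grid):
        # halving dt moves the t=2 complex field by less than the scheme's
        # own step-to-step scale on a short smoke run
        params = ModelParameters(epsilon=0.06)
        spec = InitialConditionSpec(seed=3)
        a = simulate(params, spec, grid, t_cap=2, dt=1e-3)
        b = simulate(params, spec, grid, t_cap=2, dt=5e-4)
        diff = np.abs(a.at(2).K1 - b.at(2).K1).max()
        assert diff < 5e-2
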