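"""Free energy, chemical potentials and reaction kinetics."""

import numpy as np
import pytest

from llps_gsa.model import (FieldState, ModelParameters,
                            bulk_free_energy_density, chemical_potentials,
                            free_energy, reaction_terms, solvent_field)

from conftest import random_admissible_state


def uniform_state(K1, K2, P=0.2, R1=0.1, R2=0.1, shape=(16, 16), h=0.1):
    full = np.full
    return FieldState(K1=full(shape, K1), K2=full(shape, K2),
                      P=full(shape, P), R1=full(shape, R1),
                      R2=full(shape, R2), h=h)


class TestSolventField:
    def test_uniform_identity(self):
        S = solvent_field(uniform_state(0.2, 0.3))
        assert np.allclose(S, 0.5)

    def test_empty_complex_limit(self):
        S = solvent_field(uniform_state(0.0, 0.0))
        assert np.allclose(S, 1.0)

    def test_pointwise_partition_of_unity(self, random_state):
        S = solvent_field(random_state)
        total = S + random_state.K1 + random_state.K2
        assert np.allclose(total, 1.0, atol=1e-14)
        assert S.min() > 0

    def test_raises_when_solvent_exhausted(self):
        state = uniform_state(0.6, 0.5)
        with pytest.raises(ValueError, match="S <= 0"):
            solvent_field(state)


class TestFreeEnergy:
    def test_uniform_closed_form(self, params):
        # K1 = K2 = S = 1/3: gradient term vanishes, bulk has a closed form
        state = uniform_state(1 / 3, 1 / 3, h=0.25)
        area = state.K1.size * state.h**2
        expected = area * params.A * (np.log(1 / 3)
                                      + params.chi_K1K2 / 9
                                      + 2 * params.chi_S / 9)
        assert free_energy(state, params) == pytest.approx(expected, rel=1e-12)

    def test_solvent_only_limit(self, params):
        # K1 = K2 -> 0: S ln S -> 0 and the energy vanishes up to the
        # O(A * delta) offset of the regularised entropy below its clamp
        from llps_gsa.model import LOG_CLAMP
        state = uniform_state(1e-12, 1e-12)
        area = state.K1.size * state.h**2
        bound = 1.5 * params.A * LOG_CLAMP * area
        assert abs(free_energy(state, params)) < bound

    def test_matches_direct_summation_oracle(self, params, random_state):
        # independent oracle: evaluate the integrand cell by cell with
        # centred-difference gradients, then sum
        s = random_state
        eps = params.resolve_epsilon(s.h)
        total = 0.0
        nx, ny = s.shape
        for i in range(nx):
            for j in range(ny):
                gx1 = (s.K1[(i + 1) % nx, j] - s.K1[i - 1, j]) / (2 * s.h)
                gy1 = (s.K1[i, (j + 1) % ny] - s.K1[i, j - 1]) / (2 * s.h)
                gx2 = (s.K2[(i + 1) % nx, j] - s.K2[i - 1, j]) / (2 * s.h)
                gy2 = (s.K2[i, (j + 1) % ny] - s.K2[i, j - 1]) / (2 * s.h)
                K1, K2 = s.K1[i, j], s.K2[i, j]
                S = 1 - K1 - K2
                bulk = params.A * (K1 * np.log(K1) + K2 * np.log(K2)
                                   + S * np.log(S) + params.chi_K1K2 * K1 * K2
                                   + params.chi_S * K1 * S
                                   + params.chi_S * K2 * S)
                total += (0.5 * eps**2 * (gx1**2 + gy1**2 + gx2**2 + gy2**2)
                          + bulk) * s.h**2
        assert free_energy(s, params, method="fd") == pytest.approx(
            total, rel=1e-10)

    def test_translation_invariance(self, params, random_state):
        s = random_state
        shifted = FieldState(
            **{k: np.roll(v, (3, -5), axis=(0, 1))
               for k, v in s.fields().items()}, h=s.h)
        for method in ("spectral", "fd"):
            assert free_energy(shifted, params, method) == pytest.approx(
                free_energy(s, params, method), rel=1e-12)

    def test_discretizations_agree_on_smooth_field(self, params):
        # on a well-resolved smooth field the spectral and centred-difference
        # energies agree to discretisation error
        n, h = 64, 0.1
        x = np.arange(n) * h
        X, Y = np.meshgrid(x, x, indexing="ij")
        Lx = n * h
        K = 0.25 + 0.05 * np.sin(2 * np.pi * X / Lx) \
            * np.cos(4 * np.pi * Y / Lx)
        state = FieldState(K1=K, K2=K[::-1].copy(), P=np.full_like(K, 0.2),
                           R1=np.full_like(K, 0.1), R2=np.full_like(K, 0.1),
                           h=h)
        fs = free_energy(state, params, "spectral")
        fd = free_energy(state, params, "fd")
        assert fd == pytest.approx(fs, rel=1e-2)


class TestChemicalPotentials:
    def test_exchange_symmetry(self, params, random_state):
        s = random_state
        mu1, mu2 = chemical_potentials(s, params)
        swapped = FieldState(K1=s.K2, K2=s.K1, P=s.P, R1=s.R1, R2=s.R2,
                             h=s.h)
        mu1s, mu2s = chemical_potentials(swapped, params)
        assert np.allclose(mu1s, mu2, atol=1e-13)
        assert np.allclose(mu2s, mu1, atol=1e-13)

    def test_uniform_bulk_closed_form(self, params):
        K1, K2 = 0.3, 0.2
        state = uniform_state(K1, K2)
        S = 1 - K1 - K2
        expected1 = params.A * (np.log(K1 / S) + params.chi_K1K2 * K2
                                + params.chi_S * (1 - 2 * K1 - 2 * K2))
        expected2 = params.A * (np.log(K2 / S) + params.chi_K1K2 * K1
                                + params.chi_S * (1 - 2 * K1 - 2 * K2))
        mu1, mu2 = chemical_potentials(state, params)
        assert np.allclose(mu1, expected1, atol=1e-12)
        assert np.allclose(mu2, expected2, atol=1e-12)

    def test_matches_finite_difference_of_free_energy(self, params, rng):
        # the discrete variational derivative: dF/dK1_ij = mu1_ij * h^2
        s = random_admissible_state(rng, shape=(16, 16), h=0.15)
        mu1, mu2 = chemical_potentials(s, params)
        delta = 1e-6   # below this, roundoff in F dominates the quotient
        cells = [(rng.integers(16), rng.integers(16)) for _ in range(120)]
        for i, j in cells:
            for mu, name in ((mu1, "K1"), (mu2, "K2")):
                plus = s.copy()
                getattr(plus, name)[i, j] += delta
                minus = s.copy()
                getattr(minus, name)[i, j] -= delta
                fd = (free_energy(plus, params) - free_energy(minus, params)) \
                    / (2 * delta * s.h**2)
                # abs floor covers cells where mu ~ 0 and the quotient is
                # dominated by roundoff in F
                assert fd == pytest.approx(mu[i, j], rel=1e-6, abs=1e-6)


class TestReactionTerms:
    def test_direct_substitution(self):
        state = uniform_state(0.0, 0.1, P=0.5, R1=0.25, R2=0.1)
        params = ModelParameters(a1=1.0, a2=0.01)
        src = reaction_terms(state, params)
        assert np.allclose(src["K1"], 0.125)

    def test_no_protein_no_reactions(self):
        state = uniform_state(0.0, 0.0, P=0.0, R1=0.2, R2=0.2)
        params = ModelParameters(a2=0.0, a4=0.0)
        src = reaction_terms(state, params)
        for arr in src.values():
            assert np.allclose(arr, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_pointwise_conservation_triples(self, seed):
        rng = np.random.default_rng(seed)
        state = random_admissible_state(rng)
        params = ModelParameters(a1=rng.uniform(0.5, 1.5),
                                 a2=rng.uniform(0, 0.5),
                                 a3=rng.uniform(0.5, 1.5),
                                 a4=rng.uniform(0, 0.5))
        src = reaction_terms(state, params)
        zero = np.zeros_like(src["K1"])
        assert np.allclose(src["P"] + src["K1"] + src["K2"], zero, atol=1e-15)
        assert np.allclose(src["R1"] + src["K1"], zero, atol=1e-15)
        assert np.allclose(src["R2"] + src["K2"], zero, atol=1e-15)


class TestAlgebraicProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    frac = st.floats(1e-6, 0.45, allow_nan=False)
    rate = st.floats(1e-3, 1.5, allow_nan=False)

    @given(k1=frac, k2=frac, p=frac, r1=frac, r2=frac,
           a1=rate, a2=rate, a3=rate, a4=rate)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_reaction_conservation_everywhere(self, k1, k2, p, r1, r2,
                                              a1, a2, a3, a4):
        """The kinetic sources always cancel in the conserved
        combinations P+K1+K2, R1+K1, R2+K2, for any admissible state."""
        state = uniform_state(k1, k2, P=p, R1=r1, R2=r2, shape=(4, 4))
        params = ModelParameters(a1=a1, a2=a2, a3=a3, a4=a4)
        src = reaction_terms(state, params)
        assert abs(src["P"] + src["K1"] + src["K2"]).max() < 1e-15
        assert abs(src["R1"] + src["K1"]).max() < 1e-15
        assert abs(src["R2"] + src["K2"]).max() < 1e-15

    @given(k1=frac, k2=frac)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_solvent_partition_of_unity(self, k1, k2):
        state = uniform_state(k1, k2, shape=(4, 4))
        S = solvent_field(state)
        assert np.allclose(S + k1 + k2, 1.0, atol=1e-14)


class TestParameterValidation:
    def test_defaults_are_reported_values(self, params):
        assert params.chi_S == 4.25
        assert params.chi_K1K2 == 4.5
        assert params.A == 0.2
        assert (params.a1, params.a2, params.a3, params.a4) == (1.0, 0.01,
                                                                1.0, 0.01)
        assert params.lambda_P == 3.75

    @pytest.mark.parametrize("bad", [dict(lambda_P=-1), dict(a1=0),
                                     dict(a2=-0.1), dict(A=0),
                                     dict(epsilon=-1)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)
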