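"""Exchange-matrix construction, eigenstructure, signal simulation and the
Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import dexsim as dx

KT, KG = 300.0, 30.0


def random_fractions(draw_vals):
    f = np.asarray(draw_vals, dtype=float) + 1e-3
    return f / f.sum()


fractions3 = st.builds(
    random_fractions,
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))


class TestBuildExchangeMatrix:
    def test_two_site_equal_fractions(self):
        K = dx.build_exchange_matrix(dx.ExchangeSpec.two_site(300.0),
                                     (0.5, 0.5))
        assert np.allclose(K, 300.0 * np.array([[0.5, -0.5], [-0.5, 0.5]]))

    def test_equilibrium_is_null_vector(self):
        f = (0.32, 0.34, 0.34)
        K = dx.build_exchange_matrix(dx.ExchangeSpec.three_site(KT, KG), f)
        assert np.allclose(K @ np.asarray(f), 0.0, atol=1e-12)

    def test_vanishing_ecs_reduces_to_geometric_two_site(self):
        """With no ECS the a-site decouples and b<->c exchange at k_g
        remains."""
        K = dx.build_exchange_matrix(dx.ExchangeSpec.three_site(KT, KG),
                                     (0.0, 0.5, 0.5))
        assert np.allclose(K[0, 1:], 0.0)
        assert np.allclose(K[1:, 1:], KG * np.array([[0.5, -0.5],
                                                     [-0.5, 0.5]]))

    @given(f=fractions3, kt=st.floats(1.0, 1000.0), kg=st.floats(1.0, 500.0))
    @settings(derandomize=True, max_examples=100)
    def test_column_sums_and_detailed_balance(self, f, kt, kg):
        K = dx.build_exchange_matrix(dx.ExchangeSpec.three_site(kt, kg), f)
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-10)
        for i in range(3):
            for j in range(3):
                if i != j:
                    # unidirectional flux balance k_ij f_i = k_ji f_j
                    assert -K[j, i] * f[i] == pytest.approx(
                        -K[i, j] * f[j], abs=1e-9)

    def test_general_mode_validates_column_sums(self):
        with pytest.raises(ValueError):
            dx.ExchangeSpec.general(np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            dx.ExchangeSpec.three_site(-1.0, 30.0)


class TestEigenvalues:
    def test_two_site_spectrum(self):
        """Two-site eigenvalues are exactly (0, k)."""
        spec = dx.ExchangeSpec.two_site(300.0)
        for fa in (0.2, 0.5, 0.8):
            K = dx.build_exchange_matrix(spec, (fa, 1.0 - fa))
            assert np.allclose(sorted(np.linalg.eigvals(K).real), [0.0, 300.0])

    def test_three_site_closed_form_value(self):
        """lam2 = fa*kt + (1-fa)*kg: 115 s^-1 at the normal ECS fraction."""
        ev = dx.exchange_eigenvalues(dx.ExchangeSpec.three_site(KT, KG),
                                     (0.315, 0.3425, 0.3425))
        assert ev[1] == pytest.approx(115.0, abs=0.2)
        assert ev[2] == KT

    def test_vanishing_ecs_limit(self):
        ev = dx.exchange_eigenvalues(dx.ExchangeSpec.three_site(KT, KG),
                                     (0.0, 0.5, 0.5))
        assert ev[1] == pytest.approx(KG)

    @given(f=fractions3, kt=st.floats(10.0, 1000.0), kg=st.floats(1.0, 500.0))
    @settings(derandomize=True, max_examples=100)
    def test_closed_form_matches_eigensolver(self, f, kt, kg):
        spec = dx.ExchangeSpec.three_site(kt, kg)
        K = dx.build_exchange_matrix(spec, f)
        numeric = np.sort(np.linalg.eigvals(K).real)
        closed = np.sort(dx.exchange_eigenvalues(spec, f))
        assert np.allclose(numeric, closed,
                           rtol=1e-9, atol=1e-9 * max(kt, kg))


class TestSimulateDexsy:
    def test_total_magnetization_conserved_at_zero_b(self, protocol):
        """With b1 = b2 = 0 and R1 = 0 the signal is 1 at every tm."""
        prot = dx.DEXSYProtocol(
            encodings=(dx.SGSEEncoding(0.0, 0.0),), tm_ms=protocol.tm_ms)
        system = dx.CompartmentSystem.three_site(0.3, R1=0.0)
        tab = dx.simulate_dexsy(system, dx.ExchangeSpec.three_site(KT, KG),
                                prot)
        assert np.allclose(tab.signal, 1.0, atol=1e-12)

    def test_no_mixing_gives_tm_independent_mixture(self, protocol):
        """K = 0 and R1 = 0: S = sum f_j exp(-(b1+b2) ADC_j), flat in tm."""
        system = dx.CompartmentSystem.three_site(0.3, R1=0.0)
        spec = dx.ExchangeSpec.three_site(0.0, 0.0)
        tab = dx.simulate_dexsy(system, spec, protocol)
        for _, g in tab.groupby("encoding_id"):
            b = g.b1.iloc[0] + g.b2.iloc[0]
            expected = sum(f * np.exp(-b * a)
                           for f, a in zip(system.f, system.ADC))
            assert np.allclose(g.signal, expected, atol=1e-12)

    def test_signals_positive_and_bounded(self, protocol, fo_normal):
        tab = dx.simulate_dexsy(dx.CompartmentSystem.three_site(fo_normal),
                                dx.ExchangeSpec.three_site(KT, KG), protocol)
        assert (tab.signal > 0).all()
        assert (tab.signal <= 1.0).all()

    def test_exchange_contrast_monotone_in_tm(self):
        """Equal-b encodings with distinct ADCs and R1 = 0: mixing can only
        add attenuation as tm grows."""
        prot = dx.DEXSYProtocol(encodings=(dx.SGSEEncoding(0.593, 0.580),),
                                tm_ms=dx.TM_DEFAULT_MS)
        system = dx.CompartmentSystem.three_site(0.4, R1=0.0)
        tab = dx.simulate_dexsy(system, dx.ExchangeSpec.three_site(KT, KG),
                                prot)
        assert np.all(np.diff(tab.signal.to_numpy()) <= 1e-12)

    @given(f=fractions3, kt=st.floats(10.0, 600.0), kg=st.floats(1.0, 100.0),
           t1=st.floats(1.0, 100.0), t2=st.floats(1.0, 100.0))
    @settings(derandomize=True, max_examples=50)
    def test_semigroup_property(self, f, kt, kg, t1, t2):
        """expm(-t1 K) expm(-t2 K) = expm(-(t1+t2) K)."""
        K = dx.build_exchange_matrix(dx.ExchangeSpec.three_site(kt, kg), f)
        left = expm(-t1e3(t1) * K) @ expm(-t1e3(t2) * K)
        right = expm(-t1e3(t1 + t2) * K)
        assert np.allclose(left, right, atol=1e-9)

    @given(f=fractions3)
    @settings(derandomize=True, max_examples=50)
    def test_conservation_under_mixing(self, f):
        """1' expm(-tm K) S0 = sum(S0) for any start vector (zero column
        sums conserve total magnetization)."""
        K = dx.build_exchange_matrix(dx.ExchangeSpec.three_site(KT, KG), f)
        S0 = np.array([0.2, 0.5, 0.1])
        for tm in (0.001, 0.05, 0.3):
            total = np.ones(3) @ expm(-tm * K) @ S0
            assert total == pytest.approx(S0.sum(), abs=1e-10)

    def test_encoding_exchange_option_changes_signal(self, protocol,
                                                     fo_normal):
        system = dx.CompartmentSystem.three_site(fo_normal)
        spec = dx.ExchangeSpec.three_site(KT, KG)
        default = dx.simulate_dexsy(system, spec, protocol)
        full = dx.simulate_dexsy(system, spec, protocol,
                                 include_encoding_exchange=True)
        assert not np.allclose(default.signal, full.signal)


def t1e3(ms: float) -> float:
    return ms * 1e-3


class TestPredictADC:
    def test_pure_ecs(self):
        assert dx.predict_adc(dx.CompartmentSystem.three_site(1.0)) == 1.0

    def test_fraction_weighted_sum(self):
        system = dx.CompartmentSystem(f=(0.32, 0.34, 0.34),
                                      ADC=(1.0, 1.0, 0.1), R1=(1.0,) * 3)
        assert dx.predict_adc(system) == pytest.approx(0.55 + 0.45 * 0.32)

    def test_uniform_adc(self):
        system = dx.CompartmentSystem(f=(1 / 3,) * 3, ADC=(1.0,) * 3,
                                      R1=(1.0,) * 3)
        assert dx.predict_adc(system) == pytest.approx(1.0)


class TestCTMCOracle:
    def test_no_exchange_recovers_mixture(self, protocol):
        system = dx.CompartmentSystem.three_site(0.3, R1=0.0)
        spec = dx.ExchangeSpec.three_site(0.0, 0.0)
        mc = dx.ctmc_oracle(system, spec, protocol, n_particles=20_000,
                            seed=7)
        exact = dx.simulate_dexsy(system, spec, protocol)
        z = (mc.signal - exact.signal) / mc.signal_se
        assert np.abs(z).max() < 3.0

    def test_two_site_self_consistency(self, protocol):
        system = dx.CompartmentSystem.two_site(0.5)
        spec = dx.ExchangeSpec.two_site(300.0)
        mc = dx.ctmc_oracle(system, spec, protocol, n_particles=50_000,
                            seed=11)
        exact = dx.simulate_dexsy(system, spec, protocol)
        z = (mc.signal - exact.signal) / mc.signal_se
        assert np.abs(z).max() < 3.0

    def test_seed_reproducibility(self, protocol, fo_normal):
        system = dx.CompartmentSystem.three_site(fo_normal)
        spec = dx.ExchangeSpec.three_site(KT, KG)
        a = dx.ctmc_oracle(system, spec, protocol, n_particles=5_000, seed=3)
        b = dx.ctmc_oracle(system, spec, protocol, n_particles=5_000, seed=3)
        assert (a.signal == b.signal).all()
        assert (a.signal_se == b.signal_se).all()
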