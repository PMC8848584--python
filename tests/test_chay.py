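import numpy as np
import pytest

from spikerhythm.chay import (ChayParams, ChayState, IntegrationBlowup, NoiseSpec,
                              chay_derivatives, gating_variables, sample_ou,
                              simulate_deterministic, simulate_stochastic)
from spikerhythm.datasets import load_chay_regimes
from spikerhythm.spikes import detect_spikes, extract_isi


def hh_gates(V):
    """Independent re-derivation of the gating steady states (test-local oracle)."""
    a_m = 0.1 * (V + 25) / (1 - np.exp(-0.1 * V - 2.5)) if abs(V + 25) > 1e-9 else 1.0
    b_m = 4 * np.exp(-(V + 50) / 18)
    a_h = 0.07 * np.exp(-0.05 * V - 2.5)
    b_h = 1 / (1 + np.exp(-0.1 * V - 2))
    a_n = 0.01 * (V + 20) / (1 - np.exp(-0.1 * V - 2)) if abs(V + 20) > 1e-9 else 0.1
    b_n = 0.125 * np.exp(-(V + 30) / 80)
    return (a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n),
            a_n + b_n)


class TestDerivatives:
    def test_gating_fixed_point_for_both_forms(self):
        """dn/dt vanishes at n = n_inf regardless of the gating scale w_K."""
        V = -35.0
        _, _, n_inf, tau_n = gating_variables(V)
        for wk in (1.0, 0.7, 1.3):
            st = ChayState(V=V, n=n_inf, C=0.4)
            _, dn, _ = chay_derivatives(st, ChayParams(w_K=wk))
            assert dn == pytest.approx(0.0, abs=1e-12)

    def test_wk_one_reduces_to_original_form(self):
        st = ChayState(V=-22.0, n=0.35, C=0.8)
        d1 = chay_derivatives(st, ChayParams(w_K=1.0))
        base = ChayParams()
        assert base.w_K == 1.0
        d2 = chay_derivatives(st, base)
        assert d1 == d2

    def test_wk_scales_gating_rate_only(self):
        st = ChayState(V=-22.0, n=0.35, C=0.8)
        dV1, dn1, dC1 = chay_derivatives(st, ChayParams(w_K=1.0))
        dV2, dn2, dC2 = chay_derivatives(st, ChayParams(w_K=2.0))
        assert dV2 == dV1 and dC2 == dC1
        assert dn2 == pytest.approx(2.0 * dn1, rel=1e-12)

    def test_toy_voltage_current_sum(self):
        """Term-by-term arithmetic oracle: unit conductances, zero reversals."""
        V, n, C = 10.0, 0.3, 0.5
        m_inf, h_inf, n_inf, rates = hh_gates(V)
        expected_dV = (m_inf**3 * h_inf * (0 - V) + n**4 * (0 - V)
                       + C / (1 + C) * (0 - V) + (0 - V))
        p = ChayParams(g_I=1, g_KV=1, g_KC=1, g_L=1, V_I=0, V_K=0, V_L=0, V_C=0)
        dV, dn, dC = chay_derivatives(ChayState(V=V, n=n, C=C), p)
        assert dV == pytest.approx(expected_dV, rel=1e-12)
        # gating and calcium against the same oracle
        assert dn == pytest.approx((n_inf - n) * (p.lambda_n * rates), rel=1e-10)
        assert dC == pytest.approx(p.rho * (m_inf**3 * h_inf * (0 - V) - p.K_C * C),
                                   rel=1e-12)

    def test_nonfinite_state_rejected(self):
        st = ChayState(V=-30.0, n=0.2, C=0.1)
        st.V = np.nan
        with pytest.raises(ValueError, match="V"):
            chay_derivatives(st, ChayParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ChayParams(g_KV=-1.0)
        with pytest.raises(ValueError):
            ChayParams(w_K=0.0)
        with pytest.raises(ValueError):
            ChayState(n=1.5)


class TestDeterministic:
    def test_zero_duration_returns_initial_state(self):
        init = ChayState(V=-41.0, n=0.25, C=0.6)
        tr = simulate_deterministic(ChayParams(), init, dt=0.01, T=0.0)
        assert len(tr.t) == 1
        assert tr.V[0] == init.V and tr.n[0] == init.n and tr.C[0] == init.C

    def test_step_refinement_agreement(self):
        """RK4 at dt and Euler at dt/100 converge to the same state over a
        sub-threshold (pre-spike) window."""
        p, init = ChayParams(g_KC=10.0), ChayState(V=-40.0, n=0.3, C=0.5)
        v_rk4 = simulate_deterministic(p, init, dt=0.001, T=0.4, method="rk4").V[-1]
        v_euler = simulate_deterministic(p, init, dt=0.00001, T=0.4, method="euler").V[-1]
        assert v_rk4 == pytest.approx(v_euler, abs=0.05)

    def test_rk4_step_halving_converges(self):
        p, init = ChayParams(g_KC=10.0), ChayState(V=-40.0, n=0.3, C=0.5)
        v1 = simulate_deterministic(p, init, dt=0.002, T=0.4, method="rk4").V[-1]
        v2 = simulate_deterministic(p, init, dt=0.001, T=0.4, method="rk4").V[-1]
        assert abs(v1 - v2) < 1e-3

    def test_periodic_regime_has_constant_isi(self):
        """The configured tonic-spiking regime fires with CV < 0.01."""
        regime = load_chay_regimes()["classes"]["PD"]
        p = ChayParams(**regime["params"])
        tr = simulate_deterministic(p, ChayState(V=-40.0, n=0.3, C=0.5),
                                    dt=regime["dt"], T=100.0, method="rk4")
        train = detect_spikes(tr, threshold=regime["threshold"],
                              refractory=regime["refractory"])
        isi = extract_isi(train).values[10:]  # discard the settling transient
        assert len(isi) > 50
        assert isi.std() / isi.mean() < 0.01

    def test_blowup_raises_with_time(self):
        p = ChayParams(g_I=1e9)  # absurd drive forces the guard
        with pytest.raises(IntegrationBlowup):
            simulate_deterministic(p, ChayState(V=-40.0, n=0.3, C=0.5),
                                   dt=0.01, T=10.0)

    def test_deterministic_is_bitwise_reproducible(self):
        p, init = ChayParams(), ChayState()
        a = simulate_deterministic(p, init, dt=0.001, T=1.0, method="rk4")
        b = simulate_deterministic(p, init, dt=0.001, T=1.0, method="rk4")
        assert np.array_equal(a.V, b.V)


class TestStochastic:
    @pytest.mark.parametrize("kind", ["global_white", "global_colored",
                                      "k_white", "k_colored"])
    def test_zero_noise_matches_deterministic_euler_bitwise(self, kind):
        p, init = ChayParams(g_KC=11.0), ChayState(V=-40.0, n=0.3, C=0.5)
        det = simulate_deterministic(p, init, dt=0.001, T=2.0, method="euler")
        sto = simulate_stochastic(p, init, NoiseSpec(kind=kind, D=0.0, tau=0.5,
                                                     N_K=100, seed=0),
                                  dt=0.001, T=2.0)
        assert np.array_equal(det.V, sto.V)
        assert np.array_equal(det.n, sto.n)
        assert np.array_equal(det.C, sto.C)

    def test_seeded_reproducibility(self):
        p, init = ChayParams(), ChayState()
        spec = NoiseSpec(kind="global_white", D=5.0, seed=7)
        a = simulate_stochastic(p, init, spec, dt=0.001, T=1.0)
        b = simulate_stochastic(p, init, spec, dt=0.001, T=1.0)
        c = simulate_stochastic(p, init, NoiseSpec(kind="global_white", D=5.0, seed=8),
                                dt=0.001, T=1.0)
        assert np.array_equal(a.V, b.V)
        assert not np.array_equal(a.V, c.V)

    def test_channel_noise_variance_scales_inversely_with_nk(self, rng):
        """Var(eta_n) at fixed (V, n) falls by ~100x when N_K grows 100x."""
        V, n = -35.0, 0.4
        _, _, _, tau_n = gating_variables(V)
        amp = np.sqrt(2.0 * n * (1 - n) / tau_n)
        draws = rng.standard_normal(200_000)
        eta_small = draws * amp / np.sqrt(100)
        eta_big = draws * amp / np.sqrt(10_000)
        ratio = eta_small.var() / eta_big.var()
        assert ratio == pytest.approx(100.0, rel=1e-6)

    def test_channel_noise_perturbs_gating_not_voltage_directly(self):
        """First step: k-channel noise changes n, while V takes the
        deterministic first step."""
        p, init = ChayParams(), ChayState(V=-40.0, n=0.3, C=0.5)
        det = simulate_deterministic(p, init, dt=0.001, T=0.002, method="euler")
        sto = simulate_stochastic(p, init, NoiseSpec(kind="k_white", D=50.0,
                                                     N_K=10, seed=3),
                                  dt=0.001, T=0.002)
        assert sto.V[1] == det.V[1]
        assert sto.n[1] != det.n[1]

    def test_unknown_kind_and_bad_tau_rejected(self):
        with pytest.raises(ValueError, match="unknown noise kind"):
            NoiseSpec(kind="pink")
        with pytest.raises(ValueError, match="tau"):
            NoiseSpec(kind="global_colored", D=1.0, tau=0.0)


class TestOU:
    def test_zero_intensity_gives_zero_path(self):
        assert np.all(sample_ou(0.0, 0.5, 0.01, 1000, seed=0) == 0.0)

    def test_stationary_moments(self):
        """Mean -> 0 and variance -> D/tau within 3 standard errors."""
        D, tau, dt, n = 1.0, 0.5, 0.01, 400_000
        x = sample_ou(D, tau, dt, n, seed=11)
        var_target = D / tau
        # effective sample size accounts for the exp(-dt/tau) autocorrelation
        a = np.exp(-dt / tau)
        n_eff = n * (1 - a) / (1 + a)
        se_mean = np.sqrt(var_target / n_eff)
        se_var = var_target * np.sqrt(2.0 / n_eff)
        assert abs(x.mean()) < 3 * se_mean
        assert abs(x.var() - var_target) < 3 * se_var

    def test_exponential_autocovariance(self):
        D, tau, dt, n = 2.0, 0.4, 0.01, 400_000
        x = sample_ou(D, tau, dt, n, seed=5)
        xc = x - x.mean()
        for lag_t in (0.1, 0.2, 0.4):
            lag = int(round(lag_t / dt))
            acov = np.mean(xc[:-lag] * xc[lag:])
            expected = (D / tau) * np.exp(-lag_t / tau)
            assert acov == pytest.approx(expected, abs=0.12)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            sample_ou(1.0, -1.0, 0.01, 100)

    def test_white_noise_increment_variance(self):
        """Discretized white forcing contributes Var = 2*D*dt per step."""
        D, dt = 4.0, 0.001
        rng = np.random.default_rng(0)
        incr = np.sqrt(2 * D * dt) * rng.standard_normal(100_000)
        assert incr.var() == pytest.approx(2 * D * dt, rel=0.05)
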