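"""Chay three-variable excitable-cell model and its stochastic variants.

The model tracks membrane potential ``V`` (mV), the potassium-channel open
probability ``n`` and the dimensionless intracellular free-calcium
concentration ``C``:

    dV/dt = g_I m∞³ h∞ (V_I − V) + g_KV n⁴ (V_K − V)
          + g_KC C/(1+C) (V_K − V) + g_L (V_L − V)
    dn/dt = w_K (n∞ − n)/τ_n
    dC/dt = ρ (m∞³ h∞ (V_C − V) − K_C C)

with Hodgkin–Huxley-style instantaneous activation m∞, h∞ and voltage
dependent n∞, τ_n.  ``w_K = 1`` recovers the original model; ``w_K ≠ 1``
is the "improved" variant in which the K⁺ gating speed is rescaled so that
irregular rhythms appear without any noise source.

Stochastic variants add, via Euler–Maruyama:

* ``global_white`` / ``global_colored`` — a Gaussian white noise ξ(t) with
  ⟨ξ(t)ξ(t′)⟩ = 2D δ(t−t′), or a stationary Ornstein–Uhlenbeck (colored)
  process σ(t) with autocovariance (D/τ)·exp(−|t−t′|/τ), on the voltage
  equation;
* ``k_white`` / ``k_colored`` — channel noise
  η_n = ξ_n(t) · (1/√N_K) · √(2 n(1−n)/τ_n(V)) on the gating equation,
  representing finite-population K⁺-channel fluctuations (variance ∝ 1/N_K).

Time is dimensionless model time; the default step is ``dt = 0.001``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "ChayParams",
    "ChayState",
    "NoiseSpec",
    "MembraneTrace",
    "IntegrationBlowup",
    "chay_derivatives",
    "gating_variables",
    "simulate_deterministic",
    "simulate_stochastic",
    "sample_ou",
    "NOISE_KINDS",
]

NOISE_KINDS = ("none", "global_white", "global_colored", "k_white", "k_colored")


class IntegrationBlowup(RuntimeError):
    """Raised when |V| exceeds the guard; carries the model time of failure."""

    def __init__(self, t_fail: float, guard: float):
        self.t_fail = t_fail
        super().__init__(f"|V| exceeded the {guard} mV guard at t = {t_fail:.6g}")


@dataclass
class ChayParams:
    """Conductances, reversal potentials and kinetic constants.

    Defaults are the canonical parameter set of the original model
    (conductances in the model's dimensionless units, potentials in mV);
    ``g_KC`` is the usual bifurcation parameter and ``w_K`` the gating-speed
    control of the improved variant.
    """

    g_I: float = 1800.0
    g_KV: float = 1700.0
    g_KC: float = 12.0
    g_L: float = 7.0
    V_I: float = 100.0
    V_K: float = -75.0
    V_L: float = -40.0
    V_C: float = 100.0
    K_C: float = 3.3 / 18.0
    rho: float = 0.27
    lambda_n: float = 230.0
    w_K: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_I", "g_KV", "g_KC", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.w_K <= 0:
            raise ValueError("w_K must be > 0")

    def to_tuple(self) -> tuple:
        return (
            self.g_I, self.g_KV, self.g_KC, self.g_L,
            self.V_I, self.V_K, self.V_L, self.V_C,
            self.K_C, self.rho, self.lambda_n, self.w_K,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ChayParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class ChayState:
    """Dynamical state (V in mV, n in [0,1], C >= 0)."""

    V: float = -40.0
    n: float = 0.3
    C: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.n <= 1.0):
            raise ValueError(f"n must lie in [0, 1], got {self.n}")
        if self.C < 0:
            raise ValueError(f"C must be >= 0, got {self.C}")


@dataclass
class NoiseSpec:
    """Stochastic forcing: kind, intensity D, OU correlation time tau,
    K-channel count N_K and the RNG seed."""

    kind: str = "none"
    D: float = 0.0
    tau: float = 1.0
    N_K: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}")
        if self.D < 0:
            raise ValueError("noise intensity D must be >= 0")
        if "colored" in self.kind and self.tau <= 0:
            raise ValueError("tau must be > 0 for colored noise")
        if self.kind.startswith("k_") and self.N_K < 1:
            raise ValueError("N_K must be >= 1 for channel noise")


@dataclass
class MembraneTrace:
    """Uniformly sampled trajectory with provenance metadata."""

    t: np.ndarray
    V: np.ndarray
    n: Optional[np.ndarray] = None
    C: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"t": self.t, "V": self.V}
        if self.n is not None:
            cols["n"] = self.n
        if self.C is not None:
            cols["C"] = self.C
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(self.t, self.V, lw=0.6)
        ax.set_xlabel("time (model units)")
        ax.set_ylabel("V (mV)")
        return ax


# ---------------------------------------------------------------------------
# jitted numerics
# ---------------------------------------------------------------------------

@njit(fastmath=False)
def _gates(V: float, lambda_n: float):
    """m_inf, h_inf, n_inf, tau_n at voltage V (removable singularities guarded)."""
    vm = V + 25.0
    if abs(vm) < 1e-7:
        a_m = 1.0
    else:
        a_m = 0.1 * vm / (1.0 - np.exp(-0.1 * vm))
    b_m = 4.0 * np.exp(-(V + 50.0) / 18.0)
    a_h = 0.07 * np.exp(-0.05 * (V + 50.0))
    b_h = 1.0 / (1.0 + np.exp(-0.1 * (V + 20.0)))
    vn = V + 20.0
    if abs(vn) < 1e-7:
        a_n = 0.1
    else:
        a_n = 0.01 * vn / (1.0 - np.exp(-0.1 * vn))
    b_n = 0.125 * np.exp(-(V + 30.0) / 80.0)
    m_inf = a_m / (a_m + b_m)
    h_inf = a_h / (a_h + b_h)
    n_inf = a_n / (a_n + b_n)
    tau_n = 1.0 / (lambda_n * (a_n + b_n))
    return m_inf, h_inf, n_inf, tau_n


@njit(fastmath=False)
def _derivs(V, n, C, gI, gKV, gKC, gL, VI, VK, VL, VC, KC, rho, lambda_n, wK):
    m_inf, h_inf, n_inf, tau_n = _gates(V, lambda_n)
    mh = m_inf ** 3 * h_inf
    dV = (
        gI * mh * (VI - V)
        + gKV * n ** 4 * (VK - V)
        + gKC * C / (1.0 + C) * (VK - V)
        + gL * (VL - V)
    )
    dn = wK * (n_inf - n) / tau_n
    dC = rho * (mh * (VC - V) - KC * C)
    return dV, dn, dC, tau_n


@njit(fastmath=False)
def _euler_core(V0, n0, C0, gI, gKV, gKC, gL, VI, VK, VL, VC, KC, rho, lambda_n,
                wK, dt, n_steps, noise_V, noise_n, channel, inv_sqrt_NK, guard):
    Vs = np.empty(n_steps + 1)
    ns = np.empty(n_steps + 1)
    Cs = np.empty(n_steps + 1)
    V, n, C = V0, n0, C0
    Vs[0], ns[0], Cs[0] = V, n, C
    for i in range(n_steps):
        dV, dn, dC, tau_n = _derivs(V, n, C, gI, gKV, gKC, gL, VI, VK, VL, VC,
                                    KC, rho, lambda_n, wK)
        if channel:
            amp = inv_sqrt_NK * np.sqrt(max(2.0 * n * (1.0 - n), 0.0) / tau_n)
        else:
            amp = 1.0
        V = V + dV * dt + noise_V[i]
        n = n + dn * dt + noise_n[i] * amp
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        C = C + dC * dt
        if C < 0.0:
            C = 0.0
        Vs[i + 1], ns[i + 1], Cs[i + 1] = V, n, C
        if not (np.isfinite(V) and abs(V) <= guard):
            return Vs, ns, Cs, i + 1
    return Vs, ns, Cs, -1


@njit(fastmath=False)
def _rk4_core(V0, n0, C0, gI, gKV, gKC, gL, VI, VK, VL, VC, KC, rho, lambda_n,
              wK, dt, n_steps, guard):
    Vs = np.empty(n_steps + 1)
    ns = np.empty(n_steps + 1)
    Cs = np.empty(n_steps + 1)
    V, n, C = V0, n0, C0
    Vs[0], ns[0], Cs[0] = V, n, C
    for i in range(n_steps):
        k1V, k1n, k1C, _ = _derivs(V, n, C, gI, gKV, gKC, gL, VI, VK, VL, VC, KC, rho, lambda_n, wK)
        k2V, k2n, k2C, _ = _derivs(V + 0.5 * dt * k1V, n + 0.5 * dt * k1n, C + 0.5 * dt * k1C,
                                   gI, gKV, gKC, gL, VI, VK, VL, VC, KC, rho, lambda_n, wK)
        k3V, k3n, k3C, _ = _derivs(V + 0.5 * dt * k2V, n + 0.5 * dt * k2n, C + 0.5 * dt * k2C,
                                   gI, gKV, gKC, gL, VI, VK, VL, VC, KC, rho, lambda_n, wK)
        k4V, k4n, k4C, _ = _derivs(V + dt * k3V, n + dt * k3n, C + dt * k3C,
                                   gI, gKV, gKC, gL, VI, VK, VL, VC, KC, rho, lambda_n, wK)
        V = V + dt / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
        n = n + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        C = C + dt / 6.0 * (k1C + 2.0 * k2C + 2.0 * k3C + k4C)
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        if C < 0.0:
            C = 0.0
        Vs[i + 1], ns[i + 1], Cs[i + 1] = V, n, C
        if not (np.isfinite(V) and abs(V) <= guard):
            return Vs, ns, Cs, i + 1
    return Vs, ns, Cs, -1


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def gating_variables(V: float, lambda_n: float = 230.0):
    """(m_inf, h_inf, n_inf, tau_n) at voltage ``V``."""
    return _gates(float(V), float(lambda_n))


def chay_derivatives(state: ChayState, params: ChayParams):
    """Right-hand side (dV/dt, dn/dt, dC/dt) at ``state``.

    Uses the improved gating form w_K·(n∞−n)/τ_n, which reduces to the
    original model when ``params.w_K == 1``.
    """
    for name, val in (("V", state.V), ("n", state.n), ("C", state.C)):
        if not np.isfinite(val):
            raise ValueError(f"non-finite state component {name} = {val}")
    dV, dn, dC, _ = _derivs(state.V, state.n, state.C, *params.to_tuple())
    return dV, dn, dC


def _check_grid(dt: float, T: float) -> int:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if T < 0:
        raise ValueError("T must be >= 0")
    return int(np.floor(T / dt + 1e-12))


def simulate_deterministic(
    params: ChayParams,
    init: ChayState,
    dt: float = 0.001,
    T: float = 100.0,
    method: str = "euler",
    guard: float = 500.0,
) -> MembraneTrace:
    """Fixed-step deterministic integration (``euler`` or ``rk4``).

    Identical inputs produce bitwise-identical traces.
    """
    n_steps = _check_grid(dt, T)
    p = params.to_tuple()
    if method == "euler":
        zeros = np.zeros(n_steps)
        Vs, ns, Cs, fail = _euler_core(init.V, init.n, init.C, *p, dt, n_steps,
                                       zeros, zeros, False, 0.0, guard)
    elif method == "rk4":
        Vs, ns, Cs, fail = _rk4_core(init.V, init.n, init.C, *p, dt, n_steps, guard)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'euler' or 'rk4'")
    if fail >= 0:
        raise IntegrationBlowup(fail * dt, guard)
    t = np.arange(n_steps + 1) * dt
    meta = {"params": asdict(params), "init": asdict(init), "dt": dt, "T": T,
            "method": method, "noise": None}
    return MembraneTrace(t=t, V=Vs, n=ns, C=Cs, meta=meta)


def sample_ou(D: float, tau: float, dt: float, n_steps: int,
              seed=None, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path of length ``n_steps``.

    Exact discretization: σ_{k+1} = a σ_k + √((D/τ)(1−a²)) z_k with
    a = exp(−dt/τ) and σ_0 drawn from the stationary law N(0, D/τ), so the
    sample mean tends to 0 and the sample variance to D/τ.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if D < 0:
        raise ValueError("D must be >= 0")
    if n_steps < 1:
        return np.empty(0)
    if D == 0:
        return np.zeros(n_steps)
    if rng is None:
        rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau)
    var = D / tau
    sigma = np.empty(n_steps)
    sigma[0] = rng.normal(0.0, np.sqrt(var))
    if n_steps > 1:
        from scipy.signal import lfilter

        w = rng.normal(0.0, np.sqrt(var * (1.0 - a * a)), size=n_steps - 1)
        # recursion sigma[k] = a*sigma[k-1] + w[k] as an IIR filter
        sigma[1:] = lfilter([1.0], [1.0, -a], w, zi=np.array([a * sigma[0]]))[0]
    return sigma


def simulate_stochastic(
    params: ChayParams,
    init: ChayState,
    noise: NoiseSpec,
    dt: float = 0.001,
    T: float = 100.0,
    guard: float = 500.0,
    rng: Optional[np.random.Generator] = None,
) -> MembraneTrace:
    """Euler–Maruyama integration with the forcing described by ``noise``.

    Global kinds perturb dV/dt; K⁺-channel kinds perturb dn/dt with the
    state-dependent amplitude (1/√N_K)·√(2 n(1−n)/τ_n).  ``n`` is clamped to
    [0, 1] and ``C`` floored at 0 after every step.  With ``D = 0`` the
    trajectory is bitwise identical to the deterministic Euler run.
    """
    n_steps = _check_grid(dt, T)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    zeros = np.zeros(n_steps)
    noise_V, noise_n = zeros, zeros
    channel = noise.kind.startswith("k_")
    inv_sqrt_NK = 1.0 / np.sqrt(noise.N_K) if channel else 0.0
    if noise.D > 0 and noise.kind != "none":
        if noise.kind == "global_white":
            noise_V = np.sqrt(2.0 * noise.D * dt) * rng.standard_normal(n_steps)
        elif noise.kind == "global_colored":
            noise_V = sample_ou(noise.D, noise.tau, dt, n_steps, rng=rng) * dt
        elif noise.kind == "k_white":
            noise_n = np.sqrt(2.0 * noise.D * dt) * rng.standard_normal(n_steps)
        elif noise.kind == "k_colored":
            noise_n = sample_ou(noise.D, noise.tau, dt, n_steps, rng=rng) * dt
    Vs, ns, Cs, fail = _euler_core(init.V, init.n, init.C, *params.to_tuple(),
                                   dt, n_steps, noise_V, noise_n, channel,
                                   inv_sqrt_NK, guard)
    if fail >= 0:
        raise IntegrationBlowup(fail * dt, guard)
    t = np.arange(n_steps + 1) * dt
    meta = {"params": asdict(params), "init": asdict(init), "dt": dt, "T": T,
            "method": "euler_maruyama", "noise": asdict(noise)}
    return MembraneTrace(t=t, V=Vs, n=ns, C=Cs, meta=meta)
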