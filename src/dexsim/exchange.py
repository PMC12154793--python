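"""Multisite exchange matrices and SGSE-DEXSY signal simulation.

Sites are distinguished by apparent diffusivity (ADC) along the static
gradient.  The three-site gray-matter model orders sites as
(a, b, c) = (ECS, mobile ICS, restricted ICS): transmembrane exchange at
rate constant ``k_t`` connects a↔b and a↔c, geometric exchange at ``k_g``
connects b↔c.  Signal fractions evolve under the master equation
dS/dt = −K·S with a rate matrix K whose columns sum to zero (total
magnetization balance) and which satisfies detailed balance against the
equilibrium fractions f.

A DEXSY acquisition is two diffusion encodings separated by a mixing time
tm; the simulated signal is the operator product

    S(b1, b2, tm) = 1' · expm(−b2·D) · expm(−tm·(K + R1)) · expm(−b1·D) · f

optionally including exchange and spin–spin relaxation during the encoding
periods themselves.  A continuous-time Markov-chain particle simulator of
the same observable serves as an independent Monte-Carlo oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .physchem import b_value

__all__ = [
    "CompartmentSystem",
    "ExchangeSpec",
    "SGSEEncoding",
    "DEXSYProtocol",
    "SIGNAL_COLUMNS",
    "TM_DEFAULT_MS",
    "build_exchange_matrix",
    "exchange_eigenvalues",
    "simulate_dexsy",
    "predict_adc",
    "ctmc_oracle",
]

#: mixing times (ms) of the default two-encoding protocol
TM_DEFAULT_MS = (0.2, 1.0, 2.0, 4.0, 7.0, 10.0, 20.0, 40.0, 80.0, 160.0, 300.0)

#: signal-table schema shared by the simulator, oracle and fitters
SIGNAL_COLUMNS = ["encoding_id", "tau1_ms", "tau2_ms", "b1", "b2",
                  "tm_ms", "signal"]

MS = 1e-3  # ms -> s for rate·time products


@dataclass(frozen=True)
class CompartmentSystem:
    """Site fractions and per-site NMR properties.

    f sums to 1; ADC in μm²/ms; R1 (and optional R2) in s⁻¹.
    """

    f: tuple[float, ...]
    ADC: tuple[float, ...]
    R1: tuple[float, ...]
    R2: tuple[float, ...] | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.f)
        if len(self.ADC) != n or len(self.R1) != n:
            raise ValueError("f, ADC and R1 must have equal length")
        if self.R2 is not None and len(self.R2) != n:
            raise ValueError("R2 length mismatch")
        if any(x < 0 for x in self.f) or not np.isclose(sum(self.f), 1.0,
                                                        atol=1e-9):
            raise ValueError("fractions must be non-negative and sum to 1")
        if any(a < 0 for a in self.ADC) or any(r < 0 for r in self.R1):
            raise ValueError("ADC and R1 must be non-negative")
        if self.R2 is not None and any(r < 0 for r in self.R2):
            raise ValueError("R2 must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.f)

    @classmethod
    def three_site(cls, fa: float, ADC=(1.0, 1.0, 0.1), R1=1.0,
                   split: float = 0.5) -> "CompartmentSystem":
        """ECS fraction ``fa`` with the ICS remainder split between the
        mobile (b) and restricted (c) sites (equal split by default)."""
        if not 0.0 <= fa <= 1.0:
            raise ValueError("fa must lie in [0, 1]")
        fb = (1.0 - fa) * split
        fc = (1.0 - fa) * (1.0 - split)
        r1 = (R1,) * 3 if np.isscalar(R1) else tuple(R1)
        return cls(f=(fa, fb, fc), ADC=tuple(ADC), R1=r1,
                   labels=("ECS", "ICS_mobile", "ICS_restricted"))

    @classmethod
    def two_site(cls, fa: float, ADC=(1.0, 0.1), R1=1.0) -> "CompartmentSystem":
        if not 0.0 <= fa <= 1.0:
            raise ValueError("fa must lie in [0, 1]")
        r1 = (R1,) * 2 if np.isscalar(R1) else tuple(R1)
        return cls(f=(fa, 1.0 - fa), ADC=tuple(ADC), R1=r1,
                   labels=("ECS", "ICS"))


@dataclass(frozen=True)
class ExchangeSpec:
    """Exchange topology and rate constants (s⁻¹).

    mode "two_site" uses a single rate ``k``; "three_site" uses the
    transmembrane rate ``k_t`` (a↔b, a↔c) and geometric rate ``k_g`` (b↔c);
    "general" takes a full rate matrix ``K_raw`` with zero column sums.
    """

    mode: str
    k: float | None = None
    k_t: float | None = None
    k_g: float | None = None
    K_raw: np.ndarray | None = None

    @classmethod
    def two_site(cls, k: float) -> "ExchangeSpec":
        if k < 0:
            raise ValueError("rate constant must be non-negative")
        return cls(mode="two_site", k=k)

    @classmethod
    def three_site(cls, k_t: float, k_g: float) -> "ExchangeSpec":
        if k_t < 0 or k_g < 0:
            raise ValueError("rate constants must be non-negative")
        return cls(mode="three_site", k_t=k_t, k_g=k_g)

    @classmethod
    def general(cls, K: np.ndarray) -> "ExchangeSpec":
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(K.sum(axis=0), 0.0, atol=1e-9):
            raise ValueError("columns of K must sum to zero")
        return cls(mode="general", K_raw=K)


@dataclass(frozen=True)
class SGSEEncoding:
    """One double-encoding pair: half-echo times (ms) and gradient (T/m).

    b-values (ms/μm²) are derived from (g, τ) unless given explicitly.
    """

    tau1: float
    tau2: float
    g: float = 15.3
    b1: float = field(default=None)  # type: ignore[assignment]
    b2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.b1 is None:
            object.__setattr__(self, "b1", b_value(self.g, self.tau1))
        if self.b2 is None:
            object.__setattr__(self, "b2", b_value(self.g, self.tau2))


@dataclass(frozen=True)
class DEXSYProtocol:
    """A set of encodings acquired over a common mixing-time grid (ms)."""

    encodings: tuple[SGSEEncoding, ...]
    tm_ms: tuple[float, ...] = TM_DEFAULT_MS

    def __post_init__(self) -> None:
        tm = np.asarray(self.tm_ms, dtype=float)
        if tm.size == 0 or np.any(tm < 0) or np.any(np.diff(tm) <= 0):
            raise ValueError("tm grid must be non-negative, strictly "
                             "increasing and non-empty")

    @classmethod
    def default(cls, g: float = 15.3,
                tm_ms=TM_DEFAULT_MS) -> "DEXSYProtocol":
        """Reference (low-b1, high-b2) and equal-b encoding pair."""
        return cls(encodings=(SGSEEncoding(0.200, 0.735, g=g),
                              SGSEEncoding(0.593, 0.580, g=g)),
                   tm_ms=tuple(tm_ms))


def build_exchange_matrix(spec: ExchangeSpec, f) -> np.ndarray:
    """Exchange rate matrix K (s⁻¹) for equilibrium fractions ``f``.

    Columns sum to zero (K·f = 0), and the two-/three-site forms satisfy
    detailed balance k_ij·f_i = k_ji·f_j by construction.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("fractions must be non-negative and sum to 1")
    if spec.mode == "two_site":
        if f.size != 2:
            raise ValueError("two_site spec needs 2 fractions")
        fa, fb = f
        return spec.k * np.array([[fb, -fa], [-fb, fa]])
    if spec.mode == "three_site":
        if f.size != 3:
            raise ValueError("three_site spec needs 3 fractions")
        fa, fb, fc = f
        kt, kg = spec.k_t, spec.k_g
        return np.array([
            [(fb + fc) * kt, -fa * kt, -fa * kt],
            [-fb * kt, fa * kt + fc * kg, -fb * kg],
            [-fc * kt, -fc * kg, fa * kt + fb * kg],
        ])
    if spec.mode == "general":
        if spec.K_raw.shape[0] != f.size:
            raise ValueError("K dimension does not match fractions")
        return spec.K_raw.copy()
    raise ValueError(f"unknown exchange mode {spec.mode!r}")


def exchange_eigenvalues(spec: ExchangeSpec, f) -> tuple[float, ...]:
    """Closed-form eigenvalues of the exchange matrix (s⁻¹), slowest first.

    Two-site: (0, k).  Three-site: (0, fa·k_t + (fb+fc)·k_g, k_t); the
    middle eigenvalue is the spectral gap that dominates the long-tm decay.
    """
    f = np.asarray(f, dtype=float)
    if spec.mode == "two_site":
        return (0.0, float(spec.k))
    if spec.mode == "three_site":
        fa = f[0]
        lam2 = fa * spec.k_t + (1.0 - fa) * spec.k_g
        return (0.0, float(lam2), float(spec.k_t))
    ev = np.sort(np.real(np.linalg.eigvals(build_exchange_matrix(spec, f))))
    return tuple(float(v) for v in ev)


def predict_adc(system: CompartmentSystem) -> float:
    """Fraction-weighted apparent diffusion coefficient Σ f_j·ADC_j
    (μm²/ms)."""
    return float(np.dot(system.f, system.ADC))


def simulate_dexsy(system: CompartmentSystem, spec: ExchangeSpec,
                   protocol: DEXSYProtocol,
                   include_encoding_exchange: bool = False,
                   include_R2: bool = False) -> pd.DataFrame:
    """Simulate DEXSY signals for every (encoding, tm) of a protocol.

    By default the encoding-period operators contain only diffusion
    weighting (exchange and R2 during the sub-millisecond encodings are
    negligible for τ ≪ 1/k and τ ≪ T2); set the flags to include the full
    expm(−b·D − 2τ·R2 − 2τ·K) operators.

    Returns a DataFrame with the :data:`SIGNAL_COLUMNS` schema, normalized
    so that total magnetization is 1 at b = 0, tm = 0.
    """
    K = build_exchange_matrix(spec, system.f)
    D = np.diag(system.ADC)
    R1 = np.diag(system.R1)
    R2 = np.diag(system.R2) if system.R2 is not None else np.zeros_like(D)
    S0 = np.asarray(system.f, dtype=float)
    ones = np.ones(system.n_sites)

    rows = []
    for enc_id, enc in enumerate(protocol.encodings):
        ops = []
        for b, tau in ((enc.b1, enc.tau1), (enc.b2, enc.tau2)):
            M = b * D
            if include_encoding_exchange:
                M = M + 2.0 * tau * MS * K
            if include_R2:
                M = M + 2.0 * tau * MS * R2
            ops.append(expm(-M))
        O1, O2 = ops
        for tm in protocol.tm_ms:
            OE = expm(-tm * MS * (K + R1))
            s = float(ones @ O2 @ OE @ O1 @ S0)
            rows.append((enc_id, enc.tau1, enc.tau2, enc.b1, enc.b2, tm, s))
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def _jump_rates(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exit rates and jump-probability rows of the CTMC generated by K.

    The master equation dS/dt = −K·S corresponds to particles leaving site
    i at rate K_ii and jumping i→j with rate −K[j, i].
    """
    n = K.shape[0]
    exit_rates = np.diag(K).copy()
    P = np.zeros((n, n))
    for i in range(n):
        if exit_rates[i] > 0:
            col = -K[:, i].copy()
            col[i] = 0.0
            P[i] = col / exit_rates[i]
    return exit_rates, P


def ctmc_oracle(system: CompartmentSystem, spec: ExchangeSpec,
                protocol: DEXSYProtocol, n_particles: int = 100_000,
                seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo estimate of the DEXSY signal via particle simulation.

    Each particle starts in a site drawn from f, carries diffusion weight
    exp(−b1·ADC) for its initial site, accumulates path-integrated R1 decay
    while jumping between sites during tm with the rates generated by K,
    and picks up exp(−b2·ADC) for the site it occupies at tm.  This is an
    unbiased estimator of the operator-product signal with the default
    (no encoding exchange, no R2) options.

    Returns the signal-table schema plus a ``signal_se`` standard-error
    column.  Bitwise reproducible for a fixed seed.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    K = build_exchange_matrix(spec, system.f)
    exit_rates, P = _jump_rates(K)
    ADC = np.asarray(system.ADC)
    R1 = np.asarray(system.R1)
    tm_s = np.asarray(protocol.tm_ms) * MS

    state0 = rng.choice(system.n_sites, size=n_particles, p=np.asarray(system.f))
    state = state0.copy()
    r1_integral = np.zeros(n_particles)
    # site occupancy and accumulated R1 decay recorded at each tm checkpoint
    states_at_tm = np.empty((len(tm_s), n_particles), dtype=np.int64)
    r1_at_tm = np.empty((len(tm_s), n_particles))

    t_prev = 0.0
    for j, t_ck in enumerate(tm_s):
        remaining = np.full(n_particles, t_ck - t_prev)
        active = remaining > 0
        while np.any(active):
            idx = np.nonzero(active)[0]
            rates = exit_rates[state[idx]]
            waits = np.where(rates > 0,
                             rng.exponential(1.0, size=idx.size)
                             / np.where(rates > 0, rates, 1.0),
                             np.inf)
            stay = waits >= remaining[idx]
            dwell = np.minimum(waits, remaining[idx])
            r1_integral[idx] += dwell * R1[state[idx]]
            remaining[idx] -= dwell
            jumpers = idx[~stay]
            if jumpers.size:
                u = rng.random(jumpers.size)
                cum = np.cumsum(P[state[jumpers]], axis=1)
                state[jumpers] = (u[:, None] < cum).argmax(axis=1)
            active[idx[stay]] = False
        states_at_tm[j] = state
        r1_at_tm[j] = r1_integral
        t_prev = t_ck

    rows = []
    for enc_id, enc in enumerate(protocol.encodings):
        w_enc1 = np.exp(-enc.b1 * ADC[state0])
        for j, tm in enumerate(protocol.tm_ms):
            w = w_enc1 * np.exp(-r1_at_tm[j]) \
                * np.exp(-enc.b2 * ADC[states_at_tm[j]])
            rows.append((enc_id, enc.tau1, enc.tau2, enc.b1, enc.b2, tm,
                         float(w.mean()),
                         float(w.std(ddof=1) / np.sqrt(n_particles))))
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS + ["signal_se"])
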