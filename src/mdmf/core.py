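"""Node-level equations of the multiscale dynamic mean field model.

Pure functions: input currents, the sigmoidal-like transfer function of the
reduced Wong-Wang populations, the concentration-dependent gating drift, the
inhibitory plasticity drift, analytic steady-state gating, and an
event-driven single-synapse receptor-kinetics oracle (Poisson presynaptic
spike train) against which the mean-field gating kinetics are validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import HZ_TO_PER_MS, Concentrations, ModelParameters

__all__ = [
    "NodeState",
    "SynapseOracleConfig",
    "OracleResult",
    "input_currents",
    "transfer_rate",
    "gating_drift",
    "plasticity_drift",
    "steady_state_gating",
    "destexhe_oracle",
]


@dataclass
class NodeState:
    """Per-region dynamical state: gating variables and inhibitory weight.

    SE, SI are average synaptic gating variables (fraction of open
    channels, in [0, 1]); J is the inhibitory-to-excitatory coupling
    weight (nA per unit gating, >= 0) adjusted by the plasticity rule.
    """

    SE: np.ndarray
    SI: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.SE = np.asarray(self.SE, dtype=float)
        self.SI = np.asarray(self.SI, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if not (self.SE.shape == self.SI.shape == self.J.shape):
            raise ValueError("SE, SI and J must have identical shapes")
        if self.SE.ndim != 1:
            raise ValueError("node state arrays must be one-dimensional")
        for name, arr in (("SE", self.SE), ("SI", self.SI)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.J < 0):
            raise ValueError("J must be non-negative")

    @property
    def n(self) -> int:
        return self.SE.size

    @classmethod
    def initial(cls, n: int, J0: float = 1.0) -> "NodeState":
        """Default initial condition: near-rest gating, uniform J."""
        return cls(SE=np.full(n, 0.001), SI=np.full(n, 0.001), J=np.full(n, J0))


def _check_connectivity(C: np.ndarray, n: int) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got shape {C.shape}")
    if C.shape[0] != n:
        raise ValueError(
            f"connectivity dimension {C.shape[0]} does not match state length {n}"
        )
    if np.any(np.diag(C) != 0):
        raise ValueError("connectivity diagonal must be zero (no self-coupling)")
    return C


def input_currents(
    state: NodeState,
    params: ModelParameters,
    C: np.ndarray,
    G: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Input currents (nA) to the excitatory and inhibitory populations.

    IE_i = WE*I0 + wplus*JNMDA*SE_i + G*JNMDA*sum_j C_ij SE_j - J_i*SI_i
    II_i = WI*I0 + JNMDA*SE_i - SI_i

    Long-range coupling is excitatory-to-excitatory only and instantaneous
    (conduction delays are neglected).
    """
    C = _check_connectivity(C, state.n)
    g = params.G if G is None else float(G)
    IE = (
        params.WE * params.I0
        + params.wplus * params.JNMDA * state.SE
        + g * params.JNMDA * (C @ state.SE)
        - state.J * state.SI
    )
    II = params.WI * params.I0 + params.JNMDA * state.SE - state.SI
    return IE, II


def transfer_rate(I, a: float, b: float, d: float):
    """Population firing rate (Hz) from input current (nA).

    r(I) = (a I - b) / (1 - exp(-d (a I - b)))

    The removable singularity at a I = b is filled with its limit 1/d;
    the function is continuous, non-negative, and asymptotically linear
    in a I - b for strong inputs.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("input current must be finite")
    x = a * I - b
    with np.errstate(over="ignore", invalid="ignore"):
        denom = -np.expm1(-d * x)
        r = np.where(np.abs(d * x) < 1e-8, 1.0 / d + x / 2.0, x / denom)
    # large negative x: x/(1 - e^{-dx}) -> 0 from above; overflow gives inf
    # in the discarded branch, never in the result
    r = np.where(np.isfinite(r), r, 0.0)
    out = np.maximum(r, 0.0)
    return float(out) if out.ndim == 0 else out


def gating_drift(
    state: NodeState,
    rE: np.ndarray,
    rI: np.ndarray,
    conc: Concentrations,
    params: ModelParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic drift (per ms) of the average synaptic gating variables.

    dS/dt = -beta S + alpha (1 - S) T r~   with r~ = r / 1000 (ms^-1).

    The drift is non-positive at S = 1 and non-negative at S = 0, so the
    noiseless flow keeps gating inside [0, 1].
    """
    rE = np.asarray(rE, dtype=float)
    rI = np.asarray(rI, dtype=float)
    if np.any(rE < 0) or np.any(rI < 0):
        raise ValueError("firing rates must be non-negative")
    dSE = (
        -params.betaE * state.SE
        + params.alphaE * (1.0 - state.SE) * conc.Tglu * rE * HZ_TO_PER_MS
    )
    dSI = (
        -params.betaI * state.SI
        + params.alphaI * (1.0 - state.SI) * conc.Tgaba * rI * HZ_TO_PER_MS
    )
    return dSE, dSI


def plasticity_drift(rE, rI, params: ModelParameters):
    """Inhibitory plasticity drift dJ/dt (per ms).

    dJ/dt = gamma * rI~ * (rE~ - rho~)  with all rates in ms^-1.

    The drift vanishes exactly when the excitatory rate sits at the
    homeostatic target rho or when the inhibitory population is silent,
    and is positive iff rE > rho (with rI > 0).
    """
    rE = np.asarray(rE, dtype=float)
    rI = np.asarray(rI, dtype=float)
    if np.any(rE < 0) or np.any(rI < 0):
        raise ValueError("firing rates must be non-negative")
    out = (
        params.gamma
        * (rI * HZ_TO_PER_MS)
        * ((rE - params.rho) * HZ_TO_PER_MS)
    )
    return float(out) if out.ndim == 0 else out


def steady_state_gating(alpha: float, beta: float, T: float, r):
    """Analytic steady-state gating for a constant presynaptic rate.

    S_ss = alpha T r~ / (beta + alpha T r~), r~ = r/1000 in ms^-1.

    Strictly increasing in both r and T; 0 at r = 0; bounded above by 1.
    """
    if beta <= 0:
        raise ValueError("beta must be strictly positive")
    if alpha <= 0 or T <= 0:
        raise ValueError("alpha and T must be strictly positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    x = alpha * T * r * HZ_TO_PER_MS
    out = x / (beta + x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SynapseOracleConfig:
    """Configuration of the single-synapse Poisson-driven kinetics oracle.

    rate : presynaptic Poisson mean firing rate (Hz), in [0, 300]
    Tmax : transmitter concentration at the cleft (mM)
    alpha, beta : forward (ms^-1 mM^-1) / backward (ms^-1) rate constants
    duration : simulated time (ms); should be >> 1/beta
    dt : nominal step (ms), kept for provenance (integration is event-driven
        and exact between spikes)
    seed : RNG seed for the Poisson train
    """

    rate: float
    Tmax: float
    alpha: float
    beta: float
    duration: float = 60_000.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 300:
            raise ValueError("rate must lie in [0, 300] Hz")
        if min(self.Tmax, self.alpha, self.beta) <= 0:
            raise ValueError("Tmax, alpha and beta must be strictly positive")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be strictly positive")


@dataclass(frozen=True)
class OracleResult:
    """Long-time mean gating from the single-synapse oracle."""

    mean_gating: float
    converged: bool
    n_spikes: int
    averaged_time: float  # ms over which the mean was taken


def destexhe_oracle(config: SynapseOracleConfig) -> OracleResult:
    """Monte-Carlo mean gating of a single synapse driven by Poisson spikes.

    Integrates ds/dt = -beta s between spikes (exact exponential decay) and
    applies the instantaneous receptor-binding jump s -> s + alpha Tmax (1-s)
    at each spike (each delta-spike contributes unit integral).  Returns the
    time average of s over the post-burn-in window, which for a stationary
    Poisson drive converges to the analytic steady state
    alpha T r~ / (beta + alpha T r~).

    The result is flagged unconverged when the duration is short relative
    to the decay time constant 1/beta or to the mean inter-spike interval.
    """
    rng = np.random.default_rng(config.seed)
    beta = config.beta
    jump = config.alpha * config.Tmax  # fraction of the closed channels opened

    burn = min(0.5 * config.duration, max(10.0 / beta, 0.1 * config.duration))
    window = config.duration - burn
    converged = config.duration * beta >= 50.0
    if config.rate == 0.0:
        return OracleResult(0.0, converged, 0, window)
    converged = converged and window * config.rate * HZ_TO_PER_MS >= 20.0

    rate_per_ms = config.rate * HZ_TO_PER_MS
    # draw inter-spike intervals in blocks until the horizon is covered
    spike_times: list[np.ndarray] = []
    t_last = 0.0
    while t_last < config.duration:
        block = rng.exponential(1.0 / rate_per_ms, size=max(64, int(rate_per_ms * config.duration * 1.2)))
        times = t_last + np.cumsum(block)
        spike_times.append(times)
        t_last = times[-1]
    spikes = np.concatenate(spike_times)
    spikes = spikes[spikes < config.duration]

    s = 0.0
    integral = 0.0  # integral of s(t) dt over [burn, duration]
    t = 0.0
    for ts in spikes:
        dt_seg = ts - t
        if ts > burn:
            lo = max(t, burn)
            s_lo = s * np.exp(-beta * (lo - t))
            integral += s_lo * (1.0 - np.exp(-beta * (ts - lo))) / beta
        s = s * np.exp(-beta * dt_seg)
        s = min(1.0, s + jump * (1.0 - s))
        t = ts
    # tail segment to the horizon
    lo = max(t, burn)
    s_lo = s * np.exp(-beta * (lo - t))
    integral += s_lo * (1.0 - np.exp(-beta * (config.duration - lo))) / beta

    mean = integral / window
    if not converged:
        warnings.warn(
            "oracle duration too short for a converged asymptotic estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    return OracleResult(float(mean), bool(converged), int(spikes.size), float(window))
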