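"""Model parameters for the multiscale dynamic mean field (MDMF) model.

The MDMF model describes each cortical region as a pair of excitatory and
inhibitory neural-mass populations whose synaptic gating kinetics depend
explicitly on glutamate and GABA concentrations through receptor-binding
forward/backward rate constants.  The constants collected here are the
standard reduced Wong-Wang / dynamic-mean-field values plus the kinetic
rates of the receptor-binding scheme.

Unit conventions
----------------
Currents are in nA, firing rates in Hz, kinetic rate constants in ms^-1
(forward rates in ms^-1 mM^-1), neurotransmitter concentrations in mM.
Inside the gating and plasticity ODEs every rate symbol is converted to
ms^-1 (Hz / 1000) so that all terms share units with the backward rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the MDMF node equations.

    Attributes
    ----------
    I0 : float
        Effective external input current (nA).
    WE, WI : float
        Scaling of the external current onto the excitatory / inhibitory
        population (dimensionless).
    wplus : float
        Recurrent excitatory self-coupling weight (dimensionless).
    JNMDA : float
        Excitatory (NMDA-mediated) synaptic coupling (nA per unit gating).
    aE, aI : float
        Transfer-function gains (nC^-1).
    bE, bI : float
        Transfer-function input offsets (Hz).
    dE, dI : float
        Transfer-function curvature constants (s).
    alphaE, alphaI : float
        Forward (binding) rate constants (ms^-1 mM^-1).
    betaE, betaI : float
        Backward (unbinding) rate constants (ms^-1).
    sigma : float
        Amplitude of the Gaussian noise added to both gating equations
        (treated as gating-units amplitude; see docs/methods.md).
    G : float
        Global coupling scaling long-range excitatory connections.
    gamma : float
        Learning rate of the inhibitory plasticity rule (dimensionless).
    rho : float
        Target excitatory firing rate of the plasticity rule (Hz).
    """

    I0: float = 0.382
    WE: float = 1.0
    WI: float = 0.7
    wplus: float = 1.4
    JNMDA: float = 0.15
    aE: float = 310.0
    bE: float = 125.0
    dE: float = 0.16
    aI: float = 615.0
    bI: float = 177.0
    dI: float = 0.087
    alphaE: float = 0.072
    betaE: float = 0.0066
    alphaI: float = 0.53
    betaI: float = 0.18
    sigma: float = 0.001
    G: float = 0.69
    gamma: float = 1.0
    rho: float = 3.0

    def __post_init__(self) -> None:
        positive = (
            "I0 WE WI wplus JNMDA aE bE dE aI bI dI "
            "alphaE betaE alphaI betaI rho"
        ).split()
        for name in positive:
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(self.sigma >= 0, "sigma must be non-negative")
        _require(self.G >= 0, "G must be non-negative")

    def with_(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given constants replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Concentrations:
    """Glutamate and GABA concentrations (mM), uniform across regions.

    Defaults are resting-state precuneus values from magnetic resonance
    spectroscopy of a healthy adult brain.
    """

    Tglu: float = 7.46
    Tgaba: float = 1.82

    def __post_init__(self) -> None:
        _require(self.Tglu > 0, "Tglu must be strictly positive")
        _require(self.Tgaba > 0, "Tgaba must be strictly positive")

    def to_dict(self) -> dict:
        return {"Tglu": self.Tglu, "Tgaba": self.Tgaba}

    @classmethod
    def from_dict(cls, d: dict) -> "Concentrations":
        return cls(**d)


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel hemodynamic constants (standard literature values).

    kappa : vasodilatory signal decay rate, s^-1
    gamma_f : flow-dependent elimination (autoregulation) rate, s^-1
    tau : hemodynamic transit time, s
    alpha : vessel stiffness (Grubb) exponent, dimensionless, in (0, 1)
    E0 : resting oxygen extraction fraction, dimensionless, in (0, 1)
    V0 : resting blood volume fraction, dimensionless
    k1, k2, k3 : BOLD readout weights (1.5 T convention:
        k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2)
    """

    kappa: float = 0.65
    gamma_f: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    E0: float = 0.34
    V0: float = 0.02
    k1: float = field(default=7.0 * 0.34)
    k2: float = 2.0
    k3: float = field(default=2.0 * 0.34 - 0.2)

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_f", "tau", "V0", "k1", "k2", "k3"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(0 < self.alpha < 1, "alpha must lie in (0, 1)")
        _require(0 < self.E0 < 1, "E0 must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "HemodynamicParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown hemodynamic parameter(s): {sorted(unknown)}")
        return cls(**d)


#: Conversion factor from firing rate in Hz to ms^-1.
HZ_TO_PER_MS = 1e-3
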