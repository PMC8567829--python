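"""Euler-Maruyama integration of the coupled N-region MDMF system.

Per time step the integrator computes population input currents, maps them
through the transfer function to firing rates, advances both gating
variables by drift * dt + sigma * sqrt(dt) * N(0,1) (independent noise per
region and per population), clamps gating to [0, 1], and advances the
inhibitory weight J by the plasticity drift while the plasticity schedule
is active.  Identical (seed, config) pairs yield identical trajectories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .connectome import Connectome
from .params import HZ_TO_PER_MS, Concentrations, ModelParameters

__all__ = ["SimulationConfig", "StateTrajectory", "simulate", "g_sweep"]

_PLASTICITY_MODES = ("on_throughout", "freeze_after_burn_in", "off")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt : step (ms); duration : total simulated time (ms); burn_in :
    initial epoch (ms) excluded from the recorded trajectory;
    record_stride : steps between recorded samples; plasticity_mode :
    whether the inhibitory weight evolves throughout, only during
    burn-in, or not at all.  ``G`` overrides the model-parameter value
    when not None.
    """

    duration: float
    dt: float = 0.1
    burn_in: float = 0.0
    record_stride: int = 10
    seed: int = 0
    plasticity_mode: str = "on_throughout"
    G: float | None = None
    J0: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if not 0 <= self.burn_in < self.duration:
            raise ValueError("burn_in must satisfy 0 <= burn_in < duration")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.plasticity_mode not in _PLASTICITY_MODES:
            raise ValueError(
                f"plasticity_mode must be one of {_PLASTICITY_MODES}"
            )


@dataclass
class StateTrajectory:
    """Recorded time courses of the regional state variables.

    time is in ms (uniform, strictly increasing, burn-in excluded);
    SE/SI/J/rE/rI are (samples x regions); rates are in Hz.
    """

    time: np.ndarray
    SE: np.ndarray
    SI: np.ndarray
    J: np.ndarray
    rE: np.ndarray
    rI: np.ndarray
    config: SimulationConfig
    params: ModelParameters
    conc: Concentrations
    labels: list[str] | None = None
    clamp_fraction: float = 0.0

    @property
    def n_regions(self) -> int:
        return self.SE.shape[1]

    @property
    def sampling_interval_ms(self) -> float:
        return self.config.dt * self.config.record_stride

    def save_text(self, path) -> None:
        """Delimited-text export: time column plus per-region columns."""
        cols = {"time_ms": self.time}
        names = self.labels or [f"R{i + 1:03d}" for i in range(self.n_regions)]
        for name, arr in (("SE", self.SE), ("SI", self.SI), ("J", self.J),
                          ("rE", self.rE), ("rI", self.rI)):
            for k, lab in enumerate(names):
                cols[f"{name}_{lab}"] = arr[:, k]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")

    def save_npz(self, path) -> None:
        """Binary cache with the full configuration embedded as JSON."""
        meta = json.dumps(
            {
                "config": asdict(self.config),
                "params": self.params.to_dict(),
                "conc": self.conc.to_dict(),
                "labels": self.labels,
                "clamp_fraction": self.clamp_fraction,
            }
        )
        np.savez_compressed(
            path, time=self.time, SE=self.SE, SI=self.SI, J=self.J,
            rE=self.rE, rI=self.rI, meta=np.array(meta),
        )

    @classmethod
    def load_npz(cls, path) -> "StateTrajectory":
        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                time=z["time"], SE=z["SE"], SI=z["SI"], J=z["J"],
                rE=z["rE"], rI=z["rI"],
                config=SimulationConfig(**meta["config"]),
                params=ModelParameters.from_dict(meta["params"]),
                conc=Concentrations.from_dict(meta["conc"]),
                labels=meta["labels"],
                clamp_fraction=meta["clamp_fraction"],
            )


def _as_weights(connectome) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(connectome, Connectome):
        return connectome.weights, connectome.labels
    C = np.asarray(connectome, dtype=float)
    return C, None


def simulate(
    connectome,
    params: ModelParameters | None = None,
    conc: Concentrations | None = None,
    sim: SimulationConfig | None = None,
) -> StateTrajectory:
    """Integrate the coupled MDMF system and record the trajectory.

    ``connectome`` may be a Connectome or a bare square weight matrix with
    zero diagonal.  Raises RuntimeError with the first offending region and
    time on numerical blow-up (non-finite state).
    """
    params = params or ModelParameters()
    conc = conc or Concentrations()
    if sim is None:
        raise ValueError("a SimulationConfig is required")
    C, labels = _as_weights(connectome)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {C.shape}")
    if np.any(np.diag(C) != 0):
        raise ValueError("connectivity diagonal must be zero")
    n = C.shape[0]

    dt = sim.dt
    g = params.G if sim.G is None else sim.G
    n_steps = int(round(sim.duration / dt))
    rec_start = int(round(sim.burn_in / dt))
    rec_idx = np.arange(rec_start, n_steps, sim.record_stride)
    n_rec = rec_idx.size

    # near-rest start: with S ~ 0 the external current alone puts the
    # excitatory rate close to the homeostatic target, so the plasticity
    # transient stays mild
    SE = np.full(n, 0.001)
    SI = np.full(n, 0.001)
    J = np.full(n, float(sim.J0))

    out = {
        k: np.empty((n_rec, n))
        for k in ("SE", "SI", "J", "rE", "rI")
    }
    time = rec_idx * dt

    rng = np.random.default_rng(sim.seed)
    sqrt_dt = np.sqrt(dt)
    aE, bE, dE = params.aE, params.bE, params.dE
    aI, bI, dI = params.aI, params.bI, params.dI
    kE = params.alphaE * conc.Tglu * HZ_TO_PER_MS
    kI = params.alphaI * conc.Tgaba * HZ_TO_PER_MS
    wrec = params.wplus * params.JNMDA
    glr = g * params.JNMDA
    IE0 = params.WE * params.I0
    II0 = params.WI * params.I0
    gamma_ms = params.gamma * HZ_TO_PER_MS * HZ_TO_PER_MS
    freeze_step = rec_start if sim.plasticity_mode == "freeze_after_burn_in" else n_steps
    plasticity_on = sim.plasticity_mode != "off"

    clamp_events = 0
    chunk = 4096
    noise = None
    rec_ptr = 0
    next_rec = rec_idx[0] if n_rec else n_steps

    def _rate(x, d):
        # inline transfer function: x/(1 - e^{-dx}) with the removable
        # singularity and the large-negative tail handled (see transfer_rate)
        r = x / -np.expm1(-d * x)
        bad = ~np.isfinite(r)
        if bad.any():
            r[bad] = np.maximum(1.0 / d + x[bad] / 2.0, 0.0)
        return r

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for step in range(n_steps):
            if params.sigma > 0 and step % chunk == 0:
                noise = rng.standard_normal((min(chunk, n_steps - step), 2, n))

            IE = IE0 + wrec * SE + glr * (C @ SE) - J * SI
            II = II0 + params.JNMDA * SE - SI
            rE = _rate(aE * IE - bE, dE)
            rI = _rate(aI * II - bI, dI)

            if step == next_rec:
                out["SE"][rec_ptr] = SE
                out["SI"][rec_ptr] = SI
                out["J"][rec_ptr] = J
                out["rE"][rec_ptr] = rE
                out["rI"][rec_ptr] = rI
                rec_ptr += 1
                next_rec = rec_idx[rec_ptr] if rec_ptr < n_rec else n_steps
                if not np.all(np.isfinite(SE)):
                    bad = int(np.argwhere(~np.isfinite(SE))[0, 0])
                    raise RuntimeError(
                        f"non-finite state in region {bad} at t = {step * dt:g} ms"
                    )

            SE = SE + dt * (-params.betaE * SE + kE * (1.0 - SE) * rE)
            SI = SI + dt * (-params.betaI * SI + kI * (1.0 - SI) * rI)
            if params.sigma > 0:
                z = noise[step % chunk]
                SE += params.sigma * sqrt_dt * z[0]
                SI += params.sigma * sqrt_dt * z[1]
            clamped = (SE < 0) | (SE > 1) | (SI < 0) | (SI > 1)
            if clamped.any():
                clamp_events += int(clamped.sum())
                np.clip(SE, 0.0, 1.0, out=SE)
                np.clip(SI, 0.0, 1.0, out=SI)
            if plasticity_on and step < freeze_step:
                J = np.maximum(J + dt * gamma_ms * rI * (rE - params.rho), 0.0)

    if not np.all(np.isfinite(SE)) or not np.all(np.isfinite(SI)):
        bad_arr = SE if not np.all(np.isfinite(SE)) else SI
        bad = int(np.argwhere(~np.isfinite(bad_arr))[0, 0])
        raise RuntimeError(
            f"non-finite state in region {bad} at t = {n_steps * dt:g} ms"
        )

    clamp_fraction = clamp_events / (2.0 * n * n_steps)
    if clamp_fraction > 1e-3:
        warnings.warn(
            f"gating clamped in {clamp_fraction:.2%} of updates", stacklevel=2
        )
    return StateTrajectory(
        time=time, SE=out["SE"], SI=out["SI"], J=out["J"],
        rE=out["rE"], rI=out["rI"], config=sim, params=params, conc=conc,
        labels=labels, clamp_fraction=clamp_fraction,
    )


def g_sweep(
    connectome,
    params: ModelParameters,
    conc: Concentrations,
    sim: SimulationConfig,
    G_values,
    empirical_fc=None,
    tr: float = 1.97,
    band: tuple[float, float] | None = (0.01, 0.10),
) -> pd.DataFrame:
    """Sweep the global coupling G, one full simulation per value.

    Returns a table with columns G, mean_rE, mean_rI and status; when an
    empirical FC matrix is supplied each cell also runs the hemodynamic +
    FC stage and reports fc_distance and fc_correlation.  Per-G failures
    are flagged in the status column without aborting the sweep.
    """
    from .hemodynamics import bold_from_activity
    from .observables import fc_correlation, fc_distance, functional_connectivity

    G_values = list(G_values)
    if not G_values:
        raise ValueError("G_values must be non-empty")
    rows = []
    for g in G_values:
        row: dict = {"G": float(g), "status": "ok", "error": ""}
        try:
            traj = simulate(connectome, params, conc, replace(sim, G=float(g)))
            row["mean_rE"] = float(traj.rE.mean())
            row["mean_rI"] = float(traj.rI.mean())
            if empirical_fc is not None:
                bold = bold_from_activity(traj, tr=tr)
                fc = functional_connectivity(bold, band=band)
                row["fc_distance"] = fc_distance(fc, empirical_fc)
                row["fc_correlation"] = fc_correlation(fc, empirical_fc)
        except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
            row.update(
                status="failed", error=str(exc),
                mean_rE=np.nan, mean_rI=np.nan,
            )
            if empirical_fc is not None:
                row.update(fc_distance=np.nan, fc_correlation=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
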