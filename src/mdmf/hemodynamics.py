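"""Balloon-Windkessel hemodynamics: regional synaptic activity to BOLD.

Four coupled ODEs per region — vasodilatory signal s, normalized inflow f,
venous volume v, deoxyhemoglobin content q — driven by a neural activity
variable z(t), followed by the nonlinear BOLD readout

    B = V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)).

ds/dt = z - kappa s - gamma_f (f - 1)
df/dt = s
tau dv/dt = f - v^(1/alpha)
tau dq/dt = f E(f)/E0 - v^(1/alpha) q / v,  E(f) = 1 - (1 - E0)^(1/f)

At rest (z = 0) the fixed point is s = 0, f = v = q = 1, B = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import HemodynamicParameters
from .simulate import StateTrajectory

__all__ = ["BoldSeries", "bold_from_activity", "save_bold", "load_bold"]

_INPUT_VARIABLES = ("SE", "rE", "SE+SI")


@dataclass
class BoldSeries:
    """Regional BOLD samples at a fixed repetition time.

    values is (regions x samples); tr in seconds.
    """

    tr: float
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.tr <= 0:
            raise ValueError("TR must be strictly positive")
        if self.values.shape[1] < 2:
            raise ValueError("a BOLD series needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _neural_input(traj: StateTrajectory, input_variable: str) -> np.ndarray:
    if input_variable == "SE":
        return traj.SE
    if input_variable == "rE":
        return traj.rE
    if input_variable == "SE+SI":
        return traj.SE + traj.SI
    raise ValueError(f"input_variable must be one of {_INPUT_VARIABLES}")


def bold_from_activity(
    traj: StateTrajectory,
    hemo: HemodynamicParameters | None = None,
    tr: float = 1.97,
    input_variable: str = "SE",
    transient: float = 20.0,
    substep_ms: float = 1.0,
) -> BoldSeries:
    """Integrate the hemodynamic model along a trajectory and sample at TR.

    The recorded neural series (default: excitatory gating SE, the
    convention of the antecedent mean-field literature; ``rE`` and
    ``SE+SI`` are available) is resampled to ``substep_ms`` resolution
    and the four-state system integrated by forward Euler — the stage is
    deterministic.  The first ``transient`` seconds of BOLD output are
    discarded before downsampling at TR.
    """
    hemo = hemo or HemodynamicParameters()
    if tr <= 0:
        raise ValueError("TR must be strictly positive")
    z_rec = _neural_input(traj, input_variable)
    t_rec = traj.time  # ms
    total_ms = t_rec[-1] - t_rec[0]
    if total_ms < 2 * tr * 1000.0:
        raise ValueError(
            f"trajectory spans {total_ms / 1000.0:g} s, needs at least 2 TR = {2 * tr:g} s"
        )
    n = z_rec.shape[1]

    t_fine = np.arange(t_rec[0], t_rec[-1] + 0.5 * substep_ms, substep_ms)
    z = np.empty((t_fine.size, n))
    for k in range(n):
        z[:, k] = np.interp(t_fine, t_rec, z_rec[:, k])

    dt_s = substep_ms / 1000.0
    inv_alpha = 1.0 / hemo.alpha
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    bold_fine = np.empty((t_fine.size, n))
    for i in range(t_fine.size):
        bold_fine[i] = hemo.V0 * (
            hemo.k1 * (1.0 - q) + hemo.k2 * (1.0 - q / v) + hemo.k3 * (1.0 - v)
        )
        fv = v ** inv_alpha
        E_f = 1.0 - (1.0 - hemo.E0) ** (1.0 / f)
        ds = z[i] - hemo.kappa * s - hemo.gamma_f * (f - 1.0)
        df = s
        dv = (f - fv) / hemo.tau
        dq = (f * E_f / hemo.E0 - fv * q / v) / hemo.tau
        s = s + dt_s * ds
        f = f + dt_s * df
        v = v + dt_s * dv
        q = q + dt_s * dq
    if not (np.all(np.isfinite(bold_fine)) and np.all(v > 0) and np.all(q > 0)):
        raise RuntimeError("hemodynamic integration left the physical regime")

    t0 = t_fine[0] + transient * 1000.0
    sample_times = np.arange(t0, t_fine[-1] + 1e-9, tr * 1000.0)
    if sample_times.size < 2:
        raise ValueError(
            "trajectory too short for 2 BOLD samples after the transient; "
            "reduce `transient` or extend the simulation"
        )
    idx = np.searchsorted(t_fine, sample_times - 1e-9)
    return BoldSeries(tr=tr, values=bold_fine[idx].T, labels=traj.labels)


def save_bold(bold: BoldSeries, path, seed: int | None = None, extra: dict | None = None) -> None:
    """Write BOLD as delimited text (regions x samples) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        bold.values,
        index=bold.labels or [f"R{i + 1:03d}" for i in range(bold.n_regions)],
    )
    df.to_csv(path, sep="\t", header=False, float_format="%.10g")
    sidecar = {"tr_s": bold.tr, "n_regions": bold.n_regions,
               "n_samples": bold.n_samples, "seed": seed}
    sidecar.update(extra or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_bold(path, tr: float | None = None) -> BoldSeries:
    """Read a BOLD table written by :func:`save_bold`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if tr is None:
        if not sidecar.exists():
            raise ValueError("TR not given and no JSON sidecar found")
        tr = json.loads(sidecar.read_text())["tr_s"]
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return BoldSeries(tr=tr, values=df.to_numpy(), labels=[str(x) for x in df.index])
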