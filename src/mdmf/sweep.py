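"""Parameter-sweep driver over (glutamate, GABA[, G]) grids.

Each grid cell runs the full pipeline — simulate, Balloon-Windkessel BOLD,
band-passed FC, metastability, graph metrics at the chosen proportional
threshold, and (when an empirical FC is supplied) FC distance and
correlation.  Results are written incrementally so interrupted sweeps
resume; per-cell seeds derive from the cell's grid coordinates, making the
table invariant to execution order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, load_connectome, synthetic_connectome
from .graph import graph_metrics_row, proportional_threshold
from .hemodynamics import bold_from_activity
from .observables import (
    bandpass,
    fc_correlation,
    fc_distance,
    functional_connectivity,
    instantaneous_phase,
    kuramoto_order,
)
from .params import Concentrations, ModelParameters
from .simulate import SimulationConfig, simulate

__all__ = ["SweepConfig", "run_sweep"]

_CELL_SEED_MOD = 2**31 - 1


@dataclasses.dataclass
class SweepConfig:
    """Grid and pipeline settings for a concentration sweep.

    glutamate / gaba values are in mM and must lie in (0, 15]; ``G``
    may be a scalar or a list.  ``seeds_per_cell`` independent noise
    realizations are averaged per cell.
    """

    glutamate: list[float]
    gaba: list[float]
    G: float | list[float] = 0.69
    seeds_per_cell: int = 1
    base_seed: int = 0
    connectome_path: str | None = None
    synthetic_n: int = 68
    synthetic_seed: int = 1
    synthetic_density: float = 0.35
    duration: float = 120_000.0
    burn_in: float = 60_000.0
    dt: float = 0.1
    record_stride: int = 10
    plasticity_mode: str = "on_throughout"
    tr: float = 1.97
    fc_band: tuple[float, float] | None = (0.01, 0.10)
    meta_band: tuple[float, float] = (0.03, 0.06)
    psw: float = 0.25
    bold_input: str = "SE"
    bold_transient: float = 20.0
    empirical_fc_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("glutamate", "gaba"):
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"{name} grid must be non-empty")
            if any(not 0 < v <= 15 for v in vals):
                raise ValueError(f"{name} values must lie in (0, 15] mM")
        if self.seeds_per_cell < 1:
            raise ValueError("seeds_per_cell must be >= 1")

    @property
    def g_values(self) -> list[float]:
        return list(self.G) if isinstance(self.G, (list, tuple)) else [float(self.G)]

    def resolve_connectome(self) -> Connectome:
        if self.connectome_path is not None:
            return load_connectome(self.connectome_path)
        return synthetic_connectome(
            self.synthetic_n, seed=self.synthetic_seed, density=self.synthetic_density
        )


def _cell_seed(base: int, idx: int, rep: int) -> int:
    # deterministic in (cell index, repetition), independent of run order
    return (base * 1_000_003 + idx * 9_176 + rep * 7_919) % _CELL_SEED_MOD


def _run_cell(
    conn: Connectome,
    params: ModelParameters,
    conc: Concentrations,
    cfg: SweepConfig,
    g: float,
    seed: int,
    empirical_fc,
) -> dict:
    sim = SimulationConfig(
        duration=cfg.duration, dt=cfg.dt, burn_in=cfg.burn_in,
        record_stride=cfg.record_stride, seed=seed,
        plasticity_mode=cfg.plasticity_mode, G=g,
    )
    traj = simulate(conn, params, conc, sim)
    out = {"mean_rE": float(traj.rE.mean()), "mean_rI": float(traj.rI.mean())}
    bold = bold_from_activity(
        traj, tr=cfg.tr, input_variable=cfg.bold_input, transient=cfg.bold_transient
    )
    fs = 1.0 / cfg.tr
    zscored = (bold.values - bold.values.mean(axis=1, keepdims=True))
    sd = bold.values.std(axis=1, keepdims=True)
    zscored = np.divide(zscored, np.where(sd == 0, 1.0, sd))
    narrow = bandpass(zscored, cfg.meta_band[0], cfg.meta_band[1], fs)
    out["metastability"] = kuramoto_order(instantaneous_phase(narrow)).metastability
    fc = functional_connectivity(bold, band=cfg.fc_band)
    if empirical_fc is not None:
        out["fc_distance"] = fc_distance(fc, empirical_fc)
        out["fc_correlation"] = fc_correlation(fc, empirical_fc)
    graph = proportional_threshold(fc, cfg.psw)
    out.update(graph_metrics_row(graph, seed=seed))
    return out


def run_sweep(cfg: SweepConfig, out_path=None, params: ModelParameters | None = None) -> pd.DataFrame:
    """Run the (glutamate, GABA[, G]) grid and return the result table.

    With ``out_path`` the table is written incrementally as tab-delimited
    text after every cell; an existing file is loaded first and completed
    cells (status "ok") are skipped, making the sweep resumable.  Failed
    cells are flagged in the status column and do not abort the sweep.
    """
    params = params or ModelParameters()
    conn = cfg.resolve_connectome()
    from .observables import load_fc

    empirical_fc = (
        load_fc(cfg.empirical_fc_path, provenance="empirical")
        if cfg.empirical_fc_path
        else None
    )

    cells = [
        (tg, tb, g)
        for tg in cfg.glutamate
        for tb in cfg.gaba
        for g in cfg.g_values
    ]
    done: dict[tuple, dict] = {}
    if out_path is not None and Path(out_path).exists():
        prev = pd.read_csv(out_path, sep="\t")
        for _, row in prev.iterrows():
            if row.get("status") == "ok":
                done[(row["Tglu"], row["Tgaba"], row["G"])] = row.to_dict()

    rows = []
    for idx, (tg, tb, g) in enumerate(cells):
        key = (tg, tb, g)
        if key in done:
            rows.append(done[key])
            continue
        base_row = {"Tglu": tg, "Tgaba": tb, "G": g}
        seeds = [_cell_seed(cfg.base_seed, idx, rep) for rep in range(cfg.seeds_per_cell)]
        base_row["seeds"] = ";".join(str(s) for s in seeds)
        try:
            conc = Concentrations(Tglu=tg, Tgaba=tb)
            reps = [
                _run_cell(conn, params, conc, cfg, g, s, empirical_fc)
                for s in seeds
            ]
            merged = {k: float(np.mean([r[k] for r in reps])) for k in reps[0]}
            base_row.update(merged, status="ok", error="")
        except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
            base_row.update(status="failed", error=str(exc))
        rows.append(base_row)
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False,
                                      float_format="%.10g")
    return pd.DataFrame(rows)
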