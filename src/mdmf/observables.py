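"""Functional-connectivity and synchrony observables.

FC matrices (Pearson correlations of z-scored BOLD), the scaled Frobenius
FC distance, FC correlation over the strict upper triangle, zero-phase
band-pass filtering, Hilbert instantaneous phases, the Kuramoto order
parameter R(t) and its temporal standard deviation (metastability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import pearsonr

from .hemodynamics import BoldSeries

__all__ = [
    "FCMatrix",
    "PhaseSeries",
    "OrderParameterSeries",
    "bandpass",
    "instantaneous_phase",
    "kuramoto_order",
    "functional_connectivity",
    "fc_distance",
    "fc_correlation",
    "save_fc",
    "load_fc",
]


@dataclass
class FCMatrix:
    """Pearson functional-connectivity matrix with region labels."""

    values: np.ndarray
    labels: list[str] | None = None
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"FC matrix must be square, got {V.shape}")
        if not np.allclose(V, V.T, atol=1e-9):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-9):
            raise ValueError("FC matrix must have a unit diagonal")
        if np.any(V < -1 - 1e-9) or np.any(V > 1 + 1e-9):
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = np.clip((V + V.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.values, 1.0)
        if self.labels is not None and len(self.labels) != V.shape[0]:
            raise ValueError("label count does not match FC dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, labels: list[str]) -> "FCMatrix":
        """Submatrix restricted to the given region labels, in their order."""
        if self.labels is None:
            raise ValueError("this FC matrix carries no labels to subset by")
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise ValueError(f"labels not present: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return FCMatrix(
            self.values[np.ix_(idx, idx)],
            labels=list(labels),
            provenance="subset",
        )


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians), regions x time."""

    phases: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")


@dataclass
class OrderParameterSeries:
    """Kuramoto order parameter R(t) with its temporal summaries."""

    R: np.ndarray
    mean: float
    metastability: float

    def __post_init__(self) -> None:
        if np.any(self.R < -1e-12) or np.any(self.R > 1 + 1e-9):
            raise ValueError("R(t) must lie in [0, 1]")


def bandpass(series: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass, per region.

    ``series`` is (regions x time); DC is removed by the filter itself.
    The band must satisfy 0 < low < high < fs/2.
    """
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low:g}, {high:g}) Hz invalid for Nyquist {nyq:g} Hz"
        )
    series = np.atleast_2d(np.asarray(series, dtype=float))
    sos = butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, series - series.mean(axis=1, keepdims=True), axis=1)


def instantaneous_phase(series: np.ndarray, band: tuple[float, float] | None = None) -> PhaseSeries:
    """Analytic-signal (Hilbert) phase of each regional series.

    Expects band-limited, zero-mean input; constant rows are rejected
    because their phase is undefined.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    ptp = series.max(axis=1) - series.min(axis=1)
    if np.any(ptp <= 0):
        bad = int(np.argwhere(ptp <= 0)[0, 0])
        raise ValueError(f"region {bad} is constant; phase undefined")
    analytic = hilbert(series - series.mean(axis=1, keepdims=True), axis=1)
    return PhaseSeries(np.angle(analytic), band=band)


def kuramoto_order(phases: PhaseSeries | np.ndarray, edge_exclude: int = 10) -> OrderParameterSeries:
    """Kuramoto order parameter R(t) = |sum_k exp(i phi_k(t))| / n.

    ``mean`` averages R(t) over all samples; ``metastability`` is the
    standard deviation of R(t) with ``edge_exclude`` samples dropped at
    each end (Hilbert edge artifact), or over everything when the series
    is too short to trim.
    """
    if isinstance(phases, PhaseSeries):
        phi = phases.phases
    else:
        phi = np.atleast_2d(np.asarray(phases, dtype=float))
    if phi.size == 0:
        raise ValueError("empty phase matrix")
    if phi.shape[0] < 2:
        raise ValueError("need at least 2 regions for an order parameter")
    R = np.abs(np.exp(1j * phi).mean(axis=0))
    R = np.minimum(R, 1.0)
    if R.size > 2 * edge_exclude + 1:
        core = R[edge_exclude: R.size - edge_exclude]
    else:
        core = R
    return OrderParameterSeries(R=R, mean=float(R.mean()), metastability=float(core.std()))


def functional_connectivity(
    bold: BoldSeries | np.ndarray,
    band: tuple[float, float] | None = None,
    labels: list[str] | None = None,
    fs: float | None = None,
) -> FCMatrix:
    """Pairwise Pearson correlations of z-scored regional BOLD.

    With ``band`` the series is zero-phase band-pass filtered first
    (sampling rate taken from the BOLD TR unless ``fs`` is given).
    Zero-variance regions get zero correlations with a warning.
    """
    if isinstance(bold, BoldSeries):
        X = bold.values
        labels = labels if labels is not None else bold.labels
        fs = fs if fs is not None else 1.0 / bold.tr
    else:
        X = np.atleast_2d(np.asarray(bold, dtype=float))
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate FC")
    if band is not None:
        if fs is None:
            raise ValueError("band-pass FC needs a sampling rate")
        X = bandpass(X, band[0], band[1], fs)
    sd = X.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance region(s); correlations set to 0",
            stacklevel=2,
        )
        X = X.copy()
        X[dead] = 0.0
        sd = np.where(dead, 1.0, sd)
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    fc = (Z @ Z.T) / X.shape[1]
    fc[dead, :] = 0.0
    fc[:, dead] = 0.0
    np.fill_diagonal(fc, 1.0)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    return FCMatrix(fc, labels=labels)


def _paired(A: FCMatrix, B: FCMatrix, subset: list[str] | None) -> tuple[np.ndarray, np.ndarray]:
    if subset is not None:
        A, B = A.subset(subset), B.subset(subset)
    if A.n != B.n:
        raise ValueError(f"FC dimensions differ: {A.n} vs {B.n}")
    if A.labels is not None and B.labels is not None and A.labels != B.labels:
        raise ValueError("FC label orders differ")
    return A.values, B.values


def fc_distance(A: FCMatrix, B: FCMatrix, subset: list[str] | None = None) -> float:
    """Scaled Frobenius distance: (1/N) sqrt(sum_ij (A_ij - B_ij)^2).

    The sum runs over all N^2 entries (the unit diagonals cancel).  With
    ``subset`` both matrices are first restricted to those region labels,
    e.g. the nine default-mode-network regions.
    """
    a, b = _paired(A, B, subset)
    return float(np.sqrt(np.sum((a - b) ** 2)) / a.shape[0])


def fc_correlation(A: FCMatrix, B: FCMatrix, subset: list[str] | None = None) -> float:
    """Pearson correlation of the vectorized strict upper triangles."""
    a, b = _paired(A, B, subset)
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant upper triangle; correlation undefined")
    return float(pearsonr(x, y).statistic)


def save_fc(fc: FCMatrix, path, delimiter: str = ",") -> None:
    """Delimited text with a header row of region labels."""
    labels = fc.labels or [f"R{i + 1:03d}" for i in range(fc.n)]
    np.savetxt(path, fc.values, fmt="%.10g", delimiter=delimiter,
               header=delimiter.join(labels), comments="")


def load_fc(path, provenance: str = "loaded") -> FCMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else ("\t" if "\t" in first else None)
    tokens = [t.strip() for t in first.strip().split(delim) if t.strip()]
    try:
        float(tokens[0])
        labels, skip = None, 0
    except ValueError:
        labels, skip = tokens, 1
    vals = np.genfromtxt(path, delimiter=delim, skip_header=skip)
    return FCMatrix(np.atleast_2d(vals), labels=labels, provenance=provenance)
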