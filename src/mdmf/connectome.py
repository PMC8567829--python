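"""Structural-connectome I/O, validation, labels, and synthetic generation.

A connectome here is a max-normalized, zero-diagonal, non-negative weight
matrix in [0, 1], the form produced by probabilistic tractography pipelines
after normalization.  The synthetic generator emulates that form — modular
(two-hemisphere) block structure on an exponential distance kernel — so the
whole simulation stack is testable without neuroimaging data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Connectome",
    "load_connectome",
    "save_connectome",
    "synthetic_connectome",
    "desikan_labels",
    "dmn_labels",
]

# Desikan-Killiany cortical parcellation: the 34 per-hemisphere region
# abbreviations in atlas (area-ID) order.
_DESIKAN_34 = [
    "BSTS", "CAC", "CMF", "CUN", "ENT", "FUS", "IP", "IF", "IC", "LO",
    "LOF", "LIN", "MOF", "MT", "PH", "PC", "PAOP", "PAOR", "PT", "PEC",
    "POCE", "POCI", "PRCE", "PRCU", "RAC", "RMF", "SF", "SP", "ST", "SM",
    "FP", "TP", "TT", "INS",
]

_DMN_9 = ["LIC", "LIP", "LMOF", "LPH", "LSF", "RIP", "RMOF", "RPH", "RSF"]


def desikan_labels() -> list[str]:
    """The 68 cortical region labels, left hemisphere first, atlas order."""
    return [f"L{a}" for a in _DESIKAN_34] + [f"R{a}" for a in _DESIKAN_34]


def dmn_labels() -> list[str]:
    """The nine default-mode-network labels (subset of desikan_labels)."""
    return list(_DMN_9)


@dataclass
class Connectome:
    """Validated structural connectivity: weights in [0,1], zero diagonal."""

    weights: np.ndarray
    labels: list[str] | None = None
    provenance: str = ""
    _atol: float = field(default=1e-12, repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {W.shape}")
        if W.shape[0] < 2:
            raise ValueError("a connectome needs at least 2 regions")
        if np.any(~np.isfinite(W)):
            i, j = np.argwhere(~np.isfinite(W))[0]
            raise ValueError(f"non-finite weight at ({i}, {j})")
        if np.any(W < -self._atol) or np.any(W > 1 + self._atol):
            i, j = np.argwhere((W < -self._atol) | (W > 1 + self._atol))[0]
            raise ValueError(f"weight out of [0, 1] at ({i}, {j}): {W[i, j]}")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = np.clip(W, 0.0, 1.0)
        if self.labels is not None and len(self.labels) != W.shape[0]:
            raise ValueError("label count does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def _sniff_delimiter(first_line: str) -> str | None:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return None  # whitespace


def load_connectome(path, labels: list[str] | None = None) -> Connectome:
    """Load a delimited-text weight matrix and validate it.

    Accepts comma-, tab- or whitespace-delimited matrices with an optional
    single header row of region labels.  A nonzero diagonal is zeroed with
    a warning; weights above 1 trigger max-normalization with a warning.
    Negative or NaN entries are rejected with their coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    tokens = first.strip().split(delim)
    has_header = False
    try:
        float(tokens[0])
    except ValueError:
        has_header = True
    data = np.genfromtxt(path, delimiter=delim, skip_header=int(has_header))
    if has_header and labels is None:
        labels = [t.strip() for t in tokens if t.strip()]
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] != data.shape[1]:
        raise ValueError(
            f"connectome file must hold a square matrix, got {data.shape[0]}x{data.shape[1]}"
        )
    if np.any(np.isnan(data)):
        i, j = np.argwhere(np.isnan(data))[0]
        raise ValueError(f"NaN entry at row {i}, column {j}")
    if np.any(data < 0):
        i, j = np.argwhere(data < 0)[0]
        raise ValueError(f"negative weight at row {i}, column {j}: {data[i, j]}")
    if np.any(np.diag(data) != 0):
        warnings.warn("nonzero diagonal zeroed on load", stacklevel=2)
        np.fill_diagonal(data, 0.0)
    if data.max() > 1.0:
        warnings.warn(
            f"weights exceed 1 (max {data.max():g}); max-normalizing", stacklevel=2
        )
        data = data / data.max()
    return Connectome(data, labels=labels, provenance=f"loaded:{path.name}")


def save_connectome(conn: Connectome, path, delimiter: str = ",") -> None:
    """Write a connectome as delimited text (10 significant digits).

    A single header row of labels is emitted when the connectome has them.
    """
    path = Path(path)
    header = delimiter.join(conn.labels) if conn.labels is not None else ""
    np.savetxt(
        path,
        conn.weights,
        fmt="%.10g",
        delimiter=delimiter,
        header=header,
        comments="",
    )


def synthetic_connectome(
    n: int,
    seed: int,
    module_count: int = 2,
    density: float = 0.35,
    length_scale: float = 0.15,
    module_gain: float = 3.0,
    weight_jitter: float = 1.0,
) -> Connectome:
    """Seeded synthetic structural connectome with hemisphere-like modules.

    Regions get random planar positions in the unit square; base weights
    follow an exponential decay kernel exp(-dist/length_scale) with
    lognormal jitter, amplified by ``module_gain`` inside each of
    ``module_count`` contiguous blocks (a two-hemisphere analogue at the
    default).  The weakest connections are pruned to the target density,
    the matrix is symmetrized, max-normalized, and the diagonal zeroed.

    These are fixtures emulating the statistical shape of tractography
    output, not claims about anatomy.
    """
    if n < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(size=(n, 2))
    module = (np.arange(n) * module_count) // n
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    W = np.exp(-dist / length_scale)
    same = module[:, None] == module[None, :]
    W = W * np.where(same, module_gain, 1.0)
    jitter = rng.lognormal(mean=0.0, sigma=weight_jitter, size=(n, n))
    W = W * (jitter + jitter.T) / 2.0
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)

    iu, ju = np.triu_indices(n, k=1)
    vals = W[iu, ju]
    keep = max(1, int(round(density * vals.size)))
    if keep < vals.size:
        thresh = np.partition(vals, vals.size - keep)[vals.size - keep]
        mask = np.zeros_like(W, dtype=bool)
        sel = vals >= thresh
        mask[iu[sel], ju[sel]] = True
        mask |= mask.T
        W = np.where(mask, W, 0.0)
    W = W / W.max()

    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp > 1:
        warnings.warn(
            f"synthetic connectome is disconnected ({n_comp} components) "
            f"at density {density}",
            stacklevel=2,
        )
    labels = desikan_labels() if n == 68 else [f"R{i + 1:03d}" for i in range(n)]
    return Connectome(
        W,
        labels=labels,
        provenance=f"synthetic(n={n}, seed={seed}, modules={module_count}, density={density})",
    )
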