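"""Batch self-organizing map on a hexagonal sheet lattice.

The map is a flat (non-toroidal) sheet of nodes on a hexagonal lattice with
offset coordinates: node (row, col) is embedded at
``(col + 0.5 * (row % 2), row * sqrt(3)/2)``, so every pair of adjacent
hexagonal nodes sits at unit distance.  Codebook vectors are initialized
uniformly within each feature's observed range and trained with the batch
rule in two phases (rough, then fine-tuning), using the Epanechnikov ("ep")
neighbourhood kernel ``max(0, 1 - (d/r)^2)`` with a linearly shrinking
radius.  Map quality is summarized by the quantization error (mean Euclidean
distance of the data to their best-matching units) and the topographic error
(fraction of data whose first and second BMUs are not lattice neighbours).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

_ROW_PITCH = math.sqrt(3.0) / 2.0
#: Lattice distances below this count as hexagonal adjacency.
_ADJACENT = 1.0 + 1e-9


def hex_positions(n_rows: int, n_cols: int) -> np.ndarray:
    """Planar embedding of an offset hexagonal grid (odd rows shifted +0.5)."""
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = cols + 0.5 * (rows % 2)
    y = rows * _ROW_PITCH
    return np.column_stack([x, y]).astype(float)


def ep_neighbourhood(lattice_distance, radius: float):
    """Epanechnikov kernel ``max(0, 1 - (d/radius)^2)``; peak 1 at d = 0."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    d = np.asarray(lattice_distance, dtype=float)
    w = np.maximum(0.0, 1.0 - (d / radius) ** 2)
    return float(w) if w.ndim == 0 else w


@dataclass
class TrainingSchedule:
    """Two-phase batch schedule: rough ordering then fine tuning.

    Epoch counts follow the source protocol (20 rough + 50 fine); radii are
    in lattice units and interpolate linearly within each phase.  A ``None``
    rough start radius defaults to ``max(n_rows, n_cols) / 4``, floored at 2
    lattice units: the ep kernel has compact support, so a start radius at or
    below the unit lattice spacing would never couple neighbouring nodes and
    randomly initialized empty nodes could never be pulled toward the data.
    """

    rough_epochs: int = 20
    fine_epochs: int = 50
    rough_radius: tuple[float | None, float] = (None, 1.0)
    fine_radius: tuple[float, float] = (1.0, 0.5)
    seed: int = 0

    def radii(self, n_rows: int, n_cols: int) -> np.ndarray:
        start = self.rough_radius[0]
        if start is None:
            start = max(2.0, max(n_rows, n_cols) / 4.0)
        start = max(start, self.rough_radius[1])
        seq = [
            np.linspace(start, self.rough_radius[1], max(self.rough_epochs, 1)),
            np.linspace(*self.fine_radius, max(self.fine_epochs, 1)),
        ]
        radii = np.concatenate(
            [s for s, n in zip(seq, (self.rough_epochs, self.fine_epochs)) if n > 0]
        )
        if not np.all(np.diff(radii) <= 1e-12):
            raise ValueError("radius schedule must be non-increasing")
        return radii


@dataclass
class SomMap:
    """One trained map layer: geometry, codebook and quality metrics."""

    n_rows: int
    n_cols: int
    codebook: np.ndarray                   # (n_nodes, n_features)
    node_positions: np.ndarray = None      # (n_nodes, 2) planar embedding
    qe: float = float("nan")
    te: float = float("nan")
    training_log: list = field(default_factory=list)  # (radius, qe, sse) per epoch

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows * self.n_cols < 2:
            raise ValueError("map needs at least 2 nodes")
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.n_rows * self.n_cols:
            raise ValueError("codebook rows must equal n_rows * n_cols")
        if self.node_positions is None:
            self.node_positions = hex_positions(self.n_rows, self.n_cols)

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def lattice_distances(self) -> np.ndarray:
        return cdist(self.node_positions, self.node_positions)

    def adjacency(self) -> np.ndarray:
        d = self.lattice_distances()
        return (d > 0) & (d <= _ADJACENT)


def init_map(n_rows: int, n_cols: int, n_features: int, data, seed: int) -> SomMap:
    """Random codebook, uniform within each feature's observed range."""
    x = _as_array(data)
    if x.shape[1] != n_features:
        raise ValueError(
            f"data has {x.shape[1]} features, expected {n_features}"
        )
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    codebook = rng.uniform(0.0, 1.0, size=(n_rows * n_cols, n_features))
    codebook = lo + codebook * (hi - lo)
    return SomMap(n_rows, n_cols, codebook)


def _as_array(data) -> np.ndarray:
    x = getattr(data, "values", data)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("data must be a non-empty 2-D matrix")
    return x


def bmu(som: SomMap, x) -> int:
    """Index of the nearest codebook row (ties to the lowest node index)."""
    d = np.linalg.norm(som.codebook - np.asarray(x, dtype=float), axis=1)
    return int(np.argmin(d))


def second_bmu(som: SomMap, x) -> int:
    d = np.linalg.norm(som.codebook - np.asarray(x, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")
    return int(order[1])


def bmus(som: SomMap, data) -> np.ndarray:
    """Vectorized BMU indices for every row of ``data``."""
    d = cdist(_as_array(data), som.codebook)
    return d.argmin(axis=1)


def batch_train(som: SomMap, data, schedule: TrainingSchedule | None = None) -> SomMap:
    """Two-phase batch training; returns a new map with final QE/TE recorded.

    Each epoch assigns every datum to its BMU and replaces each codebook row
    by the neighbourhood-weighted mean of all data (weights: ep kernel of the
    lattice distance between the node and each datum's BMU at the current
    radius).  Nodes receiving zero total weight keep their codebook row.
    """
    schedule = schedule or TrainingSchedule()
    x = _as_array(data)
    if x.shape[1] != som.codebook.shape[1]:
        raise ValueError("data and codebook feature dimensions differ")
    codebook = som.codebook.copy()
    lat = cdist(som.node_positions, som.node_positions)
    log: list[tuple[float, float, float]] = []
    for radius in schedule.radii(som.n_rows, som.n_cols):
        dist = cdist(x, codebook)
        assign = dist.argmin(axis=1)
        best = dist[np.arange(len(x)), assign]
        log.append((float(radius), float(best.mean()), float((best ** 2).sum())))
        occupied = np.unique(assign)
        if len(occupied) == 1 and som.n_nodes > 1:
            # degenerate collapse: every datum shares one BMU, so the coupled
            # update would map every node to the same mean and jam the map;
            # reseed the unoccupied nodes at the farthest data points
            # (the batch analogue of the k-means empty-cluster rule)
            order = np.argsort(best)[::-1]
            empty = [j for j in range(som.n_nodes) if j != occupied[0]]
            for slot, j in enumerate(empty):
                codebook[j] = x[order[slot % len(order)]]
            continue
        # per-BMU sufficient statistics, spread through the kernel
        sums = np.zeros_like(codebook)
        np.add.at(sums, assign, x)
        counts = np.bincount(assign, minlength=som.n_nodes).astype(float)
        kernel = np.maximum(0.0, 1.0 - (lat / max(radius, 1e-12)) ** 2)
        numer = kernel @ sums
        denom = kernel @ counts
        upd = denom > 0
        codebook[upd] = numer[upd] / denom[upd, None]
    trained = SomMap(som.n_rows, som.n_cols, codebook,
                     node_positions=som.node_positions.copy(),
                     training_log=log)
    trained.qe = quantization_error(trained, x)
    trained.te = topographic_error(trained, x)
    return trained


def quantization_error(som: SomMap, data) -> float:
    """Mean Euclidean distance from each datum to its BMU."""
    d = cdist(_as_array(data), som.codebook)
    return float(d.min(axis=1).mean())


def topographic_error(som: SomMap, data) -> float:
    """Fraction of data whose first and second BMUs are not hex-adjacent."""
    if som.n_nodes < 2:
        raise ValueError("topographic error needs at least 2 nodes")
    d = cdist(_as_array(data), som.codebook)
    order = np.argsort(d, axis=1, kind="stable")
    adj = som.adjacency()
    ok = adj[order[:, 0], order[:, 1]]
    return float(1.0 - ok.mean())


def u_matrix(som: SomMap) -> np.ndarray:
    """Per-node mean codebook distance to lattice neighbours, as a grid.

    High ridges in the U-matrix mark cluster boundaries on the map.
    Returned with shape (n_rows, n_cols).
    """
    adj = som.adjacency()
    cd = cdist(som.codebook, som.codebook)
    out = np.array([
        cd[i, adj[i]].mean() if adj[i].any() else 0.0
        for i in range(som.n_nodes)
    ])
    return out.reshape(som.n_rows, som.n_cols)


def write_u_matrix(som: SomMap, path) -> None:
    np.savetxt(path, u_matrix(som), delimiter="\t", fmt="%.6g")


def select_map_size(
    data,
    candidates: list[tuple[int, int]] | None = None,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
) -> tuple[tuple[int, int], list[dict]]:
    """Choose map dimensions by joint quantization/topographic quality.

    One map per candidate is trained from a seed-derived initialization; the
    candidate minimizing the sum of QE rank and TE rank wins, ties breaking
    toward fewer nodes.  Returns the winner plus the full (size, qe, te)
    table for logging.
    """
    from scipy.stats import rankdata

    x = _as_array(data)
    if candidates is None:
        candidates = default_size_candidates(x.shape[0])
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    schedule = schedule or TrainingSchedule()
    rows = []
    for i, (r, c) in enumerate(candidates):
        som = batch_train(init_map(r, c, x.shape[1], x, seed + i), x, schedule)
        rows.append({"rows": r, "cols": c, "qe": som.qe, "te": som.te})
    ranks = rankdata([t["qe"] for t in rows]) + rankdata([t["te"] for t in rows])
    for t, rk in zip(rows, ranks):
        t["rank_sum"] = float(rk)
    best = min(
        range(len(rows)),
        key=lambda i: (ranks[i], rows[i]["rows"] * rows[i]["cols"], i),
    )
    return (rows[best]["rows"], rows[best]["cols"]), rows


def default_size_candidates(n: int) -> list[tuple[int, int]]:
    """Rectangles around the ``5 * sqrt(n)`` map-units heuristic."""
    target = 5.0 * math.sqrt(n)
    base = [(8, 6), (7, 7), (10, 5), (6, 6), (9, 5), (12, 4)]
    if 40 <= target <= 60:
        return base
    side = max(2, round(math.sqrt(target)))
    return [(side, side), (side + 1, side), (side + 2, side - 1 or 1), (side, side - 1 or 1)]
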