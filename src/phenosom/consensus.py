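"""Stacked multi-layer SOM clustering, k-means reference, and the
mode-consensus stability protocol.

The stack trains a first SOM on the standardized cohort, then feeds each
patient's best-matching-unit codebook vector into a smaller second map, and
so on; patients sharing an upstream BMU collapse onto identical inputs, so
successive layers coarsen the partition until the number of occupied
final-layer nodes equals the target cluster count.  Because single runs are
start-dependent, the clustering (SOM stack or k-means) is repeated many
times, runs are aligned by optimal label assignment, and the per-patient
mode is taken; that consensus is itself repeated three times, and the result
counts as stable only when fewer than 10% of patients change cluster across
the three consensus runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .som import SomMap, TrainingSchedule, batch_train, bmus, init_map

#: Stability threshold: the consensus triplet may disagree on < 10% of patients.
STABILITY_THRESHOLD = 0.10


def kmeans(data, k: int, seed: int, max_iter: int = 300) -> np.ndarray:
    """Lloyd k-means with random distinct data points as initial centroids.

    Squared-Euclidean assignment, iterated until assignments are fixed or
    ``max_iter`` sweeps; a centroid left with no members is re-seeded at the
    point farthest from its assigned centroid.  Deterministic given ``seed``.
    Returns labels in {1, ..., k}.
    """
    x = np.asarray(getattr(data, "values", data), dtype=float)
    n = x.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n={n}, got {k}")
    rng = np.random.default_rng(seed)
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_iter):
        d2 = cdist(x, centroids, metric="sqeuclidean")
        new_assign = d2.argmin(axis=1)
        for j in range(k):
            if not np.any(new_assign == j):
                far = int(d2[np.arange(n), new_assign].argmax())
                centroids[j] = x[far]
                new_assign[far] = j
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = x[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
    return assign + 1


@dataclass
class LayerStack:
    """Ordered SOM layers with chained per-patient BMU paths."""

    layers: list[SomMap]
    bmu_paths: np.ndarray          # (n_layers, n_patients) node indices
    final_labels: np.ndarray       # (n_patients,), values in {1..k}
    target_k: int

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def train_stack(
    data,
    target_k: int = 2,
    first_layer_size: tuple[int, int] = (8, 6),
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    max_layers: int = 8,
) -> LayerStack:
    """Train the stacked SOM until the partition has ``target_k`` clusters.

    Layer 1 is trained on the data; each patient's input to layer l+1 is the
    codebook vector of their BMU at layer l.  Layer node counts shrink by
    roughly halving, with the aspect ratio following the first-two-PC
    variance ratio of the data; a final 1 x target_k layer is allowed so the
    stack can always terminate.  A cluster is an occupied final-layer node.
    """
    schedule = schedule or TrainingSchedule()
    x = np.asarray(getattr(data, "values", data), dtype=float)
    n, p = x.shape
    if first_layer_size[0] * first_layer_size[1] < target_k:
        raise ValueError("first layer must have at least target_k nodes")
    rng = np.random.default_rng(seed)
    sizes = _layer_sizes(x, first_layer_size, target_k, max_layers)

    layers: list[SomMap] = []
    paths = []
    rep = x
    labels = None
    for (r, c) in sizes:
        som = batch_train(
            init_map(r, c, rep.shape[1], rep, int(rng.integers(2 ** 31))),
            rep,
            schedule,
        )
        assign = bmus(som, rep)
        layers.append(som)
        paths.append(assign)
        occupied = np.unique(assign)
        if len(occupied) == target_k:
            remap = {node: i + 1 for i, node in enumerate(occupied)}
            labels = np.array([remap[a] for a in assign])
            break
        rep = som.codebook[assign]
    if labels is None:
        raise RuntimeError(
            f"stack did not reach {target_k} clusters within {len(sizes)} layers "
            f"(last layer occupied {len(np.unique(paths[-1]))} nodes)"
        )
    return LayerStack(layers, np.asarray(paths), labels, target_k)


def _layer_sizes(
    x: np.ndarray,
    first: tuple[int, int],
    target_k: int,
    max_layers: int,
) -> list[tuple[int, int]]:
    # aspect ratio from the top two principal variances, clipped for sanity
    xc = x - x.mean(axis=0)
    sv = np.linalg.svd(xc, compute_uv=False)
    ratio = float(np.clip(sv[0] / max(sv[1], 1e-12), 1.0, 3.0)) if len(sv) > 1 else 1.0
    sizes = [tuple(first)]
    nodes = first[0] * first[1]
    while len(sizes) < max_layers:
        nodes = max(target_k, int(np.ceil(nodes / 2)))
        if nodes <= target_k:
            rows, cols = 1, target_k
        else:
            cols = max(1, round(np.sqrt(nodes / ratio)))
            rows = max(1, int(np.ceil(nodes / cols)))
            if rows * cols < max(4, target_k):
                rows, cols = 2, 2
        if (rows, cols) == sizes[-1]:
            rows, cols = 1, target_k
        sizes.append((rows, cols))
        if rows * cols <= target_k:
            break
    return sizes


def align_labels(reference, candidate) -> np.ndarray:
    """Relabel ``candidate`` (a permutation of its cluster ids) to best match
    ``reference``, by optimal assignment on the contingency table."""
    ref = np.asarray(reference)
    cand = np.asarray(candidate)
    if ref.shape != cand.shape:
        raise ValueError("label vectors must have the same length")
    ref_ids = np.unique(ref)
    cand_ids = np.unique(cand)
    table = np.zeros((len(cand_ids), len(ref_ids)))
    for i, ci in enumerate(cand_ids):
        for j, rj in enumerate(ref_ids):
            table[i, j] = np.sum((cand == ci) & (ref == rj))
    rows, cols = linear_sum_assignment(-table)
    mapping = {}
    used = set()
    for i, j in zip(rows, cols):
        mapping[cand_ids[i]] = ref_ids[j]
        used.add(ref_ids[j])
    spare = iter([r for r in range(1, len(cand_ids) + len(ref_ids) + 2)
                  if r not in used])
    out = np.empty_like(cand)
    for ci in cand_ids:
        out[cand == ci] = mapping.get(ci, next(spare))
    return out


@dataclass
class RunEnsemble:
    """Labels from repeated clustering runs plus their aligned consensus."""

    method: str
    runs: np.ndarray               # (n_repetitions, n_patients) raw labels
    aligned_runs: np.ndarray = field(init=False)
    mode_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        runs = np.asarray(self.runs)
        aligned = [runs[0]]
        for r in runs[1:]:
            aligned.append(align_labels(runs[0], r))
        self.aligned_runs = np.asarray(aligned)
        self.mode_labels = consensus_mode(self.aligned_runs)

    @property
    def n_repetitions(self) -> int:
        return self.runs.shape[0]


def consensus_mode(aligned_runs) -> np.ndarray:
    """Per-patient most frequent aligned label; ties to the smaller id."""
    runs = np.asarray(aligned_runs)
    out = np.empty(runs.shape[1], dtype=int)
    for i in range(runs.shape[1]):
        ids, counts = np.unique(runs[:, i], return_counts=True)
        out[i] = ids[counts.argmax()]   # unique() sorts ids ascending
    return out


@dataclass
class StabilityReport:
    """Outcome of the triplet-of-consensus stability protocol."""

    method: str
    consensus_triplet: np.ndarray   # (3, n_patients) aligned mode labels
    n_discordant: int
    instability: float
    stable: bool
    final_labels: np.ndarray | None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_discordant": int(self.n_discordant),
            "instability": float(self.instability),
            "stable": bool(self.stable),
            "final_labels": None
            if self.final_labels is None
            else [int(v) for v in self.final_labels],
        }


def _run_once(data, method: str, target_k: int, seed: int, **kwargs) -> np.ndarray:
    if method == "som":
        return train_stack(data, target_k=target_k, seed=seed, **kwargs).final_labels
    if method == "kmeans":
        return kmeans(data, target_k, seed)
    raise ValueError(f"unknown method {method!r}")


def stability_protocol(
    data,
    method: str = "som",
    target_k: int = 2,
    n_reps: int = 100,
    n_triplet: int = 3,
    master_seed: int = 0,
    **run_kwargs,
) -> StabilityReport:
    """Triplet of mode-consensus runs with the <10% discordance rule.

    Repetition r of consensus t uses seed ``master_seed + 1000 * (t+1) + r``,
    so every individual run is independently reproducible.  The three
    consensus vectors are aligned to the first; patients not identically
    labelled across all three count as discordant.  When stable, the final
    labels are the per-patient mode of the aligned triplet.
    """
    consensus = []
    for t in range(n_triplet):
        runs = np.asarray([
            _run_once(data, method, target_k,
                      int(master_seed + 1000 * (t + 1) + r), **run_kwargs)
            for r in range(n_reps)
        ])
        consensus.append(RunEnsemble(method, runs).mode_labels)
    return triplet_stability(consensus, method=method)


def triplet_stability(consensus_vectors, method: str = "som") -> StabilityReport:
    """Aggregate repeated consensus labelings into a stability verdict.

    The vectors are aligned to the first; a patient is discordant when the
    aligned labels are not identical across all repetitions.
    """
    aligned = [np.asarray(consensus_vectors[0])] + [
        align_labels(consensus_vectors[0], c) for c in consensus_vectors[1:]
    ]
    aligned = np.asarray(aligned)
    discord = np.any(aligned != aligned[0], axis=0).sum()
    n = aligned.shape[1]
    instability = discord / n
    stable = bool(instability < STABILITY_THRESHOLD)
    final = consensus_mode(aligned) if stable else None
    return StabilityReport(method, aligned, int(discord), float(instability),
                           stable, final)


def method_overlap(labels_a, labels_b) -> tuple[float, np.ndarray]:
    """Fraction of identically labelled patients after optimal alignment,
    plus the k x k cross-tabulation (rows: a, cols: aligned b)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    b_aligned = align_labels(a, b)
    ids = np.unique(np.concatenate([a, b_aligned]))
    table = np.zeros((len(ids), len(ids)), dtype=int)
    for i, ai in enumerate(ids):
        for j, bj in enumerate(ids):
            table[i, j] = np.sum((a == ai) & (b_aligned == bj))
    return float(np.mean(a == b_aligned)), table
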