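"""Network-level structure of a weighted bipartite network.

Implements connectance, NODF nestedness (binary and weighted variants),
pairwise dependence asymmetry, and mean Horn niche overlap within a guild.
All metrics operate on an :class:`~antplantnet.matrix_io.InteractionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .matrix_io import Guild, InteractionMatrix


@dataclass(frozen=True)
class NetworkMetricsReport:
    """Flat record of the network-level indices."""

    connectance: float
    nodf: float
    wnodf: float
    dependence_asymmetry: float
    niche_overlap_ants: float
    niche_overlap_plants: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def connectance(m: InteractionMatrix) -> float:
    """Realized fraction of all possible plant × ant links: L / (P·A)."""
    return m.n_links / (m.n_plants * m.n_ants)


def _nodf_axis_binary(b: np.ndarray) -> tuple[float, int]:
    """Sum of paired overlap scores over all unordered row pairs of a 0/1 matrix.

    A pair contributes only under decreasing fill: the lower-degree row's
    fraction of partners shared with the strictly higher-degree row, scaled to
    0–100.  Equal-degree pairs contribute 0.
    """
    deg = b.sum(axis=1)
    shared = b @ b.T  # pairwise co-occurrence counts
    n = b.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if deg[i] == deg[j]:
                continue
            lo, hi = (i, j) if deg[i] < deg[j] else (j, i)
            total += 100.0 * shared[lo, hi] / deg[lo]
    return total, n * (n - 1) // 2


def _nodf_axis_weighted(w: np.ndarray) -> tuple[float, int]:
    """Weighted paired-overlap sum over rows.

    Decreasing fill still gates the pair: the member with the strictly
    larger binary degree is "hi" and equal-degree pairs score 0.  The score
    is the percentage of the poorer row's occupied cells whose count is
    positive but strictly below hi's count in the same column.
    """
    deg = (w > 0).sum(axis=1)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if deg[i] == deg[j]:
                continue
            lo, hi = (i, j) if deg[i] < deg[j] else (j, i)
            lo_nonzero = w[lo] > 0
            filled = np.count_nonzero(lo_nonzero & (w[lo] < w[hi]))
            total += 100.0 * filled / deg[lo]
    return total, n * (n - 1) // 2


def nodf(m: InteractionMatrix | np.ndarray, use_weights: bool = False) -> float:
    """NODF nestedness (0–100): paired overlap with decreasing fill.

    Binary mode scores, for each within-guild species pair with unequal
    degrees, the percentage of the poorer species' partners shared with the
    richer one; the weighted variant (WNODF) orders each pair by marginal
    totals and counts the cells where the poorer species' count is positive
    but strictly below the richer one's.  Scores are averaged over all row
    pairs and column pairs together.
    """
    w = m.weights if isinstance(m, InteractionMatrix) else np.asarray(m)
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError("NODF undefined for a single row or column")
    axis_fn = _nodf_axis_weighted if use_weights else _nodf_axis_binary
    mat = w if use_weights else (w > 0).astype(np.int64)
    rows_sum, rows_pairs = axis_fn(mat)
    cols_sum, cols_pairs = axis_fn(mat.T)
    return (rows_sum + cols_sum) / (rows_pairs + cols_pairs)


def dependence_matrix(m: InteractionMatrix, guild: Guild) -> np.ndarray:
    """Fraction of each species' total visits contributed by each partner.

    For the plant guild, row i is plant i's dependence on each ant (rows sum
    to 1); for the ant guild, column j is ant j's dependence on each plant
    (columns sum to 1).
    """
    w = m.weights.astype(float)
    if guild == "plant":
        return w / w.sum(axis=1, keepdims=True)
    return w / w.sum(axis=0, keepdims=True)


def dependence_asymmetry(m: InteractionMatrix) -> float:
    """Mean per-link asymmetry between the two directions of dependence.

    For every realized link, the absolute difference between the plant's
    dependence on the ant and the ant's on the plant, normalized by the
    larger of the two; averaged over all links.  0 means perfectly
    reciprocal dependences.
    """
    dp = dependence_matrix(m, "plant")
    da = dependence_matrix(m, "ant")
    mask = m.weights > 0
    hi = np.maximum(dp[mask], da[mask])
    return float(np.mean(np.abs(dp[mask] - da[mask]) / hi))


def horn_overlap(x: np.ndarray, y: np.ndarray) -> float:
    """Horn's information-theoretic overlap of two use-proportion profiles.

    Computed on the normalized profiles, so it is invariant to rescaling
    either species' counts by a positive constant; ranges 0 (disjoint
    partners) to 1 (identical proportions).
    """
    p = np.asarray(x, dtype=float)
    q = np.asarray(y, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    s = p + q

    def xlogx(v: np.ndarray) -> float:
        nz = v > 0
        return float(np.sum(v[nz] * np.log(v[nz])))

    val = (xlogx(s) - xlogx(p) - xlogx(q)) / (2.0 * np.log(2.0))
    return float(min(max(val, 0.0), 1.0))


def niche_overlap(m: InteractionMatrix, guild: Guild) -> float:
    """Mean Horn overlap over all unordered within-guild species pairs."""
    w = m.weights if guild == "plant" else m.weights.T
    n = w.shape[0]
    if n < 2:
        raise ValueError("niche overlap needs at least two species in the guild")
    vals = [
        horn_overlap(w[i], w[j]) for i in range(n) for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def network_metrics(m: InteractionMatrix) -> NetworkMetricsReport:
    """All network-level indices in one report."""
    return NetworkMetricsReport(
        connectance=connectance(m),
        nodf=nodf(m, use_weights=False),
        wnodf=nodf(m, use_weights=True),
        dependence_asymmetry=dependence_asymmetry(m),
        niche_overlap_ants=niche_overlap(m, "ant"),
        niche_overlap_plants=niche_overlap(m, "plant"),
    )
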