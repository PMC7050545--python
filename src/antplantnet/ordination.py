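"""Non-metric multidimensional scaling of Bray-Curtis dissimilarities and
permutation-based fitting of species attributes onto the ordination.

Plants (rows of the interaction matrix) are the ordinated observations;
ants are placed afterwards at the interaction-weighted average of their
partner plants' coordinates.  The NMDS minimizes Kruskal stress-1 by
alternating monotone (isotonic) regression of configuration distances on
the input dissimilarities with a Guttman configuration update, over several
random starts plus one metric (classical scaling) start.  Attribute fitting
follows the usual post-hoc approach: factors score the between-level spread
of the 2-D scores (r^2 = 1 - SS_within/SS_total), vectors the best linear
fit of the variable on the axes, both with add-one permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .matrix_io import Guild, InteractionMatrix, SpeciesAttributes


@dataclass(frozen=True)
class OrdinationResult:
    """2-D NMDS configuration for both guilds."""

    plant_scores: pd.DataFrame = field(repr=False)
    ant_scores: pd.DataFrame = field(repr=False)
    stress: float = np.nan
    n_starts: int = 0
    best_start_index: int = -1
    converged: bool = False
    stress_trace: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class EnvfitRecord:
    name: str
    kind: Literal["factor", "vector"]
    r2: float
    p_value: float
    n_perm: int
    detail: dict = field(default_factory=dict, repr=False)


def bray_curtis(m: InteractionMatrix | np.ndarray, guild: Guild = "plant") -> np.ndarray:
    """Bray-Curtis dissimilarity between partner-use vectors within a guild.

    d(x, y) = sum|x_k - y_k| / sum(x_k + y_k); joint absences do not
    contribute, which is why this coefficient suits community counts.
    """
    w = m.weights if isinstance(m, InteractionMatrix) else np.asarray(m, dtype=float)
    if guild == "ant":
        w = w.T
    if w.shape[0] < 2:
        raise ValueError("need at least two species in the guild")
    return squareform(pdist(w.astype(float), metric="braycurtis"))


def wisconsin(w: np.ndarray) -> np.ndarray:
    """Wisconsin double standardization: columns by maxima, then rows to sum 1."""
    w = np.asarray(w, dtype=float)
    colmax = w.max(axis=0)
    colmax[colmax == 0] = 1.0
    w = w / colmax
    rowsum = w.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return w / rowsum


def transform_counts(w: np.ndarray, auto: bool = True) -> np.ndarray:
    """Square-root + Wisconsin standardization applied when counts are large.

    Mirrors the common community-ecology auto-transform: raw counts with a
    maximum above 9 are square-rooted and Wisconsin-standardized before
    dissimilarities are computed; set ``auto=False`` to ordinate raw counts.
    """
    w = np.asarray(w, dtype=float)
    if not auto or w.max() <= 9:
        return w
    return wisconsin(np.sqrt(w))


def _stress1(delta: np.ndarray, dhat: np.ndarray) -> float:
    return float(np.sqrt(np.sum((delta - dhat) ** 2) / np.sum(delta**2)))


def _nmds_single(
    d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    """One NMDS start from configuration ``x0``; returns (config, stress, trace).

    Alternates isotonic regression (pool-adjacent-violators, ties averaged)
    of the configuration distances on the dissimilarities with a Guttman
    update using the fitted disparities.  Stops when stress-1 improves by
    less than ``tol``; a step that increases stress is rolled back, so the
    recorded trace is non-increasing.
    """
    n = x0.shape[0]
    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = x0.copy()
    delta = pdist(x)
    trace: list[float] = []
    prev_stress = np.inf
    for _ in range(max_iter):
        # monotone regression of distances on dissimilarity ranks
        dhat = np.empty_like(delta)
        dhat[order] = iso.fit_transform(dvec[order], delta[order])
        stress = _stress1(delta, dhat)
        # rescale disparities for the update step to guard against collapse
        ssq = np.sum(dhat**2)
        if ssq > 0:
            dhat = dhat * np.sqrt(np.sum(delta**2) / ssq)
        if stress > prev_stress + 1e-12:
            break  # roll back: keep previous configuration
        trace.append(stress)
        if prev_stress - stress < tol:
            prev_stress = stress
            x_best = x.copy()
            break
        prev_stress = stress
        x_best = x.copy()
        # Guttman transform
        dh = squareform(dhat)
        dl = squareform(delta)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dl > 0, dh / dl, 0.0)
        bmat = -ratio
        np.fill_diagonal(bmat, ratio.sum(axis=1))
        x = bmat @ x / n
        delta = pdist(x)
    return x_best, prev_stress, trace


def _principal_axes(x: np.ndarray) -> np.ndarray:
    """Center and rotate a configuration onto its principal axes."""
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    rot = x @ vt.T
    # deterministic sign: make the largest-magnitude loading positive per axis
    for k in range(rot.shape[1]):
        idx = np.argmax(np.abs(rot[:, k]))
        if rot[idx, k] < 0:
            rot[:, k] = -rot[:, k]
    return rot


def _classical_mds(d: np.ndarray, n_dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(bmat)
    idx = np.argsort(vals)[::-1][:n_dims]
    lam = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _procrustes_error(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(a, b)
    return float(disparity)


def nmds(
    d: np.ndarray,
    labels: list[str] | tuple[str, ...] | None = None,
    n_dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    rng_seed: int = 0,
) -> OrdinationResult:
    """Best-of-several-starts 2-D NMDS of a dissimilarity matrix.

    Start 0 is the classical-scaling (metric) configuration; the remaining
    starts are random.  The lowest-stress solution is returned centered and
    rotated to principal axes.  Convergence is declared when a second start
    reaches the best solution within Procrustes tolerance 1e-3.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 4:
        raise ValueError("NMDS needs at least 4 objects")
    if labels is None:
        labels = [f"obj{i}" for i in range(n)]
    rng = np.random.default_rng(rng_seed)
    best_x, best_stress, best_idx, best_trace = None, np.inf, -1, []
    solutions = []
    for s in range(n_starts):
        if s == 0:
            x0 = _classical_mds(d, n_dims)
            if np.allclose(x0, 0):
                x0 = rng.standard_normal((n, n_dims))
        else:
            x0 = rng.standard_normal((n, n_dims)) * d[np.triu_indices(n, 1)].mean()
        x, stress, trace = _nmds_single(d, x0, max_iter, tol)
        solutions.append((x, stress))
        if stress < best_stress - 1e-12:
            best_x, best_stress, best_idx, best_trace = x, stress, s, trace
    converged = any(
        i != best_idx
        and abs(st - best_stress) < 1e-3
        and _procrustes_error(best_x, x) < 1e-3
        for i, (x, st) in enumerate(solutions)
    )
    coords = _principal_axes(best_x)
    plant_scores = pd.DataFrame(
        coords, index=list(labels), columns=[f"NMDS{k+1}" for k in range(n_dims)]
    )
    return OrdinationResult(
        plant_scores=plant_scores,
        ant_scores=pd.DataFrame(columns=plant_scores.columns),
        stress=best_stress,
        n_starts=n_starts,
        best_start_index=best_idx,
        converged=converged,
        stress_trace=tuple(best_trace),
    )


def second_guild_scores(m: InteractionMatrix, plant_scores: pd.DataFrame) -> pd.DataFrame:
    """Each ant at the interaction-weight-weighted mean of its plants' coordinates."""
    coords = plant_scores.loc[list(m.plant_labels)].to_numpy()
    w = m.weights.astype(float)
    ant = (w.T @ coords) / w.sum(axis=0)[:, None]
    return pd.DataFrame(ant, index=list(m.ant_labels), columns=plant_scores.columns)


def ordinate(
    m: InteractionMatrix,
    n_starts: int = 20,
    auto_transform: bool = True,
    rng_seed: int = 0,
) -> OrdinationResult:
    """Full ordination workflow: transform, Bray-Curtis on plants, NMDS, ant scores."""
    w = transform_counts(m.weights, auto=auto_transform)
    d = squareform(pdist(w, metric="braycurtis"))
    res = nmds(d, labels=list(m.plant_labels), n_starts=n_starts, rng_seed=rng_seed)
    ants = second_guild_scores(m, res.plant_scores)
    return OrdinationResult(
        plant_scores=res.plant_scores,
        ant_scores=ants,
        stress=res.stress,
        n_starts=res.n_starts,
        best_start_index=res.best_start_index,
        converged=res.converged,
        stress_trace=res.stress_trace,
    )


# -- attribute fitting -------------------------------------------------------


def _factor_r2(scores: np.ndarray, levels: np.ndarray) -> float:
    grand = scores.mean(axis=0)
    ss_total = float(np.sum((scores - grand) ** 2))
    ss_within = 0.0
    for lev in np.unique(levels):
        sub = scores[levels == lev]
        ss_within += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    if ss_total == 0:
        return 0.0
    return 1.0 - ss_within / ss_total


def _vector_r2(scores: np.ndarray, values: np.ndarray) -> tuple[float, np.ndarray]:
    """R^2 of the best linear combination of axes predicting the variable."""
    x = scores - scores.mean(axis=0)
    y = values - values.mean()
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else beta
    return r2, direction


def envfit(
    scores: pd.DataFrame,
    attributes: SpeciesAttributes,
    columns: list[str] | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    drop_levels: dict[str, set[str]] | None = None,
) -> list[EnvfitRecord]:
    """Fit attribute factors and vectors onto ordination scores by permutation.

    Categorical columns are fitted as factors (r^2 from between-level spread
    of the coordinates), numeric columns as vectors (r^2 of the best linear
    combination of axes).  Significance is the add-one fraction of ``n_perm``
    row permutations of the attribute achieving an r^2 at least as large.
    ``drop_levels`` removes listed factor levels (treated as missing) before
    fitting, e.g. the mixed-habitat level when contrasting open vs. shaded.
    """
    table = attributes.aligned_to(list(scores.index))
    if columns is None:
        columns = list(table.columns)
    rng = np.random.default_rng(rng_seed)
    coords_all = scores.to_numpy(dtype=float)
    records: list[EnvfitRecord] = []
    for col in columns:
        series = table[col]
        numeric = pd.api.types.is_numeric_dtype(series)
        mask = series.notna().to_numpy()
        if not numeric and drop_levels and col in drop_levels:
            mask &= ~series.isin(list(drop_levels[col])).to_numpy()
        coords = coords_all[mask]
        vals = series.to_numpy()[mask]
        if numeric:
            vals = vals.astype(float)
            obs_r2, direction = _vector_r2(coords, vals)
            detail = {"direction": tuple(direction)}
        else:
            if len(set(vals)) < 2:
                raise ValueError(f"factor {col!r} has a single level after filtering")
            obs_r2 = _factor_r2(coords, vals)
            detail = {
                "centroids": {
                    str(lev): tuple(coords[vals == lev].mean(axis=0))
                    for lev in np.unique(vals)
                }
            }
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(vals))
            if numeric:
                r2p, _ = _vector_r2(coords, vals[perm])
            else:
                r2p = _factor_r2(coords, vals[perm])
            if r2p >= obs_r2 - 1e-12:
                count += 1
        records.append(
            EnvfitRecord(
                name=col,
                kind="vector" if numeric else "factor",
                r2=obs_r2,
                p_value=(count + 1) / (n_perm + 1),
                n_perm=n_perm,
                detail=detail,
            )
        )
    return records
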