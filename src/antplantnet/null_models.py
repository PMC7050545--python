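"""Degree-proportional Bernoulli null model and Monte-Carlo significance tests.

The null model (often called "Ce", or Null Model II) assigns each cell an
occurrence probability equal to the mean of its row and column fill
fractions of the binarized observed matrix, so the expected fill equals the
observed fill.  Null matrices with empty rows or columns are rejected and
redrawn, keeping network dimensions fixed across the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .matrix_io import InteractionMatrix


@dataclass(frozen=True)
class NullEnsembleResult:
    """Observed statistic vs. a Monte-Carlo null ensemble."""

    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    n_reps: int
    p_value: float
    seed: int
    alternative: str = "greater"
    null_values: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_reps": self.n_reps,
            "p_value": self.p_value,
            "seed": self.seed,
            "alternative": self.alternative,
        }
        return d


def cell_probabilities_nm2(m: InteractionMatrix | np.ndarray) -> np.ndarray:
    """Cell occurrence probabilities p_ij = (k_i/A + k_j/P) / 2 on the binary matrix.

    The mean of these probabilities equals the observed fill L/(P·A) exactly.
    """
    b = m.binary() if isinstance(m, InteractionMatrix) else (np.asarray(m) > 0).astype(int)
    row_fill = b.sum(axis=1) / b.shape[1]
    col_fill = b.sum(axis=0) / b.shape[0]
    return (row_fill[:, None] + col_fill[None, :]) / 2.0


_MAX_RETRIES = 10_000


def sample_null(
    m: InteractionMatrix | np.ndarray,
    rng: np.random.Generator | int,
    reject_degenerate: bool = True,
) -> np.ndarray:
    """One binary null matrix: independent Bernoulli draws at the Ce probabilities.

    Draws containing an all-zero row or column are rejected and redrawn
    (bounded retries) so every null network has the observed dimensions.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = cell_probabilities_nm2(m)
    for _ in range(_MAX_RETRIES):
        draw = (rng.random(p.shape) < p).astype(np.int64)
        if not reject_degenerate:
            return draw
        if draw.sum(axis=1).all() and draw.sum(axis=0).all():
            return draw
    raise RuntimeError(
        "could not draw a null matrix without empty rows/columns in "
        f"{_MAX_RETRIES} attempts; the matrix may be too sparse"
    )


def null_test(
    m: InteractionMatrix,
    statistic: Callable[[np.ndarray], float],
    statistic_name: str = "statistic",
    n_reps: int = 1000,
    rng_seed: int = 0,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
    keep_null_values: bool = False,
) -> NullEnsembleResult:
    """Monte-Carlo significance of a scalar statistic under the Ce null model.

    The statistic must be defined on a binary 0/1 matrix.  The p-value uses
    the add-one convention (#{null at least as extreme} + 1) / (n_reps + 1),
    so it is never exactly zero.  Replicate seeds are spawned deterministically
    from ``rng_seed`` so the ensemble is reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    observed = float(statistic(m.binary()))
    children = np.random.SeedSequence(rng_seed).spawn(n_reps)
    nulls = np.empty(n_reps)
    for r, child in enumerate(children):
        nulls[r] = statistic(sample_null(m, np.random.default_rng(child)))
    if alternative == "greater":
        extreme = int(np.sum(nulls >= observed))
    elif alternative == "less":
        extreme = int(np.sum(nulls <= observed))
    else:
        centered = np.abs(nulls - nulls.mean())
        extreme = int(np.sum(centered >= abs(observed - nulls.mean())))
    return NullEnsembleResult(
        statistic=statistic_name,
        observed=observed,
        null_mean=float(nulls.mean()),
        null_sd=float(nulls.std(ddof=1)) if n_reps > 1 else 0.0,
        n_reps=n_reps,
        p_value=(extreme + 1) / (n_reps + 1),
        seed=rng_seed,
        alternative=alternative,
        null_values=tuple(nulls) if keep_null_values else (),
    )
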