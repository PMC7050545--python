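"""Bipartite (Barber) modularity: scoring, simulated-annealing search, oracle.

Modularity Q_B measures the excess of within-module links over a
degree-preserving random expectation, summed over plant–ant pairs sharing a
module, on the binarized network:

    Q_B = (1/F) * sum_{i,j} (B_ij - k_i d_j / F) * [g_i == g_j]

with F total links, k_i/d_j binary degrees and g the module assignment.
The optimizer uses single-species relocation moves (to an existing or a
fresh module) under a geometric cooling schedule, followed by a greedy
polish, keeping the best partition ever visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix_io import InteractionMatrix
from .null_models import NullEnsembleResult, sample_null


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule. ``steps_per_t=None`` means 2*(P+A)^2."""

    t0: float = 1.0
    cooling: float = 0.95
    steps_per_t: int | None = None
    t_min: float = 1e-4
    n_restarts: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling must be in (0, 1)")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.t_min <= 0 or self.t_min >= self.t0:
            raise ValueError("t_min must satisfy 0 < t_min < t0")


#: Reduced budget used when re-optimizing many null replicates.
FAST_SA = SAConfig(t0=0.25, cooling=0.85, steps_per_t=600, t_min=1e-3, n_restarts=1)


@dataclass(frozen=True)
class ModulePartition:
    """Module assignment for every species, with its Q_B score."""

    module_of: dict[str, int]
    n_modules: int
    qb: float
    anneal_trace: tuple[tuple[float, float], ...] = field(default=(), repr=False)


def _as_module_arrays(
    m: InteractionMatrix, partition: Mapping[str, int] | Sequence[int]
) -> np.ndarray:
    """Module id per node, plants first then ants, validated for coverage."""
    n = m.n_plants + m.n_ants
    if isinstance(partition, Mapping):
        out = np.empty(n, dtype=np.int64)
        for idx, lab in enumerate(m.plant_labels + m.ant_labels):
            if lab not in partition:
                raise ValueError(f"species missing from module assignment: {lab!r}")
            out[idx] = partition[lab]
        return out
    arr = np.asarray(partition, dtype=np.int64)
    if arr.shape != (n,):
        raise ValueError(f"partition must assign all {n} species")
    return arr


def qb_score(m: InteractionMatrix, partition: Mapping[str, int] | Sequence[int]) -> float:
    """Barber modularity of a given module assignment on the binarized matrix."""
    g = _as_module_arrays(m, partition)
    b = m.binary()
    f = b.sum()
    gp = g[: m.n_plants]
    ga = g[m.n_plants :]
    same = gp[:, None] == ga[None, :]
    k = b.sum(axis=1).astype(float)
    d = b.sum(axis=0).astype(float)
    expected = np.outer(k, d) / f
    return float(((b - expected) * same).sum() / f)


def _qb_from_aggregates(e_in: float, kd_in: float, f: int) -> float:
    return (e_in - kd_in / f) / f


class _State:
    """Mutable partition state with O(degree) move evaluation.

    Per module m it tracks E_m (within-module links), K_m (plant degree sum)
    and D_m (ant degree sum); Q_B = (1/F) * sum_m (E_m - K_m * D_m / F).
    """

    def __init__(self, b: np.ndarray, modules: np.ndarray):
        self.P, self.A = b.shape
        self.n = self.P + self.A
        self.f = int(b.sum())
        self.kdeg = b.sum(axis=1)
        self.adeg = b.sum(axis=0)
        # adjacency: for node u, list of opposite-guild node indices
        self.neigh: list[np.ndarray] = [np.flatnonzero(b[i]) + self.P for i in range(self.P)]
        self.neigh += [np.flatnonzero(b[:, j]) for j in range(self.A)]
        self.deg = np.concatenate([self.kdeg, self.adeg])
        self.g = modules.copy()
        nmod = int(self.g.max()) + 1
        self.E = [0.0] * (nmod + 1)
        self.K = [0.0] * (nmod + 1)
        self.D = [0.0] * (nmod + 1)
        for i in range(self.P):
            self.K[self.g[i]] += self.kdeg[i]
        for j in range(self.A):
            self.D[self.g[self.P + j]] += self.adeg[j]
        for i in range(self.P):
            gi = self.g[i]
            for u in self.neigh[i]:
                if self.g[u] == gi:
                    self.E[gi] += 1

    def qb(self) -> float:
        f = self.f
        return sum(e - k * d / f for e, k, d in zip(self.E, self.K, self.D)) / f

    def links_to(self, u: int, mod_a: int, mod_b: int) -> tuple[int, int]:
        la = lb = 0
        g = self.g
        for v in self.neigh[u]:
            gv = g[v]
            if gv == mod_a:
                la += 1
            elif gv == mod_b:
                lb += 1
        return la, lb

    def delta(self, u: int, target: int) -> float:
        """Change in Q_B from moving node u to module ``target``."""
        cur = self.g[u]
        if target == cur:
            return 0.0
        la, lb = self.links_to(u, cur, target)
        f = self.f
        if u < self.P:
            other_a, other_b = self.D[cur], self.D[target]
        else:
            other_a, other_b = self.K[cur], self.K[target]
        du = self.deg[u]
        return ((lb - la) - du * (other_b - other_a) / f) / f

    def move(self, u: int, target: int) -> None:
        cur = self.g[u]
        la, lb = self.links_to(u, cur, target)
        self.E[cur] -= la
        self.E[target] += lb
        if u < self.P:
            self.K[cur] -= self.deg[u]
            self.K[target] += self.deg[u]
        else:
            self.D[cur] -= self.deg[u]
            self.D[target] += self.deg[u]
        self.g[u] = target

    def ensure_spare(self) -> int:
        """Index of an empty module, growing the bookkeeping if needed."""
        for mod, (e, k, d) in enumerate(zip(self.E, self.K, self.D)):
            if k == 0 and d == 0:
                return mod
        self.E.append(0.0)
        self.K.append(0.0)
        self.D.append(0.0)
        return len(self.E) - 1


def _greedy_polish(st: _State) -> None:
    """Sweep best single-node relocations until no move improves Q_B."""
    improved = True
    while improved:
        improved = False
        for u in range(st.n):
            spare = st.ensure_spare()
            candidates = {st.g[v] for v in st.neigh[u]}
            candidates.add(spare)
            best_mod, best_gain = st.g[u], 1e-12
            for mod in candidates:
                gain = st.delta(u, mod)
                if gain > best_gain:
                    best_mod, best_gain = mod, gain
            if best_mod != st.g[u]:
                st.move(u, best_mod)
                improved = True


def _compact(modules: np.ndarray) -> tuple[np.ndarray, int]:
    uniq = {}
    out = np.empty_like(modules)
    for idx, mod in enumerate(modules):
        out[idx] = uniq.setdefault(int(mod), len(uniq))
    return out, len(uniq)


def optimize_sa(
    m: InteractionMatrix,
    config: SAConfig = SAConfig(),
    rng_seed: int = 0,
) -> ModulePartition:
    """Maximize Q_B by simulated annealing over species-to-module assignments.

    Each restart anneals single-relocation moves (worsening moves accepted
    with probability exp(dQ/T)) under geometric cooling, then applies a
    greedy polish; the best partition across restarts is returned with empty
    modules compacted and a per-temperature trace of the best score so far.
    """
    if m.n_plants < 2 or m.n_ants < 2:
        raise ValueError("modularity optimization needs at least a 2x2 matrix")
    b = m.binary()
    n = m.n_plants + m.n_ants
    steps = config.steps_per_t if config.steps_per_t is not None else 2 * n * n
    root = np.random.SeedSequence(rng_seed)
    best_g: np.ndarray | None = None
    best_q = -np.inf
    trace: list[tuple[float, float]] = []
    for child in root.spawn(config.n_restarts):
        rng = np.random.default_rng(child)
        st = _State(b, np.arange(n))  # every species starts in its own module
        cur_q = st.qb()
        run_best_q, run_best_g = cur_q, st.g.copy()
        t = config.t0
        while t > config.t_min:
            for _ in range(steps):
                u = int(rng.integers(n))
                spare = st.ensure_spare()
                nmod = len(st.E)
                target = int(rng.integers(nmod))
                if target == st.g[u]:
                    target = spare
                dq = st.delta(u, target)
                if dq > 0 or rng.random() < np.exp(dq / t):
                    st.move(u, target)
                    cur_q += dq
                    if cur_q > run_best_q:
                        run_best_q, run_best_g = cur_q, st.g.copy()
            trace.append((float(t), float(max(run_best_q, best_q))))
            t *= config.cooling
        st = _State(b, run_best_g)
        _greedy_polish(st)
        polished_q = st.qb()
        if polished_q > run_best_q:
            run_best_q, run_best_g = polished_q, st.g.copy()
        if run_best_q > best_q:
            best_q, best_g = run_best_q, run_best_g
    assert best_g is not None
    compacted, nmod = _compact(best_g)
    labels = m.plant_labels + m.ant_labels
    module_of = {lab: int(compacted[i]) for i, lab in enumerate(labels)}
    exact_q = qb_score(m, compacted)  # recompute: incremental sums drift is bounded but nonzero
    return ModulePartition(
        module_of=module_of, n_modules=nmod, qb=exact_q, anneal_trace=tuple(trace)
    )


def brute_force_qb(m: InteractionMatrix) -> ModulePartition:
    """Exact Q_B optimum by exhaustive search over all set partitions.

    Only feasible for tiny networks (at most 10 species); used as the test
    oracle for the annealer.
    """
    n = m.n_plants + m.n_ants
    if n > 10:
        raise ValueError("brute force limited to 10 species")
    best_q = -np.inf
    best: np.ndarray | None = None
    # enumerate restricted growth strings
    a = np.zeros(n, dtype=np.int64)

    def rec(i: int, maxm: int) -> None:
        nonlocal best_q, best
        if i == n:
            q = qb_score(m, a)
            if q > best_q + 1e-15:
                best_q, best = q, a.copy()
            return
        for mod in range(maxm + 2):
            a[i] = mod
            rec(i + 1, max(maxm, mod))

    a[0] = 0
    rec(1, 0)
    assert best is not None
    compacted, nmod = _compact(best)
    labels = m.plant_labels + m.ant_labels
    return ModulePartition(
        module_of={lab: int(compacted[i]) for i, lab in enumerate(labels)},
        n_modules=nmod,
        qb=float(best_q),
    )


def modularity_significance(
    m: InteractionMatrix,
    n_reps: int = 1000,
    rng_seed: int = 0,
    sa_config: SAConfig = SAConfig(),
    null_sa_config: SAConfig = FAST_SA,
) -> tuple[ModulePartition, NullEnsembleResult]:
    """Observed optimized Q_B versus Q_B of re-optimized Ce null matrices.

    Each null replicate is drawn from the degree-proportional Bernoulli null
    and re-optimized with a reduced annealing budget; the add-one p-value is
    one-sided (greater).
    """
    from .matrix_io import InteractionMatrix as IM

    root = np.random.SeedSequence(rng_seed)
    obs_seed, *rep_seeds = root.spawn(n_reps + 1)
    observed = optimize_sa(m, sa_config, rng_seed=int(obs_seed.generate_state(1)[0] % 2**31))
    nulls = np.empty(n_reps)
    for r, child in enumerate(rep_seeds):
        rng = np.random.default_rng(child)
        nb = sample_null(m, rng)
        nm = IM(
            plant_labels=tuple(f"p{i}" for i in range(nb.shape[0])),
            ant_labels=tuple(f"a{j}" for j in range(nb.shape[1])),
            weights=nb,
        )
        part = optimize_sa(
            nm, null_sa_config, rng_seed=int(child.generate_state(1)[0] % 2**31)
        )
        nulls[r] = part.qb
    p = (int(np.sum(nulls >= observed.qb)) + 1) / (n_reps + 1)
    result = NullEnsembleResult(
        statistic="qb",
        observed=observed.qb,
        null_mean=float(nulls.mean()),
        null_sd=float(nulls.std(ddof=1)) if n_reps > 1 else 0.0,
        n_reps=n_reps,
        p_value=p,
        seed=rng_seed,
    )
    return observed, result
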