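"""Species-level ("fine-grain") metrics and core–periphery classification.

Per-species quantities: binary degree, species strength (the summed
dependence of the opposite guild on the species), the d' specialization
index (standardized Kullback–Leibler divergence of partner use from partner
availability), and the standardized-degree core/periphery score Gc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import Guild, InteractionMatrix
from .network_metrics import dependence_matrix


@dataclass(frozen=True)
class SpeciesMetricsReport:
    """Per-species metric table for both guilds."""

    table: pd.DataFrame = field(repr=False)  # species, guild, degree, strength, dprime, gc, core

    def core_species(self, guild: Guild) -> list[str]:
        t = self.table
        sel = t[(t["guild"] == guild) & t["core"]]
        return list(sel.index)


def degrees(m: InteractionMatrix, guild: Guild) -> np.ndarray:
    """Binary degree (number of partner species) per species of the guild."""
    b = m.binary()
    return b.sum(axis=1) if guild == "plant" else b.sum(axis=0)


def species_strength(m: InteractionMatrix, guild: Guild) -> np.ndarray:
    """Sum over a species' partners of their dependence on it.

    Strength of an ant is the summed dependences of the plants it visits;
    strengths over one guild always total the size of the opposite guild.
    """
    if guild == "ant":
        return dependence_matrix(m, "plant").sum(axis=0)
    return dependence_matrix(m, "ant").sum(axis=1)


def _kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def _d_extremes(total: int, partner_totals: np.ndarray, grand_total: int) -> tuple[float, float]:
    """Integer-allocation extremes of the raw specialization d for one species.

    ``d_min``: the species' integer visit total is spread over partners as
    proportionally to availability as integers allow (largest-remainder
    rounding).  ``d_max``: visits are packed greedily into the scarcest
    partners first, each up to that partner's marginal total.
    """
    q = partner_totals / grand_total
    # d_min: proportional allocation with largest-remainder integer rounding
    ideal = total * q
    base = np.floor(ideal).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(ideal - base))
        base[order[:short]] += 1
    p_min = base[base > 0] / total
    d_min = _kl_divergence(p_min, q[base > 0])
    # d_max: fill the rarest partners first, bounded by their marginal totals
    alloc = np.zeros_like(partner_totals)
    remaining = total
    for j in np.argsort(partner_totals):
        take = min(remaining, int(partner_totals[j]))
        alloc[j] = take
        remaining -= take
        if remaining == 0:
            break
    if remaining > 0:  # totals cannot absorb everything; dump on the rarest
        alloc[np.argmin(partner_totals)] += remaining
    p_max = alloc[alloc > 0] / total
    d_max = _kl_divergence(p_max, q[alloc > 0])
    return d_min, d_max


def dprime(m: InteractionMatrix, guild: Guild) -> np.ndarray:
    """Standardized specialization d' in [0, 1] per species of the guild.

    The raw index is the Kullback–Leibler divergence of the species' partner
    use proportions from partner availability (partner marginal totals over
    the grand total).  It is standardized between the integer-allocation
    minimum and maximum achievable for the species' observed visit total, so
    0 means partner use proportional to availability and 1 maximal
    selectiveness.  Invariant to multiplying the whole matrix by a positive
    integer.
    """
    w = m.weights if guild == "plant" else m.weights.T
    grand = int(w.sum())
    partner_totals = w.sum(axis=0)
    out = np.zeros(w.shape[0])
    q = partner_totals / grand
    for i in range(w.shape[0]):
        total = int(w[i].sum())
        p = w[i] / total
        d_raw = _kl_divergence(p[p > 0], q[p > 0])
        d_min, d_max = _d_extremes(total, partner_totals, grand)
        if d_max <= d_min:
            out[i] = 0.0
        else:
            out[i] = min(max((d_raw - d_min) / (d_max - d_min), 0.0), 1.0)
    return out


def core_periphery(
    m: InteractionMatrix, guild: Guild, sample_sd: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Standardized degree Gc per species and the core set (Gc >= 1).

    Gc_i = (k_i - mean k) / sd k over binary degrees within the guild; species
    at least one standard deviation above the guild mean form the generalist
    core.  The sample standard deviation (n-1) is the default.
    """
    k = degrees(m, guild).astype(float)
    sd = k.std(ddof=1 if sample_sd else 0)
    if sd == 0:
        raise ValueError("core/periphery undefined: zero degree variance")
    gc = (k - k.mean()) / sd
    labels = m.plant_labels if guild == "plant" else m.ant_labels
    core = [labels[i] for i in range(len(labels)) if gc[i] >= 1.0]
    return gc, core


def species_metrics(m: InteractionMatrix) -> SpeciesMetricsReport:
    """Full per-species table for both guilds."""
    frames = []
    for guild, labels in (("plant", m.plant_labels), ("ant", m.ant_labels)):
        gc, _ = core_periphery(m, guild)  # may raise on degenerate guilds
        frames.append(
            pd.DataFrame(
                {
                    "guild": guild,
                    "degree": degrees(m, guild),
                    "strength": species_strength(m, guild),
                    "dprime": dprime(m, guild),
                    "gc": gc,
                    "core": gc >= 1.0,
                },
                index=list(labels),
            )
        )
    table = pd.concat(frames)
    table.index.name = "species"
    return SpeciesMetricsReport(table=table)
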