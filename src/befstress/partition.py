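"""Additive tripartite partitioning of the net biodiversity effect.

The net biodiversity effect of a mixture is the deviation of its total
yield from the yield expected under the null hypothesis that inter- and
intraspecific competition are equal, in which case each species realises
its initial proportion (the expected relative yield RY_E) of its
monoculture yield M:

    dY = sum_i Y_i - sum_i RY_E_i * M_i

With observed relative yields RY_O_i = Y_i / M_i and their total
RYT_O = sum_i RY_O_i, the deviation splits additively into three parts:

    dominance                 = n * cov(M, RY_O/RYT_O - RY_E)
    trait-dependent compl.    = n * cov(M, RY_O - RY_O/RYT_O)
    trait-independent compl.  = n * mean(RY_O - RY_E) * mean(M)

using the population (divide-by-n) covariance; the three components sum
to dY exactly.  Dominance captures zero-sum competitive replacement
(species trading shares of the relative yield total), trait-dependent
complementarity captures non-zero-sum deviations that correlate with
monoculture yield, and trait-independent complementarity the average
deviation irrespective of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PartitionResult",
    "tripartite_partition",
    "stress_change",
    "partition_table",
    "stress_change_table",
]


@dataclass(frozen=True)
class PartitionResult:
    """Net biodiversity effect and its three additive components (biovolume units)."""

    delta_y: float
    dominance: float
    trait_dependent: float
    trait_independent: float
    ry_o: np.ndarray = None
    ryt_o: float = float("nan")
    delta_ry: np.ndarray = None
    assemblage: str | None = None
    day: int | None = None
    stress: float | None = None
    flagged: bool = False

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.dominance, self.trait_dependent, self.trait_independent)


def _pop_cov(x: np.ndarray, y: np.ndarray) -> float:
    """Population (1/n) covariance, the form under which the partition is additive."""
    return float(np.mean((x - x.mean()) * (y - y.mean())))


def tripartite_partition(
    M, Y, ry_e=None, *, assemblage=None, day=None, stress=None, flagged=False
) -> PartitionResult:
    """Partition the net biodiversity effect of one mixture.

    Parameters
    ----------
    M : array
        Monoculture yields of the member species (must be > 0), matched
        to the mixture's day and stress level.
    Y : array
        Observed per-species yields in the mixture (>= 0).
    ry_e : array, optional
        Expected relative yields (initial proportions); defaults to 1/n,
        matching equal-biovolume inoculation.  Must sum to 1.

    Returns
    -------
    PartitionResult
        dY and the dominance / trait-dependent / trait-independent
        components, which sum to dY.
    """
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = M.size
    if n == 0:
        raise ValueError("empty mixture")
    if Y.size != n:
        raise ValueError("M and Y must have the same length")
    if np.any(M <= 0):
        raise ValueError("monoculture yields must be positive (undefined relative yield)")
    if np.any(Y < 0):
        raise ValueError("mixture yields must be non-negative")
    if ry_e is None:
        ry_e = np.full(n, 1.0 / n)
    else:
        ry_e = np.asarray(ry_e, dtype=float)
        if abs(ry_e.sum() - 1.0) > 1e-8:
            raise ValueError("expected relative yields must sum to 1")

    ry_o = Y / M
    ryt_o = float(ry_o.sum())
    if ryt_o == 0.0:
        raise ValueError("degenerate mixture: all species extinct (RYT_O = 0)")
    delta_ry = ry_o - ry_e

    delta_y = float(Y.sum() - (ry_e * M).sum())
    zero_sum_share = ry_o / ryt_o
    dominance = n * _pop_cov(M, zero_sum_share - ry_e)
    trait_dep = n * _pop_cov(M, ry_o - zero_sum_share)
    trait_indep = n * float(delta_ry.mean()) * float(M.mean())

    return PartitionResult(
        delta_y=delta_y,
        dominance=dominance,
        trait_dependent=trait_dep,
        trait_independent=trait_indep,
        ry_o=ry_o,
        ryt_o=ryt_o,
        delta_ry=delta_ry,
        assemblage=assemblage,
        day=day,
        stress=stress,
        flagged=flagged,
    )


def stress_change(control: PartitionResult, stressed: PartitionResult) -> dict:
    """Componentwise stress-induced change (stressed minus control).

    Both results must describe the same assemblage and day.
    """
    if control.assemblage != stressed.assemblage or control.day != stressed.day:
        raise ValueError(
            f"mismatched partition pair: {control.assemblage}/{control.day} vs "
            f"{stressed.assemblage}/{stressed.day}"
        )
    return {
        "delta_dominance": stressed.dominance - control.dominance,
        "delta_trait_dependent": stressed.trait_dependent - control.trait_dependent,
        "delta_trait_independent": stressed.trait_independent - control.trait_independent,
        "delta_delta_y": stressed.delta_y - control.delta_y,
    }


def partition_table(
    data: pd.DataFrame,
    design,
    monoculture_floor: float = 1.0,
) -> pd.DataFrame:
    """Partition every mixed community at every (day, stress) in a density table.

    Monoculture yields M_i(c, day) are replicate means of the matching
    richness-1 assemblage; mixture yields Y_i are replicate means of the
    mixed assemblage.  Monocultures that collapsed below
    ``monoculture_floor`` are floored and the community flagged.

    Returns one row per (assemblage, day, stress) with dY and the three
    components.
    """
    means = (
        data.groupby(["assemblage", "stress", "day", "species"])["biovolume"]
        .mean()
        .reset_index()
    )
    mono_ids = {sp: design.monoculture_id(sp) for sp in design.species_pool}
    mono = means[means["assemblage"].isin([m for m in mono_ids.values() if m])]
    mono_yield = {
        (row.species, row.stress, row.day): row.biovolume
        for row in mono.itertuples()
    }
    rows = []
    for aid in design.mixed_assemblages():
        members = design.assemblages[aid]
        sub = means[means["assemblage"] == aid]
        for (stress, day), grp in sub.groupby(["stress", "day"]):
            y = grp.set_index("species")["biovolume"]
            M, Y, flagged = [], [], False
            ok = True
            for sp in members:
                key = (sp, stress, day)
                if key not in mono_yield or sp not in y.index:
                    ok = False
                    break
                m_val = mono_yield[key]
                if m_val < monoculture_floor:
                    m_val = monoculture_floor
                    flagged = True
                M.append(m_val)
                Y.append(y[sp])
            if not ok:
                continue
            res = tripartite_partition(
                M, Y, assemblage=aid, day=int(day), stress=float(stress),
                flagged=flagged,
            )
            rows.append(
                {
                    "assemblage": aid,
                    "richness": len(members),
                    "stress": float(stress),
                    "day": int(day),
                    "delta_y": res.delta_y,
                    "dominance": res.dominance,
                    "trait_dependent": res.trait_dependent,
                    "trait_independent": res.trait_independent,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def stress_change_table(partitions: pd.DataFrame, control: float = 0.0) -> pd.DataFrame:
    """Per-component stress-induced changes relative to the control level.

    One row per (assemblage, day, stress level != control).
    """
    ctrl = partitions[partitions["stress"] == control].set_index(["assemblage", "day"])
    rows = []
    for stress, grp in partitions[partitions["stress"] != control].groupby("stress"):
        for row in grp.itertuples():
            key = (row.assemblage, row.day)
            if key not in ctrl.index:
                continue
            c = ctrl.loc[key]
            rows.append(
                {
                    "assemblage": row.assemblage,
                    "richness": row.richness,
                    "stress": float(stress),
                    "day": row.day,
                    "delta_dominance": row.dominance - c["dominance"],
                    "delta_trait_dependent": row.trait_dependent - c["trait_dependent"],
                    "delta_trait_independent": row.trait_independent
                    - c["trait_independent"],
                    "delta_delta_y": row.delta_y - c["delta_y"],
                }
            )
    return pd.DataFrame(rows)
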