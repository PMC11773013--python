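"""Sørensen beta-diversity partitioned into turnover and nestedness.

Total compositional dissimilarity (Sørensen) decomposes additively into a
species-replacement component (Simpson dissimilarity, "turnover") and a
richness-difference component ("nestedness-resultant dissimilarity"):
beta_sor = beta_sim + beta_sne, pairwise and across multiple sites
(Baselga's multiple-site formulas).  Presence/absence only.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import AbstractSet

from .inventory import CommunityMatrix

__all__ = ["BetaPartition", "pairwise_beta", "multisite_beta"]


@dataclass(frozen=True)
class BetaPartition:
    """Additive decomposition total = turnover + nestedness, each in [0, 1]."""

    total: float
    turnover: float
    nestedness: float

    def __post_init__(self) -> None:
        if abs(self.total - (self.turnover + self.nestedness)) > 1e-12:
            raise ValueError("partition identity violated")
        for v in (self.total, self.turnover, self.nestedness):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError("beta components must lie in [0, 1]")


def pairwise_beta(
    presence_i: AbstractSet[str], presence_j: AbstractSet[str]
) -> BetaPartition:
    """Pairwise Sørensen dissimilarity and its partition.

    With ``a`` shared species and ``b``, ``c`` exclusive species counts:
    ``beta_sor = (b + c) / (2a + b + c)``,
    ``beta_sim = min(b, c) / (a + min(b, c))``,
    ``beta_sne = beta_sor - beta_sim``.
    """
    si, sj = set(presence_i), set(presence_j)
    if not si and not sj:
        raise ValueError("beta diversity undefined for two empty assemblages")
    a = len(si & sj)
    b = len(si - sj)
    c = len(sj - si)
    total = (b + c) / (2 * a + b + c)
    m = min(b, c)
    turnover = m / (a + m) if (a + m) > 0 else 0.0
    return BetaPartition(total, turnover, total - turnover)


def multisite_beta(matrix: CommunityMatrix) -> BetaPartition:
    """Multiple-site Sørensen dissimilarity partition over all sites.

    With site richnesses ``S_i``, pooled richness ``S_T`` and pairwise
    exclusive counts ``b_ij = |X_i \\ X_j|``:

        beta_SIM = sum min(b_ij, b_ji) / [(sum S_i - S_T) + sum min]
        beta_SOR = [sum min + sum max] /
                   [2 (sum S_i - S_T) + sum min + sum max]
        beta_SNE = beta_SOR - beta_SIM

    For exactly two sites this reduces to :func:`pairwise_beta`.
    """
    pres = matrix.presence()
    if len(pres.sites) < 2:
        raise ValueError("multisite beta requires at least two sites")
    sets = [pres.site_set(s) for s in pres.sites]
    for label, s in zip(pres.sites, sets):
        if not s:
            raise ValueError(f"site {label!r} holds no species")

    sum_Si = sum(len(s) for s in sets)
    S_T = len(frozenset().union(*sets))
    shared_deficit = sum_Si - S_T  # sum of pairwise-overlap "a" mass
    sum_min = 0
    sum_max = 0
    for si, sj in combinations(sets, 2):
        b_ij = len(si - sj)
        b_ji = len(sj - si)
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)

    turnover = sum_min / (shared_deficit + sum_min) if (shared_deficit + sum_min) else 0.0
    denom = 2 * shared_deficit + sum_min + sum_max
    total = (sum_min + sum_max) / denom if denom else 0.0
    return BetaPartition(total, turnover, total - turnover)
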