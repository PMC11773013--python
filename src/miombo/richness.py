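"""Nonparametric species-richness estimation from abundance data.

Implements the bias-corrected Chao1 estimator and the abundance-based
coverage estimator (ACE).  Both extrapolate total richness from the
frequency-of-frequencies of a sample: Chao1 from the singleton/doubleton
counts, ACE from sample coverage among rare species (abundance <= a
cutoff, conventionally 10).
"""
from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["FrequencyCounts", "RichnessEstimate", "frequency_counts", "chao1", "ace"]


@dataclass(frozen=True)
class FrequencyCounts:
    """Frequency-of-frequencies summary of an abundance vector.

    ``f[i]`` is the number of species observed exactly ``i`` times;
    ``S_obs`` the observed richness; ``N`` the total individuals.
    """

    f: dict[int, int]
    S_obs: int
    N: int

    def __post_init__(self) -> None:
        if sum(self.f.values()) != self.S_obs:
            raise ValueError("sum of f_i must equal S_obs")
        if sum(i * fi for i, fi in self.f.items()) != self.N:
            raise ValueError("sum of i * f_i must equal N")

    def __getitem__(self, i: int) -> int:
        return self.f.get(i, 0)


@dataclass(frozen=True)
class RichnessEstimate:
    estimator: str
    estimate: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.se is not None and self.se < 0:
            raise ValueError("standard error must be non-negative")


def frequency_counts(abundances: Sequence[int] | Iterable[int]) -> FrequencyCounts:
    counts = [int(a) for a in abundances]
    if not counts:
        raise ValueError("abundance vector is empty")
    if any(a < 1 for a in counts):
        raise ValueError("abundances must be >= 1 (drop absent species)")
    if any(a != b for a, b in zip(counts, (float(x) for x in abundances))):
        raise ValueError("abundances must be integers")
    f = dict(Counter(counts))
    return FrequencyCounts(f=f, S_obs=len(counts), N=sum(counts))


def chao1(abundances: Sequence[int]) -> RichnessEstimate:
    """Bias-corrected Chao1 richness estimate with its standard error.

    Point estimate ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))``; the SE is the
    square root of the standard bias-corrected variance companion formula.
    With no singletons the correction vanishes and the estimate equals the
    observed richness.
    """
    fc = frequency_counts(abundances)
    f1, f2 = fc[1], fc[2]
    correction = f1 * (f1 - 1) / (2 * (f2 + 1))
    estimate = fc.S_obs + correction
    var = (
        f1 * (f1 - 1) / (2 * (f2 + 1))
        + f1 * (2 * f1 - 1) ** 2 / (4 * (f2 + 1) ** 2)
        + f1**2 * f2 * (f1 - 1) ** 2 / (4 * (f2 + 1) ** 4)
    )
    return RichnessEstimate("chao1", float(estimate), math.sqrt(max(var, 0.0)))


def ace(abundances: Sequence[int], rare_cutoff: int = 10) -> RichnessEstimate:
    """Abundance-based coverage estimator of species richness.

    Species with abundance <= ``rare_cutoff`` form the rare group from
    which sample coverage ``C = 1 - f1 / N_rare`` and the squared
    coefficient of variation of rare-species abundances are estimated:

        S_ace = S_abund + S_rare / C + (f1 / C) * gamma^2

    Degenerate rare groups (all singletons, C = 0) fall back to Chao1 with
    a warning, as is conventional; the estimate is clamped below at the
    observed richness.  No SE is reported.
    """
    fc = frequency_counts(abundances)
    arr = np.asarray([int(a) for a in abundances])
    rare = arr[arr <= rare_cutoff]
    S_abund = int((arr > rare_cutoff).sum())
    S_rare = int(rare.size)
    if S_rare == 0:
        return RichnessEstimate("ace", float(S_abund), None)
    N_rare = int(rare.sum())
    f1 = fc[1]
    C = 1.0 - f1 / N_rare
    if C == 0.0 or N_rare <= 1:
        warnings.warn(
            "ACE coverage is zero (all rare species are singletons); "
            "falling back to Chao1",
            RuntimeWarning,
            stacklevel=2,
        )
        est = chao1(abundances)
        return RichnessEstimate("ace(chao1 fallback)", est.estimate, est.se)
    sum_i = sum(i * (i - 1) * fi for i, fi in fc.f.items() if i <= rare_cutoff)
    gamma2 = max((S_rare / C) * sum_i / (N_rare * (N_rare - 1)) - 1.0, 0.0)
    estimate = S_abund + S_rare / C + (f1 / C) * gamma2
    return RichnessEstimate("ace", float(max(estimate, fc.S_obs)), None)
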