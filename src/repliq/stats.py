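"""Significance machinery for probe-resolution copy-number claims.

Adjacent ddPCR probes measured in technical replicates are compared by
one-way ANOVA followed by Tukey's honestly-significant-difference test
(Tukey-Kramer for unequal replicate counts). From the pairwise results the
number of statistically distinguishable copy-number states along a probe
panel is counted, and a Monte-Carlo power analysis inverts the question:
given the measurement CV, what copy-number difference is detectable?
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "ReplicateTable",
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "significance_stars",
    "count_significant_states",
    "theoretical_states",
    "min_detectable_difference",
]


@dataclass(frozen=True)
class ReplicateTable:
    """Replicate measurements per probe (concentrations or copy numbers)."""

    groups: Mapping[str, Sequence[float]]
    units: str = "copies/ul"

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError(f"need >=2 groups, got {len(self.groups)}")
        for name, vals in self.groups.items():
            if len(vals) < 2:
                raise ValueError(f"group {name!r} has {len(vals)} replicate(s); need >=2")

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def one_way_anova(table: ReplicateTable) -> AnovaResult:
    """Classical one-way between/within variance decomposition.

    The fully degenerate case (all groups identical constants, zero
    between- and within-group variance) is reported as F = 0, p = 1 rather
    than NaN.
    """
    groups = list(table.arrays().values())
    n_total = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        return AnovaResult(0.0, 1.0, df_b, df_w)
    if ss_within == 0.0:
        return AnovaResult(float("inf"), 0.0, df_b, df_w)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(_st.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <=0.05, ** <=0.01, *** <=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def tukey_hsd(table: ReplicateTable) -> pd.DataFrame:
    """All-pairs Tukey HSD with studentized-range adjusted p-values.

    Uses the Tukey-Kramer statistic for unequal replicate counts. Returns a
    tidy frame with one row per unordered pair: group_a, group_b,
    mean_diff (b - a), p_adj, stars.
    """
    names = list(table.groups)
    arrays = table.arrays()
    res = _st.tukey_hsd(*[arrays[n] for n in names])
    rows = []
    for i, j in combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(arrays[names[j]].mean() - arrays[names[i]].mean()),
                "p_adj": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def count_significant_states(
    ordered_probes: Sequence[str],
    tukey: pd.DataFrame,
    alpha: float = 0.05,
) -> int:
    """Distinguishable copy-number states along a genomically ordered panel.

    Cuts the ordered probe sequence at every adjacent pair whose adjusted p
    is at or below alpha; the state count is one plus the number of cuts,
    so it never exceeds the number of probes.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if len(ordered_probes) == 0:
        return 0
    lookup = {
        frozenset((row.group_a, row.group_b)): row.p_adj for row in tukey.itertuples()
    }
    cuts = 0
    for a, b in zip(ordered_probes, ordered_probes[1:]):
        key = frozenset((a, b))
        if key not in lookup:
            raise KeyError(f"no Tukey comparison for adjacent pair ({a!r}, {b!r})")
        if lookup[key] <= alpha:
            cuts += 1
    return cuts + 1


def theoretical_states(min_detectable_difference: float) -> int:
    """How many states fit on the one-to-two replication scale.

    With smallest detectable copy-number difference d, floor((2 - 1)/d)
    states are distinguishable; d = 0.07 gives 14.
    """
    d = float(min_detectable_difference)
    if not 0.0 < d <= 1.0:
        raise ValueError(f"min detectable difference must be in (0, 1], got {d}")
    return int(math.floor(1.0 / d))


def _two_group_power(
    delta: float, cv: float, n: int, alpha: float, rng: np.random.Generator, n_sims: int
) -> float:
    # Two-group Tukey HSD == pooled two-sided t-test (k=2: q = sqrt(2)|t|),
    # so the Monte-Carlo power loop runs on the vectorized t form.
    a = rng.normal(1.0, cv, size=(n_sims, n))
    b = rng.normal(1.0 + delta, cv * (1.0 + delta), size=(n_sims, n))
    var_pooled = 0.5 * (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1))
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(2.0 * var_pooled / n)
    p = 2.0 * _st.t.sf(np.abs(t), df=2 * n - 2)
    return float(np.mean(p <= alpha))


def min_detectable_difference(
    cv: float,
    n_replicates: int,
    alpha: float = 0.05,
    power: float = 0.8,
    seed: int = 0,
    n_sims: int = 2000,
    tol: float = 1e-3,
) -> float:
    """Smallest copy-number difference detectable at the given power.

    Bisects the two-group difference Delta on the [1, 2] replication scale,
    estimating power by Monte-Carlo simulation of replicate tables with
    multiplicative noise of the given CV, tested at level alpha. Seeded and
    reproducible; the same seed is reused at every bisection step so the
    power curve is monotone in Delta.
    """
    if cv <= 0:
        raise ValueError(f"cv must be > 0, got {cv}")
    if n_replicates < 2:
        raise ValueError(f"need >=2 replicates, got {n_replicates}")
    lo, hi = 0.0, 1.0
    if _two_group_power(hi, cv, n_replicates, alpha, np.random.default_rng(seed), n_sims) < power:
        raise RuntimeError(
            f"difference of 1.0 not detectable at power {power} (cv={cv}, n={n_replicates})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        rng = np.random.default_rng(seed)
        if _two_group_power(mid, cv, n_replicates, alpha, rng, n_sims) >= power:
            hi = mid
        else:
            lo = mid
    return hi
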