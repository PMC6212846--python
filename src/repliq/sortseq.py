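"""Relative copy number from binned sequencing counts (sort-seq).

Sort-seq sequences a FACS-sorted replicating (S-phase) sample and a
non-replicating control, bins the mapped reads, and takes the
depth-normalized per-bin count ratio

    r_i = (rep_i / nonRep_i) * (nonRepSum / repSum)

as a relative copy-number estimate. Because sequencing depth only fixes the
genome-wide mean, the raw ratio is rescaled onto the biologically meaningful
[1, 2] replication scale by the factor that minimizes the summed exceedance
outside that range (:func:`adjust_to_unit_range`). Profiles can be smoothed
(LOESS or a GCV cubic smoothing spline, never across chromosome
boundaries), intersected with ddPCR probe locations, and compared to
probe-based measurements by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.interpolate import make_smoothing_spline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .copynumber import ProbeSpec

__all__ = [
    "BinnedCounts",
    "BinnedRatioProfile",
    "LinearComparison",
    "compute_ratio",
    "adjust_to_unit_range",
    "smooth_profile",
    "extract_probe_windows",
    "compare_profiles",
    "MISSING",
]

#: Marker for probes without an overlapping bin.
MISSING = float("nan")

_BIN_COLUMNS = ("chrom", "start", "end")


def _validate_bins(df: pd.DataFrame) -> None:
    for col in _BIN_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("bins must satisfy start < end")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not (np.all(np.diff(starts) > 0) and np.all(starts[1:] >= ends[:-1])):
            raise ValueError(f"bins on {chrom} must be sorted and non-overlapping")


@dataclass(frozen=True)
class BinnedCounts:
    """Per-bin read counts for a replicating and a non-replicating sample.

    ``data`` has columns chrom, start, end (0-based half-open), rep, nonrep.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _validate_bins(df)
        for col in ("rep", "nonrep"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
            if (df[col] < 0).any():
                raise ValueError(f"negative counts in column {col!r}")

    @property
    def rep_sum(self) -> float:
        return float(self.data["rep"].sum())

    @property
    def nonrep_sum(self) -> float:
        return float(self.data["nonrep"].sum())


@dataclass(frozen=True)
class BinnedRatioProfile:
    """Per-bin replicating/non-replicating ratio, raw and range-adjusted.

    ``data`` has columns chrom, start, end, raw_ratio and (after
    adjustment) adjusted_ratio = f * raw_ratio. ``excluded`` records bins
    dropped before ratio computation, with reasons.
    """

    data: pd.DataFrame
    adjustment_factor: float | None = None
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=[*_BIN_COLUMNS, "reason"])
    )

    @property
    def values(self) -> np.ndarray:
        col = "adjusted_ratio" if self.adjustment_factor is not None else "raw_ratio"
        return self.data[col].to_numpy()


def compute_ratio(counts: BinnedCounts, min_nonrep: int = 1) -> BinnedRatioProfile:
    """Depth-normalized per-bin count ratio.

    Bins with non-replicating counts below ``min_nonrep`` are excluded
    (ratios there are unstable) and recorded; the depth sums are taken over
    included bins only. The formula is invariant to the global sequencing
    depth of either sample.
    """
    df = counts.data
    keep = df["nonrep"] >= max(min_nonrep, 1)
    excluded = df.loc[~keep, list(_BIN_COLUMNS)].copy()
    excluded["reason"] = f"nonrep < {max(min_nonrep, 1)}"
    kept = df.loc[keep]
    if kept.empty:
        raise ValueError("all bins excluded: no bin has sufficient non-replicating coverage")
    rep_sum = float(kept["rep"].sum())
    nonrep_sum = float(kept["nonrep"].sum())
    if rep_sum <= 0:
        raise ValueError("replicating sample has zero reads in included bins")
    out = kept[list(_BIN_COLUMNS)].copy()
    out["raw_ratio"] = (kept["rep"] / kept["nonrep"]) * (nonrep_sum / rep_sum)
    return BinnedRatioProfile(
        data=out.reset_index(drop=True), excluded=excluded.reset_index(drop=True)
    )


def _out_of_range_mass(f: float, r: np.ndarray) -> float:
    fr = f * r
    return float(np.maximum(0.0, 1.0 - fr).sum() + np.maximum(0.0, fr - 2.0).sum())


def adjust_to_unit_range(profile: BinnedRatioProfile) -> BinnedRatioProfile:
    """Rescale the raw ratio onto the [1, 2] replication scale.

    Finds the multiplicative factor f minimizing the summed linear
    exceedance of f*r outside [1, 2]. The objective is piecewise linear in
    f with breakpoints at f = 1/r_i and 2/r_i, so the exact minimum is
    found by evaluating the breakpoints; on a zero (or tied) plateau the
    factor closest to 1 is chosen, which makes the operation idempotent.
    """
    r = profile.data["raw_ratio"].to_numpy()
    if r.size == 0:
        raise ValueError("empty profile")
    r_pos = r[r > 0]
    if r_pos.size == 0:
        raise ValueError("no positive ratios to adjust")
    breaks = np.unique(np.concatenate([1.0 / r_pos, 2.0 / r_pos]))
    objs = np.array([_out_of_range_mass(f, r) for f in breaks])
    best = objs.min()
    # The objective is convex piecewise linear, so the minimizing set is an
    # interval whose endpoints are breakpoints; pick the point closest to 1.
    at_min = np.flatnonzero(objs <= best + 1e-12 * (1.0 + best))
    lo, hi = float(breaks[at_min.min()]), float(breaks[at_min.max()])
    f = float(np.clip(1.0, lo, hi))
    data = profile.data.copy()
    data["adjusted_ratio"] = f * data["raw_ratio"]
    return replace(profile, data=data, adjustment_factor=f)


def smooth_profile(
    profile: BinnedRatioProfile,
    method: Literal["spline", "loess"] = "loess",
    span_or_spar: float | None = None,
) -> np.ndarray:
    """Smooth the (adjusted, if available) ratio per chromosome.

    LOESS uses a local-regression fraction (default 0.1); the spline is a
    cubic smoothing spline with a GCV-selected penalty (pass a value to fix
    the penalty instead). Smoothing never crosses chromosome boundaries.
    Chromosomes with fewer than 10 bins are passed through with a warning.
    Output is aligned with the profile rows.
    """
    if method not in ("spline", "loess"):
        raise ValueError(f"unknown smoothing method {method!r}")
    values = profile.values.astype(float)
    out = np.empty_like(values)
    for chrom, sub in profile.data.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        y = values[idx]
        x = ((sub["start"] + sub["end"]) / 2.0).to_numpy(dtype=float)
        if len(idx) < 10:
            warnings.warn(
                f"{chrom}: only {len(idx)} bins, returning unsmoothed values", stacklevel=2
            )
            out[idx] = y
            continue
        if method == "loess":
            frac = 0.1 if span_or_spar is None else float(span_or_spar)
            out[idx] = lowess(y, x, frac=frac, return_sorted=False)
        else:
            lam = None if span_or_spar is None else float(span_or_spar)
            out[idx] = make_smoothing_spline(x, y, lam=lam)(x)
    return out


def extract_probe_windows(
    profile: BinnedRatioProfile,
    probes: Sequence[ProbeSpec],
    values: np.ndarray | None = None,
) -> dict[str, float]:
    """Profile value at each ddPCR probe location.

    A probe inside a single bin takes that bin's value; a probe spanning
    exactly two bins takes their unweighted mean; more than two overlapping
    bins also average, with a warning (unusually long probe). Probes with
    no overlapping bin map to NaN rather than failing the extraction.
    """
    vals = profile.values if values is None else np.asarray(values, dtype=float)
    if vals.shape[0] != len(profile.data):
        raise ValueError("values must align with profile bins")
    out: dict[str, float] = {}
    by_chrom = {chrom: sub for chrom, sub in profile.data.groupby("chrom", sort=False)}
    for probe in probes:
        sub = by_chrom.get(probe.chrom)
        if sub is None:
            out[probe.probe_id] = MISSING
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        hit = (starts < probe.end) & (ends > probe.start)
        n_hit = int(hit.sum())
        if n_hit == 0:
            out[probe.probe_id] = MISSING
            continue
        if n_hit > 2:
            warnings.warn(
                f"probe {probe.probe_id} overlaps {n_hit} bins; averaging all", stacklevel=2
            )
        out[probe.probe_id] = float(vals[sub.index.to_numpy()[hit]].mean())
    return out


@dataclass(frozen=True)
class LinearComparison:
    """OLS comparison of two per-probe measurement sets."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    n: int


def compare_profiles(
    x: Mapping[str, float], y: Mapping[str, float]
) -> LinearComparison:
    """Ordinary least squares of y on x over shared, non-missing probes.

    Reports the adjusted coefficient of determination
    ``1 - (1 - R^2)(n - 1)/(n - 2)`` used to compare probe-based and
    sequencing-based copy-number measurements.
    """
    shared = [
        k
        for k in x
        if k in y and np.isfinite(x[k]) and np.isfinite(y[k])
    ]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared probes with values, got {len(shared)}")
    xv = np.array([x[k] for k in shared])
    yv = np.array([y[k] for k in shared])
    fit = _st.linregress(xv, yv)
    r2 = fit.rvalue**2
    n = len(shared)
    return LinearComparison(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        adj_r_squared=float(1.0 - (1.0 - r2) * (n - 1) / (n - 2)),
        n=n,
    )
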