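"""Sigmoid replication kinetics and bulk flow-cytometry replication.

A locus' normalized copy number through a synchronized S phase rises from 1
to 2; its median replication time (Trep) is the midpoint of that rise. The
rise is modelled with the Boltzmann sigmoid

    y(x) = A2 + (A1 - A2) / (1 + exp((x - x0) / dx))

where A1 and A2 are the plateaus, x0 the midpoint and dx the transition
width. The same fit applied to bulk DNA content from flow cytometry (after
normalizing to the arrested sample and contrast-stretching the dynamic
range onto [1, 2]) gives the population replication curve used to select
samples at a target bulk-replication fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BoltzmannFit",
    "BulkReplication",
    "BulkReplicationCourse",
    "DegenerateDataError",
    "FitConvergenceError",
    "boltzmann",
    "fit_boltzmann",
    "trep_of",
    "bulk_replication_from_fc",
    "select_sample_by_replication",
]


class DegenerateDataError(ValueError):
    """The response carries no usable range (flat y)."""


class FitConvergenceError(RuntimeError):
    """The sigmoid optimizer failed; carries the last iterate as .last_params."""

    def __init__(self, message: str, last_params: tuple | None = None):
        super().__init__(message)
        self.last_params = last_params


def boltzmann(x, A1, A2, x0, dx):
    """Boltzmann sigmoid: A1 plateau at x << x0, A2 plateau at x >> x0 (dx > 0)."""
    return A2 + (A1 - A2) / (1.0 + np.exp((np.asarray(x, dtype=float) - x0) / dx))


@dataclass(frozen=True)
class BoltzmannFit:
    """Results of a Boltzmann sigmoid least-squares fit.

    Stored in canonical form with dx > 0, so A1 is always the low-x plateau
    and the fitted curve is non-decreasing exactly when A1 < A2. (The model
    has a twin parameterization with A1/A2 swapped and dx negated; both
    describe the same curve.)
    """

    A1: float
    A2: float
    x0: float
    dx: float
    rss: float
    converged: bool
    n: int

    def predict(self, x) -> np.ndarray:
        return boltzmann(x, self.A1, self.A2, self.x0, self.dx)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.A1, self.A2, self.x0, self.dx)

    def summary(self) -> str:
        lines = [
            "Boltzmann sigmoid fit",
            f"  n points   : {self.n}",
            f"  A1 (start) : {self.A1:.6g}",
            f"  A2 (end)   : {self.A2:.6g}",
            f"  x0 (midpt) : {self.x0:.6g}",
            f"  dx (width) : {self.dx:.6g}",
            f"  RSS        : {self.rss:.6g}",
            f"  converged  : {self.converged}",
        ]
        return "\n".join(lines)


def fit_boltzmann(x: Sequence[float], y: Sequence[float]) -> BoltzmannFit:
    """Least-squares Boltzmann sigmoid fit.

    Initialization: plateaus at min/max of y, midpoint at the x whose y is
    closest to mid-range, width at a tenth of the x range (signed by the
    apparent orientation). Raises :class:`DegenerateDataError` for flat y
    and :class:`FitConvergenceError` when the optimizer fails.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 5:
        raise ValueError(f"need >=5 points to fit a 4-parameter sigmoid, got {x.size}")
    y_range = float(y.max() - y.min())
    if y_range <= 1e-9 * max(abs(float(y.mean())), 1e-300):
        raise DegenerateDataError("y is flat: no transition to fit")

    rising = y[np.argmax(x)] >= y[np.argmin(x)]
    a1, a2 = (y.min(), y.max()) if rising else (y.max(), y.min())
    mid = 0.5 * (y.min() + y.max())
    x0 = float(x[np.argmin(np.abs(y - mid))])
    dx0 = (x.max() - x.min()) / 10.0 or 1.0
    p0 = (a1, a2, x0, dx0)
    try:
        popt, _ = curve_fit(boltzmann, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(f"Boltzmann fit did not converge: {exc}", p0) from exc
    A1, A2, x0, dx = (float(v) for v in popt)
    if dx == 0 or not np.all(np.isfinite(popt)):
        raise FitConvergenceError("Boltzmann fit returned a degenerate width", tuple(popt))
    if dx < 0:  # fold the twin parameterization onto dx > 0
        A1, A2, dx = A2, A1, -dx
    resid = y - boltzmann(x, A1, A2, x0, dx)
    return BoltzmannFit(
        A1=A1, A2=A2, x0=x0, dx=dx, rss=float(resid @ resid), converged=True, n=int(x.size)
    )


def trep_of(fit: BoltzmannFit) -> float:
    """Median replication time: the midpoint x0 of a converged sigmoid fit."""
    if not fit.converged:
        raise FitConvergenceError("cannot take Trep of an unconverged fit", fit.params)
    return fit.x0


@dataclass(frozen=True)
class BulkReplication:
    """Bulk genome replication of one sample from its DNA-content signal."""

    sample_id: str
    time: float
    median_signal: float
    stretched: float  # in [1, 2] after contrast stretch
    fraction_replicated: float  # stretched - 1


@dataclass(frozen=True)
class BulkReplicationCourse:
    """Contrast-stretched course with an attached sigmoid fit when one is
    supportable (>=5 samples and a converged optimizer), else fit is None."""

    points: tuple[BulkReplication, ...]
    fit: BoltzmannFit | None


def bulk_replication_from_fc(
    medians: Mapping[str, tuple[float, float]] | Sequence[tuple[str, float, float]],
    arrested_signal: float,
) -> BulkReplicationCourse:
    """Bulk replication fractions from per-sample DNA-content medians.

    ``medians`` maps sample_id -> (time_min, signal) (or an equivalent
    sequence of triples). Signals are normalized to the arrested (G1)
    sample, then linearly contrast-stretched so the observed course spans
    exactly [1, 2]; the replicated fraction is the stretched value minus 1.
    A Boltzmann fit over (time, stretched) is attached.
    """
    if arrested_signal <= 0:
        raise ValueError(f"arrested_signal must be > 0, got {arrested_signal}")
    if isinstance(medians, Mapping):
        rows = [(sid, t, s) for sid, (t, s) in medians.items()]
    else:
        rows = [tuple(r) for r in medians]
    rows.sort(key=lambda r: r[1])
    if len(rows) < 2:
        raise ValueError("need >=2 samples to stretch a dynamic range")
    norm = np.array([s / arrested_signal for _, _, s in rows])
    rng = float(norm.max() - norm.min())
    if rng <= 0:
        raise DegenerateDataError("all normalized signals identical: zero dynamic range")
    stretched = 1.0 + (norm - norm.min()) / rng
    points = tuple(
        BulkReplication(
            sample_id=sid,
            time=float(t),
            median_signal=float(s),
            stretched=float(st),
            fraction_replicated=float(st - 1.0),
        )
        for (sid, t, s), st in zip(rows, stretched)
    )
    times = np.array([p.time for p in points])
    fit: BoltzmannFit | None
    try:
        fit = fit_boltzmann(times, stretched)
    except (ValueError, FitConvergenceError) as exc:
        warnings.warn(f"no sigmoid fit attached to bulk course: {exc}", stacklevel=2)
        fit = None
    return BulkReplicationCourse(points=points, fit=fit)


def select_sample_by_replication(
    course: BulkReplicationCourse, target_fraction: float
) -> BulkReplication:
    """Sample whose fitted bulk-replication fraction is nearest the target.

    Fractions are read off the attached sigmoid fit at each sample's time
    (robust to single-sample noise); ties break toward the earlier time.
    """
    if not course.points:
        raise ValueError("empty course")
    times = np.array([p.time for p in course.points])
    if course.fit is not None:
        fraction = course.fit.predict(times) - 1.0
    else:
        fraction = np.array([p.fraction_replicated for p in course.points])
    dist = np.abs(fraction - target_fraction)
    return course.points[int(np.argmin(dist))]  # argmin: first (earliest) of ties
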