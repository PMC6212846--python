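"""Poisson quantification of droplet digital PCR wells.

A ddPCR well partitions a diluted DNA sample into ``n_total`` droplets of
known volume (about 1 nl on the instrument class modelled here). After
end-point amplification each droplet is read as positive or negative. With
template molecules Poisson-distributed over droplets at mean occupancy
``lambda`` (copies per droplet), the positive fraction is
``p = 1 - exp(-lambda)``, so the occupancy is recovered from the observed
fraction by ``lambda = -ln(1 - p_hat)`` and converted to an absolute
concentration in copies per microlitre by dividing by the droplet volume.

The sampling error of this estimator is binomial in the droplet calls; the
delta method gives ``sd(lambda_hat) = sqrt(p / (n (1 - p)))``, which is the
basis of the per-well confidence interval and of :func:`cv_of_estimator`.
The CV is U-shaped in occupancy: subsampling error dominates dilute wells,
partitioning error dominates nearly saturated ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "DropletCount",
    "ConcentrationEstimate",
    "ReplicateSummary",
    "SaturatedWellError",
    "EmptyWellError",
    "estimate_concentration",
    "concentration_ci",
    "replicate_ci",
    "merge_technical_replicates",
    "cv_of_estimator",
    "DEFAULT_DROPLET_VOLUME_NL",
    "DEFAULT_DROPLETS_PER_WELL",
]

#: Nominal droplet volume in nanolitres. The droplets are "around 1 nl";
#: 1 nl makes occupancy (copies/droplet) and concentration (copies/ul)
#: numerically related by a factor of 1000. Instruments may calibrate to a
#: slightly smaller value (~0.85 nl); every entry point accepts an override.
DEFAULT_DROPLET_VOLUME_NL = 1.0

#: Typical accepted-droplet count of a well on this instrument class.
DEFAULT_DROPLETS_PER_WELL = 20_000


class SaturatedWellError(ValueError):
    """Every droplet is positive: the occupancy is unquantifiable.

    The Poisson inversion diverges at p_hat = 1; the sample must be diluted
    and re-run.
    """


class EmptyWellError(ValueError):
    """A well with no droplets (or no usable replicates) was supplied."""


@dataclass(frozen=True)
class DropletCount:
    """One ddPCR well: positive/total droplet calls at a known volume."""

    probe_id: str
    sample_id: str
    replicate_id: str
    n_positive: int
    n_total: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise EmptyWellError(
                f"well {self.probe_id}/{self.sample_id}/{self.replicate_id}: "
                f"n_total must be positive, got {self.n_total}"
            )
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError(
                f"n_positive={self.n_positive} outside [0, n_total={self.n_total}]"
            )
        if self.droplet_volume_nl <= 0:
            raise ValueError(f"droplet_volume_nl must be > 0, got {self.droplet_volume_nl}")

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_total


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Poisson-corrected absolute concentration for one well.

    ``occupancy_lambda`` is in copies per droplet; ``concentration`` and the
    confidence bounds are in copies per microlitre; ``cv`` is the analytic
    (delta-method) coefficient of variation of the estimator.
    """

    probe_id: str
    sample_id: str
    replicate_id: str
    occupancy_lambda: float
    concentration: float
    ci_low: float
    ci_high: float
    cv: float
    level: float = 0.95


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean concentration over technical replicates with a t-based CI."""

    mean: float
    ci_low: float
    ci_high: float
    n: int
    level: float


def _lambda_sd(p_hat: float, n_total: int) -> float:
    # Delta method on lambda_hat = -ln(1 - p_hat), Var(p_hat) = p(1-p)/n.
    return math.sqrt(p_hat / (n_total * (1.0 - p_hat)))


def _to_copies_per_ul(occupancy: float, droplet_volume_nl: float) -> float:
    return occupancy / (droplet_volume_nl * 1e-3)


def estimate_concentration(count: DropletCount, level: float = 0.95) -> ConcentrationEstimate:
    """Poisson-correct one well into an absolute concentration.

    Raises :class:`SaturatedWellError` when all droplets are positive.
    A well with zero positives legitimately estimates zero concentration.
    """
    if count.n_positive == count.n_total:
        raise SaturatedWellError(
            f"all {count.n_total} droplets positive in well "
            f"{count.probe_id}/{count.sample_id}/{count.replicate_id}; "
            "dilute the sample to quantify"
        )
    p_hat = count.fraction_positive
    lam = -math.log1p(-p_hat)
    conc = _to_copies_per_ul(lam, count.droplet_volume_nl)
    if count.n_positive == 0:
        lo = hi = 0.0
        cv = float("nan")
    else:
        lo, hi = concentration_ci(count, level)
        cv = cv_of_estimator(lam, count.n_total)
    return ConcentrationEstimate(
        probe_id=count.probe_id,
        sample_id=count.sample_id,
        replicate_id=count.replicate_id,
        occupancy_lambda=lam,
        concentration=conc,
        ci_low=lo,
        ci_high=hi,
        cv=cv,
        level=level,
    )


def concentration_ci(count: DropletCount, level: float = 0.95) -> tuple[float, float]:
    """Per-well delta-method CI on the concentration, in copies/ul.

    Symmetric normal-quantile interval on the occupancy scale, clipped at
    zero after unit conversion. Distinct from :func:`replicate_ci`, which
    summarises scatter *between* wells.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if count.n_positive == 0:
        raise EmptyWellError("no positive droplets: occupancy CI undefined (use 0)")
    if count.n_positive == count.n_total:
        raise SaturatedWellError("saturated well: occupancy CI undefined")
    p_hat = count.fraction_positive
    lam = -math.log1p(-p_hat)
    z = _st.norm.ppf(0.5 + level / 2.0)
    half = z * _lambda_sd(p_hat, count.n_total)
    lo = _to_copies_per_ul(max(lam - half, 0.0), count.droplet_volume_nl)
    hi = _to_copies_per_ul(lam + half, count.droplet_volume_nl)
    return lo, hi


def replicate_ci(
    estimates: Sequence[ConcentrationEstimate | float], level: float = 0.95
) -> ReplicateSummary:
    """Mean and Student-t CI over technical replicates of one probe/sample.

    Uses t with n-1 degrees of freedom, so two replicates are allowed
    (t with 1 df). With fewer than two replicates there is no between-well
    scatter to summarise: fall back to the per-well partitioning CI.
    """
    values = np.asarray(
        [e.concentration if isinstance(e, ConcentrationEstimate) else float(e) for e in estimates],
        dtype=float,
    )
    if values.size < 2:
        raise EmptyWellError(
            "replicate_ci needs >=2 replicates; use concentration_ci for a single well"
        )
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(values.size))
    t = float(_st.t.ppf(0.5 + level / 2.0, df=values.size - 1))
    return ReplicateSummary(
        mean=mean, ci_low=mean - t * sem, ci_high=mean + t * sem, n=values.size, level=level
    )


def merge_technical_replicates(counts: Iterable[DropletCount]) -> DropletCount:
    """Pool wells of the same probe/sample before Poisson correction.

    Positives and totals are summed; pooling before the log-inversion is the
    correct way to combine wells at equal occupancy and strictly reduces the
    estimator CV. The merged replicate id concatenates the source well ids.
    """
    counts = list(counts)
    if not counts:
        raise EmptyWellError("no wells to merge")
    first = counts[0]
    for c in counts[1:]:
        if c.probe_id != first.probe_id or c.sample_id != first.sample_id:
            raise ValueError(
                f"cannot merge wells from different probe/sample: "
                f"{(c.probe_id, c.sample_id)} vs {(first.probe_id, first.sample_id)}"
            )
        if c.droplet_volume_nl != first.droplet_volume_nl:
            raise ValueError("cannot merge wells with different droplet volumes")
    return replace(
        first,
        replicate_id="+".join(c.replicate_id for c in counts),
        n_positive=sum(c.n_positive for c in counts),
        n_total=sum(c.n_total for c in counts),
    )


def cv_of_estimator(occupancy_lambda: float, n_droplets: int) -> float:
    """Analytic CV of the Poisson-corrected occupancy estimator.

    ``cv = sqrt(p / ((1-p) n)) / lambda`` with ``p = 1 - exp(-lambda)``.
    U-shaped in lambda: subsampling noise dominates at low occupancy,
    partitioning noise near saturation, with a minimum around lambda ~ 1.6.
    """
    if occupancy_lambda <= 0:
        raise ValueError(f"occupancy must be > 0, got {occupancy_lambda}")
    if n_droplets <= 0:
        raise ValueError(f"n_droplets must be > 0, got {n_droplets}")
    p = -math.expm1(-occupancy_lambda)
    return math.sqrt(p / ((1.0 - p) * n_droplets)) / occupancy_lambda
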