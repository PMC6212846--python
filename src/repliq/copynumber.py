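"""Relative DNA copy number and inter-sample replication statistics.

In a replicating cell population the per-locus DNA abundance lies between
one (unreplicated in every cell) and two (replicated in every cell), so a
copy-adjusted, baseline-normalized concentration is a proxy for replication
timing. This module turns per-probe concentrations into that relative scale
and provides the statistics that make independent samples comparable:

* :func:`baseline_normalize` — divide by the copy-adjusted mean over probes,
  so unique probes in non-replicating material read 1 and duplicated /
  triplicated loci read their integer copy number;
* :func:`control_ratio` / :func:`find_switch_point` / :func:`dual_normalize`
  — time-course normalization against a late-replicating control early in
  S phase and a (ploidy-adjusted) early-replicating control afterwards;
* :func:`replication_index` — affine rescaling sending an early control to 0
  and a late control to 1, invariant to the sample's dynamic range;
* :func:`allele_delay` — mutant/wild-type copy-number ratio at a
  heterozygous locus with replicate-based significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .droplet import ConcentrationEstimate

__all__ = [
    "ProbeSpec",
    "CopyNumberValue",
    "TimeCoursePoint",
    "SwitchPoint",
    "AlleleDelayResult",
    "ROLES",
    "baseline_normalize",
    "bootstrap_ratio_ci",
    "control_ratio",
    "find_switch_point",
    "dual_normalize",
    "replication_index",
    "allele_delay",
]

ROLES = ("target", "early_control", "late_control")


@dataclass(frozen=True)
class ProbeSpec:
    """A genomic ddPCR amplicon.

    ``copies_per_haploid`` is the locus copy number per haploid genome
    (1 for unique probes, 2/3 for duplicated/triplicated families).
    ``allele_tag`` marks allele-specific probes in heterozygous designs;
    ``role`` marks normalization controls.
    """

    probe_id: str
    chrom: str
    start: int
    end: int
    copies_per_haploid: int = 1
    allele_tag: str | None = None
    role: str = "target"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"probe {self.probe_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.copies_per_haploid < 1:
            raise ValueError(
                f"probe {self.probe_id}: copies_per_haploid must be >= 1, "
                f"got {self.copies_per_haploid}"
            )
        if self.role not in ROLES:
            raise ValueError(f"probe {self.probe_id}: unknown role {self.role!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class CopyNumberValue:
    """A probe's relative copy number with an optional confidence interval."""

    probe_id: str
    value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")


@dataclass(frozen=True)
class TimeCoursePoint:
    """One time-course sample: minutes after release plus per-probe concentrations."""

    sample_id: str
    time: float
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"sample {self.sample_id}: time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class SwitchPoint:
    """Index of the control-ratio maximum; degenerate if the course is flat."""

    index: int
    ratio: float
    degenerate: bool = False


@dataclass(frozen=True)
class AlleleDelayResult:
    ratio: float
    p_value: float
    significant: bool
    alpha: float


def _conc(value: float | ConcentrationEstimate) -> float:
    if isinstance(value, ConcentrationEstimate):
        return value.concentration
    return float(value)


def baseline_normalize(
    concentrations: Mapping[str, float | ConcentrationEstimate],
    probes: Sequence[ProbeSpec],
) -> list[CopyNumberValue]:
    """Normalize concentrations to the copy-adjusted mean over all probes.

    The baseline is ``mean_i(c_i / k_i)`` with ``k_i`` the per-haploid copy
    number; each probe's value is ``c_i / baseline`` (not divided by its own
    ``k_i``), so non-unique probes read their integer copy number in
    non-replicating material. Confidence bounds, when present on the inputs,
    are scaled by the same baseline.
    """
    if not probes:
        raise ValueError("no probes supplied")
    missing = [p.probe_id for p in probes if p.probe_id not in concentrations]
    if missing:
        raise KeyError(f"probes without concentrations: {missing}")
    values = {p.probe_id: _conc(concentrations[p.probe_id]) for p in probes}
    if any(v <= 0 for v in values.values()):
        bad = [pid for pid, v in values.items() if v <= 0]
        raise ValueError(f"non-positive concentrations for probes {bad}")
    baseline = float(np.mean([values[p.probe_id] / p.copies_per_haploid for p in probes]))
    out = []
    for p in probes:
        est = concentrations[p.probe_id]
        if isinstance(est, ConcentrationEstimate):
            lo, hi = est.ci_low / baseline, est.ci_high / baseline
        else:
            lo = hi = float("nan")
        out.append(
            CopyNumberValue(
                probe_id=p.probe_id, value=values[p.probe_id] / baseline, ci_low=lo, ci_high=hi
            )
        )
    return out


def control_ratio(point: TimeCoursePoint, early_id: str, late_id: str) -> float:
    """Early-control / late-control concentration ratio for one sample.

    Close to 1 in G1 (neither control replicated) and again in G2 (both
    replicated); approaches 2 in mid S phase, when the early control is
    fully replicated and the late one has not started.
    """
    for pid in (early_id, late_id):
        if pid not in point.concentrations:
            raise KeyError(f"sample {point.sample_id}: missing control probe {pid!r}")
    late = _conc(point.concentrations[late_id])
    if late <= 0:
        raise ValueError(f"sample {point.sample_id}: non-positive late-control concentration")
    return _conc(point.concentrations[early_id]) / late


def find_switch_point(
    course: Sequence[TimeCoursePoint], early_id: str, late_id: str
) -> SwitchPoint:
    """Locate the mid-S sample maximizing the control ratio.

    This is the last sample normalized against the late control in
    :func:`dual_normalize`. Ties break toward the earlier time; a flat
    course is flagged degenerate rather than rejected.
    """
    if len(course) < 3:
        raise ValueError(f"need >=3 time points, got {len(course)}")
    ratios = np.array([control_ratio(p, early_id, late_id) for p in course])
    idx = int(np.argmax(ratios))  # argmax takes the first of tied maxima
    degenerate = bool(np.all(np.isclose(ratios, ratios[0])))
    return SwitchPoint(index=idx, ratio=float(ratios[idx]), degenerate=degenerate)


def dual_normalize(
    course: Sequence[TimeCoursePoint],
    switch_index: int,
    early_id: str,
    late_id: str,
    ploidy_factor: float = 2.0,
) -> dict[str, np.ndarray]:
    """Normalize a synchronized time course against stage-appropriate controls.

    Samples up to and including ``switch_index`` are divided by the late
    control (still unreplicated, so constant); later samples are divided by
    the early control and multiplied by ``ploidy_factor`` (the early control
    is itself fully replicated, i.e. at copy number 2, from the switch on,
    which makes the series continuous for an already-replicated probe).
    Returns one array per probe over all samples.
    """
    if not course:
        raise ValueError("empty time course")
    if not 0 <= switch_index < len(course):
        raise IndexError(f"switch_index {switch_index} outside course of {len(course)} samples")
    probe_ids = list(course[0].concentrations)
    out: dict[str, list[float]] = {pid: [] for pid in probe_ids}
    for i, point in enumerate(course):
        for pid in (early_id, late_id):
            if pid not in point.concentrations:
                raise KeyError(f"sample {point.sample_id}: missing control probe {pid!r}")
        if i <= switch_index:
            denom = _conc(point.concentrations[late_id])
            scale = 1.0
        else:
            denom = _conc(point.concentrations[early_id])
            scale = ploidy_factor
        if denom <= 0:
            raise ValueError(f"sample {point.sample_id}: non-positive control concentration")
        for pid in probe_ids:
            out[pid].append(scale * _conc(point.concentrations[pid]) / denom)
    return {pid: np.asarray(vals) for pid, vals in out.items()}


def replication_index(
    c_probe: float | np.ndarray,
    c_early: float,
    c_late: float,
) -> float | np.ndarray:
    """Affine map of S-phase copy number sending the controls to 0 and 1.

    ``RI = (c_early - c_probe) / (c_early - c_late)``: 0 at the early
    control, 1 at the late control, increasing with later replication.
    Invariant under multiplicative rescaling of all three concentrations,
    which is what makes samples with different sorted-fraction dynamic
    ranges comparable. Values slightly outside [0, 1] are legitimate for
    probes earlier/later than the controls.
    """
    c_early = float(c_early)
    c_late = float(c_late)
    if c_early <= c_late:
        raise ValueError(
            "degenerate controls: the early control must have higher S-phase "
            f"concentration than the late control (got {c_early} <= {c_late})"
        )
    return (c_early - np.asarray(c_probe, dtype=float)) / (c_early - c_late)


def bootstrap_ratio_ci(
    numerator_replicates: Sequence[float],
    denominator_replicates: Sequence[float],
    level: float = 0.95,
    n_boot: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded parametric bootstrap CI for a ratio of replicate means.

    First-order error propagation through ratios is adequate for three or
    more replicates; at two replicates the normal approximation is poor,
    and this bootstrap (Gaussian resampling at the observed mean/sd of each
    group) is the safer interval.
    """
    num = np.asarray(numerator_replicates, dtype=float)
    den = np.asarray(denominator_replicates, dtype=float)
    if num.size < 2 or den.size < 2:
        raise ValueError("bootstrap needs >=2 replicates per group")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    num_draws = rng.normal(num.mean(), num.std(ddof=1), size=(n_boot, num.size)).mean(axis=1)
    den_draws = rng.normal(den.mean(), den.std(ddof=1), size=(n_boot, den.size)).mean(axis=1)
    ratios = num_draws / den_draws
    alpha = 1.0 - level
    lo, hi = np.quantile(ratios, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def allele_delay(
    wildtype_replicates: Sequence[float],
    mutant_replicates: Sequence[float],
    alpha: float = 0.05,
) -> AlleleDelayResult:
    """Mutant/wild-type copy-number ratio at a heterozygous locus.

    A ratio below 1 means the mutant allele is less replicated in S-phase
    material, i.e. its replication is delayed. Significance is assessed on
    the technical replicates with a Tukey HSD comparison of the two allele
    groups (equivalent to a pooled t-test for two groups), so it composes
    with multi-allele designs.
    """
    from .stats import ReplicateTable, tukey_hsd

    wt = np.asarray(wildtype_replicates, dtype=float)
    mut = np.asarray(mutant_replicates, dtype=float)
    if wt.size < 2 or mut.size < 2:
        raise ValueError("allele_delay needs >=2 replicates per allele")
    table = tukey_hsd(ReplicateTable({"wildtype": wt.tolist(), "mutant": mut.tolist()}))
    p = float(table["p_adj"].iloc[0])
    return AlleleDelayResult(
        ratio=float(mut.mean() / wt.mean()),
        p_value=p,
        significant=p <= alpha,
        alpha=alpha,
    )
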