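"""Synthetic replication-timing data with the statistical structure the
analysis assumes.

The generator stands in for the wet lab: a chromosome is described by
replication origins (position, firing time, efficiency) and a constant fork
speed, which define a median replication time trep(x) landscape
(nearest-origin kinematics). Cell populations — synchronized with S-entry
jitter, FACS-sorted S fractions with G1/G2 contamination, or asynchronous
mixtures — convert that landscape into expected relative copy numbers, and
the measurement layers add the noise the real assays see: binomial droplet
partitioning at ~1 nl droplet volume for ddPCR, and negative-binomial
binned read counts (calibrated to ~5% CV at 1000 reads/bin) for sort-seq.

Every generator is deterministic given (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copynumber import ProbeSpec
from .droplet import (
    DEFAULT_DROPLET_VOLUME_NL,
    DEFAULT_DROPLETS_PER_WELL,
    DropletCount,
)
from .sortseq import BinnedCounts

__all__ = [
    "Origin",
    "ReplicationModel",
    "Synchronized",
    "SortedS",
    "Asynchronous",
    "AlleleModel",
    "trep_profile",
    "copy_number_profile",
    "asynchronous_dynamic_range",
    "simulate_droplets",
    "simulate_ddpcr_experiment",
    "simulate_sortseq_counts",
    "simulate_allele_experiment",
    "simulate_screen",
    "DEFAULT_NB_SIZE",
    "DEFAULT_SYNCHRONY_SD_MIN",
]

#: Negative-binomial size parameter calibrated so binned counts have ~5% CV
#: at a mean of 1000 reads/bin (CV^2 = 1/1000 + 1/640 ~ 0.0026).
DEFAULT_NB_SIZE = 640.0

#: Default S-entry dispersion of a synchronized population (minutes). The
#: synchrony of a real arrest/release is not sharply known; 3 min gives the
#: slightly-sub-2 mid-S control ratios real courses show.
DEFAULT_SYNCHRONY_SD_MIN = 3.0


@dataclass(frozen=True)
class Origin:
    """A replication origin: position (bp), firing time (min), efficiency."""

    position: float
    firing_time: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError(f"efficiency must be in (0, 1], got {self.efficiency}")


@dataclass(frozen=True)
class ReplicationModel:
    """Origins plus a constant fork speed defining trep(x) on one chromosome."""

    chrom_length: int
    origins: tuple[Origin, ...]
    fork_speed_kb_min: float = 1.5
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.fork_speed_kb_min <= 0:
            raise ValueError(f"fork speed must be > 0, got {self.fork_speed_kb_min}")
        for o in self.origins:
            if not 0 <= o.position < self.chrom_length:
                raise ValueError(
                    f"origin position {o.position} outside [0, {self.chrom_length})"
                )

    def with_origin_delayed(self, position: float, delay: float) -> "ReplicationModel":
        """Copy of the model with the origin nearest `position` fired later."""
        if not self.origins:
            raise ValueError("model has no origins")
        dists = [abs(o.position - position) for o in self.origins]
        idx = int(np.argmin(dists))
        target = self.origins[idx]
        new = Origin(target.position, target.firing_time + delay, target.efficiency)
        return ReplicationModel(
            chrom_length=self.chrom_length,
            origins=self.origins[:idx] + (new,) + self.origins[idx + 1 :],
            fork_speed_kb_min=self.fork_speed_kb_min,
            chrom=self.chrom,
        )


@dataclass(frozen=True)
class Synchronized:
    """Arrest/release population at time t with Gaussian S-entry jitter."""

    time: float
    entry_sd: float = DEFAULT_SYNCHRONY_SD_MIN

    def __post_init__(self) -> None:
        if self.entry_sd < 0:
            raise ValueError("entry_sd must be >= 0")


@dataclass(frozen=True)
class SortedS:
    """FACS-sorted S-phase gate with non-replicating contamination.

    Defaults mirror the few-percent G1/G2 carry-over of a clean DNA-content
    gate; S cells are uniform over normalized S-phase progression.
    """

    g1_contamination: float = 0.05
    g2_contamination: float = 0.05

    def __post_init__(self) -> None:
        for frac in (self.g1_contamination, self.g2_contamination):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("contamination fractions must be in [0, 1]")
        if self.g1_contamination + self.g2_contamination >= 1.0:
            raise ValueError("contamination fractions must sum to < 1")


@dataclass(frozen=True)
class Asynchronous:
    """Asynchronous cycling population by cell-cycle phase fractions."""

    s_fraction: float
    g2_fraction: float = 0.0

    def __post_init__(self) -> None:
        for frac in (self.s_fraction, self.g2_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("phase fractions must be in [0, 1]")
        if self.s_fraction + self.g2_fraction > 1.0:
            raise ValueError("phase fractions must sum to <= 1")


PopulationModel = Synchronized | SortedS | Asynchronous


@dataclass(frozen=True)
class AlleleModel:
    """Two haplotypes of one chromosome with differing origin sets."""

    haplotype_a: ReplicationModel
    haplotype_b: ReplicationModel

    def __post_init__(self) -> None:
        if self.haplotype_a.chrom_length != self.haplotype_b.chrom_length:
            raise ValueError("haplotypes must share chrom_length")
        if self.haplotype_a.fork_speed_kb_min != self.haplotype_b.fork_speed_kb_min:
            raise ValueError("haplotypes must share fork speed")


def trep_profile(
    model: ReplicationModel,
    positions: Sequence[float],
    n_cells: int = 1000,
    seed: int | None = 0,
) -> np.ndarray:
    """Median replication time at each position, in minutes.

    With fully efficient origins this is the deterministic nearest-origin
    arrival time min_i(t_i + |x - o_i| / v). With sub-unit efficiencies the
    per-cell active origin set is Bernoulli-sampled (cells with no active
    origin are redrawn) and the population median over ``n_cells`` cells is
    returned; seeded for reproducibility.
    """
    if not model.origins:
        raise ValueError("model has no origins")
    x = np.asarray(positions, dtype=float)
    v = model.fork_speed_kb_min * 1000.0  # bp / min
    arrivals = np.stack(
        [o.firing_time + np.abs(x - o.position) / v for o in model.origins]
    )  # (n_origins, n_positions)
    effs = np.array([o.efficiency for o in model.origins])
    if np.all(effs == 1.0):
        return arrivals.min(axis=0)
    rng = np.random.default_rng(seed)
    active = rng.random((n_cells, effs.size)) < effs
    empty = ~active.any(axis=1)
    while empty.any():
        active[empty] = rng.random((int(empty.sum()), effs.size)) < effs
        empty = ~active.any(axis=1)
    # per cell: min over active origins; mask inactive with +inf
    percell = np.where(active[:, :, None], arrivals[None, :, :], np.inf).min(axis=1)
    return np.median(percell, axis=0)


def _normalized_s_progress(model: ReplicationModel, trep: np.ndarray) -> np.ndarray:
    """P(locus replicated) for an S cell uniform over normalized S progression.

    S-phase progression is normalized to the trep range of the whole
    chromosome (1 kb grid), so the earliest-replicating locus is replicated
    in every S cell and the latest in none.
    """
    grid = np.arange(0.0, model.chrom_length, 1000.0)
    tgrid = trep_profile(model, grid)
    t_lo, t_hi = float(tgrid.min()), float(tgrid.max())
    if t_hi == t_lo:
        return np.full_like(trep, 0.5)
    return np.clip((t_hi - trep) / (t_hi - t_lo), 0.0, 1.0)


def copy_number_profile(
    model: ReplicationModel,
    population: PopulationModel,
    positions: Sequence[float],
    seed: int | None = 0,
) -> np.ndarray:
    """Expected relative copy number per position under a population model.

    synchronized: the probability that a cell has replicated x by time t is
    Phi((t - trep(x)) / sigma) over Gaussian S-entry jitter (a step function
    at sigma = 0); copies = 1 + P.

    sorted_S: S cells are uniform over normalized S progression; G1 and G2
    contaminants contribute copies 1 and 2; the profile is renormalized so
    the latest-replicating locus reads exactly 1 (contamination then
    compresses the upper end below 2).

    asynchronous: G1/S/G2 mixture with the same uniform-S model; before G2
    dilution the dynamic range is exactly 1 to 1 + s_fraction, and the
    profile is renormalized by the latest-replicating locus as above.
    """
    x = np.asarray(positions, dtype=float)
    trep = trep_profile(model, x, seed=seed)
    if isinstance(population, Synchronized):
        if population.entry_sd == 0.0:
            p_rep = (population.time >= trep).astype(float)
        else:
            from scipy.stats import norm

            p_rep = norm.cdf((population.time - trep) / population.entry_sd)
        return 1.0 + p_rep
    p_s = _normalized_s_progress(model, trep)
    if isinstance(population, SortedS):
        g1, g2 = population.g1_contamination, population.g2_contamination
        s_frac = 1.0 - g1 - g2
        copies = s_frac * (1.0 + p_s) + g1 * 1.0 + g2 * 2.0
        latest = s_frac * 1.0 + g1 * 1.0 + g2 * 2.0  # p_s = 0 locus
        return copies / latest
    if isinstance(population, Asynchronous):
        f_s, f_g2 = population.s_fraction, population.g2_fraction
        copies = 1.0 + f_s * p_s + f_g2
        latest = 1.0 + f_g2
        return copies / latest
    raise TypeError(f"unknown population model {population!r}")


def asynchronous_dynamic_range(population: Asynchronous) -> tuple[float, float]:
    """Copy-number range of an asynchronous population, before G2 dilution.

    The earliest-replicating locus is replicated in every S cell and the
    latest in none, so the range is 1 to 1 + s_fraction.
    """
    return (1.0, 1.0 + population.s_fraction)


def simulate_droplets(
    concentration: float,
    n_droplets: int = DEFAULT_DROPLETS_PER_WELL,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    seed: int | np.random.Generator | None = 0,
    probe_id: str = "probe",
    sample_id: str = "sample",
    replicate_id: str = "r1",
) -> DropletCount:
    """One simulated ddPCR well at the given concentration (copies/ul).

    Template molecules Poisson-partition over droplets at occupancy
    lambda = concentration * volume, so each droplet is positive with
    probability 1 - exp(-lambda) and the positive count is binomial.
    """
    if concentration < 0 or n_droplets <= 0 or droplet_volume_nl <= 0:
        raise ValueError("concentration, n_droplets and droplet_volume_nl must be non-negative/positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam = concentration * droplet_volume_nl * 1e-3
    p = -np.expm1(-lam)
    n_positive = int(rng.binomial(n_droplets, p))
    return DropletCount(
        probe_id=probe_id,
        sample_id=sample_id,
        replicate_id=replicate_id,
        n_positive=n_positive,
        n_total=n_droplets,
        droplet_volume_nl=droplet_volume_nl,
    )


def _probe_copies(probes: Sequence[ProbeSpec] | None, probe_id: str) -> int:
    if probes is None:
        return 1
    for p in probes:
        if p.probe_id == probe_id:
            return p.copies_per_haploid
    return 1


def simulate_ddpcr_experiment(
    copy_numbers: Mapping[str, float],
    base_concentration: float = 1000.0,
    n_replicates: int = 3,
    n_droplets: int = DEFAULT_DROPLETS_PER_WELL,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    probes: Sequence[ProbeSpec] | None = None,
    sample_id: str = "sample",
    seed: int | np.random.Generator | None = 0,
) -> list[DropletCount]:
    """Independent wells for a panel of probes at known relative copy numbers.

    Each probe's target concentration is base_concentration * copy_number *
    copies_per_haploid (copies_per_haploid taken from ``probes`` when
    given). Warns when any well's occupancy leaves the quantifiable range
    (lambda > 6, approaching droplet saturation).
    """
    if any(v <= 0 for v in copy_numbers.values()):
        raise ValueError("copy numbers must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    wells = []
    for probe_id, cn in copy_numbers.items():
        conc = base_concentration * cn * _probe_copies(probes, probe_id)
        lam = conc * droplet_volume_nl * 1e-3
        if lam > 6.0:
            warnings.warn(
                f"probe {probe_id}: occupancy {lam:.2f} copies/droplet exceeds the "
                "quantifiable range; dilute the simulated sample",
                stacklevel=2,
            )
        for rep in range(1, n_replicates + 1):
            wells.append(
                simulate_droplets(
                    conc,
                    n_droplets=n_droplets,
                    droplet_volume_nl=droplet_volume_nl,
                    seed=rng,
                    probe_id=probe_id,
                    sample_id=sample_id,
                    replicate_id=f"r{rep}",
                )
            )
    return wells


def simulate_sortseq_counts(
    copy_numbers: Sequence[float],
    mean_depth: float = 1000.0,
    overdispersion: float = 1.0 / DEFAULT_NB_SIZE,
    seed: int | np.random.Generator | None = 0,
    bin_width: int = 1000,
    chrom: str = "chrS",
) -> BinnedCounts:
    """Overdispersed binned read counts for a replicating/non-replicating pair.

    Replicating-sample means are proportional to the per-bin copy number,
    non-replicating means are flat. Counts are negative-binomial with
    CV^2 = 1/mean + overdispersion; ``overdispersion`` -> 0 reduces to
    Poisson, and the default reproduces ~5% CV at 1000 reads/bin.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    cn = np.asarray(copy_numbers, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def draw(means: np.ndarray) -> np.ndarray:
        if overdispersion == 0.0:
            return rng.poisson(means)
        size = 1.0 / overdispersion
        return rng.negative_binomial(size, size / (size + means))

    rep = draw(mean_depth * cn)
    nonrep = draw(np.full_like(cn, mean_depth))
    starts = np.arange(cn.size, dtype=int) * bin_width
    return BinnedCounts(
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + bin_width,
                "rep": rep,
                "nonrep": nonrep,
            }
        )
    )


def simulate_allele_experiment(
    alleles: AlleleModel,
    population: PopulationModel,
    probes: Sequence[ProbeSpec],
    base_concentration: float = 1000.0,
    n_replicates: int = 3,
    n_droplets: int = DEFAULT_DROPLETS_PER_WELL,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    sample_id: str = "sample",
    seed: int | np.random.Generator | None = 0,
) -> list[DropletCount]:
    """ddPCR wells for allele-specific and pan-allelic probes on a diploid.

    Allele-specific probes (allele_tag "A" or "B") draw from their
    haplotype's copy number at the probe midpoint; pan-allelic probes
    (allele_tag None) sum both haplotypes. Unknown tags are an error.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    haplos = {"A": alleles.haplotype_a, "B": alleles.haplotype_b}
    wells = []
    for probe in probes:
        mid = [probe.midpoint]
        if probe.allele_tag is None:
            conc = base_concentration * sum(
                float(copy_number_profile(h, population, mid)[0]) for h in haplos.values()
            )
        elif probe.allele_tag in haplos:
            conc = base_concentration * float(
                copy_number_profile(haplos[probe.allele_tag], population, mid)[0]
            )
        else:
            raise ValueError(
                f"probe {probe.probe_id}: allele tag {probe.allele_tag!r} maps to no haplotype"
            )
        for rep in range(1, n_replicates + 1):
            wells.append(
                simulate_droplets(
                    conc,
                    n_droplets=n_droplets,
                    droplet_volume_nl=droplet_volume_nl,
                    seed=rng,
                    probe_id=probe.probe_id,
                    sample_id=sample_id,
                    replicate_id=f"r{rep}",
                )
            )
    return wells


def simulate_screen(
    baseline: ReplicationModel,
    mutants: Mapping[str, float],
    probes: Sequence[ProbeSpec],
    target_position: float,
    population: SortedS | None = None,
    base_concentration: float = 1000.0,
    n_replicates: int = 3,
    n_droplets: int = DEFAULT_DROPLETS_PER_WELL,
    seed: int | np.random.Generator | None = 0,
) -> dict[str, list[DropletCount]]:
    """Per-strain sorted-S ddPCR panels for a mutant screen.

    Each mutant delays the firing of the origin nearest ``target_position``
    by its stated delay (minutes); the wild type ("wt") is always included.
    Strains get independent sorted-S samples whose overall concentration
    scale is randomized (seeded), so downstream comparisons must use a
    dynamic-range-invariant statistic such as the replication index.
    """
    if any(d < 0 for d in mutants.values()):
        raise ValueError("delays must be >= 0")
    population = population or SortedS()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    strains = {"wt": baseline}
    for name, delay in mutants.items():
        strains[name] = baseline.with_origin_delayed(target_position, delay)
    out: dict[str, list[DropletCount]] = {}
    for name, model in strains.items():
        mids = [p.midpoint for p in probes]
        cns = copy_number_profile(model, population, mids)
        scale = float(rng.lognormal(mean=0.0, sigma=0.15))  # sample-to-sample dynamic range
        out[name] = simulate_ddpcr_experiment(
            {p.probe_id: float(c) for p, c in zip(probes, cns)},
            base_concentration=base_concentration * scale,
            n_replicates=n_replicates,
            n_droplets=n_droplets,
            probes=probes,
            sample_id=name,
            seed=rng,
        )
    return out
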