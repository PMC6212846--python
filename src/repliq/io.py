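"""File formats: droplet CSV, probe BED6+2, bedGraph pairs, flow-cytometry CSV.

All genomic coordinates are 0-based half-open (BED convention) throughout.
Numeric TSV/CSV output is written at 6 significant digits; JSON provenance
records keep full precision. No reader mutates its input file.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .copynumber import CopyNumberValue, ProbeSpec, ROLES
from .droplet import DropletCount
from .sortseq import BinnedCounts

__all__ = [
    "read_droplet_csv",
    "write_droplet_csv",
    "read_probes",
    "write_copy_number_tsv",
    "read_bedgraph_pair",
    "read_fc_csv",
    "write_provenance",
]

logger = logging.getLogger("repliq")

_DROPLET_COLUMNS = [
    "sample_id",
    "probe_id",
    "replicate_id",
    "n_positive",
    "n_total",
    "droplet_volume_nl",
]


def read_droplet_csv(path: str | Path) -> list[DropletCount]:
    """Read a droplet-count table (header required, UTF-8, decimal point)."""
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty:
        raise ValueError(f"{path}: empty droplet table")
    missing = [c for c in _DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    counts = []
    for row in df.itertuples():
        if row.n_positive > row.n_total:
            raise ValueError(
                f"{path}: n_positive > n_total for well "
                f"{row.probe_id}/{row.sample_id}/{row.replicate_id}"
            )
        counts.append(
            DropletCount(
                probe_id=str(row.probe_id),
                sample_id=str(row.sample_id),
                replicate_id=str(row.replicate_id),
                n_positive=int(row.n_positive),
                n_total=int(row.n_total),
                droplet_volume_nl=float(row.droplet_volume_nl),
            )
        )
    return counts


def write_droplet_csv(counts: Sequence[DropletCount], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "probe_id": c.probe_id,
                "replicate_id": c.replicate_id,
                "n_positive": c.n_positive,
                "n_total": c.n_total,
                "droplet_volume_nl": c.droplet_volume_nl,
            }
            for c in counts
        ]
    ).to_csv(path, index=False, encoding="utf-8")


def read_probes(path: str | Path) -> list[ProbeSpec]:
    """Read a BED6+2 probe file.

    Columns: chrom, start, end, probe_id, score (unused), strand (parsed,
    unused: copy number is strand-symmetric), copies_per_haploid,
    role-or-allele-tag. A value in the role vocabulary sets the probe role;
    anything else is taken as an allele tag on a target probe. Files
    truncated after column 4 default to copies_per_haploid = 1 (warned).
    """
    probes: list[ProbeSpec] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 tab-separated fields")
            chrom, start_s, end_s, probe_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if probe_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate probe id {probe_id!r}")
            seen.add(probe_id)
            if len(fields) >= 7 and fields[6] != "":
                try:
                    copies = int(fields[6])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: copies_per_haploid must be an integer"
                    ) from exc
            else:
                warnings.warn(
                    f"{path}:{lineno}: missing copies_per_haploid, defaulting to 1",
                    stacklevel=2,
                )
                copies = 1
            role, allele_tag = "target", None
            if len(fields) >= 8 and fields[7] != "":
                if fields[7] in ROLES:
                    role = fields[7]
                else:
                    allele_tag = fields[7]
            try:
                probes.append(
                    ProbeSpec(
                        probe_id=probe_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        copies_per_haploid=copies,
                        allele_tag=allele_tag,
                        role=role,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not probes:
        raise ValueError(f"{path}: no probe records found")
    return probes


def write_copy_number_tsv(values: Sequence[CopyNumberValue], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tvalue\tci_low\tci_high\n")
        for v in values:
            fh.write(f"{v.probe_id}\t{v.value:.6g}\t{v.ci_low:.6g}\t{v.ci_high:.6g}\n")


def _read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "count"],
        skiprows=_count_track_lines(path),
    )
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph")
    return df


def _count_track_lines(path: str | Path) -> int:
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def read_bedgraph_pair(
    rep_path: str | Path, nonrep_path: str | Path, bin_width: int | None = None
) -> BinnedCounts:
    """Read matched replicating/non-replicating bedGraphs into binned counts.

    The two files must describe identical bins; the first mismatching
    interval is named in the error. ``bin_width``, when given, is validated
    against the file contents.
    """
    rep = _read_bedgraph(rep_path)
    nonrep = _read_bedgraph(nonrep_path)
    if len(rep) != len(nonrep):
        raise ValueError(
            f"bedGraphs differ in bin count: {len(rep)} vs {len(nonrep)}"
        )
    for col in ("chrom", "start", "end"):
        neq = rep[col].to_numpy() != nonrep[col].to_numpy()
        if neq.any():
            i = int(neq.argmax())
            raise ValueError(
                "bedGraph bins mismatch at "
                f"{rep['chrom'].iloc[i]}:{rep['start'].iloc[i]}-{rep['end'].iloc[i]} vs "
                f"{nonrep['chrom'].iloc[i]}:{nonrep['start'].iloc[i]}-{nonrep['end'].iloc[i]}"
            )
    if bin_width is not None:
        widths = (rep["end"] - rep["start"]).unique()
        if len(widths) != 1 or widths[0] != bin_width:
            raise ValueError(f"expected uniform bin width {bin_width}, found {sorted(widths)}")
    return BinnedCounts(
        pd.DataFrame(
            {
                "chrom": rep["chrom"],
                "start": rep["start"],
                "end": rep["end"],
                "rep": rep["count"],
                "nonrep": nonrep["count"],
            }
        )
    )


def read_fc_csv(path: str | Path) -> pd.DataFrame:
    """Read a flow-cytometry summary table.

    Requires sample_id and time_min plus a median_signal or mean_signal
    column; when both are present the median is used (logged).
    """
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty:
        raise ValueError(f"{path}: empty flow-cytometry table")
    for col in ("sample_id", "time_min"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "median_signal" in df.columns:
        signal = "median_signal"
    elif "mean_signal" in df.columns:
        signal = "mean_signal"
    else:
        raise ValueError(f"{path}: need a median_signal or mean_signal column")
    logger.info("flow-cytometry signal column: %s", signal)
    out = df[["sample_id", "time_min", signal]].rename(columns={signal: "signal"})
    out.attrs["signal_column"] = signal
    return out


def write_provenance(path: str | Path, inputs: dict, config: dict) -> None:
    """Write the JSON provenance record every CLI run emits."""
    record = {
        "tool": "repliq",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "inputs": inputs,
        "config": config,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True), encoding="utf-8")
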