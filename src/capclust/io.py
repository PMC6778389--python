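"""Reading and writing per-bp stranded CTSS tracks.

Inputs are pairs of per-sample tracks (one per strand) holding the number of
tag 5' ends at each bp, in BigWig or bedGraph form, plus a TSV sample sheet
mapping sample ids to track paths.  Some pipelines encode minus-strand
signal as negative values; ``negative_minus=True`` accepts that dialect and
takes absolute values.

Chromosomes present in the genome but absent from a file contribute zero
signal.  Extra contigs in a file that the genome does not declare raise a
warning (and are skipped); a declared chromosome whose length disagrees with
the genome is an error.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracks import CTSSDataset, GenomeInfo, SparseTrack

logger = logging.getLogger(__name__)

#: tolerance within which a float track value is accepted as an integer count
INTEGER_TOL = 1e-6


class FormatError(ValueError):
    """Malformed track contents (negative counts, non-integers, overlaps)."""


class GenomeMismatchError(ValueError):
    """Track declares a chromosome length incompatible with the genome."""


@dataclass
class SampleRecord:
    sample_id: str
    plus_path: str
    minus_path: str
    group: str | None = None


@dataclass
class SampleSheet:
    """Sample id -> (plus track, minus track[, group]) table."""

    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample sheet")
        for s in self.samples:
            if not s.plus_path or not s.minus_path:
                raise ValueError(f"sample {s.sample_id!r} is missing a track path")

    @classmethod
    def from_file(cls, path) -> "SampleSheet":
        """Read a TSV with header ``sample<TAB>plus<TAB>minus[<TAB>group]``."""
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"sample", "plus", "minus"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(
                    f"sample sheet must have columns sample/plus/minus, got {reader.fieldnames}"
                )
            for row in reader:
                records.append(
                    SampleRecord(
                        sample_id=row["sample"],
                        plus_path=row["plus"],
                        minus_path=row["minus"],
                        group=row.get("group") or None,
                    )
                )
        if not records:
            raise ValueError(f"empty sample sheet: {path}")
        return cls(records)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def _coerce_counts(values: np.ndarray, strand: str, path, negative_minus: bool) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if negative_minus and strand == "-":
        values = np.abs(values)
    if np.any(values < 0):
        raise FormatError(f"negative value on {strand} strand track {path}")
    rounded = np.rint(values)
    if np.any(np.abs(values - rounded) > INTEGER_TOL):
        bad = values[np.abs(values - rounded) > INTEGER_TOL][0]
        raise FormatError(f"non-integer count {bad} in {path}")
    return rounded.astype(np.int64)


# ---------------------------------------------------------------------------
# BigWig


def _read_bigwig(path, strand: str, genome: GenomeInfo, negative_minus: bool) -> SparseTrack:
    import pyBigWig

    track = SparseTrack(strand)
    bw = pyBigWig.open(str(path))
    try:
        declared = bw.chroms()
        for chrom, length in declared.items():
            if chrom not in genome:
                warnings.warn(f"{path}: contig {chrom!r} not in genome, skipping")
                continue
            if int(length) != genome[chrom]:
                raise GenomeMismatchError(
                    f"{path}: {chrom} length {length} != genome length {genome[chrom]}"
                )
        for chrom in genome:
            if chrom not in declared:
                continue
            ivals = bw.intervals(chrom)
            if not ivals:
                continue
            pos_parts, val_parts = [], []
            for start, end, value in ivals:
                if value == 0:
                    continue
                pos_parts.append(np.arange(start, end, dtype=np.int64))
                val_parts.append(np.full(end - start, value))
            if not pos_parts:
                continue
            pos = np.concatenate(pos_parts)
            val = _coerce_counts(np.concatenate(val_parts), strand, path, negative_minus)
            track._set(chrom, pos, val)
    finally:
        bw.close()
    track.validate_genome(genome)
    return track


def read_ctss_bigwig_pair(
    plus_path, minus_path, genome: GenomeInfo, negative_minus: bool = False
) -> tuple[SparseTrack, SparseTrack]:
    """Read one sample's (plus, minus) BigWig pair into sparse count tracks.

    Run-length BigWig intervals are expanded so every nonzero bp becomes one
    entry; values must be non-negative integers (within ``INTEGER_TOL``).
    """
    plus = _read_bigwig(plus_path, "+", genome, negative_minus)
    minus = _read_bigwig(minus_path, "-", genome, negative_minus)
    return plus, minus


# ---------------------------------------------------------------------------
# bedGraph


def _read_bedgraph(path, strand: str, genome: GenomeInfo, negative_minus: bool) -> SparseTrack:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if end <= start:
                raise FormatError(f"{path}:{ln}: empty or inverted interval")
            if chrom not in genome:
                warnings.warn(f"{path}: contig {chrom!r} not in genome, skipping")
                continue
            by_chrom.setdefault(chrom, []).append((start, end, value))
    track = SparseTrack(strand)
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        prev_end = -1
        for start, end, _ in ivals:
            if start < prev_end:
                raise FormatError(f"{path}: overlapping bedGraph intervals on {chrom}")
            prev_end = end
        pos_parts, val_parts = [], []
        for start, end, value in ivals:
            if value == 0:
                continue
            pos_parts.append(np.arange(start, end, dtype=np.int64))
            val_parts.append(np.full(end - start, value))
        if not pos_parts:
            continue
        pos = np.concatenate(pos_parts)
        val = _coerce_counts(np.concatenate(val_parts), strand, path, negative_minus)
        track._set(chrom, pos, val)
    track.validate_genome(genome)
    return track


def read_ctss_bedgraph_pair(
    plus_path, minus_path, genome: GenomeInfo, negative_minus: bool = False
) -> tuple[SparseTrack, SparseTrack]:
    """bedGraph fallback for :func:`read_ctss_bigwig_pair` (0-based half-open)."""
    plus = _read_bedgraph(plus_path, "+", genome, negative_minus)
    minus = _read_bedgraph(minus_path, "-", genome, negative_minus)
    return plus, minus


# ---------------------------------------------------------------------------
# Writing


def _run_length(pos: np.ndarray, val: np.ndarray):
    """Merge adjacent equal-valued bps into (start, end, value) runs."""
    runs = []
    i = 0
    n = pos.size
    while i < n:
        j = i + 1
        while j < n and pos[j] == pos[j - 1] + 1 and val[j] == val[i]:
            j += 1
        runs.append((int(pos[i]), int(pos[j - 1]) + 1, val[i]))
        i = j
    return runs


def write_track(track: SparseTrack, path, genome: GenomeInfo, format: str = "bedgraph") -> None:
    """Write a sparse track as bedGraph or BigWig, run-length merged.

    Integer counts round-trip bit-exactly; float (TPM/pooled) values are
    written with six decimals in bedGraph.
    """
    track.validate_genome(genome)
    chroms = [c for c in genome if c in track.chroms]
    if format == "bedgraph":
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{getattr(track, "strand", ".")}"\n')
            for chrom in chroms:
                pos, val = track.arrays(chrom)
                for start, end, value in _run_length(pos, val):
                    if float(value).is_integer():
                        fh.write(f"{chrom}\t{start}\t{end}\t{int(value)}\n")
                    else:
                        fh.write(f"{chrom}\t{start}\t{end}\t{value:.6f}\n")
    elif format == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(str(path), "w")
        try:
            bw.addHeader(list(genome.items()))
            for chrom in chroms:
                pos, val = track.arrays(chrom)
                runs = _run_length(pos, val)
                bw.addEntries(
                    [chrom] * len(runs),
                    [s for s, _, _ in runs],
                    ends=[e for _, e, _ in runs],
                    values=[float(v) for _, _, v in runs],
                )
        finally:
            bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")


# ---------------------------------------------------------------------------
# Dataset assembly


def _reader_for(path):
    p = str(path).lower()
    if p.endswith((".bw", ".bigwig")):
        return _read_bigwig
    return _read_bedgraph


def assemble_dataset(
    sheet: SampleSheet, genome: GenomeInfo, negative_minus: bool = False
) -> CTSSDataset:
    """Load every sample's track pair and return a validated dataset.

    Per-sample total tag counts (library sizes) are logged at INFO level.
    The file format is chosen per path by extension (.bw/.bigwig vs text
    bedGraph), so mixed sheets are allowed.
    """
    plus_tracks: dict[str, SparseTrack] = {}
    minus_tracks: dict[str, SparseTrack] = {}
    for rec in sheet.samples:
        plus_tracks[rec.sample_id] = _reader_for(rec.plus_path)(
            rec.plus_path, "+", genome, negative_minus
        )
        minus_tracks[rec.sample_id] = _reader_for(rec.minus_path)(
            rec.minus_path, "-", genome, negative_minus
        )
        total = plus_tracks[rec.sample_id].total() + minus_tracks[rec.sample_id].total()
        logger.info("sample %s: %d tags", rec.sample_id, int(total))
    groups = {s.sample_id: s.group for s in sheet.samples if s.group}
    return CTSSDataset(genome, sheet.sample_ids, plus_tracks, minus_tracks, groups=groups)
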