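"""Sparse genomic signal containers.

5'-end assays (CAGE, PRO-Cap and relatives) reduce each sequenced tag to the
single base pair where its 5' end maps, per strand.  The resulting per-bp
count tracks are extremely sparse: most of the genome carries no signal, and
only a small fraction of covered positions carry many tags.  The containers
here store only the nonzero positions, so memory scales with the number of
CTSSs (CAGE-defined TSSs), never with genome length.

Coordinates are 0-based, half-open throughout (the BigWig/BED convention);
a CTSS is a width-1 interval addressed by its start.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class GenomeInfo:
    """Ordered mapping of sequence name -> length in bp.

    Every position referenced by any track must lie in ``[0, length)`` of
    its sequence; readers and writers validate against this.
    """

    def __init__(self, sizes: Mapping[str, int]):
        names = list(sizes)
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names in genome")
        for name, length in sizes.items():
            if int(length) <= 0:
                raise ValueError(f"non-positive length for sequence {name!r}")
        self._sizes = {str(n): int(l) for n, l in sizes.items()}

    @classmethod
    def from_file(cls, path) -> "GenomeInfo":
        """Read a two-column chrom-sizes text file (name<TAB>length)."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"malformed chrom-sizes line: {line!r}")
                if fields[0] in sizes:
                    raise ValueError(f"duplicate sequence name: {fields[0]!r}")
                sizes[fields[0]] = int(fields[1])
        if not sizes:
            raise ValueError(f"empty chrom-sizes file: {path}")
        return cls(sizes)

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeInfo) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    def __repr__(self) -> str:
        return f"GenomeInfo({self._sizes!r})"


class SparseTrack:
    """Per-strand sparse per-bp signal: sequence -> (positions, values).

    Positions are strictly increasing int64 arrays; values are positive
    (zero entries are never stored).  Used both for raw integer tag counts
    and for float-valued TPM / pooled signal.
    """

    def __init__(self, strand: str, data: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        if strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        self.strand = strand
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (pos, val) in data.items():
                self._set(chrom, np.asarray(pos), np.asarray(val))

    def _set(self, chrom: str, pos: np.ndarray, val: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=np.int64)
        val = np.asarray(val)
        if pos.shape != val.shape:
            raise ValueError("positions and values differ in length")
        if pos.size == 0:
            return
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        if np.any(np.diff(pos) == 0):
            raise ValueError(f"duplicate positions on {chrom}")
        keep = val != 0
        pos, val = pos[keep], val[keep]
        if np.any(val < 0):
            raise ValueError(f"negative signal values on {chrom}")
        if pos.size:
            self._data[chrom] = (pos, val)

    @classmethod
    def from_entries(cls, strand: str, entries: Mapping[tuple[str, int], float]) -> "SparseTrack":
        """Build from a {(chrom, position): value} mapping (mainly for tests)."""
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for (chrom, pos), val in entries.items():
            by_chrom.setdefault(chrom, []).append((pos, val))
        track = cls(strand)
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            val = np.array([v for _, v in pairs])
            track._set(chrom, pos, val)
        return track

    # -- introspection ----------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @property
    def n_entries(self) -> int:
        return sum(pos.size for pos, _ in self._data.values())

    def total(self) -> float:
        return float(sum(val.sum() for _, val in self._data.values()))

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, values) for one sequence; empty arrays if absent."""
        if chrom in self._data:
            return self._data[chrom]
        return np.empty(0, dtype=np.int64), np.empty(0)

    def entries(self) -> Iterator[tuple[str, int, float]]:
        for chrom, (pos, val) in self._data.items():
            for p, v in zip(pos.tolist(), val.tolist()):
                yield chrom, p, v

    def to_dict(self) -> dict[tuple[str, int], float]:
        return {(c, p): v for c, p, v in self.entries()}

    # -- arithmetic -------------------------------------------------------

    def scale(self, factor: float) -> "SparseTrack":
        out = SparseTrack(self.strand)
        for chrom, (pos, val) in self._data.items():
            out._data[chrom] = (pos.copy(), val * factor)
        return out

    def range_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of values at positions in [start, end)."""
        pos, val = self.arrays(chrom)
        if pos.size == 0:
            return 0.0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return float(val[lo:hi].sum())

    def filter_positions(self, keep: Mapping[str, np.ndarray]) -> "SparseTrack":
        """Restrict to positions present in ``keep`` (per-chrom sorted arrays)."""
        out = SparseTrack(self.strand)
        for chrom, (pos, val) in self._data.items():
            kp = keep.get(chrom)
            if kp is None or len(kp) == 0:
                continue
            mask = np.isin(pos, kp, assume_unique=True)
            if mask.any():
                out._data[chrom] = (pos[mask], val[mask])
        return out

    @staticmethod
    def sum_tracks(tracks: Iterable["SparseTrack"]) -> "SparseTrack":
        """Positionwise sum of same-strand tracks (used for pooling)."""
        tracks = list(tracks)
        strands = {t.strand for t in tracks}
        if len(strands) != 1:
            raise ValueError("cannot sum tracks from different strands")
        out = SparseTrack(strands.pop())
        chroms = sorted({c for t in tracks for c in t.chroms})
        for chrom in chroms:
            parts = [t.arrays(chrom) for t in tracks if chrom in t._data]
            allpos = np.concatenate([p for p, _ in parts])
            allval = np.concatenate([v for _, v in parts])
            upos, inverse = np.unique(allpos, return_inverse=True)
            summed = np.zeros(upos.size, dtype=allval.dtype if allval.dtype.kind == "f" else np.float64)
            np.add.at(summed, inverse, allval)
            out._data[chrom] = (upos, summed)
        return out

    def validate_genome(self, genome: GenomeInfo) -> None:
        for chrom, (pos, _) in self._data.items():
            if chrom not in genome:
                raise ValueError(f"track sequence {chrom!r} absent from genome")
            if pos.size and (pos[0] < 0 or pos[-1] >= genome[chrom]):
                raise ValueError(
                    f"position out of bounds on {chrom}: [{pos[0]}, {pos[-1]}] vs length {genome[chrom]}"
                )

    def __repr__(self) -> str:
        return f"SparseTrack(strand={self.strand!r}, n_entries={self.n_entries})"


class CTSSDataset:
    """Multi-sample CTSS collection: one plus and one minus track per sample.

    All tracks share one :class:`GenomeInfo`; the sample order is fixed at
    construction and reused by every downstream expression matrix.
    """

    def __init__(
        self,
        genome: GenomeInfo,
        sample_ids: list[str],
        plus: Mapping[str, SparseTrack],
        minus: Mapping[str, SparseTrack],
        groups: Mapping[str, str] | None = None,
        is_tpm: bool = False,
        library_sizes: Mapping[str, float] | None = None,
    ):
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        for sid in sample_ids:
            if sid not in plus or sid not in minus:
                raise ValueError(f"missing track(s) for sample {sid!r}")
            if plus[sid].strand != "+" or minus[sid].strand != "-":
                raise ValueError(f"strand mismatch in tracks for sample {sid!r}")
            plus[sid].validate_genome(genome)
            minus[sid].validate_genome(genome)
        self.genome = genome
        self.sample_ids = list(sample_ids)
        self.plus = dict(plus)
        self.minus = dict(minus)
        self.groups = dict(groups) if groups else {}
        self.is_tpm = is_tpm
        #: raw per-sample tag totals; carried through TPM normalization so
        #: count-scale quantities remain recoverable.
        self.library_sizes = dict(library_sizes) if library_sizes else None

    def track(self, sample_id: str, strand: str) -> SparseTrack:
        if strand == "+":
            return self.plus[sample_id]
        if strand == "-":
            return self.minus[sample_id]
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_total(self, sample_id: str) -> float:
        return self.plus[sample_id].total() + self.minus[sample_id].total()

    def __repr__(self) -> str:
        return (
            f"CTSSDataset(n_samples={self.n_samples}, "
            f"genome={len(self.genome)} sequences, is_tpm={self.is_tpm})"
        )


class PooledTrack:
    """Per-strand pooled signal: sum of per-sample TPM at each bp.

    Without sample-support filtering, the grand total over both strands is
    ``n_samples * 1e6`` (each sample's TPM sums to one million).
    """

    def __init__(self, plus: SparseTrack, minus: SparseTrack, n_samples: int, genome: GenomeInfo):
        if plus.strand != "+" or minus.strand != "-":
            raise ValueError("pooled tracks must be ('+', '-')")
        plus.validate_genome(genome)
        minus.validate_genome(genome)
        self.plus = plus
        self.minus = minus
        self.n_samples = int(n_samples)
        self.genome = genome

    def strand_track(self, strand: str) -> SparseTrack:
        return self.plus if strand == "+" else self.minus

    def total(self) -> float:
        return self.plus.total() + self.minus.total()

    def __repr__(self) -> str:
        return (
            f"PooledTrack(n_samples={self.n_samples}, "
            f"entries=({self.plus.n_entries}+, {self.minus.n_entries}-))"
        )
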