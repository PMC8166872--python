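"""Alignment ingestion, feature counting and per-base coverage.

Alignments (SAM/BAM via pysam) are loaded once into an in-memory
:class:`AlignmentStore` holding read-level metadata and the aligned
blocks of every segment. Two counting policies are provided:

``pcg``
    reads assigned to a feature only at mapping quality >= the
    threshold (default 10); a fragment (read name) counts once per
    feature it overlaps.
``trna``
    no mapping-quality filter, so multi-mapped records are counted;
    a fragment still counts once per feature.

Per-base coverage applies no quality filter and counts every aligned
segment block, so spliced or clipped alignments contribute only where
bases were actually aligned.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pysam

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 10


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned segment: blocks are the aligned pieces after CIGAR."""

    read_id: str
    interval: GenomicInterval
    mapq: int
    hit_count: int = 1
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq out of range: {self.mapq}")
        if self.hit_count < 1:
            raise ValueError(f"hit_count must be >= 1: {self.hit_count}")


@dataclass
class CoverageTrack:
    """Per-base read coverage over a region."""

    region: GenomicInterval
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.region.length,):
            raise ValueError("counts length must equal region length")
        if (self.counts < 0).any():
            raise ValueError("negative coverage")

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if other.region != self.region:
            raise ValueError("cannot add tracks over different regions")
        return CoverageTrack(self.region, self.counts + other.counts)


@dataclass(frozen=True)
class ReplicateGroup:
    """A biological group (tissue / sub-region) with one alignment source
    per replicate."""

    group_id: str
    replicate_ids: tuple[str, ...]
    alignment_sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_ids) != len(self.alignment_sources):
            raise ValueError("one alignment source per replicate required")
        if len(self.replicate_ids) < 1:
            raise ValueError("at least one replicate required")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)


class _ChromIndex:
    """Block and read arrays for one chromosome."""

    __slots__ = ("block_start", "block_end", "block_read",
                 "read_qname", "read_mapq")

    def __init__(self, records: list[tuple[str, int, int, int]],
                 blocks: list[tuple[int, int, int]]) -> None:
        self.read_qname = np.array([r[0] for r in records], dtype=object)
        self.read_mapq = np.array([r[1] for r in records], dtype=np.int64)
        self.block_start = np.array([b[0] for b in blocks], dtype=np.int64)
        self.block_end = np.array([b[1] for b in blocks], dtype=np.int64)
        self.block_read = np.array([b[2] for b in blocks], dtype=np.int64)


class AlignmentStore:
    """All mapped segments of one SAM/BAM file, indexed by chromosome."""

    def __init__(self, chroms: Mapping[str, _ChromIndex], n_records: int,
                 source: str = "<memory>") -> None:
        self._chroms = dict(chroms)
        self.n_records = n_records
        self.source = source

    @classmethod
    def from_path(cls, path: Union[str, Path]) -> "AlignmentStore":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"alignment source not found: {path}")
        mode = "rb" if path.suffix == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            return cls._from_segments(fh, str(path))

    @classmethod
    def from_records(cls, records: Iterable[AlignmentRecord],
                     source: str = "<memory>") -> "AlignmentStore":
        per_chrom_reads: dict[str, list[tuple[str, int, int, int]]] = {}
        per_chrom_blocks: dict[str, list[tuple[int, int, int]]] = {}
        n = 0
        for rec in records:
            chrom = rec.interval.chrom
            reads = per_chrom_reads.setdefault(chrom, [])
            blocks = per_chrom_blocks.setdefault(chrom, [])
            idx = len(reads)
            reads.append((rec.read_id, rec.mapq, rec.interval.start, rec.interval.end))
            for s, e in (rec.blocks or ((rec.interval.start, rec.interval.end),)):
                blocks.append((s, e, idx))
            n += 1
        chroms = {
            c: _ChromIndex(per_chrom_reads[c], per_chrom_blocks[c])
            for c in per_chrom_reads
        }
        return cls(chroms, n, source)

    @classmethod
    def _from_segments(cls, fh: pysam.AlignmentFile, source: str) -> "AlignmentStore":
        per_chrom_reads: dict[str, list[tuple[str, int, int, int]]] = {}
        per_chrom_blocks: dict[str, list[tuple[int, int, int]]] = {}
        n = 0
        for seg in fh:
            if seg.is_unmapped or seg.reference_name is None:
                continue
            chrom = seg.reference_name
            reads = per_chrom_reads.setdefault(chrom, [])
            blocks = per_chrom_blocks.setdefault(chrom, [])
            idx = len(reads)
            reads.append((seg.query_name, seg.mapping_quality,
                          seg.reference_start, seg.reference_end or seg.reference_start))
            segment_blocks = seg.get_blocks() or [
                (seg.reference_start, seg.reference_end or seg.reference_start)
            ]
            for s, e in segment_blocks:
                blocks.append((s, e, idx))
            n += 1
        chroms = {
            c: _ChromIndex(per_chrom_reads[c], per_chrom_blocks[c])
            for c in per_chrom_reads
        }
        return cls(chroms, n, source)

    # -- queries ---------------------------------------------------------

    def _overlapping_reads(self, region: GenomicInterval) -> np.ndarray:
        """Indices of reads with >=1 aligned block overlapping the region."""
        ci = self._chroms.get(region.chrom)
        if ci is None:
            return np.empty(0, dtype=np.int64)
        mask = (ci.block_start < region.end) & (ci.block_end > region.start)
        return np.unique(ci.block_read[mask])

    def count_overlapping_fragments(
        self, region: GenomicInterval, mapq_min: int = 0
    ) -> int:
        """Distinct read names with an aligned block in the region."""
        ci = self._chroms.get(region.chrom)
        if ci is None:
            return 0
        idx = self._overlapping_reads(region)
        if mapq_min > 0:
            idx = idx[ci.read_mapq[idx] >= mapq_min]
        return len(set(ci.read_qname[idx]))

    def coverage(self, region: GenomicInterval) -> CoverageTrack:
        """Per-base segment coverage over the region (no mapq filter)."""
        n = region.length
        if n == 0:
            return CoverageTrack(region, np.zeros(0, dtype=np.int64))
        ci = self._chroms.get(region.chrom)
        diff = np.zeros(n + 1, dtype=np.int64)
        if ci is not None:
            mask = (ci.block_start < region.end) & (ci.block_end > region.start)
            starts = np.clip(ci.block_start[mask] - region.start, 0, n)
            ends = np.clip(ci.block_end[mask] - region.start, 0, n)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        return CoverageTrack(region, np.cumsum(diff[:-1]))


def count_feature_reads(
    store: AlignmentStore,
    features: Mapping[str, GenomicInterval],
    policy: str,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> dict[str, int]:
    """Raw fragment counts per feature under one counting policy.

    ``policy='pcg'`` applies the mapping-quality threshold; ``policy='trna'``
    counts all records including multi-mapped ones. Features on
    chromosomes absent from the alignments count 0 with a warning.
    """
    if policy not in ("pcg", "trna"):
        raise ValueError(f"unknown counting policy {policy!r}")
    threshold = mapq_min if policy == "pcg" else 0
    counts: dict[str, int] = {}
    for fid, region in features.items():
        if region.chrom not in store._chroms:
            logger.warning(
                "feature %s on chromosome %s absent from %s; count 0",
                fid, region.chrom, store.source,
            )
            counts[fid] = 0
            continue
        counts[fid] = store.count_overlapping_fragments(region, threshold)
    return counts


def per_base_coverage(store: AlignmentStore, region: GenomicInterval) -> CoverageTrack:
    """Coverage track over a region; empty regions yield empty tracks."""
    return store.coverage(region)


def merged_coverage(
    stores: Sequence[AlignmentStore], region: GenomicInterval
) -> CoverageTrack:
    """Total coverage over the region summed across replicate stores."""
    track = CoverageTrack(region, np.zeros(region.length, dtype=np.int64))
    for store in stores:
        track = track + store.coverage(region)
    return track


def mean_region_coverage(track: CoverageTrack) -> float:
    """Arithmetic mean reads/base; undefined (error) for empty regions."""
    if track.region.length == 0:
        raise ValueError(
            f"mean coverage undefined for empty region {track.region!r}"
        )
    return float(track.counts.mean())


def write_bedgraph(track: CoverageTrack, handle: TextIO) -> None:
    """Write a coverage track as bedGraph (runs of equal coverage)."""
    region = track.region
    counts = track.counts
    if len(counts) == 0:
        return
    change = np.flatnonzero(np.diff(counts)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(counts)]))
    for s, e in zip(starts, ends):
        handle.write(
            f"{region.chrom}\t{region.start + s}\t{region.start + e}\t{counts[s]}\n"
        )


def write_count_matrix(
    counts_by_sample: Mapping[str, Mapping[str, int]], handle: TextIO
) -> None:
    """Write a feature x sample TSV of raw counts."""
    samples = list(counts_by_sample)
    features = sorted({f for c in counts_by_sample.values() for f in c})
    handle.write("feature\t" + "\t".join(samples) + "\n")
    for f in features:
        row = "\t".join(str(counts_by_sample[s].get(f, 0)) for s in samples)
        handle.write(f"{f}\t{row}\n")
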