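from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from dirtseq.coverage_engine import AlignmentRecord, AlignmentStore
from dirtseq.genome_model import ProteinCodingGene, TrnaGene
from dirtseq.intervals import GenomicInterval


def sam_text(refs: dict[str, int], records: list[tuple]) -> str:
    """Minimal SAM: records are (qname, chrom, start0, cigar, mapq, nh)."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in refs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for qname, chrom, start0, cigar, mapq, nh in records:
        lines.append(
            f"{qname}\t0\t{chrom}\t{start0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*\tNH:i:{nh}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def make_sam(tmp_path):
    """Write a SAM file and return its path."""
    counter = {"n": 0}

    def _make(refs: dict[str, int], records: list[tuple], name: str | None = None) -> Path:
        counter["n"] += 1
        path = tmp_path / (name or f"reads{counter['n']}.sam")
        path.write_text(sam_text(refs, records))
        return path

    return _make


def mk_gene(gene_id: str, chrom: str, exons: list[tuple[int, int]],
            strand: str = "+") -> ProteinCodingGene:
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons))
    span = GenomicInterval(chrom, ivs[0].start, ivs[-1].end, strand)
    return ProteinCodingGene(gene_id, span, ivs)


def mk_trna(trna_id: str, chrom: str, start: int, end: int) -> TrnaGene:
    return TrnaGene.from_name(trna_id, GenomicInterval(chrom, start, end, "+"))


def region_reads(region: GenomicInterval, n: int, prefix: str) -> list[AlignmentRecord]:
    """n records, each spanning the whole region."""
    return [
        AlignmentRecord(f"{prefix}{i}", region, mapq=60)
        for i in range(n)
    ]


def store_from(records) -> AlignmentStore:
    return AlignmentStore.from_records(records)


def brute_force_coverage(blocks: list[tuple[int, int]],
                         region: GenomicInterval) -> np.ndarray:
    """Independent per-base interval-stabbing oracle."""
    out = np.zeros(region.length, dtype=np.int64)
    for i in range(region.length):
        base = region.start + i
        out[i] = sum(1 for s, e in blocks if s <= base < e)
    return out


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH by direct definition: sort, p*m/rank, cumulative min."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for k in range(m - 1, -1, -1):
        running = min(running, p[order[k]] * m / (k + 1))
        q_sorted[k] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out
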