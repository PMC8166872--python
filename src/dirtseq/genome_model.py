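"""Gene models, tRNA annotations and tRNA/protein-coding-gene pairing.

Reads protein-coding gene models from GFF3 (Ensembl Plants dialect) and
tRNA loci from BED6 with GtRNAdb-style names, derives introns, and
assembles candidate tRNA-PCG pairs: for every tRNA that does not overlap
any gene span, up to two pairs (the nearest gene on each side), together
with the intergenic interval and the one or two gene introns closest to
it. Pairing ignores strand.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

TRNA_NAME_RE = re.compile(
    r"^tRNA-(?P<aa>[A-Za-z]{2,4})-(?P<anticodon>[ACGTN]{3})"
    r"-(?P<family>\d+)-(?P<copy>\d+)$"
)

#: orientation labels, tRNA position relative to the protein-coding gene
TRNA_UPSTREAM = "tRNA-upstream"
TRNA_DOWNSTREAM = "tRNA-downstream"


class GffParseError(ValueError):
    """Record-level GFF3 failure; message carries the offending line."""


@dataclass(frozen=True)
class TrnaGene:
    """A tRNA locus with identity parsed from its GtRNAdb-style name."""

    trna_id: str
    interval: GenomicInterval
    amino_acid: str = "Und"
    anticodon: str = "NNN"
    isodecoder_family: int = 0
    gene_copy: int = 0

    @property
    def undefined_flag(self) -> bool:
        return self.amino_acid == "Und"

    @classmethod
    def from_name(cls, name: str, interval: GenomicInterval) -> "TrnaGene":
        """Parse ``tRNA-<AA>-<anticodon>-<family>-<copy>``.

        Names that do not match the scheme are kept verbatim with the
        undefined amino-acid code.
        """
        m = TRNA_NAME_RE.match(name)
        if m is None:
            return cls(trna_id=name, interval=interval)
        return cls(
            trna_id=name,
            interval=interval,
            amino_acid=m["aa"],
            anticodon=m["anticodon"],
            isodecoder_family=int(m["family"]),
            gene_copy=int(m["copy"]),
        )


@dataclass(frozen=True)
class ProteinCodingGene:
    """A protein-coding gene spanning 5'UTR through 3'UTR.

    ``exons`` belong to the canonical (longest) transcript, sorted and
    non-overlapping; ``interval`` spans first exon start to last exon end.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
        if (
            self.interval.start != self.exons[0].start
            or self.interval.end != self.exons[-1].end
        ):
            raise ValueError(f"{self.gene_id}: interval does not match exon span")


@dataclass(frozen=True)
class TrnaPcgPair:
    """A tRNA and an adjacent protein-coding gene with the gap between them."""

    trna: TrnaGene
    pcg: ProteinCodingGene
    orientation: str  # TRNA_UPSTREAM or TRNA_DOWNSTREAM
    intergenic: GenomicInterval
    introns_by_proximity: tuple[GenomicInterval, ...] = ()
    tie_flagged: bool = False

    @property
    def distance(self) -> int:
        return self.intergenic.length

    @property
    def pair_id(self) -> str:
        return f"{self.trna.trna_id}|{self.pcg.gene_id}"


def _parse_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _strip_prefix(feature_id: str) -> str:
    for prefix in ("gene:", "mRNA:", "transcript:", "CDS:"):
        if feature_id.startswith(prefix):
            return feature_id[len(prefix):]
    return feature_id


def parse_gene_models(stream: Iterable[str]) -> list[ProteinCodingGene]:
    """Read protein-coding genes from a GFF3 stream.

    One gene per ``gene`` record, carrying the exons of its canonical
    transcript (the longest mRNA by genomic span; ties resolved toward the
    lexicographically smaller transcript id). GFF3 1-based inclusive
    coordinates are converted to 0-based half-open. Genes without any
    exon-bearing transcript are skipped with a warning; exons whose Parent
    is unknown are skipped with a warning; a record with end < start
    raises :class:`GffParseError` naming the line.
    """
    genes: dict[str, tuple[str, int, int, str]] = {}  # id -> (chrom, s, e, strand)
    mrnas: dict[str, tuple[str, int, int]] = {}  # mRNA id -> (gene id, s, e)
    exons: dict[str, list[tuple[int, int]]] = {}  # mRNA id -> [(s, e)]
    order: list[str] = []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GffParseError(f"line {lineno}: expected 9 columns: {line!r}")
        chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GffParseError(f"line {lineno}: non-integer coordinate: {line!r}") from exc
        if end1 < start1:
            raise GffParseError(f"line {lineno}: end < start: {line!r}")
        start, end = start1 - 1, end1  # to 0-based half-open
        attributes = _parse_attributes(attrs)
        if ftype == "gene":
            gid = attributes.get("ID", f"gene-{lineno}")
            genes[gid] = (chrom, start, end, strand if strand in "+-" else ".")
            order.append(gid)
        elif ftype in ("mRNA", "transcript"):
            parent = attributes.get("Parent", "")
            tid = attributes.get("ID", f"mRNA-{lineno}")
            if parent not in genes:
                logger.warning("line %d: %s with unknown Parent %r skipped", lineno, ftype, parent)
                continue
            mrnas[tid] = (parent, start, end)
        elif ftype == "exon":
            parent = attributes.get("Parent", "")
            # exons may list several parent transcripts
            known = [p for p in parent.split(",") if p in mrnas]
            if not known:
                logger.warning("line %d: exon with unknown Parent %r skipped", lineno, parent)
                continue
            for p in known:
                exons.setdefault(p, []).append((start, end))

    out: list[ProteinCodingGene] = []
    by_gene: dict[str, list[str]] = {}
    for tid, (gid, _s, _e) in mrnas.items():
        by_gene.setdefault(gid, []).append(tid)

    for gid in order:
        chrom, _gs, _ge, strand = genes[gid]
        candidates = [t for t in by_gene.get(gid, []) if exons.get(t)]
        if not candidates:
            logger.warning("gene %s has no exon-bearing transcript; skipped", gid)
            continue
        # canonical transcript: longest genomic span, ties toward smaller id
        canonical = min(
            candidates,
            key=lambda t: (-(mrnas[t][2] - mrnas[t][1]), t),
        )
        merged = _merge_blocks(sorted(exons[canonical]))
        exon_ivs = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in merged
        )
        span = GenomicInterval(chrom, exon_ivs[0].start, exon_ivs[-1].end, strand)
        out.append(ProteinCodingGene(_strip_prefix(gid), span, exon_ivs))
    return out


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def parse_trna_annotations(stream: Iterable[str]) -> list[TrnaGene]:
    """Read tRNA loci from a BED6 stream (0-based half-open, as-is)."""
    out: list[TrnaGene] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ValueError(f"BED line {lineno}: need >= 4 columns: {line!r}")
        chrom, start_s, end_s, name = cols[:4]
        strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "."
        iv = GenomicInterval(chrom, int(start_s), int(end_s), strand)
        out.append(TrnaGene.from_name(name, iv))
    return out


def derive_introns(pcg: ProteinCodingGene) -> list[GenomicInterval]:
    """Introns = gaps between consecutive exons, in genomic order."""
    return [
        GenomicInterval(pcg.interval.chrom, a.end, b.start, pcg.interval.strand)
        for a, b in zip(pcg.exons, pcg.exons[1:])
        if b.start > a.end
    ]


def _introns_by_proximity(
    pcg: ProteinCodingGene, orientation: str, limit: int = 2
) -> tuple[GenomicInterval, ...]:
    introns = derive_introns(pcg)
    if orientation == TRNA_DOWNSTREAM:
        # gene lies left of the tRNA; the gap abuts the gene end, so the
        # last intron is nearest
        introns = introns[::-1]
    return tuple(introns[:limit])


def assemble_pairs(
    trnas: Iterable[TrnaGene],
    pcgs: Iterable[ProteinCodingGene],
    max_distance: Optional[int] = None,
) -> list[TrnaPcgPair]:
    """Pair each tRNA with its nearest gene on each side of the genome.

    tRNAs overlapping any gene span (UTRs and introns included) are
    excluded entirely. Equidistant genes on one side are resolved toward
    the smaller start coordinate and the pair is tie-flagged. Pairs whose
    intergenic distance exceeds ``max_distance`` are dropped
    (``None`` = unlimited). Strand is ignored throughout.
    """
    trnas = list(trnas)
    by_chrom: dict[str, list[ProteinCodingGene]] = {}
    for pcg in pcgs:
        by_chrom.setdefault(pcg.interval.chrom, []).append(pcg)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))

    pairs: list[TrnaPcgPair] = []
    for trna in trnas:
        chrom_pcgs = by_chrom.get(trna.interval.chrom)
        if not chrom_pcgs:
            logger.info(
                "tRNA %s on chromosome %s absent from gene models; no pair",
                trna.trna_id, trna.interval.chrom,
            )
            continue
        if any(trna.interval.overlaps(g.interval) for g in chrom_pcgs):
            continue
        for side in ("left", "right"):
            pair = _nearest_side(trna, chrom_pcgs, side)
            if pair is None:
                continue
            if max_distance is not None and pair.distance > max_distance:
                continue
            pairs.append(pair)
    pairs.sort(key=lambda p: (p.intergenic.chrom, p.intergenic.start, p.pair_id))
    return pairs


def _nearest_side(
    trna: TrnaGene, chrom_pcgs: list[ProteinCodingGene], side: str
) -> Optional[TrnaPcgPair]:
    iv = trna.interval
    if side == "left":
        candidates = [g for g in chrom_pcgs if g.interval.end <= iv.start]
        if not candidates:
            return None
        best_gap = min(iv.start - g.interval.end for g in candidates)
        tied = [g for g in candidates if iv.start - g.interval.end == best_gap]
    else:
        candidates = [g for g in chrom_pcgs if g.interval.start >= iv.end]
        if not candidates:
            return None
        best_gap = min(g.interval.start - iv.end for g in candidates)
        tied = [g for g in candidates if g.interval.start - iv.end == best_gap]

    tie_flagged = len(tied) > 1
    pcg = min(tied, key=lambda g: (g.interval.start, g.gene_id))
    if tie_flagged:
        logger.warning(
            "tRNA %s: equidistant genes on %s side; choosing %s",
            trna.trna_id, side, pcg.gene_id,
        )
    if side == "left":
        orientation = TRNA_DOWNSTREAM
        intergenic = GenomicInterval(iv.chrom, pcg.interval.end, iv.start)
    else:
        orientation = TRNA_UPSTREAM
        intergenic = GenomicInterval(iv.chrom, iv.end, pcg.interval.start)
    return TrnaPcgPair(
        trna=trna,
        pcg=pcg,
        orientation=orientation,
        intergenic=intergenic,
        introns_by_proximity=_introns_by_proximity(pcg, orientation),
        tie_flagged=tie_flagged,
    )


PAIR_TABLE_COLUMNS = (
    "trna_id", "gene_id", "chrom", "orientation",
    "intergenic_start", "intergenic_end", "distance",
)


def write_pair_table(pairs: Iterable[TrnaPcgPair], handle: TextIO) -> None:
    """Write candidate pairs as TSV."""
    handle.write("\t".join(PAIR_TABLE_COLUMNS) + "\n")
    for p in pairs:
        handle.write(
            "\t".join(
                str(x)
                for x in (
                    p.trna.trna_id, p.pcg.gene_id, p.intergenic.chrom,
                    p.orientation, p.intergenic.start, p.intergenic.end,
                    p.distance,
                )
            )
            + "\n"
        )
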