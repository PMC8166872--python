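"""Synthetic dataset generator for the detector.

Lays out tRNA/protein-coding-gene loci (one locus per synthetic
chromosome so pairing is unambiguous), plants a configurable fraction of
them as dicistronic, and emits already-aligned single-end reads as
coordinate-sorted SAM, plus GFF3 gene models, a BED6 tRNA annotation and
a truth table. Everything is driven by one integer seed and is
byte-deterministic.

Read model: Poisson fragment sampling. For a target region at per-base
depth ``d`` and read length ``L``, a Poisson number of reads of length
``L' = min(L, len)`` is placed uniformly at starts that keep the read
inside the allowed span, calibrated so interior bases see per-base
coverage ``d`` in expectation. Planted dicistronic loci additionally
receive fragments spanning tRNA + intergenic gap + nearest gene exon
contiguously, so every intergenic base is covered in expectation;
monocistronic loci receive reads strictly inside the tRNA and exons.
Background reads are scattered uniformly along each chromosome.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

# amino-acid / anticodon combinations used to mint valid tRNA names
_AA_ANTICODONS = (
    ("Gly", "GCC"), ("Gly", "TCC"), ("Ala", "AGC"), ("Pro", "TGG"),
    ("Thr", "AGT"), ("Val", "CAC"), ("Phe", "GAA"), ("Leu", "TAA"),
    ("Ile", "AAT"), ("Met", "CAT"), ("His", "GTG"), ("Arg", "TCG"),
    ("Asn", "GTT"), ("Ser", "AGA"), ("Lys", "CTT"), ("Glu", "CTC"),
    ("Asp", "GTC"), ("Cys", "GCA"), ("Trp", "CCA"), ("Tyr", "GTA"),
)

_TRNA_LEN = 72
_EXON_LEN = 200
_INTRON_LEN = 150
_MARGIN = 300


@dataclass(frozen=True)
class SimConfig:
    n_pairs: int = 100
    dicistronic_fraction: float = 0.2
    replicates_per_group: int = 4
    groups: tuple[str, ...] = ("g1",)
    read_length: int = 75
    depth_dicistronic: float = 30.0
    depth_monocistronic_trna: float = 30.0
    depth_monocistronic_pcg: float = 30.0
    background_rate: float = 0.1
    intergenic_min: int = 1
    intergenic_max: int = 1065
    intergenic_median: int = 133
    intergenic_sigma: float = 0.8
    intron_counts: tuple[int, ...] = (1, 2, 3)
    intron_count_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dicistronic_fraction <= 1.0:
            raise ValueError("dicistronic_fraction must lie in [0, 1]")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        if min(self.depth_dicistronic, self.depth_monocistronic_trna,
               self.depth_monocistronic_pcg, self.background_rate) < 0:
            raise ValueError("rates must be >= 0")
        if not 1 <= self.intergenic_min <= self.intergenic_median <= self.intergenic_max:
            raise ValueError("intergenic length bounds are inconsistent")


@dataclass(frozen=True)
class SimLocus:
    """Geometry of one synthetic locus (one per chromosome)."""

    chrom: str
    chrom_length: int
    trna_id: str
    trna_start: int
    trna_end: int
    gene_id: str
    exons: tuple[tuple[int, int], ...]
    trna_first: bool  # tRNA upstream (left) of the gene in coordinates
    planted: bool

    @property
    def gene_start(self) -> int:
        return self.exons[0][0]

    @property
    def gene_end(self) -> int:
        return self.exons[-1][1]

    @property
    def intergenic(self) -> tuple[int, int]:
        if self.trna_first:
            return (self.trna_end, self.gene_start)
        return (self.gene_end, self.trna_start)

    @property
    def pair_id(self) -> str:
        return f"{self.trna_id}|{self.gene_id}"


@dataclass
class SimTruth:
    """Planted status and expected per-feature depths keyed by pair id."""

    records: dict[str, dict] = field(default_factory=dict)

    def planted_ids(self) -> set[str]:
        return {k for k, v in self.records.items() if v["planted_dicistronic"]}


@dataclass
class SimDataset:
    config: SimConfig
    loci: list[SimLocus]
    truth: SimTruth
    gff3_path: Path
    bed_path: Path
    truth_path: Path
    config_path: Path
    sam_paths: dict[str, dict[str, Path]]  # group -> replicate -> path


def _sample_intergenic_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Discretized log-normal, median-targeted, clipped to the bounds."""
    raw = rng.lognormal(mean=np.log(cfg.intergenic_median),
                        sigma=cfg.intergenic_sigma, size=cfg.n_pairs)
    return np.clip(np.rint(raw), cfg.intergenic_min, cfg.intergenic_max).astype(int)


def _layout(cfg: SimConfig, rng: np.random.Generator) -> list[SimLocus]:
    gaps = _sample_intergenic_lengths(cfg, rng)
    intron_counts = rng.choice(
        cfg.intron_counts, size=cfg.n_pairs,
        p=np.asarray(cfg.intron_count_weights) / sum(cfg.intron_count_weights),
    )
    trna_first = rng.random(cfg.n_pairs) < 0.5
    n_planted = int(round(cfg.n_pairs * cfg.dicistronic_fraction))
    planted = np.zeros(cfg.n_pairs, dtype=bool)
    planted[rng.choice(cfg.n_pairs, size=n_planted, replace=False)] = True

    loci = []
    for i in range(cfg.n_pairs):
        aa, anticodon = _AA_ANTICODONS[i % len(_AA_ANTICODONS)]
        family = i // len(_AA_ANTICODONS) + 1
        trna_id = f"tRNA-{aa}-{anticodon}-{family}-1"
        gene_id = f"SIMG{i:05d}"
        chrom = f"simchr{i:04d}"
        n_introns = int(intron_counts[i])
        gene_len = (n_introns + 1) * _EXON_LEN + n_introns * _INTRON_LEN
        pos = _MARGIN
        if trna_first[i]:
            trna_start, trna_end = pos, pos + _TRNA_LEN
            gene_pos = trna_end + int(gaps[i])
        else:
            gene_pos = pos
            trna_start = gene_pos + gene_len + int(gaps[i])
            trna_end = trna_start + _TRNA_LEN
        exons = []
        p = gene_pos
        for k in range(n_introns + 1):
            exons.append((p, p + _EXON_LEN))
            p += _EXON_LEN + _INTRON_LEN
        chrom_length = max(trna_end, exons[-1][1]) + _MARGIN
        loci.append(SimLocus(
            chrom=chrom, chrom_length=chrom_length, trna_id=trna_id,
            trna_start=trna_start, trna_end=trna_end, gene_id=gene_id,
            exons=tuple(exons), trna_first=bool(trna_first[i]),
            planted=bool(planted[i]),
        ))
    return loci


def _poisson_reads(
    rng: np.random.Generator,
    span_start: int,
    span_end: int,
    depth: float,
    read_length: int,
) -> np.ndarray:
    """Start positions for reads of length min(read_length, span) kept
    inside [span_start, span_end).

    The read count is calibrated so that interior bases (>= one read
    length from either span edge) see per-base coverage ``depth`` in
    expectation; coverage tapers toward the span edges.
    """
    span = span_end - span_start
    if span <= 0 or depth <= 0:
        return np.empty(0, dtype=int)
    rl = min(read_length, span)
    n_pos = span - rl + 1
    n = rng.poisson(depth * n_pos / min(rl, n_pos))
    if n == 0:
        return np.empty(0, dtype=int)
    return rng.integers(span_start, span_end - rl + 1, size=n)


def _replicate_reads(
    cfg: SimConfig, loci: Sequence[SimLocus], rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """(chrom, start, length) for every read of one replicate."""
    reads: list[tuple[str, int, int]] = []
    L = cfg.read_length
    for locus in loci:
        def emit(span_start: int, span_end: int, depth: float) -> None:
            rl = min(L, span_end - span_start)
            for s in _poisson_reads(rng, span_start, span_end, depth, L):
                reads.append((locus.chrom, int(s), rl))

        if locus.planted:
            # contiguous fragments across tRNA + gap + nearest exon
            if locus.trna_first:
                span = (locus.trna_start, locus.exons[0][1])
            else:
                span = (locus.exons[-1][0], locus.trna_end)
            emit(span[0], span[1], cfg.depth_dicistronic)
            for es, ee in locus.exons:
                emit(es, ee, cfg.depth_monocistronic_pcg)
        else:
            emit(locus.trna_start, locus.trna_end, cfg.depth_monocistronic_trna)
            for es, ee in locus.exons:
                emit(es, ee, cfg.depth_monocistronic_pcg)
        if cfg.background_rate > 0:
            emit(0, locus.chrom_length, cfg.background_rate)
    return reads


def _write_sam(path: Path, loci: Sequence[SimLocus],
               reads: list[tuple[str, int, int]]) -> None:
    order = {locus.chrom: i for i, locus in enumerate(loci)}
    reads = sorted(reads, key=lambda r: (order[r[0]], r[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for locus in loci:
            fh.write(f"@SQ\tSN:{locus.chrom}\tLN:{locus.chrom_length}\n")
        for i, (chrom, start, length) in enumerate(reads):
            fh.write(
                f"simread{i:07d}\t0\t{chrom}\t{start + 1}\t60\t{length}M\t*\t0\t0\t*\t*\tNH:i:1\n"
            )


def _write_gff3(path: Path, loci: Sequence[SimLocus]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            gs, ge = locus.gene_start, locus.gene_end
            fh.write(
                f"{locus.chrom}\tsim\tgene\t{gs + 1}\t{ge}\t.\t+\t.\t"
                f"ID=gene:{locus.gene_id}\n"
            )
            tid = f"transcript:{locus.gene_id}.1"
            fh.write(
                f"{locus.chrom}\tsim\tmRNA\t{gs + 1}\t{ge}\t.\t+\t.\t"
                f"ID={tid};Parent=gene:{locus.gene_id}\n"
            )
            for es, ee in locus.exons:
                fh.write(
                    f"{locus.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t+\t.\t"
                    f"Parent={tid}\n"
                )


def _write_bed(path: Path, loci: Sequence[SimLocus]) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.trna_start}\t{locus.trna_end}\t"
                f"{locus.trna_id}\t0\t+\n"
            )


def simulate_dataset(config: SimConfig, out_dir: Path | str) -> SimDataset:
    """Generate a full dataset under ``out_dir``; deterministic per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    loci = _layout(config, rng)

    truth = SimTruth()
    for locus in loci:
        truth.records[locus.pair_id] = {
            "planted_dicistronic": locus.planted,
            "expected_intergenic_depth":
                config.depth_dicistronic if locus.planted else config.background_rate,
            "expected_trna_depth":
                config.depth_dicistronic if locus.planted
                else config.depth_monocistronic_trna,
            "expected_pcg_exon_depth": config.depth_monocistronic_pcg,
        }

    gff3_path = out_dir / "annotation.gff3"
    bed_path = out_dir / "trna.bed"
    truth_path = out_dir / "truth.tsv"
    config_path = out_dir / "sim_config.json"
    _write_gff3(gff3_path, loci)
    _write_bed(bed_path, loci)
    with open(truth_path, "w") as fh:
        fh.write("pair_id\tplanted_dicistronic\texpected_intergenic_depth\t"
                 "expected_trna_depth\texpected_pcg_exon_depth\n")
        for pair_id, rec in truth.records.items():
            fh.write(
                f"{pair_id}\t{int(rec['planted_dicistronic'])}\t"
                f"{rec['expected_intergenic_depth']}\t"
                f"{rec['expected_trna_depth']}\t"
                f"{rec['expected_pcg_exon_depth']}\n"
            )
    with open(config_path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
        fh.write("\n")

    sam_paths: dict[str, dict[str, Path]] = {}
    # one independent child seed per (group, replicate), order-stable
    for gi, group in enumerate(config.groups):
        sam_paths[group] = {}
        for ri in range(config.replicates_per_group):
            rep_rng = np.random.default_rng(
                [config.seed, 1_000_003, gi, ri]
            )
            reads = _replicate_reads(config, loci, rep_rng)
            rep_id = f"{group}_rep{ri + 1}"
            path = out_dir / f"reads_{rep_id}.sam"
            _write_sam(path, loci, reads)
            sam_paths[group][rep_id] = path
    return SimDataset(
        config=config, loci=loci, truth=truth, gff3_path=gff3_path,
        bed_path=bed_path, truth_path=truth_path, config_path=config_path,
        sam_paths=sam_paths,
    )


def scenario_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named scenario presets used by the acceptance checks."""
    presets = {
        "planted_strong": dict(
            n_pairs=100, dicistronic_fraction=0.2, replicates_per_group=4,
            depth_dicistronic=30.0, depth_monocistronic_trna=30.0,
            depth_monocistronic_pcg=30.0, background_rate=0.1,
        ),
        "null": dict(
            n_pairs=100, dicistronic_fraction=0.0, replicates_per_group=4,
            depth_dicistronic=0.0, depth_monocistronic_trna=10.0,
            depth_monocistronic_pcg=10.0, background_rate=0.1,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}")
    params = dict(presets[name])
    params.update(overrides)
    return SimConfig(seed=seed, **params)


# ---------------------------------------------------------------------------
# packaged candidate fixture (19 grapevine candidates, leaf/berry labels)

def candidate_fixture_text() -> str:
    from importlib.resources import files

    return files("dirtseq.data").joinpath("grapevine_candidates.tsv").read_text()


def write_candidate_fixture(path: Path | str) -> Path:
    """Copy the packaged 19-row grapevine candidate table to ``path``."""
    path = Path(path)
    path.write_text(candidate_fixture_text())
    return path
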