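"""Dicistronic transcript decision procedure.

For each candidate tRNA/protein-coding-gene pair within a replicate
group, the pipeline applies, in order:

1. expression filters on group-level raw counts (tRNA >= 1 read,
   gene >= 10 reads by default);
2. a paired one-sided t-test per available intron contrast
   (intergenic mean coverage > intron mean coverage across biological
   replicates), with Benjamini-Hochberg adjustment pooled over every
   contrast in the group run;
3. a directionality check on replicate-merged coverage (intergenic mean
   strictly greater than each intron mean);
4. a continuity check: every intergenic base covered by at least one
   read in the merged alignments.

A pair is called dicistronic only if all four hold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, TextIO

import numpy as np
from scipy import stats

from .coverage_engine import (
    AlignmentStore,
    CoverageTrack,
    count_feature_reads,
    mean_region_coverage,
    merged_coverage,
)
from .genome_model import TrnaPcgPair

logger = logging.getLogger(__name__)

#: p-value substituted when replicate differences are a nonzero constant
#: (zero sample variance): the evidence is unbounded, but the statistic
#: is degenerate, so the result is flagged.
DEGENERATE_P = 1e-300

VERDICTS = (
    "dicistronic",
    "rejected_expression",
    "rejected_test",
    "rejected_direction",
    "rejected_continuity",
    "untestable",
)


@dataclass(frozen=True)
class DetectionConfig:
    trna_min_reads: int = 1
    pcg_min_reads: int = 10
    fdr_alpha: float = 0.05
    mapq_min: int = 10
    max_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.trna_min_reads, self.pcg_min_reads, self.mapq_min) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")


@dataclass(frozen=True)
class ContrastResult:
    p_value: float
    direction: int  # sign of mean(intergenic - intron) over replicates
    degenerate: bool = False


@dataclass
class DicistronicCall:
    pair: TrnaPcgPair
    group_id: str
    trna_count: int = 0
    pcg_count: int = 0
    intergenic_means: tuple[float, ...] = ()
    intron_means: tuple[tuple[float, ...], ...] = ()
    p_values: tuple[float, ...] = ()
    q_values: tuple[float, ...] = ()
    direction_ok: bool = False
    continuous: bool = False
    degenerate: bool = False
    verdict: str = "untestable"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def filter_expressed_pairs(
    pairs: Sequence[TrnaPcgPair],
    trna_counts: Mapping[str, int],
    pcg_counts: Mapping[str, int],
    config: DetectionConfig = DetectionConfig(),
) -> list[TrnaPcgPair]:
    """Keep pairs whose tRNA and gene meet the raw-count thresholds."""
    kept = []
    for pair in pairs:
        if pair.trna.trna_id not in trna_counts:
            raise KeyError(f"no tRNA count for pair {pair.pair_id}")
        if pair.pcg.gene_id not in pcg_counts:
            raise KeyError(f"no gene count for pair {pair.pair_id}")
        if (
            trna_counts[pair.trna.trna_id] >= config.trna_min_reads
            and pcg_counts[pair.pcg.gene_id] >= config.pcg_min_reads
        ):
            kept.append(pair)
    return kept


def intron_contrast_test(
    intergenic_means: Sequence[float], intron_means: Sequence[float]
) -> ContrastResult:
    """Paired one-sided t-test of intergenic > intron mean coverage.

    Both vectors hold one mean-coverage value per biological replicate,
    aligned by replicate. Conventions for degenerate inputs: all
    differences zero -> p = 1; nonzero constant differences -> a
    flagged near-zero p (positive direction) or p = 1 (negative).
    """
    x = np.asarray(intergenic_means, dtype=float)
    y = np.asarray(intron_means, dtype=float)
    if x.shape != y.shape:
        raise ValueError("replicate vectors must align")
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 replicates for the contrast test")
    d = x - y
    mean_d = float(d.mean())
    direction = int(np.sign(mean_d))
    if np.all(d == d[0]):
        if d[0] == 0:
            return ContrastResult(p_value=1.0, direction=0)
        # constant nonzero differences: zero variance, infinite t
        if mean_d > 0:
            return ContrastResult(p_value=DEGENERATE_P, direction=1, degenerate=True)
        return ContrastResult(p_value=1.0, direction=-1, degenerate=True)
    res = stats.ttest_rel(x, y, alternative="greater")
    return ContrastResult(p_value=float(res.pvalue), direction=direction)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def continuity_check(track: CoverageTrack) -> bool:
    """True iff every base of the track has >= 1 read (vacuous if empty)."""
    if track.region.length == 0:
        return True
    return bool(track.counts.min() >= 1)


def run_dirt(
    pairs: Sequence[TrnaPcgPair],
    group_stores: Mapping[str, Sequence[AlignmentStore]],
    config: DetectionConfig = DetectionConfig(),
) -> dict[str, list[DicistronicCall]]:
    """Run the full decision procedure, one independent run per group.

    ``group_stores`` maps a group id to its replicate alignment stores
    (one per biological replicate, in a fixed order). Returns one
    :class:`DicistronicCall` per pair per group.
    """
    results: dict[str, list[DicistronicCall]] = {}
    for group_id, stores in group_stores.items():
        results[group_id] = _run_group(list(pairs), group_id, list(stores), config)
    return results


def _run_group(
    pairs: list[TrnaPcgPair],
    group_id: str,
    stores: list[AlignmentStore],
    config: DetectionConfig,
) -> list[DicistronicCall]:
    if config.max_distance is not None:
        pairs = [p for p in pairs if p.distance <= config.max_distance]
    if len(stores) < 2:
        logger.warning(
            "group %s has %d replicate(s); < 2 makes every pair untestable",
            group_id, len(stores),
        )
        return [
            DicistronicCall(pair=p, group_id=group_id, verdict="untestable",
                            reason="fewer than 2 replicates")
            for p in pairs
        ]

    trna_features = {p.trna.trna_id: p.trna.interval for p in pairs}
    pcg_features = {p.pcg.gene_id: p.pcg.interval for p in pairs}
    trna_counts: dict[str, int] = {f: 0 for f in trna_features}
    pcg_counts: dict[str, int] = {f: 0 for f in pcg_features}
    for store in stores:
        for f, c in count_feature_reads(store, trna_features, policy="trna").items():
            trna_counts[f] += c
        for f, c in count_feature_reads(
            store, pcg_features, policy="pcg", mapq_min=config.mapq_min
        ).items():
            pcg_counts[f] += c

    expressed = set(
        p.pair_id
        for p in filter_expressed_pairs(pairs, trna_counts, pcg_counts, config)
    )

    calls: list[DicistronicCall] = []
    tested: list[tuple[DicistronicCall, int]] = []  # (call, n contrasts)
    pooled_p: list[float] = []

    for pair in pairs:
        call = DicistronicCall(
            pair=pair,
            group_id=group_id,
            trna_count=trna_counts[pair.trna.trna_id],
            pcg_count=pcg_counts[pair.pcg.gene_id],
        )
        calls.append(call)
        if pair.pair_id not in expressed:
            call.verdict = "rejected_expression"
            call.reason = (
                f"tRNA count {call.trna_count} (min {config.trna_min_reads}), "
                f"gene count {call.pcg_count} (min {config.pcg_min_reads})"
            )
            continue
        if pair.intergenic.length == 0:
            call.verdict = "untestable"
            call.reason = "adjacent features, empty intergenic region"
            continue
        if not pair.introns_by_proximity:
            call.verdict = "untestable"
            call.reason = "intronless gene, no intron background"
            continue

        call.intergenic_means = tuple(
            mean_region_coverage(s.coverage(pair.intergenic)) for s in stores
        )
        call.intron_means = tuple(
            tuple(mean_region_coverage(s.coverage(intron)) for s in stores)
            for intron in pair.introns_by_proximity
        )
        contrasts = [
            intron_contrast_test(call.intergenic_means, im)
            for im in call.intron_means
        ]
        call.p_values = tuple(c.p_value for c in contrasts)
        call.degenerate = any(c.degenerate for c in contrasts)
        pooled_p.extend(call.p_values)
        tested.append((call, len(contrasts)))

        merged_inter = merged_coverage(stores, pair.intergenic)
        merged_intron_means = [
            mean_region_coverage(merged_coverage(stores, intron))
            for intron in pair.introns_by_proximity
        ]
        inter_mean = mean_region_coverage(merged_inter)
        call.direction_ok = all(inter_mean > m for m in merged_intron_means)
        call.continuous = continuity_check(merged_inter)

    # BH pooled over every contrast in this group run
    q = bh_adjust(pooled_p)
    offset = 0
    for call, k in tested:
        call.q_values = tuple(q[offset:offset + k])
        offset += k
        if not all(qv < config.fdr_alpha for qv in call.q_values):
            call.verdict = "rejected_test"
            call.reason = f"max FDR q = {max(call.q_values):.4g}"
        elif not call.direction_ok:
            call.verdict = "rejected_direction"
            call.reason = "merged intergenic mean not above every intron mean"
        elif not call.continuous:
            call.verdict = "rejected_continuity"
            call.reason = "zero-coverage base inside the intergenic region"
        else:
            call.verdict = "dicistronic"
            call.reason = ""
    return calls


CALL_TABLE_COLUMNS = (
    "group_id", "trna_id", "gene_id", "chrom", "orientation", "distance",
    "trna_count", "pcg_count", "intergenic_mean", "intron_means",
    "p_values", "q_values", "direction_ok", "continuous", "verdict", "reason",
)


def write_call_table(
    calls_by_group: Mapping[str, Sequence[DicistronicCall]], handle: TextIO
) -> None:
    """Write one TSV row per pair per group (deterministic order)."""
    handle.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
    for group_id in calls_by_group:
        for call in calls_by_group[group_id]:
            p = call.pair
            inter_mean = (
                f"{float(np.mean(call.intergenic_means)):.6g}"
                if call.intergenic_means else "NA"
            )
            intron_means = ";".join(
                f"{float(np.mean(im)):.6g}" for im in call.intron_means
            ) or "NA"
            pvals = ";".join(f"{v:.6g}" for v in call.p_values) or "NA"
            qvals = ";".join(f"{v:.6g}" for v in call.q_values) or "NA"
            handle.write("\t".join(str(x) for x in (
                group_id, p.trna.trna_id, p.pcg.gene_id, p.intergenic.chrom,
                p.orientation, p.distance, call.trna_count, call.pcg_count,
                inter_mean, intron_means, pvals, qvals,
                call.direction_ok, call.continuous, call.verdict, call.reason,
            )) + "\n")


def write_candidate_bed(
    calls_by_group: Mapping[str, Sequence[DicistronicCall]], handle: TextIO
) -> None:
    """BED6 of dicistronic candidates (tRNA span through gene span)."""
    for group_id in calls_by_group:
        for call in calls_by_group[group_id]:
            if call.verdict != "dicistronic":
                continue
            p = call.pair
            start = min(p.trna.interval.start, p.pcg.interval.start)
            end = max(p.trna.interval.end, p.pcg.interval.end)
            name = f"{p.trna.trna_id}|{p.pcg.gene_id}|{group_id}"
            handle.write(
                f"{p.intergenic.chrom}\t{start}\t{end}\t{name}\t0\t.\n"
            )
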