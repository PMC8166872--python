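"""Expression normalization, component correlation and candidate summaries."""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import TRNA_NAME_RE

logger = logging.getLogger(__name__)

# two-digit chromosome token inside Ensembl grapevine accessions
_CHROM_TOKEN_RE = re.compile(r"^VIT_(\d{2})s")


@dataclass
class ExpressionTable:
    """Raw counts (features x samples) with total-mapped library sizes."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.library_sizes = self.library_sizes.astype(float).reindex(
            self.counts.columns
        )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes.isna().any():
            raise ValueError("library size missing for some samples")


def cpm(table: ExpressionTable, log: bool = False) -> pd.DataFrame:
    """Counts per million mapped reads; ``log`` applies log2(CPM + 1)."""
    if (table.library_sizes <= 0).any():
        bad = table.library_sizes[table.library_sizes <= 0].index.tolist()
        raise ValueError(f"zero/negative library size for samples {bad}")
    out = table.counts * 1e6 / table.library_sizes
    if log:
        out = np.log2(out + 1.0)
    return out


@dataclass(frozen=True)
class ComponentCorrelation:
    candidate_id: str
    contrast: str  # "trna_vs_intergenic" or "pcg_vs_intergenic"
    r: Optional[float]
    p_value: Optional[float]
    significant: Optional[bool]
    n: int
    note: str = ""


def correlate_components(
    expr_trna: pd.DataFrame,
    expr_intergenic: pd.DataFrame,
    expr_pcg: pd.DataFrame,
    alpha: float = 0.05,
) -> list[ComponentCorrelation]:
    """Pearson correlation of tRNA-vs-intergenic and gene-vs-intergenic
    expression across groups, per candidate.

    The intergenic signal serves as the proxy for dicistronic-transcript
    expression. All frames are candidate x group, aligned on both axes.
    Zero-variance vectors yield ``r = None`` with an explanatory note.
    """
    if not (expr_trna.index.equals(expr_intergenic.index)
            and expr_pcg.index.equals(expr_intergenic.index)):
        raise ValueError("candidate indexes must align")
    if not (expr_trna.columns.equals(expr_intergenic.columns)
            and expr_pcg.columns.equals(expr_intergenic.columns)):
        raise ValueError("group columns must align")
    if expr_intergenic.shape[1] < 3:
        raise ValueError("need >= 3 groups for correlation")

    out: list[ComponentCorrelation] = []
    for cid in expr_intergenic.index:
        y = expr_intergenic.loc[cid].to_numpy(dtype=float)
        for contrast, frame in (
            ("trna_vs_intergenic", expr_trna),
            ("pcg_vs_intergenic", expr_pcg),
        ):
            x = frame.loc[cid].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out.append(ComponentCorrelation(
                    cid, contrast, None, None, None, len(x),
                    note="zero variance in one component",
                ))
                continue
            r, p = stats.pearsonr(x, y)
            out.append(ComponentCorrelation(
                cid, contrast, float(r), float(p), bool(p < alpha), len(x),
            ))
    return out


def correlation_frame(results: Sequence[ComponentCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


@dataclass
class CandidateSummary:
    n_candidates: int = 0
    tissue_counts: dict[str, int] = field(default_factory=dict)
    n_multi_tissue: int = 0
    n_distinct_trna_genes: int = 0
    n_isoacceptor_families: int = 0
    n_distinct_anticodons: int = 0
    n_distinct_chromosomes: int = 0
    distance_median: Optional[float] = None
    distance_max: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)


def _tissues(label: str) -> list[str]:
    return [t.strip() for t in str(label).split(" and ") if t.strip()]


def summarize_candidates(table: pd.DataFrame) -> CandidateSummary:
    """Characterize a candidate table (trna_id, gene_id, tissue columns).

    Rows labelled "A and B" count toward both tissues. Chromosome tokens
    are parsed from grapevine-style accessions (``VIT_08s... -> 08``);
    rows with other accession styles are excluded from the chromosome
    tally. Malformed tRNA names count as candidates but are excluded
    from family/anticodon tallies with a warning.
    """
    summary = CandidateSummary(n_candidates=len(table))
    if len(table) == 0:
        return summary

    tissue_counts: dict[str, int] = {}
    n_multi = 0
    for label in table["tissue"]:
        tissues = _tissues(label)
        if len(tissues) > 1:
            n_multi += 1
        for t in tissues:
            tissue_counts[t] = tissue_counts.get(t, 0) + 1
    summary.tissue_counts = tissue_counts
    summary.n_multi_tissue = n_multi

    summary.n_distinct_trna_genes = table["trna_id"].nunique()

    aas, anticodons = set(), set()
    for name in table["trna_id"].unique():
        m = TRNA_NAME_RE.match(name)
        if m is None:
            logger.warning("unparseable tRNA name %r excluded from tallies", name)
            continue
        aas.add(m["aa"])
        anticodons.add(m["anticodon"])
    summary.n_isoacceptor_families = len(aas)
    summary.n_distinct_anticodons = len(anticodons)

    chroms = set()
    for gid in table["gene_id"]:
        m = _CHROM_TOKEN_RE.match(str(gid))
        if m is not None:
            chroms.add(m.group(1))
    summary.n_distinct_chromosomes = len(chroms)

    if "distance" in table.columns:
        d = pd.to_numeric(table["distance"], errors="coerce").dropna()
        if len(d):
            summary.distance_median = float(d.median())
            summary.distance_max = float(d.max())
    return summary


def expression_set_summary(sets: Mapping[str, set]) -> dict:
    """Set-partition report for per-tissue expressed-feature id sets.

    Returns per-set sizes, all pairwise intersection sizes, the size of
    the overall union and, for two sets, the exclusive counts.
    """
    names = list(sets)
    report: dict = {
        "sizes": {name: len(sets[name]) for name in names},
        "union": len(set().union(*sets.values())) if names else 0,
        "intersections": {},
    }
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            report["intersections"][f"{a}&{b}"] = len(sets[a] & sets[b])
    if len(names) == 2:
        a, b = names
        report["exclusive"] = {
            a: len(sets[a] - sets[b]),
            b: len(sets[b] - sets[a]),
        }
    return report
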