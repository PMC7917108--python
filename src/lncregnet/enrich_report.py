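"""Hypergeometric enrichment and the summary/report arithmetic.

Enrichment is the plain hypergeometric upper tail (no length-bias
weighting): for a query of size n drawn from a background of size N, a term
annotating K background features and overlapping the query in k,
p = P(X >= k), BH-adjusted across all tested terms.

Percentages are rounded half-even at 2 digits so that printed summary
numbers are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .identify import LncRNA
from .io_formats import ExpressionMatrix

__all__ = [
    "EnrichmentResult",
    "SampleStats",
    "SummaryStats",
    "hypergeom_enrich",
    "percent_of",
    "aggregate_sample_stats",
    "summarize_lncrnas",
    "read_sample_stats_tsv",
    "read_term_map_tsv",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n) or self.k > self.N:
            raise ValueError("overlap larger than term/query/background")

    @property
    def significant(self) -> bool:
        return self.q_value < 0.05


@dataclass(frozen=True)
class SampleStats:
    sample: str
    replicate: str
    clean_reads: int
    clean_bases_gb: float
    q30_percent: float
    unique_mapped_reads: int

    def __post_init__(self) -> None:
        if self.unique_mapped_reads > self.clean_reads:
            raise ValueError("mapped reads exceed clean reads")
        if not (0 <= self.q30_percent <= 100):
            raise ValueError("Q30 percentage outside [0, 100]")


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean_length: float
    median_length: float
    mean_exons: float
    mean_fpkm: float
    median_fpkm: float


def hypergeom_enrich(
    query: set[str],
    background: set[str],
    term_map: Mapping[str, tuple[str, set[str]]],
    alpha_q: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``query`` against every term.

    ``term_map``: term_id -> (term_name, feature set).  Term features are
    intersected with the background; terms with no background features are
    skipped.  Results sorted by p-value.
    """
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for term_id in sorted(term_map):
        term_name, feats = term_map[term_id]
        term_feats = feats & background
        K = len(term_feats)
        if K == 0:
            continue
        k = len(term_feats & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, term_name, k, K, p))
    if not rows:
        return []
    q = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(
            term_id=tid, term_name=tname, k=k, K=K, n=n, N=N,
            p_value=p, q_value=float(qv),
        )
        for (tid, tname, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def percent_of(count: int, total: int, digits: int = 2) -> float:
    """round(100 * count / total, digits) with half-even rounding, done in
    decimal arithmetic so printed percentages are exact."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= count <= total):
        raise ValueError("need 0 <= count <= total")
    q = Decimal(1).scaleb(-digits)
    val = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, ROUND_HALF_EVEN)
    return float(val)


def aggregate_sample_stats(
    rows: Sequence[SampleStats],
) -> tuple[float, dict[str, float], dict[str, float]]:
    """(total clean Gb, per-sample clean-Gb sums, mapped % per replicate)."""
    if not rows:
        raise ValueError("no rows")
    per_sample: dict[str, float] = {}
    for r in rows:
        per_sample[r.sample] = per_sample.get(r.sample, 0.0) + r.clean_bases_gb
    per_sample = {s: round(v, 2) for s, v in per_sample.items()}
    total = round(sum(r.clean_bases_gb for r in rows), 2)
    mapped = {
        r.replicate: percent_of(r.unique_mapped_reads, r.clean_reads) for r in rows
    }
    return total, per_sample, mapped


def summarize_lncrnas(
    lncrnas: Sequence[LncRNA],
    expr: ExpressionMatrix | None = None,
) -> tuple[SummaryStats, dict[str, int]]:
    """Length/exon/FPKM summary plus per-class counts."""
    counts = {"lincRNA": 0, "incRNA": 0, "lncNAT": 0}
    for l in lncrnas:
        counts[l.positional_class] += 1
    if not lncrnas:
        return SummaryStats(0, 0.0, 0.0, 0.0, 0.0, 0.0), counts
    lengths = np.array([l.transcript.length for l in lncrnas], dtype=float)
    exons = np.array([l.transcript.n_exons for l in lncrnas], dtype=float)
    if expr is not None:
        fpkm = np.array(
            [
                float(expr.values.loc[l.transcript.transcript_id].mean())
                if l.transcript.transcript_id in expr.values.index
                else 0.0
                for l in lncrnas
            ]
        )
    else:
        fpkm = np.zeros(len(lncrnas))
    stats_out = SummaryStats(
        n=len(lncrnas),
        mean_length=round(float(lengths.mean()), 2),
        median_length=float(np.median(lengths)),
        mean_exons=round(float(exons.mean()), 2),
        mean_fpkm=round(float(fpkm.mean()), 2),
        median_fpkm=round(float(np.median(fpkm)), 2),
    )
    return stats_out, counts


def read_sample_stats_tsv(path) -> list[SampleStats]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleStats(
            sample=str(r.sample),
            replicate=str(r.replicate),
            clean_reads=int(r.clean_reads),
            clean_bases_gb=float(r.clean_bases_gb),
            q30_percent=float(r.q30_percent),
            unique_mapped_reads=int(r.unique_mapped_reads),
        )
        for r in df.itertuples(index=False)
    ]


def read_term_map_tsv(path) -> dict[str, tuple[str, set[str]]]:
    """term_id, term_name, gene_id TSV -> {term_id: (name, gene set)}."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[str, set[str]]] = {}
    for r in df.itertuples(index=False):
        name, feats = out.get(str(r.term_id), (str(r.term_name), set()))
        feats.add(str(r.gene_id))
        out[str(r.term_id)] = (name, feats)
    return out
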