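"""cis / trans regulatory relations between DE lncRNAs and DE mRNAs.

* cis: protein-coding genes whose span lies within a 100 kb window of the
  lncRNA span (boundary-to-boundary gap, inclusive at exactly 100,000 bp;
  an exclusive reading is available via ``inclusive=False``).
* trans: coexpression by Pearson correlation, |r| > 0.95 and p < 0.01
  (both strict), by default on the five stage means.
* both: the pair-level intersection of the two.
* SA pairs: sense–antisense — opposite strands with >=1 bp span overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .expression import pcc
from .identify import LncRNA
from .io_formats import ExpressionMatrix, GeneModel, write_network_tsv

log = logging.getLogger(__name__)

__all__ = [
    "RegEdge",
    "cis_targets",
    "trans_targets",
    "combine_cis_trans",
    "sa_pairs",
    "degree_tables",
    "export_network",
]


@dataclass(frozen=True)
class RegEdge:
    lncrna_id: str
    mrna_id: str
    mode: str  # cis | trans | both
    distance_bp: int | None = None
    r: float | None = None
    p: float | None = None
    comparisons_present: frozenset[str] = field(default_factory=frozenset)
    sa_pair: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans", "both"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.mode in ("cis", "both") and self.distance_bp is None:
            raise ValueError("cis edge without distance")
        if self.mode in ("trans", "both") and (self.r is None or self.p is None):
            raise ValueError("trans edge without r/p")

    @property
    def key(self) -> tuple[str, str]:
        return (self.lncrna_id, self.mrna_id)


def cis_targets(
    lncrnas: Sequence[LncRNA],
    genes: Sequence[GeneModel],
    window: int = 100_000,
    inclusive: bool = True,
) -> list[RegEdge]:
    """One edge per protein-coding gene within ``window`` bp of each lncRNA
    (gap between nearest span boundaries; 0 for overlap)."""
    edges = []
    for lnc in lncrnas:
        span = lnc.transcript.span
        for g in genes:
            if not g.is_coding or g.span.chrom != span.chrom:
                continue
            gap = span.gap_to(g.span)
            if (gap <= window) if inclusive else (gap < window):
                edges.append(
                    RegEdge(
                        lncrna_id=lnc.transcript.transcript_id,
                        mrna_id=g.gene_id,
                        mode="cis",
                        distance_bp=gap,
                    )
                )
    return edges


def trans_targets(
    de_lnc: Iterable[str],
    de_mrna: Iterable[str],
    expr: ExpressionMatrix,
    r_min: float = 0.95,
    p_max: float = 0.01,
    basis: str = "stages",
    de_by_comparison: Mapping[str, tuple[set[str], set[str]]] | None = None,
) -> list[RegEdge]:
    """Coexpression edges: |r| > r_min AND p < p_max (both strict).

    ``de_by_comparison`` optionally maps a comparison name to its
    (DE lncRNA set, DE mRNA set); an edge is present in a comparison when
    BOTH endpoints are DE there.
    """
    edges = []
    vectors = {}
    for fid in list(de_lnc) + list(de_mrna):
        if fid in vectors:
            continue
        v = expr.vector(fid, basis=basis).to_numpy()
        if v.max() == v.min():
            log.info("trans_targets: %s has constant expression; skipped", fid)
            vectors[fid] = None
        else:
            vectors[fid] = v
    for lid in sorted(set(de_lnc)):
        if vectors[lid] is None:
            continue
        for mid in sorted(set(de_mrna)):
            if mid == lid or vectors[mid] is None:
                continue
            res = pcc(vectors[lid], vectors[mid])
            if abs(res.r) > r_min and res.p_value < p_max:
                present = frozenset(
                    comp
                    for comp, (lset, mset) in (de_by_comparison or {}).items()
                    if lid in lset and mid in mset
                )
                edges.append(
                    RegEdge(
                        lncrna_id=lid,
                        mrna_id=mid,
                        mode="trans",
                        r=res.r,
                        p=res.p_value,
                        comparisons_present=present,
                    )
                )
    return edges


def combine_cis_trans(cis: Iterable[RegEdge], trans: Iterable[RegEdge]) -> list[RegEdge]:
    """Pair-level intersection; distance from the cis edge, r/p from trans."""
    cis_by_key = {e.key: e for e in cis}
    out = []
    for te in trans:
        ce = cis_by_key.get(te.key)
        if ce is None:
            continue
        out.append(
            RegEdge(
                lncrna_id=te.lncrna_id,
                mrna_id=te.mrna_id,
                mode="both",
                distance_bp=ce.distance_bp,
                r=te.r,
                p=te.p,
                comparisons_present=te.comparisons_present,
                sa_pair=ce.sa_pair or te.sa_pair,
            )
        )
    return out


def sa_pairs(
    edges: Iterable[RegEdge],
    lncrnas: Sequence[LncRNA],
    genes: Sequence[GeneModel],
) -> list[RegEdge]:
    """Subset of edges that are sense–antisense pairs (flag set on return).

    SA requires opposite strands and >=1 bp overlap of the transcript/gene
    spans."""
    lnc_span = {l.transcript.transcript_id: l.transcript.span for l in lncrnas}
    gene_span = {g.gene_id: g.span for g in genes}
    out = []
    for e in edges:
        ls = lnc_span.get(e.lncrna_id)
        gs = gene_span.get(e.mrna_id)
        if ls is None or gs is None:
            continue
        if ls.strand != gs.strand and {ls.strand, gs.strand} == {"+", "-"} and ls.overlaps(gs):
            out.append(replace(e, sa_pair=True))
    return out


def degree_tables(edges: Iterable[RegEdge]) -> tuple[dict[str, int], dict[str, int]]:
    """(per-lncRNA target counts, per-mRNA regulator counts), sorted keys."""
    lnc: dict[str, int] = {}
    mrna: dict[str, int] = {}
    for e in edges:
        lnc[e.lncrna_id] = lnc.get(e.lncrna_id, 0) + 1
        mrna[e.mrna_id] = mrna.get(e.mrna_id, 0) + 1
    return dict(sorted(lnc.items())), dict(sorted(mrna.items()))


def export_network(edges: Sequence[RegEdge], path_prefix) -> None:
    """Node/edge TSVs for external layout tools (Gephi/Cytoscape import)."""
    nodes = {(e.lncrna_id, "lncRNA") for e in edges} | {(e.mrna_id, "mRNA") for e in edges}
    rows = [
        {
            "source": e.lncrna_id,
            "target": e.mrna_id,
            "mode": e.mode,
            "distance_bp": "" if e.distance_bp is None else e.distance_bp,
            "r": "" if e.r is None else round(e.r, 6),
            "p": "" if e.p is None else e.p,
            "n_comparisons": len(e.comparisons_present),
            "sa_pair": int(e.sa_pair),
        }
        for e in edges
    ]
    write_network_tsv(sorted(nodes), rows, path_prefix)
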