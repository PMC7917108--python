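"""lncRNA screening and positional classification.

Assembled transcripts are run through a strict screening cascade — minimum
length 200 nt, removal of unreliable (low-FPKM) mono-exonic models, removal
of transcripts whose exons overlap protein-coding exons on the same strand,
and removal of transcripts with coding potential — and the survivors are
classified by genomic position relative to protein-coding genes:

* ``lincRNA`` — intergenic;
* ``incRNA``  — wholly inside an intron of a coding transcript (either
  strand), with no coding-exon overlap;
* ``lncNAT``  — natural antisense: >=1 bp exon overlap with a coding exon on
  the opposite strand.

Antisense exon overlap takes precedence over intronic containment.  Coding
potential is taken from externally supplied labels (CNCI/CPC-style callers
are upstream of this package); in their absence a simple longest-ORF rule
(>=100 aa removed) stands in and is explicitly not equivalent to those
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .io_formats import ExpressionMatrix, GeneModel, TranscriptModel

__all__ = [
    "FilterParams",
    "LncRNA",
    "FilterTrace",
    "filter_candidates",
    "classify_position",
    "orf_stand_in",
    "identify_lncrnas",
]

POSITIONAL_CLASSES = ("lincRNA", "incRNA", "lncNAT")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FilterParams:
    min_length: int = 200
    drop_monoexonic_below_fpkm: float = 2.0
    coding_labels: Mapping[str, str] | None = None
    orf_aa_cutoff: int = 100
    sequences: Mapping[str, str] | None = None  # needed only for the ORF stand-in

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.drop_monoexonic_below_fpkm < 0 or self.orf_aa_cutoff < 0:
            raise ValueError("cutoffs must be >= 0")


@dataclass
class LncRNA:
    transcript: TranscriptModel
    positional_class: str
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.positional_class not in POSITIONAL_CLASSES:
            raise ValueError(f"unknown positional class {self.positional_class!r}")


FilterTrace = dict[str, list[tuple[str, bool]]]

FILTER_ORDER = ("length", "monoexonic_fpkm", "coding_exon_overlap", "coding_potential")


def _coding_exon_trees(genes: Iterable[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    """Interval trees of protein-coding exons keyed by (chrom, strand)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        if not g.is_coding:
            continue
        for t in g.transcripts:
            for e in t.exons:
                trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(e.start, e.end)
    return trees


def _overlaps_coding_exon(
    tx: TranscriptModel,
    trees: Mapping[tuple[str, str], IntervalTree],
    same_strand: bool,
) -> bool:
    if same_strand:
        strands = [tx.span.strand]
    else:
        strands = [s for s in ("+", "-") if s != tx.span.strand]
    for strand in strands:
        tree = trees.get((tx.span.chrom, strand))
        if tree is None:
            continue
        if any(tree.overlap(e.start, e.end) for e in tx.exons):
            return True
    return False


def orf_stand_in(seq: str) -> int:
    """Longest ATG..stop ORF across the three forward frames, in aa
    (excluding the stop codon).  Returns 0 when no complete ORF exists."""
    seq = seq.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        i = frame
        open_starts: list[int] = []
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon == "ATG" and not open_starts:
                open_starts.append(i)
            if codon in _STOPS and open_starts:
                best = max(best, (i - open_starts[0]) // 3)
                open_starts.clear()
            i += 3
    return best


def _max_fpkm(expr: ExpressionMatrix | None, tx_id: str) -> float:
    if expr is None or tx_id not in expr.values.index:
        return 0.0
    return float(expr.values.loc[tx_id].max())


def filter_candidates(
    transcripts: list[TranscriptModel],
    genes: list[GeneModel],
    expr: ExpressionMatrix | None,
    params: FilterParams | None = None,
) -> tuple[list[TranscriptModel], FilterTrace]:
    """Run the screening cascade; returns survivors (input order) and a
    per-transcript trace of every filter decision.

    Filters, in order: (1) length >= min_length (200 nt kept); (2) mono-exonic
    with max FPKM below the reliability cutoff removed; (3) same-strand exon
    overlap with any protein-coding exon removed (antisense overlap is kept —
    it defines the lncNAT class); (4) coding transcripts removed, judged by
    external labels or, failing that, the longest-ORF stand-in.
    """
    params = params or FilterParams()
    trees = _coding_exon_trees(genes)
    retained: list[TranscriptModel] = []
    trace: FilterTrace = {}

    for tx in transcripts:
        steps: list[tuple[str, bool]] = []
        trace[tx.transcript_id] = steps

        ok = tx.length >= params.min_length
        steps.append(("length", ok))
        if not ok:
            continue

        low_mono = tx.n_exons == 1 and _max_fpkm(expr, tx.transcript_id) < params.drop_monoexonic_below_fpkm
        steps.append(("monoexonic_fpkm", not low_mono))
        if low_mono:
            continue

        hit = _overlaps_coding_exon(tx, trees, same_strand=True)
        steps.append(("coding_exon_overlap", not hit))
        if hit:
            continue

        if params.coding_labels is not None and tx.transcript_id in params.coding_labels:
            coding = params.coding_labels[tx.transcript_id] == "coding"
        elif params.sequences is not None and tx.transcript_id in params.sequences:
            coding = orf_stand_in(params.sequences[tx.transcript_id]) >= params.orf_aa_cutoff
        else:
            coding = False
        steps.append(("coding_potential", not coding))
        if coding:
            continue

        retained.append(tx)
    return retained, trace


def _intron_trees(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if not g.is_coding:
            continue
        for t in g.transcripts:
            for intron in t.introns():
                trees.setdefault(intron.chrom, IntervalTree()).addi(intron.start, intron.end)
    return trees


def _classify(
    tx: TranscriptModel,
    exon_trees: Mapping[tuple[str, str], IntervalTree],
    intron_trees: Mapping[str, IntervalTree],
) -> str:
    if _overlaps_coding_exon(tx, exon_trees, same_strand=True):
        raise ValueError(
            f"{tx.transcript_id} overlaps a same-strand coding exon; run filter_candidates first"
        )
    if _overlaps_coding_exon(tx, exon_trees, same_strand=False):
        return "lncNAT"
    tree = intron_trees.get(tx.span.chrom)
    if tree is not None:
        for iv in tree.overlap(tx.span.start, tx.span.end):
            if iv.begin <= tx.span.start and tx.span.end <= iv.end:
                return "incRNA"
    return "lincRNA"


def classify_position(tx: TranscriptModel, genes: list[GeneModel]) -> str:
    """Positional class of a screened transcript.

    Precedence: lncNAT (antisense coding-exon overlap) > incRNA (span wholly
    inside one intron of a coding transcript, either strand) > lincRNA.
    A same-strand coding-exon overlap is an error: such transcripts should
    have been removed by the screen.
    """
    return _classify(tx, _coding_exon_trees(genes), _intron_trees(genes))


def identify_lncrnas(
    transcripts: list[TranscriptModel],
    genes: list[GeneModel],
    expr: ExpressionMatrix | None = None,
    params: FilterParams | None = None,
) -> tuple[list[LncRNA], FilterTrace]:
    """Screen and classify in one call."""
    retained, trace = filter_candidates(transcripts, genes, expr, params)
    exon_trees = _coding_exon_trees(genes)
    intron_trees = _intron_trees(genes)
    out = [
        LncRNA(tx, _classify(tx, exon_trees, intron_trees), trace[tx.transcript_id])
        for tx in retained
    ]
    return out, trace
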