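"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based, half-open internally; GFF3/GTF 1-based
inclusive coordinates are converted only at this I/O boundary.  FASTA input
may be DNA or RNA: ``U`` is normalised to ``T`` on read, and the duplex code
re-interprets ``T`` as ``U`` when it pairs strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "ExpressionMatrix",
    "HomologyHit",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_network_tsv",
    "read_network_tsv",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation / network input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance between nearest boundaries; 0 when overlapping."""
        if self.chrom != other.chrom:
            raise AnnotationError("gap_to across chromosomes is undefined")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class TranscriptModel:
    transcript_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    gene_id: str | None = None
    biotype: str = "transcript"

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        for e in self.exons:
            if e.chrom != self.span.chrom or e.strand != self.span.strand:
                raise AnnotationError(f"{self.transcript_id}: exon off-span")
            if e.start < self.span.start or e.end > self.span.end:
                raise AnnotationError(f"{self.transcript_id}: exon outside span")

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.span.chrom, a.end, b.start, self.span.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        ]


@dataclass
class GeneModel:
    gene_id: str
    span: GenomicInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            if tx.span.start < self.span.start or tx.span.end > self.span.end:
                raise AnnotationError(
                    f"{self.gene_id}: transcript {tx.transcript_id} outside gene span"
                )
            if tx.span.strand != self.span.strand:
                raise AnnotationError(f"{self.gene_id}: strand mismatch")

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


class ExpressionMatrix:
    """FPKM values (features x samples) with stage/replicate structure."""

    def __init__(
        self,
        values: pd.DataFrame,
        sample_to_stage: Mapping[str, str],
        stage_order: Sequence[str],
    ):
        if (values.values < 0).any():
            raise ValueError("negative FPKM values")
        missing = set(values.columns) - set(sample_to_stage)
        if missing:
            raise ValueError(f"samples without a stage: {sorted(missing)}")
        stages_seen = {sample_to_stage[s] for s in values.columns}
        for st in stage_order:
            if st not in stages_seen:
                raise ValueError(f"stage {st!r} has no samples")
        self.values = values
        self.sample_to_stage = dict(sample_to_stage)
        self.stage_order = list(stage_order)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def stage_samples(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}")
        return [s for s in self.values.columns if self.sample_to_stage[s] == stage]

    def stage_means(self) -> pd.DataFrame:
        """Per-stage mean FPKM, columns ordered by stage_order."""
        return pd.DataFrame(
            {st: self.values[self.stage_samples(st)].mean(axis=1) for st in self.stage_order}
        )

    def vector(self, feature_id: str, basis: str = "stages") -> pd.Series:
        """Expression vector for one feature: stage means or raw replicates."""
        if basis == "stages":
            return self.stage_means().loc[feature_id]
        if basis == "replicates":
            return self.values.loc[feature_id]
        raise ValueError(f"unknown basis {basis!r}")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    subject_species: str = ""

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if self.alignment_length < 1:
            raise ValueError("alignment length < 1")


# ---------------------------------------------------------------------------
# annotation


def _validate_annotation_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise AnnotationError(f"{path}:{lineno}: end < start")


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Parse GFF3/GTF into GeneModels with 0-based half-open coordinates.

    Transcripts whose gene record is absent get a synthesized single-transcript
    gene (logged).  Feature types other than gene/mRNA/transcript/exon are
    ignored with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    _validate_annotation_lines(path)

    import contextlib
    import io
    import warnings

    # gffutils prints gene-extent inference progress to stderr; keep it quiet
    with warnings.catch_warnings(), contextlib.redirect_stderr(io.StringIO()):
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=(dialect == "gff3"),
            disable_infer_transcripts=True,
            verbose=False,
        )

    tx_types = {"mRNA", "transcript", "lnc_RNA", "ncRNA"}
    known = {"gene"} | tx_types | {"exon"}
    ignored = sum(
        db.count_features_of_type(t)
        for t in db.featuretypes()
        if t not in known
    )
    if ignored:
        log.info("read_annotation: ignored %d records of unknown feature type", ignored)

    def _biotype(feat) -> str:
        for key in ("biotype", "gene_biotype", "gene_type"):
            if key in feat.attributes:
                return feat.attributes[key][0]
        return "protein_coding" if feat.featuretype == "gene" else "transcript"

    genes: list[GeneModel] = []
    seen_tx: set[str] = set()
    for g in db.features_of_type("gene", order_by="start"):
        gene_span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        transcripts = []
        for t in db.children(g, level=1, order_by="start"):
            if t.featuretype not in tx_types:
                continue
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            tx_id = t.id
            tx_bio = _biotype(t)
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    span=GenomicInterval(t.seqid, t.start - 1, t.end, t.strand),
                    exons=exons or [GenomicInterval(t.seqid, t.start - 1, t.end, t.strand)],
                    gene_id=g.id,
                    biotype=tx_bio,
                )
            )
            seen_tx.add(tx_id)
        genes.append(
            GeneModel(gene_id=g.id, span=gene_span, transcripts=transcripts, biotype=_biotype(g))
        )

    # orphan transcripts -> synthesized single-transcript genes
    for t in db.features_of_type(tuple(tx_types), order_by="start"):
        if t.id in seen_tx:
            continue
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(t, featuretype="exon", order_by="start")
        ]
        tx = TranscriptModel(
            transcript_id=t.id,
            span=GenomicInterval(t.seqid, t.start - 1, t.end, t.strand),
            exons=exons or [GenomicInterval(t.seqid, t.start - 1, t.end, t.strand)],
            gene_id=t.id + "_gene",
            biotype=_biotype(t),
        )
        log.info("read_annotation: synthesized gene for orphan transcript %s", t.id)
        genes.append(
            GeneModel(gene_id=tx.gene_id, span=tx.span, transcripts=[tx], biotype=tx.biotype)
        )
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path, dialect: str = "gff3") -> None:
    """Write GeneModels back to GFF3 or GTF (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
            s = g.span
            if dialect == "gff3":
                fh.write(
                    f"{s.chrom}\tlncregnet\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t"
                    f"ID={g.gene_id};biotype={g.biotype}\n"
                )
            for t in g.transcripts:
                ts = t.span
                if dialect == "gff3":
                    attrs = f"ID={t.transcript_id};Parent={g.gene_id};biotype={t.biotype}"
                else:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'biotype "{t.biotype}";'
                    )
                ftype = "mRNA" if dialect == "gff3" else "transcript"
                fh.write(
                    f"{ts.chrom}\tlncregnet\t{ftype}\t{ts.start + 1}\t{ts.end}\t.\t"
                    f"{ts.strand}\t.\t{attrs}\n"
                )
                for i, e in enumerate(t.exons, 1):
                    if dialect == "gff3":
                        eattrs = f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                    else:
                        eattrs = attrs
                    fh.write(
                        f"{e.chrom}\tlncregnet\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{eattrs}\n"
                    )


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}, uppercased, U normalised to T."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(
    path: str | Path,
    max_evalue: float = 1e-5,
    subject_species: str | Mapping[str, str] = "",
) -> list[HomologyHit]:
    """Parse 12-column BLAST outfmt 6; keep rows with evalue strictly below
    ``max_evalue`` (the screening convention is a strict ``<``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    bad = df.isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: wrong column count at line {int(bad.idxmax()) + 1}")
    kept, dropped = [], 0
    for row in df.itertuples(index=False):
        if not (row.evalue < max_evalue):
            dropped += 1
            continue
        if isinstance(subject_species, str):
            sp = subject_species
        else:
            sp = subject_species.get(row.sseqid, "")
        kept.append(
            HomologyHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                e_value=float(row.evalue),
                bit_score=float(row.bitscore),
                subject_species=sp,
            )
        )
    log.info("read_blast_tab: kept %d, dropped %d (E >= %g)", len(kept), dropped, max_evalue)
    return kept


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(
    path: str | Path,
    sample_to_stage: Mapping[str, str] | None = None,
    stage_order: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """TSV with feature ids in the first column, sample ids in the header.

    When no sample->stage mapping is given, stages are inferred from sample
    names of the form ``<stage>-<replicate>`` (e.g. ``T1-2``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_to_stage is None:
        sample_to_stage = {s: s.rsplit("-", 1)[0] for s in df.columns}
    if stage_order is None:
        stage_order = list(dict.fromkeys(sample_to_stage[s] for s in df.columns))
    return ExpressionMatrix(df, sample_to_stage, stage_order)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# network export


def write_network_tsv(
    nodes: Iterable[tuple[str, str]],
    edges: Iterable[Mapping[str, object]],
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write ``<prefix>.nodes.tsv`` / ``<prefix>.edges.tsv``.

    Nodes are (id, type) pairs; each edge mapping must carry ``source`` and
    ``target`` referencing node ids, plus arbitrary attribute columns.
    Ordering is deterministic (sorted by id / endpoint pair).
    """
    nodes = sorted(set(nodes))
    node_ids = {n for n, _ in nodes}
    edges = list(edges)
    for e in edges:
        if e["source"] not in node_ids or e["target"] not in node_ids:
            raise AnnotationError(f"edge references unknown node: {dict(e)}")
    prefix = Path(path_prefix)
    node_path = prefix.with_suffix(prefix.suffix + ".nodes.tsv")
    edge_path = prefix.with_suffix(prefix.suffix + ".edges.tsv")

    pd.DataFrame(nodes, columns=["id", "type"]).to_csv(node_path, sep="\t", index=False)
    cols = ["source", "target"] + sorted(
        {k for e in edges for k in e} - {"source", "target"}
    )
    edf = pd.DataFrame(edges, columns=cols)
    if len(edf):
        edf = edf.sort_values(["source", "target"]).reset_index(drop=True)
    edf.to_csv(edge_path, sep="\t", index=False)
    return node_path, edge_path


def read_network_tsv(path_prefix: str | Path) -> tuple[list[tuple[str, str]], list[dict]]:
    prefix = Path(path_prefix)
    ndf = pd.read_csv(prefix.with_suffix(prefix.suffix + ".nodes.tsv"), sep="\t")
    edf = pd.read_csv(prefix.with_suffix(prefix.suffix + ".edges.tsv"), sep="\t")
    nodes = [(str(r.id), str(r.type)) for r in ndf.itertuples(index=False)]
    edges = edf.to_dict(orient="records")
    return nodes, edges
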