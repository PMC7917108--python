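"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the design of a heat-stress lncRNA study: a toy
genome with protein-coding genes and lncRNA loci of known positional class,
a 5-stage x 3-replicate FPKM matrix with planted stage profiles and planted
lncRNA–mRNA coexpression, miRNA/lncRNA/mRNA sequence sets with planted
decoy and target sites (both rule-conformant and rule-violating), and
multi-species lncRNA sets with planted homologies and hairpin families.

Every planted object is re-verified against the consuming module's
predicate before it is returned (a failed verification redraws the object),
so the emitted truth tables are consistent by construction.  All outputs
are a deterministic function of the seed.

Default scale — 200 coding genes, 30 lncRNAs per positional class, a
5x3 expression matrix, 10 miRNAs, 5 species — keeps a full end-to-end run
well under a minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cerna, conservation, identify
from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    write_annotation,
    write_expression_tsv,
    write_fasta,
)

__all__ = [
    "SimParams",
    "AnnotationSim",
    "ExpressionSim",
    "CernaSim",
    "SpeciesSim",
    "simulate_annotation",
    "simulate_expression",
    "simulate_cerna",
    "simulate_species_sets",
    "simulate_all",
]

_COMP = str.maketrans("ACGT", "TGCA")

STAGES = ("control", "T1", "T4", "T8", "T12")

# stage-mean FPKM shapes mirroring heat-response archetypes: an early spike
# (heat-shock-protein-like), an early drop (ABA-receptor-like), a late rise,
# a mid peak, and a flat background
PROFILES = {
    "early_spike": (2.0, 40.0, 18.0, 8.0, 4.0),
    "early_drop": (30.0, 6.0, 4.0, 3.0, 2.0),
    "late_rise": (2.0, 3.0, 6.0, 14.0, 30.0),
    "mid_peak": (3.0, 8.0, 30.0, 12.0, 5.0),
    "flat": (8.0, 8.0, 8.0, 8.0, 8.0),
}
_PAIR_PROFILES = ("early_spike", "early_drop", "late_rise", "mid_peak")


@dataclass
class SimParams:
    seed: int = 0
    n_genes: int = 200
    n_lnc_per_class: int = 30
    n_filter_decoys: int = 5  # per removal category
    genome_len: int = 2_500_000
    n_stages: int = 5
    n_reps: int = 3
    n_planted_trans_pairs: int = 100
    n_mirnas: int = 10
    n_planted_decoys: int = 1  # conformant sites per miRNA
    n_planted_violations: int = 4  # one per rule per miRNA
    noise_sd: float = 0.05
    n_species: int = 5
    n_families: int = 8
    n_lnc_per_species: int = 30
    n_planted_homologs: int = 15

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_lnc_per_class", "n_filter_decoys", "genome_len",
            "n_planted_trans_pairs", "n_mirnas", "n_species", "n_families",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _noncoding_seq(rng: np.random.Generator, n: int, cutoff_aa: int = 100) -> str:
    """Random sequence re-drawn until the longest-ORF stand-in calls it
    noncoding (keeps planted lncRNAs consistent with the screen)."""
    for _ in range(100):
        s = _rand_seq(rng, n)
        if identify.orf_stand_in(s) < cutoff_aa:
            return s
    raise RuntimeError("could not draw a noncoding sequence")


# ---------------------------------------------------------------------------
# annotation


@dataclass
class AnnotationSim:
    genome: dict[str, str]
    genes: list[GeneModel]
    candidates: list[TranscriptModel]
    sequences: dict[str, str]
    coding_labels: dict[str, str]
    planted_fpkm: dict[str, float]
    truth: pd.DataFrame  # transcript_id, category, expected_retained, expected_class

    def write_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_annotation(self.genes, outdir / "genes.gff3", dialect="gff3")
        cand_genes = [
            GeneModel(gene_id=t.gene_id or t.transcript_id + "_g", span=t.span,
                      transcripts=[t], biotype="transcript")
            for t in self.candidates
        ]
        write_annotation(cand_genes, outdir / "transcripts.gtf", dialect="gtf")
        write_fasta(self.sequences, outdir / "transcripts.fa")
        self.truth.to_csv(outdir / "truth_annotation.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(k, v) for k, v in sorted(self.coding_labels.items())],
            columns=["transcript_id", "label"],
        ).to_csv(outdir / "coding_labels.tsv", sep="\t", index=False)


def _make_tx(
    tx_id: str, chrom: str, strand: str, exon_coords: Sequence[tuple[int, int]],
    biotype: str = "transcript", gene_id: str | None = None,
) -> TranscriptModel:
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    span = GenomicInterval(chrom, exon_coords[0][0], exon_coords[-1][1], strand)
    return TranscriptModel(
        transcript_id=tx_id, span=span, exons=exons, gene_id=gene_id, biotype=biotype
    )


def _extract_seq(genome: str, tx: TranscriptModel) -> str:
    s = "".join(genome[e.start : e.end] for e in tx.exons)
    return _revcomp(s) if tx.span.strand == "-" else s


def _plant_seq(genome: list[str], tx: TranscriptModel, seq: str) -> None:
    """Write a transcript sequence into the genome at the exon positions."""
    if tx.span.strand == "-":
        seq = _revcomp(seq)
    pos = 0
    for e in tx.exons:
        genome[e.start : e.end] = list(seq[pos : pos + len(e)])
        pos += len(e)


def simulate_annotation(p: SimParams | None = None) -> AnnotationSim:
    """Toy genome + coding annotation + candidate transcripts with known
    screening outcome and positional class."""
    p = p or SimParams()
    rng = np.random.default_rng(p.seed)
    chrom = "chr1"
    genome = list(_rand_seq(rng, p.genome_len))

    genes: list[GeneModel] = []
    gene_slots: list[dict] = []  # geometry bookkeeping for lncRNA planting
    cursor = 2000
    for i in range(p.n_genes):
        gap_len = int(rng.integers(4000, 8000))
        start = cursor + gap_len
        strand = "+" if rng.random() < 0.5 else "-"
        e1 = (start, start + 300)
        intron1 = (e1[1], e1[1] + 2000)
        e2 = (intron1[1], intron1[1] + 200)
        intron2 = (e2[1], e2[1] + 400)
        e3 = (intron2[1], intron2[1] + 300)
        gid = f"GENE_{i:04d}"
        tx = _make_tx(f"{gid}.t1", chrom, strand, [e1, e2, e3], "mRNA", gid)
        genes.append(
            GeneModel(gene_id=gid, span=tx.span, transcripts=[tx], biotype="protein_coding")
        )
        gene_slots.append(
            {"gap": (cursor, start), "e1": e1, "intron1": intron1, "strand": strand}
        )
        cursor = e3[1]
        if cursor > p.genome_len - 10_000:
            raise ValueError("genome_len too small for the requested gene count")

    candidates: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    coding_labels: dict[str, str] = {}
    planted_fpkm: dict[str, float] = {}
    truth_rows: list[dict] = []

    def add(tx: TranscriptModel, category: str, retained: bool, klass: str | None,
            fpkm: float = 8.0, label: str | None = None, noncoding_seq: bool = True):
        candidates.append(tx)
        seq = (
            _noncoding_seq(rng, tx.length)
            if noncoding_seq
            else _rand_seq(rng, tx.length)
        )
        _plant_seq(genome, tx, seq)
        sequences[tx.transcript_id] = seq
        planted_fpkm[tx.transcript_id] = fpkm
        if label is not None:
            coding_labels[tx.transcript_id] = label
        truth_rows.append(
            {
                "transcript_id": tx.transcript_id,
                "category": category,
                "expected_retained": retained,
                "expected_class": klass or "",
            }
        )

    n_slots = len(gene_slots)
    slot_iter = iter(range(n_slots))

    def next_slot() -> dict:
        try:
            return gene_slots[next(slot_iter)]
        except StopIteration:
            raise ValueError("not enough genes to host the requested lncRNAs") from None

    for i in range(p.n_lnc_per_class):
        # lincRNA: mid-gap, 2 exons, well clear of both flanking genes
        slot = next_slot()
        g0, g1 = slot["gap"]
        start = g0 + 500
        strand = "+" if rng.random() < 0.5 else "-"
        tx = _make_tx(
            f"LINC_{i:03d}", chrom, strand,
            [(start, start + 250), (start + 350, start + 600)],
        )
        add(tx, "lincRNA", True, "lincRNA")

        # incRNA: wholly inside the large intron of a coding gene
        slot = next_slot()
        i0, i1 = slot["intron1"]
        strand = "+" if rng.random() < 0.5 else "-"
        start = i0 + 200
        tx = _make_tx(
            f"LINT_{i:03d}", chrom, strand,
            [(start, start + 300), (start + 400, start + 700)],
        )
        add(tx, "incRNA", True, "incRNA")

        # lncNAT: first exon overlaps a coding exon on the opposite strand
        slot = next_slot()
        e1s, e1e = slot["e1"]
        strand = "-" if slot["strand"] == "+" else "+"
        start = e1s + 100  # 200 bp overlap with the coding exon
        tx = _make_tx(
            f"LNAT_{i:03d}", chrom, strand,
            [(start, start + 300), (start + 400, start + 650)],
        )
        add(tx, "lncNAT", True, "lncNAT")

    for i in range(p.n_filter_decoys):
        # too short (< 200 nt)
        slot = next_slot()
        g0, _ = slot["gap"]
        tx = _make_tx(
            f"SHORT_{i:02d}", chrom, "+",
            [(g0 + 500, g0 + 590), (g0 + 700, g0 + 760)],
        )
        add(tx, "short", False, None)

        # unreliable mono-exonic (max FPKM < 2)
        slot = next_slot()
        g0, _ = slot["gap"]
        tx = _make_tx(f"MONO_{i:02d}", chrom, "+", [(g0 + 500, g0 + 900)])
        add(tx, "lowfpkm_mono", False, None, fpkm=0.5)

        # same-strand coding-exon overlap
        slot = next_slot()
        e1s, e1e = slot["e1"]
        tx = _make_tx(
            f"SOVL_{i:02d}", chrom, slot["strand"],
            [(e1s + 100, e1s + 400), (e1s + 500, e1s + 750)],
        )
        add(tx, "samestrand_overlap", False, None)

        # labelled coding
        slot = next_slot()
        g0, _ = slot["gap"]
        tx = _make_tx(
            f"CODL_{i:02d}", chrom, "+",
            [(g0 + 500, g0 + 800), (g0 + 900, g0 + 1200)],
        )
        add(tx, "coding_label", False, None, label="coding", noncoding_seq=False)

    genome_str = "".join(genome)
    truth = pd.DataFrame(truth_rows)

    sim = AnnotationSim(
        genome={chrom: genome_str},
        genes=genes,
        candidates=candidates,
        sequences={t.transcript_id: _extract_seq(genome_str, t) for t in candidates},
        coding_labels=coding_labels,
        planted_fpkm=planted_fpkm,
        truth=truth,
    )

    # re-verify the planted truth against the identify module before emission
    expr = ExpressionMatrix(
        pd.DataFrame({"s1": planted_fpkm}),
        {"s1": "single"},
        ["single"],
    )
    params = identify.FilterParams(
        coding_labels=coding_labels, sequences=sim.sequences
    )
    lncs, _ = identify.identify_lncrnas(sim.candidates, sim.genes, expr, params)
    got = {l.transcript.transcript_id: l.positional_class for l in lncs}
    for row in truth_rows:
        tid = row["transcript_id"]
        if row["expected_retained"]:
            if got.get(tid) != row["expected_class"]:
                raise RuntimeError(f"planted {tid} verifies as {got.get(tid)!r}")
        elif tid in got:
            raise RuntimeError(f"planted removal candidate {tid} survived the screen")
    return sim


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSim:
    expr: ExpressionMatrix
    trans_pairs: list[tuple[str, str]]  # planted coexpressed (lncRNA, mRNA)
    de_truth: dict[str, set[str]]  # comparison -> planted DE features
    profile_of: dict[str, str]

    def write_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_tsv(self.expr, outdir / "fpkm.tsv")
        pd.DataFrame(self.trans_pairs, columns=["lncrna_id", "mrna_id"]).to_csv(
            outdir / "truth_trans_pairs.tsv", sep="\t", index=False
        )


def simulate_expression(
    lnc_ids: Sequence[str],
    mrna_ids: Sequence[str],
    p: SimParams | None = None,
    low_fpkm_ids: Sequence[str] = (),
) -> ExpressionSim:
    """FPKM matrix over 5 stages x 3 replicates with planted stage profiles.

    The first ``n_planted_trans_pairs`` (lncRNA, mRNA) pairs share a non-flat
    profile (with independent scale factors — scale does not move Pearson r);
    noise is multiplicative log-normal with sd ``noise_sd`` on the log2
    scale.  Features in ``low_fpkm_ids`` get a uniformly low profile
    (max FPKM < 2) for the mono-exonic reliability filter.
    """
    p = p or SimParams()
    rng = np.random.default_rng(p.seed + 1)
    low = set(low_fpkm_ids)
    pairable_lnc = [f for f in lnc_ids if f not in low]
    pairable_mrna = [f for f in mrna_ids if f not in low]
    n_pairs = min(p.n_planted_trans_pairs, len(pairable_lnc), len(pairable_mrna))
    samples = [f"{st}-{r + 1}" for st in STAGES for r in range(p.n_reps)]
    stage_of = {s: s.rsplit("-", 1)[0] for s in samples}

    profile_of: dict[str, str] = {}
    scale_of: dict[str, float] = {}
    trans_pairs: list[tuple[str, str]] = []

    for i in range(n_pairs):
        prof = _PAIR_PROFILES[i % len(_PAIR_PROFILES)]
        for fid in (pairable_lnc[i], pairable_mrna[i]):
            profile_of[fid] = prof
            scale_of[fid] = float(rng.uniform(0.5, 2.0))
        trans_pairs.append((pairable_lnc[i], pairable_mrna[i]))

    all_ids = list(dict.fromkeys(list(lnc_ids) + list(mrna_ids)))
    for fid in all_ids:
        if fid in profile_of:
            continue
        if fid in low:
            profile_of[fid] = "flat"
            scale_of[fid] = 0.06  # max FPKM ~0.5, safely below the cutoff
        else:
            profile_of[fid] = "flat"
            scale_of[fid] = float(rng.uniform(0.5, 2.0))

    values = np.empty((len(all_ids), len(samples)))
    for r, fid in enumerate(all_ids):
        shape = np.array(PROFILES[profile_of[fid]])
        base = np.repeat(shape, p.n_reps) * scale_of[fid]
        noise = 2.0 ** rng.normal(0.0, p.noise_sd, size=base.size)
        values[r] = base * noise
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=all_ids, columns=samples), stage_of, list(STAGES)
    )

    control = STAGES[0]
    de_truth: dict[str, set[str]] = {}
    for st in STAGES[1:]:
        comp = f"{st}_vs_{control}"
        si = STAGES.index(st)
        de_truth[comp] = {
            fid
            for fid in all_ids
            if fid not in low
            and max(
                PROFILES[profile_of[fid]][si] / PROFILES[profile_of[fid]][0],
                PROFILES[profile_of[fid]][0] / PROFILES[profile_of[fid]][si],
            )
            >= 4.0
        }
    return ExpressionSim(expr, trans_pairs, de_truth, profile_of)


# ---------------------------------------------------------------------------
# ceRNA


@dataclass
class CernaSim:
    mirnas: dict[str, str]
    lncrnas: dict[str, str]
    mrnas: dict[str, str]
    truth_sites: pd.DataFrame  # lncrna_id, mirna_id, kind, violated_rule, start
    truth_targets: list[tuple[str, str]]  # (mirna_id, mrna_id)

    def write_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.mirnas, outdir / "mirnas.fa")
        write_fasta(self.lncrnas, outdir / "lncrnas_cerna.fa")
        write_fasta(self.mrnas, outdir / "mrnas_cerna.fa")
        self.truth_sites.to_csv(outdir / "truth_decoy_sites.tsv", sep="\t", index=False)
        pd.DataFrame(self.truth_targets, columns=["mirna_id", "mrna_id"]).to_csv(
            outdir / "truth_target_pairs.tsv", sep="\t", index=False
        )


def _decoy_site(mirna: str, rng: np.random.Generator, bulge: tuple[int, int] | None,
                mm_positions: Sequence[int] = ()) -> str:
    """Target site (5'->3', DNA alphabet) pairing the miRNA antiparallel with
    an optional bulge after miRNA position k and self-base mismatches at the
    given miRNA positions (a base never pairs itself, so partner := base)."""
    partners = []
    for pos, b in enumerate(mirna, start=1):  # 3'->5' of the site
        partners.append(b if pos in mm_positions else b.translate(_COMP))
    if bulge is not None:
        k, blen = bulge
        extra = list(_rand_seq(rng, blen))
        partners = partners[:k] + extra + partners[k:]
    return "".join(reversed(partners))


def _embed(background: str, site: str, at: int) -> str:
    return background[:at] + site + background[at + len(site):]


def simulate_cerna(p: SimParams | None = None) -> CernaSim:
    """miRNA set plus lncRNAs carrying one rule-conformant decoy site and one
    single-rule violator per rule, and mRNAs carrying perfect target sites.

    Every planted site is verified against ``decoy_search`` (conformant =>
    accepted, violator => rejected, with the energy/seed/mismatch violators
    additionally checked for the intended failure reason); a miRNA whose
    geometry cannot realise all five constructs is redrawn.
    """
    p = p or SimParams()
    rng = np.random.default_rng(p.seed + 2)
    mirnas: dict[str, str] = {}
    lncrnas: dict[str, str] = {}
    mrnas: dict[str, str] = {}
    rows: list[dict] = []
    truth_targets: list[tuple[str, str]] = []

    for mi in range(p.n_mirnas):
        mid = f"miR{mi + 1:02d}"
        for _attempt in range(200):
            mir = _rand_seq(rng, 21, gc=0.55)
            allowed_k = (9, 10, 11)
            allowed_b = (2, 3, 4)
            constructs = {
                "conformant": dict(
                    bulge=(int(rng.choice(allowed_k)), int(rng.choice(allowed_b))),
                    mm=(),
                ),
                "energy": dict(bulge=(10, 4), mm=(13, 15, 17, 19)),
                "bulge": dict(bulge=(10, 5), mm=()),
                "seed": dict(bulge=None, mm=(5,)),
                "mismatch_count": dict(bulge=None, mm=(9, 10, 11, 12, 13)),
            }
            cand_lnc: dict[str, tuple[str, int]] = {}
            for kind, cfg in constructs.items():
                site = _decoy_site(mir, rng, cfg["bulge"], cfg["mm"])
                bg = _noncoding_seq(rng, 320)
                at = int(rng.integers(40, 320 - len(site) - 40))
                cand_lnc[kind] = (_embed(bg, site, at), at)

            hits = {
                kind: cerna.decoy_search({mid: mir}, {"x": seq})[0]
                for kind, (seq, _at) in cand_lnc.items()
            }
            ok = hits["conformant"].accepted
            ok = ok and not any(h.accepted for k, h in hits.items() if k != "conformant")
            ok = ok and hits["energy"].rejection_reasons == ("energy",)
            ok = ok and "seed-violation" in hits["seed"].rejection_reasons
            ok = ok and "energy" not in hits["seed"].rejection_reasons
            ok = ok and "mismatch-count" in hits["mismatch_count"].rejection_reasons
            ok = ok and "energy" not in hits["mismatch_count"].rejection_reasons
            if not ok:
                continue

            mirnas[mid] = mir
            for j, (kind, (seq, at)) in enumerate(cand_lnc.items()):
                lid = f"LNC_{mi + 1:02d}_{kind}"
                lncrnas[lid] = seq
                rows.append(
                    {
                        "lncrna_id": lid,
                        "mirna_id": mid,
                        "kind": "conformant" if kind == "conformant" else "violator",
                        "violated_rule": "" if kind == "conformant" else kind,
                        "site_start": at,
                    }
                )
            # two mRNAs with perfect (expectation 0) target sites
            for t in range(2):
                gid = f"MRNA_{mi + 1:02d}_{t + 1}"
                site = _decoy_site(mir, rng, bulge=None)
                bg = _rand_seq(rng, 500)
                at = int(rng.integers(50, 500 - len(site) - 50))
                mrnas[gid] = _embed(bg, site, at)
                truth_targets.append((mid, gid))
            break
        else:
            raise RuntimeError(f"could not realise planted sites for {mid}")

    # verify target plantings
    target_hits = cerna.predict_targets(mirnas, mrnas)
    found = {(t.mirna_id, t.mrna_id) for t in target_hits}
    missing = set(truth_targets) - found
    if missing:
        raise RuntimeError(f"planted target sites not recovered: {missing}")

    return CernaSim(
        mirnas=mirnas,
        lncrnas=lncrnas,
        mrnas=mrnas,
        truth_sites=pd.DataFrame(rows),
        truth_targets=truth_targets,
    )


# ---------------------------------------------------------------------------
# species sets


@dataclass
class SpeciesSim:
    species_sets: dict[str, conservation.SpeciesSet]
    hairpins: dict[str, str]
    truth_homologs: list[tuple[str, str, str]]  # (query id, subject species, subject id)
    truth_presence: pd.DataFrame  # family x species booleans

    def write_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp, ss in self.species_sets.items():
            write_fasta(ss.lncrna_seqs, outdir / f"lncrna_{sp}.fa")
        write_fasta(self.hairpins, outdir / "hairpins.fa")
        self.truth_presence.to_csv(outdir / "truth_presence.tsv", sep="\t")


def simulate_species_sets(p: SimParams | None = None) -> SpeciesSim:
    """Per-species lncRNA sets with planted homolog blocks (0–5% mutations)
    and hairpin families embedded per a planted presence matrix."""
    p = p or SimParams()
    if p.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(p.seed + 3)
    species = [f"species_{chr(ord('A') + i)}" for i in range(p.n_species)]

    seqs: dict[str, dict[str, str]] = {
        sp: {
            f"{sp}_lnc{j:03d}": _rand_seq(rng, int(rng.integers(250, 400)))
            for j in range(p.n_lnc_per_species)
        }
        for sp in species
    }

    # homologs: blocks copied from the focal (first) species into others
    focal = species[0]
    focal_ids = sorted(seqs[focal])
    truth_homologs: list[tuple[str, str, str]] = []
    for h in range(min(p.n_planted_homologs, len(focal_ids))):
        qid = focal_ids[h]
        target_sp = species[1 + h % (p.n_species - 1)]
        tid = sorted(seqs[target_sp])[h % p.n_lnc_per_species]
        block = seqs[focal][qid][:250]
        mut_rate = float(rng.uniform(0.0, 0.05))
        chars = list(block)
        n_mut = int(round(mut_rate * len(chars)))
        for pos in rng.choice(len(chars), size=n_mut, replace=False):
            chars[pos] = "ACGT"[int(rng.integers(4))]
        tseq = seqs[target_sp][tid]
        seqs[target_sp][tid] = "".join(chars) + tseq[250:]
        truth_homologs.append((qid, target_sp, tid))

    # hairpin families and their planted presence pattern
    fam_names = [f"MIR{400 + 10 * i}" for i in range(p.n_families)]
    hairpins = {f: _rand_seq(rng, 100) for f in fam_names}
    presence = np.zeros((p.n_families, p.n_species), dtype=bool)
    for i in range(p.n_families):
        if i == 0:
            members = list(range(p.n_species))  # one family common to all
        else:
            size = 1 + int(rng.integers(0, p.n_species))
            members = sorted(rng.choice(p.n_species, size=size, replace=False))
        for s in members:
            presence[i, s] = True
            sp = species[s]
            # dedicated host lncRNA, extended with the hairpin copy
            host = f"{sp}_mirhost{i:02d}"
            seqs[sp][host] = _rand_seq(rng, 80) + hairpins[fam_names[i]] + _rand_seq(rng, 80)

    sets = {
        sp: conservation.SpeciesSet(species=sp, lncrna_seqs=dict(sorted(seqs[sp].items())))
        for sp in species
    }
    truth_presence = pd.DataFrame(presence, index=fam_names, columns=species)

    # verify: the precursor scan reproduces the planted presence matrix
    records = {
        sp: conservation.precursor_scan(sets[sp], hairpins) for sp in species
    }
    mat = conservation.family_presence(records)
    got = pd.DataFrame(mat.present, index=mat.families, columns=mat.species)
    got = got.reindex(index=fam_names, columns=species, fill_value=False)
    if not got.equals(truth_presence):
        raise RuntimeError("planted family presence not recovered by the scan")

    return SpeciesSim(
        species_sets=sets,
        hairpins=hairpins,
        truth_homologs=truth_homologs,
        truth_presence=truth_presence,
    )


# ---------------------------------------------------------------------------


@dataclass
class FullSim:
    annotation: AnnotationSim
    expression: ExpressionSim
    cerna: CernaSim
    species: SpeciesSim


def simulate_all(p: SimParams | None = None) -> FullSim:
    """All fixture families for an end-to-end pipeline run."""
    p = p or SimParams()
    ann = simulate_annotation(p)
    lnc_ids = [
        r.transcript_id
        for r in ann.truth.itertuples(index=False)
        if r.expected_retained or r.category == "lowfpkm_mono"
    ]
    mrna_ids = [g.gene_id for g in ann.genes]
    low = [t for t in lnc_ids if t.startswith("MONO_")]
    expr = simulate_expression(lnc_ids, mrna_ids, p, low_fpkm_ids=low)
    cer = simulate_cerna(p)
    spc = simulate_species_sets(p)
    return FullSim(annotation=ann, expression=expr, cerna=cer, species=spc)
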