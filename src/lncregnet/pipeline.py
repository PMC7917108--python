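"""End-to-end orchestration with a single flat config and a run manifest.

Stages run in dependency order: identify -> (expression | conservation) ->
regnet -> cerna -> enrichment/report.  Every stage writes TSVs into the run
directory; a stage whose inputs are not configured is skipped.  The manifest
records the package version, the config (and its hash), the seed, and a
checksum of every input file, which is sufficient to reproduce the outputs
byte-for-byte.

Every threshold default is the screening value the pipeline is built
around (length 200 nt, cis window 100 kb, |r| > 0.95 with p < 0.01,
q < 0.05, MFE < −25 kcal/mol, expectation <= 3, HSP >= 20, E < 1e-5);
overrides are explicit config keys and land in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cerna import DecoyRules, build_triads, decoy_search, export_cerna_network, predict_targets
from .conservation import SpeciesSet, family_presence, precursor_scan, unique_common
from .enrich_report import (
    aggregate_sample_stats,
    hypergeom_enrich,
    read_sample_stats_tsv,
    read_term_map_tsv,
    summarize_lncrnas,
)
from .expression import de_call_all, de_features, detect_expressed, write_de_tsv
from .identify import FilterParams, identify_lncrnas
from .io_formats import read_annotation, read_expression_tsv, read_fasta
from .regnet import cis_targets, combine_cis_trans, export_network, sa_pairs, trans_targets

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    # inputs
    annotation: str | None = None
    transcripts: str | None = None
    transcripts_fasta: str | None = None
    expr: str | None = None
    coding_labels: str | None = None
    mirnas: str | None = None
    cerna_lncrnas: str | None = None
    cerna_mrnas: str | None = None
    term_map: str | None = None
    sample_stats: str | None = None
    species_fastas: list[str] = field(default_factory=list)
    hairpins: str | None = None
    # thresholds (defaults are the pipeline's screening values)
    min_length: int = 200
    drop_monoexonic_below_fpkm: float = 2.0
    min_fpkm: float = 0.1
    window: int = 100_000
    r_min: float = 0.95
    p_max: float = 0.01
    q_max: float = 0.05
    mfe_max: float = -25.0
    expectation_max: float = 3.0
    hsp_min: int = 20
    evalue_max: float = 1e-5
    # flags
    pcc_basis: str = "stages"
    seed_allow_gu: bool = False
    window_exclusive: bool = False
    upe: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    """Flat TOML config -> RunConfig; unknown keys are an error."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all configured stages; returns a summary dict (also written
    as ``manifest.json`` / ``summary.json`` in the run directory)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    inputs = {
        k: v
        for k, v in config.to_dict().items()
        if isinstance(v, str) and Path(v).is_file()
    }
    for f in config.species_fastas:
        inputs[f"species:{f}"] = f

    # --- identify ----------------------------------------------------------
    lncrnas = []
    expr = None
    if config.expr:
        expr = read_expression_tsv(config.expr)
    if config.annotation and config.transcripts:
        genes = read_annotation(config.annotation, dialect="gff3")
        asm = read_annotation(config.transcripts, dialect="gtf")
        candidates = [t for g in asm for t in g.transcripts]
        labels = None
        if config.coding_labels:
            ldf = pd.read_csv(config.coding_labels, sep="\t")
            labels = dict(zip(ldf.transcript_id, ldf.label))
        seqs = read_fasta(config.transcripts_fasta) if config.transcripts_fasta else None
        params = FilterParams(
            min_length=config.min_length,
            drop_monoexonic_below_fpkm=config.drop_monoexonic_below_fpkm,
            coding_labels=labels,
            sequences=seqs,
        )
        lncrnas, trace = identify_lncrnas(candidates, genes, expr, params)
        pd.DataFrame(
            [
                {
                    "transcript_id": l.transcript.transcript_id,
                    "class": l.positional_class,
                    "length": l.transcript.length,
                    "exons": l.transcript.n_exons,
                    "filter_trace": ";".join(f"{n}={'pass' if ok else 'fail'}" for n, ok in l.filter_trace),
                }
                for l in lncrnas
            ]
        ).to_csv(out / "lncrna.tsv", sep="\t", index=False)
        stats, class_counts = summarize_lncrnas(lncrnas, expr)
        summary["identify"] = {"n_lncrna": len(lncrnas), "class_counts": class_counts,
                               "mean_length": stats.mean_length,
                               "median_length": stats.median_length}

    # --- expression --------------------------------------------------------
    de_by_comparison: dict[str, list] = {}
    if expr is not None:
        detected = {st: detect_expressed(expr, st, config.min_fpkm) for st in expr.stage_order}
        pd.DataFrame(
            [(st, len(feats)) for st, feats in detected.items()],
            columns=["stage", "n_detected"],
        ).to_csv(out / "detected.tsv", sep="\t", index=False)
        de_by_comparison = de_call_all(expr, alpha_q=config.q_max)
        all_recs = [r for recs in de_by_comparison.values() for r in recs]
        write_de_tsv(all_recs, out / "de.tsv")
        summary["expression"] = {
            comp: len(de_features(recs, config.q_max))
            for comp, recs in de_by_comparison.items()
        }

    # --- regulatory network -------------------------------------------------
    if lncrnas and expr is not None:
        gene_ids = {g.gene_id for g in genes}
        de_any_lnc = set()
        de_any_mrna = set()
        de_sets = {}
        for comp, recs in de_by_comparison.items():
            feats = de_features(recs, config.q_max)
            lset = {f for f in feats if f in {l.transcript.transcript_id for l in lncrnas}}
            mset = {f for f in feats if f in gene_ids}
            de_sets[comp] = (lset, mset)
            de_any_lnc |= lset
            de_any_mrna |= mset
        de_lncrnas = [l for l in lncrnas if l.transcript.transcript_id in de_any_lnc]
        cis = cis_targets(de_lncrnas, genes, window=config.window,
                          inclusive=not config.window_exclusive)
        trans = trans_targets(
            de_any_lnc, de_any_mrna, expr,
            r_min=config.r_min, p_max=config.p_max, basis=config.pcc_basis,
            de_by_comparison=de_sets,
        )
        both = combine_cis_trans(cis, trans)
        sa = sa_pairs(both, de_lncrnas, genes)
        for name, edges in (("cis", cis), ("trans", trans), ("both", both), ("sa", sa)):
            export_network(edges, out / f"regnet_{name}")
        summary["regnet"] = {
            "cis": len(cis), "trans": len(trans), "both": len(both), "sa_pairs": len(sa)
        }

    # --- ceRNA --------------------------------------------------------------
    if config.mirnas and config.cerna_lncrnas and config.cerna_mrnas:
        mirs = read_fasta(config.mirnas)
        clnc = read_fasta(config.cerna_lncrnas)
        cmrna = read_fasta(config.cerna_mrnas)
        rules = DecoyRules(mfe_max=config.mfe_max, seed_allow_gu=config.seed_allow_gu)
        decoys = decoy_search(mirs, clnc, rules)
        targets = predict_targets(
            mirs, cmrna,
            expectation_max=config.expectation_max,
            hsp_min=config.hsp_min,
            check_upe=config.upe,
        )
        triads = build_triads(decoys, targets)
        pd.DataFrame(
            [
                {
                    "lncrna_id": d.lncrna_id, "mirna_id": d.mirna_id,
                    "site_start": d.site[0], "site_end": d.site[1],
                    "mfe": d.duplex.mfe_kcal_mol, "accepted": d.accepted,
                    "reasons": ";".join(d.rejection_reasons),
                }
                for d in decoys
            ]
        ).to_csv(out / "decoys.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "mirna_id": t.mirna_id, "mrna_id": t.mrna_id,
                    "site_start": t.site[0], "site_end": t.site[1],
                    "expectation": t.expectation, "hsp_len": t.hsp_len,
                }
                for t in targets
            ]
        ).to_csv(out / "targets.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triads],
            columns=["lncrna_id", "mirna_id", "mrna_id"],
        ).to_csv(out / "triads.tsv", sep="\t", index=False)
        node_counts = export_cerna_network(triads, out / "cerna_network")
        summary["cerna"] = {
            "accepted_decoys": sum(d.accepted for d in decoys),
            "targets": len(targets),
            "triads": len(triads),
            "nodes": node_counts,
        }

    # --- conservation -------------------------------------------------------
    if config.species_fastas and config.hairpins:
        hairpins = read_fasta(config.hairpins)
        records = {}
        for f in config.species_fastas:
            sp = Path(f).stem.replace("lncrna_", "")
            ss = SpeciesSet(sp, read_fasta(f))
            records[sp] = precursor_scan(ss, hairpins, max_evalue=config.evalue_max)
        matrix = family_presence(records)
        pd.DataFrame(
            matrix.present, index=matrix.families, columns=matrix.species
        ).to_csv(out / "presence.tsv", sep="\t")
        common, unique = unique_common(matrix, matrix.species)
        summary["conservation"] = {
            "families": len(matrix.families),
            "common_all": len(common),
            "unique": len(unique),
        }

    # --- enrichment / report ------------------------------------------------
    if config.term_map and summary.get("regnet") and expr is not None:
        term_map = read_term_map_tsv(config.term_map)
        background = {g.gene_id for g in genes}
        query = {e.mrna_id for e in trans}
        if query:
            results = hypergeom_enrich(query, background, term_map, alpha_q=config.q_max)
            pd.DataFrame([r.__dict__ for r in results]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            summary["enrichment"] = {
                "tested": len(results),
                "significant": sum(r.q_value < config.q_max for r in results),
            }
    if config.sample_stats:
        rows = read_sample_stats_tsv(config.sample_stats)
        total, per_sample, mapped = aggregate_sample_stats(rows)
        summary["sequencing"] = {"total_clean_gb": total, "per_sample_gb": per_sample}

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
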