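"""End-to-end pipeline: site scan -> circle calls -> event calls -> consensus.

Each stage writes its outputs as soon as it finishes, so a failing stage
preserves everything produced before it; failures are re-raised with the
stage name.  User-facing TSV coordinates are 1-based inclusive (noted in the
header line); BED output stays 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .circles import CircleJunctionCall, JunctionType, analyze_circle_read
from .events import EventType, call_chimeras, call_reverse_splice_sites
from .io import PipelineConfig, SeqRead, load_reference, read_fasta, read_fastq, write_bed, write_tsv
from .logo import AnchoredSeq, adjust_alignment, build_pfm, stack_on_junction
from .motifs import scan_transcript

log = logging.getLogger("retrosplice")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _read_reads(path) -> list[SeqRead]:
    p = str(path)
    if p.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz")):
        return read_fastq(path)
    return read_fasta(path)


def _placement_row(target_id: str, m) -> dict:
    return {
        "target_id": target_id,
        "ibs2_start": m.ibs2_start + 1,
        "spacer_len": m.spacer_len,
        "ibs1_start": m.ibs1_start + 1,
        "ibs1_end": m.ibs1_end,
        "score11": m.score11,
        "ibs1_paired": m.ibs1_paired,
        "ibs2_paired": m.ibs2_paired,
        "strength": m.strength.value,
    }


def stage_scan(cfg: PipelineConfig, reference, out: Path) -> pd.DataFrame:
    rows = []
    bed_rows = []
    for gene in reference.genes:
        t = reference.transcript_seq(gene)
        for m in scan_transcript(t, cfg.ebs, cfg.min_score, allow_wobble=cfg.allow_wobble,
                                 target_id=gene.gene_id):
            rows.append(_placement_row(gene.gene_id, m))
            bed_rows.append(
                (gene.seq_id,
                 gene.start + m.motif_start if gene.strand == "+" else gene.end - m.motif_end,
                 gene.start + m.motif_end if gene.strand == "+" else gene.end - m.motif_start,
                 f"{gene.gene_id}:{m.ibs1_end}", m.score11, gene.strand)
            )
    columns = ["target_id", "ibs2_start", "spacer_len", "ibs1_start", "ibs1_end",
               "score11", "ibs1_paired", "ibs2_paired", "strength"]
    df = pd.DataFrame(rows, columns=columns)
    write_tsv(df, out / "sites.tsv", "sites", note="coords=1-based-inclusive")
    write_bed(bed_rows, out / "sites.bed")
    return df


def stage_circles(cfg: PipelineConfig, reads, intron, reference, out: Path):
    calls = [
        analyze_circle_read(
            r, intron, reference, cfg.ebs,
            anchor_len=cfg.anchor_len, min_insert=cfg.min_insert,
            min_map_len=cfg.min_map_len, max_mismatches=cfg.max_mismatches,
            allow_wobble=cfg.allow_wobble,
        )
        for r in reads
    ]
    resolved = [c for c in calls if c.junction_type is not JunctionType.unresolved]
    rows = []
    flank_records = []
    for c in resolved:
        row = {
            "read_id": c.read_id,
            "junction_type": c.junction_type.value,
            "insert_len": c.insert_len,
            "gene_id": c.origin.gene_id if c.origin else "",
            "seq_id": c.origin.seq_id if c.origin else "",
            "insert_start": c.origin.start + 1 if c.origin else "",
            "insert_end": c.origin.end if c.origin else "",
            "strand": c.origin.strand if c.origin else "",
            "spans_intergenic": c.origin.spans_intergenic if c.origin else False,
            "ambiguous": c.origin.ambiguous if c.origin else False,
            "flank5_score": c.flank5_motif.score11 if c.flank5_motif else "",
            "flank3_score": c.flank3_motif.score11 if c.flank3_motif else "",
        }
        rows.append(row)
        if c.flank5:
            flank_records.append(SeqRead(f"{c.read_id}|5p", c.flank5))
        if c.flank3:
            flank_records.append(SeqRead(f"{c.read_id}|3p", c.flank3))
    circle_cols = ["read_id", "junction_type", "insert_len", "gene_id", "seq_id",
                   "insert_start", "insert_end", "strand", "spans_intergenic",
                   "ambiguous", "flank5_score", "flank3_score"]
    df = pd.DataFrame(rows, columns=circle_cols)
    write_tsv(df, out / "circle_calls.tsv", "circle_calls", note="coords=1-based-inclusive")
    from .io import write_fasta

    write_fasta(flank_records, out / "circle_flanks.fasta")
    return calls, resolved


def stage_events(cfg: PipelineConfig, reads, intron, e1, reference, out: Path):
    rs = call_reverse_splice_sites(
        reads, intron, reference, cfg.ebs,
        anchor_len=cfg.anchor_len, min_score=cfg.min_score,
        min_map_len=cfg.min_map_len, max_mismatches=cfg.max_mismatches,
        allow_wobble=cfg.allow_wobble,
    )
    consumed = {rid for c in rs for rid in c.read_ids}
    leftover = [r for r in reads if r.id not in consumed]
    chim = call_chimeras(
        leftover, e1, reference, cfg.ebs,
        anchor_len=cfg.anchor_len, min_score=cfg.min_score,
        min_map_len=cfg.min_map_len, allow_wobble=cfg.allow_wobble,
        intron_ref=intron,
    )
    calls = rs + chim
    rows = [
        {
            "event_type": c.event_type.value,
            "transcript_id": c.transcript_id,
            "donor_id": c.donor_id or "",
            "junction_pos": c.junction_pos + 1,
            "score11": c.motif.score11,
            "strength": c.motif.strength.value,
            "support": c.support,
            "read_ids": ",".join(c.read_ids),
        }
        for c in calls
    ]
    event_cols = ["event_type", "transcript_id", "donor_id", "junction_pos",
                  "score11", "strength", "support", "read_ids"]
    write_tsv(pd.DataFrame(rows, columns=event_cols), out / "events.tsv", "events",
              note="coords=1-based-inclusive")
    return calls


def stage_consensus(cfg: PipelineConfig, reference, circle_calls, event_calls, out: Path):
    """Raw and motif-adjusted consensus matrices for flank and rs-site sets."""
    sets: dict[str, list[AnchoredSeq]] = {"circle_flank5": [], "circle_flank3": [], "rs_sites": []}
    for c in circle_calls:
        if c.junction_type is JunctionType.inserted and c.origin and not c.origin.ambiguous:
            seq = reference.seqs[c.origin.seq_id]
            if c.origin.strand == "-":
                from .pairing import revcomp

                seq = revcomp(seq)
                start = len(seq) - c.origin.end
                end = len(seq) - c.origin.start
            else:
                start, end = c.origin.start, c.origin.end
            sets["circle_flank5"].append(AnchoredSeq(f"{c.read_id}|5p", seq, start))
            sets["circle_flank3"].append(AnchoredSeq(f"{c.read_id}|3p", seq, end))
    for c in event_calls:
        if c.event_type in (EventType.rs_5prime, EventType.rs_3prime):
            t = reference.transcript_seq(c.transcript_id)
            sets["rs_sites"].append(
                AnchoredSeq(f"{c.transcript_id}:{c.junction_pos}", t, c.junction_pos)
            )
    summaries = {}
    for name, records in sets.items():
        if not records:
            continue
        raw = build_pfm(stack_on_junction(records), anchor="raw_junction")
        adj_seqs, flagged = adjust_alignment(records, cfg.ebs, cfg.min_score,
                                             allow_wobble=cfg.allow_wobble)
        adj = build_pfm(adj_seqs, anchor="adjusted_motif")
        adj.flagged_ids = tuple(flagged)
        write_tsv(raw.to_frame(), out / f"consensus_{name}_raw.tsv", f"consensus_{name}_raw")
        write_tsv(adj.to_frame(), out / f"consensus_{name}_adjusted.tsv",
                  f"consensus_{name}_adjusted")
        summaries[name] = {"n": raw.n_sequences, "flagged": len(flagged)}
    return summaries


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute scan -> circles -> events -> consensus and write a report.

    Returns the report dictionary (also written to ``report.json``).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("retrosplice %s seed=%d config=%s", __version__, cfg.seed, cfg.digest())

    def _run(stage, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(stage, exc) from exc

    reference = _run("load", load_reference, cfg.transcriptome_fasta, cfg.annotations)
    intron = read_fasta(cfg.intron_fasta)[0].seq
    e1 = read_fasta(cfg.e1_fasta)[0].seq
    reads = _read_reads(cfg.reads)

    sites_df = _run("scan", stage_scan, cfg, reference, out)
    circle_calls, resolved = _run("circles", stage_circles, cfg, reads, intron, reference, out)
    circle_ids = {c.read_id for c in resolved}
    leftover = [r for r in reads if r.id not in circle_ids]
    event_calls = _run("events", stage_events, cfg, leftover, intron, e1, reference, out)
    consensus = _run("consensus", stage_consensus, cfg, reference, circle_calls, event_calls, out)

    event_ids = {rid for c in event_calls for rid in c.read_ids}
    counts = {
        "reads_total": len(reads),
        "perfect_circles": sum(c.junction_type is JunctionType.perfect for c in circle_calls),
        "inserted_circles": sum(c.junction_type is JunctionType.inserted for c in circle_calls),
        "rs_5prime_sites": sum(c.event_type is EventType.rs_5prime for c in event_calls),
        "rs_3prime_sites": sum(c.event_type is EventType.rs_3prime for c in event_calls),
        "e1_chimeras": sum(c.event_type is EventType.e1_chimera for c in event_calls),
        "mrna_chimeras": sum(c.event_type is EventType.mrna_chimera for c in event_calls),
        "unassigned_reads": len(reads) - len(circle_ids) - len(event_ids),
        "scanned_sites": int(len(sites_df)),
    }
    hist = (
        sites_df["score11"].value_counts().sort_index().to_dict() if len(sites_df) else {}
    )
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "counts": counts,
        "site_score_histogram": {str(k): int(v) for k, v in hist.items()},
        "consensus": consensus,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
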