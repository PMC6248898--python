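"""Standard-format I/O, the annotated reference container, and pipeline config.

FASTA/FASTQ records are parsed with Biopython and exposed as RNA (DNA ``T`` is
converted to ``U`` once on read, per the alphabet policy in
:mod:`retrosplice.pairing`).  Gene annotations come either from GFF3 (parsed
with ``gffutils``) or from a simple 5-column gene table
(``gene_id  seq_id  start  end  strand``, 1-based inclusive coordinates).
Internally all coordinates are 0-based half-open; user-facing TSV is 1-based
inclusive and BED stays 0-based half-open.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .pairing import EBSConfig, revcomp, to_rna

log = logging.getLogger("retrosplice")

TSV_FORMAT_VERSION = "retrosplice-tsv/1"


@dataclass
class SeqRead:
    """One sequence record (FASTA or FASTQ), stored as RNA."""

    id: str
    seq: str
    qual: str | None = None


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SeqRead]:
    with _open_text(path) as fh:
        records = [SeqRead(r.id, to_rna(str(r.seq))) for r in SeqIO.parse(fh, "fasta")]
    if not records:
        log.warning("empty FASTA: %s", path)
    return records


def read_fastq(path) -> list[SeqRead]:
    records: list[SeqRead] = []
    try:
        with _open_text(path) as fh:
            for r in SeqIO.parse(fh, "fastq"):
                qual = "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"])
                records.append(SeqRead(r.id, to_rna(str(r.seq)), qual))
    except ValueError as exc:
        with _open_text(path) as fh:
            n_lines = sum(1 for _ in fh)
        raise ValueError(
            f"malformed FASTQ {path} near line {n_lines - n_lines % 4 + 1}: {exc}"
        ) from exc
    if not records:
        log.warning("empty FASTQ: %s", path)
    return records


def write_fasta(records, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_fastq(records, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path, name: str, note: str = "") -> None:
    """Write a table with a versioned comment header.

    User-facing coordinate columns are 1-based inclusive; callers convert
    before handing the frame over.
    """
    with _open_text(path, "wt") as fh:
        fh.write(f"# {TSV_FORMAT_VERSION} table={name}")
        if note:
            fh.write(f" {note}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_bed(rows, path) -> None:
    """Write BED6 rows (seq_id, start, end, name, score, strand), 0-based half-open."""
    with _open_text(path, "wt") as fh:
        for seq_id, start, end, name, score, strand in rows:
            fh.write(f"{seq_id}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Annotated reference


@dataclass(frozen=True)
class Gene:
    """One annotated gene; start/end are 0-based half-open on seq_id."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: bad interval {self.start}..{self.end}")


@dataclass
class Reference:
    """Reference sequences plus gene annotations.

    ``transcript_seq`` returns a gene's mRNA on the transcribed strand, which
    is the only strand inserts and split reads are mapped against.
    """

    seqs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            if g.seq_id not in self.seqs:
                raise ValueError(f"gene {g.gene_id} references unknown sequence {g.seq_id}")
            if g.end > len(self.seqs[g.seq_id]):
                raise ValueError(f"gene {g.gene_id} extends past the end of {g.seq_id}")

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def transcript_seq(self, gene: Gene | str) -> str:
        if isinstance(gene, str):
            gene = self.gene(gene)
        s = self.seqs[gene.seq_id][gene.start : gene.end]
        return s if gene.strand == "+" else revcomp(s)

    def genes_overlapping(self, seq_id: str, start: int, end: int) -> list[Gene]:
        return [
            g
            for g in self.genes
            if g.seq_id == seq_id and g.start < end and start < g.end
        ]

    def gene_at(self, seq_id: str, pos: int) -> Gene | None:
        hits = self.genes_overlapping(seq_id, pos, pos + 1)
        return hits[0] if hits else None


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start positions of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


@dataclass(frozen=True)
class TranscriptHit:
    """Exact match of a segment on a gene's transcribed strand (transcript coords)."""

    gene_id: str
    start: int
    end: int


def map_segment(reference: Reference, segment: str, min_len: int = 15) -> list[TranscriptHit]:
    """Exact-match a read segment against every annotated transcript.

    Matching is on the transcribed strand only.  Returns all hits; a unique
    hit means an unambiguous origin.
    """
    if len(segment) < min_len:
        return []
    hits: list[TranscriptHit] = []
    for g in reference.genes:
        t = reference.transcript_seq(g)
        for s in find_all(t, segment):
            hits.append(TranscriptHit(g.gene_id, s, s + len(segment)))
    return hits


def read_gene_table(path) -> list[Gene]:
    """Read a 5-column gene table (1-based inclusive coordinates)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["gene_id", "seq_id", "start", "end", "strand"],
        dtype={"gene_id": str, "seq_id": str},
        header=None,
    )
    if len(df) and df.iloc[0]["gene_id"] == "gene_id":  # header line present
        df = df.iloc[1:]
    return [
        Gene(r.gene_id, r.seq_id, int(r.start) - 1, int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def read_gff3(path) -> list[Gene]:
    """Extract gene features from GFF3 via an in-memory gffutils database."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(gid, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return genes


def load_reference(fasta_path, annotation_path) -> Reference:
    seqs = {r.id: r.seq for r in read_fasta(fasta_path)}
    ann = str(annotation_path)
    if ann.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        genes = read_gff3(annotation_path)
    else:
        genes = read_gene_table(annotation_path)
    return Reference(seqs=seqs, genes=genes)


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Validated configuration for the full pipeline run."""

    intron_fasta: str
    e1_fasta: str
    transcriptome_fasta: str
    annotations: str
    reads: str
    out_dir: str
    ebs: EBSConfig
    min_score: int = 7
    min_insert: int = 8
    min_map_len: int = 15
    anchor_len: int = 20
    max_mismatches: int = 0
    allow_wobble: bool = True
    seed: int = 0

    def validate(self) -> None:
        for attr in ("intron_fasta", "e1_fasta", "transcriptome_fasta", "annotations", "reads"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if not 0 <= self.min_score <= 12:
            # 12 is allowed as a deliberately unreachable threshold
            raise ValueError("min_score must be in 0..12")
        if self.anchor_len < 8:
            raise ValueError("anchor_len must be >= 8")
        if self.min_insert < 1:
            raise ValueError("min_insert must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with _open_text(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        ebs = EBSConfig(
            name=raw.pop("ebs_name", "intron"),
            ebs1=raw.pop("ebs1"),
            ebs2=raw.pop("ebs2"),
        )
        return cls(ebs=ebs, **raw)

    def digest(self) -> str:
        payload = yaml.safe_dump(
            {k: v for k, v in sorted(self.__dict__.items()) if k != "ebs"}
            | {"ebs1": self.ebs.ebs1, "ebs2": self.ebs.ebs2},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
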