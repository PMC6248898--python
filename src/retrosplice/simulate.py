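"""Mechanistic simulator of intron splicing products with a truth manifest.

The generator emulates the in-vivo pathway model: excised lariats recognize
IBS1/2-like motifs on host mRNAs and reverse-splice there; circularization
from an invaded transcript either rejoins the intron termini head-to-tail
(perfect circle), captures the segment between the invaded site and a
stronger upstream alternative site (inserted circle), or trans-splices free
exon 1 / a processed mRNA fragment onto the downstream segment (E1-mRNA and
mRNA-mRNA chimeras).  A branch-point-deleted mode mimics a reverse-splicing-
deficient intron: only perfect circles and background reads are emitted.

Every emitted read traces to exactly one manifest record or to the
background pool, so callers can be benchmarked for recall and precision at
nucleotide-exact junction resolution.  Identical seed and config give
byte-identical FASTQ and manifest output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Gene, Reference, SeqRead, write_fasta, write_fastq, write_tsv
from .motifs import best_placement, junction_window, placement_at_end
from .pairing import RNA_BASES, EBSConfig, pairs

_BASES = np.array(list("ACGU"))

# geometry margins for planted sites: room for the motif window on the left
# and read context on both sides
_SITE_MARGIN = 70


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated dataset.

    Defaults are the reference desk-scale conditions: a 50-gene toy
    transcriptome of 1-2 kb genes, 20 planted sites spanning the weak-to-
    strong score range 7-11, ten reverse-splice insertions, five circles with
    captured inserts of 20-576 nt (the observed size range), five chimeras of
    each type and 500 background reads, error-free.
    """

    seed: int = 0
    n_genes: int = 50
    gene_len_range: tuple[int, int] = (1000, 2000)
    gc_content: float = 0.36
    n_planted_sites: int = 20
    planted_sites: list[tuple[int, int, int, int]] | None = None  # (gene_idx, junction, score, spacer)
    n_perfect_circles: int = 5
    n_inserted_circles: int = 5
    insert_len_range: tuple[int, int] = (20, 576)
    n_rs_events: int = 10
    n_e1_chimeras: int = 5
    n_mrna_chimeras: int = 5
    n_background_reads: int = 500
    read_len: int = 100
    error_rate: float = 0.0
    event_read_copies: int = 1  # independent clone reads emitted per event junction
    reverse_splicing: bool = True  # False = branch-point-deleted (dA) mode
    chimeras_imply_rs: bool = True
    cleavage_jitter_max: int = 0  # junction may fall 0..max nt 3' of the motif end
    intron_len: int = 300
    e1_len: int = 120
    intergenic_len_range: tuple[int, int] = (60, 150)
    anchor_emit: int = 30  # intron/E1 terminal length emitted in junction reads
    context_len: int = 40  # mRNA context emitted on each side of a junction

    def validate(self) -> None:
        lo, hi = self.insert_len_range
        if not 1 <= lo <= hi:
            raise ValueError("insert_len_range must be a positive range")
        if hi > self.gene_len_range[1] - 2 * _SITE_MARGIN:
            raise ValueError("insert_len_range upper bound leaves no room in genes")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.cleavage_jitter_max < 0 or self.cleavage_jitter_max > 3:
            raise ValueError("cleavage_jitter_max must be in 0..3")
        if self.planted_sites:
            for g, pos, score, spacer in self.planted_sites:
                if not 7 <= score <= 11:
                    raise ValueError(f"planted score {score} outside 7..11")
                if not 0 <= spacer <= 2:
                    raise ValueError(f"planted spacer {spacer} outside 0..2")


@dataclass
class PlantedSite:
    gene_id: str
    junction: int  # transcript coordinate of the first nt 3' of IBS1
    score11: int
    spacer_len: int
    role: str = "background"


@dataclass
class TruthEvent:
    event_type: str  # rs_insertion | perfect_circle | inserted_circle | e1_chimera | mrna_chimera
    read_ids: list[str]
    gene_id: str | None = None
    junction: int | None = None  # transcript coordinate of the cleavage junction
    site_junction: int | None = None  # transcript coordinate of the motif 3' end
    score11: int | None = None
    donor_id: str | None = None
    donor_junction: int | None = None
    donor_score11: int | None = None
    insert: dict | None = None  # seq_id / chrom+transcript bounds / flank scores


@dataclass
class TruthManifest:
    sites: list[PlantedSite] = field(default_factory=list)
    events: list[TruthEvent] = field(default_factory=list)
    background_ids: list[str] = field(default_factory=list)

    def events_of(self, event_type: str) -> list[TruthEvent]:
        return [e for e in self.events if e.event_type == event_type]


@dataclass
class SimResult:
    reference: Reference
    intron: str
    e1: str
    reads: list[SeqRead]
    manifest: TruthManifest
    config: GeneratorConfig
    ebs: EBSConfig


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_perfect_partner(ebs: str, rng: np.random.Generator) -> str:
    """One random perfect partner (candidate orientation, 5'->3')."""
    table = {"A": ("U",), "C": ("G",), "G": ("C", "U"), "U": ("A", "G")}
    n = len(ebs)
    return "".join(
        table[ebs[n - 1 - j]][rng.integers(len(table[ebs[n - 1 - j]]))] for j in range(n)
    )


def _non_pairing_base(ebs_base: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGU" if not pairs(ebs_base, b, allow_wobble=True)]
    return options[rng.integers(len(options))]


def plant_site(
    gene_seq: str,
    position: int,
    target_score: int,
    config: EBSConfig,
    rng: np.random.Generator,
    spacer_len: int = 0,
    max_tries: int = 50,
) -> str:
    """Write an IBS2+spacer+IBS1 word scoring exactly ``target_score`` ending
    at ``position``.

    Starts from a random perfect word (wobble variants included) and degrades
    ``11 - target_score`` randomly chosen scored positions to non-pairing
    bases.  The locus is then re-scored: both the best placement in the
    junction window and the best placement ending exactly at ``position``
    must equal the target, otherwise (flanking-context collisions) the word
    is re-drawn.  Raises after ``max_tries`` failures, naming the locus.
    """
    if not 7 <= target_score <= 11:
        raise ValueError(f"target score {target_score} outside the plantable range 7..11")
    word_len = 11 + spacer_len
    if position - word_len < 0 or position > len(gene_seq):
        raise ValueError(f"position {position} leaves no room for a {word_len}-nt motif")
    for _ in range(max_tries):
        ibs2c = list(_random_perfect_partner(config.ebs2, rng))
        ibs1c = list(_random_perfect_partner(config.ebs1, rng))
        degrade = rng.choice(11, size=11 - target_score, replace=False)
        for d in degrade:
            if d < 5:  # an IBS2-candidate position
                ebs_base = config.ebs2[5 - 1 - d]
                ibs2c[d] = _non_pairing_base(ebs_base, rng)
            else:
                j = d - 5
                ebs_base = config.ebs1[6 - 1 - j]
                ibs1c[j] = _non_pairing_base(ebs_base, rng)
        spacer = random_seq(rng, spacer_len) if spacer_len else ""
        word = "".join(ibs2c) + spacer + "".join(ibs1c)
        new_seq = gene_seq[: position - word_len] + word + gene_seq[position:]
        bp = best_placement(junction_window(new_seq, position), config)
        pe = placement_at_end(new_seq, position, config)
        if bp.score11 == target_score and pe is not None and pe.score11 == target_score:
            return new_seq
    raise RuntimeError(
        f"could not plant a {target_score}/11 site at position {position} "
        f"after {max_tries} attempts"
    )


class _GeneratorState:
    """Mutable per-run state: gene sequences, occupancy, reads, manifest."""

    def __init__(self, config: GeneratorConfig, ebs: EBSConfig):
        config.validate()
        self.cfg = config
        self.ebs = ebs
        self.rng = np.random.default_rng(config.seed)
        self.gene_seqs: list[str] = []
        self.gene_ids: list[str] = []
        self.occupied: list[list[tuple[int, int]]] = []
        self.reads: list[SeqRead] = []
        self.manifest = TruthManifest()
        self._read_no = 0

    # -- infrastructure -----------------------------------------------------

    def next_read_id(self) -> str:
        self._read_no += 1
        return f"r{self._read_no:05d}"

    def emit(self, seq: str) -> str:
        rid = self.next_read_id()
        seq = self._with_errors(seq)
        self.reads.append(SeqRead(rid, seq, "I" * len(seq)))
        return rid

    def emit_copies(self, seq: str) -> list[str]:
        """Emit one read per simulated amplicon clone of an event junction."""
        return [self.emit(seq) for _ in range(self.cfg.event_read_copies)]

    def _with_errors(self, seq: str) -> str:
        rate = self.cfg.error_rate
        if rate <= 0:
            return seq
        chars = list(seq)
        hits = np.nonzero(self.rng.random(len(chars)) < rate)[0]
        for i in hits:
            alts = [b for b in "ACGU" if b != chars[i]]
            chars[i] = alts[self.rng.integers(3)]
        return "".join(chars)

    def _free(self, gene_idx: int, lo: int, hi: int) -> bool:
        return all(hi <= a or b <= lo for a, b in self.occupied[gene_idx])

    def _reserve(self, gene_idx: int, lo: int, hi: int) -> None:
        self.occupied[gene_idx].append((lo, hi))

    def _plant_at(self, gene_idx: int, junction: int, score: int, spacer: int,
                  role: str) -> PlantedSite:
        self.gene_seqs[gene_idx] = plant_site(
            self.gene_seqs[gene_idx], junction, score, self.ebs, self.rng, spacer
        )
        self._reserve(gene_idx, junction - 40, junction + 20)
        site = PlantedSite(self.gene_ids[gene_idx], junction, score, spacer, role)
        self.manifest.sites.append(site)
        return site

    def _place_site(self, score: int, spacer: int, role: str,
                    max_tries: int = 200, exclude_gene: int | None = None
                    ) -> tuple[int, PlantedSite]:
        """Plant a site at a random non-overlapping locus; returns (gene_idx, site)."""
        for _ in range(max_tries):
            g = int(self.rng.integers(self.cfg.n_genes))
            if g == exclude_gene:
                continue
            glen = len(self.gene_seqs[g])
            j = int(self.rng.integers(_SITE_MARGIN, glen - _SITE_MARGIN))
            if self._free(g, j - 40, j + 20):
                return g, self._plant_at(g, j, score, spacer, role)
        raise RuntimeError(f"no free locus found for a {score}/11 {role} site")

    def _jitter(self) -> int:
        if self.cfg.cleavage_jitter_max == 0:
            return 0
        return int(self.rng.integers(0, self.cfg.cleavage_jitter_max + 1))

    # -- event emission -----------------------------------------------------

    def build_references(self, intron_ref: str | None, e1_ref: str | None) -> None:
        cfg, rng = self.cfg, self.rng
        self.intron = intron_ref or random_seq(rng, cfg.intron_len, cfg.gc_content)
        if e1_ref is None:
            e1 = random_seq(rng, cfg.e1_len, cfg.gc_content)
            # the cognate exon 1 ends in a perfect IBS1/2 word
            e1 = plant_site(e1, len(e1), 11, self.ebs, rng, spacer_len=0)
            self.e1 = e1
        else:
            self.e1 = e1_ref
        lo, hi = cfg.gene_len_range
        for i in range(cfg.n_genes):
            self.gene_seqs.append(random_seq(rng, int(rng.integers(lo, hi + 1)), cfg.gc_content))
            self.gene_ids.append(f"g{i + 1:03d}")
            self.occupied.append([])

    def plant_background_sites(self) -> None:
        cfg = self.cfg
        if cfg.planted_sites is not None:
            for g, pos, score, spacer in cfg.planted_sites:
                self._plant_at(g, pos, score, spacer, role="background")
            return
        scores = [7, 8, 9, 10, 11]
        for i in range(cfg.n_planted_sites):
            self._place_site(scores[i % 5], i % 3, role="background")

    def _emit_rs_pair(self, gene_idx: int, site: PlantedSite) -> TruthEvent:
        """Both junction reads of one reverse-splice insertion."""
        cfg = self.cfg
        t = self.gene_seqs[gene_idx]
        j = site.junction + self._jitter()
        r5 = self.emit_copies(t[j - cfg.context_len : j] + self.intron[: cfg.anchor_emit])
        r3 = self.emit_copies(self.intron[-cfg.anchor_emit :] + t[j : j + cfg.context_len])
        ev = TruthEvent(
            "rs_insertion", r5 + r3, gene_id=site.gene_id, junction=j,
            site_junction=site.junction, score11=site.score11,
        )
        self.manifest.events.append(ev)
        return ev

    def emit_rs_events(self) -> None:
        scores = [7, 8, 9, 10, 11]
        for i in range(self.cfg.n_rs_events):
            g, site = self._place_site(scores[i % 5], 0, role="rs")
            self._emit_rs_pair(g, site)

    def emit_perfect_circles(self) -> None:
        cfg = self.cfg
        for _ in range(cfg.n_perfect_circles):
            rids = self.emit_copies(self.intron[-cfg.anchor_emit :] + self.intron[: cfg.anchor_emit])
            self.manifest.events.append(TruthEvent("perfect_circle", rids))

    def emit_inserted_circles(self) -> None:
        cfg, rng = self.cfg, self.rng
        up_scores = [11, 10, 9]
        for i in range(cfg.n_inserted_circles):
            s_up = up_scores[i % 3]
            s_down = int(rng.integers(7, s_up + 1))
            ins_len = int(rng.integers(cfg.insert_len_range[0], cfg.insert_len_range[1] + 1))
            for _ in range(200):
                g = int(rng.integers(cfg.n_genes))
                glen = len(self.gene_seqs[g])
                if glen < ins_len + 2 * _SITE_MARGIN:
                    continue
                j_up = int(rng.integers(_SITE_MARGIN, glen - _SITE_MARGIN - ins_len))
                j_down = j_up + ins_len
                if self._free(g, j_up - 40, j_up + 20) and self._free(g, j_down - 40, j_down + 20):
                    break
            else:
                raise RuntimeError("no room for an inserted-circle site pair")
            up = self._plant_at(g, j_up, s_up, 0, role="circle_up")
            down = self._plant_at(g, j_down, s_down, 0, role="circle_down")
            # freeze the whole captured segment: later planting must not
            # mutate reference bases inside an already-emitted insert
            self._reserve(g, j_up - 40, j_down + 20)
            d_up, d_down = self._jitter(), self._jitter()
            a, b = j_up + d_up, j_down + d_down
            t = self.gene_seqs[g]
            insert = t[a:b]
            rids = self.emit_copies(
                self.intron[-cfg.anchor_emit :] + insert + self.intron[: cfg.anchor_emit]
            )
            self.manifest.events.append(
                TruthEvent(
                    "inserted_circle", rids, gene_id=up.gene_id,
                    insert={
                        "gene_id": up.gene_id,
                        "transcript_start": a,
                        "transcript_end": b,
                        "len": b - a,
                        "flank5_score": s_up,
                        "flank3_score": s_down,
                        "flank5_site_junction": j_up,
                        "flank3_site_junction": j_down,
                    },
                )
            )

    def emit_e1_chimeras(self) -> None:
        cfg = self.cfg
        for i in range(cfg.n_e1_chimeras):
            g, site = self._place_site(10 + i % 2, 0, role="e1")
            rs_ev = None
            if cfg.chimeras_imply_rs:
                rs_ev = self._emit_rs_pair(g, site)
            j = rs_ev.junction if rs_ev else site.junction + self._jitter()
            t = self.gene_seqs[g]
            rids = self.emit_copies(self.e1[-cfg.anchor_emit :] + t[j : j + cfg.context_len])
            self.manifest.events.append(
                TruthEvent(
                    "e1_chimera", rids, gene_id=site.gene_id, junction=j,
                    site_junction=site.junction, score11=site.score11, donor_id="E1",
                )
            )

    def emit_mrna_chimeras(self) -> None:
        cfg = self.cfg
        for i in range(cfg.n_mrna_chimeras):
            gd, donor = self._place_site(9, 0, role="mrna_donor")
            ga, acceptor = self._place_site(10, 0, role="mrna_acceptor", exclude_gene=gd)
            rs_ev = None
            if cfg.chimeras_imply_rs:
                rs_ev = self._emit_rs_pair(ga, acceptor)
            ja = rs_ev.junction if rs_ev else acceptor.junction + self._jitter()
            jd = donor.junction + self._jitter()
            td, ta = self.gene_seqs[gd], self.gene_seqs[ga]
            rids = self.emit_copies(td[jd - cfg.context_len : jd] + ta[ja : ja + cfg.context_len])
            self.manifest.events.append(
                TruthEvent(
                    "mrna_chimera", rids, gene_id=acceptor.gene_id, junction=ja,
                    site_junction=acceptor.junction, score11=acceptor.score11,
                    donor_id=donor.gene_id, donor_junction=jd,
                    donor_score11=donor.score11,
                )
            )

    def emit_background(self) -> None:
        cfg, rng = self.cfg, self.rng
        for _ in range(cfg.n_background_reads):
            g = int(rng.integers(cfg.n_genes))
            t = self.gene_seqs[g]
            start = int(rng.integers(0, len(t) - cfg.read_len + 1))
            rid = self.emit(t[start : start + cfg.read_len])
            self.manifest.background_ids.append(rid)

    def assemble_reference(self) -> Reference:
        cfg, rng = self.cfg, self.rng
        lo, hi = cfg.intergenic_len_range
        chunks = []
        genes = []
        pos = 0
        for gid, gseq in zip(self.gene_ids, self.gene_seqs):
            gap = random_seq(rng, int(rng.integers(lo, hi + 1)), cfg.gc_content)
            chunks.append(gap)
            pos += len(gap)
            chunks.append(gseq)
            genes.append(Gene(gid, "chr1", pos, pos + len(gseq), "+"))
            pos += len(gseq)
        chunks.append(random_seq(rng, int(rng.integers(lo, hi + 1)), cfg.gc_content))
        return Reference(seqs={"chr1": "".join(chunks)}, genes=genes)


def simulate_reads(
    config: GeneratorConfig,
    ebs: EBSConfig,
    intron_ref: str | None = None,
    e1_ref: str | None = None,
) -> SimResult:
    """Run the full generator; see module docstring for the pathway model.

    Event classes that require reverse splicing (insertions, inserted circles
    and both chimera types) are suppressed in branch-point-deleted mode
    (``reverse_splicing=False``).  The RNG call order is fixed, so identical
    seed and config give byte-identical output.
    """
    state = _GeneratorState(config, ebs)
    state.build_references(intron_ref, e1_ref)
    state.plant_background_sites()
    if config.reverse_splicing:
        state.emit_rs_events()
        state.emit_inserted_circles()
        state.emit_e1_chimeras()
        state.emit_mrna_chimeras()
    state.emit_perfect_circles()
    state.emit_background()
    reference = state.assemble_reference()
    # attach chromosome coordinates to insert records
    by_id = {g.gene_id: g for g in reference.genes}
    for ev in state.manifest.events:
        if ev.insert is not None:
            g = by_id[ev.insert["gene_id"]]
            ev.insert["seq_id"] = g.seq_id
            ev.insert["chrom_start"] = g.start + ev.insert["transcript_start"]
            ev.insert["chrom_end"] = g.start + ev.insert["transcript_end"]
    return SimResult(
        reference=reference,
        intron=state.intron,
        e1=state.e1,
        reads=state.reads,
        manifest=state.manifest,
        config=config,
        ebs=ebs,
    )


def write_outputs(sim: SimResult, out_dir) -> dict[str, str]:
    """Write transcriptome FASTA, gene table, references, reads and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcriptome": out / "transcriptome.fasta",
        "genes": out / "genes.tsv",
        "intron": out / "intron.fasta",
        "e1": out / "e1.fasta",
        "reads": out / "reads.fastq",
        "manifest": out / "manifest.json",
        "sites": out / "planted_sites.tsv",
    }
    write_fasta([SeqRead(sid, s) for sid, s in sim.reference.seqs.items()], paths["transcriptome"])
    genes_df = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "seq_id": g.seq_id, "start": g.start + 1,
             "end": g.end, "strand": g.strand}
            for g in sim.reference.genes
        ]
    )
    genes_df.to_csv(paths["genes"], sep="\t", index=False, header=False)
    write_fasta([SeqRead("intron", sim.intron)], paths["intron"])
    write_fasta([SeqRead("E1", sim.e1)], paths["e1"])
    write_fastq(sim.reads, paths["reads"])
    manifest_dict = {
        "sites": [dataclasses.asdict(s) for s in sim.manifest.sites],
        "events": [dataclasses.asdict(e) for e in sim.manifest.events],
        "background_ids": sim.manifest.background_ids,
        "config": dataclasses.asdict(sim.config),
        "ebs": {"name": sim.ebs.name, "ebs1": sim.ebs.ebs1, "ebs2": sim.ebs.ebs2},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest_dict, fh, indent=1, sort_keys=True)
        fh.write("\n")
    sites_df = pd.DataFrame(
        [
            {"gene_id": s.gene_id, "junction": s.junction + 1, "score11": s.score11,
             "spacer_len": s.spacer_len, "role": s.role}
            for s in sim.manifest.sites
        ]
    )
    write_tsv(sites_df, paths["sites"], "planted_sites", note="coords=1-based")
    return {k: str(v) for k, v in paths.items()}
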