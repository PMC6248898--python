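"""Reverse-splice insertion-site and trans-splicing chimera calling.

A lariat that reverse-splices into an mRNA creates two new junctions:
``mRNA|intron-5'`` (the 5' junction) and ``intron-3'|mRNA`` (the 3' junction),
both immediately downstream of an IBS1/2-like motif on the invaded
transcript.  Subsequent circularization from the invaded site trans-splices
either the free ltrB exon 1 (E1-mRNA chimera) or a processed mRNA fragment
carrying an IBS-like 3' end (mRNA-mRNA chimera) onto the downstream segment.

Callers here split junction-spanning reads at exact intron/E1 anchor matches,
map the non-intron part to the transcribed strand of annotated transcripts,
and keep only events supported by a motif scoring at least ``min_score``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .circles import find_approx, has_circular_anchors
from .io import Reference, map_segment
from .motifs import MotifPlacement, best_placement, junction_window
from .pairing import EBSConfig, to_rna

log = logging.getLogger("retrosplice")


class EventType(str, enum.Enum):
    rs_5prime = "rs_5prime"
    rs_3prime = "rs_3prime"
    e1_chimera = "e1_chimera"
    mrna_chimera = "mrna_chimera"


@dataclass
class SpliceEventCall:
    """One motif-supported splicing event on an acceptor transcript.

    ``junction_pos`` is the 0-based transcript position of the first
    nucleotide 3' of the junction; ``support`` counts reads collapsed onto
    the same (event_type, transcript, junction) key.
    """

    event_type: EventType
    transcript_id: str
    junction_pos: int
    motif: MotifPlacement
    donor_id: str | None = None
    support: int = 1
    read_ids: list[str] = field(default_factory=list)


def _merge(calls: list[SpliceEventCall]) -> list[SpliceEventCall]:
    merged: dict[tuple, SpliceEventCall] = {}
    for c in calls:
        key = (c.event_type, c.transcript_id, c.junction_pos, c.donor_id)
        if key in merged:
            merged[key].support += 1
            merged[key].read_ids.extend(c.read_ids)
        else:
            merged[key] = c
    return sorted(
        merged.values(), key=lambda c: (c.event_type.value, c.transcript_id, c.junction_pos)
    )


def _motif_at(reference: Reference, gene_id: str, junction: int,
              config: EBSConfig, allow_wobble: bool) -> MotifPlacement:
    tseq = reference.transcript_seq(gene_id)
    return best_placement(junction_window(tseq, junction, gene_id), config,
                          allow_wobble=allow_wobble)


def call_reverse_splice_sites(
    reads,
    intron_ref: str,
    reference: Reference,
    config: EBSConfig,
    anchor_len: int = 20,
    min_score: int = 7,
    min_map_len: int = 15,
    max_mismatches: int = 0,
    allow_wobble: bool = True,
) -> list[SpliceEventCall]:
    """Call reverse-splice insertion sites from split reads.

    ``mRNA|intron-5'`` reads yield rs_5prime calls and ``intron-3'|mRNA``
    reads rs_3prime calls, both placed at the transcript position where the
    mRNA part meets the intron.  Reads showing both intron termini in
    circular order are circle-junction reads and are skipped; reads whose
    mRNA part cannot be uniquely placed are discarded (counted in the log).
    """
    intron_ref = to_rna(intron_ref)
    head = intron_ref[:anchor_len]
    tail = intron_ref[-anchor_len:]
    calls: list[SpliceEventCall] = []
    n_unmapped = 0
    for read in reads:
        seq = to_rna(read.seq)
        if has_circular_anchors(seq, intron_ref, anchor_len, max_mismatches):
            continue
        head_hits = find_approx(seq, head, max_mismatches)
        tail_hits = find_approx(seq, tail, max_mismatches)
        if head_hits and head_hits[0] >= min_map_len:
            # mRNA prefix then intron 5' terminus
            prefix = seq[: head_hits[0]]
            hits = map_segment(reference, prefix, min_map_len)
            if len(hits) == 1:
                junction = hits[0].end
                motif = _motif_at(reference, hits[0].gene_id, junction, config, allow_wobble)
                if motif.score11 >= min_score:
                    calls.append(
                        SpliceEventCall(
                            EventType.rs_5prime, hits[0].gene_id, junction, motif,
                            read_ids=[read.id],
                        )
                    )
            else:
                n_unmapped += 1
        elif tail_hits and len(seq) - (tail_hits[0] + anchor_len) >= min_map_len:
            # intron 3' terminus then mRNA suffix
            suffix = seq[tail_hits[0] + anchor_len :]
            hits = map_segment(reference, suffix, min_map_len)
            if len(hits) == 1:
                junction = hits[0].start
                motif = _motif_at(reference, hits[0].gene_id, junction, config, allow_wobble)
                if motif.score11 >= min_score:
                    calls.append(
                        SpliceEventCall(
                            EventType.rs_3prime, hits[0].gene_id, junction, motif,
                            read_ids=[read.id],
                        )
                    )
            else:
                n_unmapped += 1
    if n_unmapped:
        log.info("reverse-splice caller: %d split reads had unmappable mRNA parts", n_unmapped)
    return _merge(calls)


def _e1_prefix_len(seq: str, e1_ref: str, anchor_len: int) -> int:
    """Longest L >= anchor_len with seq[:L] == e1_ref[-L:], else 0."""
    for L in range(min(len(e1_ref), len(seq)), anchor_len - 1, -1):
        if seq.startswith(e1_ref[-L:]):
            return L
    return 0


def call_chimeras(
    reads,
    e1_ref: str,
    reference: Reference,
    config: EBSConfig,
    anchor_len: int = 20,
    min_score: int = 7,
    min_map_len: int = 15,
    require_donor_motif: bool = True,
    allow_wobble: bool = True,
    intron_ref: str | None = None,
) -> list[SpliceEventCall]:
    """Call E1-mRNA and mRNA-mRNA trans-splicing chimeras.

    An e1_chimera read starts with the 3' terminus of ltrB exon 1 and
    continues inside another transcript immediately 3' of an IBS-like site.
    An mrna_chimera read joins a donor transcript prefix, ending at an
    IBS-like 3' end, to an acceptor transcript suffix starting just 3' of an
    IBS-like site.  Reads whose two parts are colinear on one transcript are
    ordinary unspliced reads and are discarded.
    """
    e1_ref = to_rna(e1_ref)
    calls: list[SpliceEventCall] = []
    for read in reads:
        seq = to_rna(read.seq)
        if intron_ref is not None:
            # defensive: intron-containing reads belong to the other callers
            if find_approx(seq, intron_ref[:anchor_len]) or find_approx(
                seq, intron_ref[-anchor_len:]
            ):
                continue
        L = _e1_prefix_len(seq, e1_ref, anchor_len)
        if L and len(seq) - L >= min_map_len:
            hits = map_segment(reference, seq[L:], min_map_len)
            if len(hits) == 1:
                junction = hits[0].start
                motif = _motif_at(reference, hits[0].gene_id, junction, config, allow_wobble)
                if motif.score11 >= min_score:
                    calls.append(
                        SpliceEventCall(
                            EventType.e1_chimera, hits[0].gene_id, junction, motif,
                            donor_id="E1", read_ids=[read.id],
                        )
                    )
            continue
        # whole read colinear on some transcript -> ordinary read
        if map_segment(reference, seq, min_map_len):
            continue
        best = None
        best_key = None
        colinear = False
        for k in range(min_map_len, len(seq) - min_map_len + 1):
            ph = map_segment(reference, seq[:k], min_map_len)
            sh = map_segment(reference, seq[k:], min_map_len)
            if len(ph) != 1 or len(sh) != 1:
                continue
            p, s = ph[0], sh[0]
            if p.gene_id == s.gene_id and s.start == p.end:
                colinear = True
                break
            am = _motif_at(reference, s.gene_id, s.start, config, allow_wobble)
            if am.score11 < min_score:
                continue
            dm = _motif_at(reference, p.gene_id, p.end, config, allow_wobble)
            if require_donor_motif and dm.score11 < min_score:
                continue
            key = (
                -(am.score11 + dm.score11),
                abs(am.ibs1_end_offset_from_junction),
                abs(dm.ibs1_end_offset_from_junction),
                k,
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (p, s, am)
        if colinear or best is None:
            continue
        p, s, am = best
        calls.append(
            SpliceEventCall(
                EventType.mrna_chimera, s.gene_id, s.start, am,
                donor_id=p.gene_id, read_ids=[read.id],
            )
        )
    return _merge(calls)
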