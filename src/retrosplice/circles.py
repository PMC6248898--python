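"""Intron-circle splice-junction read classification and insert analysis.

Excised intron circles join the intron's last nucleotide to its first.  A read
spanning the circle splice junction therefore shows the intron 3' terminus
followed by the intron 5' terminus (a circular permutation of the linear
intron).  Circles released by alternative circularization additionally carry a
captured mRNA fragment between the two termini; the fragment maps to the
transcribed strand of a host gene, and IBS1/2-like motifs sit immediately
upstream of both of its extremities on the source transcript.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .io import Gene, Reference, find_all
from .motifs import MotifPlacement, best_placement, junction_window
from .pairing import EBSConfig, revcomp, to_rna


class JunctionType(str, enum.Enum):
    perfect = "perfect"
    inserted = "inserted"
    unresolved = "unresolved"


@dataclass(frozen=True)
class Origin:
    """Mapping of an insert onto the reference (0-based half-open, seq coords)."""

    seq_id: str
    start: int
    end: int
    strand: str
    gene_id: str | None
    spans_intergenic: bool = False
    ambiguous: bool = False
    all_hits: tuple = ()


@dataclass
class CircleJunctionCall:
    read_id: str
    junction_type: JunctionType
    insert_seq: str = ""
    insert_len: int = 0
    reason: str = ""
    origin: Origin | None = None
    flank5: str = ""
    flank3: str = ""
    flank5_motif: MotifPlacement | None = None
    flank3_motif: MotifPlacement | None = None


def find_approx(haystack: str, needle: str, max_mismatches: int = 0) -> list[int]:
    """Start positions where needle matches haystack with <= max_mismatches."""
    if max_mismatches == 0:
        return find_all(haystack, needle)
    n, m = len(haystack), len(needle)
    out = []
    for s in range(n - m + 1):
        mm = 0
        for a, b in zip(haystack[s : s + m], needle):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            out.append(s)
    return out


def has_circular_anchors(read: str, intron_ref: str, anchor_len: int = 20,
                         max_mismatches: int = 0) -> bool:
    """True if the read shows intron 3' anchor followed by intron 5' anchor."""
    tail = intron_ref[-anchor_len:]
    head = intron_ref[:anchor_len]
    for t in find_approx(read, tail, max_mismatches):
        if any(h >= t + anchor_len for h in find_approx(read, head, max_mismatches)):
            return True
    return False


def classify_junction_read(
    read: str,
    intron_ref: str,
    anchor_len: int = 20,
    min_insert: int = 8,
    max_mismatches: int = 0,
    read_id: str = "",
) -> CircleJunctionCall:
    """Classify one read spanning the excised-intron splice junction.

    The intron 3'-terminal anchor must precede the 5'-terminal anchor
    (circular permutation).  Adjacent anchors mean a perfectly joined circle;
    an intervening segment of at least ``min_insert`` nt is a captured insert.
    Anchors absent, in linear order, or separated by a sub-threshold gap give
    an unresolved call with the reason recorded.
    """
    read = to_rna(read)
    intron_ref = to_rna(intron_ref)
    if len(read) < 2 * anchor_len:
        return CircleJunctionCall(read_id, JunctionType.unresolved, reason="read_too_short")
    tail = intron_ref[-anchor_len:]
    head = intron_ref[:anchor_len]
    tail_hits = find_approx(read, tail, max_mismatches)
    head_hits = find_approx(read, head, max_mismatches)
    for t in tail_hits:
        after = [h for h in head_hits if h >= t + anchor_len]
        if not after:
            continue
        h = after[0]
        gap = h - (t + anchor_len)
        if gap == 0:
            return CircleJunctionCall(read_id, JunctionType.perfect)
        if gap >= min_insert:
            insert = read[t + anchor_len : h]
            return CircleJunctionCall(
                read_id, JunctionType.inserted, insert_seq=insert, insert_len=gap
            )
        return CircleJunctionCall(
            read_id, JunctionType.unresolved, reason="insert_below_min"
        )
    if head_hits and tail_hits:
        return CircleJunctionCall(read_id, JunctionType.unresolved, reason="linear_arrangement")
    return CircleJunctionCall(read_id, JunctionType.unresolved, reason="anchors_missing")


def _hit_origin(reference: Reference, seq_id: str, start: int, end: int, strand: str) -> Origin:
    genes = [g for g in reference.genes_overlapping(seq_id, start, end) if g.strand == strand]
    genes.sort(key=lambda g: g.start)
    if not genes:
        return Origin(seq_id, start, end, strand, gene_id=None)
    if len(genes) == 1:
        return Origin(seq_id, start, end, strand, gene_id=genes[0].gene_id)
    # hit spans >1 gene on the same strand plus the intergenic gap(s)
    return Origin(
        seq_id,
        start,
        end,
        strand,
        gene_id=";".join(g.gene_id for g in genes),
        spans_intergenic=True,
    )


def map_insert(insert: str, reference: Reference, min_map_len: int = 15) -> Origin | None:
    """Exact-match an insert on the transcribed strand of annotated genes.

    Forward-strand occurrences are attributed to ``+`` genes and reverse-
    complement occurrences to ``-`` genes, so a reported gene hit is always on
    the transcribed strand.  A hit covering two adjacent genes and the gap
    between them is flagged ``spans_intergenic``.  Multiple distinct loci give
    an ambiguous origin listing all hits; no hit returns None.
    """
    insert = to_rna(insert)
    if len(insert) < min_map_len:
        return None
    raw_hits: list[tuple[str, int, int, str]] = []
    rc = revcomp(insert)
    for seq_id, seq in reference.seqs.items():
        for s in find_all(seq, insert):
            raw_hits.append((seq_id, s, s + len(insert), "+"))
        for s in find_all(seq, rc):
            raw_hits.append((seq_id, s, s + len(insert), "-"))
    origins = [_hit_origin(reference, *h) for h in raw_hits]
    # keep hits attributable to a transcribed-strand gene; fall back to bare loci
    gene_hits = [o for o in origins if o.gene_id is not None]
    pool = gene_hits or origins
    if not pool:
        return None
    if len(pool) > 1:
        first = pool[0]
        return Origin(
            first.seq_id,
            first.start,
            first.end,
            first.strand,
            gene_id=first.gene_id,
            spans_intergenic=first.spans_intergenic,
            ambiguous=True,
            all_hits=tuple(pool),
        )
    return pool[0]


def extract_flanks(
    origin: Origin,
    reference: Reference,
    config: EBSConfig,
    width: int = 30,
    allow_wobble: bool = True,
) -> tuple[str, str, MotifPlacement, MotifPlacement]:
    """Reference context and junction motifs at both insert extremities.

    Each flank is ``width`` nt centered on the extremity (width/2 on each
    side), on the transcribed strand; the motif is the best placement in the
    -14/+4 window anchored at the extremity.  Flanks are shorter near
    transcript ends and the placement carries a truncation flag.
    """
    half = width // 2
    seq = reference.seqs[origin.seq_id]
    if origin.strand == "-":
        # work in transcribed-strand coordinates
        seq = revcomp(seq)
        start = len(seq) - origin.end
        end = len(seq) - origin.start
    else:
        start, end = origin.start, origin.end
    flank5 = seq[max(0, start - half) : start + half]
    flank3 = seq[max(0, end - half) : end + half]
    m5 = best_placement(junction_window(seq, start, origin.seq_id), config,
                        allow_wobble=allow_wobble)
    m3 = best_placement(junction_window(seq, end, origin.seq_id), config,
                        allow_wobble=allow_wobble)
    return flank5, flank3, m5, m3


def analyze_circle_read(
    read,
    intron_ref: str,
    reference: Reference,
    config: EBSConfig,
    anchor_len: int = 20,
    min_insert: int = 8,
    min_map_len: int = 15,
    max_mismatches: int = 0,
    allow_wobble: bool = True,
) -> CircleJunctionCall:
    """classify -> map -> flank extraction for one junction read."""
    call = classify_junction_read(
        read.seq, intron_ref, anchor_len, min_insert, max_mismatches, read_id=read.id
    )
    if call.junction_type is JunctionType.inserted:
        origin = map_insert(call.insert_seq, reference, min_map_len)
        call.origin = origin
        if origin is not None and not origin.ambiguous:
            call.flank5, call.flank3, call.flank5_motif, call.flank3_motif = extract_flanks(
                origin, reference, config, allow_wobble=allow_wobble
            )
    return call
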