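"""IBS1/2-like motif search around junctions and across transcripts.

A target site is an ``[IBS2-like (5 nt)][spacer 0-2 nt][IBS1-like (6 nt)]``
arrangement whose 11 informative positions base pair (Watson-Crick + G·U
wobble) with the intron's EBS2 and EBS1.  Junction-anchored searches use a
window spanning 14 nt upstream to 4 nt downstream of the junction, because
cleavage is not always precisely downstream of the recognized motif: the best
motif may end a few nucleotides to either side of the observed junction.

Sites pairing 10-11/11 positions are classified *strong*, 7-9/11 *weak*; below
7/11 a placement is reported as *below_threshold* and is not considered a
functional site by downstream callers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .pairing import EBSConfig, score_duplex

#: Junction window geometry: [junction - WINDOW_UP, junction + WINDOW_DOWN)
WINDOW_UP = 14
WINDOW_DOWN = 4

STRONG_MIN = 10
WEAK_MIN = 7


class Strength(str, enum.Enum):
    strong = "strong"
    weak = "weak"
    below_threshold = "below_threshold"


def classify_strength(score11: int) -> Strength:
    """Map an 11-position pairing score to the strong/weak site classes."""
    if not 0 <= score11 <= 11:
        raise ValueError(f"score11 out of range 0..11: {score11}")
    if score11 >= STRONG_MIN:
        return Strength.strong
    if score11 >= WEAK_MIN:
        return Strength.weak
    return Strength.below_threshold


@dataclass(frozen=True)
class JunctionWindow:
    """Sequence context around one junction.

    ``junction_pos`` is the 0-based index (on the parent sequence) of the
    first nucleotide 3' of the junction.  ``window_seq`` covers
    ``[junction_pos - 14, junction_pos + 4)`` clipped to the sequence;
    ``truncated`` flags clipping.
    """

    target_id: str
    junction_pos: int
    window_seq: str
    window_start: int
    truncated: bool = False

    @property
    def junction_index(self) -> int:
        """Index of the junction within ``window_seq``."""
        return self.junction_pos - self.window_start


def junction_window(seq: str, junction_pos: int, target_id: str = "") -> JunctionWindow:
    """Extract the -14/+4 window around ``junction_pos`` on ``seq``."""
    if not 0 <= junction_pos <= len(seq):
        raise ValueError(f"junction {junction_pos} outside sequence of length {len(seq)}")
    start = max(0, junction_pos - WINDOW_UP)
    end = min(len(seq), junction_pos + WINDOW_DOWN)
    truncated = start != junction_pos - WINDOW_UP or end != junction_pos + WINDOW_DOWN
    return JunctionWindow(
        target_id=target_id,
        junction_pos=junction_pos,
        window_seq=seq[start:end],
        window_start=start,
        truncated=truncated,
    )


@dataclass(frozen=True)
class MotifPlacement:
    """One scored IBS2-spacer-IBS1 placement on a target sequence.

    Coordinates are 0-based on the target; ``ibs1_end_offset_from_junction``
    is 0 when IBS1 ends exactly at the junction, negative upstream.
    """

    target_id: str
    ibs2_start: int
    spacer_len: int
    ibs1_start: int
    ibs1_end_offset_from_junction: int
    score11: int
    ibs1_paired: int
    ibs2_paired: int
    strength: Strength
    truncated: bool = False
    ibs1_flags: tuple[bool, ...] = field(default=(), repr=False)
    ibs2_flags: tuple[bool, ...] = field(default=(), repr=False)

    @property
    def ibs1_end(self) -> int:
        """0-based exclusive end of IBS1 (= functional cleavage anchor)."""
        return self.ibs1_start + 6

    @property
    def motif_start(self) -> int:
        return self.ibs2_start

    @property
    def motif_end(self) -> int:
        return self.ibs1_end


def _null_placement(target_id: str, junction_pos: int, truncated: bool) -> MotifPlacement:
    return MotifPlacement(
        target_id=target_id,
        ibs2_start=junction_pos,
        spacer_len=0,
        ibs1_start=junction_pos,
        ibs1_end_offset_from_junction=0,
        score11=0,
        ibs1_paired=0,
        ibs2_paired=0,
        strength=Strength.below_threshold,
        truncated=truncated,
    )


def _score_at(
    window_seq: str,
    ibs2_start: int,
    spacer: int,
    config: EBSConfig,
    allow_wobble: bool,
):
    ibs1_start = ibs2_start + 5 + spacer
    d2 = score_duplex(config.ebs2, window_seq[ibs2_start : ibs2_start + 5], allow_wobble)
    d1 = score_duplex(config.ebs1, window_seq[ibs1_start : ibs1_start + 6], allow_wobble)
    return d1, d2


def best_placement(
    window: JunctionWindow,
    config: EBSConfig,
    max_spacer: int = 2,
    allow_wobble: bool = True,
) -> MotifPlacement:
    """Best-scoring motif placement fully inside a junction window.

    Enumerates every ``(ibs2_start, spacer in 0..max_spacer)`` placement and
    maximizes the 11-position pairing score.  Ties are broken, in order, by:
    smallest ``|ibs1 end - junction|``, larger IBS1 pairing (IBS1-like motifs
    are the better defined half of the consensus), smaller spacer, leftmost.
    """
    w = window.window_seq
    if len(w) < 11:
        return _null_placement(window.target_id, window.junction_pos, truncated=True)
    best = None
    best_key = None
    for spacer in range(0, max_spacer + 1):
        motif_len = 11 + spacer
        for s in range(0, len(w) - motif_len + 1):
            d1, d2 = _score_at(w, s, spacer, config, allow_wobble)
            score = d1.paired + d2.paired
            ibs1_end_w = s + 5 + spacer + 6
            offset = ibs1_end_w - window.junction_index
            key = (-score, abs(offset), -d1.paired, spacer, s)
            if best_key is None or key < best_key:
                best_key = key
                best = (s, spacer, d1, d2, offset)
    s, spacer, d1, d2, offset = best
    return MotifPlacement(
        target_id=window.target_id,
        ibs2_start=window.window_start + s,
        spacer_len=spacer,
        ibs1_start=window.window_start + s + 5 + spacer,
        ibs1_end_offset_from_junction=offset,
        score11=d1.paired + d2.paired,
        ibs1_paired=d1.paired,
        ibs2_paired=d2.paired,
        strength=classify_strength(d1.paired + d2.paired),
        truncated=window.truncated,
        ibs1_flags=d1.flags,
        ibs2_flags=d2.flags,
    )


def placement_at_end(
    seq: str,
    ibs1_end: int,
    config: EBSConfig,
    max_spacer: int = 2,
    allow_wobble: bool = True,
    target_id: str = "",
) -> MotifPlacement | None:
    """Best placement whose IBS1 ends exactly at ``ibs1_end`` (exclusive).

    Maximizes over the spacer only; returns None if no placement fits.
    """
    best = None
    best_key = None
    for spacer in range(0, max_spacer + 1):
        ibs2_start = ibs1_end - 11 - spacer
        if ibs2_start < 0 or ibs1_end > len(seq):
            continue
        d2 = score_duplex(config.ebs2, seq[ibs2_start : ibs2_start + 5], allow_wobble)
        d1 = score_duplex(config.ebs1, seq[ibs1_end - 6 : ibs1_end], allow_wobble)
        score = d1.paired + d2.paired
        key = (-score, -d1.paired, spacer)
        if best_key is None or key < best_key:
            best_key = key
            best = (ibs2_start, spacer, d1, d2)
    if best is None:
        return None
    ibs2_start, spacer, d1, d2 = best
    return MotifPlacement(
        target_id=target_id,
        ibs2_start=ibs2_start,
        spacer_len=spacer,
        ibs1_start=ibs1_end - 6,
        ibs1_end_offset_from_junction=0,
        score11=d1.paired + d2.paired,
        ibs1_paired=d1.paired,
        ibs2_paired=d2.paired,
        strength=classify_strength(d1.paired + d2.paired),
        ibs1_flags=d1.flags,
        ibs2_flags=d2.flags,
    )


def scan_transcript(
    seq: str,
    config: EBSConfig,
    min_score: int = 7,
    max_spacer: int = 2,
    allow_wobble: bool = True,
    target_id: str = "",
) -> list[MotifPlacement]:
    """Report every IBS1-end position on ``seq`` with a site scoring >= min_score.

    One placement per qualifying IBS1 3'-end coordinate (the functional
    cleavage anchor), best over spacers; overlapping sites are all reported.
    Results are sorted by position.
    """
    if not seq:
        return []
    out: list[MotifPlacement] = []
    for end in range(11, len(seq) + 1):
        p = placement_at_end(seq, end, config, max_spacer, allow_wobble, target_id)
        if p is not None and p.score11 >= min_score:
            out.append(p)
    return out
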