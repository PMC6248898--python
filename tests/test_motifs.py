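"""Junction-window motif search against a brute-force oracle."""

import numpy as np
import pytest

from retrosplice import (
    Strength,
    best_placement,
    classify_strength,
    junction_window,
    scan_transcript,
    wc_complement,
)
from retrosplice.motifs import placement_at_end

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _oracle_paired(ebs, cand):
    n = len(ebs)
    return sum((ebs[i], cand[n - 1 - i]) in _PAIRS for i in range(n))


def oracle_best(window_seq, junction_idx, config, max_spacer=2):
    """Independent enumeration of every (start, spacer) placement with the
    documented tie-break: score, |IBS1-end offset|, IBS1 pairing, spacer,
    leftmost."""
    results = []
    for spacer in range(max_spacer + 1):
        motif_len = 11 + spacer
        for s in range(len(window_seq) - motif_len + 1):
            i2 = window_seq[s : s + 5]
            i1 = window_seq[s + 5 + spacer : s + motif_len]
            p1 = _oracle_paired(config.ebs1, i1)
            p2 = _oracle_paired(config.ebs2, i2)
            offset = s + motif_len - junction_idx
            results.append(((-(p1 + p2), abs(offset), -p1, spacer, s), p1 + p2, s, spacer))
    results.sort(key=lambda r: r[0])
    return results[0]


def _rand_window(rng):
    return "".join(rng.choice(list("ACGU"), size=18))


def test_planted_perfect_site_scores_eleven(ebs_wt):
    word = wc_complement(ebs_wt.ebs2) + wc_complement(ebs_wt.ebs1)
    window_seq = "C" * 3 + word + "C" * 4  # IBS1 ends exactly at the junction
    w = junction_window(window_seq, 14)
    m = best_placement(w, ebs_wt)
    assert (m.score11, m.spacer_len, m.ibs1_end_offset_from_junction) == (11, 0, 0)
    assert m.strength is Strength.strong
    assert m.ibs1_paired == 6 and m.ibs2_paired == 5


def test_best_placement_matches_bruteforce_oracle(ebs_wt):
    rng = np.random.default_rng(42)
    for _ in range(300):
        seq = _rand_window(rng)  # 18 nt: the full -14/+4 window
        w = junction_window(seq, 14)
        m = best_placement(w, ebs_wt)
        key, score, s, spacer = oracle_best(w.window_seq, w.junction_index, ebs_wt)
        assert m.score11 == score
        assert (m.ibs2_start - w.window_start, m.spacer_len) == (s, spacer)


def test_motif_ending_upstream_of_junction_gets_negative_offset(ebs_wt):
    # plant a perfect site whose IBS1 ends 3 nt 5' of the junction; the
    # all-C filler cannot host a competitive placement
    word = wc_complement(ebs_wt.ebs2) + wc_complement(ebs_wt.ebs1)
    window_seq = word + "C" * 7  # IBS1 ends at index 11, junction at 14
    m = best_placement(junction_window(window_seq, 14), ebs_wt)
    assert m.score11 == 11
    assert m.ibs1_end_offset_from_junction == -3


def test_short_window_reports_below_threshold():
    from retrosplice import EBSConfig

    cfg = EBSConfig(name="x", ebs1="GUUGUG", ebs2="CGUGA")
    m = best_placement(junction_window("ACGUACGU", 4), cfg)
    assert m.score11 == 0
    assert m.truncated
    assert m.strength is Strength.below_threshold


@pytest.mark.parametrize(
    "score, expected",
    [(11, Strength.strong), (10, Strength.strong), (9, Strength.weak),
     (7, Strength.weak), (6, Strength.below_threshold), (0, Strength.below_threshold)],
)
def test_strength_classes(score, expected):
    assert classify_strength(score) is expected


def test_strength_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_strength(12)
    with pytest.raises(ValueError):
        classify_strength(-1)


def test_scan_recovers_two_planted_sites_with_oracle_check(ebs_wt):
    rng = np.random.default_rng(5)
    word = wc_complement(ebs_wt.ebs2) + wc_complement(ebs_wt.ebs1)
    seq = "".join(rng.choice(list("ACGU"), size=200))
    seq = seq[:50] + word + seq[61:130] + word + seq[141:]
    hits = scan_transcript(seq, ebs_wt, min_score=7)
    perfect_ends = {m.ibs1_end for m in hits if m.score11 == 11}
    assert {61, 141} <= perfect_ends
    # every reported hit agrees with an independent per-end enumeration
    for m in hits:
        best = max(
            _oracle_paired(ebs_wt.ebs2, seq[m.ibs1_end - 11 - sp : m.ibs1_end - 6 - sp])
            + _oracle_paired(ebs_wt.ebs1, seq[m.ibs1_end - 6 : m.ibs1_end])
            for sp in range(3)
            if m.ibs1_end - 11 - sp >= 0
        )
        assert m.score11 == best
    # and no qualifying end is missing
    reported = {m.ibs1_end for m in hits}
    for end in range(11, len(seq) + 1):
        p = placement_at_end(seq, end, ebs_wt)
        assert (p.score11 >= 7) == (end in reported)


def test_polya_transcript_pairs_only_via_u_positions(ebs_wt):
    # EBS1 = GUUGUG against poly-A: only the three U positions can pair (U-A);
    # G pairs C/U, never A, so ibs1_paired is exactly 3 everywhere
    hits = scan_transcript("A" * 60, ebs_wt, min_score=0)
    assert hits, "min_score=0 reports every position"
    assert {m.ibs1_paired for m in hits} == {3}


def test_antisense_scan_does_not_report_sense_coordinates(ebs_wt):
    from retrosplice import revcomp

    rng = np.random.default_rng(9)
    word = wc_complement(ebs_wt.ebs2) + wc_complement(ebs_wt.ebs1)
    seq = "".join(rng.choice(list("ACGU"), size=120))
    seq = seq[:40] + word + seq[51:]
    sense = {m.ibs1_end for m in scan_transcript(seq, ebs_wt) if m.score11 == 11}
    antisense = {m.ibs1_end for m in scan_transcript(revcomp(seq), ebs_wt) if m.score11 == 11}
    assert 51 in sense
    assert 51 not in antisense


def test_empty_sequence_gives_empty_scan(ebs_wt):
    assert scan_transcript("", ebs_wt) == []


def test_score_bounds_hold_on_random_windows(ebs_wt):
    rng = np.random.default_rng(123)
    for _ in range(100):
        m = best_placement(junction_window(_rand_window(rng), 14), ebs_wt)
        assert 0 <= m.ibs1_paired <= 6
        assert 0 <= m.ibs2_paired <= 5
        assert m.score11 == m.ibs1_paired + m.ibs2_paired <= 11
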