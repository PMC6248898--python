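"""Base-pairing rules, duplex scoring and perfect-partner enumeration."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrosplice import (
    enumerate_perfect_partners,
    pairs,
    score_duplex,
    to_rna,
    wc_complement,
)
from retrosplice.pairing import EBSConfig

# independent pairing oracle used to cross-check scoring
_ORACLE_PAIRS = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),  # Watson-Crick
    ("G", "U"), ("U", "G"),  # wobble
}


def oracle_paired(ebs: str, cand: str) -> int:
    n = len(ebs)
    return sum((ebs[i], cand[n - 1 - i]) in _ORACLE_PAIRS for i in range(n))


rna_text = st.text(alphabet="ACGU", min_size=1, max_size=6)


@pytest.mark.parametrize(
    "e, t, wobble, expected",
    [
        ("G", "C", True, True),
        ("G", "U", True, True),  # wobble counted in target recognition
        ("U", "G", True, True),
        ("G", "U", False, False),  # Watson-Crick only
        ("A", "G", True, False),  # never a pair
        ("A", "U", False, True),
        ("C", "U", True, False),
    ],
)
def test_pairing_rules(e, t, wobble, expected):
    assert pairs(e, t, allow_wobble=wobble) is expected


def test_non_rna_characters_rejected_with_position():
    with pytest.raises(ValueError, match="position 2"):
        to_rna("ACXG", allow_n=False)
    with pytest.raises(ValueError):
        pairs("X", "A")
    with pytest.raises(ValueError):
        pairs("A", "X")


@pytest.mark.parametrize(
    "ebs, cand, expected",
    [
        ("GUUGUG", "CACAAC", 6),  # perfect Watson-Crick complement
        ("CAACAC", "GUGUUG", 6),  # the unique partner of the stringent EBS1
        ("GUUGUG", "CACAAA", 5),  # one broken pair (brute-force verified)
    ],
)
def test_score_duplex_examples(ebs, cand, expected):
    d = score_duplex(ebs, cand)
    assert d.paired == expected == oracle_paired(ebs, cand)
    assert d.paired == sum(d.flags)


def test_score_duplex_length_mismatch_reports_both_lengths():
    with pytest.raises(ValueError, match="6 nt.*5 nt"):
        score_duplex("GUUGUG", "CACAA")


def test_candidate_n_scores_unpaired():
    d = score_duplex("GUUGUG", "CACANC")
    assert d.paired == 5
    assert d.flags[1] is False  # EBS position 1 (U) faces the N


def test_wobble_positions_recorded():
    # GUUGUG vs antiparallel all-perfect wobble word: G:U, U:G at every position
    cand = "".join({"G": "U", "U": "G"}[b] for b in reversed("GUUGUG"))
    d = score_duplex("GUUGUG", cand)
    assert d.paired == 6
    assert d.wobble_positions == (0, 1, 2, 3, 4, 5)


@pytest.mark.parametrize(
    "ebs, wobble, expected_size",
    [
        ("GUUGUG", True, 64),  # every G/U position has two admissible partners
        ("CAACAC", True, 1),
        ("GUUGUG", False, 1),
    ],
)
def test_enumerate_perfect_partner_counts(ebs, wobble, expected_size):
    partners = enumerate_perfect_partners(ebs, allow_wobble=wobble)
    assert len(partners) == expected_size
    assert all(oracle_paired(ebs, c) == len(ebs) for c in partners)


def test_stringent_ebs1_unique_partner_identity():
    assert enumerate_perfect_partners("CAACAC") == {"GUGUUG"}
    assert enumerate_perfect_partners("GUUGUG", allow_wobble=False) == {"CACAAC"}


@settings(derandomize=True, max_examples=60, deadline=None)
@given(rna_text)
def test_perfect_partner_count_closed_form(ebs):
    """|perfect partners| = 2^(#G + #U), checked against exhaustive enumeration."""
    partners = enumerate_perfect_partners(ebs)
    assert len(partners) == 2 ** sum(b in "GU" for b in ebs)
    exhaustive = {
        "".join(c)
        for c in itertools.product("ACGU", repeat=len(ebs))
        if oracle_paired(ebs, "".join(c)) == len(ebs)
    }
    assert partners == exhaustive


@settings(derandomize=True, max_examples=60, deadline=None)
@given(rna_text)
def test_wc_complement_always_perfect(ebs):
    assert score_duplex(ebs, wc_complement(ebs)).paired == len(ebs)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.text(alphabet="ACGU", min_size=2, max_size=8), st.data())
def test_monotonicity_fixing_a_position_never_decreases_score(ebs, data):
    """Changing one non-paired candidate position to a pairing base never
    decreases the pairing count."""
    n = len(ebs)
    cand = data.draw(st.text(alphabet="ACGU", min_size=n, max_size=n))
    before = score_duplex(ebs, cand)
    unpaired = [i for i, f in enumerate(before.flags) if not f]
    if not unpaired:
        return
    i = data.draw(st.sampled_from(unpaired))
    j = n - 1 - i  # candidate position facing EBS position i
    fixed = cand[:j] + wc_complement(ebs[i]) + cand[j + 1 :]
    assert score_duplex(ebs, fixed).paired >= before.paired + 1


def test_ebs_config_validation():
    cfg = EBSConfig(name="wt", ebs1="gttgtg", ebs2="cgtga")  # DNA, lowercase
    assert cfg.ebs1 == "GUUGUG"
    assert cfg.ibs1 == wc_complement("GUUGUG")
    with pytest.raises(ValueError):
        EBSConfig(name="bad", ebs1="GUUGU", ebs2="CGUGA")
    with pytest.raises(ValueError):
        EBSConfig(name="bad", ebs1="GUUGUG", ebs2="CGUG")
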