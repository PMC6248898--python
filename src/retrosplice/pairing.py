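"""RNA alphabet, antiparallel base-pairing rules and duplex scoring.

Group IIA introns select their targets by base pairing between intron-internal
exon binding sequences (EBS1, 6 nt; EBS2, 5 nt) and complementary intron
binding sequences (IBS1/IBS2) on the target RNA.  Target recognition tolerates
G·U wobble pairs, so an EBS rich in G and U accepts many distinct perfect
partners (2 per G/U position), while a mutant EBS built from A and C accepts
exactly one.

Conventions fixed here and imported by every other module:

* Sequences are RNA, uppercase, 5'->3'.  DNA ``T`` is converted to ``U`` on
  input (:func:`to_rna`); the conversion is logged once per process.
* Duplexes are antiparallel: EBS position ``i`` (5'->3') pairs with candidate
  position ``len(candidate) - 1 - i``.
* ``N`` in a *candidate* scores as unpaired (sequencer ambiguity is tolerated);
  ``N`` in an EBS is rejected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

log = logging.getLogger("retrosplice")

RNA_BASES = frozenset("ACGU")

#: Watson-Crick pairs, as (ebs_base, target_base).
WC_PAIRS = frozenset({("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")})
#: G·U wobble pairs, counted as pairing during target recognition.
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})

#: For each EBS base, the target bases it can pair with (wobble on).
_PARTNERS_WOBBLE = {"A": ("U",), "C": ("G",), "G": ("C", "U"), "U": ("A", "G")}
_PARTNERS_WC = {"A": ("U",), "C": ("G",), "G": ("C",), "U": ("A",)}

_RC_TABLE = str.maketrans("ACGUN", "UGCAN")
_DNA_TABLE = str.maketrans("Tt", "Uu")

_t_conversion_logged = False


def to_rna(seq: str, *, allow_n: bool = True) -> str:
    """Uppercase ``seq`` and convert DNA T to RNA U, validating the alphabet.

    Raises ``ValueError`` naming the first offending position for any
    character outside {A,C,G,U} (plus N when ``allow_n``).
    """
    global _t_conversion_logged
    up = seq.upper()
    if "T" in up and not _t_conversion_logged:
        log.info("DNA input detected: converting T -> U (reported once)")
        _t_conversion_logged = True
    rna = up.translate(_DNA_TABLE)
    allowed = RNA_BASES | ({"N"} if allow_n else set())
    for i, b in enumerate(rna):
        if b not in allowed:
            raise ValueError(f"non-RNA character {b!r} at position {i}")
    return rna


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


def wc_complement(seq: str) -> str:
    """The unique Watson-Crick perfect partner of ``seq`` (antiparallel, 5'->3')."""
    return revcomp(seq)


@dataclass(frozen=True)
class EBSConfig:
    """Exon binding sequences of one intron variant.

    ``ebs1`` is the 6-nt EBS1 and ``ebs2`` the 5-nt EBS2, both RNA 5'->3'.
    Together they contribute the 11 scored pairing positions of a target site.
    """

    name: str
    ebs1: str
    ebs2: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ebs1", to_rna(self.ebs1, allow_n=False))
        object.__setattr__(self, "ebs2", to_rna(self.ebs2, allow_n=False))
        if len(self.ebs1) != 6:
            raise ValueError(f"EBS1 must be 6 nt, got {len(self.ebs1)}")
        if len(self.ebs2) != 5:
            raise ValueError(f"EBS2 must be 5 nt, got {len(self.ebs2)}")

    @property
    def ibs1(self) -> str:
        """Perfect Watson-Crick IBS1 (the cognate exon motif)."""
        return wc_complement(self.ebs1)

    @property
    def ibs2(self) -> str:
        return wc_complement(self.ebs2)


@dataclass(frozen=True)
class DuplexScore:
    """Per-position pairing outcome of one EBS/candidate duplex.

    ``flags`` is ordered along the EBS 5'->3'; ``wobble_positions`` lists the
    EBS indices whose pair is G·U or U·G.
    """

    paired: int
    flags: tuple[bool, ...]
    wobble_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.paired != sum(self.flags):
            raise ValueError("paired must equal the number of set flags")


def pairs(ebs_base: str, target_base: str, allow_wobble: bool = True) -> bool:
    """True iff ``ebs_base`` pairs ``target_base`` under the recognition rules.

    Watson-Crick pairs always count; G·U / U·G count when ``allow_wobble``.
    A candidate ``N`` never pairs.  Any other non-RNA character is rejected.
    """
    if ebs_base not in RNA_BASES:
        raise ValueError(f"non-RNA character {ebs_base!r} in EBS base")
    if target_base == "N":
        return False
    if target_base not in RNA_BASES:
        raise ValueError(f"non-RNA character {target_base!r} in target base")
    duo = (ebs_base, target_base)
    return duo in WC_PAIRS or (allow_wobble and duo in WOBBLE_PAIRS)


def score_duplex(ebs: str, candidate: str, allow_wobble: bool = True) -> DuplexScore:
    """Score the antiparallel duplex between ``ebs`` and ``candidate``.

    Both strings are 5'->3'; EBS position ``i`` is tested against candidate
    position ``len - 1 - i``.  Returns the number of paired positions with
    per-position flags along the EBS.
    """
    ebs = to_rna(ebs, allow_n=False)
    candidate = to_rna(candidate)
    if len(candidate) != len(ebs):
        raise ValueError(
            f"length mismatch: EBS is {len(ebs)} nt, candidate is {len(candidate)} nt"
        )
    n = len(ebs)
    flags = []
    wobbles = []
    for i in range(n):
        tb = candidate[n - 1 - i]
        ok = pairs(ebs[i], tb, allow_wobble)
        flags.append(ok)
        if ok and (ebs[i], tb) in WOBBLE_PAIRS:
            wobbles.append(i)
    return DuplexScore(paired=sum(flags), flags=tuple(flags), wobble_positions=tuple(wobbles))


def enumerate_perfect_partners(ebs: str, allow_wobble: bool = True) -> frozenset[str]:
    """All candidate strings that pair at every position of ``ebs``.

    The set size is the product over EBS positions of the number of admissible
    partner bases: 2 for G/U with wobble on, otherwise 1 — i.e.
    ``2**(#G + #U)`` with wobble.
    """
    ebs = to_rna(ebs, allow_n=False)
    if not ebs:
        raise ValueError("EBS must be non-empty")
    table = _PARTNERS_WOBBLE if allow_wobble else _PARTNERS_WC
    # candidate position j pairs EBS position len-1-j
    per_position = [table[ebs[len(ebs) - 1 - j]] for j in range(len(ebs))]
    return frozenset("".join(tpl) for tpl in itertools.product(*per_position))
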