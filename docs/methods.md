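# Methods

## Target recognition model

A group IIA intron selects its splice and insertion sites by base pairing
between two intron-internal exon binding sequences — EBS1 (6 nt) and EBS2
(5 nt) — and complementary intron binding sequences (IBS1, IBS2) on the
target RNA. Recognition tolerates G·U wobble pairs, so the admissible pairs
are {G-C, C-G, A-U, U-A, G-U, U-G}. Duplexes are antiparallel: EBS position
`i` (5'→3') is scored against candidate position `len−1−i`. This single
convention lives in `retrosplice.pairing` and every other module imports it.

A *site* is an arrangement `[IBS2-like (5 nt)][spacer 0–2 nt][IBS1-like
(6 nt)]` whose 11 informative positions are scored against EBS2+EBS1
(`score11`, 0–11). Sites pairing 10–11/11 are classified **strong**, 7–9/11
**weak**, and below 7/11 **below_threshold**. The weak floor of 7/11 is the
default `min_score` for every caller because weaker arrangements are
indistinguishable from background pairing; it is configurable everywhere.

A direct consequence of the wobble rule: an EBS string accepts
`2^(#G + #U)` distinct perfect partners, because each G or U position admits
two target bases (C/U and A/G respectively) while A and C admit one. A
G/U-rich EBS1 such as 5'-GUUGUG-3' therefore accepts 64 perfect 6-mer
partners, whereas an A/C-only variant (5'-CAACAC-3') accepts exactly one
(5'-GUGUUG-3'). Both counts are recomputed by exhaustive enumeration in the
test suite and the acceptance script.

## Junction-anchored motif search

Observed junctions (circle-insert extremities, reverse-splice sites, chimera
joints) are not always cleaved precisely downstream of the recognized motif.
The junction search therefore scores every placement of the motif inside a
window spanning **14 nt upstream to 4 nt downstream** of the junction
(half-open slice `[junction−14, junction+4)`, 18 nt), so the IBS1 3' end may
fall up to 3 nt to either side of the observed junction while the full
11–13 nt arrangement still fits. Both flexibilities are implemented: the
0–2 nt spacer between IBS2 and IBS1, and the window slack between IBS1 and
the junction.

Ties on `score11` are broken deterministically, in order:

1. smallest `|IBS1 end − junction|` (prefer motifs ending at the junction);
2. larger IBS1 pairing (the IBS1-like half of observed consensuses is the
   better defined one);
3. smaller spacer;
4. leftmost placement.

Windows shorter than 11 nt (junctions at sequence ends) yield a
`below_threshold` placement flagged truncated rather than an error.

The transcriptome-wide scan (`scan_transcript`) reports one placement per
IBS1-3'-end coordinate — the functional cleavage anchor — maximizing over
the spacer only, so overlapping sites are all reported. Internal coordinates
are 0-based half-open; user-facing TSV is 1-based inclusive; BED stays
0-based half-open.

## Read classification

**Circle junctions.** A read spanning the excised-intron splice junction
shows the intron 3'-terminal anchor followed by the 5'-terminal anchor
(default anchor length 20 nt, exact match; one mismatch per anchor optional
since amplicon clones are Sanger-grade). Adjacent anchors → perfect circle;
a gap of at least `min_insert` (default 8 nt, safely below the smallest
observed 20-nt insert) → captured insert; anchors missing, in linear order,
or separated by a sub-threshold gap → unresolved with the reason recorded.
Lariat-junction amplicons (branch-point readthrough) are deliberately left
unresolved: their product size depends on primer positions that are not part
of this model.

**Insert mapping.** Inserts are exact-matched against the reference;
forward-strand occurrences are attributed to `+` genes and reverse-complement
occurrences to `−` genes, so an insert is only ever assigned to the
transcribed strand (`min_map_len` 15 nt for uniqueness on toy references). A
hit covering two same-strand genes plus the gap between them is flagged
`spans_intergenic` (polycistronic capture). Flanks are the 30 nt of
transcribed-strand reference centered on each insert extremity (15 nt each
side); each extremity is scored with the junction-anchored search above.

**Reverse-splice sites.** Split reads are cut at the intron anchor
(`mRNA|intron-5'` → rs_5prime; `intron-3'|mRNA` → rs_3prime), the mRNA part
is uniquely exact-matched in transcript space, and the junction must carry a
motif scoring ≥ `min_score`. Reads showing both intron termini in circular
order are circle reads and skipped. Support counts collapse identical
(event type, transcript, junction) keys, not identical read sequences; the
minimum support for a reported event is 1 after this de-duplication.

**Chimeras.** An E1-mRNA chimera read starts with the exon-1 3' terminus
(longest-suffix match, ≥ anchor length) and continues inside another
transcript just 3' of a qualifying motif. An mRNA-mRNA chimera read is
found by trying every split point: both parts must map uniquely, a colinear
pair (same transcript, abutting coordinates) is discarded as an ordinary
read, and by default the donor boundary must itself score ≥ `min_score` —
mechanistically, donor fragments carry IBS-like 3' ends; the check can be
disabled for exploratory use. Among valid splits the caller prefers higher
combined motif score, then motifs ending exactly at the junctions, then the
smaller split offset; this keeps single-base coincidences at the joint from
shifting the called junction.

## Consensus matrices

Junction sets are stacked into 4×L count matrices with per-column
information content `IC = 2 − H` bits, `H = −Σ f log₂ f` over observed
frequencies. `N` (padding, ambiguity) is excluded from column counts. No
pseudocount or small-sample correction is applied by default (both are
flags); bits rather than nats match logo convention. *Raw* mode anchors each
sequence on its observed junction; *adjusted* mode re-anchors on the 3' end
of the best motif placement (sequences with no placement ≥ `min_score` stay
junction-anchored and are flagged). When cleavage is jittered relative to
the motif, adjustment concentrates the motif columns, so summed IC over the
11 motif columns in adjusted mode is ≥ raw mode — a property the test suite
checks on generator output.

## Synthetic data generator

The generator implements the pathway model directly: it plants
IBS2+spacer+IBS1 words of exact target score (a random perfect word —
wobble variants included — degraded at randomly chosen positions to
non-pairing bases, then re-scored in context and re-drawn on collision) and
emits reads for each event class:

- reverse-splice insertions: both junction reads per insertion;
- perfect circles: head-to-tail intron junction reads;
- inserted circles: the captured segment is the reference between a weak
  invaded site and a **stronger upstream alternative site** (downstream
  flank score ≤ upstream flank score, as the alternative-circularization
  model predicts);
- E1-mRNA and mRNA-mRNA chimera reads joined at planted sites — chimera
  acceptor sites also emit a reverse-splice read pair by default
  (`chimeras_imply_rs`), because chimeras arise at intron-invaded sites;
  this is what makes the E1-junction ⊆ rs-junction identity testable;
- background reads sampled from transcripts.

Default conditions: 50 genes of 1–2 kb at GC 0.36 (a realistic low-GC
firmicute-like composition), 20 planted sites cycling scores 7–11 and
spacers 0–2, 10 insertions, 5 inserted circles with inserts drawn uniformly
from 20–576 nt (the observed size range), 5 chimeras of each type, 500
background reads of 100 nt, error rate 0. `reverse_splicing=False` emulates
a branch-point-deleted intron: all reverse-splicing-dependent classes
(insertions, inserted circles, both chimera types) are suppressed and only
perfect circles plus background remain. `cleavage_jitter_max` (0–3) offsets
junctions 0–3 nt downstream of the planted motif end, i.e. motif offsets in
{−3..0}. `event_read_copies` emits multiple independent clone reads per
event junction, emulating repeated amplicon clones; with 1% per-base error,
three copies and 1-mismatch anchors, strong-site recall stays ≥ 95%
(seeded test).

All randomness flows through one `numpy` Generator, so identical seed and
config give byte-identical FASTQ and manifest. Reads carry constant 'I'
quality; errors are substitutions only.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic coverage and fragmentation, RNA
degradation, platform-specific error profiles, codon structure or
compositional heterogeneity of real genes (background is i.i.d. at fixed GC,
which makes incidental IBS-like hits occur at a predictable rate), relative
in-vivo event frequencies (user-set, not fitted), and the
external-nucleophilic-attack branch of circle formation, whose read-level
products are indistinguishable from the reverse-splicing branch and are
therefore not simulated separately.

## Problem sizes and numerical choices

The reference recovery run (50 genes, ~75 kb, 560 reads) completes in a few
seconds; the exhaustive 6-mer enumerations cover all 4096 candidates.
Exact-substring search (`str.find`) is used for all mapping — appropriate
for toy references where uniqueness is effectively guaranteed; no aligner
heuristics are involved, so recovered boundaries are exact by construction
when reads are error-free. `min_score` may be set to 12 to deliberately
silence all motif-gated callers while leaving the pipeline running.

## Known limitations

- Mapping is exact-match only (plus optional 1-mismatch anchors); reads
  with errors in the mRNA segment are dropped, not rescued.
- δ–δ' 3'-splice-site recognition is not modeled (no δ'-like signal exists
  at ectopic sites in this system), nor is RNA secondary-structure
  accessibility weighting or thermodynamic (ΔG) duplex scoring.
- Quantitative efficiency estimates (e.g. per-transcript invasion rates or
  expression ratios) are out of scope; support counts are de-duplicated
  junction tallies, not abundance estimates.
- The EBS2 sequence is mandatory configuration: the toolkit ships no
  organism-specific default.
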