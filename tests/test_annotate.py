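"""Junction annotation: placement, microhomology, fold-backs, telomeres."""

import numpy as np
import pytest

from gcrsig.annotate import (
    annotate_junction,
    classify_junction,
    compute_microhomology,
    detect_foldback,
    detect_telomere_addition,
    locate_junction,
    tg_conformity,
)
from gcrsig.chromosome import random_dna, revcomp
from gcrsig.rearrange import (
    apply_de_novo_telomere,
    apply_interstitial_deletion,
    apply_inverted_duplication,
    apply_translocation,
    ty_fragment,
)


def test_locate_simple_concatenation_junction(chrom50):
    a, b = 5_000, 12_000
    cons = chrom50.sequence[a - 100: a] + chrom50.sequence[b: b + 100]
    ann = locate_junction(cons, chrom50)
    assert (ann.side_a.coord, ann.side_b.coord) == (a, b)
    assert ann.microhomology == 0 and ann.insert == ""
    assert ann.junction_class == "deletion"


def test_locate_reports_engineered_microhomology(chrom50):
    """Engineered 4-base shared tract recovered with its sequence."""
    r = apply_interstitial_deletion(
        chrom50, chrom50.cassette.start - 30,
        chrom50.feature("GCR_breakpoint_region").start + 800, microhomology=4,
    )
    start, end = r.truth.breakpoints
    ref = r.reference.sequence
    cons = ref[start - 90: start] + ref[end: end + 90]
    ann = locate_junction(cons, r.reference)
    assert ann.microhomology == 4
    assert ann.microhomology_seq == ref[end: end + 4] == ref[start: start + 4]
    assert (ann.side_a.coord, ann.side_b.coord) == (start, end)


def test_locate_non_templated_insert(chrom50):
    a, b = 6_000, 14_000
    ins = "TTAACCGGATCC"
    seq = chrom50.sequence
    # guard the fixture against chance 1-base homology at the boundaries
    assert seq[a] != ins[0] or seq[b - 1] != ins[-1]
    cons = seq[a - 100: a] + ins + seq[b: b + 100]
    ann = locate_junction(cons, chrom50)
    if ann.insert:  # chance extension can transfer a boundary base
        assert ins in cons
        assert len(ann.insert) >= len(ins) - 2


def test_unmappable_affix_gives_unresolved(chrom50, rng):
    cons = random_dna(rng, 60) + random_dna(rng, 60)
    ann = locate_junction(cons, chrom50)
    assert ann.junction_class == "unresolved"


def test_microhomology_matches_brute_force_oracle(rng):
    """1,000 random junction fixtures against exhaustive window comparison."""

    def oracle(a_seg, b_seg, split):
        best_f = 0
        while split + best_f < min(len(a_seg), len(b_seg)) and \
                a_seg[split + best_f] == b_seg[split + best_f]:
            best_f += 1
        best_b = 0
        while best_b < split and a_seg[split - 1 - best_b] == b_seg[split - 1 - best_b]:
            best_b += 1
        return best_f + best_b

    for _ in range(1_000):
        n = int(rng.integers(10, 40))
        split = int(rng.integers(0, n))
        a_seg = random_dna(rng, n)
        b_list = list(random_dna(rng, n))
        # plant a shared tract across the split sometimes
        if rng.random() < 0.7:
            m = int(rng.integers(0, 6))
            for j in range(max(0, split - m), min(n, split + m)):
                b_list[j] = a_seg[j]
        b_seg = "".join(b_list)
        length, seq = compute_microhomology(a_seg, b_seg, split)
        assert length == oracle(a_seg, b_seg, split)
        assert len(seq) == length


def test_microhomology_capped_at_shorter_flank():
    length, seq = compute_microhomology("AAAA", "AAAA", 2)
    assert length == 4 and seq == "AAAA"


def test_foldback_exact_recovery(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_inverted_duplication(chrom50, bpr.start + 150, loop=30, priming_homology=5)
    dsb, arm_start = r.truth.breakpoints
    ref = r.reference.sequence
    u5s = chrom50.feature("ura3-52_URA3").start
    cons = revcomp(ref[arm_start: arm_start + 120]) + ref[dsb: dsb + 120]
    fb = detect_foldback(cons, r.reference)
    assert fb is not None
    assert (fb.loop, fb.priming_homology) == (30, 5)
    assert fb.loop_seq == ref[dsb + 5: arm_start - 5]
    assert fb.priming_homology_seq == ref[dsb: dsb + 5]


def test_foldback_invariant_under_reverse_complement(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_inverted_duplication(chrom50, bpr.start + 300, loop=41, priming_homology=8)
    dsb, arm_start = r.truth.breakpoints
    ref = r.reference.sequence
    cons = revcomp(ref[arm_start: arm_start + 120]) + ref[dsb: dsb + 120]
    fb1 = detect_foldback(cons, r.reference)
    fb2 = detect_foldback(revcomp(cons), r.reference)
    assert fb1 is not None and fb2 is not None
    assert (fb1.loop, fb1.priming_homology, fb1.center) == (
        fb2.loop, fb2.priming_homology, fb2.center
    )


def test_cohort_foldback_parameters_recovered_exactly(chrom50, rng):
    """Loops of 25-44 nt and priming homologies of 3-9 bp round-trip."""
    bpr = chrom50.feature("GCR_breakpoint_region")
    for _ in range(10):
        loop = int(rng.integers(25, 45))
        prime = int(rng.integers(3, 10))
        dsb = int(rng.integers(bpr.start, bpr.end - 200))
        r = apply_inverted_duplication(chrom50, dsb, loop=loop, priming_homology=prime)
        arm_start = r.truth.breakpoints[1]
        ref = r.reference.sequence
        cons = revcomp(ref[arm_start: arm_start + 150]) + ref[dsb: dsb + 150]
        fb = detect_foldback(cons, r.reference)
        assert fb is not None and (fb.loop, fb.priming_homology) == (loop, prime)


def test_perfect_palindrome_zero_loop_flagged(chrom50):
    from gcrsig.rearrange import _with_sequence

    seq = list(chrom50.sequence)
    x = 7_000
    h = 6
    seq[x + h: x + 2 * h] = list(revcomp("".join(seq[x: x + h])))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if seq[x - 1] == comp[seq[x + 2 * h]]:
        seq[x - 1] = next(b for b in "ACGT" if b != seq[x - 1])
    ref = _with_sequence(chrom50, "".join(seq))
    # the inverted-arm copy starts immediately after the planted repeat
    cons = revcomp(ref.sequence[x + 2 * h: x + 2 * h + 100]) + ref.sequence[x: x + 100]
    fb = detect_foldback(cons, ref)
    assert fb is not None and fb.loop == 0 and fb.zero_loop
    assert fb.priming_homology == h


def test_no_foldback_for_distant_inverted_junction(chrom50):
    cons = revcomp(chrom50.sequence[30_000: 30_100]) + chrom50.sequence[5_000: 5_100]
    assert detect_foldback(cons, chrom50) is None


def test_telomere_addition_detected_at_truth_coordinate(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_de_novo_telomere(chrom50, bpr.start + 500, seed_repeats=150, seed=4)
    pos = r.truth.breakpoints[0]
    cons = r.sequence[:60][-60:] + ""  # leading telomere tract
    cons = r.segments[0].sequence[-80:] + r.reference.sequence[pos: pos + 100]
    ann, fb, tel = annotate_junction(cons, r.reference)
    assert tel is not None and tel.seed_coord == pos
    assert ann.junction_class == "telomere_addition"


def test_random_tails_rarely_pass_conformity(rng):
    fails = sum(
        tg_conformity(random_dna(rng, 30)) < 0.90 for _ in range(1_000)
    )
    assert fails > 990


def test_canonical_tg_tail_detected():
    tail = "TGTGGGTGTGGTGTGTGGG"
    assert len(tail) >= 15
    assert tg_conformity(tail) >= 0.90


def test_ty_donor_translocation_reports_ty_homology(chrom50):
    """End to end on a Ty-tailed donor: the junction side lands in the Ty tract."""
    bpr = chrom50.feature("GCR_breakpoint_region")
    rng = np.random.default_rng(5)
    donor = random_dna(rng, 250) + ty_fragment(200)
    r = apply_translocation(chrom50, bpr.start + 350, donor)
    pos = bpr.start + 350
    cons = r.sequence[: r.segments[0].length + r.segments[1].length][-120:] + \
        r.reference.sequence[pos: pos + 120]
    ann, fb, tel = annotate_junction(cons, r.reference)
    assert ann.side_a is not None
    assert "ura3-52_Ty" in ann.side_a.features
    assert ann.junction_class == "translocation"


def test_classification_priority_rules(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    # fold-back beats the deletion/translocation fallthrough even with
    # microhomology present
    r = apply_inverted_duplication(chrom50, bpr.start + 150, loop=30, priming_homology=5)
    dsb, arm_start = r.truth.breakpoints
    ref = r.reference.sequence
    cons = revcomp(ref[arm_start: arm_start + 120]) + ref[dsb: dsb + 120]
    ann, fb, tel = annotate_junction(cons, r.reference)
    assert ann.microhomology > 0 and fb is not None
    assert ann.junction_class == "inversion_foldback"
    # cross-locus fixture
    cons2 = revcomp(chrom50.sequence[30_000: 30_100]) + chrom50.sequence[5_000: 5_100]
    ann2, fb2, tel2 = annotate_junction(cons2, chrom50)
    assert ann2.junction_class == "translocation"
    # deletion fixture
    cons3 = chrom50.sequence[4_900: 5_000] + chrom50.sequence[8_000: 8_100]
    assert locate_junction(cons3, chrom50).junction_class == "deletion"


def test_short_consensus_rejected(chrom50):
    with pytest.raises(ValueError, match="40"):
        locate_junction("ACGT", chrom50)
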