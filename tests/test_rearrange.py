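"""Rearrangement constructors: truth exactness and sequence accounting."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcrsig.chromosome import revcomp
from gcrsig.rearrange import (
    apply_de_novo_telomere,
    apply_interstitial_deletion,
    apply_inverted_duplication,
    apply_translocation,
    ty_fragment,
    unrearranged,
)


def _brute_force_palindrome(window: str, max_loop: int = 120):
    """Oracle: largest inverted repeat with an unpaired spacer, by scanning
    all centre positions and spacer lengths."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(window)
    best = (0, None)
    for c in range(n):
        for lam in range(0, max_loop + 1):
            k = 0
            while c - 1 - k >= 0 and c + lam + k < n and \
                    window[c - 1 - k] == comp[window[c + lam + k]]:
                k += 1
            if k > best[0]:
                best = (k, lam)
    return best  # (arm length, loop)


# ---------------------------------------------------------------------------
# interstitial deletions

@pytest.mark.parametrize("mh", [0, 1, 3, 5, 10])
def test_deletion_microhomology_planted_exactly(chrom50, mh):
    bpr = chrom50.feature("GCR_breakpoint_region")
    start, end = chrom50.cassette.start - 40, bpr.start + 900
    r = apply_interstitial_deletion(chrom50, start, end, microhomology=mh)
    ref = r.reference.sequence
    assert ref[start:start + mh] == ref[end:end + mh]
    assert ref[start + mh] != ref[end + mh]
    assert ref[start - 1] != ref[end - 1]
    assert r.truth.microhomology == mh
    assert r.length == chrom50.length - (end - start)
    assert r.hph_present()


def test_deletion_with_ty_insert_length_arithmetic(chrom_full):
    """A ~4 kb Ty-fragment insert at the deletion junction."""
    bpr = chrom_full.feature("GCR_breakpoint_region")
    start, end = chrom_full.cassette.start - 500, bpr.start + 5_000
    insert = ty_fragment(4_000)
    r = apply_interstitial_deletion(chrom_full, start, end, insert=insert)
    assert r.length == chrom_full.length - (end - start) + 4_000
    assert insert in r.sequence


def test_deletion_must_span_cassette(chrom50):
    with pytest.raises(ValueError, match="cassette"):
        apply_interstitial_deletion(chrom50, 100, 300)


def test_deletion_removing_pcm1_rejected(chrom50):
    pcm1 = chrom50.feature("PCM1")
    with pytest.raises(ValueError, match="PCM1"):
        apply_interstitial_deletion(chrom50, chrom50.cassette.start - 10, pcm1.end)


def test_deletion_removing_hph_rejected(chrom50):
    hph = chrom50.feature("hph")
    with pytest.raises(ValueError, match="hph"):
        apply_interstitial_deletion(
            chrom50, hph.start, chrom50.cassette.end + 10
        )


def test_insert_with_microhomology_rejected(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    with pytest.raises(ValueError, match="mutually exclusive"):
        apply_interstitial_deletion(
            chrom50, chrom50.cassette.start - 10, bpr.start + 500,
            microhomology=3, insert="ACGT",
        )


# ---------------------------------------------------------------------------
# inverted duplications

def test_foldback_junction_palindrome_geometry(chrom50):
    """Self-alignment oracle: junction +/-200 bp aligned to its own reverse
    complement shows an inverted repeat with a 30-base unpaired spacer."""
    bpr = chrom50.feature("GCR_breakpoint_region")
    dsb = bpr.start + 150
    r = apply_inverted_duplication(chrom50, dsb, loop=30, priming_homology=5)
    ura3 = chrom50.feature("URA3")
    u5s = chrom50.feature("ura3-52_URA3").start
    arm_start = dsb + 5 + 30 + 5  # g + h
    jpos = ura3.end + (u5s - arm_start)  # product coordinate of the junction
    window = r.sequence[jpos - 200: jpos + 200]
    arms, loop = _brute_force_palindrome(window)
    assert loop == 30
    assert arms >= 150


def test_inverted_duplication_truth_and_marker(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    dsb = bpr.start + 150
    r = apply_inverted_duplication(chrom50, dsb, loop=30, priming_homology=5)
    assert r.truth.size_class == "larger"
    assert r.truth.hph_retained and r.hph_present()
    assert r.truth.breakpoints == (dsb, dsb + 5 + 30 + 5)
    ref = r.reference.sequence
    g = dsb + 5 + 30
    assert ref[g:g + 5] == revcomp(ref[dsb:dsb + 5])  # priming repeat templated


def test_published_extents_producible_at_full_scale(chrom_full):
    """Deletions of ~4-19 kb and duplications of ~80-100 kb by parameter choice."""
    ura3_end = chrom_full.feature("URA3").end
    u5s = chrom_full.feature("ura3-52_URA3").start
    bpr = chrom_full.feature("GCR_breakpoint_region")
    for dsb, want_del in [(bpr.start + 1_100, 4_000), (bpr.end - 250, 19_000)]:
        r = apply_inverted_duplication(chrom_full, dsb, loop=30, priming_homology=5)
        deletion = dsb - ura3_end
        duplication = u5s - r.truth.breakpoints[1]
        assert abs(deletion - want_del) < 2_000
        assert 60_000 <= duplication <= 100_000
    # the canonical event sits in the published ranges
    r = apply_inverted_duplication(chrom_full, bpr.start + 1_200, loop=30, priming_homology=5)
    assert 4_000 <= (bpr.start + 1_200) - ura3_end <= 19_000
    assert 80_000 <= u5s - r.truth.breakpoints[1] <= 100_000


@pytest.mark.parametrize("resolution,hph", [("ura3-52", True), ("ty", False), ("none", False)])
def test_resolution_determines_marker_retention(chrom50, resolution, hph):
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_inverted_duplication(
        chrom50, bpr.start + 200, loop=25, priming_homology=4, resolution=resolution
    )
    assert r.truth.hph_retained is hph
    assert r.hph_present() is hph
    assert r.truth.size_class == "larger"


def test_foldback_parameter_validation(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    with pytest.raises(ValueError, match="loop"):
        apply_inverted_duplication(chrom50, bpr.start + 100, loop=5, priming_homology=5)
    with pytest.raises(ValueError, match="priming"):
        apply_inverted_duplication(chrom50, bpr.start + 100, loop=30, priming_homology=1)
    with pytest.raises(ValueError, match="breakpoint region"):
        apply_inverted_duplication(chrom50, 100, loop=30, priming_homology=5)
    with pytest.raises(ValueError, match="foldback"):
        apply_inverted_duplication(
            chrom50, bpr.start + 100, loop=30, priming_homology=5, foldback=bpr.start
        )


# ---------------------------------------------------------------------------
# de novo telomeres and translocations

def test_de_novo_telomere_product_structure(chrom50):
    import re
    bpr = chrom50.feature("GCR_breakpoint_region")
    pos = bpr.start + 400
    r = apply_de_novo_telomere(chrom50, pos, seed_repeats=120)
    m = re.match(r"(?:TG{1,3})+", r.sequence)
    assert m and m.end() >= 15
    assert not r.hph_present()
    assert r.sequence.endswith(chrom50.sequence[-1000:])


def test_de_novo_telomere_rejections(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    with pytest.raises(ValueError, match="seed"):
        apply_de_novo_telomere(chrom50, bpr.start + 100, seed_repeats=0)
    with pytest.raises(ValueError, match="CAN1/URA3"):
        apply_de_novo_telomere(chrom50, chrom50.cassette.start - 100)


def test_translocation_donor_maps_to_distinct_locus(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    pos, da, db = bpr.start + 300, 30_000, 33_000
    r = apply_translocation(chrom50, pos, revcomp(chrom50.sequence[da:db]), donor_map=(da, -1))
    left = r.project(0, 100)
    right = r.project(r.length - 100, r.length)
    assert left is not None and right is not None
    assert left[2] == -1 and right[2] == 1
    assert abs(left[0] - right[0]) > 10_000
    assert not r.hph_present()


def test_translocation_empty_donor_rejected(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    with pytest.raises(ValueError, match="donor"):
        apply_translocation(chrom50, bpr.start + 100, "")


# ---------------------------------------------------------------------------
# conservation property

def _composition(s: str) -> Counter:
    return Counter(s)


@settings(max_examples=15, deadline=None)
@given(
    data=st.data(),
    event=st.sampled_from(["deletion", "invdup", "telomere", "translocation"]),
)
def test_base_composition_conservation(chrom50, data, event):
    """Product composition equals reference composition adjusted exactly by
    the deleted/duplicated/inserted intervals (interval accounting)."""
    bpr = chrom50.feature("GCR_breakpoint_region")
    ura3 = chrom50.feature("URA3")
    if event == "deletion":
        start = data.draw(st.integers(chrom50.cassette.start - 400, chrom50.cassette.start - 1))
        end = data.draw(st.integers(chrom50.cassette.end + 50, bpr.end - 120))
        mh = data.draw(st.integers(0, 5))
        r = apply_interstitial_deletion(chrom50, start, end, microhomology=mh)
        ref = r.reference.sequence
        expect = _composition(ref) - _composition(ref[start:end])
    elif event == "invdup":
        dsb = data.draw(st.integers(bpr.start, bpr.end - 200))
        r = apply_inverted_duplication(
            chrom50, dsb, loop=data.draw(st.integers(25, 44)),
            priming_homology=data.draw(st.integers(3, 9)),
        )
        ref = r.reference.sequence
        arm_start = r.truth.breakpoints[1]
        u5s = chrom50.feature("ura3-52_URA3").start
        expect = (
            _composition(ref)
            - _composition(ref[ura3.end:dsb])
            + _composition(revcomp(ref[arm_start:u5s]))
        )
    elif event == "telomere":
        pos = data.draw(st.integers(bpr.start, bpr.end - 1))
        r = apply_de_novo_telomere(chrom50, pos, seed_repeats=100, seed=data.draw(st.integers(0, 999)))
        ref = r.reference.sequence
        tract = r.segments[0].sequence
        expect = _composition(ref) - _composition(ref[:pos]) + _composition(tract)
    else:
        pos = data.draw(st.integers(bpr.start, bpr.end - 1))
        da = data.draw(st.integers(20_000, 40_000))
        r = apply_translocation(
            chrom50, pos, revcomp(chrom50.sequence[da:da + 2_000]), donor_map=(da, -1)
        )
        ref = r.reference.sequence
        expect = (
            _composition(ref)
            - _composition(ref[:pos])
            + _composition(revcomp(ref[da:da + 2_000]))
        )
    assert _composition(r.sequence) == expect


def test_unrearranged_round_trip(chrom50):
    r = unrearranged(chrom50)
    assert r.sequence == chrom50.sequence
    assert r.project(1_000, 1_100) == (1_000, 1_100, 1)
    assert r.truth.event_class == "none"
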