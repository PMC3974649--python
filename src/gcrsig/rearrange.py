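"""Truth-labelled rearranged genomes built by the four GCR mechanisms.

Each constructor takes an :class:`~gcrsig.chromosome.AssayChromosome` and
returns a :class:`Rearrangement`: the product genome (as a list of typed
segments concatenated into a sequence), a :class:`RearrangementTruth`
record, and the reference used for that isolate.  The reference is a
locally edited copy of the input chromosome: junction microhomology and
fold-back priming homology are planted by deterministic local sequence
edits (confined to deleted intervals or the hairpin loop template), so
that truth labels are exact rather than sampled.

Event classes
-------------
interstitial_deletion
    NHEJ-style deletion spanning the CAN1/URA3 cassette, hph retained,
    optionally with a non-templated (e.g. Ty-fragment) insert.
inverted_duplication
    Hairpin-mediated fold-back: a DSB in the breakpoint region is resected,
    the single-stranded end anneals back via a short inverted repeat
    (priming homology) leaving an unpaired loop, synthesis copies the arm
    toward the centromere, and homologous recombination (URA3/ura3-52,
    Ty, or none) resolves the chromosome.  hph is retained iff resolution
    uses the URA3/ura3-52 homology.
de_novo_telomere
    Telomerase healing of the broken end with a TG1-3 seed; hph lost.
translocation
    Fusion of the broken end to a donor sequence; hph lost.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .chromosome import (
    TY_CONSENSUS,
    AssayChromosome,
    Feature,
    revcomp,
    tg_repeat_tract,
)

EVENT_CLASSES = (
    "interstitial_deletion",
    "inverted_duplication",
    "de_novo_telomere",
    "translocation",
)

SIZE_TOLERANCE = 0.02  # +/-2% PFGE-like size resolution band


@dataclass(frozen=True)
class Segment:
    """One piece of a product genome.

    ``ref_start`` is the reference coordinate of the segment on the plus
    strand; for ``strand == -1`` the segment sequence is the reverse
    complement of ``reference[ref_start:ref_start+len]``.  ``ref_start is
    None`` marks novel (non-templated) sequence.
    """

    sequence: str
    ref_start: int | None = None
    strand: int = 1
    label: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RearrangementTruth:
    """Ground-truth labels for a constructed GCR event."""

    event_class: str
    breakpoints: tuple[int, ...] = ()
    microhomology: int = 0
    priming_homology: int | None = None
    loop: int | None = None
    resolution: str | None = None
    insert: str = ""
    hph_retained: bool = True
    size_class: str = "wild_type_like"

    def __post_init__(self):
        foldback = self.event_class == "inverted_duplication"
        if foldback != (self.priming_homology is not None):
            raise ValueError("fold-back fields are populated iff the event is an inverted duplication")
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoint coordinates must be ordered")


@dataclass
class Rearrangement:
    """A product genome with its truth labels and per-isolate reference."""

    name: str
    reference: AssayChromosome
    segments: list[Segment]
    truth: RearrangementTruth
    _offsets: list[int] = field(init=False, repr=False)
    _sequence: str = field(init=False, repr=False)

    def __post_init__(self):
        offs = [0]
        for seg in self.segments:
            offs.append(offs[-1] + seg.length)
        self._offsets = offs
        self._sequence = "".join(s.sequence for s in self.segments)

    @property
    def sequence(self) -> str:
        return self._sequence

    @property
    def length(self) -> int:
        return self._offsets[-1]

    def project(self, start: int, end: int) -> tuple[int, int, int] | None:
        """Project a product interval to reference coordinates.

        Returns ``(ref_start, ref_end, strand)`` for intervals lying fully
        within a single reference-derived segment, and ``None`` for
        intervals crossing a junction or inside novel sequence — i.e. the
        behaviour of an ideal exact unique mapper.
        """
        if not (0 <= start < end <= self.length):
            raise ValueError(f"interval [{start}, {end}) outside product")
        i = bisect_right(self._offsets, start) - 1
        seg = self.segments[i]
        if end > self._offsets[i + 1] or seg.ref_start is None:
            return None
        a, b = start - self._offsets[i], end - self._offsets[i]
        if seg.strand == 1:
            return seg.ref_start + a, seg.ref_start + b, 1
        return seg.ref_start + seg.length - b, seg.ref_start + seg.length - a, -1

    def copy_number(self) -> np.ndarray:
        """Per-base copy number of the reference in the product genome."""
        cn = np.zeros(self.reference.length, dtype=np.int32)
        for seg in self.segments:
            if seg.ref_start is not None:
                cn[seg.ref_start: seg.ref_start + seg.length] += 1
        return cn

    def hph_present(self) -> bool:
        """Whether the product carries an intact hph tract (hygromycin proxy)."""
        return self.reference.feature_seq("hph") in self.sequence


def _edit(seq: list[str], i: int, avoid: set[str]) -> None:
    for b in "ACGT":
        if b not in avoid:
            seq[i] = b
            return


def _with_sequence(genome: AssayChromosome, seq: str) -> AssayChromosome:
    return AssayChromosome(
        name=genome.name,
        sequence=seq,
        features=genome.features,
        variant=genome.variant,
        homology_families=genome.homology_families,
    )


def _size_class(product_len: int, ref_len: int) -> str:
    if abs(product_len - ref_len) <= SIZE_TOLERANCE * ref_len:
        return "wild_type_like"
    return "larger" if product_len > ref_len else "smaller"


def ty_fragment(length: int, offset: int = 0) -> str:
    """A fragment of the synthetic Ty consensus, for junction inserts/donors."""
    if offset + length > len(TY_CONSENSUS):
        raise ValueError("fragment extends past the Ty consensus")
    return TY_CONSENSUS[offset: offset + length]


def unrearranged(genome: AssayChromosome, name: str = "wt") -> Rearrangement:
    """An unrearranged isolate (null genome for specificity tests)."""
    truth = RearrangementTruth(
        event_class="none", breakpoints=(), hph_retained=True,
        size_class="wild_type_like",
    )
    seg = Segment(genome.sequence, ref_start=0, strand=1, label="chromosome")
    return Rearrangement(name=name, reference=genome, segments=[seg], truth=truth)


def apply_interstitial_deletion(
    genome: AssayChromosome,
    start: int,
    end: int,
    microhomology: int = 0,
    insert: str = "",
    name: str = "deletion",
) -> Rearrangement:
    """Interstitial deletion of [start, end) spanning the cassette.

    The reference copy is edited inside the deleted interval so that the
    retained flanks share exactly ``microhomology`` identical bases across
    the junction (``reference[start:start+m] == reference[end:end+m]``)
    and no more.
    """
    cassette = genome.cassette
    pcm1 = genome.feature("PCM1")
    hph = genome.feature("hph")
    if not (0 < start < end <= genome.length):
        raise ValueError("deletion interval must satisfy 0 < start < end <= length")
    if not (start < cassette.end and cassette.start < end):
        raise ValueError("deletion must overlap the CAN1/URA3 cassette (selection)")
    if pcm1.overlaps(start, end):
        raise ValueError("deletion removes the essential gene PCM1: not viable")
    if hph.overlaps(start, end):
        raise ValueError("deletion removes hph: not an hph-retaining event")
    if not 0 <= microhomology <= 10:
        raise ValueError("microhomology must be in 0..10 bases")
    if insert and microhomology:
        raise ValueError("a non-templated insert and junction microhomology are mutually exclusive")
    if microhomology >= end - start:
        raise ValueError("microhomology must be shorter than the deletion")

    seq = list(genome.sequence)
    m = microhomology
    if insert:
        # guard against chance homology between the insert ends and the
        # retained flanks (edits fall inside the deleted interval)
        if seq[start] == insert[0]:
            _edit(seq, start, {insert[0]})
        if seq[end - 1] == insert[-1]:
            _edit(seq, end - 1, {insert[-1]})
    else:
        seq[start:start + m] = seq[end:end + m]
        # exact-m guarantee: break chance extension on either side of the
        # shared tract (both edited positions lie inside the deletion)
        if seq[start + m] == seq[end + m]:
            _edit(seq, start + m, {seq[end + m]})
        if seq[start - 1] == seq[end - 1]:
            _edit(seq, end - 1, {seq[start - 1]})
    ref = _with_sequence(genome, "".join(seq))

    segments = [Segment(ref.sequence[:start], 0, 1, "telomeric")]
    if insert:
        off = TY_CONSENSUS.find(insert)
        ty = genome.feature("ura3-52_Ty")
        if off != -1 and off + len(insert) <= ty.length:
            segments.append(Segment(insert, ty.start + off, 1, "ty_insert"))
        else:
            segments.append(Segment(insert, None, 1, "insert"))
    segments.append(Segment(ref.sequence[end:], end, 1, "centromeric"))

    truth = RearrangementTruth(
        event_class="interstitial_deletion",
        breakpoints=(start, end),
        microhomology=m,
        insert=insert,
        hph_retained=True,
        size_class=_size_class(genome.length - (end - start) + len(insert), genome.length),
    )
    return Rearrangement(name=name, reference=ref, segments=segments, truth=truth)


def apply_inverted_duplication(
    genome: AssayChromosome,
    dsb: int,
    loop: int,
    priming_homology: int,
    resolution: str = "ura3-52",
    foldback: int | None = None,
    name: str = "inverted_duplication",
    seed: int = 0,
) -> Rearrangement:
    """Hairpin-mediated inverted duplication initiated at ``dsb``.

    The resected end anneals back onto itself via a ``priming_homology``-
    length inverted repeat planted in the reference at
    ``[foldback, foldback + h)`` (``foldback = dsb + h + loop``), leaving
    the unpaired loop template ``reference[dsb + h, foldback)``.  Synthesis
    copies ``[foldback + h, anchor)`` in inverted orientation; the anchor
    and the captured telomeric side depend on ``resolution``:

    ``"ura3-52"``
        HR between the copied ura3-52 URA3 homology and the cassette URA3
        recaptures the hph-containing telomeric fragment (hph retained).
    ``"ty"``
        HR between the copied Ty tract and a Ty element elsewhere captures
        a foreign telomeric fragment (hph lost).
    ``"none"``
        the isoduplication is resolved without homology capture, modelled
        as a de novo telomere cap on the inverted arm (hph lost).
    """
    h, lam = priming_homology, loop
    bpr = genome.feature("GCR_breakpoint_region")
    if not (bpr.start <= dsb < bpr.end):
        raise ValueError("the initiating DSB must lie inside the GCR breakpoint region")
    if not 10 <= lam <= 100:
        raise ValueError("loop length must be in 10..100 bases")
    if not 2 <= h <= 12:
        raise ValueError("priming homology must be in 2..12 bases")
    g = dsb + h + lam
    if foldback is not None and foldback != g:
        raise ValueError(
            f"inconsistent geometry: foldback must equal dsb + priming_homology + loop = {g}"
        )
    if resolution not in ("ura3-52", "ty", "none"):
        raise ValueError("resolution must be one of 'ura3-52', 'ty', 'none'")

    u5 = genome.feature("ura3-52_URA3")
    ty = genome.feature("ura3-52_Ty")
    ura3 = genome.feature("URA3")
    if resolution == "ura3-52":
        anchor = u5.start
    elif resolution == "ty":
        anchor = ty.start + 3 * ty.length // 4
    else:
        # resolved elsewhere: the duplicated arm extends past ura3-52 to a
        # non-repeat point (no boundary feature for the copy-number caller)
        nxt = (
            genome.feature("IRC22").start
            if genome.has_feature("IRC22")
            else min(ty.end + 2_000, genome.length - 1_000)
        )
        anchor = (ty.end + nxt) // 2
    if g + h >= anchor:
        raise ValueError(f"resolution feature {resolution!r} is not centromeric of the fold-back")

    seq = list(genome.sequence)
    # plant the priming inverted repeat; keep it maximal at exactly h:
    # no outward extension (edit falls in the deleted interval) and no
    # inward extension into the loop (edit falls in the loop template)
    seq[g:g + h] = list(revcomp("".join(seq[dsb:dsb + h])))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if seq[dsb - 1] == comp[seq[g + h]]:
        _edit(seq, dsb - 1, {seq[dsb - 1]})
    if seq[dsb + h] == comp[seq[g - 1]]:
        _edit(seq, g - 1, {comp[seq[dsb + h]]})
    ref = _with_sequence(genome, "".join(seq))
    refseq = ref.sequence

    arm = Segment(revcomp(refseq[g + h: anchor]), g + h, -1, "inverted_arm")
    right = Segment(refseq[dsb:], dsb, 1, "centromeric")
    rng = np.random.default_rng(seed)
    if resolution == "ura3-52":
        segments = [Segment(refseq[: ura3.end], 0, 1, "captured_telomeric"), arm, right]
    elif resolution == "ty":
        stub_rand = "".join(rng.choice(list("ACGT"), size=400))
        tel = tg_repeat_tract(rng, 250)
        # the captured fragment ends in inverted Ty sequence continuing the
        # arm's Ty homology, mimicking an HR crossover inside the Ty element
        k = anchor - ty.start
        m = min(200, ty.length - k)
        segments = [
            Segment(tel, None, 1, "captured_telomere"),
            Segment(stub_rand, None, 1, "captured_spacer"),
            Segment(revcomp(refseq[anchor: anchor + m]), anchor, -1, "captured_ty"),
            arm,
            right,
        ]
    else:
        tel = tg_repeat_tract(rng, 250)
        segments = [Segment(tel, None, 1, "de_novo_telomere"), arm, right]

    # breakpoint convention: ambiguous shared bases are assigned to the
    # retained centromeric side, so the arm-side breakpoint is the arm
    # start g + h (the priming repeat [g, g+h) reads as part of the
    # centromeric side's [dsb, dsb+h) copy)
    truth = RearrangementTruth(
        event_class="inverted_duplication",
        breakpoints=(dsb, g + h),
        priming_homology=h,
        loop=lam,
        resolution=resolution,
        hph_retained=resolution == "ura3-52",
        size_class=_size_class(sum(s.length for s in segments), genome.length),
    )
    return Rearrangement(name=name, reference=ref, segments=segments, truth=truth)


def apply_de_novo_telomere(
    genome: AssayChromosome,
    pos: int,
    seed_repeats: int = 150,
    name: str = "de_novo_telomere",
    seed: int = 0,
) -> Rearrangement:
    """Telomerase healing at ``pos``: a TG1-3 seed replaces [0, pos)."""
    cassette = genome.cassette
    bpr = genome.feature("GCR_breakpoint_region")
    if seed_repeats < 1:
        raise ValueError("at least one telomere seed repeat is required")
    if pos < cassette.end:
        raise ValueError(
            "telomere addition telomeric of the cassette would retain CAN1/URA3: not selectable"
        )
    if not (bpr.start <= pos < bpr.end):
        raise ValueError("the healed break must lie inside the GCR breakpoint region")

    rng = np.random.default_rng(seed)
    units = ["TG", "TGG", "TGGG"]
    tract = "".join(units[rng.integers(0, 3)] for _ in range(seed_repeats))
    seq = list(genome.sequence)
    if seq[pos - 1] == tract[-1]:
        # block chance extension of the centromeric match into the tail,
        # which would shift the annotated seed coordinate (edit falls in
        # the deleted interval)
        _edit(seq, pos - 1, {tract[-1]})
    ref = _with_sequence(genome, "".join(seq))
    segments = [
        Segment(tract, None, 1, "de_novo_telomere"),
        Segment(ref.sequence[pos:], pos, 1, "centromeric"),
    ]
    truth = RearrangementTruth(
        event_class="de_novo_telomere",
        breakpoints=(pos,),
        hph_retained=False,
        size_class=_size_class(len(tract) + genome.length - pos, genome.length),
    )
    return Rearrangement(name=name, reference=ref, segments=segments, truth=truth)


def apply_translocation(
    genome: AssayChromosome,
    pos: int,
    donor: str,
    donor_label: str = "donor",
    donor_map: tuple[int, int] | None = None,
    name: str = "translocation",
) -> Rearrangement:
    """Fusion of a donor sequence to the broken end at ``pos``.

    ``donor_map = (ref_start, strand)`` declares that the donor derives
    from the reference (e.g. the reverse complement of a right-arm
    segment), enabling exact read projection and a fully mappable junction.
    """
    cassette = genome.cassette
    bpr = genome.feature("GCR_breakpoint_region")
    if not donor:
        raise ValueError("translocation donor must be non-empty")
    if pos < cassette.end:
        raise ValueError("translocation telomeric of the cassette would retain CAN1/URA3")
    if not (bpr.start <= pos < bpr.end):
        raise ValueError("the junction must lie inside the GCR breakpoint region")

    seq = list(genome.sequence)
    if seq[pos - 1] == donor[-1]:
        _edit(seq, pos - 1, {donor[-1]})  # inside the deleted interval
    if donor_map is not None:
        ds, strand = donor_map
        # guard against chance extension of the donor-side match across the
        # junction (would shift the annotated breakpoint by a base)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if strand == -1 and ds > 0 and comp[seq[ds - 1]] == seq[pos]:
            _edit(seq, ds - 1, {seq[ds - 1]})
        if strand == 1 and ds + len(donor) < genome.length and seq[ds + len(donor)] == seq[pos]:
            _edit(seq, ds + len(donor), {seq[ds + len(donor)]})
        refseq = "".join(seq)
        donor = (
            refseq[ds: ds + len(donor)]
            if strand == 1
            else revcomp(refseq[ds: ds + len(donor)])
        )
    ref = _with_sequence(genome, "".join(seq))

    donor_coord: int | None = None
    if donor_map is not None:
        ds, strand = donor_map
        donor_segs = [Segment(donor, ds, strand, donor_label)]
        donor_coord = ds if strand == -1 else ds + len(donor)
    else:
        # a novel donor whose junction-adjacent tail is Ty consensus maps to
        # the chromosomal Ty tract: split so reads over the tail project there
        ty = genome.feature("ura3-52_Ty")
        tyseq = ref.feature_seq("ura3-52_Ty")
        k = 0
        lo, hi = 0, len(donor)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if donor[-mid:] in tyseq:
                lo = mid
            else:
                hi = mid - 1
        k = lo
        if k >= 50:
            off = tyseq.find(donor[-k:])
            donor_segs = [
                Segment(donor[:-k], None, 1, donor_label),
                Segment(donor[-k:], ty.start + off, 1, donor_label + "_ty"),
            ]
            donor_coord = ty.start + off + k
        else:
            donor_segs = [Segment(donor, None, 1, donor_label)]
    segments = donor_segs + [Segment(ref.sequence[pos:], pos, 1, "centromeric")]
    breakpoints = (pos,) if donor_coord is None else tuple(sorted((pos, donor_coord)))
    truth = RearrangementTruth(
        event_class="translocation",
        breakpoints=breakpoints,
        hph_retained=False,
        size_class=_size_class(len(donor) + genome.length - pos, genome.length),
    )
    return Rearrangement(name=name, reference=ref, segments=segments, truth=truth)
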