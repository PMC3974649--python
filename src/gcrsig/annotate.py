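"""Placement and characterisation of junction consensus sequences.

A junction consensus is located on the reference by its maximal exact
prefix and suffix matches (either strand).  The overlap of the two matched
intervals on the consensus is the junction microhomology (short sequence
identity shared by the joined ends); a gap between them is a non-templated
insert.  Same-target junctions with opposite-strand sides and near-
adjacent coordinates are fold-back (hairpin) junctions: the shared bases
are the priming inverted repeat and the reference template between the
two sides (net of the repeat) is the unpaired hairpin loop.  A consensus
with one unmappable side matching the TG1-3 pattern is a de novo telomere
addition.

Breakpoint convention: ambiguous microhomology bases are assigned to the
suffix (side B) match; side A's coordinate is trimmed by the microhomology
length, mirroring the leftmost placement of the colon notation used in
junction displays.  ``raw_coord`` keeps the untrimmed match boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .caller import JunctionSequence
from .chromosome import AssayChromosome, revcomp

MIN_ANCHOR = 15  # minimum exact bases for a mappable side
MAX_FOLDBACK_LOOP = 200  # largest unpaired loop accepted as fold-back geometry
TEL_MIN_LEN = 15
TEL_MIN_CONFORMITY = 0.90

JUNCTION_CLASSES = (
    "deletion",
    "translocation",
    "inversion_foldback",
    "telomere_addition",
    "unresolved",
)


@dataclass
class JunctionSideHit:
    target: str
    coord: int  # junction-adjacent coordinate, microhomology trimmed (side A)
    raw_coord: int  # untrimmed maximal-match boundary
    strand: str  # '+'/'-'
    match_length: int
    features: tuple[str, ...] = ()  # feature tracts containing the match end


@dataclass
class BreakpointAnnotation:
    side_a: JunctionSideHit | None
    side_b: JunctionSideHit | None
    microhomology: int
    microhomology_seq: str
    insert: str
    junction_class: str
    consensus: str = ""

    def __post_init__(self):
        if self.microhomology != len(self.microhomology_seq):
            raise ValueError("microhomology length must equal its sequence length")
        if self.microhomology and self.insert:
            raise ValueError("microhomology and a non-templated insert are mutually exclusive")


@dataclass
class FoldbackAnnotation:
    center: float  # midpoint of the loop's reference template
    priming_homology: int
    priming_homology_seq: str
    loop: int
    loop_seq: str
    # canonical physical breakpoints, independent of consensus orientation:
    # the DSB-side coordinate (retained centromeric sequence starts here on
    # the plus strand) and the start of the inverted arm copy
    dsb: int = 0
    arm_start: int = 0
    zero_loop: bool = False  # perfect palindrome: Sae2-cleavable geometry

    def __post_init__(self):
        if self.loop != len(self.loop_seq):
            raise ValueError("loop length must equal its sequence length")

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.dsb, self.arm_start)


@dataclass
class TelomereCall:
    seed_coord: int
    conformity: float
    tail_length: int


def _all_occurrences(s: str, ref: str, ref_rc: str, cap: int = 16):
    """All occurrences of ``s`` on either strand, in plus coordinates."""
    hits = []
    i = ref.find(s)
    while i != -1 and len(hits) < cap:
        hits.append((i, i + len(s), "+"))
        i = ref.find(s, i + 1)
    j = ref_rc.find(s)
    while j != -1 and len(hits) < 2 * cap:
        lo = len(ref) - (j + len(s))
        hits.append((lo, lo + len(s), "-"))
        j = ref_rc.find(s, j + 1)
    return hits


def _longest_affix(consensus: str, ref: str, ref_rc: str, suffix: bool):
    """Maximal exact prefix (or suffix) occurrences on either strand.

    The set of matchable lengths is downward-closed (an occurrence of a
    string contains occurrences of its affixes), so binary search over the
    length applies.  Returns (length, [(ref_lo, ref_hi, strand), ...]);
    multiple occurrences arise when the matched arm lies inside a repeated
    tract (hph / URA3 homologies, Ty consensus).
    """
    n = len(consensus)

    def occurs(k: int) -> bool:
        s = consensus[-k:] if suffix else consensus[:k]
        return ref.find(s) != -1 or ref_rc.find(s) != -1

    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if occurs(mid):
            lo = mid
        else:
            hi = mid - 1
    if lo == 0:
        return 0, []
    s = consensus[-lo:] if suffix else consensus[:lo]
    return lo, _all_occurrences(s, ref, ref_rc)


def _features_at(reference: AssayChromosome, coord: int) -> tuple[str, ...]:
    return tuple(f.name for f in reference.features if f.start <= coord < f.end)


def _place(
    consensus: JunctionSequence | str,
    reference: AssayChromosome,
    min_anchor: int = MIN_ANCHOR,
    _canonical: bool = True,
) -> BreakpointAnnotation:
    seq = consensus.sequence if isinstance(consensus, JunctionSequence) else consensus
    if len(seq) < 40:
        raise ValueError("consensus must be at least 40 bases")
    ref = reference.sequence
    ref_rc = revcomp(ref)
    n = len(seq)

    plen, phits = _longest_affix(seq, ref, ref_rc, suffix=False)
    slen, shits = _longest_affix(seq, ref, ref_rc, suffix=True)
    overlap = max(0, min(plen, slen, plen + slen - n))

    def prefix_raw(hit):
        lo, hi, strand = hit
        return hi if strand == "+" else lo

    def suffix_raw(hit):
        lo, hi, strand = hit
        return lo if strand == "+" else hi

    # an arm inside a repeated tract matches several reference copies;
    # choose the prefix/suffix occurrence pair spanning the smallest
    # junction (the parsimonious placement)
    phit = shit = None
    if plen >= min_anchor and slen >= min_anchor and phits and shits:
        phit, shit = min(
            ((p, s) for p in phits for s in shits),
            key=lambda ps: abs(prefix_raw(ps[0]) - suffix_raw(ps[1])),
        )
    else:
        phit = phits[0] if plen >= min_anchor and phits else None
        shit = shits[0] if slen >= min_anchor and shits else None

    side_a = side_b = None
    if phit is not None:
        lo, hi, strand = phit
        raw = prefix_raw(phit)
        coord = raw - overlap if strand == "+" else raw + overlap
        side_a = JunctionSideHit(
            reference.name, coord, raw, strand, plen,
            _features_at(reference, min(max(coord, lo), hi - 1)),
        )
    if shit is not None:
        lo, hi, strand = shit
        raw = suffix_raw(shit)
        side_b = JunctionSideHit(
            reference.name, raw, raw, strand, slen,
            _features_at(reference, max(min(raw, hi - 1), lo)),
        )

    if (
        _canonical
        and side_a is not None
        and side_b is not None
        and side_a.strand == side_b.strand == "-"
    ):
        # a junction read from the minus strand: re-place the reverse
        # complement so breakpoints follow the canonical (leftmost-shared-
        # bases, plus-strand) convention
        return _place(revcomp(seq), reference, min_anchor, _canonical=False)

    if side_a is None or side_b is None:
        return BreakpointAnnotation(side_a, side_b, 0, "", "", "unresolved", consensus=seq)
    if overlap:
        mh_seq = seq[plen - overlap: plen]
        ins = ""
    else:
        mh_seq = ""
        ins = seq[plen: n - slen]
    return BreakpointAnnotation(
        side_a, side_b, overlap, mh_seq, ins, "unresolved", consensus=seq
    )


def locate_junction(
    consensus: JunctionSequence | str,
    reference: AssayChromosome,
    min_anchor: int = MIN_ANCHOR,
) -> BreakpointAnnotation:
    """Place a junction consensus on the reference and classify it."""
    ann = _place(consensus, reference, min_anchor)
    foldback = detect_foldback(ann, reference)
    telomere = detect_telomere_addition(ann)
    ann.junction_class = classify_junction(ann, foldback, telomere)
    return ann


def compute_microhomology(
    side_a_segment: str, side_b_segment: str, split: int
) -> tuple[int, str]:
    """Identical bases shared by the two targets across a candidate split.

    Both segments are given in junction orientation and aligned at
    ``split``: side A's reference context continues past the split, side
    B's precedes it.  The microhomology is the maximal contiguous run of
    identical bases centred on the split (forward matches at/after it plus
    backward matches before it), capped by the shorter flank.
    """
    if not 0 <= split <= min(len(side_a_segment), len(side_b_segment)):
        raise ValueError("split must fall within both segments")
    fwd = 0
    while (
        split + fwd < len(side_a_segment)
        and split + fwd < len(side_b_segment)
        and side_a_segment[split + fwd] == side_b_segment[split + fwd]
    ):
        fwd += 1
    back = 0
    while (
        back < split
        and side_a_segment[split - 1 - back] == side_b_segment[split - 1 - back]
    ):
        back += 1
    length = fwd + back
    seq = side_b_segment[split - back: split + fwd]
    return length, seq


def detect_foldback(
    consensus,
    reference: AssayChromosome,
    max_loop: int = MAX_FOLDBACK_LOOP,
) -> FoldbackAnnotation | None:
    """Fold-back hairpin geometry from an inverted same-target junction.

    Accepts a consensus (string/JunctionSequence) or an existing
    :class:`BreakpointAnnotation`.  Using the raw (untrimmed) match
    boundaries ``x < y``, the priming repeat copies are ``[x, x+h)`` and
    ``[y, y+h)`` (h = junction microhomology, which for a hairpin junction
    is exactly the annealing homology) and the unpaired loop template is
    ``[x+h, y)``.  The repeat must be templated by the reference in
    inverted orientation; the detection is invariant under reverse-
    complementing the consensus, which merely swaps the two sides.
    Returns None when no inverted repeat of at least 2 bases mediates the
    fold-back.
    """
    ann = (
        consensus
        if isinstance(consensus, BreakpointAnnotation)
        else _place(consensus, reference)
    )
    a, b = ann.side_a, ann.side_b
    if a is None or b is None or a.target != b.target or a.strand == b.strand:
        return None
    h = ann.microhomology
    if h < 2:
        return None
    x, y = sorted((a.raw_coord, b.raw_coord))
    ref = reference.sequence
    if x == y and h % 2 == 0 and ref[x: x + h] == revcomp(ref[x: x + h]):
        # perfect palindrome: both affix matches run through the whole
        # inverted repeat, so the shared overlap is twice the priming
        # homology and the hairpin loop is empty (Sae2-cleavable geometry)
        half = h // 2
        return FoldbackAnnotation(
            center=x + half,
            priming_homology=half,
            priming_homology_seq=ref[x: x + half],
            loop=0,
            loop_seq="",
            dsb=x,
            arm_start=x + h,
            zero_loop=True,
        )
    loop_len = y - x - h
    if not 0 <= loop_len <= max_loop:
        return None
    if y + h > len(ref):
        return None
    if ref[y: y + h] != revcomp(ref[x: x + h]):
        return None  # shared bases are not a reference-templated inverted repeat
    loop_seq = ref[x + h: y]
    return FoldbackAnnotation(
        center=(x + h + y) / 2,
        priming_homology=h,
        priming_homology_seq=ref[x: x + h],
        loop=loop_len,
        loop_seq=loop_seq,
        dsb=x,
        arm_start=y + h,
        zero_loop=loop_len == 0,
    )


_TEL_UNIT = re.compile(r"(?:TG{1,3})+")


def tg_conformity(seq: str) -> float:
    """Fraction of a sequence parsable as TG1-3 repeat units (best strand)."""
    if not seq:
        return 0.0

    def frac(s: str) -> float:
        return sum(m.end() - m.start() for m in _TEL_UNIT.finditer(s)) / len(s)

    return max(frac(seq), frac(revcomp(seq)))


def detect_telomere_addition(
    annotation: BreakpointAnnotation,
    min_len: int = TEL_MIN_LEN,
    min_conformity: float = TEL_MIN_CONFORMITY,
) -> TelomereCall | None:
    """De novo telomere addition: an unanchored side matching TG1-3.

    One side must be unanchored — unmappable, or mapped only inside a
    reference telomere tract (novel TG1-3 tails share long chance
    substrings with the existing telomere seeds) — while the other is
    uniquely anchored.  The tail must match the TG1-3 pattern over at
    least ``min_len`` nt at ``min_conformity`` conformity (default 90%),
    scored per 2-4 nt repeat unit on the better strand.
    """

    def telomeric(side: JunctionSideHit | None) -> bool:
        return side is None or any(f.startswith("TEL_") for f in side.features)

    a, b = annotation.side_a, annotation.side_b
    if telomeric(a) == telomeric(b):
        return None
    seq = annotation.consensus
    if telomeric(a):
        tail = seq[: len(seq) - b.match_length]
        coord = b.coord
    else:
        tail = seq[a.match_length:]
        coord = a.coord
    if len(tail) < min_len:
        return None
    conf = tg_conformity(tail)
    if conf < min_conformity:
        return None
    return TelomereCall(seed_coord=coord, conformity=conf, tail_length=len(tail))


def classify_junction(
    annotation: BreakpointAnnotation,
    foldback: FoldbackAnnotation | None = None,
    telomere: TelomereCall | None = None,
) -> str:
    """Priority classification: telomere > fold-back > deletion > translocation."""
    if telomere is not None:
        return "telomere_addition"
    a, b = annotation.side_a, annotation.side_b
    if a is None or b is None:
        return "unresolved"
    if foldback is not None:
        return "inversion_foldback"
    if a.target == b.target and a.strand == b.strand:
        increasing = b.coord > a.coord if a.strand == "+" else a.coord > b.coord
        if increasing:
            return "deletion"
    return "translocation"


def annotate_junction(
    consensus: JunctionSequence | str, reference: AssayChromosome
) -> tuple[BreakpointAnnotation, FoldbackAnnotation | None, TelomereCall | None]:
    """Full annotation: placement, fold-back geometry, telomere check."""
    ann = _place(consensus, reference)
    foldback = detect_foldback(ann, reference)
    telomere = detect_telomere_addition(ann)
    ann.junction_class = classify_junction(ann, foldback, telomere)
    return ann, foldback, telomere


def junction_report(ann: BreakpointAnnotation) -> str:
    """Human-readable junction display in colon notation.

    Bases between colons are identical in both joined fragments; a
    non-templated insert is bracketed.
    """
    seq = ann.consensus
    if ann.side_a is None or ann.side_b is None:
        return f"unresolved junction: {seq}"
    p = ann.side_a.match_length
    mh = ann.microhomology
    if ann.insert:
        body = f"{seq[:p]}[{ann.insert}]{seq[p + len(ann.insert):]}"
    elif mh:
        body = f"{seq[:p - mh]}:{seq[p - mh:p]}:{seq[p:]}"
    else:
        body = f"{seq[:p]}|{seq[p:]}"
    return (
        f"{ann.junction_class}: sideA {ann.side_a.target}:{ann.side_a.coord}"
        f"({ann.side_a.strand}) sideB {ann.side_b.target}:{ann.side_b.coord}"
        f"({ann.side_b.strand}) microhomology={mh}\n{body}"
    )
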