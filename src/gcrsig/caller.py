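"""Junction calling from mapped paired-end reads.

Re-implements the discordant read-pair analysis used for the chrV GCR
assay isolates: PCR-duplicate removal, per-base ``nread``/``nspan``
coverage tracks, insert-size statistics with a data-derived concordance
cutoff, greedy clustering of junction-defining read pairs (pairs whose
mapped positions or orientations are inconsistent with the reference),
recruitment of junction-sequencing reads (unmapped mates beside a
cluster), and greedy-overlap consensus assembly of the junction sequence.

Junction-defining read pairs require both mates uniquely mapped.  Events
whose far side is novel sequence (de novo telomere additions, foreign
translocation donors) produce no such pairs, so clusters of half-mapped
pairs (one mate uniquely mapped, the other unmapped) are additionally
emitted as one-sided calls; the unmapped mates of those pairs are the
junction-sequencing reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats as sps

from .chromosome import revcomp
from .reads import ReadPairSet

logger = logging.getLogger(__name__)

UNIQUE_MAPQ = 20  # "uniquely mapping" dialect: MAPQ >= 20, no secondary flag


@dataclass(frozen=True)
class MateInfo:
    """One mate of a pair as mapped (forward-strand sequence when mapped)."""

    target: str | None
    start: int | None
    orient: str | None  # 'F'/'R'
    mapped: bool
    unique: bool
    seq: str

    @property
    def end(self) -> int | None:
        return None if self.start is None else self.start + len(self.seq)

    def read_sequence(self) -> str:
        """The read as sequenced (reverse-complemented back if R-mapped)."""
        return revcomp(self.seq) if self.mapped and self.orient == "R" else self.seq


@dataclass(frozen=True)
class MappedPair:
    pair_id: str
    m1: MateInfo
    m2: MateInfo

    @property
    def both_unique(self) -> bool:
        return self.m1.unique and self.m2.unique

    def span(self) -> tuple[int, int] | None:
        """Outermost mapped interval when both mates map to one target."""
        if not (self.m1.mapped and self.m2.mapped):
            return None
        if self.m1.target != self.m2.target:
            return None
        return (
            min(self.m1.start, self.m2.start),
            max(self.m1.end, self.m2.end),
        )

    def convergent(self) -> bool:
        """Standard FR orientation: leftmost mate forward, rightmost reverse."""
        span = self.span()
        if span is None:
            return False
        left, right = (
            (self.m1, self.m2) if self.m1.start <= self.m2.start else (self.m2, self.m1)
        )
        return left.orient == "F" and right.orient == "R"


@dataclass
class CoverageTracks:
    nread: np.ndarray
    nspan: np.ndarray


@dataclass
class InsertStats:
    median: float
    mad: float
    cutoff: float
    n_pairs: int


@dataclass
class JunctionSide:
    target: str
    interval: tuple[int, int]  # [lo, hi) over supporting read starts
    orient: str


@dataclass
class JunctionCall:
    side_a: JunctionSide
    side_b: JunctionSide | None  # None for one-sided calls
    pair_ids: list[str]
    support: int
    significant: bool
    p_value: float
    geometry: str  # 'two_sided' | 'foldback' | 'one_sided'

    def __post_init__(self):
        if self.support != len(self.pair_ids):
            raise ValueError("support count must equal the number of supporting pairs")


@dataclass
class JunctionSequence:
    sequence: str
    n_reads: int
    agreement: float
    n_contigs: int = 1


# ---------------------------------------------------------------------------
# ingestion

def load_mapped_pairs(path: str) -> list[MappedPair]:
    """Load paired records from a SAM file (one MappedPair per template).

    Secondary/supplementary records are ignored; templates with a single
    record are rejected with a logged count.
    """
    by_name: dict[str, dict[int, MateInfo]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=True) as f:
        for rec in f:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mapped = not rec.is_unmapped
            info = MateInfo(
                target=f.get_reference_name(rec.reference_id) if mapped else None,
                start=rec.reference_start if mapped else None,
                orient=("R" if rec.is_reverse else "F") if mapped else None,
                mapped=mapped,
                unique=mapped and rec.mapping_quality >= UNIQUE_MAPQ,
                seq=rec.query_sequence or "",
            )
            slot = 2 if rec.is_read2 else 1
            by_name.setdefault(rec.query_name, {})[slot] = info
    pairs, n_unpaired = [], 0
    for name, mates in by_name.items():
        if len(mates) != 2:
            n_unpaired += 1
            continue
        pairs.append(MappedPair(name, mates[1], mates[2]))
    if n_unpaired:
        logger.warning("rejected %d unpaired templates", n_unpaired)
    if not pairs:
        logger.warning("no read pairs loaded from %s", path)
    return pairs


def pairs_from_simulation(sim: ReadPairSet) -> list[MappedPair]:
    """In-memory equivalent of writing the simulated SAM and re-loading it."""
    out = []
    for p in sim.pairs:
        mates = []
        for r in (p.r1, p.r2):
            mapped = r.ref_start is not None
            mates.append(
                MateInfo(
                    target=sim.target_name if mapped else None,
                    start=r.ref_start,
                    orient=r.ref_orient,
                    mapped=mapped,
                    unique=mapped and r.unique,
                    seq=revcomp(r.seq) if mapped and r.ref_orient == "R" else r.seq,
                )
            )
        out.append(MappedPair(p.pair_id, mates[0], mates[1]))
    return out


# ---------------------------------------------------------------------------
# core operations

def deduplicate_pairs(pairs: list[MappedPair]) -> list[MappedPair]:
    """Keep one pair per (target, start, orientation) mate-coordinate tuple.

    Coordinate-based PCR/optical duplicate removal; the first pair
    encountered in input order is retained.  Idempotent.
    """
    seen: set = set()
    out = []
    for p in pairs:
        key = tuple(
            (m.target, m.start, m.orient, m.mapped) for m in (p.m1, p.m2)
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


def compute_coverage_tracks(pairs: list[MappedPair], target_length: int) -> CoverageTracks:
    """Per-base nread (read coverage) and nspan (pair-span coverage) tracks."""
    nread = np.zeros(target_length + 1, dtype=np.int64)
    nspan = np.zeros(target_length + 1, dtype=np.int64)
    for p in pairs:
        for m in (p.m1, p.m2):
            if m.mapped:
                nread[m.start] += 1
                nread[m.end] -= 1
        span = p.span()
        if span is not None:
            nspan[span[0]] += 1
            nspan[span[1]] -= 1
    return CoverageTracks(
        nread=np.cumsum(nread[:-1]), nspan=np.cumsum(nspan[:-1])
    )


def estimate_insert_stats(
    pairs: list[MappedPair], k: float = 10.0, min_pairs: int = 100
) -> InsertStats:
    """Median/MAD of the mapped inter-read distance of concordant pairs.

    Distance is the outer span (leftmost start to rightmost end), i.e. the
    fragment length of an error-free pair.  The concordance cutoff is
    ``median + k * MAD`` (k = 10 by default).
    """
    dists = [
        p.span()[1] - p.span()[0]
        for p in pairs
        if p.both_unique and p.convergent()
    ]
    if len(dists) < min_pairs:
        raise ValueError(
            f"only {len(dists)} uniquely mapped convergent pairs (need >= "
            f"{min_pairs}); supply an explicit concordance cutoff instead"
        )
    arr = np.asarray(dists, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return InsertStats(median=med, mad=mad, cutoff=med + k * mad, n_pairs=len(arr))


def _is_discordant(p: MappedPair, cutoff: float) -> bool:
    if not (p.both_unique and p.m1.mapped and p.m2.mapped):
        return False
    if p.m1.target != p.m2.target:
        return True
    if not p.convergent():
        return True
    span = p.span()
    return span[1] - span[0] > cutoff


def _sides(p: MappedPair) -> tuple[MateInfo, MateInfo]:
    a, b = p.m1, p.m2
    if (a.target, a.start) > (b.target, b.start):
        a, b = b, a
    return a, b


def _poisson_p(support: int, rate: float) -> float:
    return float(sps.poisson.sf(support - 1, rate))


def cluster_junction_pairs(
    pairs: list[MappedPair],
    stats: InsertStats,
    min_support: int = 3,
    min_support_foldback: int = 2,
    alpha: float = 0.01,
    target_lengths: dict[str, int] | None = None,
) -> list[JunctionCall]:
    """Greedy single-linkage clustering of junction-defining read pairs.

    Pairs are discordant when their inter-read distance exceeds the
    concordance cutoff, their mates map to different targets, or their
    orientations are non-convergent.  Two pairs join a cluster iff on both
    sides the orientations match and the start coordinates differ by at
    most the cutoff.  Cluster significance combines a support floor
    (``min_support``; lower for fold-back geometry, where palindromes
    suppress library yield) with a Poisson test of the support count
    against a uniform genome-wide chimeric-pair background estimated from
    the data (``alpha`` = 0.01).

    Clusters of half-mapped pairs (one mate unique, the mate unmapped) are
    emitted as one-sided calls, which is how junctions to novel sequence
    (de novo telomeres, foreign donors) present.
    """
    cutoff = stats.cutoff
    genome_length = sum((target_lengths or {"": 2 * 10**5}).values())

    discordant = [p for p in pairs if _is_discordant(p, cutoff)]
    half_mapped = [
        p
        for p in pairs
        if (p.m1.unique and not p.m2.mapped) or (p.m2.unique and not p.m1.mapped)
    ]

    calls: list[JunctionCall] = []

    # --- two-sided clusters -------------------------------------------------
    keyed = sorted(
        discordant,
        key=lambda p: (
            _sides(p)[0].target, _sides(p)[0].start,
            _sides(p)[1].target, _sides(p)[1].start,
        ),
    )
    clusters: list[dict] = []
    for p in keyed:
        a, b = _sides(p)
        placed = False
        for cl in clusters:
            if (
                a.target == cl["ta"] and b.target == cl["tb"]
                and a.orient == cl["oa"] and b.orient == cl["ob"]
                and abs(a.start - cl["amax"]) <= cutoff
                and cl["bmin"] - cutoff <= b.start <= cl["bmax"] + cutoff
            ):
                cl["members"].append(p)
                cl["amax"] = max(cl["amax"], a.start)
                cl["amin"] = min(cl["amin"], a.start)
                cl["bmin"] = min(cl["bmin"], b.start)
                cl["bmax"] = max(cl["bmax"], b.start)
                placed = True
                break
        if not placed:
            clusters.append(
                dict(
                    ta=a.target, tb=b.target, oa=a.orient, ob=b.orient,
                    amin=a.start, amax=a.start, bmin=b.start, bmax=b.start,
                    members=[p],
                )
            )
    bg_rate = max(len(discordant), 1) * 2 * cutoff / genome_length
    for cl in clusters:
        support = len(cl["members"])
        foldback = (
            cl["ta"] == cl["tb"]
            and cl["oa"] == cl["ob"]
            and cl["amin"] <= cl["bmax"] + cutoff
            and cl["bmin"] <= cl["amax"] + cutoff
        )
        floor = min_support_foldback if foldback else min_support
        p_val = _poisson_p(support, bg_rate)
        calls.append(
            JunctionCall(
                side_a=JunctionSide(cl["ta"], (cl["amin"], cl["amax"] + 1), cl["oa"]),
                side_b=JunctionSide(cl["tb"], (cl["bmin"], cl["bmax"] + 1), cl["ob"]),
                pair_ids=[m.pair_id for m in cl["members"]],
                support=support,
                significant=support >= floor and p_val <= alpha,
                p_value=p_val,
                geometry="foldback" if foldback else "two_sided",
            )
        )

    # --- one-sided clusters (junctions into novel sequence) -----------------
    anchored = sorted(
        half_mapped,
        key=lambda p: (
            (p.m1 if p.m1.mapped else p.m2).target,
            (p.m1 if p.m1.mapped else p.m2).start,
        ),
    )
    oclusters: list[dict] = []
    for p in anchored:
        m = p.m1 if p.m1.mapped else p.m2
        placed = False
        for cl in oclusters:
            if (
                m.target == cl["t"] and m.orient == cl["o"]
                and abs(m.start - cl["max"]) <= cutoff
            ):
                cl["members"].append(p)
                cl["max"] = max(cl["max"], m.start)
                cl["min"] = min(cl["min"], m.start)
                placed = True
                break
        if not placed:
            oclusters.append(dict(t=m.target, o=m.orient, min=m.start, max=m.start, members=[p]))
    bg1 = max(len(half_mapped), 1) * 2 * cutoff / genome_length
    one_sided: list[JunctionCall] = []
    for cl in oclusters:
        support = len(cl["members"])
        p_val = _poisson_p(support, bg1)
        one_sided.append(
            JunctionCall(
                side_a=JunctionSide(cl["t"], (cl["min"], cl["max"] + 1), cl["o"]),
                side_b=None,
                pair_ids=[m.pair_id for m in cl["members"]],
                support=support,
                significant=support >= min_support and p_val <= alpha,
                p_value=p_val,
                geometry="one_sided",
            )
        )

    # one-sided clusters flanking a significant two-sided call are that
    # call's own junction-sequencing pairs (one mate spans the junction and
    # is unmapped) — absorb them rather than reporting a satellite event
    def _absorbed(c1: JunctionCall) -> bool:
        s1 = c1.side_a
        for c in calls:
            if not c.significant:
                continue
            for s in (c.side_a, c.side_b):
                if (
                    s is not None
                    and s.target == s1.target
                    and s.orient == s1.orient
                    and s1.interval[0] <= s.interval[1] + cutoff
                    and s.interval[0] - cutoff <= s1.interval[1]
                ):
                    return True
        return False

    calls.extend(c for c in one_sided if not _absorbed(c))
    return calls


def recruit_junction_reads(
    call: JunctionCall, pairs: list[MappedPair], stats: InsertStats
) -> list[str]:
    """Junction-sequencing reads for a call.

    Returns the (as-sequenced) unmapped mates of pairs whose uniquely
    mapped mate lies within one concordance cutoff of either side interval
    with the side's orientation.
    """
    sides = [s for s in (call.side_a, call.side_b) if s is not None]
    reads = []
    for p in pairs:
        for m, other in ((p.m1, p.m2), (p.m2, p.m1)):
            if not (m.unique and not other.mapped):
                continue
            for s in sides:
                if (
                    m.target == s.target
                    and m.orient == s.orient
                    and s.interval[0] - stats.cutoff <= m.start <= s.interval[1] + stats.cutoff
                ):
                    reads.append(other.read_sequence())
                    break
    return reads


# ---------------------------------------------------------------------------
# consensus assembly

def _best_overlap(a: str, b: str, min_overlap: int) -> tuple[int, int]:
    """Largest exact suffix(a)/prefix(b) overlap and the symmetric case.

    Returns (olen, mode): mode 0 = append b after a, 1 = append a after b.
    """
    best = (0, 0)
    lim = min(len(a), len(b))
    for olen in range(lim, min_overlap - 1, -1):
        if a[-olen:] == b[:olen]:
            best = (olen, 0)
            break
    for olen in range(lim, max(best[0], min_overlap - 1), -1):
        if b[-olen:] == a[:olen]:
            if olen > best[0]:
                best = (olen, 1)
            break
    return best


def assemble_junction_consensus(
    reads: list[str], min_overlap: int = 20
) -> JunctionSequence:
    """Greedy exact-overlap layout + per-column majority consensus.

    Reads may come from either strand; each is placed in the orientation
    giving the larger overlap.  Reads that cannot be joined are dropped
    from the layout (largest layout kept) and reported via ``n_contigs``.
    """
    if not reads:
        raise ValueError("at least one read is required")
    pool = sorted(set(reads), key=lambda r: (-len(r), r))
    placements: list[tuple[int, str]] = [(0, pool[0])]  # (offset, oriented read)
    contig = pool[0]
    remaining = pool[1:]
    n_placed = 1
    while remaining:
        best = None  # (olen, mode, idx, oriented)
        for idx, r in enumerate(remaining):
            for oriented in (r, revcomp(r)):
                if oriented in contig:
                    pos = contig.find(oriented)
                    best = (len(oriented), "contained", idx, oriented, pos)
                    break
                olen, mode = _best_overlap(contig, oriented, min_overlap)
                if olen and (best is None or olen > best[0]):
                    best = (olen, mode, idx, oriented, None)
            if best and best[1] == "contained":
                break
        if best is None:
            break
        olen, mode, idx, oriented, pos = best
        r = remaining.pop(idx)
        n_placed += 1
        if mode == "contained":
            placements.append((pos, oriented))
        elif mode == 0:
            placements.append((len(contig) - olen, oriented))
            contig = contig + oriented[olen:]
        else:
            shift = len(oriented) - olen
            placements = [(off + shift, s) for off, s in placements]
            placements.append((0, oriented))
            contig = oriented + contig[olen:]

    # per-column majority with lexicographic tie-break
    length = max(off + len(s) for off, s in placements)
    counts: list[dict[str, int]] = [dict() for _ in range(length)]
    for off, s in placements:
        for j, base in enumerate(s):
            col = counts[off + j]
            col[base] = col.get(base, 0) + 1
    seq_chars, agree, covered = [], 0.0, 0
    for col in counts:
        if not col:
            seq_chars.append("N")
            continue
        # lexicographic tie-break: smallest base among max-count bases
        maxn = max(col.values())
        winner = min(b for b, n in col.items() if n == maxn)
        seq_chars.append(winner)
        agree += col[winner] / sum(col.values())
        covered += 1
    n_left = len(remaining)
    if n_left:
        logger.warning("%d reads could not be joined into the main layout", n_left)
    return JunctionSequence(
        sequence="".join(seq_chars),
        n_reads=n_placed,
        agreement=agree / max(covered, 1),
        n_contigs=1 + (1 if n_left else 0),
    )
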