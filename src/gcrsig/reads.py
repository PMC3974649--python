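"""Paired-end read simulation over rearranged genomes.

Fragments are drawn uniformly along the product genome with truncated-
normal insert sizes (a ~600 bp gel-selected library by default) and read
error-free from both ends.  Alignments are emitted in *reference* space by
exact projection of each read's true origin through the rearrangement
segment map: reads crossing a novel junction are unmapped, reads whose
projected interval lies inside a multi-copy homology tract (hph /
hph-internal, cassette URA3 / ura3-52) carry MAPQ 0.  This reproduces what
an ideal exact unique mapper would report, without re-implementing short-
read mapping.  Product-space truth coordinates travel in SAM tags
(``ps``/``pe``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .chromosome import AssayChromosome, revcomp
from .rearrange import Rearrangement

DEFAULT_MAPQ = 60


@dataclass
class LibraryModel:
    """Sequencing library parameters (600 bp paired-end by default)."""

    insert_mean: int = 600
    insert_sd: float = 60.0
    read_length: int = 100
    coverage: float = 50.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.read_length > self.insert_mean:
            raise ValueError("read length must not exceed the insert mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate fraction must be in [0, 1)")


@dataclass
class SimulatedRead:
    """One mate: product-space truth plus reference-space projection."""

    seq: str
    product_start: int
    orient: str  # 'F'/'R' in product space
    ref_start: int | None  # None: unmapped (junction-crossing or novel)
    ref_orient: str | None
    unique: bool


@dataclass
class SimulatedPair:
    pair_id: str
    r1: SimulatedRead
    r2: SimulatedRead
    is_duplicate: bool


@dataclass
class ReadPairSet:
    """A simulated library with truth labels and SAM/FASTQ export."""

    pairs: list[SimulatedPair]
    target_name: str
    target_length: int
    n_unique_truth: int  # distinct fragment coordinates among all pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def write_fastq(self, path1: str, path2: str) -> None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for p in self.pairs:
                q1 = "I" * len(p.r1.seq)
                q2 = "I" * len(p.r2.seq)
                f1.write(f"@{p.pair_id}/1\n{p.r1.seq}\n+\n{q1}\n")
                f2.write(f"@{p.pair_id}/2\n{p.r2.seq}\n+\n{q2}\n")

    def _sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": self.target_name, "LN": self.target_length}],
            }
        )

    def write_sam(self, path: str) -> None:
        header = self._sam_header()
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            for p in self.pairs:
                a1 = self._to_aligned(p, p.r1, p.r2, header, first=True)
                a2 = self._to_aligned(p, p.r2, p.r1, header, first=False)
                out.write(a1)
                out.write(a2)

    def _to_aligned(self, pair, read, mate, header, first):
        a = pysam.AlignedSegment(header)
        a.query_name = pair.pair_id
        # SAM stores mapped reads on the forward reference strand
        a.query_sequence = (
            revcomp(read.seq)
            if read.ref_start is not None and read.ref_orient == "R"
            else read.seq
        )
        a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
        flag = 0x1 | (0x40 if first else 0x80)
        if read.ref_start is None:
            flag |= 0x4
        elif read.ref_orient == "R":
            flag |= 0x10
        if mate.ref_start is None:
            flag |= 0x8
        elif mate.ref_orient == "R":
            flag |= 0x20
        a.flag = flag
        if read.ref_start is not None:
            a.reference_id = 0
            a.reference_start = read.ref_start
            a.mapping_quality = DEFAULT_MAPQ if read.unique else 0
            a.cigarstring = f"{len(read.seq)}M"
        else:
            a.reference_id = 0 if mate.ref_start is not None else -1
            a.reference_start = mate.ref_start if mate.ref_start is not None else -1
            a.mapping_quality = 0
        if mate.ref_start is not None:
            a.next_reference_id = 0
            a.next_reference_start = mate.ref_start
        else:
            a.next_reference_id = a.reference_id
            a.next_reference_start = a.reference_start
        a.set_tag("ps", read.product_start)
        a.set_tag("pe", read.product_start + len(read.seq))
        return a


def _ambiguous_intervals(reference: AssayChromosome) -> list[tuple[int, int]]:
    out = []
    for fam in reference.homology_families:
        for name, _strand in fam:
            f = reference.feature(name)
            out.append((f.start, f.end))
    return out


def simulate_read_pairs(rearr: Rearrangement, model: LibraryModel) -> ReadPairSet:
    """Simulate an error-free paired-end library over a rearranged genome.

    The expected pair count is ``coverage * genome_length / (2 *
    read_length)``.  A ``duplicate_fraction`` of pairs are exact copies of
    earlier pairs (identical coordinates and sequences, fresh read names),
    matching PCR/optical duplicate semantics.  Deterministic under a fixed
    seed.
    """
    L = rearr.length
    rl = model.read_length
    if L <= 2 * model.insert_mean:
        raise ValueError("genome must be longer than twice the insert mean")
    rng = np.random.default_rng(model.seed)

    n_pairs = int(round(model.coverage * L / (2 * rl)))
    n_dup = int(round(n_pairs * model.duplicate_fraction))
    n_base = n_pairs - n_dup

    inserts = np.clip(
        np.rint(rng.normal(model.insert_mean, model.insert_sd, n_base)), rl, L
    ).astype(np.int64)
    starts = np.floor(rng.random(n_base) * (L - inserts + 1)).astype(np.int64)
    if n_dup:
        src = rng.integers(0, n_base, n_dup)
        starts = np.concatenate([starts, starts[src]])
        inserts = np.concatenate([inserts, inserts[src]])
    dup_flags = np.zeros(n_pairs, dtype=bool)
    dup_flags[n_base:] = True

    ambiguous = _ambiguous_intervals(rearr.reference)

    def is_ambiguous(a: int, b: int) -> bool:
        return any(lo <= a and b <= hi for lo, hi in ambiguous)

    product = rearr.sequence
    pairs: list[SimulatedPair] = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        mates = []
        for pstart, orient in ((s, "F"), (s + ins - rl, "R")):
            raw = product[pstart: pstart + rl]
            seq = raw if orient == "F" else revcomp(raw)
            proj = rearr.project(pstart, pstart + rl)
            if proj is None:
                mates.append(SimulatedRead(seq, pstart, orient, None, None, False))
            else:
                ra, rb, strand = proj
                ref_orient = orient if strand == 1 else ("R" if orient == "F" else "F")
                mates.append(
                    SimulatedRead(
                        seq, pstart, orient, ra, ref_orient,
                        not is_ambiguous(ra, rb),
                    )
                )
        pairs.append(
            SimulatedPair(f"{rearr.name}:p{i:07d}", mates[0], mates[1], bool(dup_flags[i]))
        )

    n_unique_truth = len({(int(a), int(b)) for a, b in zip(starts, inserts)})
    return ReadPairSet(
        pairs=pairs,
        target_name=rearr.reference.name,
        target_length=rearr.reference.length,
        n_unique_truth=n_unique_truth,
    )
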