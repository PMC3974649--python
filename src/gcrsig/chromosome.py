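"""Synthetic assay chromosome for the yeast chrV marker-loss (GCR) assays.

The assay chromosome is a pseudo-random sequence carrying the feature
topology the analysis depends on: a left telomere, the telomeric ``hph``
hygromycin marker, the ``CAN1/URA3`` counter-selection cassette, the GCR
breakpoint region (bounded by the cassette and the first essential gene
``PCM1``), the Ty-containing ``ura3-52`` allele, ``CEN5``, the ``MCM3``
probe locus, two AscI restriction sites, and a right telomere.  Feature
homology (hph duplicated into the internal AscI fragment, URA3 shared in
inverted orientation between the cassette and ura3-52, a Ty consensus
tract) is planted by construction so that probe hybridisation, homology-
mediated resolution and multi-mapping behave as in the real assay strain.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ASCI_MOTIF = "GGCGCGCC"
_BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n``."""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def tg_repeat_tract(rng: np.random.Generator, min_len: int) -> str:
    """Irregular yeast-style TG1-3 telomere tract of at least ``min_len`` nt.

    Units are drawn from {TG, TGG, TGGG}, which reproduces the irregular
    G-strand repeat structure closely enough to exercise the de novo
    telomere detector without modelling telomerase.
    """
    units = ("TG", "TGG", "TGGG")
    parts: list[str] = []
    total = 0
    while total < min_len:
        u = units[rng.integers(0, 3)]
        parts.append(u)
        total += len(u)
    return "".join(parts)


def _motif_free(rng: np.random.Generator, n: int, motif: str = ASCI_MOTIF) -> str:
    """Random DNA of length n guaranteed not to contain ``motif``."""
    while True:
        s = random_dna(rng, n)
        if motif not in s:
            return s


# A fixed ~6 kb Ty retrotransposon consensus stand-in (synthetic): shared by
# the chromosomal ura3-52 Ty tract and by any Ty-fragment donors/inserts, so
# that Ty-mediated junction homology is recognisable.
_TY_SEED = 254  # one seed for one consensus standing in for ~254 Ty-related elements
TY_CONSENSUS = _motif_free(np.random.default_rng(_TY_SEED), 5917)


@dataclass(frozen=True)
class Feature:
    """A named half-open interval [start, end) on the assay chromosome."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.name}: bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


# Anchor positions of the default uGCR layout expressed on the full-scale
# 580 kb chromosome; scaled proportionally for smaller test chromosomes.
# (name, start, length, minimum length after scaling)
_UGCR_DESIGN = (
    ("TEL_L", 0, 500, 200),
    # chrV L gene loci used by the MLPA probe panel: EAF5/YEA6 telomeric of
    # hph, VMA8/BUD16/GEA2 between PCM1 and ura3-52 (inside inverted-
    # duplication extents), IRC22/MNN1 centromeric of ura3-52
    ("EAF5", 6_000, 800, 60),
    ("YEA6", 12_000, 800, 60),
    ("hph", 20_000, 1_600, 250),
    ("AscI_1", 25_000, 8, 8),
    # URA3 is the telomeric gene of the cassette: HR between URA3 and the
    # inverted URA3 homology at ura3-52 then recaptures the hph-containing
    # end while deleting CAN1 and disrupting URA3 (Can^R 5-FOA^R selectable)
    ("hph_internal", 27_000, 1_600, 250),
    ("URA3", 30_000, 1_100, 90),
    ("CAN1", 31_300, 2_400, 200),
    ("GCR_breakpoint_region", 34_000, 16_800, 1_300),
    ("PCM1", 51_000, 1_800, 150),
    ("VMA8", 60_000, 1_000, 60),
    ("BUD16", 80_000, 1_000, 60),
    ("GEA2", 100_000, 1_000, 60),
    ("ura3-52_URA3", 116_000, 1_100, 90),
    ("ura3-52_Ty", 117_100, 4_900, 400),
    ("IRC22", 130_000, 1_000, 60),
    ("MNN1", 140_000, 1_000, 60),
    ("CEN5", 152_000, 120, 10),
    ("MCM3", 200_000, 3_000, 250),
    ("AscI_2", 400_000, 8, 8),
    ("TEL_R", 579_500, 500, 200),
)
_DESIGN_LENGTH = 580_000
MIN_LENGTH = 50_000

#: canonical left-arm feature order required by the uGCR assay
UGCR_ORDER = (
    "TEL_L",
    "hph",
    "CAN1_URA3_cassette",
    "GCR_breakpoint_region",
    "PCM1",
    "ura3-52",
    "CEN5",
)

REQUIRED_UNIQUE = (
    "TEL_L",
    "hph",
    "CAN1",
    "URA3",
    "GCR_breakpoint_region",
    "PCM1",
    "ura3-52",
    "MCM3",
    "CEN5",
    "TEL_R",
)


@dataclass
class AssayLayout:
    """Parameters controlling assay chromosome construction.

    ``overrides`` maps a feature name to an explicit (start, length) pair,
    allowing tests to construct deliberately invalid layouts.
    """

    variant: str = "ugcr"
    length: int = _DESIGN_LENGTH
    seed: int = 0
    name: str = "uGCR_chrV"
    overrides: dict = field(default_factory=dict)


class LayoutError(ValueError):
    """Raised when a layout violates the assay topology."""


@dataclass
class AssayChromosome:
    """The model assay chromosome: sequence plus coordinate-anchored features."""

    name: str
    sequence: str
    features: list[Feature]
    variant: str = "ugcr"
    # groups of feature names whose tracts share sequence (multi-mapping)
    homology_families: tuple = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def feature_seq(self, name: str) -> str:
        f = self.feature(name)
        return self.sequence[f.start:f.end]

    def asci_sites(self) -> list[Feature]:
        return [f for f in self.features if f.name.startswith("AscI")]

    @property
    def cassette(self) -> Feature:
        """The combined CAN1/URA3 cassette interval."""
        return self.feature("CAN1_URA3_cassette")

    def probe_seq(self, name: str, width: int = 80) -> str:
        """Central ``width`` bases of a feature tract, used as a Southern probe."""
        f = self.feature(name)
        w = min(width, f.length)
        mid = (f.start + f.end) // 2
        return self.sequence[mid - w // 2: mid - w // 2 + w]

    def validate(self) -> None:
        n = self.length
        for f in self.features:
            if not (0 <= f.start < f.end <= n):
                raise LayoutError(f"feature {f.name} outside [0, {n})")
        names = [f.name for f in self.features]
        for req in REQUIRED_UNIQUE:
            if names.count(req) != 1:
                raise LayoutError(f"feature {req} must be present exactly once")
        if len(self.asci_sites()) < 2:
            raise LayoutError("at least two AscI sites are required")
        pos = {f.name: f.start for f in self.features}
        if pos["CAN1_URA3_cassette"] < pos["hph"]:
            raise LayoutError(
                "the CAN1/URA3 cassette must lie centromeric of hph; a cassette "
                "telomeric of hph cannot produce hph-retaining GCRs"
            )
        if self.variant == "ugcr":
            order = [pos[name] for name in UGCR_ORDER]
            if order != sorted(order):
                raise LayoutError(
                    "uGCR left-arm feature order must be "
                    "TEL_L < hph < CAN1/URA3 cassette < GCR breakpoint region "
                    "< PCM1 < ura3-52 < CEN5"
                )
        a1, a2 = self.asci_sites()[0], self.asci_sites()[1]
        hin = self.feature("hph_internal")
        if not (a1.end <= hin.start and hin.end <= a2.start):
            raise LayoutError(
                "an hph-homologous tract must lie between the two AscI sites so "
                "the internal AscI fragment carries hph homology"
            )
        if self.sequence.count(ASCI_MOTIF) != len(self.asci_sites()):
            raise LayoutError("AscI motif count does not match AscI features")
        for fam in self.homology_families:
            seqs = set()
            for name, strand in fam:
                s = self.feature_seq(name)
                seqs.add(s if strand == "+" else revcomp(s))
            if len(seqs) != 1:
                raise LayoutError(f"homology family {fam} tracts are not identical")


def _scaled_positions(layout: AssayLayout) -> list[tuple[str, int, int]]:
    sf = layout.length / _DESIGN_LENGTH
    design = list(_UGCR_DESIGN)
    if layout.variant == "dgcr":
        # dGCR assay: modelled as a labelled layout variant that adds the
        # HXT13-DSF1 segmental-duplication tract to the breakpoint region;
        # duplication-mediated rearrangement mechanics are not simulated.
        design.append(("HXT13_DSF1", 36_000, 4_200, 350))
    out = []
    for name, start, length, floor in design:
        if name in layout.overrides:
            s, ln = layout.overrides[name]
        else:
            s = int(round(start * sf))
            ln = max(int(round(length * sf)), floor)
            if name == "TEL_R":
                s = layout.length - ln
        out.append((name, s, ln))
    # keep the ura3-52 URA3 homolog exactly as long as the cassette URA3
    lens = {name: ln for name, _, ln in out}
    out = [
        (name, s, lens["URA3"] if name == "ura3-52_URA3" else ln)
        for name, s, ln in out
    ]
    return out


def build_assay_chromosome(layout: AssayLayout | None = None, **kwargs) -> AssayChromosome:
    """Construct the model assay chromosome.

    The sequence is pseudo-random at a fixed seed except for recognisable
    tracts: hph (duplicated into the internal AscI fragment), the cassette
    URA3 (planted in inverted orientation at ura3-52), the Ty consensus,
    AscI sites (GGCGCGCC) and TG1-3 telomere seeds.  Spurious AscI motifs
    arising by chance in the random background are scrubbed so that the
    motif count equals the number of AscI site features.
    """
    if layout is None:
        layout = AssayLayout(**kwargs)
    elif kwargs:
        layout = replace(layout, **kwargs)
    if layout.variant not in ("ugcr", "dgcr"):
        raise LayoutError(f"unknown assay variant {layout.variant!r}")
    if layout.length < MIN_LENGTH:
        raise LayoutError(f"chromosome length must be >= {MIN_LENGTH} bp")

    rng = np.random.default_rng(layout.seed)
    positions = _scaled_positions(layout)

    # sanity: tract intervals in bounds and non-overlapping before planting
    # (the GCR breakpoint region is an annotation, not a tract: dsb positions
    # and, in the dGCR variant, the HXT13-DSF1 tract fall inside it)
    intervals = sorted(
        (s, s + ln, name)
        for name, s, ln in positions
        if name != "GCR_breakpoint_region"
    )
    prev_end, prev_name = 0, None
    for s, e, name in intervals:
        if s < prev_end:
            raise LayoutError(f"features {prev_name} and {name} overlap at this scale")
        if e > layout.length:
            raise LayoutError(f"feature {name} extends past the chromosome end")
        prev_end, prev_name = e, name

    # chance AscI motifs in the background are scrubbed after planting
    seq = np.frombuffer(random_dna(rng, layout.length).encode(), dtype="S1").copy()

    def plant(start: int, tract: str) -> None:
        seq[start:start + len(tract)] = np.frombuffer(tract.encode(), dtype="S1")

    pos = {name: (s, s + ln) for name, s, ln in positions}
    ln = {name: e - s for name, (s, e) in pos.items()}

    hph_tract = _motif_free(rng, ln["hph"])
    ura3_tract = _motif_free(rng, ln["URA3"])
    can1_tract = _motif_free(rng, ln["CAN1"])
    pcm1_tract = _motif_free(rng, ln["PCM1"])
    mcm3_tract = _motif_free(rng, ln["MCM3"])
    cen5_tract = _motif_free(rng, ln["CEN5"])

    plant(pos["TEL_L"][0], tg_repeat_tract(rng, ln["TEL_L"])[: ln["TEL_L"]])
    plant(pos["TEL_R"][0], revcomp(tg_repeat_tract(rng, ln["TEL_R"])[: ln["TEL_R"]]))
    plant(pos["hph"][0], hph_tract)
    plant(pos["hph_internal"][0], hph_tract[: ln["hph_internal"]])
    plant(pos["CAN1"][0], can1_tract)
    plant(pos["URA3"][0], ura3_tract)
    plant(pos["ura3-52_URA3"][0], revcomp(ura3_tract))
    plant(pos["ura3-52_Ty"][0], TY_CONSENSUS[: ln["ura3-52_Ty"]])
    plant(pos["PCM1"][0], pcm1_tract)
    plant(pos["CEN5"][0], cen5_tract)
    plant(pos["MCM3"][0], mcm3_tract)
    if "HXT13_DSF1" in pos:
        plant(pos["HXT13_DSF1"][0], _motif_free(rng, ln["HXT13_DSF1"]))

    # scrub chance AscI motifs created at tract boundaries, then plant the
    # intended sites
    text = seq.tobytes().decode()
    intended = {pos["AscI_1"][0], pos["AscI_2"][0]}
    i = text.find(ASCI_MOTIF)
    while i != -1:
        if i not in intended:
            seq[i + 3] = b"T"
            text = seq.tobytes().decode()
            i = text.find(ASCI_MOTIF)
        else:
            i = text.find(ASCI_MOTIF, i + 1)
    plant(pos["AscI_1"][0], ASCI_MOTIF)
    plant(pos["AscI_2"][0], ASCI_MOTIF)

    features = [Feature(name, s, e) for name, (s, e) in pos.items()]
    features.append(
        Feature("CAN1_URA3_cassette", pos["URA3"][0], pos["CAN1"][1])
    )
    features.append(
        Feature("ura3-52", pos["ura3-52_URA3"][0], pos["ura3-52_Ty"][1])
    )
    features.sort(key=lambda f: (f.start, f.end))

    chrom = AssayChromosome(
        name=layout.name,
        sequence=seq.tobytes().decode(),
        features=features,
        variant=layout.variant,
        homology_families=(
            (("hph", "+"), ("hph_internal", "+")),
            (("URA3", "+"), ("ura3-52_URA3", "-")),
        ),
    )
    chrom.validate()
    return chrom
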