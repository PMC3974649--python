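"""Integration of junction, copy-number, marker and PFGE evidence.

The in-silico AscI digest mirrors the pulsed-field gel logic of the
assay: the unrearranged chromosome cuts into a left telomeric fragment
(hybridising to the hph probe), an internal fragment (hph and MCM3
probes — the internal AscI fragment carries an hph-homologous tract), and
a right telomeric fragment (neither).  Inverted duplications enlarge the
internal fragment; interstitial deletions leave the chromosome within the
gel's size-resolution band.

Classification decision rules (junction evidence, being base-resolution,
takes precedence over copy-number evidence on conflict):

* >1 independent repeat-bounded duplication          -> complex
* fold-back junction, or duplication anchored in the
  breakpoint region together with a larger chromosome -> inverted_duplication
* telomere-addition junction                          -> de_novo_telomere
* deletion junction, no duplication, similar size     -> interstitial_deletion
* cross-locus junction                                -> translocation
* contradictory evidence                              -> unclassified (with notes)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import BreakpointAnnotation, FoldbackAnnotation, TelomereCall
from .chromosome import ASCI_MOTIF, AssayChromosome
from .copynumber import ChrVLArchitecture
from .rearrange import SIZE_TOLERANCE

GCR_CLASSES = (
    "interstitial_deletion",
    "inverted_duplication",
    "de_novo_telomere",
    "translocation",
    "complex",
    "unclassified",
)


@dataclass
class PFGEFragment:
    start: int
    end: int
    probes: frozenset  # subset of {"hph", "MCM3"}

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PFGEDigest:
    fragments: list[PFGEFragment]
    size_class: str  # 'similar' | 'larger' | 'smaller'
    total_length: int


@dataclass
class GCRClassification:
    isolate: str
    gcr_class: str
    hph_retained: bool
    chrvl_duplication: bool
    resolution_homology: str | None
    notes: str = ""

    def __post_init__(self):
        if self.gcr_class == "inverted_duplication" and not self.chrvl_duplication:
            raise ValueError("an inverted duplication implies a chrV L duplication")


@dataclass
class IsolateEvidence:
    """Evidence bundle for one isolate."""

    isolate: str
    junctions: list[tuple[BreakpointAnnotation, FoldbackAnnotation | None, TelomereCall | None]] = field(default_factory=list)
    architecture: ChrVLArchitecture | None = None
    digest: PFGEDigest | None = None
    hph_present: bool = True


def insilico_pfge(
    sequence: str,
    reference: AssayChromosome,
    enzyme_motif: str = ASCI_MOTIF,
    size_tolerance: float = SIZE_TOLERANCE,
) -> PFGEDigest:
    """Digest a chromosome at every enzyme motif and probe the fragments.

    Probe hybridisation is boolean per fragment: a fragment lights up for
    a probe iff it contains the probe tract sequence.  The chromosome size
    class compares total length with the unrearranged reference within a
    gel-resolution band (+/-2% by default).
    """
    cuts = []
    i = sequence.find(enzyme_motif)
    while i != -1:
        cuts.append(i)
        i = sequence.find(enzyme_motif, i + 1)
    bounds = [0] + cuts + [len(sequence)]
    if not cuts:
        import logging

        logging.getLogger(__name__).warning(
            "no %s cut sites: single-fragment digest", enzyme_motif
        )
    probes = {
        "hph": reference.probe_seq("hph"),
        "MCM3": reference.probe_seq("MCM3"),
    }
    fragments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a == b:
            continue
        frag = sequence[a:b]
        hits = frozenset(name for name, p in probes.items() if p in frag)
        fragments.append(PFGEFragment(a, b, hits))
    delta = len(sequence) - reference.length
    if abs(delta) <= size_tolerance * reference.length:
        size_class = "similar"
    else:
        size_class = "larger" if delta > 0 else "smaller"
    return PFGEDigest(fragments=fragments, size_class=size_class, total_length=len(sequence))


def _resolution_from_evidence(
    evidence: IsolateEvidence,
) -> str | None:
    """Resolution homology: architecture boundary, else junction features."""
    if evidence.architecture and evidence.architecture.boundary_feature:
        return evidence.architecture.boundary_feature
    for ann, _fb, _tel in evidence.junctions:
        for side in (ann.side_a, ann.side_b):
            if side is None:
                continue
            names = set(side.features)
            if {"URA3", "ura3-52_URA3", "ura3-52"} & names:
                return "ura3-52"
            if "ura3-52_Ty" in names:
                return "Ty"
    return None


def classify_gcr(evidence: IsolateEvidence) -> GCRClassification:
    """Integrate junction, copy-number, size and marker evidence."""
    if not (evidence.junctions or evidence.architecture or evidence.digest):
        raise ValueError("at least one evidence source is required")
    arch = evidence.architecture
    digest = evidence.digest
    jclasses = {ann.junction_class for ann, _fb, _tel in evidence.junctions}
    notes: list[str] = []
    if arch:
        notes.extend(arch.warnings)

    has_dup = arch is not None and arch.duplication_extent is not None
    dup_anchored = has_dup and not any(
        "breakpoint region" in w for w in (arch.warnings if arch else [])
    )
    larger = digest is not None and digest.size_class == "larger"
    similar = digest is not None and digest.size_class == "similar"

    def result(klass, resolution=None, extra=""):
        if extra:
            notes.append(extra)
        return GCRClassification(
            isolate=evidence.isolate,
            gcr_class=klass,
            hph_retained=evidence.hph_present,
            chrvl_duplication=has_dup or klass == "inverted_duplication",
            resolution_homology=resolution,
            notes="; ".join(notes),
        )

    if arch is not None and arch.n_duplications > 1:
        return result("complex", _resolution_from_evidence(evidence),
                      "multiple independent repeat-bounded duplications")

    foldback = "inversion_foldback" in jclasses
    if foldback or (dup_anchored and larger):
        if has_dup and similar:
            return result(
                "unclassified", None,
                "conflict: chrV L duplication with a wild-type-sized chromosome",
            )
        return result("inverted_duplication", _resolution_from_evidence(evidence))

    if has_dup and similar:
        return result(
            "unclassified", None,
            "conflict: chrV L duplication with a wild-type-sized chromosome",
        )

    if "telomere_addition" in jclasses:
        return result("de_novo_telomere")

    if "deletion" in jclasses:
        if has_dup or larger:
            return result(
                "unclassified", None,
                "conflict: deletion junction with duplication/size evidence",
            )
        return result("interstitial_deletion")

    if "translocation" in jclasses:
        return result("translocation")

    # copy-number-only evidence
    if dup_anchored and larger:
        return result("inverted_duplication", _resolution_from_evidence(evidence))
    if arch is not None and arch.deletion_extent is not None and not has_dup and (
        digest is None or similar
    ):
        if evidence.hph_present:
            return result("interstitial_deletion")
        if not arch.telomeric_retention:
            return result("unclassified", None, "terminal loss without junction evidence")
    return result("unclassified", None, "insufficient or conflicting evidence")


def percent_retained(retaining: int, total: int) -> float:
    """Retention percentage in reporting convention.

    Integer percent when at least 1%, one decimal when between 0 and 1%
    exclusive (e.g. 15 of 2435 -> 0.6).
    """
    p = 100.0 * retaining / total
    if p == 0 or p >= 1:
        return float(round(p))
    return round(p, 1)


@dataclass
class RetentionRow:
    genotype: str
    retaining: int
    total: int

    @property
    def percent(self) -> float:
        return percent_retained(self.retaining, self.total)


def tabulate_retention(
    classifications_by_genotype: dict[str, list[GCRClassification]]
) -> pd.DataFrame:
    """Per-genotype hph-retention counts and percentages."""
    import logging

    rows = []
    for genotype, classes in classifications_by_genotype.items():
        if not classes:
            logging.getLogger(__name__).warning(
                "genotype %s has no isolates: row omitted", genotype
            )
            continue
        retaining = sum(1 for c in classes if c.hph_retained)
        total = len(classes)
        rows.append(
            (genotype, retaining, total, percent_retained(retaining, total))
        )
    return pd.DataFrame(rows, columns=["genotype", "retaining", "total", "percent"])


def tabulate_duplication_by_hph(
    classifications_by_genotype: dict[str, list[GCRClassification]]
) -> pd.DataFrame:
    """Two-way table: chrV L duplication status x hph retention per genotype."""
    rows = []
    for genotype, classes in classifications_by_genotype.items():
        if not classes:
            continue
        dup = [c for c in classes if c.chrvl_duplication]
        nodup = [c for c in classes if not c.chrvl_duplication]
        rows.append(
            (
                genotype,
                len(classes),
                len(dup),
                sum(1 for c in dup if c.hph_retained),
                sum(1 for c in dup if not c.hph_retained),
                len(nodup),
                sum(1 for c in nodup if c.hph_retained),
                sum(1 for c in nodup if not c.hph_retained),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genotype", "isolates",
            "dup_total", "dup_hph_plus", "dup_hph_minus",
            "nodup_total", "nodup_hph_plus", "nodup_hph_minus",
        ],
    )
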