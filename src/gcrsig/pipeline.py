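"""Cohort orchestration: simulate -> call -> annotate -> copy number ->
classify -> summary tables, reproducibly under a single global seed.

A single global seed fans out to per-isolate, per-stage seeds through a
counter scheme, so any isolate/stage can be re-run independently with the
same stream.  Outputs land in a config-hash-named directory (no
timestamps), making re-runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as gio
from .annotate import annotate_junction
from .arrays import MLPA_NEUTRAL_PROBES, simulate_acgh, simulate_mlpa
from .caller import (
    assemble_junction_consensus,
    cluster_junction_pairs,
    deduplicate_pairs,
    estimate_insert_stats,
    pairs_from_simulation,
    recruit_junction_reads,
)
from .chromosome import AssayChromosome, AssayLayout, build_assay_chromosome, revcomp
from .classify import (
    GCRClassification,
    IsolateEvidence,
    classify_gcr,
    insilico_pfge,
    tabulate_duplication_by_hph,
    tabulate_retention,
)
from .copynumber import analyze_mlpa, interpret_chrvl_architecture, segment_log2_track
from .rearrange import (
    Rearrangement,
    apply_de_novo_telomere,
    apply_interstitial_deletion,
    apply_inverted_duplication,
    apply_translocation,
    unrearranged,
)
from .reads import LibraryModel, simulate_read_pairs

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

# observed parameter ranges for drawn events: junction microhomology 0-5 bp,
# hairpin loops 25-44 nt, priming homologies 3-9 bp
DELETION_MH_RANGE = (0, 5)
LOOP_RANGE = (25, 44)
PRIMING_RANGE = (3, 9)


@dataclass
class RunConfig:
    assay: str = "ugcr"
    length: int = 50_000
    seed: int = 0
    events: list = field(default_factory=list)  # [{"event":..., "count":..., ...}]
    library: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    acgh: dict = field(default_factory=dict)
    mlpa: dict = field(default_factory=dict)
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def digest(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stage_seed(global_seed: int, isolate_index: int, stage: int) -> int:
    """Deterministic per-isolate per-stage seed below 2**31."""
    return (global_seed * 1_000_003 + isolate_index * 101 + stage) % (2**31 - 1)


# ---------------------------------------------------------------------------
# event drawing

def draw_event(
    chrom: AssayChromosome, spec: dict, rng: np.random.Generator, name: str
) -> Rearrangement:
    """Construct one truth-labelled isolate from an event specification.

    Unspecified parameters are drawn from the observed assay ranges
    (microhomology 0-5, loop 25-44, priming homology 3-9).
    """
    event = spec["event"]
    cassette = chrom.cassette
    bpr = chrom.feature("GCR_breakpoint_region")
    hph = chrom.feature("hph")
    if event == "none":
        return unrearranged(chrom, name=name)
    if event == "interstitial_deletion":
        lo = max(hph.end + 50, cassette.start - max(2_000, cassette.length))
        start = spec.get("start", int(rng.integers(lo, cassette.start)))
        end = spec.get("end", int(rng.integers(cassette.end + 100, bpr.end - 100)))
        mh = spec.get(
            "microhomology", int(rng.integers(DELETION_MH_RANGE[0], DELETION_MH_RANGE[1] + 1))
        )
        return apply_interstitial_deletion(
            chrom, start, end, microhomology=mh, insert=spec.get("insert", ""), name=name
        )
    if event == "inverted_duplication":
        dsb = spec.get("dsb", int(rng.integers(bpr.start, bpr.end - 200)))
        loop = spec.get("loop", int(rng.integers(LOOP_RANGE[0], LOOP_RANGE[1] + 1)))
        prime = spec.get(
            "priming_homology", int(rng.integers(PRIMING_RANGE[0], PRIMING_RANGE[1] + 1))
        )
        return apply_inverted_duplication(
            chrom, dsb, loop=loop, priming_homology=prime,
            resolution=spec.get("resolution", "ura3-52"),
            name=name, seed=int(rng.integers(2**31 - 1)),
        )
    if event == "de_novo_telomere":
        pos = spec.get("pos", int(rng.integers(bpr.start, bpr.end)))
        reps = spec.get("seed_repeats", int(rng.integers(100, 200)))
        return apply_de_novo_telomere(
            chrom, pos, seed_repeats=reps, name=name, seed=int(rng.integers(2**31 - 1))
        )
    if event == "translocation":
        pos = spec.get("pos", int(rng.integers(bpr.start, bpr.end)))
        cen = chrom.feature("CEN5")
        dlen = spec.get("donor_length", int(rng.integers(2_000, 4_000)))
        da = spec.get(
            "donor_start", int(rng.integers(cen.end + 1_000, chrom.length - dlen - 2_000))
        )
        donor = revcomp(chrom.sequence[da: da + dlen])
        return apply_translocation(chrom, pos, donor, donor_map=(da, -1), name=name)
    raise ValueError(f"unknown event class {event!r}")


def draw_cohort(chrom: AssayChromosome, config: RunConfig) -> list[tuple[str, Rearrangement]]:
    """All isolates of the configured event mix: (genotype, rearrangement)."""
    out = []
    idx = 0
    for spec in config.events:
        genotype = spec.get("genotype", "cohort")
        for _ in range(int(spec.get("count", 1))):
            rng = np.random.default_rng(stage_seed(config.seed, idx, 0))
            name = spec.get("name", f"iso{idx:03d}")
            if "name" not in spec:
                name = f"iso{idx:03d}"
            out.append((genotype, draw_event(chrom, spec, rng, name)))
            idx += 1
    return out


# ---------------------------------------------------------------------------
# per-isolate analysis

@dataclass
class IsolateResult:
    name: str
    genotype: str
    rearrangement: Rearrangement
    calls: list
    annotations: list  # (annotation, foldback, telomere) per significant call
    architecture: object
    mlpa: object
    digest: object
    classification: GCRClassification
    insert_stats: object


def analyze_isolate(
    rearr: Rearrangement,
    config: RunConfig,
    isolate_index: int,
    genotype: str = "cohort",
    control_mlpa=None,
) -> IsolateResult:
    """Run the full per-isolate pipeline in memory."""
    chrom = rearr.reference
    lib = LibraryModel(
        seed=stage_seed(config.seed, isolate_index, 1), **config.library
    )
    sim = simulate_read_pairs(rearr, lib)
    pairs = deduplicate_pairs(pairs_from_simulation(sim))
    stats = estimate_insert_stats(pairs, **config.caller.get("insert", {}))
    calls = cluster_junction_pairs(
        pairs,
        stats,
        min_support=config.caller.get("min_support", 3),
        min_support_foldback=config.caller.get("min_support_foldback", 2),
        alpha=config.caller.get("alpha", 0.01),
        target_lengths={chrom.name: chrom.length},
    )
    sig = [c for c in calls if c.significant]
    annotations = []
    for call in sig:
        reads = recruit_junction_reads(call, pairs, stats)
        if not reads:
            continue
        cons = assemble_junction_consensus(reads)
        annotations.append(annotate_junction(cons, chrom))

    acgh_track = simulate_acgh(
        rearr,
        probe_spacing=config.acgh.get("probe_spacing", 200),
        noise_sd=config.acgh.get("noise_sd", 0.1),
        seed=stage_seed(config.seed, isolate_index, 2),
    )
    segments = segment_log2_track(acgh_track)
    architecture = interpret_chrvl_architecture(segments, chrom)

    noise_cv = config.mlpa.get("noise_cv", 0.05)
    if control_mlpa is None:
        control_mlpa = simulate_mlpa(
            unrearranged(chrom), noise_cv=noise_cv,
            seed=stage_seed(config.seed, isolate_index, 3),
        )
    sample_mlpa = simulate_mlpa(
        rearr, noise_cv=noise_cv, seed=stage_seed(config.seed, isolate_index, 4)
    )
    mlpa_result = analyze_mlpa(
        sample_mlpa, control_mlpa, reference_probes=list(MLPA_NEUTRAL_PROBES)
    )

    digest = insilico_pfge(rearr.sequence, chrom)
    evidence = IsolateEvidence(
        isolate=rearr.name,
        junctions=annotations,
        architecture=architecture,
        digest=digest,
        hph_present=rearr.hph_present(),
    )
    classification = classify_gcr(evidence)
    return IsolateResult(
        name=rearr.name,
        genotype=genotype,
        rearrangement=rearr,
        calls=sig,
        annotations=annotations,
        architecture=architecture,
        mlpa=mlpa_result,
        digest=digest,
        classification=classification,
        insert_stats=stats,
    )


def benchmark_cohort_events() -> list[dict]:
    """The benchmark event mix: five isolates per mechanism class.

    Inverted duplications cover all three resolution modes (URA3/ura3-52,
    Ty, none); drawn parameters follow the observed assay ranges.
    """
    return [
        {"event": "interstitial_deletion", "count": 5, "genotype": "deletion"},
        {"event": "inverted_duplication", "count": 3, "genotype": "invdup"},
        {"event": "inverted_duplication", "count": 1, "resolution": "ty", "genotype": "invdup"},
        {"event": "inverted_duplication", "count": 1, "resolution": "none", "genotype": "invdup"},
        {"event": "de_novo_telomere", "count": 5, "genotype": "telomere"},
        {"event": "translocation", "count": 5, "genotype": "translocation"},
    ]


def truth_recovery(result: "IsolateResult") -> dict:
    """Compare a pipeline result against its construction truth.

    Returns whether the classification matches the truth class, whether
    some annotated junction reproduces the truth breakpoints to the base,
    and (fold-backs only) whether the hairpin loop and priming homology
    were recovered exactly.
    """
    truth = result.rearrangement.truth
    class_correct = result.classification.gcr_class == truth.event_class
    want = set(truth.breakpoints)
    breakpoints_exact = False
    foldback_exact = None
    for ann, fb, tel in result.annotations:
        if truth.event_class == "de_novo_telomere":
            if tel is not None and tel.seed_coord == truth.breakpoints[0]:
                breakpoints_exact = True
        elif truth.event_class == "inverted_duplication":
            if fb is not None and set(fb.breakpoints) == want:
                breakpoints_exact = True
                foldback_exact = (fb.loop, fb.priming_homology) == (
                    truth.loop, truth.priming_homology,
                )
        else:
            coords = {
                s.coord for s in (ann.side_a, ann.side_b) if s is not None
            }
            if coords == want:
                breakpoints_exact = True
    if truth.event_class == "inverted_duplication" and foldback_exact is None:
        foldback_exact = False
    return {
        "class_correct": class_correct,
        "breakpoints_exact": breakpoints_exact,
        "foldback_exact": foldback_exact,
    }


# ---------------------------------------------------------------------------
# cohort run

@dataclass
class CohortReport:
    config: RunConfig
    isolates: list[IsolateResult]
    retention: object  # DataFrame
    duplication_by_hph: object  # DataFrame
    out_dir: str | None = None


def run_cohort(config: RunConfig) -> CohortReport:
    """Simulate and analyse a full cohort; write summary outputs if configured.

    Identical configuration (hence identical manifest) yields identical
    outputs.
    """
    chrom = build_assay_chromosome(
        AssayLayout(variant=config.assay, length=config.length, seed=config.seed)
    )
    isolates = draw_cohort(chrom, config)
    results: list[IsolateResult] = []
    for idx, (genotype, rearr) in enumerate(isolates):
        try:
            results.append(analyze_isolate(rearr, config, idx, genotype=genotype))
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(
                f"cohort analysis failed at isolate {rearr.name} ({genotype}): {exc}"
            ) from exc

    by_genotype: dict[str, list[GCRClassification]] = {}
    for r in results:
        by_genotype.setdefault(r.genotype, []).append(r.classification)
    retention = tabulate_retention(by_genotype)
    dup_table = tabulate_duplication_by_hph(by_genotype)

    out_dir = None
    if config.out_dir:
        out_dir = os.path.join(config.out_dir, f"run-{config.digest()}")
        os.makedirs(out_dir, exist_ok=True)
        retention.to_csv(os.path.join(out_dir, "retention.tsv"), sep="\t", index=False)
        dup_table.to_csv(
            os.path.join(out_dir, "duplication_by_hph.tsv"), sep="\t", index=False
        )
        per_isolate = [
            {
                "isolate": r.name,
                "genotype": r.genotype,
                "truth": r.rearrangement.truth,
                "classification": r.classification,
                "n_significant_calls": len(r.calls),
                "pfge_size_class": r.digest.size_class,
                "mlpa_amplified": list(r.mlpa.amplified),
            }
            for r in results
        ]
        gio.write_json(os.path.join(out_dir, "isolates.json"), per_isolate)
        gio.write_json(
            os.path.join(out_dir, "manifest.json"),
            {
                "version": __version__,
                "config": config.to_dict(),
                "config_digest": config.digest(),
                "seed": config.seed,
                "n_isolates": len(results),
            },
        )
        logger.info("cohort outputs written to %s", out_dir)
    return CohortReport(
        config=config,
        isolates=results,
        retention=retention,
        duplication_by_hph=dup_table,
        out_dir=out_dir,
    )
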