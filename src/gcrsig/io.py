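"""File formats: FASTA, BED, bedGraph, CSV/TSV, VCF breakends, JSON.

Coordinates are 0-based half-open in BED/bedGraph; VCF positions are
1-based per the standard.
"""

from __future__ import annotations

import dataclasses
import json

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import BreakpointAnnotation
from .caller import JunctionCall
from .chromosome import AssayChromosome, Feature


def write_fasta(path: str, name: str, sequence: str, description: str = "") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description=description)], path, "fasta")


def read_fasta(path: str) -> tuple[str, str]:
    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, str(rec.seq)


def write_features_bed(path: str, chrom: AssayChromosome) -> None:
    with open(path, "w") as f:
        for feat in chrom.features:
            f.write(
                f"{chrom.name}\t{feat.start}\t{feat.end}\t{feat.name}\t0\t{feat.strand}\n"
            )


def read_assay_chromosome(fasta_path: str, bed_path: str) -> AssayChromosome:
    """Reassemble an assay chromosome from its FASTA + feature BED."""
    name, seq = read_fasta(fasta_path)
    features = []
    with open(bed_path) as f:
        for line in f:
            parts = line.rstrip("\n").split("\t")
            features.append(Feature(parts[3], int(parts[1]), int(parts[2]), parts[5]))
    names = {f.name for f in features}
    families = []
    if {"hph", "hph_internal"} <= names:
        families.append((("hph", "+"), ("hph_internal", "+")))
    if {"URA3", "ura3-52_URA3"} <= names:
        families.append((("URA3", "+"), ("ura3-52_URA3", "-")))
    return AssayChromosome(
        name=name, sequence=seq, features=features,
        homology_families=tuple(families),
    )


def write_bedgraph(path: str, track: pd.DataFrame) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "log2"]
    )


def write_mlpa_csv(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_mlpa_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_calls_tsv(path: str, calls: list[JunctionCall]) -> None:
    rows = []
    for i, c in enumerate(calls):
        rows.append(
            {
                "call_id": f"jct{i:03d}",
                "geometry": c.geometry,
                "target_a": c.side_a.target,
                "interval_a": f"{c.side_a.interval[0]}-{c.side_a.interval[1]}",
                "orient_a": c.side_a.orient,
                "target_b": c.side_b.target if c.side_b else ".",
                "interval_b": (
                    f"{c.side_b.interval[0]}-{c.side_b.interval[1]}" if c.side_b else "."
                ),
                "orient_b": c.side_b.orient if c.side_b else ".",
                "support": c.support,
                "p_value": f"{c.p_value:.3g}",
                "significant": int(c.significant),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_breakend_vcf(
    path: str, annotations: list[BreakpointAnnotation], reference: AssayChromosome
) -> None:
    """Junction annotations as paired VCF breakend (BND) records."""
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##contig=<ID={reference.name},length={reference.length}>\n")
        f.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        f.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        f.write('##INFO=<ID=JCLASS,Number=1,Type=String,Description="Junction class">\n')
        f.write('##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">\n')
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, ann in enumerate(annotations):
            if ann.side_a is None or ann.side_b is None:
                continue
            for k, (side, mate) in enumerate(
                ((ann.side_a, ann.side_b), (ann.side_b, ann.side_a))
            ):
                pos = max(side.coord, 1)
                ref_base = reference.sequence[pos - 1]
                bracket = "]" if mate.strand == "-" else "["
                alt = (
                    f"{ref_base}{bracket}{mate.target}:{max(mate.coord, 1)}{bracket}"
                    if k == 0
                    else f"{bracket}{mate.target}:{max(mate.coord, 1)}{bracket}{ref_base}"
                )
                f.write(
                    f"{side.target}\t{pos}\tbnd_{i}_{k}\t{ref_base}\t{alt}\t.\tPASS\t"
                    f"SVTYPE=BND;MATEID=bnd_{i}_{1 - k};JCLASS={ann.junction_class};"
                    f"HOMLEN={ann.microhomology}\n"
                )


def write_annotations_tsv(path: str, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(path: str, obj) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {
                k: v
                for k, v in dataclasses.asdict(o).items()
                if not k.startswith("_")
            }
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        return str(o)

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=default)
        f.write("\n")
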