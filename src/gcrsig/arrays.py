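"""Simulation of aCGH log2-ratio tracks and MLPA peak-area tables.

aCGH: one probe per reference window, reporting log2(copy number) of the
rearranged genome relative to the haploid reference, with Gaussian probe
noise.  Windows covering the hph insertions (non-reference sequence in the
real strain) are not probed.  Deleted windows report a configurable floor.

MLPA: a panel of probes targeting single-copy chrV L gene loci whose
amplification products form a 6 bp ladder; each peak area is proportional
to locus copy number with multiplicative Gaussian noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chromosome import AssayChromosome
from .rearrange import Rearrangement

ACGH_FLOOR = -4.0
MLPA_GENES = ("EAF5", "YEA6", "VMA8", "BUD16", "GEA2", "IRC22", "MNN1", "PCM1")
# copy-neutral under the assayed mechanisms (outside inverted-duplication
# extents); used as the default normalisation reference
MLPA_NEUTRAL_PROBES = ("EAF5", "YEA6", "IRC22", "MNN1")
MLPA_BASE_LENGTH = 100
MLPA_STEP = 6
MLPA_BASELINE_AREA = 1000.0


def _unprobed_intervals(reference: AssayChromosome) -> list[tuple[int, int]]:
    """Intervals without aCGH probes: the hph and can1::hisG insertions."""
    out = []
    for name in ("hph", "hph_internal", "CAN1"):
        f = reference.feature(name)
        out.append((f.start, f.end))
    return out


def simulate_acgh(
    rearr: Rearrangement,
    probe_spacing: int = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
    floor: float = ACGH_FLOOR,
) -> pd.DataFrame:
    """Probe log2-ratio track for a rearranged genome vs its reference.

    Returns a coordinate-sorted DataFrame with columns ``chrom``,
    ``start``, ``end``, ``log2`` (bedGraph column order).  The probe value
    is log2 of the copy number at the window midpoint (floor for copy 0),
    plus Gaussian noise for probed copies.
    """
    if probe_spacing < 50:
        raise ValueError("probe spacing must be at least 50 bp")
    ref = rearr.reference
    rng = np.random.default_rng(seed)
    cn = rearr.copy_number()
    skip = _unprobed_intervals(ref)

    rows = []
    for start in range(0, ref.length - probe_spacing + 1, probe_spacing):
        end = start + probe_spacing
        if any(lo < end and start < hi for lo, hi in skip):
            continue
        c = int(cn[(start + end) // 2])
        if c == 0:
            value = floor
        else:
            value = np.log2(c) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append((ref.name, start, end, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2"])


def default_mlpa_probes(reference: AssayChromosome) -> pd.DataFrame:
    """The chrV L MLPA panel: one probe per gene locus, 6 bp product ladder.

    Probes are ordered telomere-to-centromere; product lengths form an
    arithmetic sequence with common difference 6 bp.
    """
    genes = sorted(MLPA_GENES, key=lambda n: reference.feature(n).start)
    rows = []
    for i, name in enumerate(genes):
        f = reference.feature(name)
        rows.append(
            (name, (f.start + f.end) // 2, MLPA_BASE_LENGTH + MLPA_STEP * i)
        )
    return pd.DataFrame(rows, columns=["probe", "target_start", "product_length"])


def simulate_mlpa(
    rearr: Rearrangement,
    probe_set: pd.DataFrame | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """MLPA peak-area table for a rearranged genome.

    Peak area is ``baseline * copy_number * (1 + N(0, noise_cv))``; probes
    whose target is absent give (near-)zero area.
    """
    ref = rearr.reference
    if probe_set is None:
        probe_set = default_mlpa_probes(ref)
    lengths = probe_set["product_length"].to_numpy()
    if len(lengths) > 1 and not np.all(np.diff(lengths) == MLPA_STEP):
        raise ValueError("probe product lengths must increase in 6 bp steps")
    ambiguous = [
        (ref.feature(name).start, ref.feature(name).end)
        for fam in ref.homology_families
        for name, _ in fam
    ]
    for t in probe_set["target_start"]:
        if any(lo <= t < hi for lo, hi in ambiguous):
            raise ValueError(f"MLPA probe target {t} lies in a multi-copy tract")

    rng = np.random.default_rng(seed)
    cn = rearr.copy_number()
    areas = []
    for t in probe_set["target_start"]:
        c = int(cn[int(t)])
        noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        areas.append(max(MLPA_BASELINE_AREA * c * (1.0 + noise), 0.0))
    out = probe_set.copy()
    out["peak_area"] = areas
    return out
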