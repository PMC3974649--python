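"""Copy-number calling from aCGH log2 tracks and MLPA peak tables.

Haploid copy-number semantics: a duplication is 2 copies (log2 +1) and a
deletion is 0 copies (track floor).  Probe classification thresholds sit
midway between states under noise (duplicated >= +0.58, deleted <= -1.0);
the guide lines drawn at +/-1 in array figures correspond to 2-fold
changes.  Runs shorter than ``min_probes`` are absorbed into their
neighbours, and segment boundaries are placed at the midpoint between the
last probe of one state and the first probe of the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromosome import AssayChromosome

DUP_THRESHOLD = 0.58
DEL_THRESHOLD = -1.0
MIN_PROBES = 3
MLPA_AMP_THRESHOLD = 1.5
MLPA_DEL_THRESHOLD = 0.3

STATES = ("deleted", "neutral", "duplicated")


@dataclass
class CopySegment:
    start: int
    end: int
    state: str
    mean_log2: float
    probe_count: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ChrVLArchitecture:
    deletion_extent: tuple[int, int] | None
    duplication_extent: tuple[int, int] | None
    boundary_feature: str | None  # repeat bounding the duplication centromerically
    telomeric_retention: bool  # hph-side territory retained
    n_duplications: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class MLPAResult:
    ratios: dict[str, float]
    amplified: tuple[str, ...]
    deleted: tuple[str, ...]
    normalization: float


def segment_log2_track(
    track: pd.DataFrame,
    dup_threshold: float = DUP_THRESHOLD,
    del_threshold: float = DEL_THRESHOLD,
    min_probes: int = MIN_PROBES,
) -> list[CopySegment]:
    """Threshold-classify probes and merge them into copy-state segments."""
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    values = track["log2"].to_numpy(dtype=float)
    if len(starts) == 0:
        return []
    if not np.all(np.diff(starts) > 0):
        raise ValueError("probes must be coordinate-sorted")

    states = np.where(
        values >= dup_threshold, 2, np.where(values <= del_threshold, 0, 1)
    )

    # run-length encode
    runs: list[list] = []  # [state, first_idx, last_idx]
    for i, s in enumerate(states):
        if runs and runs[-1][0] == s:
            runs[-1][2] = i
        else:
            runs.append([int(s), i, i])

    # absorb short runs (shortest first) into the neighbour whose mean
    # log2 level is closer; ties go to the longer neighbour
    def run_len(r):
        return r[2] - r[1] + 1

    def run_mean(r):
        return float(values[r[1]: r[2] + 1].mean())

    while len(runs) > 1:
        short = min(
            (r for r in runs if run_len(r) < min_probes),
            key=run_len,
            default=None,
        )
        if short is None:
            break
        i = runs.index(short)
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            d_left = abs(run_mean(short) - run_mean(left))
            d_right = abs(run_mean(short) - run_mean(right))
            if d_left < d_right:
                target = left
            elif d_right < d_left:
                target = right
            else:
                target = left if run_len(left) >= run_len(right) else right
        target[1] = min(target[1], short[1])
        target[2] = max(target[2], short[2])
        runs.pop(i)
        # merge neighbours that now share a state
        j = 0
        while j + 1 < len(runs):
            if runs[j][0] == runs[j + 1][0]:
                runs[j][2] = runs[j + 1][2]
                runs.pop(j + 1)
            else:
                j += 1

    segments = []
    for k, (s, i0, i1) in enumerate(runs):
        seg_start = (
            int(starts[i0])
            if k == 0
            else int((ends[runs[k - 1][2]] + starts[i0]) // 2)
        )
        seg_end = (
            int(ends[i1])
            if k == len(runs) - 1
            else int((ends[i1] + starts[runs[k + 1][1]]) // 2)
        )
        segments.append(
            CopySegment(
                start=seg_start,
                end=seg_end,
                state=STATES[s],
                mean_log2=float(values[i0: i1 + 1].mean()),
                probe_count=i1 - i0 + 1,
            )
        )
    return segments


def interpret_chrvl_architecture(
    segments: list[CopySegment], reference: AssayChromosome
) -> ChrVLArchitecture:
    """Map copy-state segments onto the chrV L feature map.

    Reports the deletion/duplication extents, which repetitive feature
    (ura3-52 vs the Ty tract vs none) bounds the duplication on its
    centromeric side, and whether the hph-side telomeric territory is
    retained (neutral or duplicated rather than deleted).
    """
    warnings: list[str] = []
    cen = reference.feature("CEN5")
    left_arm = [s for s in segments if s.start < cen.start]
    deletions = [s for s in left_arm if s.state == "deleted"]
    duplications = [s for s in left_arm if s.state == "duplicated"]

    deletion_extent = (deletions[0].start, deletions[0].end) if deletions else None
    duplication_extent = (
        (duplications[0].start, duplications[0].end) if duplications else None
    )

    # probe resolution: boundary placement is uncertain to about one
    # probe spacing, so feature anchoring checks get that much slack
    spacing = float(
        np.median([(s.end - s.start) / max(s.probe_count, 1) for s in segments])
    )
    slack = max(spacing, 50.0)

    boundary = None
    if duplication_extent is not None:
        bpr = reference.feature("GCR_breakpoint_region")
        if not (bpr.start - slack <= duplication_extent[0] <= bpr.end + slack):
            warnings.append(
                "duplication does not start in the GCR breakpoint region"
            )
        end = duplication_extent[1]
        u5 = reference.feature("ura3-52_URA3")
        ty = reference.feature("ura3-52_Ty")
        if abs(end - u5.start) <= slack:
            boundary = "ura3-52"
        elif ty.start - slack // 2 <= end <= ty.end + slack // 2:
            boundary = "Ty"
        else:
            boundary = None
            warnings.append("duplication is not bounded by a known repeat")

    # hph territory proxy: probes between TEL_L and the cassette (the hph
    # tract itself carries no probes)
    tel = reference.feature("TEL_L")
    hph = reference.feature("hph")
    probe_pos = (tel.end + hph.start) // 2
    retention = True
    for s in segments:
        if s.start <= probe_pos < s.end:
            retention = s.state != "deleted"
            break

    return ChrVLArchitecture(
        deletion_extent=deletion_extent,
        duplication_extent=duplication_extent,
        boundary_feature=boundary,
        telomeric_retention=retention,
        n_duplications=len(duplications),
        warnings=warnings,
    )


def analyze_mlpa(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    reference_probes: list[str] | None = None,
    amplification_threshold: float = MLPA_AMP_THRESHOLD,
    deletion_threshold: float = MLPA_DEL_THRESHOLD,
) -> MLPAResult:
    """Normalised per-probe copy ratios and amplification/deletion calls.

    The normalisation factor is the median of control/sample peak-area
    ratios over the declared copy-neutral reference probes — robust to a
    minority of changed probes, matching wild-type-vs-sample scatter
    comparison.
    """
    s = sample.set_index("probe")["peak_area"]
    c = control.set_index("probe")["peak_area"]
    if set(s.index) != set(c.index):
        raise ValueError("sample and control must share the probe set")
    if reference_probes is None:
        reference_probes = list(s.index)
    if not reference_probes:
        raise ValueError("at least one reference probe is required for normalization")
    ref_ratio = [
        c[p] / s[p] for p in reference_probes if s[p] > 0 and c[p] > 0
    ]
    if not ref_ratio:
        raise ValueError("no usable reference probes (zero peak areas)")
    norm = float(np.median(ref_ratio))

    ratios = {}
    for p in s.index:
        if c[p] <= 0:
            continue
        ratios[p] = float(s[p] * norm / c[p])
    amplified = tuple(
        sorted(p for p, r in ratios.items() if r >= amplification_threshold)
    )
    deleted = tuple(sorted(p for p, r in ratios.items() if r <= deletion_threshold))
    return MLPAResult(
        ratios=ratios, amplified=amplified, deleted=deleted, normalization=norm
    )
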