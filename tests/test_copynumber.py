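"""aCGH segmentation, chrV L architecture, MLPA analysis."""

import numpy as np
import pandas as pd
import pytest

from gcrsig.arrays import (
    MLPA_NEUTRAL_PROBES,
    default_mlpa_probes,
    simulate_acgh,
    simulate_mlpa,
)
from gcrsig.copynumber import (
    analyze_mlpa,
    interpret_chrvl_architecture,
    segment_log2_track,
)
from gcrsig.rearrange import (
    apply_interstitial_deletion,
    apply_inverted_duplication,
    apply_translocation,
    unrearranged,
)
from gcrsig.chromosome import revcomp


def _track(values, spacing=500):
    rows = [("chr", i * spacing, (i + 1) * spacing, v) for i, v in enumerate(values)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2"])


def test_flat_track_single_neutral_segment():
    segs = segment_log2_track(_track([0.0] * 40))
    assert len(segs) == 1
    assert segs[0].state == "neutral" and segs[0].probe_count == 40


def test_unsorted_track_rejected():
    t = _track([0.0] * 10)
    with pytest.raises(ValueError, match="sorted"):
        segment_log2_track(t.iloc[::-1].reset_index(drop=True))


def test_segmentation_invariant_to_order_after_sorting(rng):
    values = [0.0] * 20 + [1.0] * 10 + [0.0] * 20
    t = _track(values)
    shuffled = t.sample(frac=1, random_state=1).sort_values("start").reset_index(drop=True)
    a = segment_log2_track(t)
    b = segment_log2_track(shuffled)
    assert [(s.start, s.end, s.state) for s in a] == [(s.start, s.end, s.state) for s in b]


def test_noise_free_step_boundaries_within_one_probe(chrom50):
    """Simulated duplication boundaries recovered within a probe spacing."""
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_inverted_duplication(chrom50, bpr.start + 600, loop=30, priming_homology=5)
    track = simulate_acgh(r, probe_spacing=200, noise_sd=0.0)
    segs = segment_log2_track(track)
    dup = next(s for s in segs if s.state == "duplicated")
    arm_start = r.truth.breakpoints[1]
    u5s = chrom50.feature("ura3-52_URA3").start
    assert abs(dup.start - arm_start) <= 200 + 100  # midpoint placement slack
    assert abs(dup.end - u5s) <= 300


def test_noisy_boundaries_within_two_probes_in_most_seeds(chrom50):
    """sd 0.2 noise: boundaries within 2 probes of truth in >=95% of seeds."""
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_inverted_duplication(chrom50, bpr.start + 600, loop=30, priming_homology=5)
    arm_start = r.truth.breakpoints[1]
    u5s = chrom50.feature("ura3-52_URA3").start
    spacing = 200
    good = 0
    for seed in range(100):
        track = simulate_acgh(r, probe_spacing=spacing, noise_sd=0.2, seed=seed)
        segs = segment_log2_track(track)
        dups = [s for s in segs if s.state == "duplicated"]
        if len(dups) != 1:
            continue
        if abs(dups[0].start - arm_start) <= 2 * spacing and \
                abs(dups[0].end - u5s) <= 2 * spacing:
            good += 1
    assert good >= 95


def test_acgh_null_track_is_zero(chrom50):
    track = simulate_acgh(unrearranged(chrom50), noise_sd=0.0)
    assert (track["log2"] == 0).all()


def test_acgh_omits_hph_and_can1_probes(chrom50):
    track = simulate_acgh(unrearranged(chrom50), probe_spacing=100, noise_sd=0.0)
    for name in ("hph", "hph_internal", "CAN1"):
        f = chrom50.feature(name)
        inside = track[(track["start"] < f.end) & (f.start < track["end"])]
        assert inside.empty


def test_acgh_deleted_windows_at_floor(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_interstitial_deletion(chrom50, chrom50.cassette.start - 40, bpr.start + 900)
    track = simulate_acgh(r, probe_spacing=100, noise_sd=0.0)
    start, end = r.truth.breakpoints
    deleted = track[(track["start"] >= start) & (track["end"] <= end)]
    assert not deleted.empty and (deleted["log2"] == -4.0).all()


def test_acgh_duplicated_windows_at_plus_one(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_inverted_duplication(chrom50, bpr.start + 600, loop=30, priming_homology=5)
    arm_start = r.truth.breakpoints[1]
    u5s = chrom50.feature("ura3-52_URA3").start
    track = simulate_acgh(r, probe_spacing=100, noise_sd=0.0)
    inside = track[(track["start"] >= arm_start) & (track["end"] <= u5s)]
    assert not inside.empty and (inside["log2"] == 1.0).all()


def test_architecture_interpretation_by_event_class(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    # inverted duplication resolved via ura3-52
    r = apply_inverted_duplication(chrom50, bpr.start + 600, loop=30, priming_homology=5)
    arch = interpret_chrvl_architecture(
        segment_log2_track(simulate_acgh(r, probe_spacing=200)), chrom50
    )
    assert arch.boundary_feature == "ura3-52"
    assert arch.telomeric_retention and arch.n_duplications == 1
    # interstitial deletion spans the cassette, no duplication
    r2 = apply_interstitial_deletion(chrom50, chrom50.cassette.start - 40, bpr.start + 900)
    arch2 = interpret_chrvl_architecture(
        segment_log2_track(simulate_acgh(r2, probe_spacing=200)), chrom50
    )
    assert arch2.duplication_extent is None
    lo, hi = arch2.deletion_extent
    assert lo <= chrom50.cassette.start + 300 and hi >= chrom50.cassette.end - 300
    assert arch2.telomeric_retention
    # translocation deletes the whole telomeric arm segment
    r3 = apply_translocation(
        chrom50, bpr.start + 300, revcomp(chrom50.sequence[30_000:32_000]),
        donor_map=(30_000, -1),
    )
    arch3 = interpret_chrvl_architecture(
        segment_log2_track(simulate_acgh(r3, probe_spacing=200)), chrom50
    )
    assert not arch3.telomeric_retention
    assert arch3.deletion_extent[0] <= 300


# ---------------------------------------------------------------------------
# MLPA

def test_mlpa_probe_ladder_steps_of_six(chrom50):
    probes = default_mlpa_probes(chrom50)
    diffs = np.diff(probes["product_length"])
    assert (diffs == 6).all()


def test_mlpa_null_baseline_and_identity_analysis(chrom50):
    wt = simulate_mlpa(unrearranged(chrom50), noise_cv=0.0)
    assert (wt["peak_area"] == 1000.0).all()
    res = analyze_mlpa(wt, wt.copy(), reference_probes=list(MLPA_NEUTRAL_PROBES))
    assert all(abs(v - 1.0) < 1e-12 for v in res.ratios.values())
    assert res.amplified == ()


def test_mlpa_duplication_doubles_peak_areas(chrom50):
    bpr = chrom50.feature("GCR_breakpoint_region")
    r = apply_inverted_duplication(chrom50, bpr.start + 600, loop=30, priming_homology=5)
    sample = simulate_mlpa(r, noise_cv=0.0)
    wt = simulate_mlpa(unrearranged(chrom50), noise_cv=0.0)
    res = analyze_mlpa(sample, wt, reference_probes=list(MLPA_NEUTRAL_PROBES))
    assert res.amplified == ("BUD16", "GEA2", "PCM1", "VMA8")
    for p in res.amplified:
        assert abs(res.ratios[p] - 2.0) < 1e-12


def test_mlpa_noise_specificity(chrom50):
    """No-change genome at cv 0.1: empty amplified set in >=95% of seeds."""
    wt_genome = unrearranged(chrom50)
    clean = 0
    for seed in range(100):
        sample = simulate_mlpa(wt_genome, noise_cv=0.1, seed=seed)
        control = simulate_mlpa(wt_genome, noise_cv=0.1, seed=10_000 + seed)
        res = analyze_mlpa(sample, control, reference_probes=list(MLPA_NEUTRAL_PROBES))
        if not res.amplified:
            clean += 1
    assert clean >= 95


def test_mlpa_empty_reference_set_rejected(chrom50):
    wt = simulate_mlpa(unrearranged(chrom50), noise_cv=0.0)
    with pytest.raises(ValueError, match="reference probe"):
        analyze_mlpa(wt, wt.copy(), reference_probes=[])


def test_mlpa_acgh_agree_on_duplication_extent(chrom50):
    """Cross-method consistency: amplified probes are exactly the panel
    probes inside the aCGH duplication extent."""
    bpr = chrom50.feature("GCR_breakpoint_region")
    wt = simulate_mlpa(unrearranged(chrom50), noise_cv=0.0)
    probes = default_mlpa_probes(chrom50)
    for dsb_off, resolution in [(400, "ura3-52"), (700, "ura3-52"), (900, "ty"), (500, "none")]:
        r = apply_inverted_duplication(
            chrom50, bpr.start + dsb_off, loop=30, priming_homology=5, resolution=resolution
        )
        arch = interpret_chrvl_architecture(
            segment_log2_track(simulate_acgh(r, probe_spacing=200)), chrom50
        )
        res = analyze_mlpa(
            simulate_mlpa(r, noise_cv=0.0), wt, reference_probes=list(MLPA_NEUTRAL_PROBES)
        )
        lo, hi = arch.duplication_extent
        inside = tuple(
            sorted(
                probes[(probes["target_start"] >= lo) & (probes["target_start"] < hi)]["probe"]
            )
        )
        assert res.amplified == inside
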