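# Methods

## The model assay chromosome

The analysis depends on feature topology, repeat homology and motif
content, not on the actual chrV sequence, so the assay chromosome is
synthetic: a uniform-random background at a fixed seed with recognisable
tracts planted at layout positions scaled from a 580 kb design (defaults
in `gcrsig.chromosome._UGCR_DESIGN`; any length ≥ 50 kb). Coordinates are
0-based half-open, and the chromosome defines its own coordinate frame —
the same move the original product analysis makes when it remaps data to
a custom assay-chromosome frame.

Layout facts that carry analysis weight:

* left-arm order `TEL_L < hph < CAN1/URA3 cassette < breakpoint region <
  PCM1 < ura3-52 < CEN5`; the breakpoint region is bounded by the
  cassette and `PCM1` (the most telomeric essential gene), spanning
  ~34–50.8 kb at full scale so that cassette-spanning deletions of
  4–19 kb and duplications of ~80 kb (to `ura3-52` at 116 kb) are
  producible;
* within the cassette, `URA3` sits telomeric of `CAN1`, and the
  `ura3-52` locus carries the same `URA3` sequence in **inverted**
  orientation plus a Ty consensus tract. Only with that relative
  orientation does fold-back + HR yield a monocentric chromosome whose
  `URA3/ura3-52` fusion recaptures the `hph`-containing end while
  deleting `CAN1`;
* an `hph`-homologous tract is planted between the two AscI sites, a
  layout fact encoded so that the internal AscI fragment hybridises to
  the `hph` probe as well as the left telomeric fragment (the observed
  probe behaviour; the sequence basis is not documented, so it is stated
  here as a construction choice);
* telomere seeds are irregular `(TG|TGG|TGGG)+` tracts — enough
  TG1-3-like irregularity to exercise the telomere detector without
  modelling telomerase; the right telomere is the reverse complement
  (C-strand on top);
* chance occurrences of the AscI motif `GGCGCGCC` in the random
  background are scrubbed so motif count equals site count;
* eight single-copy gene loci (`EAF5 YEA6 PCM1 VMA8 BUD16 GEA2 IRC22
  MNN1`) anchor the MLPA panel; `VMA8/BUD16/GEA2/PCM1` lie inside typical
  inverted-duplication extents, the other four outside (they are the
  default copy-neutral normalisation probes).

The dGCR variant is supported only as a labelled layout (it adds the
HXT13-DSF1 segmental-duplication tract inside the breakpoint region);
duplication-mediated rearrangement mechanics are not simulated, and dGCR
numbers enter the statistics only as published count/rate inputs.

## Truth-labelled rearrangements

Each constructor returns the product genome as a list of typed segments
(reference interval + strand, or novel sequence), a truth record, and a
**locally edited copy of the reference**. The edits are what make truth
labels exact rather than sampled:

* deletion microhomology *m* is planted as
  `ref[start:start+m] == ref[end:end+m]`, with guard edits at both ends
  so the shared run is exactly *m*; all edits fall inside the deleted
  interval, so the product is untouched;
* the fold-back priming homology *h* is planted as an inverted repeat
  `ref[g:g+h] = revcomp(ref[dsb:dsb+h])` with `g = dsb + h + loop`; guard
  edits (in the deleted interval and the loop template) pin its
  maximality. The product junction is then
  `... revcomp(ref[g+h:anchor]) | ref[dsb:...]`, a long palindrome whose
  unpaired centre is the loop template `ref[dsb+h:g)` — so a
  self-alignment of the junction recovers the loop length exactly, and
  the junction's exact-match microhomology *is* the priming homology;
* the resolution mode fixes the anchor: `ura3-52` (capture of
  `ref[0:URA3.end)`, hph retained), `ty` (capture of a foreign
  telomere-capped Ty-ended stub, hph lost), or `none` (telomere-capped
  isoduplication arm ending at a non-repeat point, hph lost).

Breakpoint convention: shared (ambiguous) junction bases are assigned to
the centromeric/suffix side, so a deletion's breakpoints are
`(start, end)` and a fold-back's are `(dsb, g+h)` (the arm start).

## Read simulation and the mapper question

Fragments are uniform along the product with truncated-normal insert
sizes (default 600 ± 60 bp, 2×100 bp reads, 50×; the library emulates a
gel-selected ~600 bp paired-end prep), error-free, with an optional
fraction of exact duplicate pairs (PCR/optical semantics: identical
coordinates and sequences under fresh names).

Short-read mapping itself is out of scope, but the caller consumes
reference-space alignments. The simulator therefore emits the alignments
an ideal exact unique mapper would produce, by projecting each read's
true origin through the segment map: reads crossing a novel junction are
unmapped; reads whose projected interval lies wholly inside a multi-copy
homology tract (`hph`/`hph_internal`, cassette `URA3`/`ura3-52`) get
MAPQ 0; Ty-fragment inserts project to the chromosomal Ty tract (the one
locus carrying that consensus). Product-space truth coordinates ride
along in `ps`/`pe` SAM tags. Against real data the projection step would
be replaced by a mapper; everything downstream consumes standard paired
SAM.

## Junction calling

"Uniquely mapping" means MAPQ ≥ 20 and not secondary (configurable).
Duplicate removal is coordinate-based on both mates' (target, start,
orientation). The insert distance is the outer span (= fragment length
for error-free pairs); the concordance cutoff is median + 10·MAD
(k configurable) estimated from uniquely-mapped convergent pairs.

Junction-defining pairs — both mates unique, but distance above the
cutoff, targets different, or orientation non-convergent — are clustered
greedily in coordinate order (single linkage; two pairs join iff both
sides match in orientation and starts within one cutoff). Significance
combines a support floor (default 3) with a Poisson tail test of the
support against a uniform chimeric-background rate estimated from the
data (`n_discordant · 2·cutoff / genome_length`, α = 0.01). Fold-back
geometry (both sides one target, same orientation, overlapping
intervals) is kept as a distinct call class with a lower default floor
(2), because palindromic junctions amplify poorly and yield fewer pairs
in real libraries.

Junctions into novel sequence (de novo telomeres, foreign donors)
produce **no** junction-defining pairs — every far-side mate is
unmapped. The caller therefore also clusters half-mapped pairs (one
unique mate + one unmapped mate) into one-sided calls under the same
significance machinery. One-sided clusters flanking a significant
two-sided call are that call's own junction-spanning pairs and are
absorbed rather than reported. On unrearranged genomes the simulator
produces neither discordant nor unmapped reads, so specificity is exact
by construction; with real mapper noise the Poisson test carries the
load.

Junction-sequencing reads (unmapped mates whose anchor lies within one
cutoff of a call side, orientation matching) are assembled by greedy
exact-overlap layout (≥ 20 bp, both orientations, containment allowed)
with per-column majority consensus; ties break lexicographically and
lower the per-base agreement. Error-free input makes the consensus
exact; a base-quality-aware consensus is out of scope.

## Annotation

The consensus is placed by its maximal exact prefix and suffix matches
against the reference (either strand; binary search over the
downward-closed match lengths). When a matched arm lies inside a
repeated tract, all occurrences of the maximal affix are enumerated and
the prefix/suffix pair spanning the smallest junction is chosen (the
parsimonious placement — the same ambiguity the original Ty-insertion
junctions presented). A junction whose sides both map to the minus
strand is re-annotated from its reverse complement, so reported
breakpoints are canonical. Exact matching only: the consensus derives
from multiple error-free reads on a synthetic genome; a
mismatch-tolerant mode is deliberately out of scope.

The affix overlap on the consensus is the microhomology (assigned to
side B; side A's coordinate is trimmed), a gap is the non-templated
insert; when both descriptions are possible the microhomology is
preferred and the insert left empty. Fold-back detection takes the
raw (untrimmed) boundaries `x < y`: the priming repeat copies are
`[x,x+h)` and `[y,y+h)` (h = the junction microhomology), the unpaired
loop is `ref[x+h:y)`, and the repeat must be reference-templated in
inverted orientation (`ref[y:y+h] == revcomp(ref[x:x+h])`), with ≥ 2 bp
and loop ≤ 200 nt. This formulation is invariant under
reverse-complementing the consensus. A perfect palindrome (loop 0) makes
both affix matches run through the entire repeat; that degenerate case
is recognised separately and flagged (hairpins with no loop are the
geometry most exposed to Sae2 cleavage). The fold-back "centre" is
reported as the loop-template midpoint — geometry only, no claim about
the initiating DSB position, since more distal initiations are known.

Telomere additions: one side unanchored — unmappable, or mapped *only
inside a telomere tract*, since a novel TG1-3 tail shares long chance
substrings with the reference telomere seeds — and the tail parsing as
TG1-3 units at ≥ 90% conformity over ≥ 15 nt (per-unit regex scoring,
better strand; thresholds configurable). Random 30-mers pass at well
under 1%.

Class priority: telomere_addition → inversion_foldback → deletion
(same target, same strand, increasing) → translocation; unmappable
sides propagate `unresolved`.

## Copy number

aCGH: one probe per reference window (default spacing 200 bp at test
scale, 500 bp full scale), value = log2(copy number at the window
midpoint) + Gaussian noise, floor −4 for copy 0; windows over the
`hph`/`hph_internal`/`CAN1` insertions carry no probes (non-reference
sequence in the real strain is unprobed). Haploid semantics: duplication
= 2 copies (log2 +1), deletion = 0 copies. Probe thresholds sit midway
between states under noise (duplicated ≥ +0.58, deleted ≤ −1.0; the ±1
guide lines correspond to 2-fold changes); runs shorter than 3 probes
are absorbed into the neighbour with the closer mean level; boundaries
fall at the midpoint between the last probe of one state and the first
of the next, so boundary error is about one probe spacing — all feature-
anchoring checks (duplication starting in the breakpoint region; the
centromeric boundary being `ura3-52` vs the Ty tract vs none) use that
spacing as slack.

MLPA: peak area = baseline × copy number × (1 + N(0, cv)); product
lengths form a strict 6 bp ladder; probes must target single-copy loci.
Analysis normalises by the median control/sample ratio over declared
copy-neutral reference probes (robust to a minority of changed probes,
and degrades gracefully when telomeric reference probes are deleted —
zero-area probes drop out of the median). Amplified ≥ 1.5 (midpoint of
1 and 2 copies), deleted ≤ 0.3; no published numeric cutoff exists, the
published validation being scatter agreement with aCGH, which is
mirrored here as the cross-method consistency test.

## Classification

The in-silico AscI digest cuts at every motif occurrence and probes
fragments boolean-ly with the central 80 bp of the `hph` and `MCM3`
tracts; chromosome size class uses a ±2% band standing in for PFGE gel
resolution. `hph` presence is read from the product sequence directly
(the wet-lab proxy is growth on hygromycin). Decision rules, with
junction evidence taking precedence over copy-number evidence because it
is base-resolution: multiple independent repeat-bounded duplications →
complex; fold-back junction, or breakpoint-region-anchored duplication
with a larger chromosome → inverted duplication (resolution homology
from the copy-number boundary feature, else from junction-side
features); telomere-addition junction → de novo telomere; deletion
junction with no duplication and no size increase → interstitial
deletion; cross-locus junction → translocation; contradictions (e.g. a
chrV L duplication on a wild-type-sized chromosome) → unclassified with
an explanatory note.

Retention tables report integer percentages, except one decimal place
for rates between 0 and 1% — the printed-table convention (15 of 2435 →
0.6%).

## Statistics

* **G-test** of retention: two categories, `G = 2·Σ O ln(O/E)` with
  `0·ln 0 = 0`, df = 1, chi-square tail, **no Williams correction** —
  validated empirically by one-significant-figure agreement with all
  five published retention p-values computable from published counts
  (3×10⁻¹³, 2×10⁻⁹, 7×10⁻⁶, 6×10⁻⁸, 0.003 against expected 2/27).
* **Mann–Whitney U**: two-tailed, midrank ties; exact by enumeration for
  min(n) ≤ 8 without ties, normal approximation with tie correction
  otherwise (delegated to scipy; an independent enumeration oracle backs
  it in the tests). Significance threshold 0.01, as used for the assay
  comparisons.
* **Fluctuation rates**: the cited rate methodology gives no formulas;
  the Lea–Coulson method of the median is adopted as the standard
  estimator — solve `r̃/m − ln m = 1.24` (Brent on log m), rate = m/N.
  A median of zero mutants yields an upper bound computed at r̃ = 0.5
  and formatted with "<", reproducing the printed "<rate" convention
  deterministically. MSS maximum likelihood is out of scope, as are
  confidence intervals (none are printed). The simulator draws
  Poisson(rate·N) mutations per culture, each at a uniformly random
  division, with deterministic clone expansion (`N // s` survivors);
  this reproduces the heavy-tailed jackpot distribution. At 24 cultures
  the estimator's log10 bias is below 0.15 across 10⁻⁹–10⁻⁷ (simulation
  study in the test suite).
* **Fold increases** are rate ratios rounded to two significant figures.

Absolute published rates (e.g. 4.99×10⁻⁹) are not recomputable from the
publication alone — the per-culture cell counts behind them are not
printed — so only ratios, retention arithmetic and estimator-recovery
properties are checked.

## Reproducibility and problem sizes

A single global seed fans out to per-isolate, per-stage seeds through a
counter scheme (`stage_seed`), so any stage re-runs independently with
the same stream; cohort outputs land in a config-hash-named directory
and re-runs are byte-identical. The benchmark cohort is 20 isolates
(5 per mechanism class, all three resolution modes represented) on a
50 kb chromosome at 50× — the scaled-down study condition used
throughout; the rate-recovery study uses 200 replicate 24-culture
experiments at 10⁸ cells per culture.

## What the synthetic data does and does not show

The generator produces error-free reads, exact duplicate semantics, an
idealised unique-mapper projection, Gaussian probe noise, and a single
Ty tract standing in for the genome's ~250 Ty-related elements. Passing
tests therefore demonstrate the correctness of the algorithms and their
integration — clustering, assembly, annotation geometry, copy-number
logic, classification rules, estimators — under the assay's topology
and homology structure. They do not demonstrate robustness to sequencing
error, mapper artefacts, real repeat families, or microarray
normalisation drift; those would require the deposited real data and a
real mapper. Donor disambiguation among identical Ty copies is
explicitly not attempted (with one tract it is moot; against a real
genome the junction is inherently multi-mapping, as the original
Ty-insertion junction analysis also found). Selection on
canavanine/5-FOA media is emulated structurally — only cassette-removing
events are constructible — and telomerase-independent survivor types are
not modelled.
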