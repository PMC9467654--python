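# Methods

`veinquant` quantifies polarized secondary-wall ("wall ingrowth") deposition
in phloem parenchyma transfer cells (PP TCs) of leaf minor-vein
cross-sections, together with the distribution of a plasma-membrane sucrose
transporter along those walls.  Because no imaging data of this kind is
publicly deposited, the package is organised around a synthetic-vein
generator with complete ground truth: every measurement stage is validated
as a parameter-recovery problem.

## The measurements

**Geometry.**  Input is an integer cell-label map with per-cell types
(XY = xylem, SE = sieve element, CC = companion cell, PP = phloem
parenchyma, BS = bundle sheath, OTHER) and a pixel size in µm.  Two cells
are adjacent iff some pixel of one is 4-adjacent to some pixel of the
other; an *interface* is the ordered list of shared pixel faces, and its
length is the face count times the pixel size.  This Manhattan measure
overestimates oblique boundaries by up to √2 but is exact, unambiguous and
additive (a cell's interface lengths sum to its internal 4-connected
perimeter); all coverage statistics are ratios of such lengths, where the
bias cancels.  Vein size is the combined pixel area of XY/SE/CC/PP cells.

**Position classes.**  The abaxial axis is inferred from anatomy (unit
vector from the xylem centroid to the phloem centroid; overridable).
Bundle-sheath cells split into abaxial/adaxial halves at the median of
their centroid projections.  A cell is *abaxial* when it is directly
adjacent to, or one cell away from (graph distance ≤ 2, intervening cell of
any type), an abaxial-half BS cell; *adaxial* symmetrically; *middle*
otherwise; a cell within two hops of both halves is resolved by its own
projection against the BS median.  In small veins nearly every cell is
within two hops of some BS cell, so the projection tiebreak carries most of
the signal; a genuine *middle* call requires a vein large enough that a
cell's entire neighbourhood avoids the sheath.

**Wall-thickness profiling and ingrowth detection.**  The wall-stain
channel is converted to 8 bits and binarized with the intermeans (IsoData
variant) threshold.  Each wall pixel of a cell is attributed to the
boundary faces within 0.8 px of its nearest face ("soft" nearest-anchor
attribution); a face's local wall thickness is one plus its largest
attribution distance, floored to whole pixels.  The soft margin sits just
above the half-pixel aliasing of staircase boundaries, so no face is
shadowed by a corner neighbour; the price is a bounded lateral leak of
√(2·depth·0.8) ≈ 4 faces where a thick pad ends mid-interface.

Faces thicker than `factor` (default 1.5) times the cell's primary-wall
baseline (25th percentile of all the cell's face thicknesses, or the median
over interfaces known to carry no deposition) are flagged.  Detection runs
on the *cyclic* profile of the cell's whole boundary, because a pad that
reaches a wall junction fuses with the neighbouring wall and the
per-interface profile alone dips ambiguously there.  Flag runs are trimmed
by 4 faces per end to remove the attribution leak, except at ends showing
junction-fusion evidence (within 6 faces of an interface transition with
every intervening face ≥ 1.2× baseline).  Runs shorter than 3 faces are
suppressed as speckle.  Residual coverage error is bounded by the junction
ambiguity scale (≤ 8 faces worst case, |mean| ≤ 3 faces, asserted in
tests); arc ends within ~1 µm of a junction are genuinely
indistinguishable from junction-fused pads at this resolution.

**Deposition classes and scores.**  Per PP cell: `coverage_SE` is the
covered fraction of its total SE-facing interface length; `coverage_CC` is
per-CC-interface.  Classes: I — no coverage; II — partial SE coverage;
III — entire SE coverage with at most a small CC portion (max CC ≤
`small_cc` = 0.2); IV — entire SE plus a considerable CC portion; V —
entire SE and at least one entirely covered CC interface.  "Entire" is
operationalised as measured coverage ≥ `full` = 0.8: on calibration veins,
truly full interfaces measure 0.83–1.0 (junction faces are ambiguous)
while half coverage stays ≤ 0.6, so 0.8 splits the gap with margin.  Two
measurement-validity rules keep the CC distinction honest: CC coverage is
scored on the faces beyond a 10-face (~2 µm) junction-fusion zone next to
the SE junction, and CC interfaces with fewer than 20 scorable faces are
excluded; a cell needs a ≥ 40-face CC interface for the IV/V distinction to
be resolvable at all.  The ordinal cell score is class index − 1 (0–4); a
vein's score is the sum over its PP cells, so the typical two-PP-TC vein
spans 0–8 — consistent with the published per-vein survey range (< 3 to
> 7).  The mapping is a convention: the original visual scoring rubric is
not reproduced in the source study.

**Fluorescence statistics.**  Channels are min–max rescaled to 8 bits per
frame (rounded half-up), thresholded with the intermeans method, and summed
strictly above threshold within the ROI.  A cell's membrane ROI is its
boundary dilated by 2 px, restricted to its own label.  The calibrated
relative intensity

    F = (S2 · C1) / (S1 · C2)

(S = marker, C = wall stain; 1 = reference region, 2 = test region) cancels
any multiplicative factor applied to both channels of one region — the
depth-dependent attenuation of excitation and emission that makes adaxial
cells darker.  The cancellation is exact when the factor is constant over
the region; for a smoothly depth-varying field the residual is the
within-region covariance of factor and channel, ≈ 0.5% at realistic
attenuation.  The membrane-enrichment factor

    FC = (A1 · L2) / (A2 · L1)

compares marker per unit primary-wall length between an ingrowth site and
an ingrowth-free site of the same cell.  Site ROIs are face ribbons
(± 2 px within the cell); contested pixels between the two sites go to the
nearer site, and pixels nearer to membrane outside either site are dropped,
so third-party membrane does not inflate a read.  Sums (not means) are
used; with equal-geometry ROIs the ratio is insensitive to the choice.

**Cohort statistics.**  A PP cell counts as a transfer cell when its class
is ≥ II.  The survey aggregates: mean cell counts per vein, percentage of
abaxially positioned PP TCs (integer, rounded half away from zero — 200 of
339 → 59), percentage of veins with more than two PP TCs, interface-length
and coverage summaries, SEs/CCs abutting transfer cells and ingrowths,
Pearson correlation of PP-TC count with vein area (reported, not asserted),
and pooled-variance Student's t comparisons (Welch behind a flag; no
multiple-testing correction, matching the source analysis).

## The synthetic generator

Cell geometry is a seeded Voronoi tessellation of hand-placed generator
points — xylem adaxial, SE/CC/PP abaxial, a BS ring enclosing the bundle —
relaxed with two Lloyd iterations (raw Voronoi cells develop thin slivers
and acute wedges that no real cell has).  The outer annulus (beyond 0.86 of
the vein radius) is reserved for BS seeds so the sheath always encloses the
bundle.  PP cells are placed per their configured position class; a
"middle" PP needs a configuration with enough shielding cells (the test
suite uses XY 5 / SE 4 / CC 8 / OTHER 6 / BS 8).  Default frame 512 × 512
at 0.2 µm/px; at half that resolution sieve elements (~1.5 µm across)
become unresolvable against the wall bands.

Walls are isotropic bands of half-width 3 px (0.6 µm) around every
boundary.  Ingrowth pads extrude the band to k × its half-width over the
covered arc on the PP side; partial arcs nucleate away from interface ends
and end in a clean perpendicular cut, while fully covered interfaces fuse
into the junction nooks — as real deposition wraps a junction — and spill a
short way onto the neighbouring interface.  The Class III preset therefore
sets CC coverage 0: the "small CC portion" of that class emerges as
junction spillover.  Preset CC arcs (IV, V) grow contiguously from the
SE-adjacent junction, matching the observed progression of deposition from
the SE interface onto CC interfaces.

The marker channel deposits fluorescence only on PP boundary ribbons
(2 px), at `marker_density` (default 5000 AU/µm) per unit membrane length,
scaled by k over covered arcs (amplified membrane surface).  Both channels
are multiplied by exp(−coef·depth) with depth measured adaxially from the
abaxial image edge (default 0.004/µm ≈ 25% dimming across a 70 µm vein),
then additive Gaussian noise (σ = 20 AU; the dimmest membrane of interest
stays ~10× above it) is added and clipped at zero.

What the generator does *not* emulate: Poisson shot noise, a point-spread
function, 3-D structure (orthogonal reconstructions are reduced to 2-D
sections), papillae-scale ingrowth morphology, wall-stain variability
between cell types, and segmentation errors (the label map is ground
truth).  Passing recovery tests therefore demonstrates that the estimators
are correct and well-calibrated for geometry and intensity effects — not
that detection is robust to real-microscopy artefacts such as PSF blur or
uneven staining.

## Study-design constants

| Parameter | Default | Meaning |
|---|---|---|
| `pixel_size` | 0.2 µm/px | frame resolution |
| `shape` | 512 × 512 | frame size (~102 µm field) |
| wall half-width | 3 px (0.6 µm) | primary-wall band per side |
| `marker_density` | 5000 AU/µm | membrane fluorescence density |
| `noise_sd` | 20 AU | additive Gaussian noise |
| `attenuation_coef` | 0.004 /µm | depth dimming |
| `factor` | 1.5 | thickness detection threshold |
| `min_run` | 3 faces | despeckle |
| trim / protect | 4 / 6 faces | leak removal / junction evidence |
| `small_cc` / `full` | 0.2 / 0.8 | class boundaries |
| CC junction skip | 10 faces | fusion-zone exclusion |

Cohort sampling (summary level) draws PP-TC counts per vein from
{1: 0.28, 2: 0.37, 3: 0.25, 4: 0.10} — matching the surveyed mean of
339/156 ≈ 2.17 per vein; the published small-sample figure of ~45% of veins
with more than two PP TCs is jointly incompatible with that mean and the
sampler follows the larger survey.  Each PP TC is abaxial with probability
200/339, else middle/adaxial with equal probability; deposition scores are
Binomial(4, p) with p = 0.75/0.5/0.3 for abaxial/middle/adaxial, emulating
the reported abaxial-to-adaxial gradient.

## Problem sizes used in validation

Recovery suites run at the default 512² frame: position recovery over 12
seeds per layout, class recovery over 8 noise-free and 20 noisy seeds per
class (≈ 280 classified cells), enrichment recovery over 50 seeds per k ∈
{1, 2, 3, 5}, calibrated-intensity recovery over 30–50 seeds, cohort
recovery over 100 replicates of 156 veins, and t-test calibration over
10,000 null replicates.  Exact-cancellation checks use the congruent
twin-cell fixture with raw (un-quantised) sums; all image-pipeline checks
go through the 8-bit thresholded route.
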