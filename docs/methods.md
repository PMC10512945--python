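# Methods

This note documents the models, conventions and defaults behind `lpfoot`,
what the synthetic generators do and do not emulate, and the design choices
made where the procedure was genuinely open.

## Coordinate and arithmetic conventions

Residue positions are 1-based. "Cleavage at amino acid *i*" denotes the
peptide bond C-terminal to residue *i*; the fragment produced by cuts
*(i, j)* spans residues *i+1 … j* and has length *j − i*. Position 0 is
the intact N-terminus and *L* the intact C-terminus; a terminal K/R is not
reported as a cleavage site because cleavage there produces no new
fragment. Epitope overlap uses the interval-difference count
`max(0, min(frag_end, e₂) − max(frag_start, e₁))` rather than inclusive
counting; under this convention a fragment ending at 1314 contains 47
residues of the 1267–1379 epitope and one ending at 1369 contains 102,
matching the source study's printed arithmetic (inclusive counting would
give 48 and 103). The epitope window itself is printed in two variants in
that study (1266–1379 once, 1267–1379 in the worked arithmetic); the
package defaults to 1267–1379 and accepts either.

## Protease motifs

Rules are residue-pattern predicates registered by name; trypsin (shipped)
marks K or R not immediately followed by P. The scan excludes the last
residue and is property-tested against an independent regex oracle. The
motif-matching window defaults to 20 residues: the study's summary table
says "within 15 amino acids" while its text cites candidates at distance
18 for one site, and 20 covers both readings.

## Gel calibration

`log₁₀(mass, kDa)` is regressed on migration distance (OLS,
`scipy.stats.linregress`); migration is the predictor because that is the
measured quantity for an unknown band. Two bands give an exact line (r²
not reported); duplicate migrations with conflicting masses are rejected.
Mass→length conversion subtracts the masses of tags retained by the
fragment and divides by a mean residue mass of 110 Da (configurable); the
default tag masses are GFP 27.0 kDa, myc 1.2 kDa, GST 26.0 kDa, all
configurable, since fusion-construct studies rarely state the exact values
they subtracted. Estimates outside the ladder's migration range carry an
`extrapolated` flag. Downstream matching treats band masses as ±5%
approximate.

## Anchored inference and unmasking

Each detection route fixes one terminus: C-tag fragments anchor at the
intact tagged C-terminus, N-tag fragments at position 0, and
internal-epitope fragments enumerate candidate C-anchors over the cleavage
positions already inferred from the C-tag series (plus the intact
C-terminus), keeping candidates whose fragment would overlap the epitope.
When several anchors are feasible the pipeline keeps the smallest; this
mirrors the source study's choice of the closer cleavage (there justified
by band intensity, which this package does not model — the preference is
an explicit, documented input). Anchor ambiguity is the method's inherent
limitation: an epitope-detected fragment consistent with two anchors can
be placed wrongly by the gap between them, which is why exact-recovery
validation uses the unambiguous tag-anchored series.

Calls are clustered by single-linkage within a merge radius (default 5
residues — gel resolution at ±5% mass far exceeds single-residue
precision); the cluster representative is the low median. A membrane
cluster with no cytosol call within the radius is *unmasked*. Region
classification returns the tiling interval containing the position, with
boundary positions resolving to the upstream interval (a deterministic,
documented tie-break). Bands also present in undigested controls are
excluded upstream via the observation flag `in_control`, never inside the
inference engine.

## Packaged GBF1 reference data

The annotation tiles [1, 1859] (the canonical human GBF1 length) with DCB,
HUS, Sec7d, HDS1–3 and their linkers. Only the HDS3 span (1532–1721) is
stated outright in the source study; the other boundaries were fixed once
so that every published per-site label is honoured — 178 in DCB, 342 in
the DCB–HUS linker, 469 in HUS, 605/642/687 in the HUS–Sec7d linker, 878
in Sec7d, 1259 in HDS2, 1314/1369 in the HDS2–HDS3 linker — and lie near
the domain-assignment literature's values. Helix rows (Sec7d α8–α10, HDS2
α3/α5) are approximate spans used only to label neighbor contacts. The
site table records both printed spellings of the candidate motif for site
1259 (K1251 in the summary table, K1252 in the running text) without
resolving the discrepancy; distance computations follow the text value
(K1252, distance 7).

## Structural context

SASA is computed by the classic Shrake–Rupley procedure implemented
in-package: each heavy atom inflated by the probe radius (default 1.4 Å)
is sampled with a deterministic golden-spiral point set (default 960
points); Bondi van-der-Waals radii; per-residue sums. Tests check it
against a naive point-rejection oracle and cross-check it against
biotite's independent SASA engine with matched per-atom radii. Relative
SASA divides by the Tien et al. 2013 theoretical residue maxima
(packaged); exposure uses the conventional 0.25 threshold. Masking
neighbors are residues with minimum heavy-atom distance ≤ 5.0 Å and
|Δposition| > 4 (same-helix-turn contacts are not "masking"). The
qualitative exposure/masking labels of the source study derive from a
predicted model that is not redistributed; on any user-supplied model the
annotations are a qualitative, not bit-reproducible, comparison.

## Helical wheels

Angle of residue *i* is `(start_angle + (i−1)·twist) mod 360` with twist
100°/residue; co-angular residues (i, i+18) stack on successive radial
layers. Shapes: D/E triangles, K/R/H pentagons (histidine counted as
potentially positively charged), the classic hydrophobic set
A/V/L/I/M/F/W/C squares, remainder circles — a total partition of the
alphabet. Hydrophobicity uses the Kyte–Doolittle scale (packaged, the
default named scale) mapped green (scale maximum) → yellow (0) → red
(scale minimum). Rendering is a thin optional layer over the data table.

## Image quantification

The organelle (red) mask is `I > mean + 5·SD` with population SD over the
whole field and strict inequality; the cell (green) mask is `I > mean`.
Both are field-level statistics with no morphological cleanup, thresholded
globally and then intersected, and are invariant under positive affine
intensity transforms. The reported percentage is
`100 · Σ green[cell ∧ golgi] / Σ green[cell]`, 0 (flagged) when the cell
mask holds no signal. A consequence of the 5-SD rule worth knowing: a
bright region covering more than about 4% of the field raises the SD so
much that no pixel can clear the threshold, so fields must be acquired
with the organelle small relative to the frame. The study's measured
percentages are not reproduction targets (raw images are not deposited);
the module is validated on synthetic fields with planted fractions.

## Synthetic generators

All generators are pure functions of an explicit seed. `make_protein`
draws a random sequence at a target K/R density (default 0.1, near
natural abundance) with an optional no-K/R-before-P constraint, and tiles
it with alternating structured/linker blocks. `simulate_digestion` models
a partial digest read out per detection route: one tagged fragment per cut
for terminal tags; fragments between consecutive cuts that overlap the
epitope for internal detection; cytosol lanes carry only always-exposed
cuts and the two timepoint lanes are replicates (no kinetics).
`simulate_gel` inverts a log-linear curve (default slope −0.02/mm,
intercept 2.6) and applies relative Gaussian migration noise; the ladder
(a typical 10–250 kDa prestained series) is emitted noise-free.
`make_microscopy_pair` plants a disc organelle bright enough to clear the
5-SD threshold and splits in-cell green intensity to a chosen fraction.
The default digestion scenario mirrors the study's scale: L = 1859,
epitope [1267, 1379], ten membrane-only sites snapped to real motifs near
the study's positions, GFP/myc tags.

What the generators do **not** emulate: band intensity and shape, missed
and partial cleavages beyond the single-cut readout, endogenous-protease
background bands, per-cell heterogeneity, z-stacks or optical blur.
Passing recovery tests therefore demonstrates the correctness of the
arithmetic and thresholds, not robustness to those real-data effects.

## Validation tolerances

Zero-noise recovery is exact by construction and asserted exactly. Under
band-mass error bounded by ±2%, a fragment of mass *m* can shift a call by
at most `0.02·m/110` residues plus the one-residue quantum introduced by
rounding mass to an integer residue count; the noisy-recovery checks use
exactly that derived bound (95% of 100 seeded scenarios must recover every
planted site within it). Gel slope recovery at 1% migration noise is
checked to 5%. SASA equivalence with the naive oracle is asserted at 1%
relative per residue (same point count), and against biotite at 2%
(different point distributions). Planted image fractions are recovered
within 1 absolute point at the default SNR.

## Problem sizes

The test suite runs digest scenarios at the study scale (L = 1859; 100
seeds for the noisy-recovery sweep), motif-scan equivalence on 1,000
random sequences up to 120 residues, structural oracles on ≤30-residue
toys, and 128×128 image fields — sizes chosen so the whole suite completes
in well under a minute while still exercising every code path at realistic
scale.
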