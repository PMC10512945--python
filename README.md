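# lpfoot — limited-proteolysis footprinting analysis

Limited proteolysis probes protein conformation: a brief, mild protease
treatment cleaves only surface-accessible, flexible sites, so comparing the
fragment ladder of a protein in two states (for example cytosolic versus
membrane-bound) reveals *unmasked* sites — positions that become protease-
accessible only in one state and therefore report a conformational change.
`lpfoot` turns the western-blot arithmetic behind this kind of experiment
into a tested, reusable pipeline. It was built around a footprinting study
of GBF1, the 1859-residue Golgi Arf guanine-nucleotide exchange factor, and
ships that study's site table, domain annotation and fragment series as a
worked example.

The pipeline is aimed at bench scientists who have gel images and blot
interpretations in a notebook and want the downstream arithmetic to be
explicit, deterministic and checkable.

## The method

A blot detects only fragments carrying the probed feature — an N- or
C-terminal tag, or an internal epitope with window `[e₁, e₂]`. Each
detected fragment therefore has one **anchored** terminus at a known
position `a` (an intact end, a retained tag, or an assumed upstream
cleavage) and one unknown cleavage position `x` recovered from the
fragment's residue length `n`:

* C-anchored (C-tag or epitope detection): `x = a − n`
* N-anchored (N-tag detection): `x = a + n`

with "cleavage at amino acid `x`" meaning the bond C-terminal to residue
`x`, so a fragment spans residues `x+1 … a` and `n = a − x`. Residue
lengths come either directly or from band masses via the gel standard
curve, `log₁₀(mass in kDa) = s·d + b` fit by ordinary least squares to the
ladder's migration distances `d`, then
`n = round((mass − Σ retained tag masses) / m̄)` with mean residue mass
`m̄ = 110 Da`. An epitope-detected fragment must satisfy the overlap
condition `max(0, min(a, e₂) − max(x+1, e₁)) > 0` (the *difference*
convention, not inclusive counting).

Inferred sites are matched to protease motifs (trypsin: K or R not
followed by P) within a sequence window (default 20 residues), classified
into a structured-domain/linker annotation, and clustered across lanes
(radius 5 residues); a membrane-state cluster with no cytosol-state
counterpart is an unmasked site. Optionally, sites are annotated on a
structure model with Shrake–Rupley solvent accessibility (relative SASA ≥
0.25 ⇒ surface-exposed) and with spatial neighbors (min heavy-atom
distance ≤ 5 Å, |Δposition| > 4) that could mask them in the closed state.

Two auxiliary computations from the same kind of study are included:
helical-wheel projections (100°/residue, charge-shaped markers,
hydrophobicity color ramp) and Golgi-fraction image quantification (red
organelle mask at mean + 5 SD, green cell mask at the mean, percent of
in-cell green intensity inside the organelle mask).

## Worked example

The packaged demo reproduces the GBF1 analysis from its fragment series
(three C-tag-detected membrane fragments of 600/545/490 residues anchored
at the tagged C-terminus 1859; seven epitope-detected fragments of
1136/972/845/709/672/627/436 residues anchored at the assumed cleavage
1314):

```bash
lpfoot run --demo --out-dir demo_out
```

prints

```
10 calls; 10 unmasked sites (structured: 4, linker: 6)
report: demo_out/calls.tsv
```

and `demo_out/calls.tsv` begins

```
calculated_site  anchored_end  anchor  condition  adjacent_motifs  region                      region_kind  unmasked
178              C             1314    membrane                    DCB                         structured   True
342              C             1314    membrane                    linker between DCB and HUS  linker       True
...
1369             C             1859    membrane                    linker between HDS2 and HDS3  linker     True
```

Reading: the 1136-residue epitope fragment anchored at 1314 places a new
cleavage at 1314 − 1136 = 178, inside the structured DCB domain; across
both detection series ten distinct sites are cleaved on membranes but not
in the cytosol — the footprint of a substantial conformational opening.
The same library calls are available programmatically
(`lpfoot.infer_site`, `lpfoot.call_unmasked_sites`, …), and
`lpfoot simulate` writes a fully synthetic scenario (sequence, annotation,
ladder, bands, images, ground-truth JSON) for pipeline validation.

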