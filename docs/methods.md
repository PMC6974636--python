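# Methods

## Mass model

All arithmetic is exact integer bookkeeping over elemental formulas,
evaluated to monoisotopic masses only at the report surface. The constants
are fixed in one table (`lanthimass.formula.MONOISOTOPIC_MASS`):
C 12 (exact), H 1.00782503207, N 14.0030740048, O 15.9949146196,
S 31.97207100, plus P and Se for extensibility; the proton is
1.007276466621 Da. Protonation uses the proton mass rather than the
hydrogen-atom mass: the electron mass (0.00055 Da) already moves the
fourth decimal of a z = 2 ion, so "[M+2H]/2 with H-atom masses" would be
wrong at the precision reported here. Report surfaces round half-even to
4 dp (m/z) and 2 dp (ppm); everything internal is full precision.

The modification algebra is:

* dehydration (Ser→Dha, Thr→Dhb): −H2O per site;
* thioether cyclisation (Dha/Dhb + Cys → Lan/MeLan) and lysinoalanine
  formation: atom-neutral — the dehydration already paid the mass;
* Asp β-hydroxylation: +O per site (toggled off for "deoxy" species);
* desulfurization of k thioether bridges: −k·S + 2k·H. The lysinoalanine
  bridge has no sulfur and survives reduction.

A free N-terminus and free C-terminal acid are assumed (no amidation),
which is consistent with the reference formulas of this family.

## Structure configurations

Topology is data, not code: a YAML config carries the core sequence,
dehydration positions, thioether bridge pairs (one Cys member each), the
lysinoalanine pair and hydroxylation sites, all 1-based. The packaged
kyamicin, cinnamycin and duramycin configs share the family scaffold —
bridges 1–18, 5–11, 14–4, lysinoalanine 6–19, hydroxy-Asp15 — so a new
family member is a config file, not a code change. Leader peptide removal
is modelled as a fixed-length C-terminal cut (default 19 residues), since
the family's cores are uniformly the 19 C-terminal residues of their
precursors and no protease recognition rule is part of this model.

The duramycin core sequence is the published one and reproduces its
reference molecular formula C89H125N23O25S3 exactly through the algebra
above, which validates the residue table end to end. The kyamicin core
sequence is only published as a figure, not as machine-readable text; the
packaged sequence is reconstructed from the stated constraints — the
fixed bridge scaffold (Cys1/Thr4/Cys5/Ser6/Thr11/Cys14/Asp15/Thr18/Lys19),
six residue differences from cinnamycin and duramycin at family-variable
positions, and above all the mature-formula identity C76H108N20O25S3,
which it satisfies exactly. Every whole-molecule quantity the package
reports is invariant to any residue choice satisfying that identity;
individual y-ion m/z values do depend on it and should be treated as
provisional until checked against a measured fragment spectrum.

## Fragmentation

Tandem MS of these molecules is read after nickel-boride reduction. The
whole-molecule −S +2H shift per bridge is apportioned to the bridge
members as Cys → Ala and Dhb/Dha → Abu/Ala, matching the hydride
chemistry; the apportionment matters because fragment masses sample
individual residues. When a backbone cleavage severs the lysinoalanine,
the observed fragments correspond to a glycine residue at the Dha
position and lysine with a terminal N=CH2 (+CH2 −2H, net +C) — fixed here
by atom conservation: the two substituted residues together equal the
intact Dha + Lys pair exactly, so complementary fragments always sum to
the full molecule. Spans containing both partners are
composition-identical either way. y ions are generated as the C-terminal
n residues + H2O, singly protonated (MALDI convention); b ions and
internal fragments are not generated. The exact hydrogen bookkeeping at
the severed site is a mechanistic inference; if matching against a real
spectrum ever shows a systematic ±1 Da offset on rearranged ions, that
should be surfaced rather than absorbed (the `rearranged` flag on each
ion exists so reports make the affected subset visible). For partial
reduction (k smaller than the bridge count) the first k bridges in config
order are treated as reduced; the experimentally relevant case is full
reduction, the default.

## Annotation

Screening computes, per (species variant, charge), the nearest observed
peak in signed ppm and flags detection iff |ppm| ≤ tolerance. The default
tolerance is 10 ppm — routine high-resolution instrument accuracy is a
few ppm, and the largest identity-assignment error in the reference data
is 3.40 ppm, so 10 ppm covers it with margin while the decoy density in
realistic peak lists stays negligible at these masses. Equidistant peaks
tie-break to the more intense, then the lower m/z, making reports
deterministic. Retention time is carried through but never used to match.
Calculated m/z is reported both at 4 dp and at the 2 dp precision used
for extracted-ion-chromatogram windows.

A note on the reference table this package is checked against: four of
its seven printed calculated m/z values sit exactly one 4th-decimal unit
below what any standard monoisotopic computation gives (verified
independently with pyteomics), and its printed ladder spacings disagree
with each other at that digit, so the printed column cannot be reproduced
simultaneously by any fixed constant set. The package reports the
computed values; the discrepancy is ≤ 0.12 ppm, far inside any tolerance
used for identity assignment, and the corresponding strict test cases are
intentionally left failing as a record of the disagreement.

## Synthetic data

`simulate_peaklist` plants each species' predicted m/z perturbed by
ε ~ N(0, σ²) in ppm (default σ = 2 ppm, the routine calibrated-instrument
error scale bounded by the reference data's |3.40| ppm worst case),
drops peaks with a configurable probability, and adds uniform decoys over
the m/z range, excluded from ±3σ windows around true peaks so recovery
statistics are unambiguous. Intensities are log-normal (median 10⁴,
log-sd 1 — typical peak-height dynamic range; intensities never affect
matching except in exact ties). One integer seed drives a single
`numpy.random.Generator`; no global state. The generator makes single
monoisotopic sticks: no isotope envelopes, charge-state envelopes or
chromatographic peak shape, so passing recovery tests demonstrates the
correctness of the m/z bookkeeping and matching logic, not robustness to
deconvolution artefacts in raw instrument data.

`simulate_variant_structures` resamples random valid topologies (10–24
residues, 0–3 bridges, optional lysinoalanine ordered Dha-before-Lys,
optional hydroxylations) as fuel for the conservation and round-trip
property tests.

## Problem sizes and determinism

All headline checks are desk-scale: formulas of ~230 atoms, ladders of 18
ions, peak lists of tens of peaks. Monte-Carlo checks use 100–250 seeds
(recovery, error-scale calibration), which bounds binomial/χ² noise well
below the asserted margins while keeping the whole suite in seconds.
Hypothesis runs derandomised with 50 examples per property.

## Known limitations

* Proton adducts only (no Na+/K+), monoisotopic only (no averagine or
  isotope-pattern simulation).
* Stereochemistry is out of scope; formulas cannot distinguish it.
* The kyamicin y-ion ladder inherits the provisional core-sequence
  residues at non-scaffold positions (see above).
* mzML ingestion is not implemented; peak lists enter as CSV.
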