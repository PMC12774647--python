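# Methods

## The step descriptor and its measurement

A dinucleotide step is the sugar-to-sugar unit of two consecutive
nucleotides joined by the central phosphodiester linkage. Two residues form
a step when the O3′(i)–P(i+1) distance is at most the connectivity cutoff
(default 2.0 Å; the typical covalent bond is ≈1.6 Å, so the cutoff tolerates
strained links while rejecting chain breaks) and all descriptor atoms are
present. Each step is reduced to 12 parameters: seven backbone torsions
(δ₁ ε₁ ζ₁ α₂ β₂ γ₂ δ₂, standard atom quadruples), two glycosidic torsions
(χ, measured O4′–C1′–N9–C4 for purines and O4′–C1′–N1–C2 for pyrimidines),
the distance NN between the glycosidic nitrogens, the C1′–C1′ distance CC,
and the N–C1′–C1′–N pseudo-torsion μ. Torsions follow the IUPAC sign
convention and are reported in (−180°, +180°]; all distances are in Å.
Hydrogens are ignored throughout; every quantity is heavy-atom based.

Degenerate torsion frames (cross-product norm < 1e−10) raise an error
naming the torsion rather than returning a garbage angle. Superposition
uses the SVD construction with the determinant correction that forbids
reflections; rank-deficient point sets are rejected.

## Classification

The candidate class of a step is the argmin over the reference table of the
tolerance-scaled distance d = √(Σⱼ (Δⱼ/wⱼ)²), with wrapped angular
differences. Ties are broken by table order, and tables are sorted
alphabetically at load so the tie-break is deterministic. The assignment is
then gated in Cartesian space: the 14-atom sugar-to-sugar set (C5′ C4′ C3′
O3′ C1′ + glycosidic N of residue 1; P O5′ C5′ C4′ C3′ O3′ C1′ + N of
residue 2) is superposed onto the candidate's representative, and an RMSD
above the NANT threshold (default 0.5 Å, configurable) demotes the step to
NANT/NAN while retaining the candidate, RMSD, confal and deviation vector
as diagnostics. The 0.5 Å default mirrors the quality cutoff used to select
reference-grade steps; distances approaching 0.8 Å and beyond indicate
conformations remote from every class. Whether an authoritative
implementation gates NANT on parameter-space distance, Cartesian RMSD or
both is not publicly specified; gating on RMSD with full diagnostics
retained was chosen because it keeps the two spaces in an interpretable
relationship (candidate from parameter space, rejection from Cartesian
space).

The confal functional form is a per-parameter Gaussian kernel
sⱼ = 100·exp(−ln2·(Δⱼ/wⱼ)²) combined as a geometric mean. The published
anchors for the score are only its endpoints (0 = no match, 100 = perfect
match); this form reproduces both, is strictly decreasing in each |Δⱼ|, and
makes a one-tolerance deviation exactly halve a parameter's contribution
(a single such deviation gives 100·0.5^(1/12) ≈ 94.4). It should be read as
this toolkit's confal, not a bit-for-bit reimplementation of any published
scoring constant. A structure-level confal is the geometric mean over steps
(NANT steps contribute their diagnostic value); its percentile is reported
only when the user supplies a calibration population, since shipping one
would require a database-wide survey.

## Valence-geometry validation

Each dictionary bond/angle present in a residue is measured directly
(distance / interior planar angle); phosphodiester linkage terms (O3′–P,
C3′–O3′–P, O3′–P–O5′) are measured across covalently continuous residue
pairs. Scores against a reference distribution:

* **ProSco** = 200·min(F, 1−F) where F is the Hazen empirical-CDF position
  (rank − 0.5)/n with linear interpolation, clamped to 0 beyond the sample
  range. The Hazen convention is symmetric and makes "ProSco ≥ 5 ⇔ central
  95%" hold exactly: on any tie-free sample scored against itself, exactly
  95% of points satisfy it (the script and suite verify 95.0% on a
  100,000-point seeded normal sample).
* **Z′** = (x − median)/(1.4826·MAD). The source material calls Z′ only a
  "non-parametric standard score"; median/MAD with the normal-consistency
  constant is the standard robust choice and is documented here as an
  interpretation.
* **Tier**: Preferred inside the union of the ProSco ≥ 5 interval (the
  [2.5th, 97.5th] Hazen percentiles, computed on the raw sample without
  smoothing) and the CSD-style mean ± 3σ interval — the more permissive
  boundary on each side; otherwise Allowed when |Z′| ≤ 5; otherwise
  Of Concern.
* **Support**: with k the number of reference values within ±win of x
  (win = 0.01 Å for bonds, 1.0° for angles; k_min = 3): Unique if k = 0,
  Common if ProSco ≥ 5, Rare if k ≥ k_min, else Ambiguous. The window and
  k_min are heuristics — the published scheme names the four categories and
  one worked point but no boundaries — and are configurable.

## Synthetic fixtures: what they emulate and what they do not

`build_oligonucleotide` grows heavy-atom chains by sequential NeRF
placement from ideal bond lengths/angles (packaged in
`data/ideal_geometry.csv`) and caller-supplied step torsions. Sugar rings
and bases use a fixed internal template (idealized planar bases, one ring
pucker), so re-measuring a built fragment recovers the requested torsions
to 1e−6 and NN/CC/μ are functions of the torsions alone — in particular
they are independent of the base sequence, because the glycosidic nitrogen
is placed identically for purines and pyrimidines. Real structures have
sequence-dependent base geometry, variable sugar pucker, thermal
displacement and correlated coordinate error, none of which the generator
reproduces; passing tests therefore demonstrate the correctness of the
measurement/classification/validation machinery, not the field accuracy of
the packaged reference values. Torsion noise (Gaussian, per placed torsion)
and coordinate noise (isotropic Gaussian) are seeded and reproducible.

Where consecutive steps both constrain a shared residue's δ/χ, the 5′-side
step wins (residue 0 takes d1/ch1 of step 0; residue i ≥ 1 takes d2/ch2 of
step i−1). The first residue's γ is not a step parameter and defaults to
54°.

## The packaged class table

The shipped table is synthetic and self-consistent, not an authoritative
published class table. All 96 classes share the canonical-form sugar and
glycosidic torsions (δ = 84°, χ = −160°) and differ in the five linkage
torsions ε₁ ζ₁ α₂ β₂ γ₂, drawn from evenly strided points of the 60°-spaced
6⁵ grid; any two distinct grid points differ by ≥60° (wrapped) in at least
one coordinate, i.e. ≥6 tolerance units at the 10° linkage tolerance, so
nearest-class assignment has a clear margin everywhere. Holding δ/χ common
across classes also makes any concatenation of class means internally
consistent — a shared residue's δ/χ cannot satisfy two different classes at
once — which is what lets noiseless synthesized oligonucleotides recover
their generating classes with RMSD ≈ 0. NN/CC/μ means are measured from the
built representative of each class, so table self-consistency (representative
re-measures to the stored means within 0.5°/0.05 Å, checked at every load)
holds by construction. Tolerances default to 10° for linkage torsions, 15°
for δ/χ, 0.5 Å for NN/CC and 25° for μ. Class names are family prefix +
index; the 14 CANA family codes use the code names current in the NtC
literature (AAA, AAw, AAu, A-B, B-A, BBB, BBw, B12, BB2, miB, ICL, OPN,
SYN, ZZZ), with NAN reserved for unassigned steps. Representative
coordinates are rebuilt deterministically from the stored torsions at load
time rather than shipped as 96 coordinate files; an external table may
instead point each class at an mmCIF fragment.

## Restraints

Nine torsion restraints per step (δ₁ ε₁ ζ₁ α₂ β₂ γ₂ δ₂ χ₁ χ₂), targets at
the class means wrapped into (−180°, 180°], sigma = class tolerance/2 with
a 2° floor (or a fixed user value). The generic CSV dialect round-trips
exactly and is the one the tests parse; the Refmac/Phenix/BUSTER templates
follow each program's documented restraint style but vendor keyword syntax
varies between versions, so they are best-effort text intended for
post-editing. Macromolecule-builder output is not supported.

## I/O and CLI conventions

Parsing and serialization go through gemmi. Analysis defaults to model 1
(`--model` overrides); alternate locations resolve to the highest-occupancy
atom with alphabetical tie-break (deterministic outputs), or to a requested
label. Modified nucleotides map to parents through a packaged component
table; unknown components are skipped with a logged warning rather than
guessed. Annotated mmCIF carries the `_ntc_step` and `_ntc_valgeom`
categories; these names are stand-ins, not dictionary-conformant category
definitions. Exit codes: 0 success, 2 parse failure, 3 no nucleic-acid
content, 4 bad restraint edit. Identical inputs and configuration produce
byte-identical CSV/JSON outputs.

## Problem sizes

The test suite and acceptance script run on synthetic fragments of 2–13
residues, 200-vector assignment sweeps, and a 100,000-point ProSco
calibration sample; the full suite completes in well under a minute on one
CPU.

## Known limitations

* The packaged table's numeric values are generated, not fitted to
  experimental conformer populations; real-data classification requires
  importing an authoritative table.
* One sugar-pucker template: pseudorotation phase/amplitude is neither
  varied in fixtures nor reported.
* No base-pair classification, no density-based scores, no symmetry/
  assembly expansion; steps never span chains or models.
* Reference distributions for validation are user-supplied or synthetic;
  the toolkit does not build them from the PDB.
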