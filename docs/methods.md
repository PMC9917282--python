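# Methods

## Structure model

Structures are read from PDB files (gemmi parser) into a light hierarchical
model: protein chains of residues in author numbering, plus retained hetero
groups (ligands). Author numbering is the public coordinate system throughout,
because every residue identity of interest (S532, D617, H652, R150/R151,
S618/Q619/Q621 in SpOpB; E172, R650, S563/D648/H683 in TbOpB) is quoted that
way in the literature. Alternate locations are collapsed to the
highest-occupancy conformer (ties broken by altloc letter); waters are dropped;
hydrogens are ignored everywhere — crystal structures at ~2 Å have none, and
keeping the contact criteria heavy-atom-only keeps them uniform across inputs.
Multi-chain files default to the first protein chain, overridable.

## Domain partition and reference numbering

The two-domain split is interval-based: N-terminal loop | hinge 1 |
β-propeller | hinge 2 | α/β-hydrolase fold, with the catalytic domain defined
as N-loop ∪ hydrolase (the propeller interrupts it in sequence). The SpOpB
preset uses hinge 1 = 71–77 (the IPQQEH hinge peptide) and hinge 2 = 407–413,
reconstructed from the blade-7/hinge-2 contact residues (K407, N408, T410,
N413); the propeller end is therefore an implementer's choice and both hinge
intervals are config-overridable. The TbOpB preset is obtained by mapping the
SpOpB boundaries through the packaged pairwise alignment.

Residue-position bookkeeping across homologs uses pairwise global alignment
(BLOSUM62, gap open 10, extend 0.5, free end gaps; Biopython's
`PairwiseAligner`) against a packaged reference, rather than a multiple
alignment: for reading out two or three anchor columns per sequence the
pairwise mapping is equivalent and testable without an MSA engine. Alignment
identity is reported as matches over the reference length (robust against
gap-fragmented alignments of unrelated sequences); below 15% the mapping is
flagged unreliable rather than rejected.

The packaged reference sequences are **synthetic stand-ins** (see
`src/s9conf/data/README_data.md`): deterministic scaffolds carrying the
documented catalytic and anchor residues at the documented author positions,
with the documented SpOpB↔TbOpB numbering offsets (151→172, 532→563,
619→650). They exercise every mapping and generator code path; they are not
the UniProt entries, and identities against real proteins are not claimed.
Real reference sequences can be dropped in by replacing the two FASTA files.

## Geometry

Triad measurement returns the four discriminating distances: Cα(S)–Cα(H),
OG(S)–NE2(H), Cα(H)–Cα(D), ND1(H)–OD(D). The His–Asp functional distance is
reported both against OD2 specifically and as the minimum over OD1/OD2 — the
carboxylate oxygens are crystallographically interchangeable, and the
assembled test uses the minimum. A missing Ser OG (S→A mutants) is tolerated
and flagged, mirroring the "n/a" such structures print.

The domain separation is the distance between mass-weighted heavy-atom
centers of the catalytic domain and the propeller, hinges excluded from both.
Mass weighting (not Cα-only) is a design choice; the ±1 Å tolerance used when
reproducing published separations absorbs both this ambiguity and the
partition-boundary ambiguity.

Superposition is classical Kabsch via SVD over paired Cα atoms, with an
explicit degeneracy check (second singular value ≈ 0 ⇒ collinear input). The
test suite cross-checks it against SciPy's independent quaternion-based
`Rotation.align_vectors`.

## Solvent accessibility and interface census

SASA is an in-house Shrake–Rupley implementation: van der Waals radii
C 1.70 / N 1.55 / O 1.52 / S 1.80 Å, probe 1.4 Å, and a deterministic
golden-spiral point set (default 960 points/atom, ~1% quadrature error;
verified against analytic one- and two-sphere solutions and against biotite's
implementation). Buried surface % of a domain = (isolated SASA − SASA in the
two-domain assembly) / isolated SASA × 100; a residue is interfacial if it
buries > 0.1 Å² (operational threshold, config-overridable).

Polar contacts are heavy-atom distance criteria only (no angle terms, since
there are no hydrogens): hydrogen bond = N/O–N/O across groups at ≤ 3.5 Å;
salt bridge = Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 versus Asp OD1/OD2,
Glu OE1/OE2 at ≤ 4.0 Å. One contact is reported per (residue pair, kind) at
its minimal-distance atom pair. Absolute hydrogen-bond *counts* depend on
unpublished criteria of the original interface service; they are reported
with the cutoffs used and only the closed > open ordering is treated as
meaningful.

## State and mode classification

* **closed** ⇔ triad assembled: OG–NE2 ≤ 4.5 Å and ND1–OD ≤ 4.0 Å. The
  cutoffs sit in the wide no-man's-land between closed-state values
  (2.8–3.5 / 3.0–3.1 Å) and open/intermediate values (≥ 8.8 Å).
* else **intermediate** if catalytic-domain buried surface ≥ 10%, else
  **open**. The 10% boundary is a quantization of the published qualitative
  criterion, placed between the intermediate (11.7%) and open (8.8%)
  exemplars; no single numeric rule is published, so the boundary is
  config-overridable and every report embeds the thresholds used.
* S→A mutants (no OG) fall back to a Cα-only closed test (Cα(S)–Cα(H) ≤ 10 Å,
  between the closed 7.9–8.3 Å and open 17.4–18.5 Å exemplars) and the call
  is flagged `mutant_inference`.

Stabilization mode reads the anchor residues through the reference map:
Glu/Asp at the 151-equivalent + Arg at the 619-equivalent with a side-chain
salt bridge ≤ 4 Å ⇒ **SB1**; Arg + Gln there with ≥ 2 contacts of the RR–SQ
web (R151↔Q619, S618↔Q619 side chains, S618↔R150 backbone O, R150↔Q621)
≤ 4 Å ⇒ **complementary surface**; anything else is **undetermined** with the
evidence listed. The S618↔Q619 contact is intra-loop; it participates in the
evidence web but alone (e.g. in an opened structure) never suffices. Charge
complementarity is thus detected from residue identities and contact
distances, not from an electrostatic continuum calculation.

## Sequence grouping

Sequences shorter than 500 residues are binned `short` without alignment
(they cannot span both anchors). Otherwise the residues at the 151- and
619-equivalents decide: (R, Q) → `SpOpB_like`, (E/D, R) → `TbOpB_like`,
anything else → `other`. Anchors falling into alignment gaps are counted
`other` with a separate `unresolved_anchor` flag, since it is not published
whether the original "other" bin included them. Ambiguity codes (B/Z/X) at an
anchor also go to `other`. Tallies aggregate counts and fractions per taxon
at a requested rank of a plain lineage table (no live database queries —
reproducibility over completeness); consensus/column-frequency tables use
plurality per column (gap wins only with > 50%) and are written in a form any
logo renderer consumes.

## Kinetics

The headline estimator is the classical graphical method: unweighted
OLS of ln(activity) on time per concentration (k′ = −slope), then unweighted
OLS of 1/k′ on 1/[I] (k₂ = 1/intercept, K_i = slope·k₂). Concentrations enter
in µM; K_i is reported in mM (explicit conversion), k′ and k₂ in min⁻¹. A
non-positive reciprocal intercept means saturation was never approached and
k₂ is not identifiable (error); k′ independent of [I] gives a degenerate
K_i = 0 flag. A direct nonlinear fit of k′ = k₂[I]/(K_i+[I]) is provided as a
cross-check, not the headline estimator. Residual activity is interpreted as
fraction-of-initial ([E]/[E₀] ∈ (0, 1]); the normalization convention of the
source experiments is unstated, and this is the assumption both the simulator
and the fitter share.

## Synthetic generators

All generators are pure functions of (spec, seed) and emit machine-readable
truth records.

**Toy structures.** Each domain is a rigid oblate ellipsoid (semi-axes
6.5 × 13 × 13 Å) of alanine-like residues on a 4.2 Å grid with ±0.3 Å seeded
jitter; the flattened faces meet across the separation axis, giving ~20%
catalytic-domain burial at contact, decaying through the 10% classifier
boundary by ~2.5 Å of opening and to zero by ~6 Å — the closed→intermediate→
open pattern at realistic magnitudes. Functional side-chain atoms (triad,
SB1 Glu/Arg, RR–SQ web) are placed by explicit coordinates, so planted
distances are exact by construction; all cross-domain planted vectors run
along the separation axis, so opening by s lengthens each interdomain planted
distance by exactly s. Triad disassembly stretches the His *laterally* (the
H-loop swings to the domain periphery, as in the real mechanism), never into
the propeller. `closure_trajectory(delta)` couples separation and triad
stretch into a single opening coordinate. What the toys do **not** emulate:
real secondary structure, side-chain rotamers, realistic packing density or
absolute COM separations (~13 Å at contact versus ~30 Å in the real enzyme);
passing planted-recovery tests therefore demonstrates the correctness of the
measurement/classification chain, not crystallographic accuracy.

**Sequence sets.** Labelled groups are derived from the packaged references
by point substitution at a given off-anchor rate (group-defining anchors held
fixed); `other` gets non-matching anchors (K/M), `short` gets truncations to
320–499 residues. The default study-condition proportions are 53/34/2/11%
(SpOpB-like/TbOpB-like/other/short), the reported composition of the bacterial
OpB sequence universe. A lineage table emulates the reported taxonomic bias
(SpOpB-like enriched in FCB/Acidobacteria/Gammaproteobacteria, TbOpB-like in
Terrabacteria/Alphaproteobacteria). No indels are introduced, so anchor
recovery failures measure classifier robustness to substitution noise only.

**Inactivation curves.** activity(t) = exp(−k′t) with k′ = k₂[I]/(K_i+[I]);
default parameters are the reported point estimates K_i = 0.28 mM,
k₂ = 0.27 min⁻¹ at the reported titration range 50–260 µM, t = 0–20 min.
Optional multiplicative lognormal noise; activities are clipped into (0, 1]
to remain valid fractions.

## Numerical choices and problem sizes

Fixed sphere-point sets make SASA deterministic; reports are byte-stable for
fixed inputs and seeds. Consensus ties break by count then alphabetically.
The test suite runs interface metrics at 240 sphere points where only
orderings or planted labels are asserted and at the 960-point default where
absolute percentages matter; sequence-recovery properties use n = 1000
sequences (the planted 53/34/2/11 composition); the kinetics Monte-Carlo uses
200 replicates at 5% noise.

## Known limitations

* The intermediate/open boundary is a reconstruction; structures near 10%
  catalytic-domain burial can flip with the threshold (which is why it is
  embedded in every report).
* Hydrogen-bond counts are cutoff-dependent and not comparable in absolute
  terms to interface services that use angle terms or energy models.
* The packaged reference sequences are synthetic stand-ins; mapping real
  distant homologs benefits from replacing them with the true UniProt
  sequences.
* Kitz–Wilson linearization weights errors non-uniformly; for noisy data the
  nonlinear cross-check is the better estimator (both are reported).
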