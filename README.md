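# s9conf

Conformational-state analysis of two-domain S9-family peptidases, sequence
grouping of oligopeptidases B, and Kitz–Wilson irreversible-inhibition
kinetics.

## The problem

Peptidases of the prolyl oligopeptidase (S9) family — including oligopeptidase
B (OpB), a virulence factor of trypanosomatid parasites and a player in
bacterial resistance to antimicrobial peptides — couple a C-terminal
α/β-hydrolase catalytic domain to a seven-bladed β-propeller. Catalysis
requires the **closed** conformation: domains packed together, the
Ser/His/Asp triad assembled with its functional atoms at hydrogen-bond range.
In the **open** state the domains separate and the triad is disrupted; the
**intermediate** state keeps the domains close but the triad apart. The state
of a structure (crystallographic or predicted) can be read off a handful of
numbers:

* triad geometry — Cα(S)–Cα(H), OG(S)–NE2(H), Cα(H)–Cα(D), ND1(H)–OD1/OD2(D)
  distances (closed: OG–NE2 ≈ 2.8–3.5 Å; open: > 18 Å);
* domain center-of-mass separation (closed ≈ 30 Å, open ≈ 37 Å in OpB);
* buried surface area of each domain as % of its isolated surface, interface
  residue percentages, and the interdomain hydrogen-bond / salt-bridge census.

In the closed state the loop carrying the catalytic Asp (the D-loop) is held
in place by the facing β-propeller loop in one of two ways that split
bacterial OpBs into two large groups:

* **SB1** (TbOpB-like, ~34% of bacterial OpBs): a single interdomain salt
  bridge between a propeller Glu/Asp and a D-loop Arg (E172–R650 in TbOpB
  numbering);
* **RR–SQ complementary surfaces** (SpOpB-like, ~53%): a pair of neighbouring
  propeller arginines (R150/R151) wrapping the Ser/Gln pair after the
  catalytic Asp (S618/Q619, plus Q621).

The group membership of any OpB sequence is decided by the residues at two
alignment-anchored positions (SpOpB 151 and 619): Arg-Gln → SpOpB-like,
Glu/Asp-Arg → TbOpB-like; sequences under 500 residues are "short", the rest
"other".

Finally, irreversible inhibition of the enzyme by an active-site alkylating
inhibitor follows the two-step mechanism E + I ⇌(K_i) EI →(k₂) EI′ under
pseudo-first-order conditions, giving ln[E] = −k′t + ln[E₀] with
k′ = k₂[I]/(K_i + [I]); the double-reciprocal line 1/k′ = (K_i/k₂)(1/[I]) + 1/k₂
yields k₂ from the intercept and K_i from slope × k₂ (Kitz–Wilson analysis).

`s9conf` implements all three analyses as a tested library plus CLI, together
with seeded synthetic-data generators (planted-truth toy structures, labelled
sequence sets, simulated inactivation curves) that close the loop in the test
suite.

## Worked example

Generate a planted trio of toy two-domain structures along the closure
trajectory and classify them:

```sh
$ s9conf synth --kind structures --out toys --seed 1
$ s9conf classify --pdb toys/toy_sep0_RRSQ.pdb --pdb toys/toy_sep2_RRSQ.pdb \
                  --pdb toys/toy_sep8_RRSQ.pdb --out report --sasa-points 240
                                        toy_sep0_RRSQ toy_sep2_RRSQ toy_sep8_RRSQ
metric
conformation                                   closed  intermediate          open
stabilization_mode              complementary_surface  undetermined  undetermined
ca_S_H_A                                     7.129718     10.301097     20.675049
og_S_ne2_H_A                                 2.799912      6.399965     17.200054
ca_H_D_A                                     5.268389      7.245131     13.216412
nd1_H_od2_D_A                                     3.0           5.0          11.0
center_of_mass_distance_A                     12.9058     14.961335     21.131185
bsa_percent_cat                             19.949022     11.969965           0.0
bsa_percent_prop                            21.296956     13.052028           0.0
...
```

Reading the columns: the contact pose has an assembled triad (OG–NE2 2.8 Å,
within hydrogen-bond range) and ~20% of the catalytic domain surface buried,
so it is called closed, and the planted RR–SQ web is detected as the
complementary-surface stabilization mode. Opening the domains by 2 Å
disassembles the triad (6.4 Å) while the interface persists (12% > 10%
threshold) — intermediate; at 8 Å the interface is gone — open.

Kinetics, from simulation to fit:

```sh
$ s9conf synth --kind kinetics --out kin
$ s9conf kinetics --csv kin/inactivation.csv --out kinfit
{
 "Ki_mM": 0.28,
 "k2_per_min": 0.27,
 "r_squared": 1.0
}
```

The simulated titration (50–260 µM inhibitor) is refit through the
ln-activity slopes and the double-reciprocal line, recovering the generating
constants K_i = 0.28 mM and k₂ = 0.27 min⁻¹ exactly in the noiseless case.

Sequence grouping runs the same way: `s9conf synth --kind sequences` writes a
labelled FASTA + lineage table, and `s9conf motif --fasta … --taxonomy … --rank
superphylum` writes per-sequence anchor calls and per-taxon group tallies.

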