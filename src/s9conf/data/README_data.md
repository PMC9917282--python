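# Packaged reference data

`spopb_reference_synthetic.fasta`, `tbopb_reference_synthetic.fasta`

Synthetic stand-in reference sequences for the two oligopeptidase B anchors
of the numbering system (SpOpB, *Serratia proteamaculans*; TbOpB,
*Trypanosoma brucei*). They are **not** the UniProt entries: each is a
deterministic pseudo-random scaffold carrying the documented catalytic and
anchor residues at the documented author positions —

* SpOpB (685 aa): catalytic S532/D617/H652, nucleophile-elbow G-x-S-x-G,
  hinge-1 peptide IPQQEH at 71–76, R/E-loop S149/R150/R151, D-loop
  T613/L615/H616/D617/S618/Q619/V620/Q621, H-loop M648–K660 residues, and the
  interdomain-contact residues of the closed-state census.
* TbOpB (716 aa): the same scaffold with a 21-residue insertion in the
  N-terminal loop and a 10-residue insertion in the propeller, heavy
  off-window divergence, and the TbOpB-defining residues E172, S563, D648,
  R650, H683 — reproducing the documented cross-numbering (151→172, 532→563,
  619→650).

Pairwise anchor mapping, domain presets, and the sequence generators are
exercised against these; sequence identities to the real proteins are not
claimed.
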