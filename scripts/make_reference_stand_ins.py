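"""Regenerates the packaged synthetic reference stand-ins (src/s9conf/data).

The outputs are committed; rerunning must be byte-stable (fixed seed).
"""
import numpy as np

AAS = "ACDEFGHIKLMNPQRSTVWY"
rng = np.random.default_rng(20230124)

L_SP = 685
sp = list(rng.choice(list(AAS), size=L_SP))

def plant(seq, pos, letters, offset=0):
    for i, ch in enumerate(letters):
        seq[pos - 1 + i + offset] = ch

# documented residues at documented author positions (SpOpB numbering)
plant(sp, 71, "IPQQEH")            # hinge1 peptide
plant(sp, 146, "DSGSRRWLD")        # R/E loop: S149 R150 R151, D146/D154 ends
plant(sp, 530, "GASAG")            # nucleophile elbow G-x-S532-x-G, A533
plant(sp, 613, "TALHDSQVQAA")      # D-loop/alpha11: T613 L615 H616 D617 S618 Q619 V620 Q621
plant(sp, 648, "MDSGHGAKSARFK")    # H-loop: M648 S650 G651 H652 G653 K655 S656 R658 F659 K660
singles = {
    31: "D", 33: "R", 68: "V", 70: "R", 92: "E", 95: "N", 96: "E", 97: "Y",
    121: "A", 124: "R", 125: "E", 127: "Y", 194: "K", 222: "D", 244: "T",
    291: "K", 292: "N", 317: "M", 333: "R", 336: "G", 357: "D", 359: "T",
    361: "T", 380: "S", 382: "M", 407: "K", 408: "N", 410: "T", 412: "E",
    413: "N", 416: "S", 418: "R", 433: "L", 452: "Y", 455: "Y", 458: "S",
    460: "D", 461: "P", 463: "F", 487: "E", 488: "L", 490: "Q", 491: "L",
    494: "E", 558: "F", 574: "T", 575: "G", 576: "E", 578: "D",
    662: "Y", 663: "E", 664: "D",
}
for p, ch in singles.items():
    sp[p - 1] = ch
sp = "".join(sp)
assert len(sp) == 685
assert sp[531] == "S" and sp[616] == "D" and sp[651] == "H"
assert sp[149] == "R" and sp[150] == "R" and sp[617] == "S" and sp[618] == "Q" and sp[620] == "Q"

# Conserved windows shared with the TbOpB stand-in (SpOpB coordinates);
# everything outside is mutated at high rate to push identity to ~40%.
windows = [(66, 80), (90, 100), (120, 130), (144, 156), (190, 198), (240, 248),
           (288, 296), (330, 340), (355, 365), (378, 386), (405, 420),
           (450, 465), (485, 496), (528, 540), (555, 562), (572, 580),
           (610, 626), (645, 666)]
conserved = set()
for lo, hi in windows:
    conserved.update(range(lo, hi + 1))

tb = list(sp)
for i in range(L_SP):
    pos = i + 1
    if pos in conserved:
        continue
    if rng.random() < 0.62:
        choices = [a for a in AAS if a != tb[i]]
        tb[i] = choices[rng.integers(len(choices))]

# insertions: 21 residues after SpOpB position 50 (N-loop), 10 after 300
ins1 = "".join(rng.choice(list(AAS), size=21))
ins2 = "".join(rng.choice(list(AAS), size=10))
tb = tb[:50] + list(ins1) + tb[50:300] + list(ins2) + tb[300:]
assert len(tb) == 716

def off(p):  # SpOpB -> TbOpB author position
    if p <= 50:
        return p
    if p <= 300:
        return p + 21
    return p + 31

# TbOpB-defining residues (TbOpB numbering): E172/R650 replace R151/Q619;
# the RR-SQ neighbours are not conserved in the TbOpB-like group.
tb[off(150) - 1] = "T"   # 171: no second Arg
tb[off(151) - 1] = "E"   # 172: SB1 glutamate
tb[off(618) - 1] = "G"   # 649
tb[off(619) - 1] = "R"   # 650: SB1 arginine
tb[off(621) - 1] = "A"   # 652
tb = "".join(tb)
assert tb[562] == "S" and tb[647] == "D" and tb[682] == "H"   # S563 D648 H683
assert tb[171] == "E" and tb[649] == "R"

ident = sum(a == b for a, b in zip(sp[:50] + sp[50:], (tb[:50] + tb[71:321] + tb[331:])))
print("SpOpB/TbOpB positional identity over shared columns:", ident / 685)

import pathlib
d = pathlib.Path(__file__).resolve().parent.parent / "src" / "s9conf" / "data"
d.mkdir(parents=True, exist_ok=True)
def wrap(s):
    return "\n".join(s[i:i+60] for i in range(0, len(s), 60))
(d / "spopb_reference_synthetic.fasta").write_text(
    ">SpOpB_reference_synthetic stand-in for S. proteamaculans OpB; documented "
    "anchor residues planted at author positions\n" + wrap(sp) + "\n")
(d / "tbopb_reference_synthetic.fasta").write_text(
    ">TbOpB_reference_synthetic stand-in for T. brucei OpB; documented anchor "
    "residues planted at author positions (+21/+31 offsets vs SpOpB)\n" + wrap(tb) + "\n")
print("written")
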