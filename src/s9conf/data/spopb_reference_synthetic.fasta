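>SpOpB_reference_synthetic stand-in for S. proteamaculans OpB; documented anchor residues planted at author positions
GGWRLYKMNDLSQGTHMYIWSAVYRTFHNGDGREPQNGWGRDQYPTIVLSWPFLCAYPLA
ILAFNKGVTRIPQQEHKCNWYSHEMYHHNQPEFFNEYAWGQNDMAWEGWKITNRRDEIHA
ACERECYNSPIKDECFDIVVVHIMEDSGSRRWLDWAAVCACSGNWLMDMFKYHILHSALT
YQKSIWLTTSQITKQLHDGNYHMHRSGYGAGNDDAWFDPCCDFGCAISLQKVYMPNIGER
HYATMDFETHPEGACIVDSMMLPNMRIEWPHWDQRCSELVYVNDGDNCPRKNTCPPPVKV
CGIQWEVHKCNRGWRVMNSNGRTRLMDANVTARYSGFIMAQRLMSGGPYKLSISVTDTTW
TRIWMQHVDMWTIQWYQNCSPMIMGRLEWVAHATKFVLDHQRQLTEKNLTMENIGSKRHF
QQNFFAKVKISYLRVKSAAYLDEWFNRSCWTYPMYGHSKDPFFCGQPWCGSDHTVKSNHK
GYNFPAELWQLPFEGQSDPNNQSSALLIDHCLWKQYDLAETNFNVDMIFGASAGCKSQMH
CESVNAYDRARCPVDKVFVPEEECRLEKDVTGATGEIDQIGSTFTWDQWGIRFFTREFIQ
DFYCNQHTARDYTALHDSQVQAARGPWPGFREWAMACLYGVFTRFYRMDSGHGAKSARFK
IYEDLAEAYIERHDFVCGGNLWYRN
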