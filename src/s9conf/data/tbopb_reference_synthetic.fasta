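>TbOpB_reference_synthetic stand-in for T. brucei OpB; documented anchor residues planted at author positions (+21/+31 offsets vs SpOpB)
GGQKNTFMNVNRYDTWRNIWFADYSPFHNHDHSFHQNRYHNDCYGAIDLKRASWSAQESH
ENAVHDMFMFIAPKLCAWDLKILYFMKGVTRIPQQEHKCNWMSCEPRHHNQPEFFNEYAW
GCWDLNWHLSGVYKGRIEMHAACERECYNSPVKSYMFHIVHFHIMEDSGSTEWLDWAADC
FCSQEFLTGMAKFHPEHGKFEQLESGWLCASQITKQLHDDMYHPHFLGDEAPFIWAWPCN
MKDFGATDTLQKTRAQNIGIRHYATMDFETHIIGQMLVDQWMLPDCCASHWHKDQKDPEE
VAVNDGQNCPRKNTCPPLVDVWLITFLNVSHPQIQEEEHFPNEYWRSWTSNGRTRPSCGV
VTARYSGFIMAPTLQSGFPYWLSIEVTDTTWTRIWMQHLNQSTKMRMMNCSPMIMGRFEL
VAHEEKDFLHPQEQLTEKNLTMENIGSKRHFQANFFAKVANSLRAGKVTPQNFEHFEHSW
WTYPMYGHSKDPFFCGANWRQSEFTVRTLHWGQNKPAELWQLPFEGQSTPTNQVDFLLFD
HCLHKQYDIYIYQSNVDMIFGASAGCKSQMHCFHVNKVDRRRLPRDKVFVPEEATNLQKD
VTGATGEIDQIITIGTWEQGPCRFFVGFELASMYSNQKWARDYTALHDGRVAAARGPNQC
QKMQANYAAVQIMTRFYRMDSGHGAKSARFKIYEDLAEAVTCVADYFCSRVGWYMG
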