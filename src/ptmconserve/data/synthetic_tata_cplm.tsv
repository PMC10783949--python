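source_id	accession	position	mod_type	species	sequence	evidence	protein_name
CPLMSYN001	SYNH_TATA	66	acetylation	Synthetic organism B	KWPMRRHCKRFYAIWAKTACLFFFTHDPCQEGPQLTYFSQQQYNCCFKMACVHRHDFYFRPVHFGKRRDLYIPKVTPMFAAVWMQLRFS	PMID:0000001	synthetic TatA-like homolog (acetylated K66)
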