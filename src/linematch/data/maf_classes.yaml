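# Mapping from common MAF variant-classification spellings to the controlled
# vocabulary used by linematch.  Edit or extend as dataset vocabularies drift;
# pass a custom YAML via read_mutations(classification_map=...).
Missense_Mutation: missense
Nonsense_Mutation: nonsense
Frame_Shift_Del: frameshift
Frame_Shift_Ins: frameshift
Splice_Site: splice_site
Splice_Region: splice_site
In_Frame_Del: in_frame_indel
In_Frame_Ins: in_frame_indel
Nonstop_Mutation: nonstop
Translation_Start_Site: translation_start
Start_Codon_SNP: translation_start
Silent: silent
Intron: intron
5'UTR: utr5
3'UTR: utr3
5'Flank: flank
3'Flank: flank
IGR: igr
RNA: rna
lincRNA: rna
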