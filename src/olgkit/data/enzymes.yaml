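# Restriction enzyme recognition motifs (IUPAC, given 5'->3'; matched on
# both strands).  MnlI is the screening enzyme used for arrest-mutant
# genotyping; the rest are common 4-cutters.
MnlI: CCTC
AluI: AGCT
DpnII: GATC
HaeIII: GGCC
HhaI: GCGC
HpaII: CCGG
MseI: TTAA
NlaIII: CATG
RsaI: GTAC
TaqI: TCGA
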