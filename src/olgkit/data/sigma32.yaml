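# Sigma-32 (heat-shock sigma factor) promoter model.
#
# Consensus boxes are IUPAC strings from the sigma-32 regulon literature;
# the -10 box carries the tetra-C element (CCCC).  hard positions (0-based,
# within each box) must match exactly: the first T of the -35 box and the A
# of the -10 box are completely conserved in sigma-32 promoters.  Spacer
# optimum is 14 bp; each bp of deviation adds +1 to the mismatch score.
# The distance from the 3' end of the -10 box to the TSS is optimal at 6 bp.
box35: CTTGAAA
box10: CCCCATNT
hard35: [1]
hard10: [4]
spacer_range: [13, 15]
spacer_opt: 14
tss_distance_range: [4, 8]
tss_distance_opt: 6
max_score: 3
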