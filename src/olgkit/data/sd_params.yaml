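# Shine-Dalgarno duplex free-energy parameters (kcal/mol, 37 C).
#
# anti_sd is the 3'-tail core of the 16S rRNA (5'->3', RNA alphabet) against
# which candidate ribosome-binding sites are hybridized.  Stacking free
# energies are a symmetric RNA/RNA nearest-neighbor set (10 unique values);
# keys are the 5'->3' doublet on the candidate (mRNA) strand, both positions
# Watson-Crick paired to the anti-SD.  delta_g = initiation + sum(stacks)
# over the best contiguous, fully paired duplex.  Under this set the perfect
# SD sequence TAAGGAGGT scores -9.6 (duplex AGGAGGU) and -2.9 is the
# presence threshold.
anti_sd: ACCUCCU
initiation: 4.0
temperature_c: 37.0
sd_threshold: -2.9
stacks:
  AA: -0.9
  AC: -2.1
  AG: -1.7
  AU: -0.9
  CA: -1.8
  CC: -2.9
  CG: -2.0
  CU: -1.7
  GA: -2.3
  GC: -3.4
  GG: -2.9
  GU: -2.1
  UA: -1.1
  UC: -2.3
  UG: -1.8
  UU: -0.9
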