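# Methods

`olgkit` re-implements, as a tested pipeline, the computational workflow
used to discover and characterize a young antisense overlapping gene
embedded in an annotated bacterial gene: ORF detection from strand-specific
transcriptome/translatome alignments, regulatory-element scoring, design of
strand-specific translational-arrest mutants, competitive-index fitness
analysis, and phylostratigraphic placement of the gene's origin.  This note
records the models, their assumptions, the defaults, and the limits of what
the synthetic-data tests demonstrate.

## Coordinates and reading-frame conventions

All genomic coordinates are 0-based, half-open, on the forward strand; GFF3
input is converted at the reader boundary.  With the mother gene defined as
frame +1, the relative frame of an ORF is computed from
`p = (orf_left - mother_left) mod 3` on the forward strand: same-strand
labels +1/+2/+3 for p = 0/1/2, antisense labels -1/-2/-3 for p = 2/1/0.
The literature uses more than one antisense numbering convention and the
underlying study does not define its rule; this mapping is a single
documented function (`seqcore.relative_frame`) chosen so that the canonical
overlap geometry of the study system (antisense ORF fully embedded, offset
1 mod 3) is labelled -2, and it can be swapped without touching callers.

Translation uses NCBI genetic-code table 11 (configurable).  Codons
containing `N` translate to `X` and are never starts or stops.  ORF
enumeration accepts ATG/GTG/TTG starts (configurable), runs to the first
in-frame stop, reports nested ORFs sharing a stop, and defaults to a
20-amino-acid minimum.

## Expression quantification and the translation classifier

For each ORF and library (RNAseq transcriptome, RIBOseq translatome):

* RPKM = `count * 1e9 / (len_bp * total_mapped)`.  Read counting is
  strand-specific; the default mode counts a read overlapping the ORF by
  >= 1 bp (`within` is available).
* ORF coverage = fraction of ORF positions overlapped by at least one
  same-strand RIBOseq read.
* RCV (ribosomal coverage value) = translatome RPKM / transcriptome RPKM.
  A zero transcriptome RPKM leaves the RCV undefined (flagged `None`, never
  infinity) and fails the classifier by definition.

An ORF is called translated when, **in every biological replicate**: (i)
RIBOseq RPKM >= 1 (one read per million mapped reads normalized to 1 kbp),
(ii) coverage >= 0.5, and (iii) RCV >= 0.25.  The published wording does
not say which library criterion (i) applies to; the default applies it to
the RIBOseq library, since the filter detects translation, with a flag to
require it of both libraries.  Summary tables report means over replicates
(the RCV column is the mean of per-replicate RCVs, not the ratio of mean
RPKMs) rounded to 1 decimal for RPKM and 2 for RCV/coverage; per-replicate
profiles retain full precision.

## Shine-Dalgarno free energy

SD strength is the hybridization free energy (kcal/mol, 37 C) of the best
duplex between a substring of the 30-bp region upstream of the start codon
and the anti-SD core of the 16S rRNA 3' tail.  The model scores contiguous,
fully Watson-Crick-paired duplexes only (no bulges or loops):
`dG = initiation + sum(nearest-neighbor stacks)`.  The shipped parameter
file (`data/sd_params.yaml`) carries a symmetric Freier-style RNA/RNA stack
table, initiation +4.0 kcal/mol, and anti-SD `ACCUCCU`; under this set the
perfect SD `TAAGGAGGT` scores exactly -9.6 via its 7-bp duplex `AGGAGGU`,
and -2.9 is the presence threshold.  Scanning considers sub-windows of
length 5-12, returns the minimal-dG window, and breaks ties 5'-most.  The
parameter file is data, not code: an alternative nearest-neighbor set can
be dropped in, subject to the -9.6 calibration check in the test suite.
Because only contiguous duplexes are scored, energies for bulged SD
pairings are conservative (less negative) relative to full secondary-
structure models.

## Sigma-32 promoter scan

The heat-shock sigma factor recognizes a -35/-10 architecture.  Consensus
boxes default to `CTTGAAA` (-35) and `CCCCATNT` (-10, carrying the tetra-C
element); both are configurable data (`data/sigma32.yaml`) since consensus
renderings differ slightly across the regulon literature.  A hit requires
exact identity at the invariant positions (the first T of the -35 box, the
A of the -10 box), a spacer of 13-15 bp, and, when a TSS is supplied, a
-10-to-TSS distance of 4-8 bp (optimum 6).  The score is the IUPAC-aware
mismatch count over both boxes plus 1 per bp of spacer deviation from the
14-bp optimum — a documented heuristic standing in for the qualitative
"high similarity" judgement; promoters with a 14-bp spacer tolerate a
substitution of the second C of the tetra-C motif, which the scoring
reproduces (score 1, below the default cutoff of 3).  The scan is
strand-specific; callers pass the transcript-orientation sequence.

## Translational-arrest design

Given an overlap region in mother-gene orientation, `design_arrest`
enumerates every substitution set of size 1-3 (configurable up to 4;
search is exhaustive) within codons 2..10 of the target frame that creates
a premature stop while leaving the mother protein unchanged across the
whole region — a stricter reading than protecting only the edited codon.
The start codon is excluded from the window: arrest is by premature stop,
not start loss.  Enumeration is pruned to partner-synonymous edits per
mother codon, which is exactly equivalent because partner preservation
decomposes by codon; the test suite verifies equivalence against an
independent naive enumerator on random overlaps.  Plans are ranked by
(stop codon index, mutation count, position), annotated with the affected
partner codons, and screened for restriction-site gains/losses against a
small IUPAC-aware catalog (MnlI `CCTC` plus common 4-cutters,
`data/enzymes.yaml`), matched on both strands — site loss is the classic
digest-based screen for mutant clones.  Mutations need not be adjacent; a
flag can require a contiguous block.

## Phylostratigraphy of the overlapping frame

Each homolog of the mother gene is globally aligned to the reference
(biopython `PairwiseAligner`, match 5 / mismatch -4 / gap open -24 /
extend -0.5).  The gap-opening penalty is deliberately stiffer than the
classic EDNAFULL/Needle setting: substitution-only divergence of ~10%
between related genera should be explained by mismatches, and cheaper
openings occasionally produce compensating gap pairs inside the ORF window
that mimic frameshifts.  The homolog bases aligned to the reference ORF
interval are extracted together with an indel ledger; the segment is then
classified with the documented precedence

`disrupted_frameshift` (any indel not a multiple of 3) >
`disrupted_stop` (internal stop in the intact frame) >
`divergent` (peptide shorter than 41 aa or < 50% identical to the
reference) > `continuous`; homologs aligning over less than half the ORF
are `missing`.  The 41-aa length gate and the 0.5 identity gate
operationalize the fragment-length and similarity rules of the original
analysis and are configurable.  Stop and indel counts are always reported
so users can re-derive alternative rules.  The origin stratum is the MRCA
of all continuous tips on the supplied species tree; non-continuous tips
inside that clade are flagged as inconsistent with a single origin.
Automated calls are reproducible surrogates for manually curated
alignments, not byte-identical re-creations of them.

## Synthetic study system

`synthdata.make_overlap_genome` builds a toy genome that mirrors the study
geometry: a 1539-bp forward-strand mother gene; a 126-nt (41 aa) antisense
ORF fully embedded at frame -2; a 186-nt (61 aa) weakly translated
antisense ORF in the 289-bp 5' UTR; a TAAGGAGG SD core whose scanned
spacing to the start codon is 15 bp; transcription start 289 bp upstream of
the start codon and termination 155 bp downstream of the stop; and an
exact-consensus sigma-32 promoter with the optimal 14-bp spacer, 6 bp from
the TSS.  Filler sequence is uniform over ACGT, then repaired: accidental
antisense ORFs >= 20 aa are removed by start-codon or early-stop
substitutions that never break the mother frame, with planted elements
protected (extras nested wholly inside a planted ORF trigger a redraw of
that ORF's interior).  The embedded ORF also carries an editable arrest
context — mother codons Pro(CCT)+Arg(CGA) place Glu(GAG) at target codon 5,
so a single C>A edit creates a TAG stop, keeps Arg, and destroys the
spanning MnlI site — mirroring the canonical screen.  Every generator is a
pure function of its seed, and a ground-truth ledger (JSON) accompanies all
outputs so tests never re-derive truth from data.

Read simulation draws per-ORF Poisson counts with expectation
`rpkm * len_bp * n_total / 1e9` per library and replicate; RIBOseq targets
are transcriptome RPKM x RCV.  The shipped condition presets (`LB37`,
`BHI37`, `BHI_NaCl14`) carry the published per-condition transcriptome
RPKM / RCV / coverage values for all three genes.  RIBOseq read starts are
confined to a 5'-anchored window spanning the target coverage fraction of
the ORF, so realized coverage approximates the coverage column; RNAseq
reads are uniform over the feature.  A 5' positional bias flag exists for
footprints but is off by default.  Twenty background reads per library are
scattered genome-wide on random strands; `total_mapped` is set to the
configured depth of 1e7, mirroring a region-subsetted alignment file.  The
simulator has no sequencing-error or mapping-ambiguity model, and codon
usage is uniform — passing tests demonstrate the pipeline's arithmetic and
decision rules under Poisson sampling, not robustness to real library
artefacts.

Homolog families evolve the mother region along a fixed 8-taxon
enterobacterial tree (branch lengths in substitutions/site) with
ORF-preserving substitutions everywhere; each tip outside the designated
continuous clade (four Escherichia/Shigella-like taxa) is then disrupted
with probability 1.0 by default — a premature-stop substitution or a 1-2 bp
mid-ORF indel — so truth is exactly clade-restricted.  Competition assays
draw per-replicate CIs from multiplicative log-normal noise around a true
CI and convert them to endpoint percentages.

## Competitive index

`CI = (mutant_end x wildtype_start) / (mutant_start x wildtype_end)` after
converting chromatogram peak heights to percentages and normalizing the
t=0 ratio to 50:50 (each strain's endpoint is divided by its start
fraction and the pair re-normalized).  Replicates are aggregated by
geometric mean (a CI is a ratio); arithmetic mean is available by flag, as
the original aggregation is not stated.  Peak heights below a configurable
noise floor are clamped with a warning rather than yielding 0/infinite
CIs.  Note an arithmetic point surfaced by the analysis: a 15:85
wild-type:mutant endpoint from a 50:50 start implies CI = 5.67, while the
summary CI printed alongside that ratio in the original report is 13.6 —
a value that can only derive from unpublished per-replicate raw values.
Both numbers are surfaced here; only the 5.67 arithmetic is reproducible
and only it is asserted by the tests.

## Desk-scale limits

The following cannot be recomputed without external data and are therefore
covered by property-based checks on synthetic inputs instead: absolute
RPKM values of the original libraries (raw reads not bundled); the
gene-specific SD value of -6.8 and the exact published 3-mutation plan
(both need the reference genome sequence); the printed summary CI of 13.6
(unpublished replicate raw values); and homolog strain counts (database-
version dependent).

## Problem sizes used by the test suite

The default suite and the acceptance script run the generators at the
study geometry (2.1-kb genome, 1e7 mapped reads per library, 2 replicates),
100 seeds for classifier call rates, 200 random 30-nt regions for the
arrest-design oracle, 50 seeds for RPKM recovery, and 20 simulated homolog
families; these sizes give stable pass/fail behaviour for the stochastic
checks at the stated bounds.
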