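# Methods

`phasnet` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the small-RNA annotation and post-transcriptional
network analysis used in plant sRNA studies: MIR hairpin locus calling,
phased-siRNA (PHAS) locus detection, trigger-miRNA assignment, target
prediction, degradome validation, and classification of
miRNA–PHAS–mRNA triples into miRNA-only (Model 1) versus
miRNA+phasiRNA (Model 2) regulation. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not show.

## Preprocessing

Reads are 3'-adapter trimmed at the first exact match of the adapter's
first 8 nt, filtered to 18–34 nt with no N, and collapsed to unique
*tags* carrying per-library counts (collapse conserves per-library read
totals; tag ids are assigned in sequence-sorted order, so results are
input-order invariant). Tags matching a structural-ncRNA blacklist
(rRNA/tRNA/snoRNA, organellar) as an exact substring on either strand
are removed; near-matches are kept, the strictness being configurable.
Alignment is end-to-end and ungapped (Hamming distance, no indels), the
default behaviour of the short-read aligners this class of pipeline
uses; *all* placements with ≤ 2 mismatches on both strands are
reported, then tags with more than 20 genomic placements are dropped to
avoid repetitive regions. The multi-mapping filter is applied before
both MIR calling and PHAS scanning by default
(`multimap_filter_phas`); applying it uniformly is the conservative
choice, and the alternative (PHAS scanning on unfiltered hits) is one
flag away.

Every numeric threshold lives in `RunConfig` with its published default
(18 nt minimum length, 2 mismatches, 20 hits, 75% duplex abundance,
20–22 nt mature, 5–300 nt spacing, 100 bp / 0.001 / 10 / 30% PHAS
rules, 400 bp trigger flank with penalty ≤ 5, Allen < 7, MFE ratio >
0.65, top 30 phasiRNAs, categories 0–3 with penalty ≤ 6, |log2FC| ≥
2/1/1 with FDR ≤ 0.05, RP10M > 10, r > 0.7). Operations read the
config; nothing is hard-coded.

## MIR locus calling

Hits are clustered per strand with a 200-nt maximum gap between
consecutive tag starts (the gap must exceed plausible mature–star
spacing but split distant stacks; it is exposed in the config). Within
a candidate, the mature is the most abundant 20–22-nt tag. Duplex
validity is assessed by direct mature:star complementarity under the
Dicer 2-nt 3'-overhang register — mature position *i* pairs star
position *K*−3−*i*, Watson–Crick or G:U — with at most 5 unpaired
mature positions and an inner mature–star gap of 5–300 nt. A full
thermodynamic fold is deliberately not required: complementarity is
dependency-free, deterministic, and sufficient for duplex-level
evidence; the duplex check is an isolated function, so a thermodynamic
backend can replace it.

The locus itself is the hairpin precursor: the interval from the
outermost mature/star boundary to the other. The 75% rule — mature +
star abundance ≥ 75% of locus reads, with ±1-nt 5'/3' isomiR tolerance
when matching reads to the mature/star intervals — is computed over
reads overlapping that precursor span, not over the whole cluster;
background stacks a hundred nucleotides away are not part of the
locus and must not dilute the fraction. Because a real hairpin's star
arm is (nearly) the mature's reverse complement, the same pair of tags
also co-aligns on the opposite strand and would be called twice;
overlapping calls sharing a mature/star sequence collapse to the more
abundant one.

Naming is by homology: the best known-miRNA match with ≤ 2 mismatches
and length within ±1 assigns the family (ties: fewest mismatches, then
lexicographic reference id); unmatched loci are numbered `miRN1`,
`miRN2`, … in genomic order, so naming is a pure function of the
(sequence set, reference) pair. Loci whose mature RP10M stays below 10
in **every** library get the low-confidence "probably" flag — the
most conservative flagging under an ambiguous rule; an "any library"
mode is available.

## PHAS locus detection

A read's *phase coordinate* is its 5'-end position on the plus strand
and the 5'-end + 2 on the minus strand (the 2-nt 3'-overhang
correction). Only reads whose length equals the candidate period (21
or 24 nt) occupy positions. Windows of 11 cycles (231 nt / 264 nt)
slide by one period; within a window the occupancy statistics at a
register are

- N — eligible 5'-end positions: 2 × window length under the default
  `all` position model (every nucleotide on both strands), or window
  length under the strand-merged `grid` model;
- m — in-register positions among N (2 × cycles, or cycles);
- n / k — occupied positions and occupied in-register positions;
- P / U — summed abundance of in-register period-length reads versus
  everything else in the window.

The p-value is the exact hypergeometric upper tail P(X ≥ k) with
population N, successes m, draws n — computed with integer arithmetic
(`math.comb`), so no tail underflow — and the phasing score is
ln[(1 + 10·P/(1+U))^(k−2)] for k ≥ 3, else 0: the convention of the
phased-siRNA literature, monotone in P and k, damped by off-register
abundance, requiring at least three occupied cycles. Because N, m and
n are register-independent within a window, the minimum-p register is
the maximum-k register, which the scanner exploits (ties: larger P,
then smaller register). Windows passing p < 0.001 *and* score > 10
merge with overlapping or bookended neighbours of equal register; the
merged locus spans its in-register reads and must additionally exceed
100 bp, carry > 30% phased abundance, and have the period as its
abundance-weighted modal read length. The reported locus score is the
maximum over constituent windows, the p-value the minimum. The
spec-level `grid` alternative for N is shipped as the strand-merged
phase-coordinate model (N = window length, m = cycles), a coherent
second convention; `all` is the default and the one all acceptance
properties are stated against.

Per locus, phasiRNAs are the in-register period-length species ranked
by abundance (ties: lower coordinate); downstream target analysis uses
the top 30.

## Trigger assignment and target scoring

The duplex engine scores antiparallel sRNA:site alignments with the
additive plant-target penalty convention: mismatch 1.0, G:U 0.5, gap
2.0, penalties doubled at sRNA positions 2–13 from the 5' end. Site
search is an exhaustive ungapped scan plus every single-gap variant
(one bulged sRNA base or one bulged site base); candidate enumeration
keeps alignments whose *unweighted* penalty sum is below the relevant
threshold — a lower bound on the weighted score, so no acceptable site
is missed. Duplex stability uses a deliberately simple pair-energy
model (GC −3, AU −2, G:U −1, mismatch/gap 0): the acceptance criterion
is the *ratio* of duplex energy to the sRNA's perfect-complement
energy, which makes the model scale-free (perfect duplex = 1.0); a
nearest-neighbour backend can be swapped in behind the same function.
A target interaction is accepted iff Allen score < 7 **and** MFE
ratio > 0.65 (both strict, as printed) on the best site per
sRNA×transcript (ties: lowest coordinate) — one engine realizing the
published two-predictor intersection as a conjunction of the two
criteria.

Triggers are sought in the PHAS locus extended by 400 bp of added
flank (200 nt per side; the printed phrase is ambiguous between
400-total and 400-per-side, so the split is configurable), on both
strands, reporting assignments with penalty ≤ 5 (inclusive). Predicted
cleavage sits opposite sRNA positions 10–11 (canonical AGO slicing;
position 11 when 10 itself is bulged), and `in_register` checks that
the cleavage coordinate's phase coordinate equals the locus register —
the biological signature of a genuine trigger.

## Degradome validation

Degradome reads are exact-matched to transcripts; a read matching t
positions contributes 1/t weight to each (the fractional profile is
kept alongside its rounded view). A queried position with signal r is
categorized against the occupied positions of its transcript: 4 if r ≤
1 (single-read evidence; the ≤ generalizes the integer rule so
fractional multi-mapping weight cannot validate), 0 if r > 1 is the
unique maximum, 1 if it ties the maximum, 2 if median < r < maximum, 3
if 1 < r ≤ median — the median taken over occupied positions only. An
interaction validates iff the best signal within ±1 nt of its
predicted cleavage site (degradome 5' ends jitter by a base; slop
configurable to 0) has category ≤ 3, the interaction's alignment
penalty is ≤ 6, and at least one read supports it.

## Expression and the two-model network

Counts are normalized to reads per ten million (RP10M = raw × 10⁷ /
library total); log2(RP10M+1) is the transformed view and row z-scores
(sample sd; constant rows → 0 with a warning) feed heatmap-style
summaries. Differential expression contrasts reproductive (ovule,
embryo, FB, OS, MB, MS) against vegetative (leaf, cambium) libraries:
features must exceed RP10M 10 in at least one library (the permissive
reading of an ambiguous gate; a group-wise mode exists);
log2FC = log2((mean RP10M_rep + 0.5)/(mean RP10M_veg + 0.5)) with a
0.5 pseudocount for zeros; the p-value is a two-sided exact binomial
test of the pooled reproductive count against the pooled library-size
proportion, and FDR is Benjamini–Hochberg. This replaces a
negative-binomial GLM engine deliberately: the thresholds, not the
test engine, define the analysis, and correctness is measured as
planted-truth recovery, not numerical equality with any particular DE
package. Class thresholds: miRNA |log2FC| ≥ 2, PHAS ≥ 1 (inclusive,
as printed), mRNA > 1 (strict, from the model definitions), all at
FDR ≤ 0.05.

A triple (miRNA, PHAS, mRNA) is classified from its three log2 fold
changes. Shared requirement S: mi × mRNA < 0 with |mi| > 1 and
|mRNA| > 1. Model 1: S and (mi × PHAS < 0 or |PHAS| < 1) — the locus
is discordant or not differentially expressed, so regulation is
miRNA-only. Model 2: S and mi × PHAS > 0 and |PHAS| > 1 — concordant
trigger and locus, miRNA+phasiRNA co-regulation. All inequalities are
strict; the two models are mutually exclusive by construction, and a
miRNA with no triggered locus is a Model-1 candidate with the PHAS
clause vacuously true. Triples join the trigger table with the
miRNA→mRNA and phasiRNA→mRNA target tables (a phasiRNA target
contributes the triple of its locus's trigger); unknown feature ids
are an error, never silently dropped. The exported edge table carries
miRNA→mRNA edges (negative regulation) and miRNA→PHAS trigger edges,
the latter kept only at Pearson r > 0.7 (strict) on log2(RP10M+1)
across all libraries — the correlation filter applies to triggering
relationships, while target edges are annotated, not filtered;
Spearman is available by config.

## The synthetic study

The generator builds a complete miniature study whose every element is
recorded in a JSON truth table: a 50-kb i.i.d. genome (GC 0.42)
carrying 6 MIR hairpins (21-nt mature, 60-nt loop, star constructed to
pair under the overhang register; 3 with known-reference homologs) and
8 PHAS loci (6 × 21-nt, 2 × 24-nt, 12 cycles each) whose registers are
set by planted trigger-complementary sites; 12 transcripts of 800 nt
bearing perfect-complement target sites; 8 libraries (4 reproductive,
4 vegetative) totalling ~170k reads; and a degradome whose 5'-end
pileups peak (height 30 over ~0.4 background) at the planted cleavage
coordinates. Species counts are negative-binomial (dispersion 0.1)
around tissue-group means encoding the planted log2 fold changes
symmetrically (a +4 feature has 16× reproductive/vegetative mean
ratio). Background is a pool of 400 recurrent degradation-product
species (mean 30 reads/library) at random positions, lengths 18–26 —
recurrent species, because collapsed background tags recur across
libraries in real data, and because a per-read uniform model at this
genome scale would make every nucleotide a distinct tag and fuse the
chromosome into one cluster at any reasonable candidate gap.
Contaminant species drawn from a synthetic rRNA/tRNA blacklist
exercise the filter. Reads are emitted at 50 bp with the 3' adapter
appended, so the FASTQ path exercises trimming end to end.

The planted regulatory story: mir0 (+4, miR390-like homolog) triggers
phas0 (+2) whose cycle-2 phasiRNA cleaves the CHS-like tx00 (−4) — the
study's single Model-2 triple; mir1 (+4) triggers the discordant phas1
(−2) and cleaves tx01 (−4) — Model 1; mir2 (+4) triggers nothing and
cleaves tx02 (−4) — Model 1 by the vacuous clause. One 21-nt locus is
a trigger-less decoy; 24-nt loci take non-differentially-expressed
triggers, because an abundant trigger's own reads map onto the
cleavage site and can outweigh a 24-nt locus's phased abundance in the
dominant-length rule — a genuine failure mode of that rule worth
keeping visible rather than engineering away.

A reduced scale (14-kb genome, 4 MIR, 3 PHAS, 6 libraries, ~25k reads)
is used wherever many seeded replicates are needed; the 20-seed
recovery suites and the acceptance script run at this scale, and the
analysis drivers and one acceptance pass run at full scale. These
sizes are the package's chosen study conditions, small enough that the
entire suite runs in well under two minutes.

What passing on these data shows — and does not. The generator plants
clean hairpins, exact-period phasing, perfect-complement sites and
well-separated loci over an i.i.d. genome. Recovery there demonstrates
that the statistics, thresholds and join logic are implemented
correctly and that the planted effect sizes are detectable at the
stated noise; it does not demonstrate robustness to repeat-rich
genomes, isomiR-heavy stacks, overlapping loci, sequencing error
(beyond none), partial-complementarity sites, or batch structure —
none of which the generator emulates.

## Numerical and degenerate-case choices

Exact integer hypergeometric tails (no floating tail sums); k = 0 ⇒
p = 1; windows not a multiple of the period are an error. Score uses
`log1p` and the +1 in the U denominator guards U = 0. Constant rows
z-score to zero with a warning; constant profiles drop out of
correlation rather than propagate NaN. BH is the standard step-up with
a stable sort; ties in every ranking (mature choice, site choice,
phasiRNA ranking, novel naming) break deterministically by coordinate
then id, so identical inputs give byte-identical outputs. Empty
blacklists warn and pass tags through; empty FASTA files warn and
return empty. All internal coordinates are 0-based half-open; GFF3
emission converts to 1-based inclusive and parses back identically.

## Known limitations

Hairpin evidence is duplex-complementarity, not a thermodynamic fold;
the MFE ratio uses a three-level pair-energy model; the DE test is a
pooled exact binomial, which is anti-conservative under strong
overdispersion relative to a replicate-aware NB model (recovery, not
engine equality, is the acceptance standard here); degradome mapping
is exact-match only; the aligner is a vectorized scan suitable for
kilobase-to-megabase synthetic genomes, not an FM-index for gigabase
ones.
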