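# Methods

This note documents the models and procedures behind each module, the
defaults that matter, the numerical choices, and what the synthetic-data
tests do and do not establish about real data.

## Coordinates and I/O

All internal coordinates are 0-based, half-open, on the forward strand.
GFF3 (1-based inclusive), GenBank locations and 1-based published TSS-table
coordinates are converted exactly once, at the I/O boundary. This removes
the off-by-one class of bugs at the cost of one conversion per read/write,
which round-trip tests cover.

Sequences are uppercased on read and characters outside {A,C,G,T,N} are
mapped to N with a warning. Motif scans never match a genomic N (an N in a
window counts as a mismatch against every consensus code, including N-as-
any-base in the consensus itself): an ambiguous genome position should never
create a hit.

Intergenic regions (IGRs) are computed strand-agnostically — a base covered
by a gene on either strand is not intergenic — because both the REP-site
counting and orphan-TSS calling treat "intergenic" that way. The genome is
treated as linear by default; for a circular chromosome the origin-spanning
gap is simply reported as two intervals, which is conservative for full-
containment tests (a repeat straddling the origin would be missed; none of
the analyses here depend on that corner).

## sORF census

An sORF is an annotated ORF of at most 80 amino acids. The boundary is
inclusive and the amino-acid length excludes the stop codon
(`aa = span/3 − 1`); both conventions are configurable because published
descriptions of "less than 80 codons" vs "maximal length 80 aa" genuinely
differ, and the inclusive reading is the one consistent with the published
census count this definition comes from. Features whose span is not a
multiple of 3 are skipped with a warning rather than silently truncated.

Shine–Dalgarno annotation is a deliberate simplification: the best identity
match of a 6-mer window to `AGGAGG` with the window fully inside −20..−4
relative to the start codon, reported when at least 4 of 6 positions match.
Ties go to the window closest to the start codon. No free-energy model is
used — the annotation is meant to flag "putative SD present", not to rank
initiation strength.

## Homology search and conservation classes

The search is an exact Smith–Waterman (Gotoh affine gaps; linear when
`gap_extend == gap_open`), deterministic traceback with tie order
diagonal > up > left. At desk scale exactness is affordable and makes the
search oracle-checkable; a heuristic database search would add nothing but
noise here. Nucleotide mode aligns both query strands (defaults
+1/−2, gap 4/2); translated mode scores ungapped local segments between all
six query frames and all six subject frames under BLOSUM62, mirroring the
translated-search tools it stands in for (gapped translated alignment is
available behind a flag).

Significance uses Karlin–Altschul statistics, `E = K·m·n·e^(−λS)`, with λ
the unique positive root of `Σ pᵢpⱼ e^(λ·sᵢⱼ) = 1` (bracketed root finding,
relative tolerance 1e−9; for +1/−1 on uniform base composition the root is
ln 3, which the tests check analytically). K defaults to 0.1 — E-values here
rank and threshold hits; they are not calibrated against any particular
database, so the conventional prefactor is configuration, not science. The
default acceptance threshold is E ≤ 10⁻⁵. In translated mode m and n are
residue counts and λ comes from BLOSUM62 under uniform residue frequencies;
this is valid for the ungapped default (Karlin statistics are exact only
without gaps).

Classification counts **distinct species**, not strains or hits — strains of
one species collapse to one, and strains of the query species collapse into
a single "found in the query species" species. The category rules, applied
in order: any species outside Alphaproteobacteria ⇒ *Other*; otherwise ≥ 5
non-*Bradyrhizobium* alphaproteobacterial species ⇒ *Alpha_Conserved*,
1–4 ⇒ *Alpha_Rare*; otherwise any other *Bradyrhizobium* species ⇒
*Bradyrhizobium*; otherwise only strains of the query species ⇒
*B. japonicum*; nothing ⇒ *No homologs*. The *Other* breakdown is a 2×2 at
20 species in/outside Alphaproteobacteria; the alphaproteobacterial count
there includes *Bradyrhizobium* species by default (the published breakdown
legend omits the exclusion used for the rare/conserved split; a flag
switches this).

Best hit per (query, species) is the minimum E-value, ties broken by higher
raw score then lexicographic subject ID — determinism matters more than the
choice itself, since only presence/absence per species feeds the classifier.

## dN/dS (NG86 counting)

Implemented as Nei–Gojobori (1986) counting with Jukes–Cantor correction,
rather than a maximum-likelihood codon model: transparent, exactly testable
against brute-force enumeration, and sufficient for the directional claim
(ω ≪ 1 ⇒ purifying selection) this pipeline makes. Conventions:

- **Sites.** Per codon position, the synonymous fraction is (synonymous
  single-nt neighbours)/(non-stop single-nt neighbours); stop neighbours are
  excluded from the denominator (yn00-style). S + N = 3 per codon unless a
  position has no non-stop neighbour (does not occur in the standard code).
- **Substitutions.** Multi-difference codons are resolved by enumerating all
  orderings of single-nt steps; paths through stop codons are discarded and
  counts averaged over the remaining paths, unweighted. If every path hits a
  stop, the average falls back to all paths with a warning.
- **Distances.** pS = Sd/S and pN = Nd/N over sites averaged between the two
  sequences; d = −(3/4)·ln(1 − (4/3)p). p ≥ 3/4 is reported as saturated and
  dS = 0 as `ds_zero`; neither produces an ω, and histograms report such
  pairs separately rather than binning them.
- Codon columns containing N or a gap are dropped pairwise before counting;
  the dropped-column count is retained on the alignment object.

The codon-evolution simulator is an acceptance-sampling toy model (uniform
single-nt proposals; reject stops; accept synonymous always, nonsynonymous
with probability ω), parameterized in accepted events rather than time. It
has no transition/transversion or codon-frequency bias, which is exactly why
NG86 recovers its ω without bias corrections: the recovery tests (50 pairs
of 300 codons, 60 events per branch; neutral mean within [0.85, 1.15],
≥ 95 % of purifying ω = 0.1 estimates below 0.5) validate the counting
machinery, not NG86's robustness to real mutational biases.

## REP elements

Palindrome mismatches count arm positions i < ⌊L/2⌋ where base i fails to
complement base L−1−i (odd-length centres ignored). The palindrome scanner
enumerates arm 6–12 / loop 3–8 windows; hits sharing a loop centre merge,
keeping the candidate with the most net-paired positions (arm −
mismatches), then fewest mismatches — extending an arm across a mismatching
position adds no pairing and should not displace a cleaner hit.

Consensus scanning is vectorized Hamming distance over all windows on both
strands, IUPAC-aware (a consensus code matches any base it denotes; genomic
N matches nothing). Forward and reverse matches of a palindromic consensus
at one locus merge into a single strand-`both` hit, so palindromic sites are
counted once. Default mismatch tolerance is 2 for a 20-nt consensus
(⌊length/10⌋ in general); because no published tolerance exists for the
"approximately 200 intergenic sites" figure, the CLI sweeps 0–3 and reports
every count. IGR membership requires full containment of the hit interval.

De novo discovery counts k-mers (k = 20) by the number of distinct IGRs
containing them (both strands, canonical orientation, so palindromes count
once), keeps those in ≥ 10 IGRs, and clusters them greedily around the most
widespread seed at Hamming distance ≤ 2; each cluster's consensus is the
per-column majority over all genomic occurrences, with ties becoming IUPAC
codes. This formalizes what was a manual discovery process; it finds exactly
the planted family (and nothing else) in the generator's regime, but greedy
clustering can split highly diverged real families.

Hairpin validation is Nussinov base-pair maximization (Watson–Crick + G·U,
hairpin loops ≥ 3 nt), not a thermodynamic model: the question it answers is
"can this sequence form the expected stem", not "what is the MFE structure".
Traceback prefers pairing the leftmost base with its outermost admissible
partner, which reproduces the canonical 8-bp-stem/4-nt-loop structure for
the 20-nt REP consensus deterministically. Accepted lengths are 5–200 nt
(5 is the shortest sequence that can host one pair over a 3-nt loop).

The second REP consensus is printed in its source with an internal hyphen;
it is treated as a typographic artifact and removed, giving a 40-nt
consensus, with the central 34-nt imperfect palindrome exposed separately
as the core motif.

## sRNA calling

A TSS is *internal*/*antisense* when inside a gene on the same/opposite
strand, *gene_associated* when within 200 nt upstream of a same-strand gene
start (a 5'-UTR TSS), and *orphan* otherwise. Orphan TSSs whose TEX+ peak
is at least `min_peak` (default 100 reads — "high peak" is inherently a
judgment call, so the threshold is always reported with outputs) and whose
peak is confirmed in the supplied coverage seed candidates. The 3' end is
the last position before coverage stays below 10 % of the TSS peak for ≥ 10
consecutive nt in the direction of transcription; candidates with no such
drop within 500 nt are discarded (the transcript outruns the sRNA length
window), and candidate intervals are clipped to their IGR and filtered to
50–500 nt. 5' ends are *primary* when the TEX+/TEX− peak ratio is ≥ 2,
*processed* when the inverse ratio is ≥ 2, *ambiguous* otherwise (zero
denominators count as infinite ratio). Convergent TSS pairs yield two
independent candidates.

The coverage simulator plants rectangular plateaus over Poisson background
with TEX enrichment ×4 for primary and ÷4 for processed 5' ends. Real
dRNA-seq coverage decays raggedly rather than dropping cleanly, so the
recovery tests (100 % recall at SNR 15, 3'-end error ≤ 10 nt, zero calls on
pure noise) verify the calling logic and thresholds, not 3'-end accuracy on
real libraries.

## Synthetic data

Defaults emulate the study system: GC 0.64 (approximating the high-GC
*B. japonicum* chromosome — an emulation choice, hence configuration),
i.i.d. background sequence, non-overlapping genes with ATG/TAA caps laid
down left to right with random ≥ 20-nt gaps, Binomial(length, rate)
substitutions per planted repeat copy (optionally capped per copy), and
Poisson(5–10) coverage background. All generators are pure functions of
(parameters, seed) and every dataset ships with exact planted truth.

What the i.i.d. background does **not** emulate: compositional skew,
oligonucleotide bias, and real repeat families, all of which raise the
false-positive floor of motif scanning on real genomes; and codon-usage or
Ti/Tv bias in the evolution model (see above). Passing the planted-truth
tests therefore demonstrates correctness of the algorithms under their
stated assumptions, not performance guarantees on arbitrary genomes.

## Problem sizes in the test suite

The suite and the acceptance script use: all 61 sense codons and all 61×61
codon pairs for the counting oracles; 50 replicate pairs of 300 codons for
ω recovery; ten 1-Mb genomes with 7 planted repeat copies each for scan
sensitivity/specificity; a 7⁴-point profile grid plus 30 evolved families
for the classifier; and 200-kb genomes with 8 planted sRNAs for the caller.
These sizes give stable statistics (binomial standard errors well inside
the asserted bands) while keeping a full run in well under a minute per
stage on one CPU.
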