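# Methods

## Topology model

A putative quadruplex-forming sequence (PQS) is four guanine tracts in
close succession along duplex DNA.  On the scanned strand each tract is
a run of G (symbol `A`) or a run of C (symbol `B`, i.e. a guanine tract
on the complement).  The 4-letter word of tract symbols, read 5'→3',
identifies the topology of the quadruplex that the locus could form.
Two words that are reverse complements of each other (reverse order,
swap A↔B) name the same duplex locus scanned from opposite strands and
are identified.  Exhaustive enumeration of the sixteen words gives ten
classes: AAAA∪BBBB (the intrastrand case) plus nine interstrand
classes.  Four interstrand words are self-reverse-complementary (AABB,
BBAA, ABAB, BABA); the remaining ten words pair up into five classes of
two members each, so the member multiset over the nine interstrand
classes is {1,1,1,1,2,2,2,2,2}.  Swapping A↔B *without* reversal maps
each class to its mirror class (the quadruplex seeded from the other
strand); ABBA is its own mirror, giving five strand-swap groups.  The
class labels follow the conventional list (AABB, ABAA, ABAB, ABBA,
ABBB, BAAA, BABA, BABB, BBAA) and each interstrand class also carries
the historical Cao numbering (BAAA=1 … BABB=9).  Loop-polarity
conformers within one class cannot be distinguished from sequence and
are not modelled; i-motif formation (a cytosine structure needing
acidic pH) is out of scope.

## Matching semantics

The defining commitment of this package is that a class is *defined by*
its Perl-compatible regular expression, not merely approximated by one:

* tract = `G{t,}` or `C{t,}`, greedy, with minimum tract length t = 3
  by default (t ≥ 2 accepted);
* the first occurrence of each letter is a capturing group; later
  occurrences are backreferences, i.e. exact string repetitions of the
  first captured tract;
* same-letter adjacency uses loop `.{1,7}` (a single-strand loop needs
  ≥1 nt), different-letter adjacency uses gap `.{0,7}` (the structure
  crosses strands, so 0 is legal);
* classes with two member words are the alternation canonical-first;
  AAAA is the alternation of the all-G and all-C expressions;
* matching is global (`m//g`): leftmost match, next search resumes at
  the previous match end, so matches of one class never overlap.  A
  separate one-step search is run per class; cross-class overlaps are
  resolved downstream.

Two consequences of backtracking are accepted deliberately rather than
"cleaned up".  First, a later same-letter tract only needs to *contain*
a copy of the shortest viable first capture; surplus run letters are
absorbed by the neighbouring gaps.  Second, a greedy inter-tract gap may
consume leading bases of a longer run, so reported tract sub-spans (and
occasionally the match end, by up to run-length − t bases) reflect the
engine's first solution, not a canonical alignment.  Genome-wide counts
depend on these choices, which is why the implementation generates the
expressions and delegates to a backtracking PCRE-compatible engine
(Python `re`) instead of hand-rolling automata; a unit test checks the
generated expression of every class against the published literal
expressions match-for-match on random sequences, and a combinatorial
placement oracle (below) guards existence semantics independently of
any regex engine.

Case handling: `fold` (default) uppercases before scanning; `strict`
leaves soft-masked lowercase unable to form tracts while still allowed
in loops.  `N` and other ambiguity codes may occupy loops (`.`
semantics) but never tracts; a flag restricts loops to A/C/G/T.
Matches never span FASTA record boundaries.  Coordinates are 0-based
half-open internally and in BED; the legacy text dialect prints 1-based
starts.

## Unique sites and summary statistics

Records of different classes overlapping by ≥1 base (strict `start <
max_end` under half-open coordinates; abutting intervals do not merge)
are grouped into connected components by a single sweep over records
sorted by (sequence, start, end) — O(N log N).  Two distinct genome
statistics follow: unique interstrand sites (merge over the nine
interstrand classes only) and independent groups of any type (merge
over all ten).  Per-chromosome tables report the raw AAAA record count,
the unique interstrand site count, densities per megabase of full
assembly length (gap bases included — no gap exclusion is applied), and
their ratio; the genome-wide ratio is computed from summed counts.  The
asymptotic Poisson z, (obs − exp)/√exp, is provided for comparisons of
per-chromosome counts against an expectation; for sex-chromosome-style
contrasts the expectation is taken as the chromosome's intrastrand
count divided by the genome-wide intra/inter ratio — one reasonable
construction among several, documented as such.

## Enrichment model

For a peak set of n intervals, k = number of peaks sharing ≥1 base with
at least one site of the chosen category (each peak counted once; the
definition is directional).  The background probability that a
uniformly placed interval of length w hits at least one merged site of
length L is (L + w − 1)/G summed over merged sites, capped at 1, with
w the median peak length and G the total genome length; chromosome edge
effects of order w/G are ignored.  A Monte-Carlo alternative
(uniform random re-placement of all peaks, ≥1000 draws, seeded)
cross-checks the closed form.  Significance is the upper-tail binomial
P(X ≥ k) (computed via the survival function, checked against direct
mass summation to 1e-12 for n ≤ 1000) and the enrichment ratio is
(k/n)/p.  No multiple-testing correction is applied across peak sets.

Topology-class composition inside peaks counts *all* overlapping
records (no unique-site merging — any overlapping prediction could be
the functional one) and scores each class with the asymptotic Poisson z
of the in-peak count against genome-wide class fractions scaled to the
in-peak total, on both denominators (all PQS; interstrand-only).
Classes absent from both populations get z = 0 and a degenerate flag.

## Synthetic data and oracles

`random_sequence` draws i.i.d. letters with P(G)=P(C)=gc/2.
`pqs_free_background` additionally rewrites any base completing a G/C
run of tract length, so no tract — hence no motif of any class — can
exist anywhere; the guarantee is a necessary-condition argument
(no `GGG`/`CCC` substring) asserted by direct inspection, independent
of the scanner.  `plant_pqs` writes a motif with chosen member word,
tract lengths and gap lengths into such a background, fills loops from
{A, T} so loops can never extend tracts, and rewrites the single
flanking base on each side to T so background cannot extend terminal
tracts; it returns exact truth coordinates.  `make_planted_genome`
spaces plants ≥50 nt apart (far beyond any gap bound, so tracts of
different plants cannot combine) and fixes tract lengths at the minimum
so the greedy-gap truncation described above cannot shift truth
coordinates; gap lengths and member choice are randomised within
bounds.

The brute-force oracle enumerates, per member word, every assignment of
four ordered non-overlapping tract substrings (each a run of the
letter's nucleotide, ≥ t long; all same-letter tracts of equal length,
mirroring exact-string backreferences between identical-character runs)
with every inter-tract gap within its adjacency bounds.  Existence of a
placement is equivalent to existence of a regex match; placement counts
exceed match counts because global matching is non-overlapping and
greedy.  The oracle shares no code with the scanner and is restricted
to sequences ≤500 nt.

## What the tests do and do not show

The synthetic generator produces i.i.d. backgrounds; it does not emulate
isochores, repeats, CpG islands or real G4-rich promoter composition.
Passing tests therefore demonstrate the correctness of the matching,
merging and testing machinery under the stated motif definitions — not
the biological prevalence figures, which depend on the real genome.
Problem sizes were chosen as the smallest that make each property
sharp: oracle agreement over 500 random 120-nt sequences per GC level
{0.3, 0.5, 0.7} × 10 classes (15,000 comparisons); planted recovery on
a 100 kb genome with 10 plants per class; null calibration with 200
replicates of 200 uniformly placed 100-bp peaks on a 200 kb GC-0.6
genome (GC 0.6 gives a few hundred genuine sites, hence a background
probability far from 0 and a non-degenerate binomial; at lower GC the
calibration is vacuous).  The genome-scale test reproducing published
per-chromosome counts needs the ~3 GB hg19 assembly under `scratch/`
and 1–2 h of CPU, and reports how to supply it when absent.  Whether
the original genome-wide analysis uppercased soft-masked bases is not
recorded; both `fold` and `strict` modes are provided, and exact count
reproduction should quote the mode used.

## Numerical and interface choices

Binomial tails come from scipy's survival function; p = 0 with k > 0
reports (0, ∞); empty categories give ratio 0.  Merging and overlap
queries use sorted numpy arrays and binary search; a quadratic
union-find over the pairwise overlap graph serves as the test oracle.
Ratios with zero denominators are NaN.  All randomised entry points
take a seed and echo it in output headers; writers sort and emit
parameter headers so reruns are byte-identical.
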