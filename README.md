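# allquads

Prediction of putative G-quadruplex-forming sequences (PQS) that draw
their four guanine tracts from **one or both strands** of double-stranded
genomic DNA.

## The problem

A G-quadruplex (G4) is a four-stranded DNA structure built from stacked
guanine tetrads; it needs four runs of guanine close together.  Nearly
all genome-wide G4 predictors look for the classical intrastrand motif

    G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+        (or its C-run complement)

on a single strand.  But genomic DNA is double-stranded: the four
guanine tracts can also be distributed between the two strands.  The
duplex of `GGGAGGGACCCACCC`, for instance, pairs it with
`CCCTCCCTGGGTGGG`, and the 12 guanines of the two strands can fold into
a single G4 cage.  Writing `A` for a G-tract and `B` for a C-tract (a
G-tract on the complementary strand), read 5'→3' on the scanned strand,
the order of the four tracts defines the **topology class** of the
possible quadruplex.  Reverse-complement words describe the same duplex
locus and are not distinguished, which leaves **nine interstrand
classes** — AABB, ABAA, ABAB, ABBA, ABBB, BAAA, BABA, BABB, BBAA — in
addition to the intrastrand class AAAA (five classes if mirror-image
pairs such as ABAB/BABA are also identified).

`allquads` finds all ten classes with one Perl-compatible regular
expression per class, e.g.

    AABB:  (G{3,}).{1,7}\1.{0,7}(C{3,}).{1,7}\2
    AAAA:  (G{3,}).{1,7}\1.{1,7}\1.{1,7}\1 | (C{3,}).{1,7}\2.{1,7}\2.{1,7}\2

Loops between same-letter tracts span 1–7 nt, gaps between
different-letter tracts 0–7 nt (the structure switches strands, so
adjacency is allowed); backreferences force same-letter tracts to repeat
the first tract's exact string; matching is global, greedy and
non-overlapping within a class.  A relaxed variant replaces 7 with 12.

Downstream, overlapping predictions of different classes are merged into
*unique sites* (connected components under ≥1-shared-base overlap, by an
O(N log N) sweep), per-chromosome densities and intrastrand/interstrand
ratios are tabulated, and association with functional interval sets
(ChIP-seq peaks, replication origins, promoters) is tested with an
upper-tail binomial test: for k of n peaks overlapping a site, against a
length-aware background probability p, the significance is
P(X ≥ k), X ~ Binomial(n, p), and the enrichment ratio is (k/n)/p.
Topology-class composition shifts inside peaks are scored with
asymptotic Poisson z-scores.

Intended users: genomics researchers studying non-B DNA structure,
transcription initiation, and replication origins.

## Worked example

Scanning the duplex 15-mer from above:

```sh
$ printf ">example\nGGGAGGGACCCACCC\n" > example.fa
$ allquads scan --fasta example.fa --out-format text
# allquads 1.0.0 text min_tract=3 same_loop=1-7 cross_gap=0-7 case=fold
example	AABB	1	GGGAGGGACCCACCC
```

Exactly one PQS is reported: topology class AABB (two G-tracts then two
C-tracts), starting at position 1 (the text dialect is 1-based; BED
output is 0-based half-open).  No intrastrand (AAAA) motif exists here —
each strand alone has only two guanine runs — so classical predictors
report nothing.  The four tracts contribute 3+3+3+3 = 12 guanines to the
quadruplex cage, which `allquads.guanines_in_quadruplex` returns.

A synthetic round trip with planted ground truth:

```sh
$ allquads simulate --length 5000 --gc 0.4 --seed 5 \
      --plant AABB:100,ABAB:900,AAAA:2000 --out-prefix sim
$ allquads scan --fasta sim.fa --out-format bed --out scan.bed
$ printf "synthetic\t5000\n" > lens.tsv
$ allquads stats --in scan.bed --fai lens.tsv
seq_id	length_bp	n_interstrand_unique	n_intrastrand	density_inter_per_mb	density_intra_per_mb	intra_inter_ratio
genome_wide	5000	2	1	400.00	200.00	0.50
synthetic	5000	2	1	400.00	200.00	0.50
```

The scan recovers exactly the three planted motifs (`AABB:4`, `ABAB:6`,
`AAAA:SS` in BED name fields; the number is the historical interstrand
class index), and the statistics table reports 2 unique interstrand
sites, 1 intrastrand PQS, and their ratio 0.50.  `allquads merge` and
`allquads enrich` continue the pipeline on BED files.

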