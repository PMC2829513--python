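# Methods

## Repeat detection

A locus is a maximal perfect run of a primitive unit. Concretely, for
each unit length k ∈ {2..6} the scanner finds every maximal period-k run
(not extendable by even one base on either side), takes the leading
k-mer as the unit, and reports the locus when the unit is primitive and
the whole-copy count ⌊L/k⌋ meets the threshold. Consequences of this
definition:

* a trailing partial unit extends neither the coordinates nor the count
  (`AAG×5 + AAGA` is an AAG×6 locus of 18 bp — the full sixth copy
  counts, the final `A` does not);
* the unit is recorded in run phase as first observed, while all
  aggregation uses the canonical class, so strand and phase never
  fragment counts;
* characters outside A/C/G/T terminate runs;
* maximal runs of equal period are disjoint, so same-unit-length loci
  never overlap; loci of different unit lengths may (rarely) overlap and
  both are kept, since each satisfies its own definition;
* compound or interrupted repeats are not merged — a sequence holds as
  many independent loci as qualify.

Default thresholds are 6/5/4/4/4 copies for k = 2..6 (minimum locus
lengths 12/15/16/20/24 bp); mononucleotide runs are never reported.
Anything ≥ 12 bp total that meets its per-k copy minimum is therefore
included, dinucleotide×6 = 12 bp being the shortest admissible locus.

The canonical class of a primitive unit is the lexicographic minimum
over its cyclic rotations and those of its reverse complement. This
yields 4/10/33/102/350 classes for k = 2..6 (verified exhaustively in
the tests). Published class tables occasionally print pairs that are not
reverse complements of each other (e.g. "AGC/CGT"); we treat those as
typography and keep the standard classes.

## Summary tables

Percentages everywhere are rounded half-up to one decimal via decimal
arithmetic, which reproduces printed survey tables exactly (e.g.
1,552/2,810 → 55.2 %). Density divides loci by total scanned length at
1 Mb = 10⁶ bp (2,810 loci / 18.8 Mb → 149.5 per Mb). Frequency is
reported on two bases — loci per scanned sequence and SSR-bearing
sequences per scanned sequence — because surveys quote either without
saying which; the field names make the basis explicit. Repeat-number
bins are exact at 4..10 with a ">10" tail; unit-length rows render
sub-threshold cells as "-". The reads-per-consensus histogram uses exact
bins 2..10, 5-wide bins to 50, and a top bin for ≥ 51 counts (its
conventional label ">51" notwithstanding — a 46–50 bin followed
literally by ">51" would drop 51).

## Primer design

Candidates are every (start, length) window in each flank with length
18–28 nt, GC 40–70 %, and no homopolymer run over 4; pairs must give a
product of 100–300 bp that contains the entire repeat, with neither
primer overlapping it. Melting temperature uses the Wallace rule
2(A+T) + 4(G+C), chosen because it is deterministic, dependency-free and
exactly consistent with the 20-mer/50 %-GC/60 °C optimum; it is a
deliberate simplification relative to nearest-neighbor thermodynamics,
as is the omission of dimer/hairpin screening (the homopolymer filter
removes the worst candidates). Ranking minimizes
Σ(|len−20| + |Tm−60| + 0.5·|GC−50|) over both primers; ties break by
smaller product, then leftmost forward, then leftmost reverse start, so
output is fully deterministic. Enumeration is windowed to within one
maximum product length of the locus, and templates are capped at
5,000 bp (trim around the locus for longer inputs). Failures are
machine-readable: `product_window_empty`, `flank_too_short`,
`no_valid_forward`, `no_valid_reverse`, `no_valid_pair`.

## Diversity statistics

Per locus, over typed individuals only: Ho is the fraction of
heterozygotes; He is the unbiased gene diversity n/(n−1)·(1 − Σp²) with
n = 2 × typed individuals (the gene-diversity definition used by the
standard population-genetics packages); PIC is the Botstein form
1 − Σp² − Σ_{i<j} 2p_i²p_j². A monomorphic locus scores 0 on all three.

Dps between two individuals averages shared allele copies
(Σ_alleles min(copies_a, copies_b), 0–2 per locus) over loci typed in
both (pairwise deletion), giving ps ∈ [0,1] and distance −ln(ps). When
nothing is shared, ps is floored at half a copy over the comparable loci
(0.5/(2·n_loci)) so the distance stays finite; the choice is a
pseudo-count convention, flagged here because the classic tools leave
the ps = 0 case undefined.

## Neighbor joining and bootstrap

NJ follows Saitou–Nei agglomeration with the Studier–Keppler criterion
Q(a,b) = (r−2)d(a,b) − R_a − R_b. Ties on Q join the pair whose
canonical labels (alphabetically first leaf below each node) sort
smallest, making topologies reproducible. Negative branch-length
estimates are clamped to zero with the deficit moved to the sibling edge
(at the final trifurcation, clamped without transfer); raw estimates are
retained on the node. On additive matrices the output tree reproduces
the input path lengths to ≤ 1e-9 (tested on random trees). Bootstrap
resamples loci — not individuals — with replacement, matching the
marker-resampling convention for distance trees; supports are the
percentage of replicates containing each internal bipartition of the
full-data tree. Newick output carries branch lengths at 5 decimals and
supports as internal labels, optionally suppressing values below a
display threshold (30 by default in the examples, a common figure
convention).

Species-level trees are available by pooling individuals
(`pool_individuals`), which keeps one row per group using the first
non-missing call per locus; the default operates on individuals.

## Synthetic data

The EST generator plants exact repeats at specified offsets in i.i.d.
background sequence and re-rolls a record's background whenever the
detector output differs from the planted truth; truth tables are
therefore complete by construction and recovery tests can demand exact
equality rather than high probability. The genotype generator draws two
gene copies per individual per locus from the locus's allele-frequency
vector (Hardy–Weinberg) and masks calls at a configurable missing rate;
all randomness flows from one integer seed per call.

What the simulations do not emulate: sequencing error (including 454
homopolymer noise), assembly artifacts, linkage between loci, mutation
models (SMM/IAM), null alleles and genotyping error. Passing tests
therefore demonstrate algorithmic correctness on clean inputs, not
robustness to those real-data effects.

## Problem sizes and defaults

Recovery and equivalence checks run at sizes where the independent
oracles stay exact and fast: 1,000 random 300-bp sequences for detector
equivalence, 200 templates of ~420 bp for primer optimality against
exhaustive search, 200 individuals × 10 loci for diversity parameter
recovery (3-standard-error bands, with delta-method standard errors for
He and PIC), and 6-taxon additive matrices for NJ. Statistical
recoveries use Dirichlet(3)-drawn allele frequencies with 2–6 alleles
per locus, a realistic spread for SSR panels.

## Known limitations

* Imperfect/compound SSR detection (mismatch-tolerant, Sputnik-style)
  is out of scope; only perfect repeats are found.
* The Wallace Tm and L1 penalty are simpler than Primer3's model; ranked
  lists will differ from Primer3 even under identical constraints.
* Dps's zero-share floor and the NJ tie rule are conventions; other
  software may break ties differently and produce a different but
  equally valid resolution of tied joins.
* He/PIC assume codominant, correctly sized alleles; null alleles bias
  Ho downward and are not modeled.
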