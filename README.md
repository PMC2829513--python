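# ssrmine

Toolkit for developing EST-SSR markers from transcript sequences: mine
perfect microsatellites, summarize their frequency and motif spectrum,
design flanking primer pairs, and evaluate the resulting marker panels
with diversity statistics and distance dendrograms.

It is aimed at researchers building SSR marker sets for little-studied
plant taxa from EST/transcriptome assemblies — the setting where a few
thousand consensus sequences are scanned for repeats, a few dozen primer
pairs are synthesized, and the surviving polymorphic markers are used to
genotype a germplasm panel.

## What it computes

**SSR mining.** A perfect microsatellite is a maximal run of a primitive
unit *u* (2–6 bp; `ATAT` is a phase of the dinucleotide `AT`, never a
tetranucleotide) repeated at least 6/5/4/4/4 times for unit lengths
2/3/4/5/6; mononucleotide runs are excluded. Each locus is assigned to a
canonical motif class — the lexicographically smallest string among all
cyclic rotations of *u* and of its reverse complement — so `CTT`, `TTC`
and `AAG` all count toward the `AAG/CTT` class. There are 4, 10, 33, 102
and 350 such classes for k = 2…6. Summaries report counts and
round-half-up percentages by unit length × repeat number and by class,
plus frequency (loci per scanned sequence) and density (loci per Mb).

**Primer design.** Candidate forward/reverse pairs in the locus flanks
are enumerated exhaustively under hard constraints (length 18–28 nt, GC
40–70 %, no homopolymer > 4, product 100–300 bp containing the whole
repeat) and ranked by the L1 penalty
`|len − 20| + |Tm − 60| + 0.5·|GC − 50|` summed over both primers, with
the Wallace rule `Tm = 2(A+T) + 4(G+C)`.

**Marker diversity.** From diploid allele-size tables: allele counts,
observed heterozygosity Ho, unbiased expected heterozygosity
`He = n/(n−1)·(1 − Σpᵢ²)` (n = typed gene copies), and
`PIC = 1 − Σpᵢ² − ΣΣ 2pᵢ²pⱼ²`; between individuals the shared-allele
distance `Dps = −ln(ps)`; and neighbor-joining dendrograms (Saitou–Nei
with the Studier–Keppler Q-criterion) with bootstrap supports from
resampling loci.

A seeded simulation module generates EST sets with planted repeats (and
exact truth tables) and Hardy–Weinberg genotype tables, so the whole
pipeline is testable without external data.

## Worked example

`python examples/diversity_tree.py` simulates 12 individuals at 8
four-allele loci and prints:

```
locus        n  Na      Ho      He     PIC
EsSSR01     10   4   0.600   0.784   0.697
EsSSR02     12   4   0.917   0.779   0.699
...
NJ tree (supports = % of 100 locus-bootstrap replicates):
(((((ind001:0.47896,ind010:0.21419)33:0.15202,...,ind011:0.39430):0.08941);
```

`n` is the number of typed individuals, `Na` the allele count, and
Ho/He/PIC the per-locus diversity statistics above — Ho close to He is
what Hardy–Weinberg sampling should give, and PIC ≈ 0.65–0.70 marks an
informative marker. Internal-node labels in the Newick string are
bootstrap percentages (values below 30 suppressed). The other examples
(`mine_ssrs.py`, `design_primers.py`) print the survey tables and a
ranked primer list the same way.

The same operations are available as a CLI:

```sh
ssrmine simulate --n-records 20 --seed 1 --out work/
ssrmine detect work/synthetic_ests.fasta --out work/ --markdown
ssrmine design work/synthetic_ests.fasta work/ssr_loci.tsv --out work/
ssrmine diversity work/synthetic_genotypes.tsv --bootstrap 100 --seed 1 --out work/
```

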