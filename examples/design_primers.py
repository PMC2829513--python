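"""Design flanking primer pairs for one SSR locus.

Generates a 420-bp template with a centered AAG repeat, asks for the five
best primer pairs under the standard constraints (18-28 nt, GC 40-70%,
product 100-300 bp, Tm optimum 60 C), and prints the ranked candidates.
A penalty of 0 means both primers hit every optimum exactly (20-mer,
50% GC, Wallace Tm 60 C).
"""

from ssrmine.primer_design import design_primers
from ssrmine.simulate import random_templates_with_ssr

records, truth = random_templates_with_ssr(1, seed=11, length=420)
record, locus = records[0], truth[0]
print(f"template {record.id}: {len(record)} bp, "
      f"SSR {locus.unit}x{locus.repeat_count} at {locus.start}-{locus.end}")

result = design_primers(record, locus, max_pairs=5)
print(f"{'rank':<5}{'forward':<24}{'reverse':<24}"
      f"{'product':<9}{'Tm_f':<6}{'Tm_r':<6}{'penalty'}")
for rank, p in enumerate(result.pairs, start=1):
    print(f"{rank:<5}{p.fwd_seq:<24}{p.rev_seq:<24}"
          f"{p.product_size:<9}{p.tm_f:<6.1f}{p.tm_r:<6.1f}{p.penalty:.2f}")
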