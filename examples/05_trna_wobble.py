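"""Cloverleaf tRNA structure statistics and the H- vs L-strand wobble test.

Generates a 22-tRNA set pooled over a 37-species panel with G-U wobble
probabilities 3% (heavy strand) vs 13% (light strand), partitions each
dot-bracket structure into stems and loops, and runs the Mann-Whitney
strand comparison.  Also checks the mTERF tridecamer.
"""

from mitocomp import (
    generate_trna_set, mterf_site_check, partition_cloverleaf,
    site_frequencies, strand_comparison, wobble_table,
)
from mitocomp.trna import MTERF_TRIDECAMER

genes, truth = generate_trna_set(seed=1, n_species=37)
structs = [partition_cloverleaf(g.sequence, g.dot_bracket, name=g.name,
                                strand=g.strand, anticodon_pos=g.anticodon_pos)
           for g in genes]

summary = wobble_table(structs)
print(summary.table[["trna", "strand", "total_wobble", "total_pairs",
                     "pct_wobble"]].round(2).head(5).to_string(index=False))
print("strand means (% wobble):", dict(summary.strand_means.round(2)))
u, p = strand_comparison(summary)
print(f"Mann-Whitney U = {u:.1f}, p = {p:.2e}")

sf = site_frequencies(structs)
anchors = sf[sf.site.isin(["1-87", "12-32", "40-48", "64-74"])]
print(anchors[["stem", "site", "pct_bonded"]].round(1).to_string(index=False))

hit = mterf_site_check("ACGGT" + MTERF_TRIDECAMER + "TTACA")
print(f"mTERF tridecamer found at offset {hit.offset} with "
      f"{hit.n_mismatches} mismatches")
print("Light-strand tRNAs carry several-fold more G-U wobble pairs than "
      "heavy-strand ones, and the rank test flags the contrast at p << 0.01.")
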