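"""Control-region annotation: conserved sequence blocks, palindromes,
T-homopolymer, divergence masks.

Builds an 840 bp synthetic control region with CSB-E carrying 4 planted
substitutions, annotates it against the shipped motif library, and
prints the hits with their divergence masks ('*' identity, uppercase =
substitution, lowercase = insertion, '-' = deletion).
"""

import warnings

from mitocomp import annotate_control_region, generate_control_region

warnings.simplefilter("ignore")

region, truth = generate_control_region(seed=1, motif_edits={"CSB-E": (4, 0, 0)})
ann = annotate_control_region(region)

print(f"region: {len(region)} bp; canonical CSB order satisfied: "
      f"{ann.order_satisfied}")
for name, hit in ann.hits.items():
    if hit is None:
        print(f"  {name:<16s} no hit")
        continue
    print(f"  {name:<16s} {hit.start:>4d}-{hit.end:<4d} "
          f"sub={hit.n_substitutions} indel={hit.n_insertions + hit.n_deletions}  "
          f"{hit.mask.text}")

print("palindromic TACAT/ATGTA copies:", ann.palindromes)
print("T-homopolymer between CSB-D and CSB-1:", ann.flagged_t_run)
print("tandem repeats:", ann.tandem_repeats or "none")
print("The four uppercase letters in the CSB-E mask are the planted "
      "substitutions; the repeat-free region with a mid-length T-run "
      "mirrors the family-typical D-loop architecture.")
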