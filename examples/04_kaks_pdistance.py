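"""Pairwise p-distances and Nei-Gojobori Ka/Ks.

Simulates a three-taxon gene family under near-neutral point mutation,
then under purifying-style constraint (synonymous changes only), and
prints the partitioned p-distances and the Ka/Ks averages.
"""

import numpy as np

from mitocomp import AlignedGeneSet, gene_average_kaks, kaks_pair, p_distance
from mitocomp.codon_usage import ALL_CODONS, codon_to_aa

STOPS = {"TAA", "TAG", "AGA", "AGG"}
SENSE = [c for c in ALL_CODONS if c not in STOPS]
rng = np.random.default_rng(0)


def mutate(seq, n_mut, synonymous_only):
    q = list(seq)
    hit = set()
    while len(hit) < n_mut:
        ci = int(rng.integers(len(q) // 3))
        if ci in hit:
            continue
        old = "".join(q[ci * 3: ci * 3 + 3])
        options = [(p, b) for p in range(3) for b in "ACGT" if b != old[p]]
        for j in rng.permutation(len(options)):
            p, b = options[int(j)]
            new = old[:p] + b + old[p + 1:]
            if new in STOPS:
                continue
            if synonymous_only and codon_to_aa(new) != codon_to_aa(old):
                continue
            q[ci * 3: ci * 3 + 3] = list(new)
            hit.add(ci)
            break
    return "".join(q)


anc = "".join(rng.choice(SENSE, size=300))
neutral = {f"taxon{i}": mutate(anc, 40, synonymous_only=False) for i in range(3)}
aln = AlignedGeneSet("neutral_gene", neutral)
for part in ("all", "pos12", "pos3"):
    print(f"p-distance ({part}): {p_distance(aln, part).mean_p:.4f}")
r = gene_average_kaks(aln)
print(f"neutral family: mean Ka {r.ka:.4f}, mean Ks {r.ks:.4f}, Ka/Ks {r.ratio:.3f}")

constrained = {f"taxon{i}": mutate(anc, 40, synonymous_only=True) for i in range(3)}
rc = gene_average_kaks(AlignedGeneSet("constrained_gene", constrained))
print(f"synonymous-only family: Ka {rc.ka:.4f}, Ks {rc.ks:.4f}, Ka/Ks {rc.ratio:.3f}")
print("Unconstrained mutation gives Ka/Ks near 1; a gene admitting only "
      "silent changes gives Ka/Ks = 0, the purifying-selection signature "
      "(published per-gene averages span 0.008-0.469).")
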