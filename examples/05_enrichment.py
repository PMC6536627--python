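"""Hypergeometric over-representation analysis of a called-transcript list.

Builds a toy gene-set collection over a 2,000-id universe, spikes one set
with members of the target list, and tests each set for over-representation
(minimum 5 members within the background, BH-corrected).
"""

import numpy as np

from stresspattern import GeneSetCollection, ora

rng = np.random.default_rng(0)
background = [f"T{i:05d}" for i in range(2000)]
target = list(rng.choice(background, 120, replace=False))

sets = {}
for i in range(6):
    members = set(rng.choice(background, 40, replace=False))
    if i == 0:  # spike: half of this category comes from the target list
        members = set(target[:20]) | set(list(members)[:20])
    sets[f"pathway_{i}"] = members
sets["tiny"] = set(background[:4])  # below the 5-member floor, never tested

res = ora(target, background, GeneSetCollection(sets), min_size=5, alpha=0.05)
print(res.to_string(index=False))
print("\np is the hypergeometric upper tail of the observed overlap;")
print("q is BH-adjusted over the tested categories; 'tiny' was excluded")
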