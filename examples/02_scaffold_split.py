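"""Scaffold-based data splitting: no structural framework straddles splits.

Drugs are grouped by canonical Bemis-Murcko scaffold; whole groups are
assigned to train/valid/test in an 8:1:1 ratio, and every labeled link
inherits its most-held-out endpoint — so test links always probe a drug
from an unseen scaffold.
"""

from collections import Counter

from ddilink.chem_graph import bemis_murcko_scaffold, scaffold_split, split_links
from ddilink.synthdata import SyntheticSpec, generate_ddi, generate_molecules

spec = SyntheticSpec(n_drugs=100, seed=0)
mols = generate_molecules(spec)
drugs = [(d, s) for d, s, _ in mols]
network = generate_ddi(mols, spec)

assignment = scaffold_split(drugs, ratios=(0.8, 0.1, 0.1), seed=42)
counts = Counter(assignment.drug_split.values())
print("drug split sizes:", dict(counts))

scaffolds_by_split: dict = {}
for d, s in drugs:
    scaffolds_by_split.setdefault(assignment.drug_split[d], set()).add(
        bemis_murcko_scaffold(s)
    )
overlap = scaffolds_by_split["train"] & scaffolds_by_split.get("test", set())
print(f"scaffolds shared between train and test: {len(overlap)} (must be 0)")

link_split = split_links(network, assignment.drug_split)
print("link split sizes:", dict(Counter(link_split.values())))
print("every test link touches a drug whose scaffold was never seen in training")
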