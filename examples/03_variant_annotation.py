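"""Re-annotate fragments as 1-2-indel variants of known 5'-tRFs.

Builds an index of exact 28-36 nt tRNA 5' prefixes, generates tRF fragments
of which half carry 1-2 nt indels, and resolves each fragment back to its
source tRNA with a banded edit distance capped at 2.
"""

from evtrf import SimulationConfig, annotate_variants, five_prime_prefixes
from evtrf.simulate import build_fragment_universe, simulate_references

cfg = SimulationConfig(
    seed=13, n_case=2, n_control=2, class_mix={"tRNA": 1.0},
    n_refs={"tRNA": 40}, n_fragments={"tRNA": 120}, variant_fraction=0.5,
)
refs = simulate_references(cfg)
truth = build_fragment_universe(cfg, refs)
index = five_prime_prefixes(refs["tRNA"], range(28, 37))
print(f"indexed {len(index)} distinct 5'-tRF prefixes from {len(refs['tRNA'])} tRNAs")

variants = truth[truth["edit_count"] > 0]
ann = annotate_variants(list(variants.index), index)
print(ann["status"].value_counts().to_string())

correct = 0
for frag, row in variants.iterrows():
    sources = set(ann.loc[frag, "sources"].split(","))
    if row["source_ref"] in sources and ann.loc[frag, "distance"] == row["edit_count"]:
        correct += 1
print(f"\n{correct}/{len(variants)} indel variants resolved to their true "
      "source tRNA at the true edit distance")
row = ann[ann["status"] == "variant"].iloc[0]
print(f"example: d={row['distance']} "
      f"({row['insertions']} ins, {row['deletions']} del, "
      f"{row['substitutions']} sub) from prefix of {row['sources']}")
# Fragments that fail substitution-only database mapping are recovered here
# as minor indel variants of canonical 5'-tRNA halves.
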