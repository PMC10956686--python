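"""Differential fragment expression on a cohort with known fold changes.

Simulates count tables for 8 preeclampsia-like vs 6 control EV libraries
with 20 fragments truly upregulated 4-fold, normalises within RNA class to
RPM, applies the >100 RPM abundance filter, per-fragment two-sided
Mann-Whitney tests and Benjamini-Hochberg correction, then reports how many
true fragments were recovered and the cumulative abundance share of the
top-ranked discoveries.
"""

from evtrf import (
    FragmentTable,
    SimulationConfig,
    cumulative_share,
    differential_expression,
    rpm_normalize,
)
from evtrf.simulate import build_fragment_universe, simulate_counts, simulate_references

cfg = SimulationConfig(
    seed=5, n_case=8, n_control=6, class_mix={"tRNA": 1.0},
    n_refs={"tRNA": 60}, n_fragments={"tRNA": 500},
    n_de=20, de_fold=4.0, de_min_rpm=500.0, library_size=30_000,
)
refs = simulate_references(cfg)
truth = build_fragment_universe(cfg, refs)
counts = simulate_counts(cfg, truth)

rpm = rpm_normalize(FragmentTable(counts), truth["rna_class"])
de = differential_expression(rpm, cfg.groups, classes=truth["rna_class"])

true_de = set(truth.index[truth["fold_change"] > 1])
sig = set(de.index[de["significant"]])
tp = len(sig & true_de)
print(f"fragments passing the >100 RPM filter: {len(de)}")
print(f"significant at q<0.05: {len(sig)} "
      f"({tp} of {len(true_de)} true 4-fold fragments recovered)")

if sig:
    case_samples = cfg.groups.index[cfg.groups == "case"].tolist()
    k = min(12, len(sig))
    share = cumulative_share(de, rpm, case_samples, k)
    print(f"top-{k} discoveries carry {100 * share:.0f}% of the "
          "summed case-group normalized counts of all discoveries")
# With n=8 vs 6 the exact Mann-Whitney p-value floor is 2/3003, so only
# near-complete group separations survive BH; discoveries are concentrated
# in a handful of abundant fragments.
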