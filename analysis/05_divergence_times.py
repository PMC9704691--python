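"""Do genetic divergence times within families match the linguistic root
ages?  Root-level population pairs per family, converted to years via
t = 2 Ne x linearized FST, against the family age intervals."""

from gelamatch.data_model import read_newick
from gelamatch.popgen import divergence_time
from gelamatch.timedepth import (
    compare_family_ages,
    comparison_table,
    read_family_ages,
    root_level_pairs,
)

from common import PANELS, RESULTS, analysis_config, load_panel

panel, fst = load_panel("scenario")
cfg = analysis_config()
ages = read_family_ages(PANELS / "scenario" / "family_ages.tsv")
rows = []
for fam, rec in sorted(ages.items()):
    tree = read_newick(PANELS / "scenario" / "trees" / f"{fam}.nwk")
    pairs = root_level_pairs(tree, panel, fam)
    triples = []
    for a, b in pairs:
        ra, rb = panel[a], panel[b]
        triples.append((a, b, divergence_time(fst.get(a, b), ra.ne, rb.ne,
                                              cfg, a, b)))
    cmp = compare_family_ages(triples, rec)
    rows.append(cmp)
    if cmp.assessable:
        print(f"{fam}: {cmp.n_pairs} root pairs, median genetic time "
              f"{cmp.median_t_years:.0f} y vs interval "
              f"[{rec.bayes_low:.0f}, {rec.bayes_high:.0f}] y "
              f"(ratio to midpoint {cmp.median_ratio_to_midpoint:.2f})")

comparison_table(rows).to_csv(RESULTS / "timedepth.tsv", sep="\t", index=False)
print(f"wrote {RESULTS / 'timedepth.tsv'}")
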