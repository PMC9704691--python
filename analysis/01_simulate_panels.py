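"""Generate the study panels: one default scenario with planted events and
one event-free (null) panel, written as the plain-text inputs every later
script consumes."""

from gelamatch.data_model import write_fst_matrix, write_panel, write_newick
from gelamatch.synthetic import (
    ScenarioConfig,
    expected_fst_matrix,
    family_language_tree,
    generate_panel,
    truth_table,
)

from common import PANELS, SEED

for name, events in (("scenario", None), ("null", {})):
    cfg = (ScenarioConfig(rng_seed=SEED) if events is None
           else ScenarioConfig(rng_seed=SEED + 50, events=events))
    panel, truth = generate_panel(cfg)
    fst = expected_fst_matrix(truth, cfg)
    out = PANELS / name
    out.mkdir(parents=True, exist_ok=True)
    write_panel(panel, out / "populations.tsv")
    write_fst_matrix(fst, out / "fst_matrix.tsv")
    truth_table(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    trees = out / "trees"
    trees.mkdir(exist_ok=True)
    ages = []
    for fam in sorted(panel.family_index):
        write_newick(family_language_tree(truth, fam), trees / f"{fam}.nwk")
        root_years = truth.family_root_age_gen[fam] * cfg.generation_years
        ages.append((fam, 0.9 * root_years, 1.1 * root_years))
    with open(out / "family_ages.tsv", "w") as fh:
        fh.write("family\tbayes_low\tbayes_high\n")
        for fam, lo, hi in ages:
            fh.write(f"{fam}\t{lo:.1f}\t{hi:.1f}\n")
    ev = truth_table(truth)
    n_ev = (ev["event"] != "none").sum()
    print(f"{name}: {len(panel)} populations, {len(panel.family_index)} "
          f"families, {n_ev} planted events -> {out}")
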