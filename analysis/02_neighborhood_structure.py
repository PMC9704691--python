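"""How often are genetic neighbours linguistic relatives?  Radius counts of
other-family neighbours and the family concordance of each population's
closest-FST neighbour."""

import numpy as np

from gelamatch.geodesy import concordance_rate, neighbor_counts, neighbor_table

from common import RESULTS, load_panel

panel, fst = load_panel("scenario")
summaries = neighbor_counts(panel, fst, radii=(500.0, 1000.0))
table = neighbor_table(summaries)
table.to_csv(RESULTS / "neighbors.tsv", sep="\t", index=False)

p500 = np.mean([s.counts_other_family[500.0] > 0 for s in summaries])
p1000 = np.mean([s.counts_other_family[1000.0] > 0 for s in summaries])
disc = concordance_rate(summaries)
print(f"populations with an other-family neighbour within 500 km: {p500:.0%}")
print(f"  ... within 1000 km: {p1000:.0%}")
print(f"closest genetic neighbour in a *different* family: {disc:.1%} "
      f"of {len(summaries)} populations")
print(f"wrote {RESULTS / 'neighbors.tsv'}")
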