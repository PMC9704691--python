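# Methods

This note records the models, decision rules and numerical choices behind
`gelamatch`, and what the synthetic testbed does and does not establish
about behaviour on real data.

## Genetic distance and time

Pairwise differentiation is the two-population Weir–Cockerham θ, combined
across loci as a ratio of component sums (Σa / Σ(a+b+c)), the standard
combination with the smallest ratio bias.  Loci monomorphic across both
samples, or with fewer than two genotyped individuals in either sample, are
skipped.  Small negative estimates are legitimate sampling outcomes on
weakly differentiated pairs; they are preserved in matrices and
distributions and clamped to zero only at linearization.  A consequence
worth knowing: two *identical* finite samples do not give θ = 0 but a small
negative value, because the estimator subtracts the expected sampling
variance; θ is exactly zero for identical samples only when observed
heterozygosity equals 4p̄(1−p̄) at every usable locus.

Linearized F<sub>ST</sub> = F<sub>ST</sub>/(1−F<sub>ST</sub>) grows
approximately linearly with divergence time under pure drift, which is why
both the isolation-by-distance regressions and the time conversion use it.
Divergence time is t = 2·N<sub>e</sub>·linearized F<sub>ST</sub> generations,
with 29 years per generation.  Which N<sub>e</sub> to use for a pair is
genuinely open; the default is the harmonic mean of the two populations'
sizes (drift accumulates at rate 1/N<sub>e</sub> along each lineage), with
arithmetic mean and minimum available via `AnalysisConfig.ne_combine`.
Credible intervals on N<sub>e</sub>, when provided, propagate linearly to
time bounds.  Under the Balding–Nichols drift model used for validation the
estimate carries an upward bias of (e^τ − 1)/τ with τ = t/(2N<sub>e</sub>) —
about +11% at τ = 0.2 — which is why round-trip recovery is only asserted
to ±20% and restricted to shallow splits.

N<sub>e</sub> trajectories (from IBD-segment-based inference, consumed as
tables) pass a stability screen over generations 1–50: maximum size ≤ 10⁶,
coefficient of variation ≤ 0.5, median CI ratio ≤ 10, all configurable; the
point estimate is the geometric mean over the window.  These are concrete
defaults for a screening that is qualitative in origin; real analyses should
inspect trajectories rather than trust any fixed threshold.

## Mismatch heuristics

**Drift filter.**  Populations whose median F<sub>ST</sub> both within
their macro-region and globally exceeds 0.1 (strictly) are flagged as
drifted and excluded from distribution-based analyses, since strong drift
inflates all their distances regardless of history.

**Enclaves.**  Eligibility requires a family with more than two sampled
populations and remoteness in at least one dimension: the geographically
nearest same-family population, or the overall closest-F<sub>ST</sub>
population, lies at least `d_far_km` away (default 1000 km; the 500 km
radius floor and 1000 km neighbourhood radius anchor the scale).  The
classification rules are listed in the README; ties in closest-F<sub>ST</sub>
break by geographic distance, then lexicographic id, for determinism.  The
defaults `d_far_km = d_near_km = 1000` are explicit stand-ins for cutoffs
that are not fixed by any published formula.

**Alignment.**  The within-family set is every same-family population with a
finite F<sub>ST</sub> (not distance-restricted — a family's remote members
are precisely the signal); the between-family set is restricted to
other-family populations within the focal family's geographic span
(largest within-family distance, floored at 500 km) of the focal
population, so that the comparison is geographically fair.  Both sets need
at least `min_distribution_size = 3` members.  Misalignment is the strict
inequality median<sub>within</sub> > median<sub>between</sub>.  The 95% CI
on the difference of medians is a percentile bootstrap with independent
resampling of the two sets (2000 draws, seeded per population from the run
seed, hence bit-reproducible).

## Cohesiveness

Within- and between-family trends of linearized F<sub>ST</sub> against
distance are LOWESS local-linear fits (`frac = 0.5`, evaluated on a
50-point grid spanning the observed distances, never extrapolated); the
overall IBD line is OLS.  The published family verdicts are visual; the
quantification here is:

    cohesion_score = median over within pairs of
                     [between-trend at the pair's distance − observed linearized FST]

with *cohesive* meaning score > 0 **and** the within-trend below the
between-trend on ≥ 75% of the mutually supported grid.  A family needs ≥ 10
within pairs (and as many between pairs) to be assessed.  Jackknife
recomputes the score leaving out each member; a verdict that flips on a
single removal should not be trusted, and the analysis scripts print this.

## Time depth and trees

Root-level pairs are population pairs whose languages' MRCA in the family
classification tree is the root; populations lacking an accepted
N<sub>e</sub> or whose language is absent from the tree drop out, as do
same-language pairs.  Family summaries (median time, IQR, fraction inside
the published interval, median ratio to the interval midpoint) are computed
with and without populations carrying any mismatch flag.

Neighbor joining is the standard Saitou–Nei agglomeration; a negative
branch length is clamped to zero with the deficit moved to the sibling so
the pair's path length is preserved.  It is exact on additive matrices,
which the tests verify against independently constructed random trees and
against scikit-bio's implementation.

Quartet similarity is the fraction of all C(n,4) leaf quartets induced
identically — resolved and equal — in both trees, enumerated exhaustively
(limited to 25 leaves; ~12,650 quartets).  Induced topologies come from the
four-point condition on unit-edge-count path lengths, so polytomies yield
ties and count as unresolved; unresolved-in-either counts as non-matching.
Because that convention is one of several defensible readings, a normalized
quartet distance that credits both-unresolved agreement is emitted
alongside.  When several populations share one language, the language tip
is expanded into a zero-length multifurcation carrying one leaf per
population, keeping population-level taxa on both sides.  Calibrated-tree
node ages are measured as the maximum path length from the node down to any
leaf, which tolerates mild non-ultrametricity.

## The synthetic testbed

The generator emulates the statistical structure of a worldwide panel at
the scale the heuristics see: families are Gaussian clusters (σ = 150 km)
around centroids on a ring with 500 km between adjacent centroids; family
internal histories are random coalescent trees with root ages drawn from
2–6 ky; all families split from each other 12 ky ago; N<sub>e</sub> is
uniform on 2,000–10,000 diploids.  Linearized F<sub>ST</sub> for a pair is
t/(2·N<sub>e,harmonic</sub>) plus an IBD term of 2×10⁻⁵ per km — the order
observed across human continental panels — plus Gaussian noise
(σ = 0.003), floored at zero and mapped back to F<sub>ST</sub>.  The
geometry is deliberately compact relative to the 1000-km enclave threshold:
clusters must not produce spurious "remote relative" configurations in the
null scenario, and adjacent families must fall inside each other's spans so
that between-family comparisons exist.  The IBD term uses *genetic*
positions — a displaced colony keeps its ancestral location in that term,
since its genetic relationships predate the move.

Planted events: **shift** relabels a population, in place, to the family
whose sampled populations are most remote (the configuration of the
best-documented real shift cases; a shift to the adjacent family would be
statistically invisible at these noise levels, and `shift_to="nearest"` is
available to demonstrate exactly that); **remote colony** displaces a
population ≥ 1500 km from home with history intact; **assimilation**
displaces it likewise and replaces its lineage with a 500-year-old split
from a host population, keeping its label; **drift isolate** shrinks
N<sub>e</sub> tenfold.  Events avoid reusing an origin/target family pair so
that one event's relabeled or displaced population does not sit next to
another event's target region with a colliding label; residual cross-talk
remains possible (kin of a colony legitimately see a remote closest
relative and can be flagged, and co-planted events can occasionally push an
assimilation out of enclave eligibility while it is still caught as
misaligned), which is why recovery is asserted as precision/recall rather
than exact per-event class labels.

The genotype tier evolves Uniform(0.05, 0.95) ancestral allele frequencies
down the true population tree by Balding–Nichols draws with branch
parameter F = 1 − exp(−Δt/(2N<sub>e</sub>)) and samples binomial diploid
genotypes at the leaves.  It contains no linkage disequilibrium, selection,
SNP-chip ascertainment, admixture gradients, or migration after splits —
so passing tests establish internal consistency of the estimators and
heuristics under drift + IBD, not robustness to those real-data features.
Problem sizes throughout (10,000 loci × 25 diploids for calibrations;
48-population panels; 20 replicates per condition) were chosen as the
smallest at which the targeted tolerances are statistically meaningful.

## Known limitations

- The F<sub>ST</sub>-to-time conversion assumes pure drift at constant size;
  admixture and growth push times around in ways the pipeline only handles
  by exclusion (drift filter, stability screen, declared outliers).
- The enclave cutoffs and cohesion quantification are documented package
  choices standing in for qualitative published criteria; conclusions near
  those thresholds deserve a sensitivity check over `AnalysisConfig`.
- Quartet enumeration is O(n⁴) and capped at 25 shared leaves; larger
  families need subsampling upstream.
- Multi-source F<sub>ST</sub> matrices are assumed already merged and
  consistent; missing pairs are honoured but not imputed.
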