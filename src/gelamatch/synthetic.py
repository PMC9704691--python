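"""Synthetic panel generator with planted match/mismatch events.

Emulates the statistical structure of a worldwide gene-language panel:
language families are spatially clustered, genetic distance grows with
geographic distance (isolation by distance), and within-family genetic
distances are typically smaller than between-family distances at matched
range.  On top of this null structure, the generator plants events with known
ground truth:

* ``shift`` — a population is relabeled to another family while its genetic
  history and location are untouched (language shift in place; misalignment /
  mismatch truth).  By default the adopted family is one whose sampled
  populations are geographically remote, the configuration seen in the
  best-documented real shift cases, where the adopted family's relatives are
  mostly sampled far away.
* ``remote_colony`` — a population is displaced far from its family with
  history and label intact (matching-enclave truth);
* ``assimilation`` — a population is displaced next to a distant host family
  and its genetic lineage is replaced by a recent split from a host
  population, while it keeps its original family label (linguistic-enclave
  truth);
* ``drift_isolate`` — a population's effective size is shrunk tenfold,
  inflating all its pairwise FST (drifted-population truth).

Two fidelity tiers share the same ground truth: a closed-form expected-FST
matrix (linearized FST = t/(2*Ne_harmonic) + ibd_rate*km + noise, inverted
back to FST), and genotype-level simulation in which allele frequencies
evolve down the true population tree by Balding-Nichols draws and diploid
genotypes are sampled binomially at the leaves.  The IBD term uses *genetic*
positions: a displaced colony keeps its ancestral location in the term, since
its genetic relationships were set before the move, not by its new
neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .data_model import (
    FstMatrix,
    PopulationPanel,
    PopulationRecord,
    ValidationError,
)
from .geodesy import EARTH_RADIUS_KM, distance_matrix_km, haversine_km
from .popgen import GenotypeMatrix, combine_ne, delinearize_fst

KM_PER_DEGREE = np.pi * EARTH_RADIUS_KM / 180.0

EVENT_TYPES = ("shift", "remote_colony", "assimilation", "drift_isolate")


@dataclass
class ScenarioConfig:
    """Study conditions of a synthetic scenario.

    Defaults describe the standard testbed: six families of eight
    populations each, clustered (sigma 150 km) around centroids on a ring
    with 500 km between adjacent centroids; family root ages 2-6 ky and a
    12 ky between-family divergence; Ne of 2,000-10,000 diploids; an IBD
    gradient of 2e-5 linearized-FST per km (the order observed across human
    continental panels) with small additive noise; and, per panel, two
    language shifts, one remote colony and one assimilation.
    """

    n_families: int = 6
    populations_per_family: tuple[int, int] = (8, 8)  # inclusive range
    family_spacing_km: float = 500.0       # arc distance between adjacent centroids
    family_dispersion_km: float = 150.0
    family_root_age_years: tuple[float, float] = (2000.0, 6000.0)
    between_family_age_years: float = 12000.0
    ne_range: tuple[float, float] = (2000.0, 10000.0)
    n_loci: int = 2000
    individuals_per_pop: int = 25
    ibd_rate: float = 2e-5          # linearized FST per km
    noise_sd: float = 0.003         # additive on the linearized scale
    events: dict[str, int] = field(
        default_factory=lambda: {
            "shift": 2, "remote_colony": 1, "assimilation": 1, "drift_isolate": 0,
        }
    )
    shift_to: str = "farthest"      # family adopted by a shift: farthest | nearest
    displacement_min_km: float = 1500.0
    assimilation_age_years: float = 500.0
    generation_years: float = 29.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        for k in self.events:
            if k not in EVENT_TYPES:
                raise ValidationError(f"unknown event type {k!r}")
        if any(v < 0 for v in self.events.values()):
            raise ValidationError("event counts must be >= 0")
        if self.shift_to not in ("farthest", "nearest"):
            raise ValidationError(f"unknown shift_to {self.shift_to!r}")
        for name in ("family_spacing_km", "family_dispersion_km",
                     "between_family_age_years", "ibd_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows: per-population genetic family and
    event label, per-pair split times (generations), effective sizes actually
    driving drift, and the geographic distances entering the IBD term."""

    pop_ids: list[str]
    labeled_family: dict[str, str]
    genetic_family: dict[str, str]
    event_label: dict[str, str]      # "none" or an EVENT_TYPES member
    split_times_gen: pd.DataFrame    # symmetric, generations (genetic history)
    linguistic_times_gen: pd.DataFrame  # symmetric, generations (language history)
    ne_eff: dict[str, float]
    km_genetic: pd.DataFrame         # distances between genetic positions
    family_root_age_gen: dict[str, float] = field(default_factory=dict)

    def event_populations(self) -> list[str]:
        return [p for p in self.pop_ids if self.event_label[p] != "none"]


def _family_tree_split_times(
    members: list[str], root_age_years: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Random coalescent-style family tree: sequential random pair joins at
    increasing ages, the last at the root age.  Returns the pairwise MRCA-age
    matrix in years."""
    k = len(members)
    t = pd.DataFrame(0.0, index=members, columns=members)
    if k == 1:
        return t
    ages = np.sort(rng.uniform(0.15 * root_age_years, root_age_years, size=k - 1))
    ages[-1] = root_age_years
    clusters: list[list[str]] = [[m] for m in members]
    for age in ages:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        i, j = min(i, j), max(i, j)
        for a in clusters[i]:
            for b in clusters[j]:
                t.loc[a, b] = t.loc[b, a] = age
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return t


def _ring_centroids(n: int, spacing_km: float) -> dict[int, tuple[float, float]]:
    """Family centroids as (lat, lon) degrees on a ring around (0, 0) with
    ``spacing_km`` of arc between adjacent centroids."""
    if n == 1:
        return {0: (0.0, 0.0)}
    radius_deg = (n * spacing_km / (2.0 * np.pi)) / KM_PER_DEGREE
    out = {}
    for i in range(n):
        theta = 2.0 * np.pi * i / n
        out[i] = (radius_deg * np.cos(theta), radius_deg * np.sin(theta))
    return out


def generate_panel(cfg: ScenarioConfig) -> tuple[PopulationPanel, GroundTruth]:
    """Simulate a panel and its ground truth under ``cfg`` (fully seeded)."""
    rng = np.random.default_rng([cfg.rng_seed, 0])
    n_fam = cfg.n_families
    fam_names = [f"fam{i + 1:02d}" for i in range(n_fam)]
    centroids = {
        fam: c for fam, c in zip(fam_names, _ring_centroids(n_fam, cfg.family_spacing_km).values())
    }
    region_of = {
        fam: f"region{1 if i < (n_fam + 1) // 2 else 2}"
        for i, fam in enumerate(fam_names)
    }

    lo, hi = cfg.populations_per_family
    records: list[PopulationRecord] = []
    labeled: dict[str, str] = {}
    genetic: dict[str, str] = {}
    ne_eff: dict[str, float] = {}
    members_of: dict[str, list[str]] = {}
    for fam in fam_names:
        n_pops = int(rng.integers(lo, hi + 1))
        ids = [f"{fam}_p{j + 1}" for j in range(n_pops)]
        members_of[fam] = ids
        clat, clon = centroids[fam]
        offsets = rng.normal(0.0, cfg.family_dispersion_km, size=(n_pops, 2))
        for pid, (dy, dx) in zip(ids, offsets):
            ne = float(rng.uniform(*cfg.ne_range))
            records.append(
                PopulationRecord(
                    pop_id=pid,
                    n_individuals=cfg.individuals_per_pop,
                    lat=clat + dy / KM_PER_DEGREE,
                    lon=clon + dx / KM_PER_DEGREE,
                    language_id=f"lang_{pid}",
                    family=fam,
                    macro_region=region_of[fam],
                    ne=ne,
                    ne_ci_low=ne * 0.8,
                    ne_ci_high=ne * 1.25,
                )
            )
            labeled[pid] = fam
            genetic[pid] = fam
            ne_eff[pid] = ne

    pop_ids = [r.pop_id for r in records]
    by_id = {r.pop_id: r for r in records}
    gen_years = cfg.generation_years
    # genetic positions start at the sampled (ancestral) locations
    genetic_pos = {r.pop_id: (r.lat, r.lon) for r in records}

    # split times (years) under the null: family trees + star between families
    t_years = pd.DataFrame(cfg.between_family_age_years, index=pop_ids, columns=pop_ids)
    root_age_of: dict[str, float] = {}
    for fam in fam_names:
        root_age = float(rng.uniform(*cfg.family_root_age_years))
        root_age_of[fam] = root_age
        sub = _family_tree_split_times(members_of[fam], root_age, rng)
        t_years.loc[sub.index, sub.columns] = sub
    null_t_years = t_years.copy()

    event_label = {p: "none" for p in pop_ids}

    n_events = sum(cfg.events.values())
    if n_events:
        if n_fam < 2:
            raise ValidationError("events need at least two families")
        if n_events > len(pop_ids):
            raise ValidationError("more events than populations")
        chosen = list(rng.choice(pop_ids, size=n_events, replace=False))
    else:
        chosen = []
    queue = iter(chosen)

    def _centroid_dist_km(pos: tuple[float, float], fam: str) -> float:
        return haversine_km(pos, centroids[fam])

    used_pairs: set[frozenset] = set()

    def _pick_family(pid: str, how: str) -> str:
        # avoid re-using an origin/target family pair across events, so one
        # event's displaced or relabeled population cannot sit next to
        # another event's target region with a colliding label
        pos = (by_id[pid].lat, by_id[pid].lon)
        cands = sorted(f for f in fam_names if f != labeled[pid])
        key = lambda f: (_centroid_dist_km(pos, f), f)
        cands.sort(key=key, reverse=(how == "farthest"))
        for f in cands:
            if frozenset((labeled[pid], f)) not in used_pairs:
                used_pairs.add(frozenset((labeled[pid], f)))
                return f
        return cands[0]

    def _displace(pid: str) -> str:
        """Move a population next to its most remote family's cluster,
        pushed out so it ends at least displacement_min_km from home."""
        rec = by_id[pid]
        own = labeled[pid]
        host = _pick_family(pid, "farthest")
        assert host != own
        o, h = np.array(centroids[own]), np.array(centroids[host])
        gap = np.linalg.norm(h - o) * KM_PER_DEGREE
        u = (h - o) / max(np.linalg.norm(h - o), 1e-9)
        extra = max(0.0, cfg.displacement_min_km - gap) / KM_PER_DEGREE
        noise = rng.normal(0.0, 0.3 * cfg.family_dispersion_km, size=2) / KM_PER_DEGREE
        rec.lat, rec.lon = h + u * extra + noise
        return host

    for _ in range(cfg.events.get("shift", 0)):
        pid = next(queue)
        new_fam = _pick_family(pid, cfg.shift_to)
        by_id[pid].family = new_fam
        labeled[pid] = new_fam
        event_label[pid] = "shift"

    for _ in range(cfg.events.get("remote_colony", 0)):
        pid = next(queue)
        _displace(pid)
        event_label[pid] = "remote_colony"
        # genetic position stays at the ancestral home; geographic moved

    for _ in range(cfg.events.get("assimilation", 0)):
        pid = next(queue)
        host_fam = _displace(pid)
        genetic_pos[pid] = (by_id[pid].lat, by_id[pid].lon)
        host_members = [p for p in members_of[host_fam] if event_label[p] == "none"]
        if not host_members:
            raise ValidationError(f"assimilation infeasible for {pid}: empty host family")
        host = host_members[int(rng.integers(len(host_members)))]
        # lineage replaced: recent split from host, host-relative times elsewhere
        for other in pop_ids:
            if other == pid:
                continue
            new_t = (
                cfg.assimilation_age_years
                if other == host
                else max(cfg.assimilation_age_years, float(t_years.loc[host, other]))
            )
            t_years.loc[pid, other] = t_years.loc[other, pid] = new_t
        genetic[pid] = host_fam
        event_label[pid] = "assimilation"

    for _ in range(cfg.events.get("drift_isolate", 0)):
        pid = next(queue)
        ne_eff[pid] = ne_eff[pid] / 10.0
        by_id[pid].ne = ne_eff[pid]
        by_id[pid].ne_ci_low = ne_eff[pid] * 0.8
        by_id[pid].ne_ci_high = ne_eff[pid] * 1.25
        event_label[pid] = "drift_isolate"

    # linguistic split times follow the *labels*: a shifted population's
    # language joins the adopted family at its root; an assimilated
    # population's language keeps its original tree position
    ling_years = null_t_years.copy()
    shifted = [p for p in pop_ids if event_label[p] == "shift"]
    for pid in shifted:
        new_fam = labeled[pid]
        for other in pop_ids:
            if other == pid:
                continue
            if labeled[other] == new_fam:
                ling_years.loc[pid, other] = ling_years.loc[other, pid] = (
                    root_age_of[new_fam])
            else:
                ling_years.loc[pid, other] = ling_years.loc[other, pid] = (
                    cfg.between_family_age_years)

    panel = PopulationPanel(records)
    n = len(pop_ids)
    kmg = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            kmg[i, j] = kmg[j, i] = haversine_km(
                genetic_pos[pop_ids[i]], genetic_pos[pop_ids[j]])
    t_gen = t_years / gen_years
    np.fill_diagonal(t_gen.values, 0.0)
    ling_gen = ling_years / gen_years
    np.fill_diagonal(ling_gen.values, 0.0)
    truth = GroundTruth(
        pop_ids=pop_ids,
        labeled_family=labeled,
        genetic_family=genetic,
        event_label=event_label,
        split_times_gen=t_gen,
        linguistic_times_gen=ling_gen,
        ne_eff=ne_eff,
        km_genetic=pd.DataFrame(kmg, index=pop_ids, columns=pop_ids),
        family_root_age_gen={f: root_age_of[f] / gen_years for f in fam_names},
    )
    return panel, truth


def expected_fst(
    truth: GroundTruth,
    pop_a: str,
    pop_b: str,
    cfg: ScenarioConfig,
    noise: float = 0.0,
) -> float:
    """Closed-form expected FST for one pair: linearized FST equals
    t/(2*Ne_harmonic) plus the IBD term, plus optional noise, inverted back
    to the FST scale and floored at 0."""
    if pop_a == pop_b:
        return 0.0
    t = float(truth.split_times_gen.loc[pop_a, pop_b])
    ne = combine_ne(truth.ne_eff[pop_a], truth.ne_eff[pop_b], "harmonic")
    lin = t / (2.0 * ne) + cfg.ibd_rate * float(truth.km_genetic.loc[pop_a, pop_b]) + noise
    return float(delinearize_fst(max(lin, 0.0)))


def expected_fst_matrix(truth: GroundTruth, cfg: ScenarioConfig) -> FstMatrix:
    """Seeded expected-FST matrix over the whole panel (the fast truth tier)."""
    rng = np.random.default_rng([cfg.rng_seed, 1])
    ids = truth.pop_ids
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            eps = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
            v = expected_fst(truth, ids[i], ids[j], cfg, noise=eps)
            values[i, j] = values[j, i] = v
    return FstMatrix(ids, values)


# ---------------------------------------------------------------------------
# genotype-level tier
# ---------------------------------------------------------------------------

def _bn_draw(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F),
    with fixed loci (p in {0,1}) staying fixed."""
    if f <= 1e-12:
        return p.copy()
    out = p.copy()
    seg = (p > 0.0) & (p < 1.0)
    scale = (1.0 - f) / f
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def balding_nichols_pair(
    true_fst: float,
    n_loci: int,
    n_individuals: int,
    rng: np.random.Generator,
    p_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two populations drawn independently from the Balding-Nichols model at
    drift parameter ``true_fst`` around uniform ancestral frequencies."""
    p0 = rng.uniform(*p_range, size=n_loci)
    out = []
    for name in ("pop1", "pop2"):
        p = _bn_draw(p0, true_fst, rng)
        g = rng.binomial(2, p[:, None], size=(n_loci, n_individuals)).astype(float)
        out.append(GenotypeMatrix(name, g))
    return out[0], out[1]


def simulate_split_pair(
    t_generations: float,
    ne: float,
    n_loci: int,
    n_individuals: int,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two populations diverged ``t_generations`` ago at constant size ``ne``:
    each lineage drifts with F = 1 - exp(-t / (2 Ne))."""
    f = 1.0 - np.exp(-t_generations / (2.0 * ne))
    return balding_nichols_pair(f, n_loci, n_individuals, rng)


class _SimNode:
    __slots__ = ("age", "children", "pop_id")

    def __init__(self, age: float, pop_id: Optional[str] = None):
        self.age = age
        self.children: list["_SimNode"] = []
        self.pop_id = pop_id

    def leaves(self) -> list[str]:
        if self.pop_id is not None:
            return [self.pop_id]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _tree_from_split_times(t_gen: pd.DataFrame) -> _SimNode:
    """Reconstruct the (ultrametric) population tree from MRCA ages via
    average-linkage clustering, which is exact on an ultrametric matrix."""
    ids = list(t_gen.index)
    if len(ids) == 1:
        return _SimNode(0.0, ids[0])
    z = linkage(squareform(t_gen.to_numpy(dtype=float), checks=False),
                method="average")
    nodes: dict[int, _SimNode] = {
        i: _SimNode(0.0, pid) for i, pid in enumerate(ids)
    }
    n = len(ids)
    for k, (a, b, height, _) in enumerate(z):
        node = _SimNode(float(height))
        node.children = [nodes.pop(int(a)), nodes.pop(int(b))]
        nodes[n + k] = node
    (root,) = nodes.values()
    return root


def simulate_genotypes(
    truth: GroundTruth, cfg: ScenarioConfig
) -> dict[str, GenotypeMatrix]:
    """Genotypes for every population: ancestral frequencies Uniform(.05,.95),
    Balding-Nichols drift down the true tree with per-branch
    F = 1 - exp(-dt/(2 Ne)), binomial(2, p) genotypes at the leaves.

    Terminal branches use each population's effective size; internal branches
    use the mean Ne of their descendant populations.
    """
    rng = np.random.default_rng([cfg.rng_seed, 2])
    root = _tree_from_split_times(truth.split_times_gen)
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    out: dict[str, GenotypeMatrix] = {}

    def _branch_ne(node: _SimNode) -> float:
        if node.pop_id is not None:
            return truth.ne_eff[node.pop_id]
        return float(np.mean([truth.ne_eff[p] for p in node.leaves()]))

    def _evolve(node: _SimNode, p: np.ndarray) -> None:
        for child in node.children:
            dt = node.age - child.age
            ne = _branch_ne(child)
            f = 1.0 - np.exp(-max(dt, 0.0) / (2.0 * ne))
            pc = _bn_draw(p, f, rng)
            if child.pop_id is not None:
                g = rng.binomial(
                    2, pc[:, None], size=(cfg.n_loci, cfg.individuals_per_pop)
                ).astype(float)
                out[child.pop_id] = GenotypeMatrix(child.pop_id, g)
            else:
                _evolve(child, pc)

    if root.pop_id is not None:  # degenerate single-population panel
        g = rng.binomial(2, p0[:, None],
                         size=(cfg.n_loci, cfg.individuals_per_pop)).astype(float)
        out[root.pop_id] = GenotypeMatrix(root.pop_id, g)
    else:
        _evolve(root, p0)
    return out


def _newick_from_simnode(node: _SimNode, parent_age: Optional[float],
                         leaf_name) -> str:
    length = "" if parent_age is None else f":{parent_age - node.age:.6f}"
    if node.pop_id is not None:
        return f"{leaf_name(node.pop_id)}{length}"
    inner = ",".join(
        _newick_from_simnode(c, node.age, leaf_name) for c in node.children)
    return f"({inner}){length}"


def family_language_tree(truth: GroundTruth, family: str,
                         generation_years: float = 29.0):
    """Calibrated linguistic tree (branch lengths in years) for one labeled
    family, built from the linguistic ground-truth split times; leaves are
    the members' language identifiers."""
    import dendropy

    from .data_model import read_newick

    members = [p for p in truth.pop_ids if truth.labeled_family[p] == family]
    if not members:
        raise ValidationError(f"no members labeled {family!r}")
    sub = truth.linguistic_times_gen.loc[members, members] * generation_years
    root = _tree_from_split_times(sub)
    text = _newick_from_simnode(root, None, lambda p: f"lang_{p}") + ";"
    return read_newick(text, is_string=True)


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pop_id": truth.pop_ids,
            "labeled_family": [truth.labeled_family[p] for p in truth.pop_ids],
            "genetic_family": [truth.genetic_family[p] for p in truth.pop_ids],
            "event": [truth.event_label[p] for p in truth.pop_ids],
            "ne_eff": [truth.ne_eff[p] for p in truth.pop_ids],
        }
    )
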