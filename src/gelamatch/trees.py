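"""Distance trees and genetic-vs-linguistic tree comparison.

* Saitou-Nei neighbor-joining from a pairwise FST (or any distance) matrix,
  exact on additive matrices.
* Taxon matching between a population-level genetic tree and a language-level
  linguistic tree: populations map to language tips; a language spoken by
  several populations is expanded into a zero-length multifurcation so both
  trees end on the same population-level leaf set.
* Quartet similarity: the fraction of all C(n,4) leaf quartets on which the
  two trees induce the same resolved topology.  Quartets left unresolved by a
  polytomy in either tree count as non-matching; a normalized quartet distance
  treating both-unresolved as agreement is reported alongside.
* Per-pair comparison of linguistic MRCA ages (from a time-calibrated tree)
  against genetic divergence times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, FstMatrix, PopulationPanel, ValidationError
from .popgen import DivergenceEstimate


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(ids: Sequence[str], matrix: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Standard Q-matrix pair selection and branch-length formulas; a negative
    branch length is clamped to zero with the deficit moved to the sibling
    branch (their sum is preserved).  Exact on additive matrices.
    """
    d = np.asarray(matrix, dtype=float).copy()
    n = len(ids)
    if n < 3:
        raise ValidationError("nj_tree needs at least 3 taxa")
    if d.shape != (n, n):
        raise ValidationError("distance matrix shape does not match ids")
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isfinite(d[i, j]):
                raise ValidationError(
                    f"missing distance for pair ({ids[i]}, {ids[j]})")

    taxa = dendropy.TaxonNamespace([str(t) for t in ids])
    nodes = []
    for label in ids:
        leaf = dendropy.Node(taxon=taxa.get_taxon(str(label)))
        nodes.append(leaf)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        fi, fj = active[i_s], active[j_s]
        dij = d[fi, fj]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = dendropy.Node()
        nodes[fi].edge.length = li
        nodes[fj].edge.length = lj
        parent.add_child(nodes[fi])
        parent.add_child(nodes[fj])
        new_idx = d.shape[0]
        newrow = np.full((1, d.shape[0]), np.nan)
        d = np.vstack([d, newrow])
        d = np.hstack([d, np.full((d.shape[0], 1), np.nan)])
        for k_s in range(m):
            fk = active[k_s]
            if fk in (fi, fj):
                continue
            dk = 0.5 * (d[fi, fk] + d[fj, fk] - dij)
            d[new_idx, fk] = d[fk, new_idx] = dk
        d[new_idx, new_idx] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (fi, fj)] + [new_idx]

    # final three nodes around the central (root) node
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = max(length, 0.0)
        root.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def nj_from_fst(fst: FstMatrix, pop_ids: Optional[Sequence[str]] = None) -> dendropy.Tree:
    ids = list(pop_ids) if pop_ids is not None else fst.pop_ids
    sub = fst.submatrix(ids)
    return nj_tree(ids, sub.values)


# ---------------------------------------------------------------------------
# leaf utilities and taxon matching
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def patristic_matrix(tree: dendropy.Tree, topological: bool = False) -> pd.DataFrame:
    """Leaf-by-leaf path-length matrix; with ``topological`` every edge counts
    as length 1 regardless of its branch length."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    out = np.zeros((len(labels), len(labels)))
    for i, la in enumerate(labels):
        for j in range(i + 1, len(labels)):
            lb = labels[j]
            if topological:
                v = pdm.path_edge_count(taxa[la], taxa[lb])
            else:
                v = pdm.patristic_distance(taxa[la], taxa[lb])
            out[i, j] = out[j, i] = v
    return pd.DataFrame(out, index=labels, columns=labels)


def match_taxa(
    genetic_tree: dendropy.Tree,
    linguistic_tree: dendropy.Tree,
    panel: PopulationPanel,
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Bring a population-level genetic tree and a language-level linguistic
    tree onto a shared population-level leaf set.

    Genetic leaves are pop_ids; linguistic leaves are language_ids.  A
    language tip spoken by k sampled populations is expanded into k leaves
    joined by zero-length branches; tips unmatched on either side are pruned.
    """
    gen = genetic_tree.clone(depth=1)
    lin = linguistic_tree.clone(depth=1)
    gen_pops = set(leaf_labels(gen))
    lang_to_pops: dict[str, list[str]] = {}
    for rec in panel:
        if rec.pop_id in gen_pops:
            lang_to_pops.setdefault(rec.language_id, []).append(rec.pop_id)

    # expand/relabel linguistic tips into population-level leaves
    matched_pops: set[str] = set()
    for leaf in list(lin.leaf_node_iter()):
        lang = leaf.taxon.label
        pops = sorted(lang_to_pops.get(lang, []))
        if not pops:
            continue
        matched_pops.update(pops)
        if len(pops) == 1:
            leaf.taxon = None
            leaf.taxon = dendropy.Taxon(label=pops[0])
        else:
            leaf.taxon = None
            for p in pops:
                child = dendropy.Node(taxon=dendropy.Taxon(label=p))
                child.edge.length = 0.0
                leaf.add_child(child)
    lin.taxon_namespace = dendropy.TaxonNamespace(
        [lf.taxon for lf in lin.leaf_node_iter() if lf.taxon is not None]
    )
    shared = matched_pops & gen_pops
    if len(shared) < 4:
        raise ValidationError(
            f"only {len(shared)} shared leaves after matching; need >= 4")
    _prune_to(gen, shared)
    _prune_to(lin, shared)
    return gen, lin


def _prune_to(tree: dendropy.Tree, keep: set[str]) -> None:
    taxa = [lf.taxon for lf in tree.leaf_node_iter()
            if lf.taxon is not None and lf.taxon.label in keep]
    tree.retain_taxa(taxa)


# ---------------------------------------------------------------------------
# quartet similarity
# ---------------------------------------------------------------------------

MAX_QUARTET_LEAVES = 25


@dataclass
class TreeComparison:
    n_shared_leaves: int
    n_quartets: int
    n_same_resolved: int
    n_both_unresolved: int
    quartet_similarity: float
    normalized_quartet_distance: float


def _quartet_topology(dm: np.ndarray, i: int, j: int, k: int, l: int) -> int:
    """Induced quartet topology from a topological (unit edge) distance
    matrix via the four-point condition.

    Returns 0 for ij|kl, 1 for ik|jl, 2 for il|jk, -1 for unresolved.
    """
    s0 = dm[i, j] + dm[k, l]
    s1 = dm[i, k] + dm[j, l]
    s2 = dm[i, l] + dm[j, k]
    m = min(s0, s1, s2)
    mins = [s0 == m, s1 == m, s2 == m]
    if sum(mins) != 1:
        return -1
    return mins.index(True)


def quartet_similarity(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> TreeComparison:
    """Brute-force quartet agreement between two trees on the same leaf set."""
    l1, l2 = sorted(leaf_labels(t1)), sorted(leaf_labels(t2))
    if l1 != l2:
        raise ValidationError("quartet_similarity: leaf sets differ")
    n = len(l1)
    if n < 4:
        raise ValidationError("quartet_similarity needs >= 4 leaves")
    if n > MAX_QUARTET_LEAVES:
        raise ValidationError(
            f"brute-force quartet enumeration limited to {MAX_QUARTET_LEAVES} leaves")
    dm1 = patristic_matrix(t1, topological=True).to_numpy()
    dm2 = patristic_matrix(t2, topological=True).to_numpy()
    same = both_unres = 0
    total = 0
    for i, j, k, l in itertools.combinations(range(n), 4):
        q1 = _quartet_topology(dm1, i, j, k, l)
        q2 = _quartet_topology(dm2, i, j, k, l)
        total += 1
        if q1 == -1 and q2 == -1:
            both_unres += 1
        elif q1 == q2:
            same += 1
    sim = same / total
    ndist = 1.0 - (same + both_unres) / total
    return TreeComparison(n, total, same, both_unres, sim, ndist)


# ---------------------------------------------------------------------------
# calibrated-tree ages and per-pair time comparison
# ---------------------------------------------------------------------------

def node_age(tree: dendropy.Tree, labels: Sequence[str]) -> float:
    """Age (years BP) of the MRCA of ``labels`` in a calibrated tree: its
    maximum path length down to any descendant leaf."""
    taxa = [t for t in tree.taxon_namespace if t.label in set(labels)]
    if len(taxa) != len(set(labels)):
        missing = set(labels) - {t.label for t in taxa}
        raise ValidationError(f"labels absent from tree: {sorted(missing)}")
    mrca = tree.mrca(taxa=taxa)
    return _max_depth(mrca)


def _max_depth(node: dendropy.Node) -> float:
    if node.is_leaf():
        return 0.0
    return max(
        (child.edge.length or 0.0) + _max_depth(child)
        for child in node.child_nodes()
    )


def pairwise_time_comparison(
    calibrated_tree: dendropy.Tree,
    pairs: Sequence[tuple[str, str, DivergenceEstimate]],
    panel: PopulationPanel,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-pair linguistic MRCA age vs genetic divergence time.

    ``pairs`` carries (pop_a, pop_b, DivergenceEstimate); linguistic ages come
    from the calibrated tree via each population's language.  Populations in
    ``config.outlier_exclusions`` are dropped.  Residuals are log10 ratios
    against the 1:1 line.
    """
    excluded = set(config.outlier_exclusions)
    rows = []
    for pop_a, pop_b, est in pairs:
        if pop_a in excluded or pop_b in excluded:
            continue
        if not est.available:
            continue
        la = panel[pop_a].language_id
        lb = panel[pop_b].language_id
        if la == lb:
            continue
        try:
            age = node_age(calibrated_tree, [la, lb])
        except ValidationError:
            continue
        ratio = est.t_years / age if age > 0 else np.nan
        rows.append(
            {
                "pop_a": pop_a, "pop_b": pop_b,
                "linguistic_age_years": age,
                "genetic_t_years": est.t_years,
                "genetic_t_low": est.t_low,
                "genetic_t_high": est.t_high,
                "ratio": ratio,
                "log10_ratio": np.log10(ratio) if ratio and ratio > 0 else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["pop_a", "pop_b", "linguistic_age_years",
                       "genetic_t_years", "genetic_t_low", "genetic_t_high",
                       "ratio", "log10_ratio"],
    )
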