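"""End-to-end orchestration: the full analysis sequence over one panel.

Stage order mirrors the analysis narrative: neighbourhood structure and
closest-neighbour concordance, the drifted-population filter, enclave
classification, alignment profiling, family cohesiveness under IBD, family
root-age comparison, and genetic-vs-linguistic tree comparison.  Stages whose
optional inputs (Ne, linguistic trees, family ages) are missing are skipped
and recorded as such in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .data_model import AnalysisConfig, FstMatrix, PopulationPanel
from .geodesy import concordance_rate, neighbor_counts, neighbor_table
from .heuristics import (
    alignment_profiles,
    alignment_table,
    classify_all_enclaves,
    enclave_table,
    misalignment_summary,
)
from .cohesiveness import cohesion_assessment, cohesiveness_table
from .popgen import divergence_time, flag_drifted
from .timedepth import (
    FamilyAgeRecord,
    compare_family_ages,
    comparison_table,
    root_level_pairs,
)
from .trees import match_taxa, nj_from_fst, quartet_similarity

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    skipped_stages: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(
    panel: PopulationPanel,
    fst: FstMatrix,
    config: AnalysisConfig,
    family_ages: Optional[dict[str, FamilyAgeRecord]] = None,
    classification_trees: Optional[dict[str, dendropy.Tree]] = None,
    calibrated_trees: Optional[dict[str, dendropy.Tree]] = None,
    cohesiveness_families: Optional[list[str]] = None,
    out_dir: Optional[Path] = None,
    input_paths: Optional[dict[str, Path]] = None,
) -> dict:
    """Run every stage and return the summary dict (also written to
    ``out_dir/summary.json`` with per-stage tables when ``out_dir`` given)."""
    manifest = RunManifest(
        seed=config.rng_seed, config=asdict(config), version=__version__
    )
    for name, p in (input_paths or {}).items():
        manifest.input_digests[name] = _digest(Path(p))
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"n_populations": len(panel), "n_families": len(panel.family_index)}

    def _stage(name):
        start = time.perf_counter()

        def _done(n_rows: int):
            manifest.stage_counts[name] = n_rows
            manifest.stage_seconds[name] = round(time.perf_counter() - start, 3)
            logger.info("stage %-14s %6d rows  %6.2fs", name, n_rows,
                        manifest.stage_seconds[name])
        return _done

    # --- neighbours & concordance
    done = _stage("neighbors")
    summaries = neighbor_counts(panel, fst, radii=(500.0, 1000.0))
    tables["neighbors"] = neighbor_table(summaries)
    defined = [s for s in summaries if s.has_closest]
    summary["prop_other_family_within_500km"] = float(
        np.mean([s.counts_other_family[500.0] > 0 for s in summaries]))
    summary["prop_other_family_within_1000km"] = float(
        np.mean([s.counts_other_family[1000.0] > 0 for s in summaries]))
    summary["closest_neighbor_discordance"] = (
        concordance_rate(summaries) if defined else None)
    done(len(summaries))

    # --- drifted filter
    done = _stage("drifted")
    panel = flag_drifted(panel, fst, config)
    n_drifted = sum(bool(r.drifted) for r in panel)
    summary["n_drifted"] = n_drifted
    done(n_drifted)

    # --- enclaves
    done = _stage("enclaves")
    reports = classify_all_enclaves(panel, fst, config)
    tables["enclaves"] = enclave_table(reports)
    counts = {c: 0 for c in ("matching_enclave", "genetic_enclave",
                             "linguistic_enclave", "local_match")}
    for r in reports:
        if r.classification in counts:
            counts[r.classification] += 1
    summary["n_eligible"] = sum(r.eligible for r in reports)
    summary["enclave_counts"] = counts
    done(len(reports))

    # --- alignment
    done = _stage("alignment")
    profiles = alignment_profiles(panel, fst, config)
    tables["alignment"] = alignment_table(profiles)
    mis = misalignment_summary(profiles, panel)
    summary["misaligned_proportion"] = (
        None if np.isnan(mis.proportion) else float(mis.proportion))
    summary["n_assessable"] = mis.n_assessable
    summary["n_misaligned"] = mis.n_misaligned
    done(len(profiles))

    mismatch_flags = {r.pop_id: r.classification in (
        "matching_enclave", "genetic_enclave", "linguistic_enclave")
        for r in reports}
    for p in profiles:
        if p.assessable and p.misaligned:
            mismatch_flags[p.pop_id] = True

    # --- cohesiveness
    done = _stage("cohesiveness")
    fams = cohesiveness_families
    if fams is None:
        fams = sorted(f for f, m in panel.family_index.items() if len(m) >= 3)
    results = [cohesion_assessment(panel, fst, f, config) for f in fams]
    tables["cohesiveness"] = cohesiveness_table(results)
    summary["cohesive_families"] = {
        r.family: r.cohesive for r in results if r.assessable}
    done(len(results))

    # --- timedepth
    if family_ages and classification_trees:
        done = _stage("timedepth")
        comparisons = []
        for fam, rec in sorted(family_ages.items()):
            tree = classification_trees.get(fam)
            if tree is None:
                continue
            pairs = root_level_pairs(tree, panel, fam)
            triples = []
            for a, b in pairs:
                ra, rb = panel[a], panel[b]
                est = divergence_time(
                    fst.get(a, b), ra.ne, rb.ne, config, a, b,
                    (ra.ne_ci_low, ra.ne_ci_high) if ra.ne_ci_low else None,
                    (rb.ne_ci_low, rb.ne_ci_high) if rb.ne_ci_low else None,
                )
                triples.append((a, b, est))
            comparisons.append(compare_family_ages(triples, rec, mismatch_flags))
        tables["timedepth"] = comparison_table(comparisons)
        summary["family_age_ratio"] = {
            c.family: c.median_ratio_to_midpoint for c in comparisons if c.assessable}
        done(len(comparisons))
    else:
        manifest.skipped_stages.append("timedepth")

    # --- trees
    if classification_trees:
        done = _stage("trees")
        quartets = {}
        for fam, ltree in sorted(classification_trees.items()):
            members = [p for p in panel.family_members(fam)
                       if np.isfinite(fst.row(p).to_numpy()).any()]
            if len(members) < 4:
                continue
            gtree = nj_from_fst(fst, members)
            try:
                g2, l2 = match_taxa(gtree, ltree, panel)
                cmpres = quartet_similarity(g2, l2)
            except Exception as e:  # < 4 shared leaves, oversized, ...
                logger.warning("trees stage: %s skipped (%s)", fam, e)
                continue
            quartets[fam] = {
                "quartet_similarity": cmpres.quartet_similarity,
                "normalized_quartet_distance": cmpres.normalized_quartet_distance,
                "n_shared_leaves": cmpres.n_shared_leaves,
            }
        summary["quartet_similarities"] = quartets
        done(len(quartets))
    else:
        manifest.skipped_stages.append("trees")

    summary["manifest"] = asdict(manifest)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=_jsonable) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
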