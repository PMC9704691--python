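"""Local-scale match/mismatch heuristics.

Two complementary detectors:

* **Enclave classification.**  A population whose closest genetic and/or
  linguistic relatives are geographically remote is an *enclave*.  Using the
  smallest FST to a same-family population (f_within, at distance d_within)
  and to an other-family population (f_between, at d_between):

  - ``matching_enclave``: genetically closest to its remote family relatives
    (f_within <= f_between, d_within >= d_far) — a displaced colony that kept
    both genes and language.
  - ``genetic_enclave``: closest genetic relative is linguistically unrelated
    and remote (f_between < f_within, d_between >= d_far) — language shift
    after migration.
  - ``linguistic_enclave``: genetically assimilated to nearby other-family
    neighbours while the family relatives are remote (f_between < f_within,
    d_between < d_near, d_within >= d_far) — language retained through genetic
    replacement.

  Only populations from families with more than two sampled populations, and
  remote from their relatives in at least one dimension, are eligible.

* **Alignment profiling.**  Per population, the distribution of FST to
  same-family populations is compared with the distribution of FST to
  other-family populations within the family's geographic span.  A population
  is *misaligned* when its median within-family FST exceeds the
  between-family median; the difference of medians carries a percentile
  bootstrap CI.  Drifted populations are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, FstMatrix, PopulationPanel
from .geodesy import distance_matrix_km, family_span_km

ENCLAVE_CLASSES = (
    "matching_enclave", "genetic_enclave", "linguistic_enclave", "local_match",
    "ineligible",
)


@dataclass
class EnclaveReport:
    pop_id: str
    eligible: bool
    classification: str
    reason: str = ""
    f_within: Optional[float] = None
    f_between: Optional[float] = None
    d_within: Optional[float] = None
    d_between: Optional[float] = None
    closest_within_pop: Optional[str] = None
    closest_between_pop: Optional[str] = None


@dataclass
class AlignmentProfile:
    pop_id: str
    assessable: bool
    median_within: float = np.nan
    median_between: float = np.nan
    delta: float = np.nan          # median_between - median_within
    ci_low: float = np.nan
    ci_high: float = np.nan
    misaligned: Optional[bool] = None
    n_within: int = 0
    n_between: int = 0
    reason: str = ""


def _closest_fst(
    pop_id: str,
    panel: PopulationPanel,
    fst: FstMatrix,
    geo: pd.DataFrame,
    same_family: bool,
) -> Optional[tuple[float, str, float]]:
    """Smallest finite FST from pop to same-/other-family populations, with
    ties broken by geographic distance then pop_id.  None if no candidates."""
    fam = panel.family_of(pop_id)
    row = fst.row(pop_id)
    cands = [
        p for p in row.index
        if (panel.family_of(p) == fam) == same_family and np.isfinite(row[p])
    ]
    if not cands:
        return None
    fmin = min(row[p] for p in cands)
    best = sorted(
        (p for p in cands if row[p] == fmin),
        key=lambda p: (geo.loc[pop_id, p], p),
    )[0]
    return float(fmin), best, float(geo.loc[pop_id, best])


def enclave_eligibility(
    pop_id: str,
    panel: PopulationPanel,
    fst: FstMatrix,
    config: AnalysisConfig,
    geo: Optional[pd.DataFrame] = None,
) -> tuple[bool, str]:
    """A population is eligible for enclave classification when its family has
    more than two sampled populations and it is remote from its relatives in
    at least one dimension: the geographically nearest same-family population
    or the overall closest-FST population lies >= d_far_km away."""
    if geo is None:
        geo = distance_matrix_km(panel)
    fam = panel.family_of(pop_id)
    members = [p for p in panel.family_members(fam) if p != pop_id]
    if len(members) + 1 <= 2:
        return False, "family has <= 2 populations"
    d_nearest_same = min(geo.loc[pop_id, p] for p in members)
    row = fst.row(pop_id)
    finite = row[np.isfinite(row.to_numpy())]
    if len(finite) == 0:
        return False, "no finite FST to any population"
    fmin = finite.min()
    closest = sorted(
        finite.index[finite == fmin], key=lambda p: (geo.loc[pop_id, p], p)
    )[0]
    d_closest_fst = geo.loc[pop_id, closest]
    if d_nearest_same >= config.d_far_km or d_closest_fst >= config.d_far_km:
        return True, "remote from relatives"
    return False, "locally related genetically and linguistically"


def classify_enclave(
    pop_id: str,
    panel: PopulationPanel,
    fst: FstMatrix,
    config: AnalysisConfig,
    geo: Optional[pd.DataFrame] = None,
) -> EnclaveReport:
    if geo is None:
        geo = distance_matrix_km(panel)
    eligible, reason = enclave_eligibility(pop_id, panel, fst, config, geo)
    if not eligible:
        return EnclaveReport(pop_id, False, "ineligible", reason)
    within = _closest_fst(pop_id, panel, fst, geo, same_family=True)
    between = _closest_fst(pop_id, panel, fst, geo, same_family=False)
    if within is None:
        return EnclaveReport(pop_id, False, "ineligible",
                             "no same-family population with finite FST")
    if between is None:
        return EnclaveReport(pop_id, False, "ineligible",
                             "no other-family population with finite FST")
    f_w, p_w, d_w = within
    f_b, p_b, d_b = between
    if f_w <= f_b and d_w >= config.d_far_km:
        cls = "matching_enclave"
    elif f_b < f_w and d_b >= config.d_far_km:
        cls = "genetic_enclave"
    elif f_b < f_w and d_b < config.d_near_km and d_w >= config.d_far_km:
        cls = "linguistic_enclave"
    else:
        cls = "local_match"
    return EnclaveReport(pop_id, True, cls, "", f_w, f_b, d_w, d_b, p_w, p_b)


def classify_all_enclaves(
    panel: PopulationPanel, fst: FstMatrix, config: AnalysisConfig
) -> list[EnclaveReport]:
    geo = distance_matrix_km(panel)
    return [classify_enclave(p, panel, fst, config, geo) for p in panel.pop_ids]


def _bootstrap_delta_ci(
    within: np.ndarray,
    between: np.ndarray,
    reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """95% percentile bootstrap CI of median(between) - median(within),
    resampling the two sets independently with replacement."""
    wi = rng.integers(0, len(within), size=(reps, len(within)))
    bi = rng.integers(0, len(between), size=(reps, len(between)))
    deltas = np.median(between[bi], axis=1) - np.median(within[wi], axis=1)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return float(lo), float(hi)


def alignment_profile(
    pop_id: str,
    panel: PopulationPanel,
    fst: FstMatrix,
    config: AnalysisConfig,
    geo: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> AlignmentProfile:
    """Within- vs between-family FST distribution comparison for one
    population (drifted populations are handled by the caller).

    The between-family set is restricted to populations within the focal
    family's geographic span of the focal population; the within-family set is
    not distance-restricted.
    """
    if geo is None:
        geo = distance_matrix_km(panel)
    if rng is None:
        rng = np.random.default_rng([config.rng_seed, panel.pop_ids.index(pop_id)])
    fam = panel.family_of(pop_id)
    members = [p for p in panel.family_members(fam) if p != pop_id]
    if len(members) < 1:
        return AlignmentProfile(pop_id, False, reason="singleton family")
    span = family_span_km(panel, fam, config.radius_floor_km, geo)
    row = fst.row(pop_id)
    within = np.array(
        [row[p] for p in members if np.isfinite(row[p])], dtype=float
    )
    between = np.array(
        [
            row[p]
            for p in row.index
            if panel.family_of(p) != fam
            and np.isfinite(row[p])
            and geo.loc[pop_id, p] <= span
        ],
        dtype=float,
    )
    if len(within) < config.min_distribution_size:
        return AlignmentProfile(pop_id, False, n_within=len(within),
                                n_between=len(between),
                                reason="within-family set too small")
    if len(between) < config.min_distribution_size:
        return AlignmentProfile(pop_id, False, n_within=len(within),
                                n_between=len(between),
                                reason="between-family set too small")
    mw = float(np.median(within))
    mb = float(np.median(between))
    delta = mb - mw
    lo, hi = _bootstrap_delta_ci(within, between, config.bootstrap_reps, rng)
    lo, hi = min(lo, delta), max(hi, delta)
    return AlignmentProfile(
        pop_id, True, mw, mb, delta, lo, hi,
        misaligned=mw > mb, n_within=len(within), n_between=len(between),
    )


def alignment_profiles(
    panel: PopulationPanel, fst: FstMatrix, config: AnalysisConfig
) -> list[AlignmentProfile]:
    """Profiles for all non-drifted populations (drifted ones are excluded
    from the FST-distribution analyses)."""
    geo = distance_matrix_km(panel)
    out = []
    for i, rec in enumerate(panel):
        if rec.drifted:
            out.append(AlignmentProfile(rec.pop_id, False, reason="drifted"))
            continue
        rng = np.random.default_rng([config.rng_seed, i])
        out.append(alignment_profile(rec.pop_id, panel, fst, config, geo, rng))
    return out


@dataclass
class MisalignmentSummary:
    proportion: float
    n_assessable: int
    n_misaligned: int
    per_family: pd.DataFrame


def misalignment_summary(
    profiles: Sequence[AlignmentProfile], panel: PopulationPanel
) -> MisalignmentSummary:
    assessable = [p for p in profiles if p.assessable]
    n_mis = sum(bool(p.misaligned) for p in assessable)
    rows = []
    fams = sorted({panel.family_of(p.pop_id) for p in assessable})
    for fam in fams:
        sub = [p for p in assessable if panel.family_of(p.pop_id) == fam]
        rows.append(
            {
                "family": fam,
                "n_assessable": len(sub),
                "n_misaligned": sum(bool(p.misaligned) for p in sub),
            }
        )
    prop = n_mis / len(assessable) if assessable else np.nan
    return MisalignmentSummary(prop, len(assessable), n_mis, pd.DataFrame(rows))


def enclave_table(reports: Sequence[EnclaveReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def alignment_table(profiles: Sequence[AlignmentProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in profiles])
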