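"""Family-scale comparison of genetic divergence times with linguistic ages.

For each language family, genetic divergence times (t = 2 Ne x linearized
FST, in years) are computed over *root-level pairs*: population pairs whose
languages' most recent common ancestor in the family classification tree is
the family root.  The distribution of those times is compared with the
family's published root-age interval (a Bayesian credible interval, and
optionally an archaeological/historical range), both with and without
populations carrying a mismatch flag (enclave and/or misaligned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, PopulationPanel, ValidationError
from .popgen import DivergenceEstimate


@dataclass
class FamilyAgeRecord:
    family: str
    bayes_low: float
    bayes_high: float
    hist_low: Optional[float] = None
    hist_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bayes_low > self.bayes_high:
            raise ValidationError(f"{self.family}: bayes_low > bayes_high")
        if (
            self.hist_low is not None and self.hist_high is not None
            and self.hist_low > self.hist_high
        ):
            raise ValidationError(f"{self.family}: hist_low > hist_high")


def read_family_ages(path) -> dict[str, FamilyAgeRecord]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        def _opt(col):
            return None if col not in df.columns or pd.isna(row[col]) else float(row[col])
        out[str(row["family"])] = FamilyAgeRecord(
            str(row["family"]), float(row["bayes_low"]), float(row["bayes_high"]),
            _opt("hist_low"), _opt("hist_high"),
        )
    return out


def root_level_pairs(
    classification_tree: dendropy.Tree,
    panel: PopulationPanel,
    family: str,
    require_ne: bool = True,
) -> list[tuple[str, str]]:
    """Population pairs of a family whose languages coalesce at the root of
    the family classification tree.

    Populations whose language is absent from the tree are excluded (with a
    warning via the return value being silently smaller); populations without
    an accepted Ne are excluded when ``require_ne``.  Two populations speaking
    the same language never form a root-level pair.
    """
    tip_labels = {t.label for t in classification_tree.taxon_namespace}
    members = []
    for pop in panel.family_members(family):
        rec = panel[pop]
        if rec.language_id not in tip_labels:
            continue
        if require_ne and rec.ne is None:
            continue
        members.append(pop)
    root = classification_tree.seed_node
    out = []
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            la, lb = panel[a].language_id, panel[b].language_id
            if la == lb:
                continue
            taxa = [t for t in classification_tree.taxon_namespace
                    if t.label in (la, lb)]
            mrca = classification_tree.mrca(taxa=taxa)
            if mrca is root:
                out.append((a, b))
    return out


@dataclass
class FamilyAgeComparison:
    family: str
    assessable: bool
    n_pairs: int = 0
    median_t_years: float = np.nan
    iqr_t_years: float = np.nan
    frac_inside_interval: float = np.nan
    median_ratio_to_midpoint: float = np.nan
    n_pairs_clean: int = 0
    median_t_years_clean: float = np.nan
    iqr_t_years_clean: float = np.nan
    frac_inside_interval_clean: float = np.nan
    median_ratio_to_midpoint_clean: float = np.nan


def _summaries(times: np.ndarray, rec: FamilyAgeRecord) -> tuple[float, float, float, float]:
    med = float(np.median(times))
    q1, q3 = np.percentile(times, [25, 75])
    inside = float(np.mean((times >= rec.bayes_low) & (times <= rec.bayes_high)))
    mid = (rec.bayes_low + rec.bayes_high) / 2.0
    ratio = float(np.median(times / mid)) if mid > 0 else np.nan
    return med, float(q3 - q1), inside, ratio


def compare_family_ages(
    pairs: Sequence[tuple[str, str, DivergenceEstimate]],
    age_record: FamilyAgeRecord,
    mismatch_flags: Optional[dict[str, bool]] = None,
) -> FamilyAgeComparison:
    """Summaries of genetic root-level divergence times against the family's
    linguistic root-age interval, on all pairs and on pairs free of
    mismatch-flagged populations."""
    mismatch_flags = mismatch_flags or {}
    avail = [(a, b, e) for a, b, e in pairs if e.available]
    if not avail:
        return FamilyAgeComparison(age_record.family, False)
    times = np.array([e.t_years for _, _, e in avail], dtype=float)
    med, iqr, inside, ratio = _summaries(times, age_record)
    clean = [
        (a, b, e) for a, b, e in avail
        if not mismatch_flags.get(a, False) and not mismatch_flags.get(b, False)
    ]
    out = FamilyAgeComparison(
        age_record.family, True, len(avail), med, iqr, inside, ratio,
        n_pairs_clean=len(clean),
    )
    if clean:
        t2 = np.array([e.t_years for _, _, e in clean], dtype=float)
        (out.median_t_years_clean, out.iqr_t_years_clean,
         out.frac_inside_interval_clean, out.median_ratio_to_midpoint_clean) = _summaries(
            t2, age_record)
    return out


def comparison_table(results: Sequence[FamilyAgeComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
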