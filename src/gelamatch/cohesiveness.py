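"""Family-level genetic cohesiveness under isolation by distance (IBD).

For each major language family we compare linearized FST (FST/(1-FST), the
scale on which pure drift grows roughly linearly with time and hence with
distance under IBD) against geographic distance, for within-family pairs and
for between-family pairs falling inside the family's geographic span.  A
family is *genetically cohesive* when its within-family pairs sit below the
between-family trend across the shared distance range.

The trend curves are LOWESS (local linear regression) fits evaluated on a
fixed distance grid; the overall IBD fit is an ordinary least-squares line.
The cohesion call is quantified as

    cohesion_score = median over within pairs of
                     [between-trend at the pair's distance - observed lin. FST]

with the family declared cohesive when the score is positive and the
within-family trend lies below the between-family trend on at least 75% of
the grid points supported by both curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import AnalysisConfig, FstMatrix, PopulationPanel, ValidationError
from .geodesy import distance_matrix_km, family_span_km
from .popgen import linearize_fst


def family_pairs(
    panel: PopulationPanel,
    fst: FstMatrix,
    family: str,
    config: AnalysisConfig,
    geo: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Long-format pair table for one family.

    Within pairs: both members in the family.  Between pairs: exactly one
    member in the family and geographic distance within the family span.
    Pairs with missing FST are excluded.  Columns: pop_a, pop_b, fst,
    linearized_fst, km, same_family.
    """
    if geo is None:
        geo = distance_matrix_km(panel)
    span = family_span_km(panel, family, config.radius_floor_km, geo)
    ids = panel.pop_ids
    rows = []
    for i, a in enumerate(ids):
        fam_a = panel.family_of(a)
        for b in ids[i + 1:]:
            fam_b = panel.family_of(b)
            in_a, in_b = fam_a == family, fam_b == family
            if not (in_a or in_b):
                continue
            km = float(geo.loc[a, b])
            if in_a and in_b:
                same = True
            elif km <= span:
                same = False
            else:
                continue
            f = fst.get(a, b)
            if not np.isfinite(f):
                continue
            rows.append(
                {"pop_a": a, "pop_b": b, "fst": f,
                 "linearized_fst": float(linearize_fst(f)),
                 "km": km, "same_family": same, "family_of_pair": family}
            )
    return pd.DataFrame(
        rows, columns=["pop_a", "pop_b", "fst", "linearized_fst", "km",
                       "same_family", "family_of_pair"],
    )


@dataclass
class IbdFit:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n_pairs: int


def ibd_regression(pairs: pd.DataFrame) -> IbdFit:
    """OLS of linearized FST on geographic distance over the supplied pairs."""
    if len(pairs) < 3:
        raise ValidationError("ibd_regression needs at least 3 pairs")
    x = sm.add_constant(pairs["km"].to_numpy(dtype=float))
    y = pairs["linearized_fst"].to_numpy(dtype=float)
    fit = sm.OLS(y, x).fit()
    return IbdFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        r_squared=float(fit.rsquared),
        n_pairs=len(pairs),
    )


def smooth_trend(
    km: np.ndarray, lin_fst: np.ndarray, grid: np.ndarray, frac: float
) -> np.ndarray:
    """LOWESS local-linear trend evaluated on ``grid``; NaN outside the
    observed distance range (no extrapolation)."""
    km = np.asarray(km, dtype=float)
    lin_fst = np.asarray(lin_fst, dtype=float)
    out = np.full(grid.shape, np.nan)
    inside = (grid >= km.min()) & (grid <= km.max())
    if len(np.unique(km)) < 2:
        out[inside] = float(np.mean(lin_fst))
        return out
    if inside.any():
        out[inside] = lowess(lin_fst, km, frac=frac, xvals=grid[inside])
    return out


@dataclass
class CohesivenessResult:
    family: str
    assessable: bool
    n_within_pairs: int
    n_between_pairs: int
    ibd_slope: float = np.nan
    ibd_intercept: float = np.nan
    grid_km: np.ndarray = field(default_factory=lambda: np.array([]))
    within_curve: np.ndarray = field(default_factory=lambda: np.array([]))
    between_curve: np.ndarray = field(default_factory=lambda: np.array([]))
    cohesion_score: float = np.nan
    frac_grid_below: float = np.nan
    cohesive: Optional[bool] = None
    reason: str = ""


def cohesion_assessment(
    panel: PopulationPanel,
    fst: FstMatrix,
    family: str,
    config: AnalysisConfig,
    geo: Optional[pd.DataFrame] = None,
    pairs: Optional[pd.DataFrame] = None,
) -> CohesivenessResult:
    if pairs is None:
        pairs = family_pairs(panel, fst, family, config, geo)
    within = pairs[pairs["same_family"]]
    between = pairs[~pairs["same_family"]]
    if len(within) < config.min_within_pairs:
        return CohesivenessResult(
            family, False, len(within), len(between),
            reason=f"fewer than {config.min_within_pairs} within pairs",
        )
    if len(between) < config.min_within_pairs:
        return CohesivenessResult(
            family, False, len(within), len(between),
            reason="too few between pairs inside the family span",
        )
    all_km = pairs["km"].to_numpy(dtype=float)
    grid = np.linspace(all_km.min(), all_km.max(), config.grid_points)
    w_curve = smooth_trend(within["km"].to_numpy(), within["linearized_fst"].to_numpy(),
                           grid, config.smoother_frac)
    b_curve = smooth_trend(between["km"].to_numpy(), between["linearized_fst"].to_numpy(),
                           grid, config.smoother_frac)
    fit = ibd_regression(pairs)

    # between-trend interpolated at each within pair's distance
    b_km = between["km"].to_numpy(dtype=float)
    b_lin = between["linearized_fst"].to_numpy(dtype=float)
    b_at = smooth_trend(b_km, b_lin, np.clip(
        within["km"].to_numpy(dtype=float), b_km.min(), b_km.max()
    ), config.smoother_frac)
    score = float(np.median(b_at - within["linearized_fst"].to_numpy(dtype=float)))

    both = np.isfinite(w_curve) & np.isfinite(b_curve)
    frac_below = float(np.mean(w_curve[both] < b_curve[both])) if both.any() else np.nan
    cohesive = bool(score > 0 and frac_below >= config.cohesion_grid_fraction)
    return CohesivenessResult(
        family, True, len(within), len(between), fit.slope, fit.intercept,
        grid, w_curve, b_curve, score, frac_below, cohesive,
    )


def jackknife_cohesiveness(
    panel: PopulationPanel,
    fst: FstMatrix,
    family: str,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Leave-one-out stability of the cohesion score: drop each family member
    in turn and recompute.  Returns one row per member with the resulting
    score and its deviation from the full-panel score."""
    full = cohesion_assessment(panel, fst, family, config)
    rows = []
    for pop in panel.family_members(family):
        keep = [p for p in panel.pop_ids if p != pop]
        sub_panel = panel.subset(keep)
        sub_fst = fst.submatrix(keep)
        res = cohesion_assessment(sub_panel, sub_fst, family, config)
        rows.append(
            {
                "left_out": pop,
                "cohesion_score": res.cohesion_score,
                "cohesive": res.cohesive,
                "deviation": res.cohesion_score - full.cohesion_score
                if res.assessable and full.assessable else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cohesiveness_table(results: Sequence[CohesivenessResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "family": r.family,
                "assessable": r.assessable,
                "n_within_pairs": r.n_within_pairs,
                "n_between_pairs": r.n_between_pairs,
                "ibd_slope": r.ibd_slope,
                "ibd_intercept": r.ibd_intercept,
                "cohesion_score": r.cohesion_score,
                "frac_grid_below": r.frac_grid_below,
                "cohesive": r.cohesive,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
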