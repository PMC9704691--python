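"""Genetics arithmetic: Weir-Cockerham FST, linearization, divergence times,
the drifted-population filter and the Ne-trajectory stability screen.

The multi-locus FST combines the Weir & Cockerham (1984) variance components
as a ratio of sums across loci (sum(a) / sum(a+b+c)), the standard and less
biased combination; loci that are monomorphic across both samples, or with
fewer than two genotyped individuals in either sample, are skipped.

Divergence time between two populations follows the drift approximation
t = 2 * Ne * FST/(1 - FST) in generations, converted to years with a fixed
generation time (29 y by default).  The Ne entering the formula is a
combination (harmonic mean by default) of the two populations' effective
sizes, since the drift rate of each lineage scales as 1/Ne.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, FstMatrix, PopulationPanel, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for one population: loci x individuals, coded as the
    count of the alternate allele (0/1/2), NaN for missing calls."""

    pop_id: str
    genotypes: np.ndarray  # (L, n) float array with NaN for missing

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=float)
        if g.ndim != 2 or g.shape[1] < 1:
            raise ValidationError(f"{self.pop_id}: genotypes must be loci x individuals")
        vals = g[np.isfinite(g)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError(f"{self.pop_id}: genotype codes must be 0/1/2 or missing")
        self.genotypes = g

    def drop_empty_individuals(self) -> "GenotypeMatrix":
        keep = np.isfinite(self.genotypes).any(axis=0)
        if not keep.all():
            warnings.warn(
                f"{self.pop_id}: dropping {int((~keep).sum())} all-missing individual(s)"
            )
            return GenotypeMatrix(self.pop_id, self.genotypes[:, keep])
        return self


def _locus_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n genotyped, allele frequency, observed het proportion)."""
    called = np.isfinite(g)
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(g, axis=1) / (2.0 * n)
        h = (g == 1).sum(axis=1) / n
    return n, p, h


def wc_fst(g1: GenotypeMatrix, g2: GenotypeMatrix) -> float:
    """Two-population Weir-Cockerham theta as a ratio of component sums."""
    if g1.genotypes.shape[0] != g2.genotypes.shape[0]:
        raise ValidationError("wc_fst: the two populations must share the same loci")
    g1 = g1.drop_empty_individuals()
    g2 = g2.drop_empty_individuals()
    n1, p1, h1 = _locus_stats(g1.genotypes)
    n2, p2, h2 = _locus_stats(g2.genotypes)

    usable = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nsum = n1 + n2
        nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum
        usable &= (pbar > 0.0) & (pbar < 1.0)  # skip monomorphic-in-both loci

        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0

    if not usable.any():
        raise ValidationError("wc_fst: no usable loci (all monomorphic or undersampled)")
    num = a[usable].sum()
    den = (a + b + c)[usable].sum()
    if den == 0.0:
        raise ValidationError("wc_fst: zero total variance across usable loci")
    return float(num / den)


def linearize_fst(fst):
    """FST/(1-FST) with negative estimates clamped to 0.  Accepts scalars or
    arrays; raises on fst >= 1."""
    arr = np.asarray(fst, dtype=float)
    if np.any(arr[np.isfinite(arr)] >= 1.0):
        raise ValidationError("linearize_fst: FST must be < 1")
    clamped = np.clip(arr, 0.0, None)
    out = clamped / (1.0 - clamped)
    return float(out) if np.isscalar(fst) or arr.ndim == 0 else out


def delinearize_fst(lin):
    """Inverse of :func:`linearize_fst` on [0, inf): lin/(1+lin)."""
    arr = np.asarray(lin, dtype=float)
    out = arr / (1.0 + arr)
    return float(out) if np.isscalar(lin) or arr.ndim == 0 else out


@dataclass
class DivergenceEstimate:
    pop_a: str
    pop_b: str
    fst_used: float
    ne_combined: float
    t_generations: float
    t_years: float
    t_low: Optional[float] = None
    t_high: Optional[float] = None
    available: bool = True


def combine_ne(ne_a: float, ne_b: float, how: str = "harmonic") -> float:
    if how == "harmonic":
        return 2.0 / (1.0 / ne_a + 1.0 / ne_b)
    if how == "arithmetic":
        return (ne_a + ne_b) / 2.0
    if how == "min":
        return min(ne_a, ne_b)
    raise ValidationError(f"unknown ne_combine {how!r}")


def divergence_time(
    fst: float,
    ne_a: Optional[float],
    ne_b: Optional[float],
    config: AnalysisConfig,
    pop_a: str = "a",
    pop_b: str = "b",
    ne_a_ci: Optional[tuple[float, float]] = None,
    ne_b_ci: Optional[tuple[float, float]] = None,
) -> DivergenceEstimate:
    """t = 2 * Ne * linearized FST, in generations and years.

    If either Ne is missing the estimate is marked unavailable (the pair drops
    out of all time analyses).  If both Ne credible intervals are given, the
    time interval is propagated from the lower/upper Ne bounds.
    """
    if ne_a is None or ne_b is None:
        return DivergenceEstimate(pop_a, pop_b, fst, np.nan, np.nan, np.nan,
                                  available=False)
    if ne_a <= 0 or ne_b <= 0:
        raise ValidationError("divergence_time: Ne must be positive")
    lin = linearize_fst(fst)
    ne_c = combine_ne(ne_a, ne_b, config.ne_combine)
    t_gen = 2.0 * ne_c * lin
    t_low = t_high = None
    if ne_a_ci is not None and ne_b_ci is not None:
        t_low = 2.0 * combine_ne(ne_a_ci[0], ne_b_ci[0], config.ne_combine) * lin
        t_high = 2.0 * combine_ne(ne_a_ci[1], ne_b_ci[1], config.ne_combine) * lin
        t_low *= config.generation_years
        t_high *= config.generation_years
    return DivergenceEstimate(
        pop_a, pop_b, fst, ne_c, t_gen, config.generation_years * t_gen,
        t_low, t_high,
    )


def flag_drifted(
    panel: PopulationPanel, fst: FstMatrix, config: AnalysisConfig
) -> PopulationPanel:
    """Flag populations with both regional and global median FST above the
    drift threshold (strictly), the signature of strong genetic drift or
    isolation.  Populations alone in their macro-region cannot be assessed
    regionally and are never flagged."""
    flags: dict[str, bool] = {}
    for rec in panel:
        row = fst.row(rec.pop_id)
        finite = row[np.isfinite(row.to_numpy())]
        global_median = float(finite.median()) if len(finite) else np.nan
        regional_ids = [
            p for p in finite.index if panel[p].macro_region == rec.macro_region
        ]
        if not regional_ids:
            logger.warning(
                "flag_drifted: %s is alone in macro-region %s; not flagged",
                rec.pop_id, rec.macro_region,
            )
            flags[rec.pop_id] = False
            continue
        regional_median = float(finite[regional_ids].median())
        flags[rec.pop_id] = bool(
            regional_median > config.drift_threshold
            and global_median > config.drift_threshold
        )
    return panel.with_drifted(flags)


@dataclass
class StabilityVerdict:
    accepted: bool
    reason: str
    point_ne: Optional[float] = None


def ne_stability_filter(
    trajectory: pd.DataFrame,
    config: AnalysisConfig,
    window: tuple[int, int] = (1, 50),
) -> StabilityVerdict:
    """Screen an Ne trajectory (columns generation, ne, ci_low, ci_high) for
    demographic stability over the recent window (generations 1-50).

    Accepts when the trajectory stays below ``ne_max_threshold`` (excludes
    admixture-inflated sizes), its coefficient of variation stays below
    ``cv_max`` (excludes expansions/collapses) and the median CI width ratio
    stays below ``ci_ratio_max`` (excludes uninformative inferences).  The
    point Ne of an accepted trajectory is its geometric mean over the window.
    """
    need = {"generation", "ne"}
    if not need <= set(trajectory.columns):
        raise ValidationError("trajectory needs columns: generation, ne[, ci_low, ci_high]")
    w = trajectory[
        (trajectory["generation"] >= window[0]) & (trajectory["generation"] <= window[1])
    ]
    covered = set(w["generation"].astype(int))
    if not set(range(window[0], window[1] + 1)) <= covered:
        return StabilityVerdict(False, "trajectory does not cover the full window")
    ne = w["ne"].to_numpy(dtype=float)
    if ne.max() > config.ne_max_threshold:
        return StabilityVerdict(False, "ne exceeds maximum threshold")
    cv = ne.std(ddof=0) / ne.mean()
    if cv > config.cv_max:
        return StabilityVerdict(False, f"ne variation too large (CV={cv:.2f})")
    if {"ci_low", "ci_high"} <= set(w.columns) and w[["ci_low", "ci_high"]].notna().all().all():
        ratio = float((w["ci_high"] / w["ci_low"]).median())
        if ratio > config.ci_ratio_max:
            return StabilityVerdict(False, f"CI too wide (median ratio={ratio:.1f})")
    point = float(np.exp(np.mean(np.log(ne))))
    return StabilityVerdict(True, "stable", point)
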