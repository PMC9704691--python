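"""Core domain types and readers/writers for the gene-language panel formats.

The pipeline works from three kinds of external inputs: a population metadata
table (one row per sampled population, with coordinates, the Glottocode-style
identifier of its main language, the language family, macro-region and an
optional effective-population-size estimate), a square pairwise FST matrix
keyed by population id, and Newick trees (linguistic classifications,
time-calibrated linguistic phylogenies, genetic NJ trees).

All tabular formats are tab-separated UTF-8 with a header row; comma-separated
variants are rejected rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_INDIVIDUALS = 5

PANEL_REQUIRED_COLUMNS = (
    "pop_id",
    "n_individuals",
    "lat",
    "lon",
    "language_id",
    "family",
    "macro_region",
)
PANEL_OPTIONAL_COLUMNS = ("ne", "ne_ci_low", "ne_ci_high", "drifted")


class FormatError(ValueError):
    """Malformed external file (missing columns, bad cells, bad Newick)."""


class ValidationError(ValueError):
    """Well-formed file whose contents violate a domain invariant."""


@dataclass
class PopulationRecord:
    """Metadata for one sampled population.

    ``ne`` is the effective population size in diploid individuals, with an
    optional credible interval; ``drifted`` marks populations whose FST
    distribution is globally elevated (filled in by the drift filter).
    """

    pop_id: str
    n_individuals: int
    lat: float
    lon: float
    language_id: str
    family: str
    macro_region: str
    ne: Optional[float] = None
    ne_ci_low: Optional[float] = None
    ne_ci_high: Optional[float] = None
    drifted: Optional[bool] = None

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError(f"{self.pop_id}: n_individuals must be positive")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"{self.pop_id}: latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise ValidationError(f"{self.pop_id}: longitude {self.lon} outside (-180, 180]")
        for name in ("ne", "ne_ci_low", "ne_ci_high"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{self.pop_id}: {name} must be positive, got {v}")
        if (
            self.ne is not None
            and self.ne_ci_low is not None
            and self.ne_ci_high is not None
            and not (self.ne_ci_low <= self.ne <= self.ne_ci_high)
        ):
            raise ValidationError(
                f"{self.pop_id}: Ne CI [{self.ne_ci_low}, {self.ne_ci_high}] "
                f"does not bracket ne={self.ne}"
            )


class PopulationPanel:
    """Ordered collection of :class:`PopulationRecord` with a family index."""

    def __init__(self, records: Sequence[PopulationRecord]):
        ids = [r.pop_id for r in records]
        dup = sorted({i for i in ids if ids.count(i) > 1})
        if dup:
            raise ValidationError(f"duplicate pop_id(s): {', '.join(dup)}")
        for r in records:
            r.validate()
        self._records = list(records)
        self._by_id = {r.pop_id: r for r in records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PopulationRecord]:
        return iter(self._records)

    def __contains__(self, pop_id: str) -> bool:
        return pop_id in self._by_id

    def __getitem__(self, pop_id: str) -> PopulationRecord:
        return self._by_id[pop_id]

    @property
    def pop_ids(self) -> list[str]:
        return [r.pop_id for r in self._records]

    @property
    def family_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for r in self._records:
            idx.setdefault(r.family, []).append(r.pop_id)
        return idx

    def family_of(self, pop_id: str) -> str:
        return self._by_id[pop_id].family

    def family_members(self, family: str) -> list[str]:
        return [r.pop_id for r in self._records if r.family == family]

    def subset(self, pop_ids: Iterable[str]) -> "PopulationPanel":
        keep = set(pop_ids)
        return PopulationPanel([r for r in self._records if r.pop_id in keep])

    def with_drifted(self, flags: dict[str, bool]) -> "PopulationPanel":
        return PopulationPanel(
            [replace(r, drifted=flags.get(r.pop_id, r.drifted)) for r in self._records]
        )

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (lat, lon) in panel order."""
        return np.array([[r.lat, r.lon] for r in self._records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self._records:
            rows.append(
                {
                    "pop_id": r.pop_id,
                    "n_individuals": r.n_individuals,
                    "lat": r.lat,
                    "lon": r.lon,
                    "language_id": r.language_id,
                    "family": r.family,
                    "macro_region": r.macro_region,
                    "ne": r.ne,
                    "ne_ci_low": r.ne_ci_low,
                    "ne_ci_high": r.ne_ci_high,
                    "drifted": r.drifted,
                }
            )
        return pd.DataFrame(rows)


class FstMatrix:
    """Symmetric pairwise Weir-Cockerham FST matrix over a panel's populations.

    Missing pairs are held as NaN and excluded from every downstream
    distribution; they are never silently treated as zero.  Small negative
    estimates (down to -0.05) are legitimate output of the estimator on
    weakly differentiated pairs and are preserved.
    """

    SYMMETRY_TOL = 1e-9

    def __init__(self, pop_ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(pop_ids)
        if values.shape != (n, n):
            raise ValidationError(f"matrix shape {values.shape} does not match {n} ids")
        if len(set(pop_ids)) != n:
            raise ValidationError("duplicate pop_ids in FST matrix")
        finite_both = np.isfinite(values) & np.isfinite(values.T)
        asym = np.abs(values - values.T)
        if np.any(asym[finite_both] > self.SYMMETRY_TOL):
            i, j = np.unravel_index(
                np.argmax(np.where(finite_both, asym, 0.0)), values.shape
            )
            raise ValidationError(
                f"asymmetric FST for pair ({pop_ids[i]}, {pop_ids[j]}): "
                f"{values[i, j]} vs {values[j, i]}"
            )
        if np.any(np.abs(np.diag(values)) > 0):
            raise ValidationError("FST diagonal must be exactly 0")
        off = values[~np.eye(n, dtype=bool)]
        off = off[np.isfinite(off)]
        if off.size and (off.min() < -0.05 or off.max() >= 1.0):
            raise ValidationError("off-diagonal FST outside [-0.05, 1)")
        # symmetrize exactly (values may differ below tolerance)
        values = np.where(np.isfinite(values) & np.isfinite(values.T),
                          (values + values.T) / 2.0, values)
        self.pop_ids = list(pop_ids)
        self.values = values
        self._index = {p: i for i, p in enumerate(self.pop_ids)}

    def get(self, a: str, b: str) -> float:
        """FST for pair (a, b); NaN if the pair is missing."""
        if a == b:
            return 0.0
        return float(self.values[self._index[a], self._index[b]])

    def row(self, pop_id: str) -> pd.Series:
        i = self._index[pop_id]
        s = pd.Series(self.values[i], index=self.pop_ids)
        return s.drop(pop_id)

    def submatrix(self, pop_ids: Sequence[str]) -> "FstMatrix":
        idx = [self._index[p] for p in pop_ids]
        return FstMatrix(list(pop_ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pop_ids, columns=self.pop_ids)


@dataclass
class AnalysisConfig:
    """Thresholds and knobs of the whole pipeline.

    Values stated by the study design: the 500 km radius floor on family
    geographic spans, the 0.1 median-FST drift cutoff, the 29 y generation
    time, and the family-size > 2 eligibility rule.  The remaining defaults
    (1000 km enclave distances, bootstrap recipe, Ne combination, stability
    thresholds) are documented package choices exposed here.
    """

    radius_floor_km: float = 500.0
    d_far_km: float = 1000.0
    d_near_km: float = 1000.0
    drift_threshold: float = 0.1
    min_family_size: int = 3
    bootstrap_reps: int = 2000
    rng_seed: int = 0
    generation_years: float = 29.0
    min_distribution_size: int = 3
    ne_combine: str = "harmonic"
    outlier_exclusions: tuple[str, ...] = ()
    # family-level cohesiveness
    min_within_pairs: int = 10
    smoother_frac: float = 0.5
    grid_points: int = 50
    cohesion_grid_fraction: float = 0.75
    # Ne-trajectory stability screening
    ne_max_threshold: float = 1e6
    cv_max: float = 0.5
    ci_ratio_max: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "radius_floor_km", "d_far_km", "d_near_km", "drift_threshold",
            "generation_years", "bootstrap_reps", "min_family_size",
            "min_distribution_size",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"config.{name} must be > 0")
        if self.ne_combine not in ("harmonic", "arithmetic", "min"):
            raise ValidationError(f"unknown ne_combine {self.ne_combine!r}")
        self.outlier_exclusions = tuple(self.outlier_exclusions)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    head = path.open("r", encoding="utf-8").readline()
    if "\t" not in head and "," in head:
        raise FormatError(f"{path}: expected tab-separated values, found commas in header")
    return pd.read_csv(path, sep="\t", dtype={0: str})


def read_panel(path: str | Path, min_individuals: int = MIN_INDIVIDUALS) -> PopulationPanel:
    """Read a populations.tsv table into a validated panel.

    Populations with fewer than ``min_individuals`` genotyped individuals are
    dropped (the panel inclusion rule); the count of dropped rows is logged.
    """
    df = _read_tsv(path)
    missing = [c for c in PANEL_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records = []
    n_dropped = 0
    for _, row in df.iterrows():
        n_ind = int(row["n_individuals"])
        if n_ind < min_individuals:
            n_dropped += 1
            continue

        def _opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        drifted = None
        if "drifted" in df.columns and not pd.isna(row["drifted"]):
            drifted = bool(row["drifted"])
        records.append(
            PopulationRecord(
                pop_id=str(row["pop_id"]),
                n_individuals=n_ind,
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                language_id=str(row["language_id"]),
                family=str(row["family"]),
                macro_region=str(row["macro_region"]),
                ne=_opt("ne"),
                ne_ci_low=_opt("ne_ci_low"),
                ne_ci_high=_opt("ne_ci_high"),
                drifted=drifted,
            )
        )
    if n_dropped:
        logger.info("read_panel: dropped %d population(s) with < %d individuals",
                    n_dropped, min_individuals)
    return PopulationPanel(records)


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    panel.to_dataframe().to_csv(path, sep="\t", index=False)


def read_fst_matrix(path: str | Path, panel: PopulationPanel) -> FstMatrix:
    """Read a square FST matrix and reconcile its ids with ``panel``.

    The id sets must match exactly (a bijection): an id present in the matrix
    but absent from the panel — or vice versa — is an error, never a silent
    subset.  Empty cells become missing pairs (NaN), not zeros.
    """
    path = Path(path)
    head = path.open("r", encoding="utf-8").readline()
    if "\t" not in head and "," in head:
        raise FormatError(f"{path}: expected tab-separated values, found commas in header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as e:
        raise FormatError(f"{path}: could not parse matrix: {e}") from e
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not df.map(lambda v: isinstance(v, (int, float)) or pd.isna(v)).all().all():
        bad = [c for c in df.columns if df[c].dtype == object]
        raise FormatError(f"{path}: non-numeric cell(s) in column(s) {bad}")
    matrix_ids = list(df.index)
    if list(df.columns) != matrix_ids:
        raise ValidationError(f"{path}: row and column id order differ")
    extra = sorted(set(matrix_ids) - set(panel.pop_ids))
    absent = sorted(set(panel.pop_ids) - set(matrix_ids))
    if extra or absent:
        raise ValidationError(
            f"{path}: id reconciliation with panel failed; "
            f"not in panel: {extra or '-'}; not in matrix: {absent or '-'}"
        )
    df = df.loc[panel.pop_ids, panel.pop_ids]
    values = df.to_numpy(dtype=float)
    np.fill_diagonal(values, 0.0)
    return FstMatrix(panel.pop_ids, values)


def write_fst_matrix(fst: FstMatrix, path: str | Path) -> None:
    fst.to_dataframe().to_csv(path, sep="\t", float_format="%.10g")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_pair_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _check_parentheses(text: str, where: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"{where}: unbalanced parenthesis at character {offset}")
    if depth != 0:
        raise FormatError(f"{where}: {depth} unclosed parenthesis/es")


def read_newick(source: str | Path, is_string: bool = False) -> dendropy.Tree:
    """Parse a Newick tree, rejecting duplicate leaf labels.

    Branch lengths and internal node labels are preserved; underscores in
    labels are kept literal.
    """
    if is_string:
        text, where = str(source), "<string>"
    else:
        text = Path(source).read_text(encoding="utf-8")
        where = str(source)
    _check_parentheses(text, where)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(e):
            dup = str(e).split("Duplicate taxon labels:")[-1].strip()
            raise ValidationError(f"{where}: duplicate leaf label(s): {dup}") from e
        raise FormatError(f"{where}: Newick parse error: {e}") from e
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dup = sorted({l for l in labels if labels.count(l) > 1})
    if dup:
        raise ValidationError(f"{where}: duplicate leaf label(s): {', '.join(dup)}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick", suppress_rooting=True,
            real_value_format_specifier=".12g", unquoted_underscores=True,
        ),
        encoding="utf-8",
    )
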