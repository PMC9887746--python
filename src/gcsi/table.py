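"""Crisis-by-indicator tables: reading, validation, screening, imputation,
standardization and description.

The central container is :class:`IndicatorTable`, a crises x indicators grid
of ordinal scores (typically 0-5) with missing cells, plus per-indicator
metadata (:class:`IndicatorMeta`) recording the pillar each indicator belongs
to and its ordinal bounds.  All downstream analysis — the original pillar
aggregation, the exploratory factor analysis and the confirmatory factor
analysis — starts from this object.

Preparation for factor analysis comes in two flavours, mirroring the two
estimation strategies:

* :func:`impute_median` fills missing cells with the per-indicator median
  (used before the complete-data exploratory factor analysis);
* :func:`standardize` z-scores each indicator over its observed entries and
  leaves missing cells missing (used before the full-information maximum
  likelihood confirmatory factor analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Pillar = Literal["impact", "complexity", "conditions"]
_PILLARS = ("impact", "complexity", "conditions")


class SchemaError(ValueError):
    """Input columns cannot be resolved against the indicator schema."""


class ValidationError(ValueError):
    """A cell value violates its indicator's ordinal bounds."""


@dataclass(frozen=True)
class IndicatorMeta:
    """Metadata for one ordinal indicator.

    Parameters
    ----------
    id : str
        Short stable key used as the column name.
    name : str
        Human-readable name.
    pillar : {"impact", "complexity", "conditions"}
        The composite-index pillar (treated downstream as a latent construct).
    scale_min, scale_max : int
        Inclusive ordinal bounds, typically 0-5 or 1-5.
    crisis_related : bool
        Whether the indicator is collected from the crisis itself (as opposed
        to a routinely collected country-level index).
    collection_frequency : str or None
        Free-text collection cadence for non-crisis indicators.
    """

    id: str
    name: str = ""
    pillar: Pillar = "impact"
    scale_min: int = 0
    scale_max: int = 5
    crisis_related: bool = True
    collection_frequency: str | None = None

    def __post_init__(self) -> None:
        if self.pillar not in _PILLARS:
            raise ValueError(f"unknown pillar {self.pillar!r}; expected one of {_PILLARS}")
        if not self.scale_min < self.scale_max:
            raise ValueError(f"indicator {self.id!r}: scale_min must be < scale_max")


@dataclass(frozen=True)
class IndicatorTable:
    """Crises x indicators grid of ordinal scores with missing cells."""

    crisis_ids: tuple[str, ...]
    indicators: tuple[IndicatorMeta, ...]
    values: np.ndarray  # float array, NaN marks missing

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n, p = vals.shape
        if n != len(self.crisis_ids) or p != len(self.indicators):
            raise ValueError("grid dimensions do not match id/metadata lengths")
        if len(set(self.crisis_ids)) != n:
            raise ValueError("crisis ids must be unique")
        ids = [m.id for m in self.indicators]
        if len(set(ids)) != p:
            raise ValueError("indicator ids must be unique")
        for j, meta in enumerate(self.indicators):
            col = vals[:, j]
            obs = col[~np.isnan(col)]
            bad = (obs < meta.scale_min) | (obs > meta.scale_max)
            if bad.any():
                i = int(np.flatnonzero(~np.isnan(col))[np.flatnonzero(bad)[0]])
                raise ValidationError(
                    f"value {obs[np.flatnonzero(bad)[0]]:g} for indicator "
                    f"{meta.id!r} in crisis {self.crisis_ids[i]!r} outside "
                    f"[{meta.scale_min}, {meta.scale_max}]"
                )

    @property
    def n_crises(self) -> int:
        return len(self.crisis_ids)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def indicator_ids(self) -> list[str]:
        return [m.id for m in self.indicators]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.crisis_ids), columns=self.indicator_ids)

    def subset(self, indicator_ids: Sequence[str]) -> "IndicatorTable":
        """Return a table restricted to ``indicator_ids``, in the given order."""
        pos = {m.id: j for j, m in enumerate(self.indicators)}
        missing = [i for i in indicator_ids if i not in pos]
        if missing:
            raise KeyError(f"unknown indicator ids: {missing}")
        idx = [pos[i] for i in indicator_ids]
        return IndicatorTable(
            crisis_ids=self.crisis_ids,
            indicators=tuple(self.indicators[j] for j in idx),
            values=self.values[:, idx].copy(),
        )


@dataclass(frozen=True)
class MissingnessReport:
    """Outcome of the missing-data screen."""

    missing_fraction: dict[str, float]
    removed: tuple[str, ...]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": list(self.missing_fraction),
                "missing_fraction": list(self.missing_fraction.values()),
                "removed": [i in self.removed for i in self.missing_fraction],
            }
        )


@dataclass(frozen=True)
class PreparedMatrix:
    """A numeric matrix derived from an :class:`IndicatorTable` for modelling.

    ``preparation`` is ``"median_imputed"`` (complete grid) or
    ``"standardized"`` (z-scores, missing cells retained as NaN).  ``means``
    and ``sds`` record the per-indicator statistics used for standardization
    (observed-value means/sds for the imputed preparation too, for reference).
    """

    values: np.ndarray
    crisis_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]
    preparation: str
    means: np.ndarray
    sds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.crisis_ids), columns=list(self.indicator_ids))


# ---------------------------------------------------------------------------
# reading


def read_table(
    path: str | Path,
    schema: Iterable[IndicatorMeta],
    *,
    id_column: str | None = None,
) -> IndicatorTable:
    """Read a crisis-by-indicator table from CSV or XLSX.

    One row per crisis; the first column (or ``id_column``) holds the crisis
    id.  Blank cells and non-numeric sentinels (``"N/A"``, ``"x"`` ...) are
    coerced to missing, with each coercion logged.  Values outside an
    indicator's ordinal bounds raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, dtype=object)
    else:
        df = pd.read_csv(path, dtype=object)
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise SchemaError(f"id column {id_column!r} not found")
    schema = tuple(schema)
    wanted = [m.id for m in schema]
    unknown = [c for c in wanted if c not in df.columns]
    if unknown:
        raise SchemaError(f"schema indicators absent from file: {unknown}")

    ids = [str(v) for v in df[id_column]]
    raw = df[wanted]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    coerced = raw.notna() & numeric.isna()
    for i, j in zip(*np.nonzero(coerced.to_numpy())):
        logger.info(
            "coerced non-numeric cell to missing: crisis=%s indicator=%s value=%r",
            ids[i], wanted[j], raw.iat[i, j],
        )
    return IndicatorTable(tuple(ids), schema, numeric.to_numpy(dtype=float))


def schema_from_frame(df: pd.DataFrame) -> tuple[IndicatorMeta, ...]:
    """Build an indicator schema from a metadata frame.

    Expected columns: ``id`` plus any of ``name``, ``pillar``, ``scale_min``,
    ``scale_max``, ``crisis_related``, ``collection_frequency``.
    """
    metas = []
    for _, row in df.iterrows():
        metas.append(
            IndicatorMeta(
                id=str(row["id"]),
                name=str(row.get("name", "") or ""),
                pillar=row.get("pillar", "impact"),
                scale_min=int(row.get("scale_min", 0)),
                scale_max=int(row.get("scale_max", 5)),
                crisis_related=bool(row.get("crisis_related", True)),
                collection_frequency=row.get("collection_frequency"),
            )
        )
    return tuple(metas)


# ---------------------------------------------------------------------------
# screening and preparation


def missingness_screen(
    table: IndicatorTable, threshold: float = 0.25
) -> tuple[IndicatorTable, MissingnessReport]:
    """Drop indicators whose missing fraction strictly exceeds ``threshold``.

    The inequality is strict: an indicator missing exactly 25% of its cells
    survives a 0.25 screen, while 27% does not.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if table.n_crises == 0 or table.n_indicators == 0:
        raise ValueError("cannot screen an empty table")
    frac = {
        m.id: float(np.isnan(table.values[:, j]).mean())
        for j, m in enumerate(table.indicators)
    }
    removed = tuple(i for i, f in frac.items() if f > threshold)
    kept = [i for i in frac if i not in removed]
    return table.subset(kept), MissingnessReport(frac, removed, threshold)


def impute_median(table: IndicatorTable) -> PreparedMatrix:
    """Replace missing cells with the per-indicator median of observed values.

    The median of an even count is the midpoint of the two central order
    statistics and is kept as-is even when non-integral.
    """
    vals = table.values.copy()
    means = np.empty(table.n_indicators)
    sds = np.empty(table.n_indicators)
    for j, meta in enumerate(table.indicators):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"indicator {meta.id!r} has no observed values")
        col[np.isnan(col)] = np.median(obs)
        means[j] = obs.mean()
        sds[j] = obs.std(ddof=1) if obs.size > 1 else 0.0
    return PreparedMatrix(
        vals, table.crisis_ids, tuple(table.indicator_ids), "median_imputed", means, sds
    )


def standardize(table: IndicatorTable) -> PreparedMatrix:
    """Z-score each indicator over observed entries; missing cells stay missing.

    Uses the sample (n-1) standard deviation.  A constant indicator raises,
    since it carries no correlational information.
    """
    vals = table.values.copy()
    means = np.empty(table.n_indicators)
    sds = np.empty(table.n_indicators)
    for j, meta in enumerate(table.indicators):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        if np.unique(obs).size < 2:
            raise ValueError(f"indicator {meta.id!r} is constant (zero variance)")
        mu, sd = obs.mean(), obs.std(ddof=1)
        vals[:, j] = (col - mu) / sd
        means[j], sds[j] = mu, sd
    return PreparedMatrix(
        vals, table.crisis_ids, tuple(table.indicator_ids), "standardized", means, sds
    )


# ---------------------------------------------------------------------------
# summaries


def correlation_matrix(
    matrix: PreparedMatrix | IndicatorTable,
    method: Literal["spearman", "pearson"] = "spearman",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete correlation matrix between indicators.

    Entries backed by fewer than ``min_pairs`` complete pairs are NaN.
    """
    if isinstance(matrix, IndicatorTable):
        df = matrix.to_frame()
    else:
        df = matrix.to_frame()
    if len(df) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    corr = df.corr(method=method, min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def high_correlation_fraction(corr: pd.DataFrame, cutoff: float = 0.6) -> float:
    """Fraction of off-diagonal pairs with ``|r| > cutoff`` (NaNs excluded)."""
    a = corr.to_numpy()
    iu = np.triu_indices_from(a, k=1)
    vals = a[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.mean(np.abs(vals) > cutoff))


def describe(table: IndicatorTable) -> pd.DataFrame:
    """Per-indicator mean, sd, median, range and number of observations.

    Computed over observed values only; an all-missing indicator gets n=0
    and NaN statistics.
    """
    rows = []
    for j, meta in enumerate(table.indicators):
        col = table.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size:
            rows.append(
                {
                    "indicator": meta.id,
                    "pillar": meta.pillar,
                    "mean": obs.mean(),
                    "sd": obs.std(ddof=1) if obs.size > 1 else np.nan,
                    "median": np.median(obs),
                    "min": obs.min(),
                    "max": obs.max(),
                    "n": int(obs.size),
                }
            )
        else:
            rows.append(
                {
                    "indicator": meta.id,
                    "pillar": meta.pillar,
                    "mean": np.nan,
                    "sd": np.nan,
                    "median": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                    "n": 0,
                }
            )
    return pd.DataFrame(rows).set_index("indicator")
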