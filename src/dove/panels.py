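"""Core panel containers shared by every pipeline stage.

The pipeline works on three tabular inputs: a web-search panel
(region x period x keyword -> relative search rate on Google-Trends-like
0-100 scale), a mortality panel (region x period -> death count, population,
crude rate per 100,000), and a region adjacency list.  All three are plain
CSV on disk and thin pandas-backed containers in memory.

Periods are either uniformly yearly ("2004") or uniformly monthly
("2004-07"); a single dataset never mixes granularities.  Crude rates are
used throughout (count / population x 100,000); monthly rates use the
yearly population.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Period",
    "SearchPanel",
    "MortalityPanel",
    "AdjacencyMap",
    "read_search_panel",
    "write_search_panel",
    "read_mortality_panel",
    "write_mortality_panel",
    "read_adjacency",
    "write_adjacency",
    "pearson_correlation",
    "top_k_overlap",
]


@total_ordering
@dataclass(frozen=True)
class Period:
    """A yearly ("2004") or monthly ("2004-07") observation period.

    Ordering is (year, month); a yearly period sorts before any monthly
    period of the same year.  Panels enforce uniform granularity, so mixed
    comparisons only occur across datasets, never within one.
    """

    year: int
    month: int | None = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValidationError(f"month must be in 1..12, got {self.month}")

    @property
    def monthly(self) -> bool:
        return self.month is not None

    def _key(self) -> tuple[int, int]:
        return (self.year, self.month or 0)

    def __lt__(self, other: "Period") -> bool:
        if not isinstance(other, Period):
            return NotImplemented
        return self._key() < other._key()

    @classmethod
    def parse(cls, text: str) -> "Period":
        text = str(text).strip()
        try:
            if "-" in text:
                y, m = text.split("-")
                return cls(int(y), int(m))
            return cls(int(text))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"cannot parse period {text!r}: expected 'YYYY' or 'YYYY-MM'") from exc

    def __str__(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        return f"{self.year:04d}-{self.month:02d}"


def _check_uniform_granularity(periods: Iterable[Period]) -> None:
    kinds = {p.monthly for p in periods}
    if len(kinds) > 1:
        raise FormatError("mixed granularity: dataset contains both yearly and monthly periods")


class SearchPanel:
    """Relative search rates, wide form: rows (region_id, Period), columns keywords.

    Invariants enforced at construction: rates are non-negative, the keyword
    set is identical across all (region, period) cells (missing entries are
    filled with 0 and logged, mirroring search engines' suppression of
    low-volume queries), and periods share one granularity.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.nlevels != 2:
            raise ValidationError("SearchPanel expects a (region_id, period) MultiIndex")
        n_missing = int(data.isna().sum().sum())
        if n_missing:
            logger.warning("filled %d missing search entries with 0", n_missing)
            data = data.fillna(0.0)
        if (data.to_numpy() < 0).any():
            bad = data[(data < 0).any(axis=1)].index[0]
            raise ValidationError(f"negative search rate at {bad}")
        _check_uniform_granularity(data.index.get_level_values(1))
        self.data = data.sort_index().astype(float)
        self.data.index.names = ["region_id", "period"]

    @property
    def regions(self) -> list[str]:
        return sorted(self.data.index.get_level_values(0).unique())

    @property
    def periods(self) -> list[Period]:
        return sorted(self.data.index.get_level_values(1).unique())

    @property
    def keywords(self) -> list[str]:
        return list(self.data.columns)

    def rates(self, period: Period, keywords: Sequence[str] | None = None) -> pd.DataFrame:
        """Rates for one period: rows regions, columns keywords (ordered)."""
        sub = self.data.xs(period, level="period")
        if keywords is not None:
            missing = [k for k in keywords if k not in sub.columns]
            if missing:
                raise ValidationError(f"keywords absent from search panel: {missing}")
            sub = sub[list(keywords)]
        return sub

    def __len__(self) -> int:
        return int(self.data.size)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SearchPanel) and self.data.equals(other.data)


class MortalityPanel:
    """Death counts, populations and crude rates per 100,000 by (region, period).

    ``count`` is NaN where the source suppressed the value (true count <= 9);
    the ``suppressed`` flag records which.  For every known count the rate
    satisfies rate = count / population x 100,000.
    """

    COLUMNS = ["count", "population", "suppressed", "rate"]

    def __init__(self, data: pd.DataFrame):
        if data.index.nlevels != 2:
            raise ValidationError("MortalityPanel expects a (region_id, period) MultiIndex")
        data = data.copy()
        if "suppressed" not in data.columns:
            data["suppressed"] = data["count"].isna()
        if (data["population"] <= 0).any():
            bad = data[data["population"] <= 0].index[0]
            raise ValidationError(f"non-positive population at {bad}")
        known = ~data["suppressed"]
        if (data.loc[known, "count"] < 0).any():
            raise ValidationError("negative death count")
        if (data.loc[known, "count"] > data.loc[known, "population"]).any():
            bad = data[known & (data["count"] > data["population"])].index[0]
            raise ValidationError(f"count exceeds population at {bad}")
        data["rate"] = data["count"] / data["population"] * 1e5
        _check_uniform_granularity(data.index.get_level_values(1))
        self.data = data[self.COLUMNS].sort_index()
        self.data.index.names = ["region_id", "period"]

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, Period], float],
        populations: Mapping[tuple[str, Period], float],
    ) -> "MortalityPanel":
        idx = pd.MultiIndex.from_tuples(list(counts), names=["region_id", "period"])
        df = pd.DataFrame(
            {
                "count": [counts[k] for k in counts],
                "population": [populations[k] for k in counts],
            },
            index=idx,
        )
        return cls(df)

    @property
    def regions(self) -> list[str]:
        return sorted(self.data.index.get_level_values(0).unique())

    @property
    def periods(self) -> list[Period]:
        return sorted(self.data.index.get_level_values(1).unique())

    def rate(self, region: str, period: Period) -> float:
        return float(self.data.loc[(region, period), "rate"])

    def rates(self, period: Period) -> pd.Series:
        """Crude rates for one period, indexed by region (NaN where suppressed)."""
        return self.data.xs(period, level="period")["rate"]

    def counts(self, period: Period) -> pd.Series:
        return self.data.xs(period, level="period")["count"]

    def populations(self, period: Period) -> pd.Series:
        return self.data.xs(period, level="period")["population"]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MortalityPanel) and self.data.equals(other.data)


class AdjacencyMap:
    """Symmetric, irreflexive region adjacency; islands (no neighbors) allowed."""

    def __init__(self, neighbors: Mapping[str, Iterable[str]]):
        nb = {r: frozenset(v) for r, v in neighbors.items()}
        for r, vs in nb.items():
            if r in vs:
                raise ValidationError(f"region {r} listed as its own neighbor")
            for v in vs:
                if r not in nb.get(v, frozenset()):
                    raise ValidationError(f"asymmetric adjacency: {r} -> {v} but not {v} -> {r}")
        self.neighbors: dict[str, frozenset[str]] = dict(sorted(nb.items()))

    def __getitem__(self, region: str) -> frozenset[str]:
        try:
            return self.neighbors[region]
        except KeyError:
            raise ValidationError(f"region {region} missing from adjacency map") from None

    def __contains__(self, region: str) -> bool:
        return region in self.neighbors

    @property
    def regions(self) -> list[str]:
        return list(self.neighbors)


# ---------------------------------------------------------------------------
# CSV readers / writers.  All files are UTF-8, comma-separated, header row
# mandatory; periods serialize as "YYYY" / "YYYY-MM".
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_search_panel(path) -> SearchPanel:
    """Read a long-form searches.csv (region_id, period, keyword, rate)."""
    df = pd.read_csv(path, dtype={"region_id": str, "keyword": str})
    _require_columns(df, ["region_id", "period", "keyword", "rate"], path)
    if df.empty:
        logger.warning("%s: empty search panel (header only)", path)
        return SearchPanel(
            pd.DataFrame(index=pd.MultiIndex.from_arrays([[], []], names=["region_id", "period"]))
        )
    neg = df[df["rate"] < 0]
    if not neg.empty:
        row = neg.index[0] + 2  # header is line 1
        raise ValidationError(f"{path}: negative rate at line {row}")
    df["period"] = df["period"].map(Period.parse)
    _check_uniform_granularity(df["period"])
    wide = df.pivot_table(
        index=["region_id", "period"], columns="keyword", values="rate", aggfunc="first"
    )
    wide.columns.name = None
    return SearchPanel(wide)


def write_search_panel(panel: SearchPanel, path) -> None:
    long = panel.data.stack().rename("rate").reset_index()
    long.columns = ["region_id", "period", "keyword", "rate"]
    long["period"] = long["period"].astype(str)
    long.sort_values(["region_id", "period", "keyword"]).to_csv(path, index=False)


def read_mortality_panel(path) -> MortalityPanel:
    """Read deaths.csv (region_id, period, count, population); count may be 'suppressed'."""
    df = pd.read_csv(path, dtype={"region_id": str, "count": str})
    _require_columns(df, ["region_id", "period", "count", "population"], path)
    df["period"] = df["period"].map(Period.parse)
    suppressed = df["count"].str.strip().str.lower() == "suppressed"
    counts = pd.to_numeric(df["count"].where(~suppressed), errors="raise")
    out = pd.DataFrame(
        {
            "count": counts.to_numpy(dtype=float),
            "population": df["population"].to_numpy(dtype=float),
            "suppressed": suppressed.to_numpy(),
        },
        index=pd.MultiIndex.from_frame(df[["region_id", "period"]]),
    )
    return MortalityPanel(out)


def write_mortality_panel(panel: MortalityPanel, path) -> None:
    df = panel.data.reset_index()[["region_id", "period", "count", "population", "suppressed"]]
    df["period"] = df["period"].astype(str)
    df["count"] = [
        "suppressed" if s else (f"{c:.10g}")
        for c, s in zip(df["count"], df["suppressed"])
    ]
    df["population"] = df["population"].map(lambda v: f"{v:.10g}")
    df.drop(columns="suppressed").sort_values(["region_id", "period"]).to_csv(path, index=False)


def read_adjacency(path, regions: Sequence[str] | None = None) -> AdjacencyMap:
    """Read adjacency.csv (region_id, neighbor_id); edges are symmetrized.

    ``regions`` adds isolated regions that have no edge rows (islands).
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["region_id", "neighbor_id"], path)
    nb: dict[str, set[str]] = {r: set() for r in (regions or [])}
    for a, b in df[["region_id", "neighbor_id"]].itertuples(index=False):
        if a == b:
            raise ValidationError(f"{path}: region {a} adjacent to itself")
        nb.setdefault(a, set()).add(b)
        nb.setdefault(b, set()).add(a)
    return AdjacencyMap(nb)


def write_adjacency(adj: AdjacencyMap, path) -> None:
    rows = [
        {"region_id": a, "neighbor_id": b}
        for a in adj.regions
        for b in sorted(adj[a])
        if a < b
    ]
    pd.DataFrame(rows, columns=["region_id", "neighbor_id"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Association / ranking helpers
# ---------------------------------------------------------------------------

def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Used to measure per-keyword association with observed death rates across
    regions within a year.  Raises on constant input, where the coefficient
    is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def top_k_overlap(ranking_a: Sequence, ranking_b: Sequence, k: int) -> int:
    """|top-k(a) intersect top-k(b)| for two ordered rankings of ids."""
    if k <= 0:
        raise ValidationError("k must be positive")
    for name, r in (("a", ranking_a), ("b", ranking_b)):
        if len(set(r)) != len(r):
            raise ValidationError(f"ranking {name} contains duplicate ids")
        if k > len(r):
            raise ValidationError(f"k={k} exceeds length of ranking {name}")
    return len(set(ranking_a[:k]) & set(ranking_b[:k]))
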