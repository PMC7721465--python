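"""Design-matrix assembly: keyword rates, lagged response, spatial encodings.

A model instance is one (region, period).  Its predictors are the selected
keyword search rates for that same period (the nowcasting contract: the
target period's own searches are available before its mortality data),
optionally the last previously observed death rate for that region (the lag
feature), and optionally one of four spatial encodings over a fixed region
list:

NONE                  no spatial columns
DUMMY                 one indicator per region (identity)
NEIGHBOR              1 for self and for each geographic neighbor
POP_WEIGHTED_NEIGHBOR 1 for self; each neighbor weighted by its share of the
                      total neighboring population

Spatial columns are indexed by the full region list so train and predict
matrices align even when a region contributes no training rows.
"""
from __future__ import annotations

import enum
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DoveError, ValidationError
from .panels import AdjacencyMap, MortalityPanel, Period, SearchPanel

logger = logging.getLogger(__name__)

__all__ = ["SpatialMode", "MissingLagError", "lag_feature", "spatial_encoding", "build_design"]


class SpatialMode(str, enum.Enum):
    NONE = "NONE"
    DUMMY = "DUMMY"
    NEIGHBOR = "NEIGHBOR"
    POP_WEIGHTED_NEIGHBOR = "POP_WEIGHTED_NEIGHBOR"


class MissingLagError(DoveError):
    """No observed period strictly before the target for this region."""


def lag_feature(mortality: MortalityPanel, region: str, target: Period) -> float:
    """Most recent observed (non-suppressed) rate strictly before ``target``.

    Gaps are skipped: with observations for 2004 only and target 2006 the
    2004 rate is returned ("last available value").
    """
    rows = mortality.data.xs(region, level="region_id")
    prior = rows[[p < target for p in rows.index]]
    prior = prior[~prior["suppressed"]]
    if prior.empty:
        raise MissingLagError(f"no observed rate before {target} for region {region}")
    last = max(prior.index)
    return float(prior.loc[last, "rate"])


def spatial_encoding(
    regions: Sequence[str],
    adjacency: AdjacencyMap,
    populations: Mapping[str, float],
    mode: SpatialMode,
) -> pd.DataFrame:
    """One row per region, one column per region (prefixed ``sp_``); or no
    columns for NONE.  Entries are in [0, 1]; the diagonal is always 1 for
    the encodings that emit columns."""
    mode = SpatialMode(mode)
    cols = [f"sp_{r}" for r in regions]
    if mode is SpatialMode.NONE:
        return pd.DataFrame(index=list(regions), columns=[], dtype=float)
    mat = pd.DataFrame(0.0, index=list(regions), columns=cols)
    for r in regions:
        mat.loc[r, f"sp_{r}"] = 1.0
        if mode is SpatialMode.DUMMY:
            continue
        nbrs = sorted(adjacency[r])
        if mode is SpatialMode.NEIGHBOR:
            for v in nbrs:
                if v in regions:
                    mat.loc[r, f"sp_{v}"] = 1.0
        else:  # POP_WEIGHTED_NEIGHBOR
            total = 0.0
            for v in nbrs:
                if v not in populations:
                    raise ValidationError(f"no population for neighbor {v}")
                total += float(populations[v])
            for v in nbrs:
                if v in regions:
                    mat.loc[r, f"sp_{v}"] = float(populations[v]) / total
    return mat


def build_design(
    search: SearchPanel,
    mortality: MortalityPanel | None,
    keywords: Sequence[str],
    *,
    use_lag: bool = False,
    spatial_mode: SpatialMode = SpatialMode.NONE,
    periods: Iterable[Period],
    adjacency: AdjacencyMap | None = None,
    populations: Mapping[str, float] | None = None,
    region_list: Sequence[str] | None = None,
    with_response: bool = True,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Assemble the feature matrix (and response) for the given periods.

    One row per (region, period).  Columns, in order: the selected keyword
    rates at that period, ``lag_rate`` if enabled, then the spatial columns.
    With ``with_response`` the observed crude rate at each row's period is
    returned as y; rows whose response or lag is unavailable are dropped
    with a log message.  Prediction matrices (``with_response=False``) keep
    all regions.

    Only the lag column reaches back in time; keyword rates are always the
    row period's own.  Temporal-leakage checks against a target period are
    the caller's job (see the walk-forward harness).
    """
    mode = SpatialMode(spatial_mode)
    regions = list(region_list) if region_list is not None else search.regions
    if mode is not SpatialMode.NONE:
        if adjacency is None:
            raise ValidationError(f"spatial mode {mode.value} requires an adjacency map")
        if mode is SpatialMode.POP_WEIGHTED_NEIGHBOR and populations is None:
            raise ValidationError("POP_WEIGHTED_NEIGHBOR requires populations")
        spat = spatial_encoding(regions, adjacency, populations or {}, mode)
    else:
        spat = None

    blocks: list[pd.DataFrame] = []
    ys: list[pd.Series] = []
    n_dropped = 0
    for period in sorted(set(periods)):
        kw = search.rates(period, keywords)
        kw = kw.reindex(regions).dropna(how="all")
        block = kw.copy()
        if use_lag:
            lags = {}
            for r in block.index:
                try:
                    lags[r] = lag_feature(mortality, r, period)
                except (MissingLagError, KeyError):
                    lags[r] = np.nan
            block["lag_rate"] = pd.Series(lags)
            bad = block["lag_rate"].isna()
            n_dropped += int(bad.sum())
            block = block[~bad]
        if spat is not None:
            block = block.join(spat.reindex(block.index))
        if with_response:
            y = mortality.rates(period).reindex(block.index)
            ok = y.notna()
            n_dropped += int((~ok).sum())
            block, y = block[ok], y[ok]
            ys.append(y.set_axis([(r, period) for r in block.index]))
        block.index = pd.MultiIndex.from_tuples(
            [(r, period) for r in block.index], names=["region_id", "period"]
        )
        blocks.append(block)
    if n_dropped:
        logger.info("build_design dropped %d rows lacking lag or response", n_dropped)
    X = pd.concat(blocks) if blocks else pd.DataFrame(columns=list(keywords))
    if not with_response:
        return X, None
    y_all = pd.concat(ys) if ys else pd.Series(dtype=float)
    y_all.index = X.index
    return X, y_all
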