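"""Population-proportional imputation of suppressed county death counts.

Public mortality tables withhold county counts below 10.  The state total
is still published, so for each (state, period) the suppressed remainder
R = state_count - sum(known county counts) is known exactly and is
partitioned among the suppressed counties in proportion to their
populations.  Imputed counts are kept as non-negative reals; by
construction county counts sum to the state count.

An optional cap redistributes any allocation exceeding the suppression
ceiling (a suppressed true count is at most 9) among the remaining
suppressed counties.
"""
from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .errors import SuppressionError, ValidationError
from .panels import MortalityPanel, Period, _check_uniform_granularity, _require_columns

logger = logging.getLogger(__name__)

__all__ = ["CountyMortalityPanel", "impute_suppressed", "read_county_panel", "write_county_panel"]


class CountyMortalityPanel:
    """County death counts by (county_id, period), each county in exactly one state.

    ``count`` is NaN where suppressed; ``imputed`` marks values filled in by
    :func:`impute_suppressed`.
    """

    COLUMNS = ["state_id", "count", "population", "suppressed", "imputed"]

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        if "suppressed" not in data.columns:
            data["suppressed"] = data["count"].isna()
        if "imputed" not in data.columns:
            data["imputed"] = False
        states_per_county = data.groupby(level="county_id")["state_id"].nunique()
        if (states_per_county > 1).any():
            bad = states_per_county[states_per_county > 1].index[0]
            raise ValidationError(f"county {bad} mapped to more than one state")
        if (data["population"] <= 0).any():
            raise ValidationError("non-positive county population")
        _check_uniform_granularity(data.index.get_level_values("period"))
        self.data = data[self.COLUMNS].sort_index()
        self.data.index.names = ["county_id", "period"]

    @property
    def periods(self) -> list[Period]:
        return sorted(self.data.index.get_level_values("period").unique())

    @property
    def counties(self) -> list[str]:
        return sorted(self.data.index.get_level_values("county_id").unique())

    def state_of(self, county_id: str) -> str:
        return str(self.data.xs(county_id, level="county_id")["state_id"].iloc[0])

    def for_period(self, period: Period) -> pd.DataFrame:
        """One period's rows, indexed by county_id."""
        return self.data.xs(period, level="period")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountyMortalityPanel) and self.data.equals(other.data)


def _impute_one_period(
    cdf: pd.DataFrame, states: MortalityPanel, period: Period, cap: float | None
) -> pd.Series:
    """Return imputed counts (indexed by county) for suppressed rows of one period."""
    out = {}
    for state, grp in cdf.groupby("state_id"):
        sup = grp[grp["suppressed"]]
        if sup.empty:
            continue
        try:
            srow = states.data.loc[(state, period)]
        except KeyError:
            raise SuppressionError(f"no state total for {state} at {period}") from None
        if bool(srow["suppressed"]):
            raise SuppressionError(f"state total for {state} at {period} is itself suppressed")
        known = grp.loc[~grp["suppressed"], "count"].sum()
        remainder = float(srow["count"]) - float(known)
        if remainder < -1e-9:
            raise SuppressionError(
                f"state {state} at {period}: known county counts ({known:.10g}) exceed "
                f"state total ({srow['count']:.10g})"
            )
        remainder = max(remainder, 0.0)
        alloc = remainder * sup["population"] / sup["population"].sum()
        if cap is not None:
            # Iteratively cap and redistribute the excess among uncapped
            # suppressed counties, proportionally to population.
            pops = sup["population"].astype(float)
            alloc = alloc.astype(float)
            capped = pd.Series(False, index=alloc.index)
            for _ in range(len(alloc)):
                over = (alloc > cap + 1e-12) & ~capped
                if not over.any():
                    break
                excess = float((alloc[over] - cap).sum())
                alloc[over] = cap
                capped |= over
                free = ~capped
                if not free.any():
                    logger.warning(
                        "state %s at %s: remainder %.4g cannot fit under cap %.4g",
                        state, period, remainder, cap,
                    )
                    break
                alloc[free] += excess * pops[free] / pops[free].sum()
        for county, v in alloc.items():
            out[county] = float(v)
    return pd.Series(out, dtype=float)


def impute_suppressed(
    counties: CountyMortalityPanel,
    states: MortalityPanel,
    period: Period | None = None,
    cap: float | None = None,
) -> CountyMortalityPanel:
    """Fill every suppressed county count by population-proportional allocation.

    Parameters
    ----------
    counties, states
        County panel (with suppression) and the matching state totals.
    period
        Impute a single period; default all periods present.
    cap
        Optional ceiling per imputed count (suppression implies a true count
        <= 9); excess is redistributed among the other suppressed counties.

    The result conserves state totals: for each (state, period) the county
    counts sum exactly to the state count.
    """
    data = counties.data.copy()
    periods: Iterable[Period] = [period] if period is not None else counties.periods
    for p in periods:
        cdf = data.xs(p, level="period")
        filled = _impute_one_period(cdf, states, p, cap)
        for county, v in filled.items():
            data.loc[(county, p), "count"] = v
            data.loc[(county, p), "suppressed"] = False
            data.loc[(county, p), "imputed"] = True
    return CountyMortalityPanel(data)


def read_county_panel(path) -> CountyMortalityPanel:
    """Read counties.csv (county_id, state_id, period, count, population)."""
    df = pd.read_csv(path, dtype={"county_id": str, "state_id": str, "count": str})
    _require_columns(df, ["county_id", "state_id", "period", "count", "population"], path)
    df["period"] = df["period"].map(Period.parse)
    suppressed = df["count"].str.strip().str.lower() == "suppressed"
    counts = pd.to_numeric(df["count"].where(~suppressed), errors="raise")
    out = pd.DataFrame(
        {
            "state_id": df["state_id"].to_numpy(),
            "count": counts.to_numpy(dtype=float),
            "population": df["population"].to_numpy(dtype=float),
            "suppressed": suppressed.to_numpy(),
        },
        index=pd.MultiIndex.from_frame(df[["county_id", "period"]]),
    )
    if "imputed" in df.columns:
        out["imputed"] = df["imputed"].astype(bool).to_numpy()
    return CountyMortalityPanel(out)


def write_county_panel(panel: CountyMortalityPanel, path) -> None:
    df = panel.data.reset_index()
    df["period"] = df["period"].astype(str)
    df["count"] = [
        "suppressed" if s else f"{c:.10g}" for c, s in zip(df["count"], df["suppressed"])
    ]
    df["population"] = df["population"].map(lambda v: f"{v:.10g}")
    cols = ["county_id", "state_id", "period", "count", "population", "imputed"]
    df[cols].sort_values(["county_id", "period"]).to_csv(path, index=False)
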