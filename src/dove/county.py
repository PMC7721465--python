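"""County-level disaggregation of state predictions via share trends.

State-level predicted rates are converted to county counts and rates in
four steps: (i) for each county, compute its historical share of the
state's death count per period and fit an ordinary least-squares trend of
share against time; (ii) convert the predicted state rate to a predicted
state count via the state population; (iii) partition that count among
counties by the trend-extrapolated shares (clamped to [0, 1] and
renormalized to sum to 1 within each state); (iv) divide each county count
by the county population for the county rate.

Share regressions use counts (not rates); the time axis is the period's
position in the sorted historical period list, which only shifts the
intercept — the fitted line is always evaluated at the target's position,
so the origin choice is immaterial.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panels import MortalityPanel, Period
from .suppression import CountyMortalityPanel

logger = logging.getLogger(__name__)

__all__ = ["CountyShareModel", "fit_share_trends", "partition_state_prediction", "partition_all"]


@dataclass
class CountyShareModel:
    """Fitted share-vs-time lines and the clamped, renormalized target shares.

    ``table`` has one row per county: state_id, slope, intercept,
    raw_share (the line evaluated at the target), share (after clamping to
    [0, 1] and within-state renormalization).  Within each state the final
    shares sum to 1.
    """

    target: Period
    table: pd.DataFrame

    def shares_for(self, state_id: str) -> pd.Series:
        sub = self.table[self.table["state_id"] == state_id]
        if sub.empty:
            raise ValidationError(f"no counties for state {state_id}")
        return sub["share"]


def fit_share_trends(
    counties: CountyMortalityPanel, states: MortalityPanel, target: Period
) -> CountyShareModel:
    """OLS trend of each county's within-state count share, evaluated at ``target``.

    Requires an imputed county panel (no suppressed rows).  Periods where a
    state's total count is zero are excluded from that state's fits with a
    warning.  Counties observed in fewer than 2 periods keep their most
    recent share (logged).
    """
    if counties.data["suppressed"].any():
        raise ValidationError("county panel still contains suppressed counts; impute first")
    periods = [p for p in counties.periods if p < target]
    if len(periods) < 2:
        raise ValidationError("need at least 2 historical periods before the target")
    # Time axis: position in the sorted full period list; the target sits
    # one step after the last historical period unless it appears in it.
    all_axis = sorted(set(periods) | {target})
    pos = {p: i for i, p in enumerate(all_axis)}

    rows = []
    for county in counties.counties:
        hist = counties.data.xs(county, level="county_id")
        hist = hist[[p in pos and p < target for p in hist.index]]
        state = str(hist["state_id"].iloc[0])
        xs, ys = [], []
        for p, row in hist.iterrows():
            try:
                srow = states.data.loc[(state, p)]
            except KeyError:
                continue
            total = float(srow["count"])
            if total == 0 or bool(srow["suppressed"]):
                logger.warning("state %s at %s: zero/suppressed total excluded from share fit", state, p)
                continue
            xs.append(pos[p])
            ys.append(float(row["count"]) / total)
        if len(xs) >= 2:
            slope, intercept = np.polyfit(np.asarray(xs, dtype=float), np.asarray(ys, dtype=float), 1)
            raw = slope * pos[target] + intercept
        elif len(xs) == 1:
            logger.info("county %s has a single usable period; carrying its share forward", county)
            slope, intercept, raw = 0.0, ys[0], ys[0]
        else:
            slope, intercept, raw = 0.0, 0.0, 0.0
        rows.append(
            {"county_id": county, "state_id": state, "slope": float(slope),
             "intercept": float(intercept), "raw_share": float(raw)}
        )
    table = pd.DataFrame(rows).set_index("county_id")
    table["share"] = np.clip(table["raw_share"], 0.0, 1.0)
    for state, grp in table.groupby("state_id"):
        s = grp["share"].sum()
        if s == 0:
            # All-zero extrapolations: fall back to equal shares.
            table.loc[grp.index, "share"] = 1.0 / len(grp)
        else:
            table.loc[grp.index, "share"] = grp["share"] / s
    return CountyShareModel(target=target, table=table)


def partition_state_prediction(
    state_rate_pred: float,
    state_population: float,
    shares: pd.Series,
    county_populations: Mapping[str, float],
) -> pd.DataFrame:
    """Split one state's predicted rate into county counts and rates.

    state_count = rate x population / 100,000; county counts are
    state_count x share; county rates divide by county population.  County
    counts sum to the state count by construction.
    """
    if abs(float(shares.sum()) - 1.0) > 1e-9:
        raise ValidationError(f"shares sum to {shares.sum():.12g}, expected 1")
    state_count = state_rate_pred * state_population / 1e5
    out = []
    for county, share in shares.items():
        pop = float(county_populations[county])
        if pop <= 0:
            raise ValidationError(f"county {county} has non-positive population")
        count = state_count * float(share)
        out.append(
            {"county_id": county, "predicted_count": count,
             "predicted_rate": count / pop * 1e5, "share": float(share)}
        )
    return pd.DataFrame(out).set_index("county_id")


def partition_all(
    state_rates: pd.Series,
    state_populations: Mapping[str, float],
    shares: CountyShareModel,
    county_populations: Mapping[str, float],
) -> pd.DataFrame:
    """Partition every state's predicted rate; rows indexed by county."""
    frames = []
    for state, rate in state_rates.items():
        if state not in set(shares.table["state_id"]):
            logger.info("state %s has no county shares; skipped", state)
            continue
        df = partition_state_prediction(
            float(rate), float(state_populations[state]), shares.shares_for(state), county_populations
        )
        df["state_id"] = state
        frames.append(df)
    return pd.concat(frames).sort_index()
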