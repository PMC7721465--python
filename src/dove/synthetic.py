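"""Synthetic panels with known ground truth.

Emulates the structure of the real inputs — 51 regions, 80 keyword search
series on a 0-100 relative scale, yearly or monthly periods, crude death
rates per 100,000, county counts with small-count suppression — so that
every pipeline stage is testable without any download.  This is a
structural emulator, not a calibrated one: parameters are chosen to look
like national state-level overdose mortality (baseline rates roughly 5-50
per 100,000, populations 0.5M-40M), not fitted to any real dataset.

The generative model:

* latent rate(r, t) = region baseline (log-uniform over [5, 50]) + a
  region-specific linear trend scaled by ``trend_strength`` + AR(1) noise;
* each informative keyword is an affine function of the latent rate plus
  AR(1) noise at the requested signal-to-noise ratio, min-max rescaled to
  [0, 100]; uninformative keywords are independent AR(1) noise on the same
  scale;
* observed death counts are Poisson(latent x population / 1e5), making
  observed rates a noisy version of the latent truth;
* adjacency is a grid graph over the regions with random edge deletions
  (symmetric; islands permitted);
* county counts split each state count by Dirichlet shares drifting
  linearly in time, then counts below the suppression threshold are masked.

All randomness flows from a single integer seed through spawned
``numpy.random`` substreams, so generation is a pure function of its
parameters and byte-identical across runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .panels import AdjacencyMap, MortalityPanel, Period, SearchPanel
from .suppression import CountyMortalityPanel

__all__ = ["SyntheticTruth", "SyntheticData", "generate_panel", "generate_counties"]


@dataclass
class SyntheticTruth:
    """Ground truth retained by the generator for recovery checks."""

    informative_keywords: list[str]
    link_coefficients: dict[str, float]
    latent_rates: pd.DataFrame  # regions x periods, per 100,000
    noise_sd: dict[str, float]
    seed: int
    county_true_counts: pd.DataFrame | None = field(default=None)

    def as_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "informative_keywords": self.informative_keywords,
            "link_coefficients": self.link_coefficients,
            "noise_sd": self.noise_sd,
        }


class SyntheticData(NamedTuple):
    search: SearchPanel
    mortality: MortalityPanel
    adjacency: AdjacencyMap
    truth: SyntheticTruth


def _periods(n_periods: int, granularity: str, start_year: int = 2004) -> list[Period]:
    if granularity == "YEARLY":
        return [Period(start_year + i) for i in range(n_periods)]
    if granularity == "MONTHLY":
        return [Period(start_year + i // 12, i % 12 + 1) for i in range(n_periods)]
    raise ValidationError("granularity must be YEARLY or MONTHLY")


def _ar1(rng: np.random.Generator, shape: tuple[int, int], rho: float = 0.5) -> np.ndarray:
    """Row-wise AR(1) noise with unit marginal variance, shape (rows, T)."""
    rows, T = shape
    innov = rng.normal(size=(rows, T)) * np.sqrt(1 - rho**2)
    out = np.empty((rows, T))
    out[:, 0] = rng.normal(size=rows)
    for t in range(1, T):
        out[:, t] = rho * out[:, t - 1] + innov[:, t]
    return out


def _grid_adjacency(region_ids: list[str], rng: np.random.Generator, drop_prob: float = 0.2) -> AdjacencyMap:
    n = len(region_ids)
    cols = max(int(np.ceil(np.sqrt(n))), 1)
    rows = int(np.ceil(n / cols))
    g = nx.grid_2d_graph(rows, cols)
    nodes = sorted(g.nodes)[:n]
    g = g.subgraph(nodes).copy()
    for edge in sorted(g.edges):
        if rng.random() < drop_prob:
            g.remove_edge(*edge)
    mapping = {node: region_ids[i] for i, node in enumerate(sorted(g.nodes))}
    nb = {r: set() for r in region_ids}
    for a, b in g.edges:
        nb[mapping[a]].add(mapping[b])
        nb[mapping[b]].add(mapping[a])
    return AdjacencyMap(nb)


def generate_panel(
    n_regions: int = 51,
    n_periods: int = 14,
    granularity: str = "YEARLY",
    n_keywords: int = 80,
    m_informative: int = 5,
    snr: float = 2.0,
    trend_strength: float = 1.0,
    seed: int = 0,
) -> SyntheticData:
    """Generate matched search, mortality and adjacency panels.

    Defaults mirror the real study conditions: 51 regions, 14 yearly
    periods, 80 keywords of which a handful carry signal.  ``snr`` is the
    ratio of the informative keywords' signal standard deviation to their
    noise standard deviation.
    """
    if m_informative > n_keywords:
        raise ValidationError("m_informative cannot exceed n_keywords")
    if n_periods < 3:
        raise ValidationError("need at least 3 periods")
    root = np.random.SeedSequence(seed)
    rng_rate, rng_kw, rng_adj, rng_pop, rng_count = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    width = max(2, len(str(n_regions)))
    regions = [f"R{i + 1:0{width}d}" for i in range(n_regions)]
    kw_width = max(2, len(str(n_keywords)))
    keywords = [f"kw{j:0{kw_width}d}" for j in range(n_keywords)]
    periods = _periods(n_periods, granularity)
    T = n_periods

    baseline = np.exp(rng_rate.uniform(np.log(5.0), np.log(50.0), size=n_regions))
    slope = rng_rate.normal(0.0, 0.03, size=n_regions) * baseline * trend_strength
    noise = _ar1(rng_rate, (n_regions, T)) * (0.03 * baseline)[:, None]
    t_idx = np.arange(T)
    latent = baseline[:, None] + slope[:, None] * t_idx[None, :] + noise
    latent = np.clip(latent, 1.0, None)

    informative_idx = np.sort(rng_kw.choice(n_keywords, size=m_informative, replace=False))
    rates = np.empty((n_keywords, n_regions, T))
    link: dict[str, float] = {}
    noise_sd: dict[str, float] = {}
    for j in range(n_keywords):
        if j in informative_idx:
            b = rng_kw.uniform(0.5, 2.0)
            a = rng_kw.uniform(0.0, 10.0)
            signal = a + b * latent
            sd = float(signal.std()) / snr if np.isfinite(snr) else 0.0
            series = signal + _ar1(rng_kw, (n_regions, T)) * sd
            link[keywords[j]] = float(b)
            noise_sd[keywords[j]] = sd
        else:
            series = _ar1(rng_kw, (n_regions, T))
        lo, hi = series.min(), series.max()
        span = hi - lo if hi > lo else 1.0
        rates[j] = (series - lo) / span * 100.0

    adjacency = _grid_adjacency(regions, rng_adj)
    populations = np.exp(rng_pop.uniform(np.log(0.5e6), np.log(40e6), size=n_regions)).round()

    counts = rng_count.poisson(latent * populations[:, None] / 1e5).astype(float)

    idx = pd.MultiIndex.from_product([regions, periods], names=["region_id", "period"])
    search = SearchPanel(
        pd.DataFrame(
            rates.transpose(1, 2, 0).reshape(n_regions * T, n_keywords),
            index=idx, columns=keywords,
        )
    )
    mortality = MortalityPanel(
        pd.DataFrame(
            {
                "count": counts.reshape(-1),
                "population": np.repeat(populations, T),
                "suppressed": False,
            },
            index=idx,
        )
    )
    truth = SyntheticTruth(
        informative_keywords=[keywords[j] for j in informative_idx],
        link_coefficients=link,
        latent_rates=pd.DataFrame(latent, index=regions, columns=periods),
        noise_sd=noise_sd,
        seed=seed,
    )
    return SyntheticData(search, mortality, adjacency, truth)


def generate_counties(
    states: MortalityPanel,
    counties_per_state: tuple[int, int] = (3, 8),
    share_drift: float = 0.02,
    suppression_threshold: int = 10,
    seed: int = 0,
) -> tuple[CountyMortalityPanel, pd.DataFrame]:
    """Split each state's counts among synthetic counties, then mask small counts.

    Per state, base shares are Dirichlet; each county's share drifts
    linearly at up to ``share_drift`` per period (shares are re-clipped and
    renormalized).  County counts are the state count times the share,
    rounded with the residue assigned to the largest county so sums are
    exact.  Counts below ``suppression_threshold`` are masked SUPPRESSED.

    Returns the (masked) county panel and the unmasked true counts
    (counties x periods) for recovery checks.
    """
    lo, hi = counties_per_state
    if lo < 1 or hi < lo:
        raise ValidationError("counties_per_state must be a (low, high) range with low >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    periods = states.periods
    T = len(periods)

    rows = []
    truth_rows = {}
    for state in states.regions:
        n_c = int(rng.integers(lo, hi + 1))
        base = rng.dirichlet(np.full(n_c, 2.0))
        drift = rng.normal(size=n_c)
        drift -= drift.mean()
        mx = np.abs(drift).max()
        if mx > 0:
            drift = drift / mx * share_drift
        county_ids = [f"{state}_c{j + 1:02d}" for j in range(n_c)]
        state_pop = float(states.data.xs(state, level="region_id")["population"].iloc[0])
        county_pops = np.maximum(np.round(state_pop * base), 1.0)
        for t, period in enumerate(periods):
            shares = np.clip(base + drift * t, 0.0, None)
            shares = shares / shares.sum()
            total = states.data.loc[(state, period)]
            if bool(total["suppressed"]):
                raise ValidationError(f"state total suppressed at {state}, {period}")
            total_count = float(total["count"])
            raw = total_count * shares
            counts = np.round(raw)
            counts[int(np.argmax(shares))] += total_count - counts.sum()
            counts = np.maximum(counts, 0.0)
            # re-fix the sum if the residue push went negative elsewhere
            diff = total_count - counts.sum()
            if diff != 0:
                counts[int(np.argmax(counts))] += diff
            for j, county in enumerate(county_ids):
                suppressed = counts[j] < suppression_threshold
                truth_rows[(county, period)] = counts[j]
                rows.append(
                    {
                        "county_id": county,
                        "period": period,
                        "state_id": state,
                        "count": np.nan if suppressed else counts[j],
                        "population": county_pops[j],
                        "suppressed": suppressed,
                    }
                )
    df = pd.DataFrame(rows).set_index(["county_id", "period"])
    truth = pd.Series(truth_rows, name="true_count")
    truth.index.names = ["county_id", "period"]
    return CountyMortalityPanel(df), truth.to_frame()
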