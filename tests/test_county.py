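"""County share trends and partitioning of state predictions."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dove import (
    CountyMortalityPanel,
    MortalityPanel,
    Period,
    ValidationError,
    fit_share_trends,
    generate_counties,
    generate_panel,
    impute_suppressed,
    partition_all,
    partition_state_prediction,
)

YEARS = [Period(2004 + i) for i in range(4)]


def build_panels(shares_by_year, state_counts, pops=None):
    """shares_by_year: {county: [share per year]}; state_counts: [count per year]."""
    counties = list(shares_by_year)
    pops = pops or {c: 10_000.0 for c in counties}
    rows = []
    for t, p in enumerate(YEARS[: len(state_counts)]):
        for c in counties:
            rows.append(
                {"county_id": c, "period": p, "state_id": "S1",
                 "count": shares_by_year[c][t] * state_counts[t],
                 "population": pops[c], "suppressed": False}
            )
    cpanel = CountyMortalityPanel(pd.DataFrame(rows).set_index(["county_id", "period"]))
    idx = pd.MultiIndex.from_tuples(
        [("S1", p) for p in YEARS[: len(state_counts)]], names=["region_id", "period"]
    )
    spanel = MortalityPanel(
        pd.DataFrame({"count": [float(v) for v in state_counts],
                      "population": 1_000_000.0, "suppressed": False}, index=idx)
    )
    return cpanel, spanel


class TestFitShareTrends:
    def test_exact_linear_trend_extrapolates(self):
        cpanel, spanel = build_panels(
            {"c1": [0.10, 0.12, 0.14], "c2": [0.90, 0.88, 0.86]}, [100, 100, 100]
        )
        model = fit_share_trends(cpanel, spanel, YEARS[3])
        assert model.table.loc["c1", "raw_share"] == pytest.approx(0.16, abs=1e-12)

    def test_constant_shares_stay_constant(self):
        cpanel, spanel = build_panels(
            {"c1": [0.25] * 3, "c2": [0.75] * 3}, [100, 200, 100]
        )
        model = fit_share_trends(cpanel, spanel, YEARS[3])
        assert model.table.loc["c1", "share"] == pytest.approx(0.25, abs=1e-12)

    def test_clamp_then_renormalize(self):
        # Raw extrapolations {-0.02, 0.40, 0.62} -> clamp {0, 0.40, 0.62}
        # -> renormalize {0, 0.392..., 0.608...}
        model_table = pd.DataFrame(
            {"state_id": "S1", "raw_share": [-0.02, 0.40, 0.62]},
            index=["c1", "c2", "c3"],
        )
        clamped = np.clip(model_table["raw_share"], 0, 1)
        renorm = clamped / clamped.sum()
        np.testing.assert_allclose(renorm, [0.0, 0.40 / 1.02, 0.62 / 1.02])
        # and the fitted pipeline reproduces exactly that arithmetic
        shares = {"c1": [0.06, 0.02], "c2": [0.40, 0.40], "c3": [0.54, 0.58]}
        cpanel, spanel = build_panels(shares, [100, 100])
        model = fit_share_trends(cpanel, spanel, YEARS[2])
        np.testing.assert_allclose(
            model.table["raw_share"].to_numpy(), [-0.02, 0.40, 0.62], atol=1e-12
        )
        np.testing.assert_allclose(
            model.table["share"].to_numpy(), [0.0, 0.40 / 1.02, 0.62 / 1.02], atol=1e-12
        )

    def test_shares_sum_to_one_per_state(self):
        cpanel, spanel = build_panels(
            {"c1": [0.1, 0.3, 0.2], "c2": [0.9, 0.7, 0.8]}, [100, 50, 80]
        )
        model = fit_share_trends(cpanel, spanel, YEARS[3])
        assert model.table["share"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_suppressed_input_rejected(self):
        cpanel, spanel = build_panels({"c1": [0.5, 0.5], "c2": [0.5, 0.5]}, [100, 100])
        bad = cpanel.data.copy()
        bad.loc[bad.index[0], "suppressed"] = True
        with pytest.raises(ValidationError, match="impute"):
            fit_share_trends(CountyMortalityPanel(bad), spanel, YEARS[2])


class TestPartition:
    def test_arithmetic_chain(self):
        shares = pd.Series({"c1": 0.25, "c2": 0.75})
        out = partition_state_prediction(20.0, 1_000_000.0, shares,
                                         {"c1": 100_000.0, "c2": 400_000.0})
        assert out.loc["c1", "predicted_count"] == pytest.approx(50.0)
        assert out.loc["c2", "predicted_count"] == pytest.approx(150.0)
        assert out.loc["c1", "predicted_rate"] == pytest.approx(50.0)

    def test_single_county_identity(self):
        out = partition_state_prediction(
            10.0, 500_000.0, pd.Series({"c1": 1.0}), {"c1": 200_000.0}
        )
        assert out.loc["c1", "predicted_count"] == pytest.approx(50.0)
        assert out.loc["c1", "predicted_rate"] == pytest.approx(25.0)

    def test_zero_share_zero_count(self):
        out = partition_state_prediction(
            10.0, 1e6, pd.Series({"c1": 0.0, "c2": 1.0}), {"c1": 1e4, "c2": 1e4}
        )
        assert out.loc["c1", "predicted_count"] == 0.0
        assert out.loc["c1", "predicted_rate"] == 0.0

    def test_zero_population_rejected(self):
        with pytest.raises(ValidationError):
            partition_state_prediction(10.0, 1e6, pd.Series({"c1": 1.0}), {"c1": 0.0})

    def test_unnormalized_shares_rejected(self):
        with pytest.raises(ValidationError):
            partition_state_prediction(10.0, 1e6, pd.Series({"c1": 0.7}), {"c1": 1e4})

    def test_conservation_randomized(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(1, 10))
            raw = rng.dirichlet(np.ones(n))
            shares = pd.Series(raw, index=[f"c{i}" for i in range(n)])
            pops = {f"c{i}": float(rng.integers(1_000, 1_000_000)) for i in range(n)}
            rate = float(rng.uniform(1, 60))
            state_pop = float(rng.integers(100_000, 10_000_000))
            out = partition_state_prediction(rate, state_pop, shares, pops)
            assert out["predicted_count"].sum() == pytest.approx(
                rate * state_pop / 1e5, abs=1e-9
            )

    def test_constant_shares_scale_with_state_rate(self):
        shares = pd.Series({"c1": 0.3, "c2": 0.7})
        pops = {"c1": 50_000.0, "c2": 70_000.0}
        a = partition_state_prediction(10.0, 1e6, shares, pops)["predicted_rate"]
        b = partition_state_prediction(30.0, 1e6, shares, pops)["predicted_rate"]
        np.testing.assert_allclose(b, 3 * a)


class TestRankRecovery:
    def test_spearman_of_predicted_county_ranks_on_low_noise_panels(self):
        """With low-noise synthetic trends the predicted county-rate ranking
        tracks the true one (rank correlation > 0.9)."""
        data = generate_panel(n_regions=20, n_periods=8, n_keywords=20,
                              m_informative=3, snr=8.0, seed=13)
        counties, truth = generate_counties(
            data.mortality, share_drift=0.005, suppression_threshold=5, seed=13
        )
        target = data.mortality.periods[-1]
        imputed = impute_suppressed(counties, data.mortality)
        # restrict history to periods before target
        hist = CountyMortalityPanel(
            imputed.data[imputed.data.index.get_level_values("period") < target]
        )
        shares = fit_share_trends(hist, data.mortality, target)
        # use the true state rates as the state-level prediction: isolates
        # the partitioning step from regression error
        state_rates = data.mortality.rates(target)
        state_pops = data.mortality.populations(target).to_dict()
        county_pops = imputed.data.groupby(level="county_id")["population"].first().to_dict()
        pred = partition_all(state_rates, state_pops, shares, county_pops)
        true_counts = truth.xs(target, level="period")["true_count"]
        true_rates = true_counts / pd.Series(county_pops).reindex(true_counts.index) * 1e5
        joined = pred.join(true_rates.rename("true_rate"))
        rho = stats.spearmanr(joined["predicted_rate"], joined["true_rate"]).statistic
        assert rho > 0.9
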