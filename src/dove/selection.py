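"""Walk-forward model selection over the pipeline tuning grid.

The tuning grid crosses five pipeline parameters: regression method (8),
number of top keywords kept by MultiSURF, years of training data (only the
immediately previous period vs all available), inclusion of the lagged
observed rate, and the spatial encoding (4 levels).  Each configuration is
evaluated on every feasible target period by training strictly on earlier
periods and scoring the target-period predictions with the median absolute
error percentage (MAE%).  Per-parameter (marginal) selection then picks the
best level of each parameter independently, mirroring per-parameter tuning
on panel data; joint selection (single best cell) is available as an
alternative since the two can disagree under interactions.

A hard leakage guard refuses any training row at or after the target
period.  The held-out validation period never enters selection: the chosen
configuration is refit once on all working periods and applied to it.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LeakageError, MetricError, ValidationError
from .features import SpatialMode, build_design
from .models import RegressorSpec, fit
from .multisurf import DEFAULT_ENDPOINT_TOLERANCE, multisurf_scores, select_top_k
from .panels import AdjacencyMap, MortalityPanel, Period, SearchPanel

logger = logging.getLogger(__name__)

__all__ = [
    "YEARS_MODES",
    "ModelConfig",
    "Grid",
    "paper_grid",
    "reduced_grid",
    "enumerate_configs",
    "mae_percent",
    "national_total_error",
    "nowcast",
    "walk_forward_evaluate",
    "evaluate_grid",
    "EvaluationReport",
    "select_best",
]

YEARS_MODES = ("PREVIOUS_ONLY", "ALL_AVAILABLE")

#: 15 keyword-count levels, 5..75 in steps of 5.
KEYWORD_LEVELS_15 = tuple(range(5, 80, 5))
#: 16 levels: the 15 above plus all 80 keywords.  The full grid then has
#: 16 x 8 x 2 x 2 x 4 = 2048 cells (vs 1920 with 15 levels).
KEYWORD_LEVELS_16 = KEYWORD_LEVELS_15 + (80,)


@dataclass(frozen=True)
class ModelConfig:
    """One point of the tuning grid."""

    method: str
    n_keywords: int
    years_mode: str
    use_lag: bool
    spatial_mode: SpatialMode

    def __post_init__(self) -> None:
        if self.years_mode not in YEARS_MODES:
            raise ValidationError(f"years_mode must be one of {YEARS_MODES}")
        object.__setattr__(self, "spatial_mode", SpatialMode(self.spatial_mode))
        if self.n_keywords <= 0:
            raise ValidationError("n_keywords must be positive")

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "n_keywords": self.n_keywords,
            "years_mode": self.years_mode,
            "use_lag": self.use_lag,
            "spatial_mode": self.spatial_mode.value,
        }


@dataclass(frozen=True)
class Grid:
    """Level sets for each tuning parameter; the grid is their product."""

    methods: tuple[str, ...]
    keyword_levels: tuple[int, ...]
    years_modes: tuple[str, ...] = YEARS_MODES
    lag_options: tuple[bool, ...] = (False, True)
    spatial_modes: tuple[SpatialMode, ...] = tuple(SpatialMode)

    def __post_init__(self) -> None:
        for name in ("methods", "keyword_levels", "years_modes", "lag_options", "spatial_modes"):
            if not getattr(self, name):
                raise ValidationError(f"empty level set: {name}")

    @property
    def size(self) -> int:
        return (
            len(self.methods)
            * len(self.keyword_levels)
            * len(self.years_modes)
            * len(self.lag_options)
            * len(self.spatial_modes)
        )


def paper_grid(n_keyword_levels: int = 16) -> Grid:
    """The full 8-method tuning grid.

    With 16 keyword levels (5..75 step 5, plus all 80) the product is 2048
    configurations; with the 15 stated levels it is 1920.  Both presets are
    provided because the two counts are inconsistent in the source
    description; see docs/methods.md.
    """
    from .models import METHODS

    if n_keyword_levels == 16:
        levels = KEYWORD_LEVELS_16
    elif n_keyword_levels == 15:
        levels = KEYWORD_LEVELS_15
    else:
        raise ValidationError("n_keyword_levels must be 15 or 16")
    return Grid(methods=tuple(METHODS), keyword_levels=levels)


def reduced_grid() -> Grid:
    """Desk-scale default: 2 methods x 3 keyword levels x 2 x 2 x 2 = 48 configs."""
    return Grid(
        methods=("OLS", "EXTREMELY_RANDOM_FOREST"),
        keyword_levels=(5, 10, 20),
        years_modes=YEARS_MODES,
        lag_options=(False, True),
        spatial_modes=(SpatialMode.NONE, SpatialMode.NEIGHBOR),
    )


def enumerate_configs(grid: Grid) -> list[ModelConfig]:
    """Full Cartesian product in deterministic order.

    Order: methods, then keyword levels, then years modes, then lag
    options, then spatial modes (last varies fastest).
    """
    return [
        ModelConfig(m, k, ym, lag, sp)
        for m, k, ym, lag, sp in itertools.product(
            grid.methods, grid.keyword_levels, grid.years_modes, grid.lag_options, grid.spatial_modes
        )
    ]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mae_percent(predicted, observed) -> float:
    """Median absolute error percentage.

    median over units of |predicted - observed| / observed x 100.  Units
    with observed == 0 are excluded (logged); if all are excluded the
    metric is undefined.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1 or predicted.size == 0:
        raise ValidationError("predicted and observed must be equal-length non-empty vectors")
    keep = observed != 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("mae_percent excluded %d units with observed == 0", n_excluded)
    if not keep.any():
        raise MetricError("all units excluded (observed == 0 everywhere)")
    ape = np.abs(predicted[keep] - observed[keep]) / observed[keep] * 100.0
    return float(np.median(ape))


def national_total_error(predicted_counts: Mapping[str, float], observed_counts: Mapping[str, float]) -> float:
    """Relative error of the summed (national) death count, in percent."""
    if set(predicted_counts) != set(observed_counts):
        raise ValidationError("predicted and observed cover different region sets")
    tot_pred = float(sum(predicted_counts.values()))
    tot_obs = float(sum(observed_counts.values()))
    if tot_obs == 0:
        raise MetricError("observed total is 0; relative error undefined")
    return abs(tot_pred - tot_obs) / tot_obs * 100.0


# ---------------------------------------------------------------------------
# Walk-forward harness
# ---------------------------------------------------------------------------

class InfeasibleTargetError(ValidationError):
    """No period strictly before the target has data to train on."""


def _training_periods(available: Sequence[Period], target: Period, years_mode: str) -> list[Period]:
    prior = sorted(p for p in available if p < target)
    if not prior:
        raise InfeasibleTargetError(f"no data before {target}")
    return prior if years_mode == "ALL_AVAILABLE" else [prior[-1]]


def _guard(training_periods: Iterable[Period], target: Period) -> None:
    bad = [p for p in training_periods if not p < target]
    if bad:
        raise LeakageError(
            f"training period(s) {[str(p) for p in bad]} not strictly before target {target}"
        )


def rank_keywords(
    search: SearchPanel,
    mortality: MortalityPanel,
    training_periods: Sequence[Period],
    endpoint_tolerance: float = DEFAULT_ENDPOINT_TOLERANCE,
):
    """MultiSURF-rank all keywords on training data only (keyword columns vs rate)."""
    X, y = build_design(
        search, mortality, search.keywords, use_lag=False,
        spatial_mode=SpatialMode.NONE, periods=training_periods,
    )
    return multisurf_scores(X, y, endpoint_tolerance=endpoint_tolerance)


def nowcast(
    search: SearchPanel,
    mortality: MortalityPanel,
    config: ModelConfig,
    target: Period,
    adjacency: AdjacencyMap | None = None,
    populations: Mapping[str, float] | None = None,
    *,
    seed: int = 0,
    endpoint_tolerance: float = DEFAULT_ENDPOINT_TOLERANCE,
    hyperparameters: Mapping | None = None,
    training_periods: Sequence[Period] | None = None,
    ranking: Sequence[str] | None = None,
) -> pd.Series:
    """Predict the target period's rates using only strictly earlier responses.

    Ranks keywords by MultiSURF on the training rows, builds the training
    design per ``config``, fits, and predicts every region with target-period
    search data (the nowcasting contract: target-period searches are inputs,
    target-period mortality never is).  Raises :class:`LeakageError` if any
    training period is not strictly before the target.
    """
    available = sorted(set(search.periods) & set(mortality.periods))
    if training_periods is None:
        training_periods = _training_periods(available, target, config.years_mode)
    _guard(training_periods, target)

    if ranking is None:
        ranking = rank_keywords(search, mortality, training_periods, endpoint_tolerance).ranking
    keywords = list(ranking[: config.n_keywords])
    if len(keywords) < config.n_keywords:
        raise ValidationError(
            f"config requests {config.n_keywords} keywords but only {len(keywords)} available"
        )

    regions = search.regions
    if populations is None:
        populations = mortality.populations(max(training_periods)).to_dict()

    X_train, y_train = build_design(
        search, mortality, keywords, use_lag=config.use_lag,
        spatial_mode=config.spatial_mode, periods=training_periods,
        adjacency=adjacency, populations=populations, region_list=regions,
    )
    if len(X_train) < 2:
        # e.g. a lag model whose training rows all predate any observed rate
        raise InfeasibleTargetError(
            f"fewer than 2 usable training rows for {config.method} at target {target}"
        )
    _guard(X_train.index.get_level_values("period"), target)

    spec = RegressorSpec(config.method, seed=seed, hyperparameters=tuple(sorted((hyperparameters or {}).items())))
    model = fit(spec, X_train, y_train)

    X_pred, _ = build_design(
        search, mortality if config.use_lag else None, keywords, use_lag=config.use_lag,
        spatial_mode=config.spatial_mode, periods=[target],
        adjacency=adjacency, populations=populations, region_list=regions,
        with_response=False,
    )
    pred = model.predict(X_pred)
    pred.index = X_pred.index.get_level_values("region_id")
    return pred


def walk_forward_evaluate(
    search: SearchPanel,
    mortality: MortalityPanel,
    config: ModelConfig,
    target: Period,
    adjacency: AdjacencyMap | None = None,
    populations: Mapping[str, float] | None = None,
    **kwargs,
) -> float:
    """MAE% of ``config`` nowcasting ``target`` after training strictly earlier.

    Accepts the same keyword arguments as :func:`nowcast` (seed, tolerance,
    hyperparameters, explicit training_periods, precomputed ranking).
    """
    pred = nowcast(search, mortality, config, target, adjacency, populations, **kwargs)
    observed = mortality.rates(target).reindex(pred.index)
    ok = observed.notna()
    return mae_percent(pred[ok].to_numpy(), observed[ok].to_numpy())


@dataclass
class EvaluationReport:
    """Per-(config, target) MAE% cells plus per-config means and the winner."""

    cells: dict[tuple[ModelConfig, Period], float]
    best: ModelConfig | None = None
    grid: Grid | None = None

    @property
    def aggregates(self) -> dict[ModelConfig, float]:
        sums: dict[ModelConfig, list[float]] = {}
        for (cfg, _), v in self.cells.items():
            sums.setdefault(cfg, []).append(v)
        return {cfg: float(np.mean(vs)) for cfg, vs in sums.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**cfg.as_dict(), "target_period": str(p), "mae_percent": v}
            for (cfg, p), v in self.cells.items()
        ]
        return pd.DataFrame(rows)


def evaluate_grid(
    search: SearchPanel,
    mortality: MortalityPanel,
    configs: Sequence[ModelConfig],
    targets: Sequence[Period] | None = None,
    adjacency: AdjacencyMap | None = None,
    populations: Mapping[str, float] | None = None,
    *,
    seed: int = 0,
    endpoint_tolerance: float = DEFAULT_ENDPOINT_TOLERANCE,
    hyperparameters: Mapping | None = None,
    holdout: Period | None = None,
    grid: Grid | None = None,
) -> EvaluationReport:
    """Evaluate every (config, target) cell, reusing keyword rankings.

    ``targets`` defaults to every feasible period except the held-out last
    one (which must never enter selection).  MultiSURF rankings depend only
    on the training periods, so they are computed once per distinct
    training set and shared across configs.  ``hyperparameters`` maps a
    method name to overrides for that estimator, e.g.
    ``{"EXTREMELY_RANDOM_FOREST": {"n_estimators": 300}}``.
    """
    available = sorted(set(search.periods) & set(mortality.periods))
    if holdout is None:
        holdout = available[-1]
    if targets is None:
        targets = [p for p in available[1:] if p < holdout]
    if any(not t < holdout for t in targets):
        raise LeakageError(f"target list includes the held-out period {holdout}")

    ranking_cache: dict[tuple[Period, ...], list[str]] = {}
    cells: dict[tuple[ModelConfig, Period], float] = {}
    for target in targets:
        for config in configs:
            try:
                tp = tuple(_training_periods(available, target, config.years_mode))
            except InfeasibleTargetError as exc:
                logger.info("skipping %s for %s: %s", target, config, exc)
                continue
            if tp not in ranking_cache:
                ranking_cache[tp] = rank_keywords(
                    search, mortality, list(tp), endpoint_tolerance
                ).ranking
            try:
                cells[(config, target)] = walk_forward_evaluate(
                    search, mortality, config, target, adjacency, populations,
                    seed=seed, endpoint_tolerance=endpoint_tolerance,
                    hyperparameters=(hyperparameters or {}).get(config.method),
                    training_periods=list(tp), ranking=ranking_cache[tp],
                )
            except InfeasibleTargetError as exc:
                logger.info("skipping infeasible cell (%s, %s): %s", config, target, exc)
    report = EvaluationReport(cells=cells, grid=grid)
    report.best = select_best(report)
    return report


def select_best(report: EvaluationReport, strategy: str = "MARGINAL") -> ModelConfig:
    """Choose the final configuration from an evaluation report.

    MARGINAL (default): for each parameter independently, pick the level
    with the lowest mean MAE% over all configs sharing it, then assemble
    the config from the winning levels.  JOINT: the single config with the
    lowest aggregate MAE%.  Ties break by the level's position in the
    grid's declared order (MARGINAL) or by config enumeration order (JOINT).
    """
    if not report.cells:
        raise ValidationError("empty evaluation report")
    agg = report.aggregates
    configs = list(agg)
    if strategy == "JOINT":
        return min(configs, key=lambda c: (agg[c], configs.index(c)))
    if strategy != "MARGINAL":
        raise ValidationError("strategy must be MARGINAL or JOINT")

    def marginal_best(param: str, levels: Sequence) -> object:
        means = []
        for level in levels:
            vals = [agg[c] for c in configs if getattr(c, param) == level]
            if vals:
                means.append((float(np.mean(vals)), levels.index(level), level))
        if not means:
            raise ValidationError(f"no evaluated configs for parameter {param}")
        return min(means)[2]

    if report.grid is not None:
        g = report.grid
        level_sets = {
            "method": list(g.methods),
            "n_keywords": list(g.keyword_levels),
            "years_mode": list(g.years_modes),
            "use_lag": list(g.lag_options),
            "spatial_mode": list(g.spatial_modes),
        }
    else:
        level_sets = {
            p: sorted({getattr(c, p) for c in configs}, key=str)
            for p in ("method", "n_keywords", "years_mode", "use_lag", "spatial_mode")
        }
    chosen = {p: marginal_best(p, levels) for p, levels in level_sets.items()}
    return ModelConfig(**chosen)
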