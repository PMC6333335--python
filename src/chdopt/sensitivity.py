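"""Probabilistic, one-way, and two-way sensitivity analyses.

Every analysis re-optimizes the testing and treatment strategies under the
perturbed parameters before comparing them — the segmentation of patients
is not frozen at its base-case solution.  The probabilistic sensitivity
analysis (PSA) samples the uncertain parameters independently from the
distributions below, re-solves the optimized strategies (i-vi) at each
draw, evaluates all ten strategies, and records which attains the highest
population expected net monetary benefit; repeated over a grid of
willingness-to-pay (WTP) thresholds this yields the optimality-probability
analogue of a cost-effectiveness acceptability curve.

Distribution conventions: Gamma is shape-scale (mean = k * theta); Beta
draws are applied with the sign of the base-case parameter (the event
disutility is drawn as ``-Beta(52, 304)``); the statin risk reduction is
drawn as a Beta magnitude and applied as a relative risk reduction.  The
parameterizations make each draw's mean coincide with its base-case value,
with 95 % intervals of roughly +-15 % for event costs, +-25 % for the
event disutility, fatality probability, and risk reduction, and +-50 % for
the genetic-test cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import EconomicParameters
from .risk_update import LikelihoodTable
from .strategies import STRATEGIES, RiskDistribution, evaluate_strategies

__all__ = [
    "PSAConfig",
    "PSAResult",
    "default_psa_distributions",
    "one_way_sensitivity",
    "run_psa",
    "sample_psa_parameters",
    "two_way_sensitivity",
]


def default_psa_distributions() -> dict[str, dict]:
    """The base-case PSA distribution set (unlisted parameters stay fixed)."""
    return {
        "disutility_event": {"dist": "beta", "args": (52.0, 304.0), "scale": -1.0},
        "p_death_given_event": {"dist": "beta", "args": (48.0, 173.0), "scale": 1.0},
        "statin_relative_risk_reduction": {"dist": "beta", "args": (45.0, 121.0), "scale": 1.0},
        "cost_grs": {"dist": "uniform", "args": (100.0, 300.0)},
        "cost_nonfatal_event": {"dist": "gamma", "args": (171.0, 116.0)},
        "cost_fatal_event": {"dist": "gamma", "args": (171.0, 14.0)},
    }


def point_mass_distributions(params: EconomicParameters) -> dict[str, dict]:
    """Degenerate PSA spec: every varied parameter fixed at its base value."""
    return {
        name: {"dist": "point", "value": getattr(params, name)}
        for name in default_psa_distributions()
    }


@dataclass(frozen=True)
class PSAConfig:
    """Monte-Carlo design of the probabilistic sensitivity analysis."""

    n_trials: int = 1000
    wtp_grid: tuple[float, ...] = tuple(float(w) for w in range(0, 100_001, 2_000))
    distributions: Mapping[str, dict] = field(default_factory=default_psa_distributions)
    seed: int = 0
    #: strategy whose incremental (QALY, cost) scatter vs the reference is kept
    scatter_strategy: str = "v"
    scatter_reference: str = "i"
    scatter_wtp: float = 50_000.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if list(self.wtp_grid) != sorted(self.wtp_grid):
            raise ValueError("wtp_grid must be ordered")


@dataclass(frozen=True)
class PSAResult:
    """PSA outputs: optimality shares per WTP, per-trial table, scatter pairs."""

    shares: pd.DataFrame  # wtp, strategy, share
    trials: pd.DataFrame  # wtp, trial, strategy, nmb, cost, qaly, winner flag
    scatter: pd.DataFrame  # trial, delta_qaly, delta_cost (at scatter_wtp)


def _draw(spec: dict, rng: np.random.Generator) -> float:
    kind = spec["dist"]
    if kind == "point":
        return float(spec["value"])
    if kind == "beta":
        a, b = spec["args"]
        return float(spec.get("scale", 1.0) * rng.beta(a, b))
    if kind == "uniform":
        lo, hi = spec["args"]
        return float(rng.uniform(lo, hi))
    if kind == "gamma":
        shape, scale = spec["args"]
        return float(rng.gamma(shape, scale))
    raise ValueError(f"unknown distribution kind {kind!r}")


def sample_psa_parameters(
    base: EconomicParameters,
    distributions: Mapping[str, dict],
    rng: np.random.Generator,
) -> EconomicParameters:
    """One joint parameter draw; unvaried fields stay at their base values.

    Parameters are sampled independently, in the sorted order of their
    names so the draw sequence is well defined for a given generator state.
    """
    updates = {}
    for name in sorted(distributions):
        if name not in {f.name for f in dataclasses.fields(base)}:
            raise ValueError(f"unknown economic parameter {name!r}")
        updates[name] = _draw(distributions[name], rng)
    return base.with_updates(**updates)


def _trial_rng(seed: int, wtp_index: int, trial: int) -> np.random.Generator:
    # one independent stream per (WTP, trial) so single trials re-run in isolation
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(wtp_index, trial)))


def run_psa(
    config: PSAConfig,
    base_params: EconomicParameters,
    lik_trs: LikelihoodTable,
    lik_grs: LikelihoodTable,
    dist: RiskDistribution,
    strategy_ids: Sequence[str] | None = None,
) -> PSAResult:
    """Run the Monte-Carlo sensitivity analysis over the WTP grid.

    For each (WTP, trial): sample parameters, re-derive end-state values,
    re-solve the optimized strategies and evaluate all strategies, and
    record which attains the maximum expected NMB (ties favor the earlier
    strategy in canonical order).  Shares are exact ratios of integer
    counts over ``n_trials``.
    """
    ids = list(STRATEGIES) if strategy_ids is None else list(strategy_ids)
    trial_rows = []
    scatter_rows = []
    for wi, wtp in enumerate(config.wtp_grid):
        for trial in range(config.n_trials):
            rng = _trial_rng(config.seed, wi, trial)
            params = sample_psa_parameters(base_params, config.distributions, rng)
            params = params.with_updates(wtp=float(wtp))
            evals = {e.strategy_id: e for e in evaluate_strategies(params, lik_trs, lik_grs, dist, ids)}
            nmbs = np.array([evals[s].nmb for s in ids])
            winner = ids[int(np.argmax(nmbs))]
            for sid in ids:
                e = evals[sid]
                trial_rows.append(
                    {
                        "wtp": float(wtp),
                        "trial": trial,
                        "strategy": sid,
                        "nmb": e.nmb,
                        "cost": e.cost,
                        "qaly": e.qaly,
                        "is_optimal": sid == winner,
                    }
                )
            if (
                float(wtp) == float(config.scatter_wtp)
                and config.scatter_strategy in evals
                and config.scatter_reference in evals
            ):
                chosen = evals[config.scatter_strategy]
                ref = evals[config.scatter_reference]
                scatter_rows.append(
                    {
                        "trial": trial,
                        "delta_qaly": chosen.qaly - ref.qaly,
                        "delta_cost": chosen.cost - ref.cost,
                    }
                )
    trials = pd.DataFrame(trial_rows)
    shares = (
        trials.groupby(["wtp", "strategy"], sort=True)["is_optimal"]
        .mean()
        .rename("share")
        .reset_index()
    )
    return PSAResult(shares=shares, trials=trials, scatter=pd.DataFrame(scatter_rows))


def one_way_sensitivity(
    param: str,
    values: Sequence[float],
    base_params: EconomicParameters,
    lik_trs: LikelihoodTable,
    lik_grs: LikelihoodTable,
    dist: RiskDistribution,
    strategy: str = "v",
) -> pd.DataFrame:
    """Change in a strategy's population NMB as one parameter varies.

    The strategy is re-optimized at each parameter value; the table reports
    the NMB difference from the base case (exactly 0 at the base value).
    """
    if param not in {f.name for f in dataclasses.fields(base_params)}:
        raise ValueError(f"unknown economic parameter {param!r}")
    base_nmb = evaluate_strategies(base_params, lik_trs, lik_grs, dist, [strategy])[0].nmb
    rows = []
    for value in values:
        params = base_params.with_updates(**{param: float(value)})
        nmb = evaluate_strategies(params, lik_trs, lik_grs, dist, [strategy])[0].nmb
        rows.append({"param": param, "value": float(value), "nmb": nmb, "delta_nmb": nmb - base_nmb})
    return pd.DataFrame(rows)


def two_way_sensitivity(
    wtp_values: Sequence[float],
    grs_cost_values: Sequence[float],
    base_params: EconomicParameters,
    lik_trs: LikelihoodTable,
    lik_grs: LikelihoodTable,
    dist: RiskDistribution,
    strategy: str = "v",
) -> pd.DataFrame:
    """Where on the (WTP, genetic-test cost) plane the strategy is optimal.

    Returns a long-format grid with a boolean ``optimal`` column — whether
    the strategy attains the maximum expected NMB among all ten strategies
    at that parameter combination (weak optimality, so ties count) — and a
    ``grs_used`` column flagging whether the genetic test is actually part
    of the strategy's optimal segmentation there.  When the genetic test is
    too expensive to use, the two-test strategy collapses onto the
    TRS-only strategy and still ties for the top NMB, so the informative
    region is ``optimal & grs_used``.
    """
    if not len(wtp_values) or not len(grs_cost_values):
        raise ValueError("wtp_values and grs_cost_values must be non-empty")
    rows = []
    for wtp in wtp_values:
        for grs_cost in grs_cost_values:
            params = base_params.with_updates(wtp=float(wtp), cost_grs=float(grs_cost))
            evals = evaluate_strategies(params, lik_trs, lik_grs, dist)
            best = max(e.nmb for e in evals)
            target = next(e for e in evals if e.strategy_id == strategy)
            rows.append(
                {
                    "wtp": float(wtp),
                    "grs_cost": float(grs_cost),
                    "nmb": target.nmb,
                    "optimal": bool(target.nmb >= best - 1e-6),
                    "grs_used": bool(target.share_tested_grs > 0),
                }
            )
    return pd.DataFrame(rows)
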