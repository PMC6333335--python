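"""Backward-induction solution of testing-and-treatment strategies.

Ten population strategies are compared for targeting statin therapy:

    i     No treatment            no tests, treat nobody
    ii    Treatment optimized     no tests, treat by prior risk
    iii   TRS optimized           TRS for an optimal segment, then treat/not
    iv    GRS optimized           GRS for an optimal segment, then treat/not
    v     TRS & GRS optimized     TRS for an optimal segment, optionally GRS
    vi    GRS & TRS optimized     GRS for an optimal segment, optionally TRS
    vii   TRS for all             (reference, non-optimized)
    viii  GRS for all             (reference, non-optimized)
    ix    TRS for all & GRS for updated risk 10-20%   (reference)
    x     TRS & GRS for all       (reference)

Strategies i and ii are embedded as options in iii-vi.  Each strategy is
solved by dynamic programming: the terminal treat/no-treat decision is
valued first for any belief, and test stages are folded back by taking
expectations over the predictive result distribution.  Beliefs are updated
exactly (no grid rounding inside the recursion); the integer 0-100 % prior
grid is used for reporting segments and for population averaging.

Ties between actions are broken in favor of fewer tests, then in favor of
not treating, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .economics import EconomicParameters, EndStateValues
from .risk_update import LikelihoodTable, marginal_result_prob, posterior_update

__all__ = [
    "STRATEGIES",
    "PolicySolution",
    "RiskDistribution",
    "Strategy",
    "StrategyEvaluation",
    "StrategyModel",
    "default_risk_grid",
    "evaluate_strategy",
    "rank_strategies",
    "solve_strategy",
]

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class Strategy:
    """One of the ten testing-and-treatment strategies."""

    id: str
    name: str
    tests: tuple[str, ...] = ()
    optimized: bool = True
    #: for strategy ix: forced second-test interval of updated risk (inclusive)
    fixed_interval: tuple[float, float] | None = None


STRATEGIES: dict[str, Strategy] = {
    "i": Strategy("i", "No treatment", (), True),
    "ii": Strategy("ii", "Treatment optimized", (), True),
    "iii": Strategy("iii", "TRS optimized", ("trs",), True),
    "iv": Strategy("iv", "GRS optimized", ("grs",), True),
    "v": Strategy("v", "TRS & GRS optimized", ("trs", "grs"), True),
    "vi": Strategy("vi", "GRS & TRS optimized", ("grs", "trs"), True),
    "vii": Strategy("vii", "TRS for all", ("trs",), False),
    "viii": Strategy("viii", "GRS for all", ("grs",), False),
    "ix": Strategy(
        "ix",
        "TRS for all & GRS for 10-20%",
        ("trs", "grs"),
        False,
        fixed_interval=(0.10, 0.20),
    ),
    "x": Strategy("x", "TRS & GRS for all", ("trs", "grs"), False),
}


@dataclass(frozen=True)
class _Value:
    """Componentwise expected value at a set of beliefs.

    ``cost`` is the expected spend as a positive magnitude; ``nmb`` equals
    ``qaly * wtp - cost`` everywhere by construction.  ``p_trs``/``p_grs``/
    ``p_treat`` are the probabilities, along the realized decision paths,
    that a patient gets each test / ends up treated.
    """

    nmb: np.ndarray
    cost: np.ndarray
    qaly: np.ndarray
    p_trs: np.ndarray
    p_grs: np.ndarray
    p_treat: np.ndarray

    def where(self, mask: np.ndarray, other: "_Value") -> "_Value":
        return _Value(
            *(np.where(mask, a, b) for a, b in zip(self._tuple(), other._tuple()))
        )

    def _tuple(self):
        return (self.nmb, self.cost, self.qaly, self.p_trs, self.p_grs, self.p_treat)


@dataclass(frozen=True)
class RiskDistribution:
    """Weights over the prior-risk grid 0 %, 1 %, ..., 100 %."""

    risks: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        risks = np.asarray(self.risks, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "risks", risks)
        object.__setattr__(self, "weights", weights)
        if risks.shape != weights.shape:
            raise ValueError("risks and weights must have equal shape")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1 (+-1e-6)")

    @property
    def mean_risk(self) -> float:
        return float(self.risks @ self.weights)


@dataclass(frozen=True)
class PolicySolution:
    """Optimal actions and expected values of one strategy on the prior grid."""

    strategy_id: str
    grid: pd.DataFrame  # prior, action, nmb, cost, qaly, p_trs, p_grs, p_treat

    def segments(self) -> pd.DataFrame:
        """Contiguous prior-risk intervals sharing the same first action."""
        g = self.grid
        rows = []
        start = 0
        actions = g["action"].to_numpy()
        priors = g["prior"].to_numpy()
        for k in range(1, len(g) + 1):
            if k == len(g) or actions[k] != actions[start]:
                rows.append(
                    {
                        "strategy": self.strategy_id,
                        "action": actions[start],
                        "risk_lo": priors[start],
                        "risk_hi": priors[k - 1],
                    }
                )
                start = k
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StrategyEvaluation:
    """Population-weighted expected outcomes of one strategy."""

    strategy_id: str
    name: str
    nmb: float
    cost: float
    qaly: float
    share_tested_trs: float
    share_tested_grs: float
    share_treated: float


def default_risk_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 101)


class StrategyModel:
    """Shared machinery for valuing strategies over arrays of beliefs."""

    def __init__(
        self,
        endstates: EndStateValues,
        lik_trs: LikelihoodTable | None,
        lik_grs: LikelihoodTable | None,
        params: EconomicParameters,
    ) -> None:
        self.endstates = endstates
        self.params = params
        self.likelihoods = {"trs": lik_trs, "grs": lik_grs}
        self.test_costs = {"trs": params.cost_trs, "grs": params.cost_grs}
        es = endstates
        # positive cost magnitudes for internal accounting
        self._states = {
            "I": (-es.no_chd_untreated.cost, es.no_chd_untreated.qaly, es.no_chd_untreated.nmb),
            "II": (-es.no_chd_treated.cost, es.no_chd_treated.qaly, es.no_chd_treated.nmb),
            "III": (-es.chd_untreated.cost, es.chd_untreated.qaly, es.chd_untreated.nmb),
            "IV": (-es.chd_treated.cost, es.chd_treated.qaly, es.chd_treated.nmb),
        }

    # -- terminal stage ---------------------------------------------------

    def _terminal(self, p: np.ndarray, treat: bool) -> _Value:
        if treat:
            (c1, q1, n1), (c0, q0, n0) = self._states["IV"], self._states["II"]
        else:
            (c1, q1, n1), (c0, q0, n0) = self._states["III"], self._states["I"]
        zeros = np.zeros_like(p)
        return _Value(
            nmb=p * n1 + (1 - p) * n0,
            cost=p * c1 + (1 - p) * c0,
            qaly=p * q1 + (1 - p) * q0,
            p_trs=zeros,
            p_grs=zeros,
            p_treat=np.full_like(p, 1.0 if treat else 0.0),
        )

    def treat_decision(self, p: np.ndarray) -> _Value:
        """NMB-optimal treat/no-treat decision at beliefs ``p``."""
        value, _ = self._choose(p, [("no_treat", None), ("treat", None)])
        return value

    # -- test stage -------------------------------------------------------

    def test_value(
        self, p: np.ndarray, test: str, continuation: Callable[[np.ndarray], _Value]
    ) -> _Value:
        """Expected value of performing ``test`` at beliefs ``p``.

        The continuation is evaluated at the exact posterior for every
        result bin and folded back through the predictive result
        distribution; the test cost is charged up front.
        """
        lik = self.likelihoods[test]
        if lik is None:
            raise ValueError(f"strategy requires a likelihood table for {test!r}")
        cost = self.test_costs[test]
        marg = marginal_result_prob(p, lik)  # (..., B)
        posts = np.stack(
            [np.asarray(posterior_update(p, b, lik)) for b in range(lik.n_bins)],
            axis=-1,
        )  # (..., B)
        cont = continuation(posts.reshape(-1))
        shape = posts.shape

        def _fold(component: np.ndarray) -> np.ndarray:
            return np.sum(marg * component.reshape(shape), axis=-1)

        value = _Value(
            nmb=_fold(cont.nmb) - cost,
            cost=_fold(cont.cost) + cost,
            qaly=_fold(cont.qaly),
            p_trs=_fold(cont.p_trs),
            p_grs=_fold(cont.p_grs),
            p_treat=_fold(cont.p_treat),
        )
        if test == "trs":
            return _Value(value.nmb, value.cost, value.qaly, np.ones_like(p), value.p_grs, value.p_treat)
        return _Value(value.nmb, value.cost, value.qaly, value.p_trs, np.ones_like(p), value.p_treat)

    # -- decision nodes ---------------------------------------------------

    def _candidate(self, p, kind, continuation) -> _Value:
        if kind == "no_treat":
            return self._terminal(p, treat=False)
        if kind == "treat":
            return self._terminal(p, treat=True)
        return self.test_value(p, kind, continuation)

    def _choose(
        self, p: np.ndarray, options: Sequence[tuple[str, Callable | None]]
    ) -> tuple[_Value, np.ndarray]:
        """Componentwise argmax over candidate actions.

        ``options`` are listed in tie-break preference order; a later
        option replaces the incumbent only when strictly better (beyond a
        1e-9 tolerance).
        """
        labels = [kind for kind, _ in options]
        best = self._candidate(p, *options[0])
        choice = np.zeros(np.shape(p), dtype=int)
        for k, (kind, cont) in enumerate(options[1:], start=1):
            cand = self._candidate(p, kind, cont)
            better = cand.nmb > best.nmb + _TIE_EPS
            best = cand.where(better, best)
            choice = np.where(better, k, choice)
        return best, np.asarray(labels, dtype=object)[choice]

    # -- strategy value functions -----------------------------------------

    def value(self, strategy_id: str, p: np.ndarray) -> tuple[_Value, np.ndarray]:
        """Value and optimal first action of a strategy at beliefs ``p``."""
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("prior risks must be in [0, 1]")
        base = [("no_treat", None), ("treat", None)]
        td = self.treat_decision

        if strategy_id == "i":
            return self._terminal(p, treat=False), np.full(p.shape, "no_treat", dtype=object)
        if strategy_id == "ii":
            return self._choose(p, base)
        if strategy_id == "iii":
            return self._choose(p, base + [("trs", td)])
        if strategy_id == "iv":
            return self._choose(p, base + [("grs", td)])
        if strategy_id == "v":
            second = lambda q: self._choose(q, base + [("grs", td)])[0]
            return self._choose(p, base + [("trs", second)])
        if strategy_id == "vi":
            second = lambda q: self._choose(q, base + [("trs", td)])[0]
            return self._choose(p, base + [("grs", second)])
        if strategy_id == "vii":
            return self.test_value(p, "trs", td), np.full(p.shape, "trs", dtype=object)
        if strategy_id == "viii":
            return self.test_value(p, "grs", td), np.full(p.shape, "grs", dtype=object)
        if strategy_id == "ix":
            lo, hi = STRATEGIES["ix"].fixed_interval
            def second(q: np.ndarray) -> _Value:
                in_seg = (q >= lo - 1e-12) & (q <= hi + 1e-12)
                return self.test_value(q, "grs", td).where(in_seg, td(q))
            return self.test_value(p, "trs", second), np.full(p.shape, "trs", dtype=object)
        if strategy_id == "x":
            second = lambda q: self.test_value(q, "grs", td)
            return self.test_value(p, "trs", second), np.full(p.shape, "trs", dtype=object)
        raise KeyError(f"unknown strategy id {strategy_id!r}")


def treat_stage_value(
    p: float, endstates: EndStateValues, params: EconomicParameters | None = None
) -> tuple[str, float, float, float]:
    """Terminal treat/no-treat decision at belief ``p``.

    Returns ``(action, nmb, cost, qaly)`` of the NMB-maximizing action,
    with cost as a positive magnitude.  Ties favor no treatment.
    """
    model = StrategyModel(endstates, None, None, params or EconomicParameters(wtp=endstates.wtp))
    arr = np.asarray([p], dtype=float)
    value, action = model._choose(arr, [("no_treat", None), ("treat", None)])
    return str(action[0]), float(value.nmb[0]), float(value.cost[0]), float(value.qaly[0])


def solve_strategy(
    strategy: Strategy | str,
    endstates: EndStateValues,
    lik_trs: LikelihoodTable | None,
    lik_grs: LikelihoodTable | None,
    params: EconomicParameters,
    grid: np.ndarray | None = None,
) -> PolicySolution:
    """Solve one strategy by backward induction over the prior-risk grid."""
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    model = StrategyModel(endstates, lik_trs, lik_grs, params)
    p = default_risk_grid() if grid is None else np.asarray(grid, dtype=float)
    value, action = model.value(strategy.id, p)
    df = pd.DataFrame(
        {
            "prior": p,
            "action": action,
            "nmb": value.nmb,
            "cost": value.cost,
            "qaly": value.qaly,
            "p_trs": value.p_trs,
            "p_grs": value.p_grs,
            "p_treat": value.p_treat,
        }
    )
    return PolicySolution(strategy_id=strategy.id, grid=df)


def evaluate_strategy(policy: PolicySolution, dist: RiskDistribution) -> StrategyEvaluation:
    """Population-weighted expected NMB, cost, QALY, and testing/treated shares."""
    g = policy.grid
    if len(g) != len(dist.weights):
        raise ValueError("risk distribution does not match the policy grid")
    w = dist.weights
    return StrategyEvaluation(
        strategy_id=policy.strategy_id,
        name=STRATEGIES[policy.strategy_id].name,
        nmb=float(w @ g["nmb"].to_numpy()),
        cost=float(w @ g["cost"].to_numpy()),
        qaly=float(w @ g["qaly"].to_numpy()),
        share_tested_trs=float(w @ g["p_trs"].to_numpy()),
        share_tested_grs=float(w @ g["p_grs"].to_numpy()),
        share_treated=float(w @ g["p_treat"].to_numpy()),
    )


def evaluate_strategies(
    params: EconomicParameters,
    lik_trs: LikelihoodTable | None,
    lik_grs: LikelihoodTable | None,
    dist: RiskDistribution,
    ids: Sequence[str] | None = None,
) -> list[StrategyEvaluation]:
    """Value end states, solve each strategy, and average over the population.

    Convenience wrapper used by the base-case pipeline and every
    sensitivity analysis; ``ids`` defaults to all ten strategies.
    """
    from .economics import endstate_values

    endstates = endstate_values(params)
    ids = list(STRATEGIES) if ids is None else list(ids)
    out = []
    for sid in ids:
        policy = solve_strategy(sid, endstates, lik_trs, lik_grs, params, grid=dist.risks)
        out.append(evaluate_strategy(policy, dist))
    return out


def rank_strategies(evals: Sequence[StrategyEvaluation]) -> pd.DataFrame:
    """Strategy comparison table sorted by decreasing expected NMB."""
    if not evals:
        raise ValueError("need at least one strategy evaluation")
    df = pd.DataFrame(
        [
            {
                "strategy": e.strategy_id,
                "name": e.name,
                "nmb": e.nmb,
                "cost": e.cost,
                "qaly": e.qaly,
                "share_tested_trs": e.share_tested_trs,
                "share_tested_grs": e.share_tested_grs,
                "share_treated": e.share_treated,
            }
            for e in evals
        ]
    )
    return df.sort_values("nmb", ascending=False, kind="mergesort").reset_index(drop=True)
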