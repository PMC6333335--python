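"""Synthetic cohorts and population risk distributions.

The likelihood tables and the population prior-risk distribution that drive
the strategy optimization are, in the original setting, estimated from
large national cohort studies that cannot be redistributed.  This module
generates data with the same statistical structure so every stage of the
analysis is runnable and testable:

* a case/control cohort with a ~5.3 % ten-year event rate and two
  continuous risk scores (traditional and genetic) drawn from
  state-conditional bivariate Gaussians — the binormal ROC model, which
  gives closed-form control of each score's discrimination
  (``delta_mu / (sigma * sqrt(2)) = Phi^{-1}(AUC)``) and of the
  within-state correlation between the scores (near zero, matching the
  negligible observed correlation between traditional risk factors and
  polygenic scores);
* a right-skewed prior-risk distribution over the 0-100 % grid from a Beta
  family, standing in for the risk profile of a general population aged
  45+.

Fatality among events is independent of the scores, mirroring the single
probability-of-death parameter of the economic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .strategies import RiskDistribution, default_risk_grid

__all__ = [
    "CohortSpec",
    "build_risk_distribution",
    "cohort_summary",
    "generate_cohort",
]

#: scale of the Finnish source cohorts: 17,457 subjects, 919 events in 10 y
DEFAULT_N_SUBJECTS = 17_457
DEFAULT_EVENT_RATE = 919 / 17_457


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic case/control cohort.

    AUC targets are fixture conventions for a well-discriminating clinical
    score (0.80) and a weaker genetic score (0.65); they are inputs of the
    generator, not estimates from any study.
    """

    n_subjects: int = DEFAULT_N_SUBJECTS
    event_rate: float = DEFAULT_EVENT_RATE
    trs_auc: float = 0.80
    grs_auc: float = 0.65
    within_state_score_correlation: float = 0.0
    p_fatal: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in ("event_rate", "p_fatal"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("trs_auc", "grs_auc"):
            if not 0.5 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0.5, 1)")
        if abs(self.within_state_score_correlation) > 0.09:
            raise ValueError("within-state score correlation must satisfy |rho| <= 0.09")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort with columns id, event, fatal, trs_score, grs_score.

    Event states are Bernoulli(event_rate).  Scores are standardized within
    state; cases are shifted by ``sqrt(2) * Phi^{-1}(AUC)`` per score so the
    marginal AUC of each score hits its target.  Fatality is drawn
    Bernoulli(p_fatal) among events only.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    event = rng.random(n) < spec.event_rate

    rho = spec.within_state_score_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    scores = rng.standard_normal((n, 2)) @ chol.T

    shift = np.array(
        [
            np.sqrt(2.0) * stats.norm.ppf(spec.trs_auc),
            np.sqrt(2.0) * stats.norm.ppf(spec.grs_auc),
        ]
    )
    scores[event] += shift

    fatal = np.zeros(n, dtype=bool)
    fatal[event] = rng.random(int(event.sum())) < spec.p_fatal

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "event": event.astype(int),
            "fatal": fatal.astype(int),
            "trs_score": scores[:, 0],
            "grs_score": scores[:, 1],
        }
    )


def build_risk_distribution(
    family: str = "beta",
    params: tuple[float, ...] = (1.5, 27.0),
    grid: np.ndarray | None = None,
) -> RiskDistribution:
    """Discretize a parametric prior-risk distribution onto the 0-100 % grid.

    The grid has 101 points; weights are CDF differences over 101
    equal-width cells on [0, 1], so ``beta`` with parameters (1, 1) yields
    exactly uniform weights 1/101.  The default Beta(1.5, 27) is right-
    skewed with mean ~5.3 %, emulating a general 45+ population.  A
    ``point`` family puts all mass on the grid point nearest ``params[0]``.
    """
    risks = default_risk_grid() if grid is None else np.asarray(grid, dtype=float)
    k = len(risks)
    if family == "point":
        weights = np.zeros(k)
        weights[int(np.argmin(np.abs(risks - params[0])))] = 1.0
        return RiskDistribution(risks=risks, weights=weights)
    if family == "beta":
        a, b = params
        edges = np.linspace(0.0, 1.0, k + 1)
        weights = np.diff(stats.beta.cdf(edges, a, b))
        total = weights.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("degenerate risk distribution weights")
        return RiskDistribution(risks=risks, weights=weights / total)
    raise ValueError(f"unknown risk distribution family {family!r}")


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Summary statistics: counts, event rate, fatality, score moments by state.

    The fatal fraction is reported as NaN when the cohort has no events.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    event = cohort["event"].astype(bool)
    n_events = int(event.sum())
    out: dict = {
        "n": int(len(cohort)),
        "n_events": n_events,
        "event_rate": n_events / len(cohort),
        "fatal_fraction": (
            float(cohort.loc[event, "fatal"].mean()) if n_events else float("nan")
        ),
    }
    for state, label in ((True, "case"), (False, "control")):
        sub = cohort[event == state]
        for score in ("trs_score", "grs_score"):
            out[f"{score}_mean_{label}"] = float(sub[score].mean()) if len(sub) else float("nan")
            out[f"{score}_sd_{label}"] = float(sub[score].std(ddof=1)) if len(sub) > 1 else float("nan")
        out[f"score_corr_{label}"] = (
            float(sub["trs_score"].corr(sub["grs_score"])) if len(sub) > 2 else float("nan")
        )
    return out
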