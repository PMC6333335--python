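"""Bayesian updating of 10-year CHD risk from binned risk-score results.

A patient's belief about their state of health (CHD event within 10 years,
yes/no) is summarized entirely by the event probability.  A risk score —
traditional (TRS) or genetic (GRS) — is modelled as a test with a finite
result alphabet: the continuous score is discretized into bins, and the
test is characterized by the conditional probabilities of each bin given
the patient's state.  Observing a bin updates the risk by Bayes' rule; the
two scores are treated as conditionally independent given the state, so
sequential updating over both tests is order-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LikelihoodTable",
    "estimate_likelihoods",
    "marginal_result_prob",
    "posterior_update",
]

_TOL = 1e-9


@dataclass(frozen=True)
class LikelihoodTable:
    """Binned result probabilities of one test, conditional on CHD state.

    ``bin_edges`` has length ``n_bins + 1`` (outer edges may be +-inf);
    ``p_result_given_chd`` / ``p_result_given_no_chd`` each sum to 1.
    """

    test_name: str
    bin_edges: np.ndarray
    p_result_given_chd: np.ndarray
    p_result_given_no_chd: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        l1 = np.asarray(self.p_result_given_chd, dtype=float)
        l0 = np.asarray(self.p_result_given_no_chd, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "p_result_given_chd", l1)
        object.__setattr__(self, "p_result_given_no_chd", l0)
        if len(edges) != len(l1) + 1:
            raise ValueError("bin_edges must have length n_bins + 1")
        if len(l1) != len(l0):
            raise ValueError("conditional distributions must have equal length")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(l1 < 0) or np.any(l0 < 0):
            raise ValueError("probabilities must be non-negative")
        for p in (l1, l0):
            if abs(p.sum() - 1.0) > _TOL:
                raise ValueError("each conditional distribution must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.p_result_given_chd)

    def bin_of(self, score: float | np.ndarray) -> np.ndarray:
        """Map score value(s) to bin indices (clipped to the outer bins)."""
        idx = np.searchsorted(self.bin_edges, score, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "lower_edge": self.bin_edges[:-1],
                "upper_edge": self.bin_edges[1:],
                "p_given_chd": self.p_result_given_chd,
                "p_given_no_chd": self.p_result_given_no_chd,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, test_name: str = "test") -> "LikelihoodTable":
        df = pd.read_csv(path)
        edges = np.concatenate([df["lower_edge"].to_numpy(), [df["upper_edge"].iloc[-1]]])
        return cls(
            test_name=test_name,
            bin_edges=edges,
            p_result_given_chd=df["p_given_chd"].to_numpy(),
            p_result_given_no_chd=df["p_given_no_chd"].to_numpy(),
        )


def posterior_update(
    prior: float | np.ndarray, result_bin: int, lik: LikelihoodTable
) -> float | np.ndarray:
    """Posterior event risk after observing ``result_bin`` of a test.

    Implements Bayes' rule ``p L1 / (p L1 + (1-p) L0)``.  An uninformative
    result (``L1 == L0``) returns the prior unchanged, including the exact
    absorbing cases ``prior in {0, 1}``.  A result with ``L1 == L0 == 0``
    cannot be observed and raises ``ValueError``.
    """
    if not 0 <= result_bin < lik.n_bins:
        raise IndexError(f"result_bin {result_bin} out of range")
    l1 = lik.p_result_given_chd[result_bin]
    l0 = lik.p_result_given_no_chd[result_bin]
    if l1 == 0.0 and l0 == 0.0:
        raise ValueError("impossible result: both conditional probabilities are zero")
    p = np.asarray(prior, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("prior risk must be in [0, 1]")
    if l1 == l0:
        return prior
    denom = p * l1 + (1.0 - p) * l0
    post = np.divide(p * l1, denom, out=np.zeros_like(denom), where=denom > 0)
    # denom == 0 only when prior is an absorbing 0 or 1 against a zero
    # likelihood; the belief then stays absorbing.
    post = np.where(denom > 0, post, p)
    return float(post) if np.isscalar(prior) else post


def marginal_result_prob(prior: float | np.ndarray, lik: LikelihoodTable) -> np.ndarray:
    """Predictive probability of each result bin: ``p L1 + (1-p) L0``.

    For array priors the result has shape ``prior.shape + (n_bins,)``.
    """
    p = np.asarray(prior, dtype=float)
    return (
        p[..., None] * lik.p_result_given_chd
        + (1.0 - p[..., None]) * lik.p_result_given_no_chd
    )


def estimate_likelihoods(
    cohort: pd.DataFrame, test: str, n_bins: int = 10
) -> LikelihoodTable:
    """Estimate a binned likelihood table for one score from cohort data.

    ``cohort`` needs an ``event`` column (0/1) and a ``<test>_score`` column.
    Scores are binned at pooled (cases + controls) quantile edges; the two
    conditional distributions are bin frequencies with add-one (Laplace)
    smoothing, renormalized.  The outer edges are open (+-inf) so any score
    maps to a bin.  If the scores support fewer than ``n_bins`` distinct
    quantile edges the bin count is reduced with a warning.
    """
    col = f"{test}_score"
    if col not in cohort.columns:
        raise KeyError(f"cohort has no column {col!r}")
    event = cohort["event"].to_numpy().astype(bool)
    if event.all() or not event.any():
        raise ValueError("cohort must contain both cases and controls")
    scores = cohort[col].to_numpy(dtype=float)

    quantiles = np.linspace(0, 1, n_bins + 1)[1:-1]
    inner = np.unique(np.quantile(scores, quantiles))
    if len(inner) < n_bins - 1:
        warnings.warn(
            f"only {len(inner) + 1} distinct bins supported by {col}; reducing from {n_bins}",
            stacklevel=2,
        )
    edges = np.concatenate([[-np.inf], inner, [np.inf]])
    k = len(edges) - 1

    idx = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, k - 1)
    counts_case = np.bincount(idx[event], minlength=k).astype(float)
    counts_ctrl = np.bincount(idx[~event], minlength=k).astype(float)
    l1 = (counts_case + 1.0) / (counts_case.sum() + k)
    l0 = (counts_ctrl + 1.0) / (counts_ctrl.sum() + k)
    return LikelihoodTable(
        test_name=test,
        bin_edges=edges,
        p_result_given_chd=l1,
        p_result_given_no_chd=l0,
    )
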