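"""Three-node causal model selection: genotype, protein, trait.

With the genotype Q fixed as an exogenous root (it cannot be caused by
expression or behaviour), four directed acyclic structures are scored:

    causal       Q -> P -> T        (protein mediates the locus effect)
    reactive     Q -> T -> P        (protein responds to the trait)
    pleiotropic  Q -> P, Q -> T     (independent effects of the locus)
    full         Q -> P, Q -> T, P -> T

Each node given its parents is a Gaussian linear regression; a structure's
score is the summed maximised log-likelihood penalised by BIC
(-2 logL + k ln n).  Q's marginal term is identical across structures and
is omitted.  The minimal-BIC structure wins; the gap to the runner-up is
reported as a confidence diagnostic.

A mediation summary (share of the marginal Q->T effect absorbed by
conditioning on P) accompanies the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TripletData", "CausalFit", "select_model", "mediation_summary", "TripletModel"]

MODELS = ("causal", "reactive", "pleiotropic", "full")

#: parent sets per model for the P and T nodes (Q is always a root)
_STRUCTURE = {
    "causal": {"P": ("Q",), "T": ("P",)},
    "reactive": {"T": ("Q",), "P": ("T",)},
    "pleiotropic": {"P": ("Q",), "T": ("Q",)},
    "full": {"P": ("Q",), "T": ("Q", "P")},
}


@dataclass
class TripletData:
    """Aligned strain-level genotype dose, protein abundance and trait."""

    Q: np.ndarray
    P: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        n = len(self.Q)
        if not (len(self.P) == len(self.T) == n):
            raise ValueError("Q, P, T must have equal length")
        if n < 8:
            raise ValueError("need at least 8 observations")
        if np.ptp(self.Q) == 0:
            raise ValueError("Q is constant; triplet is uninformative")

    @property
    def n(self) -> int:
        return len(self.Q)

    def node(self, name: str) -> np.ndarray:
        return {"Q": self.Q, "P": self.P, "T": self.T}[name]


def _gauss_node_loglik(y: np.ndarray, parents: tuple[np.ndarray, ...]) -> tuple[float, int]:
    """Maximised Gaussian log-likelihood of y ~ intercept + parents.

    Returns (logL, k) with k counting intercept, slopes and the variance.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), *parents]) if parents else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        raise FloatingPointError("degenerate regression: zero residual variance")
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return ll, X.shape[1] + 1


@dataclass
class CausalFit:
    """Scores and winner of the structure search."""

    scores: dict                     # model -> BIC
    logliks: dict                    # model -> summed logL (P and T nodes)
    best: str
    delta: float                     # BIC gap to the runner-up
    n: int
    mediation: float = np.nan

    def summary(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"bic": pd.Series(self.scores), "loglik": pd.Series(self.logliks)}
        ).sort_values("bic")
        frame["best"] = frame.index == self.best
        return frame


def select_model(data: TripletData, models=MODELS) -> CausalFit:
    """Score the candidate structures by BIC and pick the minimum.

    Degenerate nodes (constant P or T) make their regressions ill-posed;
    affected structures are dropped from the candidate set.
    """
    scores: dict = {}
    logliks: dict = {}
    n = data.n
    for model in models:
        try:
            ll_total, k_total = 0.0, 0
            for child, parents in _STRUCTURE[model].items():
                ll, k = _gauss_node_loglik(
                    data.node(child), tuple(data.node(p) for p in parents)
                )
                ll_total += ll
                k_total += k
            scores[model] = -2.0 * ll_total + k_total * np.log(n)
            logliks[model] = ll_total
        except FloatingPointError:
            continue
    if not scores:
        raise ValueError("all candidate structures are degenerate")
    order = sorted(scores, key=scores.get)
    best = order[0]
    delta = scores[order[1]] - scores[best] if len(order) > 1 else np.inf
    fit = CausalFit(scores, logliks, best, float(delta), n)
    try:
        fit.mediation = mediation_summary(data)
    except ValueError:
        pass
    return fit


def mediation_summary(data: TripletData) -> float:
    """Share of the marginal Q->T effect explained by the protein.

    1 - (coefficient of Q on T adjusting for P) / (marginal coefficient of
    Q on T), clipped to [0, 1].  A marginal coefficient indistinguishable
    from zero makes the ratio meaningless and raises.
    """
    n = data.n
    X_marg = np.column_stack([np.ones(n), data.Q])
    b_marg, *_ = np.linalg.lstsq(X_marg, data.T, rcond=None)
    marginal = b_marg[1]
    scale = float(np.std(data.T)) or 1.0
    if abs(marginal) < 1e-10 * scale:
        raise ValueError("marginal Q->T effect is ~0; mediation undefined")
    X_adj = np.column_stack([np.ones(n), data.Q, data.P])
    b_adj, *_ = np.linalg.lstsq(X_adj, data.T, rcond=None)
    return float(np.clip(1.0 - b_adj[1] / marginal, 0.0, 1.0))


class TripletModel:
    """Model-style wrapper: ``TripletModel(Q, P, T).fit() -> CausalFit``."""

    def __init__(self, Q, P, T):
        self.data = TripletData(Q, P, T)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, q: str = "Q", p: str = "P", t: str = "T"):
        return cls(frame[q].to_numpy(), frame[p].to_numpy(), frame[t].to_numpy())

    def fit(self) -> CausalFit:
        return select_model(self.data)
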