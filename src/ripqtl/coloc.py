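"""Approximate-Bayes-factor colocalization of two association signals.

Given per-marker summary statistics (beta, se) for two traits over a shared
window, each marker gets a Wakefield approximate Bayes factor against the
null, and the five mutually exclusive hypotheses are scored:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  two distinct causal variants, one per trait
    H4  one shared causal variant

Posteriors are computed in log space; a posterior probability of the shared
hypothesis (PP4) above 0.8 is called a colocalization.  Applies equally to
eQTL-pQTL, trans-pQTL-cis-pQTL and pQTL-phenotype pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats

__all__ = [
    "make_window",
    "abf",
    "coloc_posterior",
    "ColocResult",
    "ColocPair",
    "polarity_concordance",
]


def make_window(center_bp: float, flank_bp: float = 500_000) -> tuple[int, int]:
    """Symmetric window around a locus, clamped at the chromosome start."""
    if center_bp < 0:
        raise ValueError("center must be >= 0")
    return (int(max(0, center_bp - flank_bp)), int(center_bp + flank_bp))


def abf(beta, se, prior_sd: float = 0.15):
    """Log approximate Bayes factor for a single-marker association.

    With z = beta/se, V = se^2 and prior effect variance W = prior_sd^2,

        log ABF = 0.5 * [ log(1 - r) + r z^2 ],   r = W / (V + W).

    Positive values favour a real effect; at beta = 0 the value is negative
    (shrinkage towards the null).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    z = beta / se
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + r * z ** 2)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: np.ndarray                  # pp0..pp4
    n_snps: int
    window: tuple | None = None
    pp4_cut: float = 0.8

    @property
    def pp0(self) -> float: return float(self.pp[0])
    @property
    def pp1(self) -> float: return float(self.pp[1])
    @property
    def pp2(self) -> float: return float(self.pp[2])
    @property
    def pp3(self) -> float: return float(self.pp[3])
    @property
    def pp4(self) -> float: return float(self.pp[4])

    @property
    def call(self) -> bool:
        return self.pp4 > self.pp4_cut

    def summary(self) -> pd.Series:
        s = pd.Series(self.pp, index=["pp0", "pp1", "pp2", "pp3", "pp4"])
        s["n_snps"] = self.n_snps
        s["call"] = self.call
        return s


def coloc_posterior(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd: float = 0.15,
    pp4_cut: float = 0.8,
    window: tuple | None = None,
) -> ColocResult:
    """Five-hypothesis posterior from two aligned summary-stat tables.

    ``stats1``/``stats2`` need ``beta`` and ``se`` columns; rows are matched
    on the index (marker ids) when both are indexed, otherwise positionally.
    Priors: ``p1``/``p2`` per-SNP association with one trait, ``p12`` shared.
    """
    for p, name in ((p1, "p1"), (p2, "p2"), (p12, "p12")):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    if p12 > min(p1, p2):
        raise ValueError("p12 must not exceed min(p1, p2)")

    if isinstance(stats1, pd.DataFrame) and isinstance(stats2, pd.DataFrame):
        shared = [m for m in stats1.index if m in set(stats2.index)]
        if len(shared) == 0:
            raise ValueError("no shared markers in window")
        l1 = abf(stats1.loc[shared, "beta"].to_numpy(), stats1.loc[shared, "se"].to_numpy(), prior_sd)
        l2 = abf(stats2.loc[shared, "beta"].to_numpy(), stats2.loc[shared, "se"].to_numpy(), prior_sd)
    else:
        raise TypeError("stats1 and stats2 must be DataFrames with beta/se columns")

    n = len(l1)
    s0 = 0.0
    s1 = logsumexp(l1) + np.log(p1)
    s2 = logsumexp(l2) + np.log(p2)
    s4 = logsumexp(l1 + l2) + np.log(p12)
    if n < 2:
        s3 = -np.inf  # no two-variant configuration exists in a 1-SNP window
    else:
        # log[ (sum e^l1)(sum e^l2) - sum e^(l1+l2) ], computed stably
        a = logsumexp(l1) + logsumexp(l2)
        c = logsumexp(l1 + l2)
        diff = np.clip(np.exp(c - a), 0.0, 1.0)
        with np.errstate(divide="ignore"):
            s3 = a + np.log1p(-diff) + np.log(p1) + np.log(p2)
    logs = np.array([s0, s1, s2, s3, s4])
    pp = np.exp(logs - logsumexp(logs))
    pp = pp / pp.sum()
    return ColocResult(pp, n, window=window, pp4_cut=pp4_cut)


class ColocPair:
    """Model-style wrapper: ``ColocPair(stats1, stats2).fit() -> ColocResult``."""

    def __init__(self, stats1: pd.DataFrame, stats2: pd.DataFrame, **kwargs):
        self.stats1, self.stats2, self.kwargs = stats1, stats2, kwargs

    def fit(self) -> ColocResult:
        return coloc_posterior(self.stats1, self.stats2, **self.kwargs)


def polarity_concordance(pairs) -> pd.Series:
    """Allelic-effect polarity agreement across colocalized locus pairs.

    ``pairs`` is an iterable of (beta1, beta2).  Returns the count and
    fraction of same-sign pairs (zero effects count as concordant with
    anything) and the Pearson r of the two effect vectors.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("no effect pairs given")
    b1, b2 = arr[:, 0], arr[:, 1]
    concordant = (np.sign(b1) == np.sign(b2)) | (b1 == 0) | (b2 == 0)
    n = len(arr)
    frac = concordant.sum() / n
    r = float(stats.pearsonr(b1, b2)[0]) if n > 1 and b1.std() > 0 and b2.std() > 0 else np.nan
    return pd.Series(
        {
            "n_pairs": n,
            "n_concordant": int(concordant.sum()),
            "fraction_concordant": float(frac),
            "percent_concordant": float(100.0 * frac),
            "pearson_r": r,
        }
    )
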