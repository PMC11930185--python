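"""Strain-level descriptive genetics of the proteome.

Differential expression between founder strains with an empirical-Bayes
moderated t (variance shrinkage towards a panel-wide prior, hyperparameters
by method-of-moments on log sample variances), Benjamini-Hochberg FDR
control, the strain-mean heritability estimator, coefficient-of-variation
flagging of highly variable proteins, paired male-female contrasts, and
mRNA-protein correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ProteinMatrix

__all__ = [
    "bh_adjust",
    "moderated_de",
    "ModeratedTTest",
    "heritability",
    "cv_flag",
    "paired_sex_test",
    "mrna_protein_correlation",
    "fold_change_from_log2",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_from_log2(mean_a: float, mean_b: float) -> float:
    """Linear-scale fold change implied by two log2 group means."""
    return float(2.0 ** (mean_a - mean_b))


# ---------------------------------------------------------------------------
# Moderated differential expression
# ---------------------------------------------------------------------------

def _inverse_trigamma(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Given gene-wise sample variances ``s2`` with ``df`` residual degrees of
    freedom each, returns ``(d0, s0_sq)``: under the hierarchical model
    s2/s0_sq ~ F(df, d0), so the excess spread of log s2 beyond trigamma(df/2)
    identifies d0, and the mean of log s2 identifies s0_sq.
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        d0 = np.inf
        log_s0 = z.mean() - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _inverse_trigamma(evar)
        log_s0 = (
            z.mean()
            - special.digamma(df / 2.0) + np.log(df / 2.0)
            + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    return float(d0), float(np.exp(log_s0))


@dataclass
class DEResults:
    """Differential-expression table plus the fitted variance prior."""

    table: pd.DataFrame
    d0: float
    s0_sq: float
    adj_p_cut: float
    lfc_cut: float

    def summary(self) -> pd.DataFrame:
        return self.table

    @property
    def n_de(self) -> int:
        return int(self.table["is_DE"].sum())


def moderated_de(
    expr,
    group_a,
    group_b,
    adj_p_cut: float = 0.01,
    lfc_cut: float = 1.0,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> DEResults:
    """Two-group moderated-t differential expression.

    Parameters
    ----------
    expr : ProteinMatrix or DataFrame
        Proteins x samples log2 abundances.
    group_a, group_b : sequence of sample ids
        The two groups to contrast; log2FC is mean(A) - mean(B).
    d0, s0_sq : float, optional
        Override the method-of-moments prior (``d0=0`` recovers the ordinary
        two-sample t; ``d0=inf`` forces the prior variance everywhere).
    """
    values = expr.values if isinstance(expr, ProteinMatrix) else expr
    a = values[list(group_a)].to_numpy(dtype=float)
    b = values[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    df = na + nb - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df

    if d0 is None or s0_sq is None:
        d0_fit, s0_fit = _fit_variance_prior(s2, df)
        d0 = d0_fit if d0 is None else d0
        s0_sq = s0_fit if s0_sq is None else s0_sq

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_mod = np.inf
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
        df_mod = df + d0

    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_mod):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_mod)
    adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2FC": lfc,
            "t_statistic": t,
            "p": p,
            "adjusted_p": adj,
            "is_DE": (adj < adj_p_cut) & (np.abs(lfc) >= lfc_cut),
        },
        index=values.index,
    )
    return DEResults(table, float(d0), float(s0_sq), adj_p_cut, lfc_cut)


class ModeratedTTest:
    """Model-style wrapper: ``ModeratedTTest(expr, a, b).fit() -> DEResults``."""

    def __init__(self, expr, group_a, group_b, **kwargs):
        self.expr, self.group_a, self.group_b = expr, group_a, group_b
        self.kwargs = kwargs

    def fit(self) -> DEResults:
        return moderated_de(self.expr, self.group_a, self.group_b, **self.kwargs)


# ---------------------------------------------------------------------------
# Heritability, variability, sex contrast, mRNA correlation
# ---------------------------------------------------------------------------

def heritability(expr: ProteinMatrix) -> pd.DataFrame:
    """Strain-mean heritability per protein.

    Total variance is the mean squared deviation of all samples from the
    grand mean; additive variance is the mean squared deviation of strain
    means from the grand mean (population variances, so perfect replicates
    give exactly h2 = 1).  h2 is the clipped ratio; proteins with zero total
    variance get ``NaN``.
    """
    vals = expr.values.to_numpy(dtype=float)
    strain_means = expr.strain_means().to_numpy(dtype=float)
    grand = np.nanmean(vals, axis=1)
    total = np.nanmean((vals - grand[:, None]) ** 2, axis=1)
    additive = np.nanmean((strain_means - grand[:, None]) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(total > 0, np.clip(additive / total, 0.0, 1.0), np.nan)
    return pd.DataFrame(
        {"h2": h2, "additive_variance": additive, "total_variance": total},
        index=expr.values.index,
    )


def cv_flag(expr: ProteinMatrix, n_sd: float = 2.0) -> pd.DataFrame:
    """Coefficient of variation of strain-mean log2 abundance, with flags.

    A protein is highly variable when its CV exceeds the panel mean CV by
    ``n_sd`` panel standard deviations (single pass; flagged proteins are not
    excluded when estimating the threshold).  Proteins with nonpositive mean
    abundance have undefined CV and do not enter the threshold.
    """
    means = expr.strain_means()
    mu = means.mean(axis=1).to_numpy()
    sd = means.std(axis=1, ddof=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > 0, sd / mu, np.nan)
    valid = np.isfinite(cv)
    threshold = cv[valid].mean() + n_sd * cv[valid].std(ddof=0) if valid.any() else np.nan
    out = pd.DataFrame({"cv": cv}, index=expr.values.index)
    out["is_highly_variable"] = valid & (cv > threshold)
    out.attrs["threshold"] = float(threshold) if np.isfinite(threshold) else np.nan
    out.attrs["mean_cv"] = float(cv[valid].mean()) if valid.any() else np.nan
    out.attrs["sd_cv"] = float(cv[valid].std(ddof=0)) if valid.any() else np.nan
    return out


def paired_sex_test(expr: ProteinMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Paired t-test of male vs female littermates, per protein.

    Uses the per-strain M - F differences with n_strains - 1 degrees of
    freedom; p-values are unadjusted.  Zero variance of the differences is
    treated as no evidence (p = 1).  The count of proteins below ``alpha``
    is stored in ``attrs['n_below']``.
    """
    males = expr.subset_sex("M")
    females = expr.subset_sex("F")
    m_strains = list(males.samples["strain"])
    f_strains = list(females.samples["strain"])
    if m_strains != f_strains:
        common = [s for s in m_strains if s in set(f_strains)]
        males_v = males.values[[males.samples.index[males.samples["strain"] == s][0] for s in common]]
        females_v = females.values[[females.samples.index[females.samples["strain"] == s][0] for s in common]]
    else:
        males_v, females_v = males.values, females.values
    diffs = males_v.to_numpy(dtype=float) - females_v.to_numpy(dtype=float)
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("need >= 2 strains with paired samples")
    mean_d = diffs.mean(axis=1)
    sd_d = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd_d > 0, mean_d / (sd_d / np.sqrt(n)), 0.0)
    p = np.where(sd_d > 0, 2.0 * stats.t.sf(np.abs(t), n - 1), 1.0)
    out = pd.DataFrame({"mean_diff": mean_d, "t": t, "p": p}, index=expr.values.index)
    out.attrs["n_below"] = int((p < alpha).sum())
    out.attrs["alpha"] = alpha
    return out


def mrna_protein_correlation(protein: ProteinMatrix, mrna: pd.DataFrame) -> tuple[pd.Series, float]:
    """Pearson correlation of protein and transcript strain profiles.

    ``mrna`` is a gene x strain log2 matrix sharing identifiers with the
    protein matrix.  Returns per-gene r across matched strains (``NaN`` for
    genes with fewer than 3 matched strains) and the overall r pooled over
    all matched (gene, strain) value pairs.
    """
    pmeans = protein.strain_means()
    genes = [g for g in pmeans.index if g in mrna.index]
    strains = [s for s in pmeans.columns if s in mrna.columns]
    if not genes or len(strains) < 3:
        raise ValueError("need shared genes and >= 3 shared strains")
    p = pmeans.loc[genes, strains].to_numpy(dtype=float)
    m = mrna.loc[genes, strains].to_numpy(dtype=float)

    pc = p - p.mean(axis=1, keepdims=True)
    mc = m - m.mean(axis=1, keepdims=True)
    num = (pc * mc).sum(axis=1)
    den = np.sqrt((pc ** 2).sum(axis=1) * (mc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene = pd.Series(np.where(den > 0, num / den, np.nan), index=genes, name="r")

    flat_p, flat_m = p.ravel(), m.ravel()
    ok = np.isfinite(flat_p) & np.isfinite(flat_m)
    overall = float(stats.pearsonr(flat_p[ok], flat_m[ok])[0])
    return per_gene, overall
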