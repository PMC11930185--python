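"""Kinship-corrected single-marker QTL scans with permutation-based FDR.

The association model is the standard one-random-effect linear mixed model

    y = W a + x b + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I)

fitted by restricted maximum likelihood after a single eigendecomposition of
the kinship matrix K: with K = U D U', the rotated model has independent
residuals with variances proportional to (lambda d_i + 1), where
lambda = sg^2/se^2 is profiled per marker over a log10 grid with local
refinement.  The marker effect is tested with a Wald t statistic on
n - q residual degrees of freedom.

Genome-wide significance is calibrated empirically: strain labels of the
expression matrix are permuted, the scan is repeated, per-trait minimum
p-values form the null, and the threshold is the largest observed value whose
estimated FDR stays at or below the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, ProteinMatrix

__all__ = [
    "kinship",
    "lmm_scan",
    "lmm_scan_multi",
    "top_variant",
    "classify_qtl",
    "permutation_fdr",
    "PermutationThreshold",
    "sex_stratified_scan",
    "lrs_lod",
    "ProteomeQTLModel",
    "ProteomeQTLResults",
]

log = logging.getLogger(__name__)

_LOG10_GRID = np.linspace(-5.0, 5.0, 21)
_LOG10_GRID_DENSE = np.linspace(-5.0, 5.0, 61)


def kinship(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Centered relatedness matrix K = (1/p) sum_k (x_k - xbar_k)(x_k - xbar_k)'.

    Missing dosages are mean-imputed per marker before centering.  Raises if
    every marker is monomorphic (K would be identically zero).
    """
    x = genotypes.values()
    if x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("need >= 2 strains and >= 1 marker")
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean[None, :], x)
    xc = x - x.mean(axis=0, keepdims=True)
    k = xc @ xc.T / x.shape[1]
    if np.allclose(k, 0.0):
        raise ValueError("all markers are monomorphic; kinship is zero")
    return pd.DataFrame(k, index=genotypes.strains, columns=genotypes.strains)


def _eigen_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, u = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    return np.clip(d, 0.0, None), u


# ---------------------------------------------------------------------------
# Single-trait scan (general covariates, grid + golden-section refinement)
# ---------------------------------------------------------------------------

def _reml_pieces(lam: float, d: np.ndarray, Xt: np.ndarray, yt: np.ndarray):
    w = 1.0 / (lam * d + 1.0)
    A = Xt.T @ (Xt * w[:, None])
    b = Xt.T @ (yt * w)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    rss = float(yt @ (yt * w) - b @ beta)
    if rss <= 0 or not np.isfinite(rss):
        return None
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return None
    n, q = Xt.shape
    ll = -0.5 * ((n - q) * (np.log(2.0 * np.pi * rss / (n - q)) + 1.0)
                 + np.sum(np.log(lam * d + 1.0)) + logdet_a)
    return ll, beta, rss, A


def _profile_lambda(d, Xt, yt, grid=_LOG10_GRID, refine: bool = True) -> float:
    lls = []
    for g in grid:
        piece = _reml_pieces(10.0 ** g, d, Xt, yt)
        lls.append(-np.inf if piece is None else piece[0])
    i = int(np.argmax(lls))
    if not refine:
        return 10.0 ** grid[i]
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    # golden-section maximisation of the REML log-likelihood on [lo, hi]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    e = a + invphi * (b - a)
    fc = _reml_pieces(10.0 ** c, d, Xt, yt)
    fe = _reml_pieces(10.0 ** e, d, Xt, yt)
    fc = -np.inf if fc is None else fc[0]
    fe = -np.inf if fe is None else fe[0]
    for _ in range(40):
        if b - a < 1e-4:
            break
        if fc > fe:
            b, e, fe = e, c, fc
            c = b - invphi * (b - a)
            p = _reml_pieces(10.0 ** c, d, Xt, yt)
            fc = -np.inf if p is None else p[0]
        else:
            a, c, fc = c, e, fe
            e = a + invphi * (b - a)
            p = _reml_pieces(10.0 ** e, d, Xt, yt)
            fe = -np.inf if p is None else p[0]
    return 10.0 ** ((a + b) / 2.0)


def lmm_scan(
    y,
    genotypes: GenotypeMatrix,
    K: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    refine: bool = True,
) -> pd.DataFrame:
    """Mixed-model association scan of one trait against every marker.

    Parameters
    ----------
    y : Series or array
        Strain-level trait, indexed like (or aligned to) the genotype strains.
    covariates : DataFrame, optional
        Extra fixed effects (an intercept is always included).

    Returns a per-marker DataFrame with ``beta``, ``se``, ``p`` and the
    profiled ``lam`` (= sg^2/se^2).
    """
    strains = genotypes.strains
    if isinstance(y, pd.Series):
        y = y.reindex(strains)
        if y.isna().any():
            keep = list(y.index[y.notna()])
            sub = GenotypeMatrix(genotypes.dosage.loc[keep], genotypes.marker_map)
            return lmm_scan(y.loc[keep], sub, K.loc[keep, keep], covariates, refine)
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        if yv.shape[0] != len(strains):
            raise ValueError("y length must equal strain count")
    n = len(yv)

    W = np.ones((n, 1))
    if covariates is not None:
        C = covariates.reindex(strains).to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
            else np.asarray(covariates, dtype=float)
        W = np.column_stack([W, C])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariates are rank deficient")

    d, u = _eigen_kinship(K.loc[strains, strains].to_numpy(dtype=float))
    yt = u.T @ yv
    Wt = u.T @ W
    G = genotypes.values()
    Gt = u.T @ G

    out = []
    for j, marker in enumerate(genotypes.markers):
        Xt = np.column_stack([Wt, Gt[:, j]])
        if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
            out.append((np.nan, np.nan, np.nan, np.nan))
            continue
        lam = _profile_lambda(d, Xt, yt, refine=refine)
        piece = _reml_pieces(lam, d, Xt, yt)
        if piece is None:
            log.info("marker %s skipped: non-finite likelihood", marker)
            out.append((np.nan, np.nan, np.nan, np.nan))
            continue
        _, beta, rss, A = piece
        q = Xt.shape[1]
        sigma2 = rss / (n - q)
        cov = np.linalg.inv(A) * sigma2
        se = float(np.sqrt(cov[-1, -1]))
        b = float(beta[-1])
        t = b / se if se > 0 else 0.0
        p = float(2.0 * stats.t.sf(abs(t), n - q))
        out.append((b, se, p, lam))

    frame = pd.DataFrame(out, columns=["beta", "se", "p", "lam"], index=genotypes.markers)
    return frame.join(genotypes.marker_map[["chrom", "pos_bp"]])


# ---------------------------------------------------------------------------
# Multi-trait vectorised scan (intercept + marker), shared dense lambda grid
# ---------------------------------------------------------------------------

def lmm_scan_multi(Y: np.ndarray, genotypes: GenotypeMatrix, K: pd.DataFrame) -> dict:
    """Scan many traits at once; returns dict of traits x markers arrays.

    ``Y`` is traits x strains, aligned to the genotype strain order.  The
    fixed part is intercept + marker; lambda is profiled per (trait, marker)
    pair on a dense shared log10 grid (no per-pair refinement), which keeps
    every REML evaluation a vectorised array operation.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    n = Y.shape[1]
    if n != genotypes.n_strains:
        raise ValueError("Y columns must equal strain count")
    d, u = _eigen_kinship(K.loc[genotypes.strains, genotypes.strains].to_numpy(dtype=float))
    Yt = Y @ u                     # T x n
    Gt = u.T @ genotypes.values()  # n x M
    ones_t = u.T @ np.ones(n)
    T, M = Yt.shape[0], Gt.shape[1]

    best_ll = np.full((T, M), -np.inf)
    best_idx = np.zeros((T, M), dtype=np.int16)
    Gt2 = Gt ** 2
    Yt2 = Yt ** 2

    def _stats_for(lam):
        w = 1.0 / (lam * d + 1.0)
        s11 = float(np.dot(w * ones_t, ones_t))
        s1x = (w * ones_t) @ Gt                    # M
        sxx = w @ Gt2                              # M
        s1y = Yt @ (w * ones_t)                    # T
        sxy = Yt @ (Gt * w[:, None])               # T x M
        syy = Yt2 @ w                              # T
        det = s11 * sxx - s1x ** 2                 # M
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (s11 * sxy - s1x[None, :] * s1y[:, None]) / det[None, :]
            alpha = (sxx[None, :] * s1y[:, None] - s1x[None, :] * sxy) / det[None, :]
            rss = syy[:, None] - alpha * s1y[:, None] - beta * sxy
        return s11, det, beta, rss, np.sum(np.log(lam * d + 1.0))

    for li, g in enumerate(_LOG10_GRID_DENSE):
        lam = 10.0 ** g
        s11, det, beta, rss, logw = _stats_for(lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = -0.5 * ((n - 2) * (np.log(2.0 * np.pi * rss / (n - 2)) + 1.0)
                         + logw + np.log(det)[None, :])
        ll = np.where(np.isfinite(ll) & (rss > 0), ll, -np.inf)
        upd = ll > best_ll
        best_ll[upd] = ll[upd]
        best_idx[upd] = li

    beta_out = np.full((T, M), np.nan)
    se_out = np.full((T, M), np.nan)
    lam_out = np.full((T, M), np.nan)
    for li in np.unique(best_idx):
        lam = 10.0 ** _LOG10_GRID_DENSE[li]
        mask = best_idx == li
        if not mask.any():
            continue
        s11, det, beta, rss, _ = _stats_for(lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = rss / (n - 2)
            se = np.sqrt(sigma2 * s11 / det[None, :])
        beta_out[mask] = beta[mask]
        se_out[mask] = se[mask]
        lam_out[mask] = lam
    bad = ~np.isfinite(best_ll)
    for arr in (beta_out, se_out, lam_out):
        arr[bad] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_out / se_out
    p_out = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), n - 2), np.nan)
    return {"beta": beta_out, "se": se_out, "p": p_out, "lam": lam_out}


# ---------------------------------------------------------------------------
# Top variant, cis/trans classification
# ---------------------------------------------------------------------------

def _chrom_key(chrom) -> tuple:
    s = str(chrom)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


def top_variant(scan: pd.DataFrame, trait_id: str | None = None) -> pd.Series:
    """Pick the QTL: smallest p, ties broken by genomic coordinate.

    ``scan`` is the per-marker frame from :func:`lmm_scan` (must carry
    ``chrom`` and ``pos_bp``).  All-NaN scans raise.
    """
    p = scan["p"]
    if p.notna().sum() == 0:
        raise ValueError("no tested markers")
    pmin = p.min()
    ties = scan[p == pmin]
    ties = ties.sort_values(by=["chrom", "pos_bp"],
                            key=lambda col: col.map(_chrom_key) if col.name == "chrom" else col)
    rec = ties.iloc[0].copy()
    rec["marker_id"] = ties.index[0]
    if trait_id is not None:
        rec["trait_id"] = trait_id
    return rec


def classify_qtl(
    record,
    annotation: pd.DataFrame,
    trait_id: str | None = None,
    cis_window_bp: float = 1_000_000,
    trans_gap_bp: float = 5_000_000,
    results_variant: bool = False,
) -> str:
    """cis/trans classification of a QTL from pure coordinate arithmetic.

    cis: same chromosome and |pos - TSS| <= ``cis_window_bp``.
    trans (default rule): different chromosome, or >= ``trans_gap_bp`` from
    the nearest exon boundary.  ``results_variant=True`` switches to the
    simpler distal rule: > 10 Mb from the TSS or a different chromosome.
    Everything else is ``"unclassified"``.
    """
    tid = trait_id if trait_id is not None else record.get("trait_id")
    if tid not in annotation.index:
        log.info("trait %r missing annotation; unclassified", tid)
        return "unclassified"
    ann = annotation.loc[tid]
    chrom, pos = str(record["chrom"]), float(record["pos_bp"])
    same_chrom = chrom == str(ann["chrom"])
    if same_chrom and abs(pos - float(ann["tss_bp"])) <= cis_window_bp:
        return "cis"
    if results_variant:
        if not same_chrom or abs(pos - float(ann["tss_bp"])) > 10_000_000:
            return "trans"
        return "unclassified"
    if not same_chrom:
        return "trans"
    lo, hi = float(ann["exon_start_bp"]), float(ann["exon_end_bp"])
    dist = 0.0 if lo <= pos <= hi else min(abs(pos - lo), abs(pos - hi))
    if dist >= trans_gap_bp:
        return "trans"
    return "unclassified"


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

@dataclass
class PermutationThreshold:
    """Empirical-FDR significance threshold from label permutations."""

    n_perm: int
    target_fdr: float
    p_threshold: float
    obs_min_p: pd.Series
    null_min_p: np.ndarray          # n_perm x n_traits
    fdr_at_threshold: float = np.nan

    def n_discoveries(self) -> int:
        return int((self.obs_min_p <= self.p_threshold).sum())

    def calls(self) -> pd.Series:
        return self.obs_min_p <= self.p_threshold


def _strain_level(expr, genotypes: GenotypeMatrix) -> np.ndarray:
    """Traits x strains matrix aligned to the genotype strain order."""
    if isinstance(expr, ProteinMatrix):
        sm = expr.strain_means()
    else:
        sm = expr
    missing = [s for s in genotypes.strains if s not in sm.columns]
    if missing:
        raise ValueError(f"expression lacks strains: {missing[:5]}")
    return sm[genotypes.strains].to_numpy(dtype=float)


def _window_stat(P: np.ndarray, trait_ids, genotypes: GenotypeMatrix,
                 annotation: pd.DataFrame | None, statistic: str,
                 cis_window_bp: float) -> np.ndarray:
    """Per-trait summary of a traits x markers p matrix.

    ``genome``: min over all markers; ``cis``: min over markers within the
    cis window of the trait's TSS (NaN when the window holds no marker).
    """
    if statistic == "genome":
        with np.errstate(invalid="ignore"):
            return np.nanmin(P, axis=1)
    if statistic != "cis":
        raise ValueError(f"unknown statistic {statistic!r}")
    if annotation is None:
        raise ValueError("cis statistic needs an annotation table")
    pos = {mk: i for i, mk in enumerate(genotypes.markers)}
    out = np.full(P.shape[0], np.nan)
    for i, tid in enumerate(trait_ids):
        if tid not in annotation.index:
            continue
        ann = annotation.loc[tid]
        mks = genotypes.markers_in_window(
            str(ann["chrom"]), float(ann["tss_bp"]) - cis_window_bp, float(ann["tss_bp"]) + cis_window_bp
        )
        if mks:
            cols = [pos[m] for m in mks]
            with np.errstate(invalid="ignore"):
                out[i] = np.nanmin(P[i, cols])
    return out


def permutation_fdr(
    expr,
    genotypes: GenotypeMatrix,
    K: pd.DataFrame,
    n_perm: int = 10,
    target_fdr: float = 0.05,
    seed: int = 0,
    statistic: str = "genome",
    annotation: pd.DataFrame | None = None,
    cis_window_bp: float = 1_000_000,
    scan_p: np.ndarray | None = None,
) -> PermutationThreshold:
    """Empirical-FDR p-value threshold from strain-label permutations.

    The observed statistic per trait is its minimum scan p-value (genome-wide
    or within the cis window).  Each permutation shuffles the strain labels
    of the expression matrix — one shuffle shared by all traits, preserving
    the within-strain replicate pairing — and the scan is repeated.  For a
    candidate threshold t, FDR(t) = mean permuted count of traits with
    min p <= t divided by the observed count; the threshold returned is the
    largest observed statistic with estimated FDR <= target.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = _strain_level(expr, genotypes)
    trait_ids = list(expr.values.index) if isinstance(expr, ProteinMatrix) else list(expr.index)
    if scan_p is None:
        scan_p = lmm_scan_multi(Y, genotypes, K)["p"]
    obs = _window_stat(scan_p, trait_ids, genotypes, annotation, statistic, cis_window_bp)
    obs = pd.Series(obs, index=trait_ids, name="min_p")

    rng = np.random.default_rng(seed)
    null = np.full((n_perm, len(trait_ids)), np.nan)
    for r in range(n_perm):
        perm = rng.permutation(Y.shape[1])
        p_perm = lmm_scan_multi(Y[:, perm], genotypes, K)["p"]
        null[r] = _window_stat(p_perm, trait_ids, genotypes, annotation, statistic, cis_window_bp)

    obs_v = np.sort(obs.dropna().to_numpy())
    null_v = np.sort(null[np.isfinite(null)])
    if obs_v.size == 0:
        return PermutationThreshold(n_perm, target_fdr, 0.0, obs, null)
    # FDR at each observed candidate threshold (step-up over the observed stats)
    obs_counts = np.arange(1, obs_v.size + 1)
    null_counts = np.searchsorted(null_v, obs_v, side="right") / n_perm
    fdr = null_counts / np.maximum(obs_counts, 1)
    ok = fdr <= target_fdr
    if not ok.any():
        log.warning("no threshold achieves FDR <= %g; returning 0 (no discoveries)", target_fdr)
        return PermutationThreshold(n_perm, target_fdr, 0.0, obs, null, float(fdr.min()))
    i = int(np.max(np.nonzero(ok)[0]))
    return PermutationThreshold(n_perm, target_fdr, float(obs_v[i]), obs, null, float(fdr[i]))


# ---------------------------------------------------------------------------
# Sex-stratified scans and LRS/LOD conversion
# ---------------------------------------------------------------------------

def _sex_matrix(expr: ProteinMatrix, sex: str) -> pd.DataFrame:
    if sex == "averaged":
        return expr.strain_means()
    if sex not in {"male", "female"}:
        raise ValueError(f"unknown sex {sex!r}")
    sub = expr.subset_sex("M" if sex == "male" else "F")
    sm = sub.strain_means()
    if sm.shape[1] < 3:
        raise ValueError("need samples of the requested sex for >= 3 strains")
    return sm


def sex_stratified_scan(
    expr: ProteinMatrix,
    genotypes: GenotypeMatrix,
    K: pd.DataFrame,
    sex: str,
    annotation: pd.DataFrame | None = None,
    n_perm: int = 10,
    target_fdr: float = 0.05,
    seed: int = 0,
    statistic: str = "cis",
    cis_window_bp: float = 1_000_000,
) -> tuple[pd.DataFrame, PermutationThreshold]:
    """Run the full scan + permutation pipeline on one sex (or the average).

    Returns the per-trait QTL records (top variant, classification,
    significance at the permutation threshold) and the threshold object.
    """
    sm = _sex_matrix(expr, sex)
    strains = [s for s in genotypes.strains if s in sm.columns]
    sub_g = GenotypeMatrix(genotypes.dosage.loc[strains], genotypes.marker_map)
    sub_k = K.loc[strains, strains]
    Y = sm[strains].to_numpy(dtype=float)
    res = lmm_scan_multi(Y, sub_g, sub_k)
    thr = permutation_fdr(
        sm[strains], sub_g, sub_k, n_perm=n_perm, target_fdr=target_fdr, seed=seed,
        statistic=statistic, annotation=annotation, cis_window_bp=cis_window_bp,
        scan_p=res["p"],
    )
    records = build_qtl_records(res, sm.index, sub_g, annotation, thr)
    return records, thr


def build_qtl_records(
    res: dict,
    trait_ids,
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame | None,
    threshold: PermutationThreshold | None = None,
    **classify_kwargs,
) -> pd.DataFrame:
    """Per-trait top-variant records from a multi-trait scan result."""
    mm = genotypes.marker_map
    chroms = mm["chrom"].to_numpy()
    pos = mm["pos_bp"].to_numpy(dtype=float)

    rows = []
    P = res["p"]
    for i, tid in enumerate(trait_ids):
        p_row = P[i]
        finite = np.isfinite(p_row)
        if not finite.any():
            continue
        pmin = np.nanmin(p_row)
        tied = np.nonzero(p_row == pmin)[0]
        # tie-break: smallest genomic coordinate
        j = min(tied, key=lambda k: (_chrom_key(chroms[k]), pos[k]))
        marker = mm.index[j]
        rec = {
            "trait_id": tid,
            "marker_id": marker,
            "chrom": str(chroms[j]),
            "pos_bp": int(pos[j]),
            "beta": float(res["beta"][i, j]),
            "se": float(res["se"][i, j]),
            "p": float(pmin),
        }
        if annotation is not None:
            rec["classification"] = classify_qtl(rec, annotation, trait_id=tid, **classify_kwargs)
        else:
            rec["classification"] = "unclassified"
        if threshold is not None:
            stat = threshold.obs_min_p.get(tid, np.nan)
            rec["significant"] = bool(np.isfinite(stat) and stat <= threshold.p_threshold)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("trait_id")


def lrs_lod(value: float, direction: str) -> float:
    """Convert between likelihood-ratio statistic and LOD: LRS = 2 ln(10) LOD."""
    if value < 0:
        raise ValueError("value must be >= 0")
    factor = 2.0 * np.log(10.0)
    if direction in {"lod_to_lrs", "lod->lrs"}:
        return float(value * factor)
    if direction in {"lrs_to_lod", "lrs->lod"}:
        return float(value / factor)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Model/Results presentation
# ---------------------------------------------------------------------------

class ProteomeQTLModel:
    """Proteome-wide QTL mapping model.

    Binds a protein matrix, genotypes and trait annotation; ``fit`` runs the
    mixed-model scan for every protein, selects top variants, classifies them
    cis/trans and calibrates cis and trans permutation thresholds.
    """

    def __init__(self, expr: ProteinMatrix, genotypes: GenotypeMatrix,
                 annotation: pd.DataFrame | None = None, K: pd.DataFrame | None = None):
        self.expr = expr
        self.genotypes = genotypes
        self.annotation = annotation
        self.K = kinship(genotypes) if K is None else K

    def fit(self, sex: str = "averaged", n_perm: int = 10, target_fdr: float = 0.05,
            seed: int = 0, cis_window_bp: float = 1_000_000) -> "ProteomeQTLResults":
        records, cis_thr = sex_stratified_scan(
            self.expr, self.genotypes, self.K, sex, annotation=self.annotation,
            n_perm=n_perm, target_fdr=target_fdr, seed=seed, statistic="cis",
            cis_window_bp=cis_window_bp,
        )
        sm = _sex_matrix(self.expr, sex)
        strains = [s for s in self.genotypes.strains if s in sm.columns]
        sub_g = GenotypeMatrix(self.genotypes.dosage.loc[strains], self.genotypes.marker_map)
        sub_k = self.K.loc[strains, strains]
        genome_thr = permutation_fdr(
            sm[strains], sub_g, sub_k, n_perm=n_perm, target_fdr=target_fdr,
            seed=seed + 1, statistic="genome",
        )
        return ProteomeQTLResults(records, cis_thr, genome_thr, sex)


@dataclass
class ProteomeQTLResults:
    """Scan output: per-protein QTL records and permutation thresholds."""

    records: pd.DataFrame
    cis_threshold: PermutationThreshold
    genome_threshold: PermutationThreshold
    sex: str = "averaged"

    def cis_calls(self) -> pd.DataFrame:
        r = self.records
        sig = self.cis_threshold.calls().reindex(r.index).fillna(False)
        return r[(r["classification"] == "cis") & sig]

    def trans_calls(self) -> pd.DataFrame:
        r = self.records
        sig = self.genome_threshold.calls().reindex(r.index).fillna(False)
        return r[(r["classification"] == "trans") & sig]

    def summary(self) -> pd.DataFrame:
        counts = self.records["classification"].value_counts()
        return pd.DataFrame(
            {
                "n_traits": [len(self.records)],
                "n_cis": [int(counts.get("cis", 0))],
                "n_trans": [int(counts.get("trans", 0))],
                "n_cis_significant": [len(self.cis_calls())],
                "n_trans_significant": [len(self.trans_calls())],
                "cis_p_threshold": [self.cis_threshold.p_threshold],
                "genome_p_threshold": [self.genome_threshold.p_threshold],
                "sex": [self.sex],
            }
        )
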