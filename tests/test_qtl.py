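"""Mixed-model scan, kinship, cis/trans classification, permutation FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import ripqtl as r
from ripqtl.containers import GenotypeMatrix, ProteinMatrix
from ripqtl.qtl import (
    kinship,
    lmm_scan,
    lmm_scan_multi,
    top_variant,
    classify_qtl,
    permutation_fdr,
    sex_stratified_scan,
    lrs_lod,
    build_qtl_records,
)


def toy_genotypes(dosage, chroms=None, pos=None):
    arr = np.asarray(dosage, dtype=float)
    n, m = arr.shape
    markers = [f"m{j}" for j in range(m)]
    mm = pd.DataFrame(
        {
            "chrom": chroms or ["1"] * m,
            "pos_bp": pos if pos is not None else (np.arange(m) + 1) * 1_000_000,
            "cM": np.arange(m, dtype=float),
        },
        index=pd.Index(markers, name="marker"),
    )
    strains = [f"st{i}" for i in range(n)]
    return GenotypeMatrix(pd.DataFrame(arr, index=strains, columns=markers), mm)


def ols_scan(y, X):
    """Closed-form intercept+marker OLS Wald p-values (the K = I oracle)."""
    n = len(y)
    out = np.empty(X.shape[1])
    betas = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        A = np.column_stack([np.ones(n), X[:, j]])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        s2 = (resid @ resid) / (n - 2)
        xc = X[:, j] - X[:, j].mean()
        se = np.sqrt(s2 / (xc @ xc))
        t = beta[1] / se
        betas[j] = beta[1]
        out[j] = 2 * stats.t.sf(abs(t), n - 2)
    return betas, out


class TestKinship:
    def test_two_opposite_strains_closed_form(self):
        g = toy_genotypes([[0, 0, 1], [1, 1, 0]])
        K = kinship(g).to_numpy()
        np.testing.assert_allclose(K, [[0.25, -0.25], [-0.25, 0.25]])
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-12)

    def test_duplicated_strains_match_diagonal(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(4, 30)).astype(float)
        dup = np.vstack([base, base[0]])
        K = kinship(toy_genotypes(dup)).to_numpy()
        assert K[0, 4] == pytest.approx(K[0, 0])
        assert K[4, 4] == pytest.approx(K[0, 0])

    def test_invariant_to_marker_order(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 2, size=(6, 20)).astype(float)
        g1 = toy_genotypes(d)
        perm = rng.permutation(20)
        g2 = GenotypeMatrix(g1.dosage.iloc[:, perm], g1.marker_map.iloc[perm])
        np.testing.assert_allclose(kinship(g1).to_numpy(), kinship(g2).to_numpy(), atol=1e-12)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            kinship(toy_genotypes([[1, 1], [1, 1], [1, 1]]))


class TestLMMScan:
    def test_identity_kinship_equals_ols(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 2, size=(30, 40)).astype(float)
        g = toy_genotypes(d)
        K = pd.DataFrame(np.eye(30), index=g.strains, columns=g.strains)
        Y = rng.standard_normal((20, 30))
        res = lmm_scan_multi(Y, g, K)
        for i in range(20):
            _, p = ols_scan(Y[i], d)
            np.testing.assert_allclose(res["p"][i], p, atol=1e-8)
        scan = lmm_scan(pd.Series(Y[0], index=g.strains), g, K)
        _, p0 = ols_scan(Y[0], d)
        np.testing.assert_allclose(scan["p"].to_numpy(), p0, atol=1e-8)

    def test_null_p_values_uniform(self):
        # independent markers (one per chromosome), trait independent of genotype
        cfg = r.SimConfig(n_strains=28, n_chromosomes=2000, markers_per_chr=1,
                          n_proteins=1, n_cis_effects=0, n_trans_effects=0, seed=21)
        g = r.simulate_ri_genotypes(cfg)
        K = kinship(g)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(g.n_strains)
        res = lmm_scan_multi(y[None, :], g, K)
        p = res["p"][0]
        p = p[np.isfinite(p)]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_effect_recovered(self):
        cfg = r.SimConfig(n_strains=28, n_chromosomes=3, markers_per_chr=20, seed=22)
        g = r.simulate_ri_genotypes(cfg)
        K = kinship(g)
        rng = np.random.default_rng(4)
        x = g.dosage.iloc[:, 10].to_numpy()
        y = 1.0 * x + rng.normal(0, 0.5, size=g.n_strains)
        res = lmm_scan_multi(y[None, :], g, K)
        assert abs(res["beta"][0, 10] - 1.0) < 3 * res["se"][0, 10]
        # linked neighbours may edge out the causal marker; peak must be local
        assert abs(np.nanargmin(res["p"][0]) - 10) <= 3

    def test_p_invariant_to_affine_transform_of_y(self):
        cfg = r.SimConfig(n_strains=20, n_chromosomes=2, markers_per_chr=15, seed=23)
        g = r.simulate_ri_genotypes(cfg)
        K = kinship(g)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(g.n_strains)
        p1 = lmm_scan_multi(y[None, :], g, K)["p"]
        p2 = lmm_scan_multi((7.0 - 3.0 * y)[None, :], g, K)["p"]
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_rank_deficient_covariates_rejected(self):
        g = toy_genotypes(np.random.default_rng(6).integers(0, 2, (10, 5)).astype(float))
        K = pd.DataFrame(np.eye(10), index=g.strains, columns=g.strains)
        covs = pd.DataFrame({"c1": np.ones(10), "c2": np.ones(10)}, index=g.strains)
        with pytest.raises(ValueError, match="rank"):
            lmm_scan(pd.Series(np.arange(10.0), index=g.strains), g, K, covariates=covs)


class TestTopVariant:
    def _scan_frame(self, p, chroms, pos):
        g = toy_genotypes(np.zeros((2, len(p))), chroms=chroms, pos=pos)
        frame = pd.DataFrame({"beta": 0.0, "se": 1.0, "p": p}, index=g.markers)
        return frame.join(g.marker_map[["chrom", "pos_bp"]])

    def test_unique_minimum(self):
        scan = self._scan_frame([0.5, 0.01, 0.2], ["1", "1", "2"], [100, 200, 300])
        assert top_variant(scan)["marker_id"] == "m1"

    def test_tie_broken_by_coordinate(self):
        scan = self._scan_frame([0.01, 0.01, 0.5], ["2", "1", "1"], [100, 900, 300])
        assert top_variant(scan)["marker_id"] == "m1"  # chrom 1 < chrom 2

    def test_all_p_one_returns_first_by_coordinate(self):
        scan = self._scan_frame([1.0, 1.0], ["1", "1"], [500, 100])
        assert top_variant(scan)["marker_id"] == "m1"


class TestClassification:
    ANN = pd.DataFrame(
        {"chrom": ["3"], "tss_bp": [50_000_000],
         "exon_start_bp": [50_000_000], "exon_end_bp": [50_030_000]},
        index=pd.Index(["prot"], name="protein"),
    )

    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("3", 50_000_000, "cis"),            # at the TSS
            ("3", 50_999_999, "cis"),            # just inside the 1 Mb window
            ("7", 50_000_000, "trans"),          # different chromosome
            ("3", 60_000_000, "trans"),          # 9.97 Mb past the exon end
            ("3", 52_000_000, "unclassified"),   # 2 Mb past TSS, 1.97 Mb from exon end
        ],
    )
    def test_window_rules(self, chrom, pos, expected):
        rec = {"chrom": chrom, "pos_bp": pos, "trait_id": "prot"}
        assert classify_qtl(rec, self.ANN) == expected

    def test_results_variant_rule(self):
        rec = {"chrom": "3", "pos_bp": 57_000_000, "trait_id": "prot"}
        assert classify_qtl(rec, self.ANN) == "trans"          # >= 5 Mb from exons
        assert classify_qtl(rec, self.ANN, results_variant=True) == "unclassified"  # < 10 Mb

    def test_missing_annotation_unclassified(self):
        rec = {"chrom": "1", "pos_bp": 1, "trait_id": "nope"}
        assert classify_qtl(rec, self.ANN) == "unclassified"

    @given(st.integers(1, 20), st.integers(1, 20),
           st.integers(0, 100_000_000), st.integers(0, 100_000_000))
    def test_pure_coordinate_function(self, c_rec, c_ann, pos, tss):
        ann = pd.DataFrame(
            {"chrom": [str(c_ann)], "tss_bp": [tss],
             "exon_start_bp": [tss], "exon_end_bp": [tss + 10_000]},
            index=pd.Index(["t"], name="protein"),
        )
        rec = {"chrom": str(c_rec), "pos_bp": pos, "trait_id": "t"}
        got = classify_qtl(rec, ann)
        if c_rec == c_ann and abs(pos - tss) <= 1_000_000:
            assert got == "cis"
        elif c_rec != c_ann:
            assert got == "trans"
        else:
            dist = 0 if tss <= pos <= tss + 10_000 else min(abs(pos - tss), abs(pos - tss - 10_000))
            assert got == ("trans" if dist >= 5_000_000 else "unclassified")


class TestPermutationFDR:
    def test_null_panel_yields_no_discoveries(self):
        cfg = r.SimConfig(n_strains=28, n_chromosomes=3, markers_per_chr=20,
                          n_proteins=100, n_cis_effects=0, n_trans_effects=0,
                          polygenic_sd=0.0, residual_sd=1.0, sex_effect_sd=0.0,
                          batch_effect_sd=0.0, seed=24)
        g = r.simulate_ri_genotypes(cfg)
        pm, _ = r.simulate_proteome(g, cfg)
        thr = permutation_fdr(pm, g, kinship(g), n_perm=5, seed=1)
        assert thr.n_discoveries() <= 2

    def test_threshold_monotone_in_target(self, small_panel, small_kinship):
        _, g, pm, truth = small_panel
        Y = pm.strain_means()[g.strains].to_numpy()
        scan_p = lmm_scan_multi(Y, g, small_kinship)["p"]
        thrs = [
            permutation_fdr(pm, g, small_kinship, n_perm=4, target_fdr=f, seed=2,
                            scan_p=scan_p).p_threshold
            for f in (0.01, 0.05, 0.2)
        ]
        assert thrs[0] <= thrs[1] <= thrs[2]

    def test_planted_effects_pass_threshold(self, small_panel, small_kinship):
        _, g, pm, truth = small_panel
        thr = permutation_fdr(pm, g, small_kinship, n_perm=10, seed=3,
                              statistic="cis", annotation=truth.annotation)
        calls = thr.calls()
        planted = set(truth.cis_assignments)
        tp = sum(1 for p in calls.index[calls] if p in planted)
        assert tp / len(planted) >= 0.8


class TestSexStratified:
    def _matched_expr(self, with_female_effect=False, seed=0):
        cfg = r.SimConfig(n_strains=28, n_chromosomes=2, markers_per_chr=15, seed=25)
        g = r.simulate_ri_genotypes(cfg)
        rng = np.random.default_rng(seed)
        n = g.n_strains
        n_prot = 20
        strain_vals = rng.normal(20, 0.5, size=(n_prot, n))
        x = g.dosage.iloc[:, 7].to_numpy()
        cols, meta = [], []
        vals = np.empty((n_prot, 2 * n))
        anno_rows = []
        for j, s in enumerate(g.strains):
            for k, sex in enumerate(("M", "F")):
                vals[:, 2 * j + k] = strain_vals[:, j]
                if with_female_effect and sex == "F":
                    vals[0, 2 * j + k] += 2.0 * x[j]
                cols.append(f"{s}_{sex}")
                meta.append((f"{s}_{sex}", s, sex, 0))
        samples = pd.DataFrame(meta, columns=["sample", "strain", "sex", "batch"]).set_index("sample")
        samples["channel"] = range(len(samples))
        values = pd.DataFrame(vals, index=[f"p{i}" for i in range(n_prot)], columns=cols)
        ann = pd.DataFrame(
            {"chrom": "1", "tss_bp": g.marker_map["pos_bp"].iloc[7],
             "exon_start_bp": g.marker_map["pos_bp"].iloc[7],
             "exon_end_bp": g.marker_map["pos_bp"].iloc[7] + 10_000},
            index=pd.Index([f"p{i}" for i in range(n_prot)], name="protein"),
        )
        return g, ProteinMatrix(values, samples), ann

    def test_identical_sexes_give_identical_qtl_sets(self):
        g, expr, ann = self._matched_expr()
        K = kinship(g)
        rec_m, thr_m = sex_stratified_scan(expr, g, K, "male", annotation=ann, n_perm=3, seed=4)
        rec_f, thr_f = sex_stratified_scan(expr, g, K, "female", annotation=ann, n_perm=3, seed=4)
        pd.testing.assert_frame_equal(rec_m, rec_f)
        assert thr_m.p_threshold == thr_f.p_threshold

    def test_female_only_effect_found_only_in_females(self):
        found_f = found_m = 0
        reps = 5
        for rep in range(reps):
            g, expr, ann = self._matched_expr(with_female_effect=True, seed=100 + rep)
            K = kinship(g)
            rec_f, thr_f = sex_stratified_scan(expr, g, K, "female", annotation=ann,
                                               n_perm=5, seed=rep)
            rec_m, thr_m = sex_stratified_scan(expr, g, K, "male", annotation=ann,
                                               n_perm=5, seed=rep)
            found_f += int(rec_f.loc["p0", "significant"]) if "p0" in rec_f.index else 0
            found_m += int(rec_m.loc["p0", "significant"]) if "p0" in rec_m.index else 0
        assert found_f >= 4
        assert found_m <= 1

    def test_empty_subset_rejected(self):
        g, expr, ann = self._matched_expr()
        males_only = ProteinMatrix(
            expr.values[[c for c in expr.values.columns if c.endswith("_M")]],
            expr.samples[expr.samples["sex"] == "M"],
        )
        with pytest.raises(ValueError):
            sex_stratified_scan(males_only, g, kinship(g), "female")


class TestLrsLod:
    def test_printed_threshold_pair(self):
        assert round(lrs_lod(3.0, "lod_to_lrs"), 1) == 13.8

    def test_zero(self):
        assert lrs_lod(0.0, "lod_to_lrs") == 0.0

    def test_round_trip(self):
        assert lrs_lod(lrs_lod(21.95, "lrs_to_lod"), "lod_to_lrs") == pytest.approx(21.95, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lrs_lod(-1.0, "lod_to_lrs")


def test_model_results_wrapper(small_panel, small_kinship):
    _, g, pm, truth = small_panel
    model = r.ProteomeQTLModel(pm, g, truth.annotation, K=small_kinship)
    res = model.fit(n_perm=4, seed=5)
    s = res.summary().iloc[0]
    assert s["n_traits"] == len(pm.proteins)
    # planted cis proteins should dominate the significant cis calls
    calls = res.cis_calls()
    assert len(calls) > 0
    planted = set(truth.cis_assignments)
    assert sum(1 for t in calls.index if t in planted) / len(calls) > 0.8
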