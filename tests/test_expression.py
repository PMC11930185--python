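"""Descriptive genetics: BH, moderated t, heritability, CV, sex test, mRNA r."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import ripqtl as r
from ripqtl.containers import ProteinMatrix
from ripqtl.expression import bh_adjust, moderated_de, fold_change_from_log2


def make_matrix(values, strains=None, sexes=None):
    arr = np.asarray(values, dtype=float)
    n = arr.shape[1]
    cols = [f"s{j}" for j in range(n)]
    strains = strains or [f"st{j // 2}" for j in range(n)]
    sexes = sexes or (["M", "F"] * (n // 2 + 1))[:n]
    samples = pd.DataFrame(
        {"strain": strains, "sex": sexes, "batch": 0, "channel": range(n)},
        index=pd.Index(cols, name="sample"),
    )
    values = pd.DataFrame(arr, columns=cols,
                          index=[f"p{i}" for i in range(arr.shape[0])])
    return ProteinMatrix(values, samples)


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_invariant_under_permutation(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = bh_adjust(p)
        shuffled = bh_adjust([p[i] for i in perm])
        unshuffled = np.empty_like(shuffled)
        unshuffled[perm] = shuffled
        np.testing.assert_allclose(direct, unshuffled, atol=1e-12)


class TestModeratedDE:
    def test_identical_groups_not_de(self):
        rng = np.random.default_rng(0)
        block = rng.normal(20, 1, size=(30, 3))
        m = make_matrix(np.hstack([block, block]))
        res = moderated_de(m, [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)])
        assert np.allclose(res.table["log2FC"], 0.0)
        assert not res.table["is_DE"].any()

    def test_d0_zero_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(100, 4))
        b = rng.normal(0.3, 1, size=(100, 4))
        m = make_matrix(np.hstack([a, b]))
        ga, gb = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]
        res = moderated_de(m, ga, gb, d0=0.0, s0_sq=1.0)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t_statistic"], t, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p, atol=1e-10)

    def test_d0_infinite_uses_prior_variance_only(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(50, 3))
        b = rng.normal(0, 1, size=(50, 3))
        m = make_matrix(np.hstack([a, b]))
        ga, gb = [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)]
        res = moderated_de(m, ga, gb, d0=np.inf, s0_sq=1.0)
        lfc = a.mean(axis=1) - b.mean(axis=1)
        z = lfc / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res.table["t_statistic"], z, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], 2 * stats.norm.sf(np.abs(z)), atol=1e-12)

    def test_simulation_fdr_and_power(self):
        # 1,000 null + 100 true |log2FC| = 2 proteins, n = 2 vs 2, sd 0.3
        rng = np.random.default_rng(3)
        null = rng.normal(20, 0.3, size=(1000, 4))
        signal = rng.normal(20, 0.3, size=(100, 4))
        signs = np.where(np.arange(100) % 2 == 0, 1.0, -1.0)
        signal[:, :2] += (2.0 * signs)[:, None]
        m = make_matrix(np.vstack([null, signal]))
        res = moderated_de(m, ["s0", "s1"], ["s2", "s3"])
        flagged = res.table["is_DE"].to_numpy()
        true_mask = np.arange(1100) >= 1000
        n_flag = flagged.sum()
        assert n_flag > 0
        fdr = (flagged & ~true_mask).sum() / n_flag
        power = (flagged & true_mask).sum() / 100
        assert fdr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_flag)
        assert power > 0.8

    def test_too_few_samples_rejected(self):
        m = make_matrix(np.ones((5, 4)))
        with pytest.raises(ValueError):
            moderated_de(m, ["s0"], ["s1", "s2"])


class TestHeritability:
    def test_perfect_replicates_give_one(self):
        m = make_matrix([[1.0, 1.0, 3.0, 3.0]], strains=["a", "a", "b", "b"])
        assert r.heritability(m)["h2"].iloc[0] == pytest.approx(1.0)

    def test_equal_strain_means_give_zero(self):
        m = make_matrix([[0.0, 2.0, 1.0, 1.0]], strains=["a", "a", "b", "b"])
        assert r.heritability(m)["h2"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_intermediate_case(self):
        # strains (0,1) and (2,3): additive = 1, total = 1.25 -> h2 = 0.8
        m = make_matrix([[0.0, 1.0, 2.0, 3.0]], strains=["a", "a", "b", "b"])
        row = r.heritability(m).iloc[0]
        assert row["additive_variance"] == pytest.approx(1.0)
        assert row["total_variance"] == pytest.approx(1.25)
        assert row["h2"] == pytest.approx(0.8)

    def test_zero_total_variance_is_missing(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0]], strains=["a", "a", "b", "b"])
        assert np.isnan(r.heritability(m)["h2"].iloc[0])

    def test_monotone_in_between_to_within_ratio(self):
        rng = np.random.default_rng(4)
        h2s = []
        for between in (0.2, 1.0, 5.0):
            strain_vals = rng.normal(0, np.sqrt(between), size=30)
            samples = np.repeat(strain_vals, 2) + rng.normal(0, 1.0, size=60)
            m = make_matrix(samples[None, :], strains=[f"st{i//2}" for i in range(60)])
            h2s.append(r.heritability(m)["h2"].iloc[0])
        assert h2s[0] < h2s[1] < h2s[2]


class TestCV:
    def test_constant_protein_not_flagged(self):
        rng = np.random.default_rng(5)
        panel = rng.normal(20, 0.5, size=(50, 10))
        panel[0] = 20.0
        m = make_matrix(panel, strains=[f"st{j}" for j in range(10)])
        out = r.cv_flag(m)
        assert out.loc["p0", "cv"] == pytest.approx(0.0)
        assert not out.loc["p0", "is_highly_variable"]

    def test_outlier_protein_flagged(self):
        rng = np.random.default_rng(6)
        panel = 20.0 + rng.normal(0, 0.2, size=(100, 10))
        cv_panel = r.cv_flag(make_matrix(panel, strains=[f"st{j}" for j in range(10)]))
        target = cv_panel.attrs["mean_cv"] + 3 * cv_panel.attrs["sd_cv"]
        outlier = 20.0 + rng.normal(0, 1, size=10)
        outlier = 20.0 + (outlier - outlier.mean()) / outlier.std(ddof=0) * (target * 20.0)
        panel2 = np.vstack([panel, outlier])
        out = r.cv_flag(make_matrix(panel2, strains=[f"st{j}" for j in range(10)]))
        assert out["is_highly_variable"].iloc[-1]


class TestSexTest:
    def test_identical_sexes_give_p_one(self):
        strain_vals = np.arange(10.0)
        vals = np.repeat(strain_vals, 2)[None, :]
        m = make_matrix(vals, strains=[f"st{i//2}" for i in range(20)])
        out = r.paired_sex_test(m)
        assert np.all(out["p"] == 1.0)
        assert out.attrs["n_below"] == 0

    def test_constant_differences_handled(self):
        # M - F = 1 for every strain: zero variance of differences -> p = 1
        vals = np.array([[1.0, 0.0, 2.0, 1.0, 3.0, 2.0, 4.0, 3.0]])
        m = make_matrix(vals, strains=["a", "a", "b", "b", "c", "c", "d", "d"])
        assert r.paired_sex_test(m)["p"].iloc[0] == 1.0

    def test_planted_sex_effects_detected(self):
        rng = np.random.default_rng(7)
        n_strains, n_prot = 30, 1000
        vals = rng.normal(20, 0.3, size=(n_prot, 2 * n_strains))
        sexes = np.array(["M", "F"] * n_strains)
        vals[:10, sexes == "M"] += 0.9  # 3 residual SDs
        m = make_matrix(vals, strains=[f"st{i//2}" for i in range(2 * n_strains)],
                        sexes=list(sexes))
        out = r.paired_sex_test(m)
        assert (out["p"].iloc[:10] < 0.01).all()
        null_rate = (out["p"].iloc[10:] < 0.01).mean()
        assert null_rate < 0.03


class TestMrnaCorrelation:
    def _panel(self, shared_frac, seed, n_genes=200, n_strains=30):
        rng = np.random.default_rng(seed)
        s = rng.normal(0, 1, size=(n_genes, n_strains))
        ep = rng.normal(0, 1, size=(n_genes, n_strains))
        em = rng.normal(0, 1, size=(n_genes, n_strains))
        a = np.sqrt(shared_frac)
        b = np.sqrt(1 - shared_frac)
        prot = 20 + a * s + b * ep
        mrna = 10 + a * s + b * em
        cols = [f"st{j}" for j in range(n_strains)]
        m = make_matrix(prot, strains=cols)
        mr = pd.DataFrame(mrna, index=m.values.index, columns=cols)
        return m, mr

    def test_identical_layers_give_r_one(self):
        m, _ = self._panel(0.5, 8)
        per_gene, overall = r.mrna_protein_correlation(
            m, m.strain_means())
        assert np.allclose(per_gene.dropna(), 1.0)
        assert overall == pytest.approx(1.0)

    def test_independent_layers_give_r_zero(self):
        m, mr = self._panel(0.0, 9)
        per_gene, _ = r.mrna_protein_correlation(m, mr)
        assert abs(per_gene.mean()) < 3 / np.sqrt(len(per_gene))

    def test_half_shared_variance_gives_r_half(self):
        m, mr = self._panel(0.5, 10)
        per_gene, _ = r.mrna_protein_correlation(m, mr)
        assert per_gene.mean() == pytest.approx(0.5, abs=0.05)


def test_fold_change_from_log2():
    assert fold_change_from_log2(21.0, 20.0) == pytest.approx(2.0)
    assert fold_change_from_log2(20.0, 21.0) == pytest.approx(0.5)
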