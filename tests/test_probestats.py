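import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tilemeth as tm
from tilemeth.errors import DomainError


def _matrix(values, n_a, n_b):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])], columns=cols)


def _design(matrix):
    return tm.GroupDesign.from_mapping(
        {c: ("A" if c.startswith("A") else "B") for c in matrix.columns}
    )


def _limma_fixture():
    """30-probe, 4 vs 6 matrix with heteroscedastic probes and 5 shifted ones."""
    rng = np.random.default_rng(20240817)
    n_probes, n_a, n_b = 30, 4, 6
    base = rng.normal(0, 1, (n_probes, n_a + n_b))
    sigma = np.exp(rng.normal(-1.0, 0.5, n_probes))
    mat = base * sigma[:, None]
    mat[:5, :n_a] += 0.8
    return _matrix(mat, n_a, n_b)


class TestEBHyperparameters:
    def test_equal_variances_give_infinite_prior_df(self):
        eb = tm.fit_eb_hyperparameters([0.5, 0.5, 0.5, 0.5], 10)
        assert math.isinf(eb.d0)
        assert eb.s0_sq == pytest.approx(0.5)

    def test_two_equal_variances(self):
        eb = tm.fit_eb_hyperparameters([1.0, 1.0], 4)
        assert math.isinf(eb.d0)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DomainError):
            tm.fit_eb_hyperparameters([0.0, 0.0, 0.0], 5)

    def test_parameter_recovery(self):
        """Variances simulated from the hierarchical model: prior scaled
        inverse chi-square (d0=4, s0^2=0.04), sampling chi-square with 18 df."""
        rng = np.random.default_rng(7)
        d0, s0_sq, df, n = 4.0, 0.04, 18, 2000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        eb = tm.fit_eb_hyperparameters(s2, df)
        assert 2.8 <= eb.d0 <= 5.6
        assert abs(eb.s0_sq - s0_sq) <= 0.25 * s0_sq


class TestModeratedT:
    def test_matches_independent_limma_reference(self):
        """Agreement with the limma implementation on a frozen fixture.

        Reference values were computed with limma 3.58.1
        (lmFit + eBayes on the identical matrix).
        """
        matrix = _limma_fixture()
        table, eb = tm.moderated_t(matrix, _design(matrix))
        assert eb.d0 == pytest.approx(2.852900289, rel=1e-8)
        assert eb.s0_sq == pytest.approx(0.07960096812, rel=1e-8)
        ref = {
            "p0": (1.2442803171499, 5.123264766307, 0.000346224359212),
            "p7": (0.0698243039989, 0.606613164918, 0.556584037668),
            "p29": (0.0938443577333, 0.709593100419, 0.492920219306),
        }
        table = table.set_index("probe_id")
        for probe, (lfc, t, p) in ref.items():
            assert table.loc[probe, "lfc"] == pytest.approx(lfc, rel=1e-8)
            assert table.loc[probe, "t_mod"] == pytest.approx(t, rel=1e-8)
            assert table.loc[probe, "p_t"] == pytest.approx(p, rel=1e-8)

    def test_identical_group_means_give_zero_t(self):
        matrix = _matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], 3, 3)
        table, _ = tm.moderated_t(matrix, _design(matrix), eb=tm.EBHyper(1.0, 1.0))
        assert table["t_mod"].iloc[0] == pytest.approx(0.0)
        assert table["p_t"].iloc[0] == pytest.approx(1.0)

    def test_zero_prior_df_recovers_ordinary_pooled_t(self):
        matrix = _matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], 3, 3)
        table, _ = tm.moderated_t(matrix, _design(matrix), eb=tm.EBHyper(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert table["t_mod"].iloc[0] == pytest.approx(t_ref)
        assert table["p_t"].iloc[0] == pytest.approx(p_ref)

    def test_group_swap_negates_t_keeps_p(self):
        matrix = _limma_fixture()
        design = _design(matrix)
        swapped = tm.GroupDesign.from_mapping(
            {c: ("B" if c.startswith("A") else "A") for c in matrix.columns}
        )
        t1, _ = tm.moderated_t(matrix, design)
        t2, _ = tm.moderated_t(matrix, swapped)
        np.testing.assert_allclose(t2["lfc"], -t1["lfc"])
        np.testing.assert_allclose(t2["t_mod"], -t1["t_mod"])
        np.testing.assert_allclose(t2["p_t"], t1["p_t"])

    def test_joint_location_shift_leaves_t_unchanged(self):
        matrix = _limma_fixture()
        design = _design(matrix)
        t1, _ = tm.moderated_t(matrix, design)
        t2, _ = tm.moderated_t(matrix + 7.5, design)
        np.testing.assert_allclose(t2["t_mod"], t1["t_mod"], atol=1e-10)
        np.testing.assert_allclose(t2["lfc"], t1["lfc"], atol=1e-10)

    def test_moderation_lies_between_ordinary_and_prior_only(self):
        matrix = _limma_fixture()
        design = _design(matrix)
        table, eb = tm.moderated_t(matrix, design)
        ordinary, _ = tm.moderated_t(matrix, design, eb=tm.EBHyper(0.0, eb.s0_sq))
        prior_only, _ = tm.moderated_t(matrix, design, eb=tm.EBHyper(math.inf, eb.s0_sq))
        lo = np.minimum(ordinary["t_mod"].abs(), prior_only["t_mod"].abs())
        hi = np.maximum(ordinary["t_mod"].abs(), prior_only["t_mod"].abs())
        assert ((table["t_mod"].abs() >= lo - 1e-9) & (table["t_mod"].abs() <= hi + 1e-9)).all()

    def test_small_group_rejected(self):
        matrix = _matrix([[1.0, 2.0, 3.0]], 1, 2)
        with pytest.raises(DomainError):
            tm.moderated_t(matrix, _design(matrix))

    def test_null_p_values_uniform(self):
        """On pure-noise data the moderated-t p-values are uniform on [0,1]."""
        rng = np.random.default_rng(99)
        matrix = _matrix(rng.normal(0, 0.4, (2000, 20)), 8, 12)
        table, _ = tm.moderated_t(matrix, _design(matrix))
        ks = stats.kstest(table["p_t"], "uniform").statistic
        assert ks < 0.05


class TestPhenotypeCorrelation:
    def _phenotype(self, subjects, levels, analyte="IL6"):
        return pd.DataFrame({"subject_id": subjects, "analyte": analyte, "level": levels})

    def test_exact_linear_relation(self):
        pheno = self._phenotype([f"A{i}" for i in range(5)], [1.0, 2.0, 3.0, 4.0, 5.0])
        matrix = _matrix([[2 * v + 1 for v in [1, 2, 3, 4, 5]]], 5, 0)
        out = tm.probe_phenotype_correlation(matrix, pheno, "IL6")
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p_r"].iloc[0] == pytest.approx(0.0)

    def test_exact_negative_relation(self):
        pheno = self._phenotype([f"A{i}" for i in range(4)], [1.0, 2.0, 3.0, 4.0])
        matrix = _matrix([[-1.0, -2.0, -3.0, -4.0]], 4, 0)
        out = tm.probe_phenotype_correlation(matrix, pheno, "IL6")
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        """x=(1,2,3,4) vs y=(2,1,4,3): r=0.6; t-transform p with 2 df ~= 0.4."""
        pheno = self._phenotype([f"A{i}" for i in range(4)], [1.0, 2.0, 3.0, 4.0])
        matrix = _matrix([[2.0, 1.0, 4.0, 3.0]], 4, 0)
        out = tm.probe_phenotype_correlation(matrix, pheno, "IL6")
        assert out["r"].iloc[0] == pytest.approx(0.6)
        assert out["p_r"].iloc[0] == pytest.approx(0.4, abs=0.01)
        r_ref, p_ref = stats.pearsonr([2, 1, 4, 3], [1, 2, 3, 4])
        assert out["p_r"].iloc[0] == pytest.approx(p_ref)

    def test_missing_phenotype_excluded_pairwise(self):
        pheno = self._phenotype(
            [f"A{i}" for i in range(5)], [1.0, 2.0, np.nan, 4.0, 5.0]
        )
        matrix = _matrix([[1.0, 2.0, 99.0, 4.0, 5.0]], 5, 0)
        out = tm.probe_phenotype_correlation(matrix, pheno, "IL6")
        assert out["n"].iloc[0] == 4
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_phenotype_rejected(self):
        pheno = self._phenotype([f"A{i}" for i in range(4)], [2.0] * 4)
        matrix = _matrix([[1.0, 2.0, 3.0, 4.0]], 4, 0)
        with pytest.raises(DomainError, match="constant"):
            tm.probe_phenotype_correlation(matrix, pheno, "IL6")

    def test_too_few_subjects_rejected(self):
        pheno = self._phenotype(["A0", "A1"], [1.0, 2.0])
        matrix = _matrix([[1.0, 2.0]], 2, 0)
        with pytest.raises(DomainError, match=">= 3"):
            tm.probe_phenotype_correlation(matrix, pheno, "IL6")
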