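"""Mixed-model normalization (EM-REML) and differential expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pubernet import (
    ExpressionMatrix,
    SimulationConfig,
    average_expression_difference,
    fit_normalization,
    fold_change,
    generate_expression,
)
from pubernet.normalize import test_de as run_de_test
from pubernet.datasets import top_de_transcripts


def build_study(y, libs, groups):
    genes = [f"g{i}" for i in range(y.shape[0])]
    samples = [f"s{j}" for j in range(y.shape[1])]
    expr = ExpressionMatrix(
        pd.DataFrame(y, index=genes, columns=samples), scale="log2"
    )
    meta = pd.DataFrame(
        {"animal": [f"a{j}" for j in range(len(samples))],
         "tissue": "muscle", "library": libs, "group": groups},
        index=samples,
    )
    return expr, meta


def reml_oracle(y, lib_indicator):
    """Direct restricted-likelihood maximization for the one-random-effect
    model (gene effect + residual, library fixed) by a generic optimizer."""
    n_g, n_s = y.shape
    Y = y.ravel()
    X = np.column_stack(
        [np.ones(n_g * n_s), np.tile(lib_indicator.astype(float), n_g)]
    )
    Z = np.kron(np.eye(n_g), np.ones((n_s, 1)))
    ZZt = Z @ Z.T

    def negremll(theta):
        s2g, s2e = np.exp(theta)
        V = s2g * ZZt + s2e * np.eye(n_g * n_s)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        b = np.linalg.solve(XtViX, X.T @ Vi @ Y)
        r = Y - X @ b
        _, ld = np.linalg.slogdet(V)
        _, ld2 = np.linalg.slogdet(XtViX)
        return 0.5 * (ld + ld2 + r @ Vi @ r)

    res = optimize.minimize(
        negremll, np.log([1.0, 0.5]), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    s2g, s2e = np.exp(res.x)
    V = s2g * ZZt + s2e * np.eye(n_g * n_s)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ Y)
    return s2g, s2e, b[1]


class TestFitNormalization:
    def test_single_library_is_identity(self, rng):
        y = rng.standard_normal((12, 6)) + 5
        expr, meta = build_study(y, ["L1"] * 6, ["PRE"] * 3 + ["POST"] * 3)
        adjusted, spec = fit_normalization(expr, meta)
        pd.testing.assert_frame_equal(adjusted.data, expr.data)
        assert spec.library_dropped

    def test_confounded_library_dropped_with_warning(self, rng):
        y = rng.standard_normal((10, 6)) + 4
        expr, meta = build_study(
            y, ["L1"] * 3 + ["L2"] * 3, ["PRE"] * 3 + ["POST"] * 3
        )
        with pytest.warns(UserWarning, match="confounded"):
            adjusted, spec = fit_normalization(expr, meta)
        assert spec.library_dropped
        pd.testing.assert_frame_equal(adjusted.data, expr.data)

    def test_planted_offset_matches_reml_oracle(self, rng):
        base = rng.uniform(2, 8, size=40)
        y = base[:, None] + 0.4 * rng.standard_normal((40, 8))
        libs = ["L1", "L2"] * 4  # library crosses groups
        delta = 1.5
        lib2 = np.array([l == "L2" for l in libs])
        y = y + delta * lib2[None, :]
        expr, meta = build_study(y, libs, ["PRE"] * 4 + ["POST"] * 4)
        adjusted, spec = fit_normalization(expr, meta)

        s2g_o, s2e_o, beta_o = reml_oracle(y, lib2)
        assert spec.sigma2_gene == pytest.approx(s2g_o, rel=1e-4)
        assert spec.sigma2_residual == pytest.approx(s2e_o, rel=1e-4)
        assert spec.library_effects["L2"] == pytest.approx(beta_o, rel=1e-4)
        # adjusted matrix = observation minus the fitted library effect
        expected = y - spec.library_effects["L2"] * lib2[None, :]
        assert np.allclose(adjusted.data.to_numpy(), expected, atol=1e-10)

    def test_gene_variance_vanishes_for_pure_noise(self):
        """With no gene-specific level differences the gene variance
        component collapses toward zero (averaged over simulations)."""
        est = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            y = 0.3 * r.standard_normal((25, 6))  # common mean, no gene effect
            libs = ["L1", "L2"] * 3
            expr, meta = build_study(y, libs, ["PRE"] * 3 + ["POST"] * 3)
            _, spec = fit_normalization(expr, meta)
            est.append(spec.sigma2_gene)
        # true sigma2_gene = 0; residual variance is 0.09
        assert np.mean(est) < 0.02

    def test_components_are_non_negative(self, default_study):
        _, expr, meta, _ = default_study
        _, spec = fit_normalization(expr, meta)
        assert spec.sigma2_gene >= 0 and spec.sigma2_residual >= 0
        assert spec.converged


class TestFoldChangeArithmetic:
    def test_published_pairs_reproduce_printed_values(self):
        """FC and average-difference columns of the study's top-DE table
        are reproduced from the printed POST/PRE means (one printed
        difference reflects the source's rounding of unrounded means:
        8.59 - 3.88 = 4.71 exactly, printed as 4.70)."""
        table = top_de_transcripts()
        for gid, row in table.iterrows():
            fc = round(fold_change(row.post_mean, row.pre_mean), 2)
            assert fc == row.printed_fc, gid
            diff = round(
                average_expression_difference(row.post_mean, row.pre_mean), 2
            )
            assert abs(diff - row.printed_diff) <= 0.01 + 1e-12, gid

    def test_identity_cases(self):
        assert fold_change(3.3, 3.3) == pytest.approx(1.0)
        assert average_expression_difference(3.3, 3.3) == 0.0
        assert np.isnan(fold_change(1.0, 0.0))

    def test_antisymmetry_under_group_swap(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.5, 10, size=2)
            assert average_expression_difference(a, b) == pytest.approx(
                -average_expression_difference(b, a)
            )
            assert fold_change(a, b) == pytest.approx(1.0 / fold_change(b, a))


class TestTestDe:
    def groups(self, n1=5, n2=6):
        idx = [f"s{j}" for j in range(n1 + n2)]
        return pd.Series(["PRE"] * n1 + ["POST"] * n2, index=idx)

    def test_identical_groups_null_result(self):
        y = np.tile(np.arange(8, dtype=float)[:, None], (1, 11))
        expr = ExpressionMatrix(
            pd.DataFrame(y, index=[f"g{i}" for i in range(8)],
                         columns=[f"s{j}" for j in range(11)]),
            scale="log2",
        )
        de = run_de_test(expr, self.groups(), alpha=0.05)
        assert (de["avg_diff"] == 0).all()
        assert (de["fc"].dropna() == 1.0).all()
        assert (de["p_value"] > 0.99).all()
        assert not de["dex_flag"].any()

    def test_counts_conservation_up_plus_down(self, default_study):
        _, expr, meta, _ = default_study
        de = run_de_test(expr, meta["group"], alpha=0.05)
        n_up = (de["dex_flag"] & (de["direction"] == "up")).sum()
        n_down = (de["dex_flag"] & (de["direction"] == "down")).sum()
        assert n_up + n_down == de["dex_flag"].sum()
        # avg_diff column is exactly post - pre
        assert np.allclose(de["avg_diff"], de["post_mean"] - de["pre_mean"])

    def test_group_swap_negates_difference(self, default_study):
        _, expr, meta, _ = default_study
        g = meta["group"]
        swapped = g.map({"PRE": "POST", "POST": "PRE"})
        de = run_de_test(expr, g)
        de_sw = run_de_test(expr, swapped)
        assert np.allclose(de["avg_diff"], -de_sw["avg_diff"])
        assert np.allclose(de["p_value"], de_sw["p_value"])

    def test_planted_truth_is_recovered(self, default_study):
        _, expr, meta, truth = default_study
        de = run_de_test(expr, meta["group"], alpha=0.05)
        assert de.loc[truth.de_gene_ids, "dex_flag"].mean() > 0.9
        assert (de.loc[truth.de_gene_ids, "direction"] == "up").all()

    def test_single_sample_group_rejected(self):
        y = np.random.default_rng(0).standard_normal((5, 3))
        expr = ExpressionMatrix(
            pd.DataFrame(y, index=[f"g{i}" for i in range(5)],
                         columns=["s0", "s1", "s2"]),
            scale="log2",
        )
        groups = pd.Series(["PRE", "POST", "POST"], index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="2 samples"):
            run_de_test(expr, groups)
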