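"""Phylogenetic GLS: covariance construction, fitting, and lambda estimation."""

import numpy as np
import pandas as pd
import pytest

import wingplan as wp
from wingplan.pgls import InvalidTreeError, aicc_from_loglik
from wingplan.synthetic import simulate_lambda_brownian

from conftest import ULTRAMETRIC_NEWICK


class TestPhyloVCV:
    def test_two_tip_star(self):
        V, labels = wp.phylo_vcv(wp.Phylogeny.from_newick("(A:1,B:1);"))
        assert labels == ["A", "B"]
        np.testing.assert_allclose(V, np.eye(2))

    def test_three_tip_hand_computed(self):
        V, labels = wp.phylo_vcv(wp.Phylogeny.from_newick("((A:1,B:1):1,C:2);"))
        i = {l: k for k, l in enumerate(labels)}
        assert V[i["A"], i["A"]] == pytest.approx(2.0)
        assert V[i["A"], i["B"]] == pytest.approx(1.0)
        assert V[i["A"], i["C"]] == pytest.approx(0.0)
        np.testing.assert_allclose(V, V.T)

    def test_ultrametric_tree_has_constant_diagonal(self, ultrametric_tree):
        V, _ = wp.phylo_vcv(ultrametric_tree)
        np.testing.assert_allclose(np.diag(V), 3.0)
        # off-diagonal bounded by the diagonal
        assert (V - np.diag(np.diag(V)) <= 3.0).all()

    def test_negative_branch_length_rejected(self):
        with pytest.raises(InvalidTreeError):
            wp.Phylogeny.from_newick("((A:1,B:-0.5):1,C:2);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(InvalidTreeError):
            wp.Phylogeny.from_newick("((A:1,A:1):1,C:2);")


class TestLambdaTransform:
    def test_identity_at_one(self):
        V = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(wp.lambda_transform(V, 1.0), V)

    def test_diagonal_at_zero(self):
        V = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(wp.lambda_transform(V, 0.0), np.diag([2.0, 2.0]))

    def test_half(self):
        V = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert wp.lambda_transform(V, 0.5)[0, 1] == 0.5

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_domain(self, lam):
        with pytest.raises(ValueError):
            wp.lambda_transform(np.eye(2), lam)


class TestGLSFit:
    def test_exact_through_origin_fit(self):
        res = wp.gls_fit([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], np.eye(3),
                         through_origin=True)
        assert res.params[0] == pytest.approx(2.0, abs=1e-12)
        assert res.rss == pytest.approx(0.0, abs=1e-20)
        assert res.rsquared == pytest.approx(1.0)

    def test_identity_vcv_matches_ols_normal_equations(self, rng):
        # brute-force OLS oracle: beta = (X'X)^-1 X'y, SE from sigma2 (X'X)^-1
        n = 25
        x = rng.normal(2.0, 1.0, n)
        y = 1.7 * x + 0.5 + rng.normal(0, 0.4, n)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 2)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        res = wp.gls_fit(x, y, np.eye(n))
        np.testing.assert_allclose(res.params, beta, rtol=1e-10)
        np.testing.assert_allclose(res.bse, se, rtol=1e-10)

    def test_scaled_identity_reproduces_ols_estimates(self, rng):
        n = 15
        x = rng.normal(size=n)
        y = 0.9 * x + rng.normal(0, 0.2, n)
        r1 = wp.gls_fit(x, y, np.eye(n), through_origin=True)
        r2 = wp.gls_fit(x, y, 7.3 * np.eye(n), through_origin=True)
        assert r2.params[0] == pytest.approx(r1.params[0], rel=1e-10)
        assert r2.bse[0] == pytest.approx(r1.bse[0], rel=1e-10)

    def test_tip_permutation_invariance(self, ultrametric_tree, rng):
        V, labels = wp.phylo_vcv(ultrametric_tree)
        n = len(labels)
        x = rng.normal(2, 1, n)
        y = 1.2 * x + rng.normal(0, 0.3, n)
        base = wp.gls_fit(x, y, V, lam=0.7)
        perm = rng.permutation(n)
        permuted = wp.gls_fit(x[perm], y[perm], V[np.ix_(perm, perm)], lam=0.7)
        np.testing.assert_allclose(permuted.params, base.params, rtol=1e-10)
        np.testing.assert_allclose(permuted.bse, base.bse, rtol=1e-10)
        assert permuted.llf == pytest.approx(base.llf, rel=1e-10)
        assert permuted.rsquared == pytest.approx(base.rsquared, rel=1e-10)

    def test_collinear_design_reported(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        with pytest.raises(np.linalg.LinAlgError, match="collinear|rank"):
            wp.PhylogeneticGLS([1, 2, 3, 4], x, vcv=np.eye(4),
                               through_origin=True).fit(lam=1.0)


class TestAgainstReferenceImplementation:
    """Frozen reference fits from nlme::gls with an ape::corPagel structure.

    Fixture: the 8-tip ultrametric tree, x drawn uniform, y = 0.8x + 1 +
    lambda-Brownian noise (all values frozen below); reference numbers
    computed once with R 4.3 (nlme 3.1, ape 5.8) on this exact fixture.
    On an ultrametric tree the correlation-matrix convention of nlme
    coincides with the covariance convention used here.
    """

    x = [4.096, 2.756, 4.434, 3.789, 1.377, 4.902, 4.045, 4.144]
    y = [4.278, 3.456, 4.3371, 3.2208, 1.6703, 3.8883, 4.0579, 5.2663]
    labels = list("ABCDEFGH")

    def model(self, through_origin=False):
        phy = wp.Phylogeny.from_newick(ULTRAMETRIC_NEWICK)
        return wp.PhylogeneticGLS(
            self.y, self.x, tree=phy, tip_labels=self.labels,
            through_origin=through_origin,
        )

    def test_fixed_lambda_coefficients_and_loglik(self):
        res = self.model().fit(lam=0.5)
        assert res.params[0] == pytest.approx(1.0799935361, abs=1e-9)
        assert res.params[1] == pytest.approx(0.7306835235, abs=1e-9)
        assert res.bse[0] == pytest.approx(0.8208668622, abs=1e-9)
        assert res.bse[1] == pytest.approx(0.2033884200, abs=1e-9)
        assert res.llf == pytest.approx(-7.2849671170, abs=1e-8)

    def test_lambda_likelihood_profile(self):
        reference = {
            0.0: -6.9672660874,
            0.25: -7.1631498755,
            0.5: -7.2849671170,
            0.75: -7.3433494484,
            1.0: -7.3219589968,
        }
        m = self.model()
        for lam, llf in reference.items():
            assert m.loglik(lam) == pytest.approx(llf, abs=1e-8)

    def test_through_origin_fit(self):
        res = self.model(through_origin=True).fit(lam=1.0)
        assert res.params[0] == pytest.approx(0.9167833985, abs=1e-9)
        assert res.bse[0] == pytest.approx(0.1042083625, abs=1e-9)
        assert res.llf == pytest.approx(-8.8128293807, abs=1e-8)

    def test_reml_loglik(self):
        assert self.model().loglik(0.5, reml=True) == pytest.approx(
            -8.3210429607, abs=1e-8
        )


class TestLambdaML:
    def test_ml_lambda_beats_grid(self, ultrametric_tree):
        traits = simulate_lambda_brownian(ultrametric_tree, 0.6, 1.0, seed=3)
        y = traits.iloc[0].to_numpy()
        x = np.arange(len(y), dtype=float) + 1.0
        m = wp.PhylogeneticGLS(y, x, tree=ultrametric_tree,
                               tip_labels=list(traits.columns))
        res = m.fit()
        grid = np.linspace(0, 1, 11)
        assert all(res.llf >= m.loglik(g) - 1e-9 for g in grid)

    def test_aicc_formula(self):
        assert aicc_from_loglik(-50.1, 2, 41) == pytest.approx(
            2 * 50.1 + 4 + 2 * 2 * 3 / (41 - 3)
        )
        # one extra parameter changes AICc by the penalty arithmetic only
        ll = -12.0
        d = aicc_from_loglik(ll, 4, 30) - aicc_from_loglik(ll, 3, 30)
        assert d == pytest.approx((2 * 4 + 40 / 25) - (2 * 3 + 24 / 26))

    def test_lambda_recovery_endpoints(self):
        # deep balanced tree: strong signal separates lambda 0 from 1
        tips = 32
        newick = _balanced_newick(tips, depth=1.0)
        phy = wp.Phylogeny.from_newick(newick)
        hits0 = hits1 = 0
        n_rep = 30
        t0 = simulate_lambda_brownian(phy, 0.0, 1.0, seed=11, n_replicates=n_rep)
        t1 = simulate_lambda_brownian(phy, 1.0, 1.0, seed=12, n_replicates=n_rep)
        x = np.ones(tips)  # intercept-only response model
        for r in range(n_rep):
            lam0 = wp.PhylogeneticGLS(
                t0.iloc[r].to_numpy(), x, tree=phy,
                tip_labels=list(t0.columns), through_origin=True,
            ).fit().lam
            lam1 = wp.PhylogeneticGLS(
                t1.iloc[r].to_numpy(), x, tree=phy,
                tip_labels=list(t1.columns), through_origin=True,
            ).fit().lam
            hits0 += lam0 < 0.1
            hits1 += lam1 > 0.9
        assert hits0 > n_rep / 2
        assert hits1 > n_rep / 2


def _balanced_newick(n_tips, depth):
    """Balanced binary tree with equal splits, total depth as given."""
    def build(labels, d):
        if len(labels) == 1:
            return f"{labels[0]}:{d}"
        half = len(labels) // 2
        step = d / 2
        return f"({build(labels[:half], step)},{build(labels[half:], step)}):{d / 2}"

    labels = [f"t{i}" for i in range(n_tips)]
    half = n_tips // 2
    return (
        f"({build(labels[:half], depth / 2)},{build(labels[half:], depth / 2)});"
    )


class TestResultsObject:
    def test_summary_and_dict(self, ultrametric_tree, rng):
        V, labels = wp.phylo_vcv(ultrametric_tree)
        x = rng.normal(2, 1, len(labels))
        y = 1.1 * x + rng.normal(0, 0.1, len(labels))
        res = wp.gls_fit(x, y, V, through_origin=True, lam=1.0)
        text = res.summary()
        assert "lambda" in text and "AICc" in text
        d = res.to_dict()
        assert d["n"] == len(labels)
        assert d["through_origin"] is True
        assert "coef_x1" in d and "se_x1" in d

    def test_from_dataframe_name_normalisation(self, ultrametric_tree):
        df = pd.DataFrame(
            {
                "species": ["A", "B", "C", "D", "E", "F", "G", "H", "Nota tip"],
                "x": np.arange(9, dtype=float) + 1,
                "y": 2.0 * (np.arange(9) + 1),
            }
        )
        m = wp.PhylogeneticGLS.from_dataframe(
            df, y="y", x="x", tree=ultrametric_tree, through_origin=True
        )
        assert m.nobs == 8
        assert m.dropped_species == ["Nota tip"]
        res = m.fit(lam=1.0)
        assert res.params[0] == pytest.approx(2.0, abs=1e-10)
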