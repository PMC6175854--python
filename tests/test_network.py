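import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import precisenet as pn
from precisenet.io import AnalysisConfig
from precisenet.network import (
    NodeFit,
    RegressionProblem,
    build_integrated_network,
    log_marginal_likelihood,
    model_posterior,
)

from conftest import flat_prior, make_expression


def build_problem(y, Z, weights=None, g=None, names=None):
    """Assemble a RegressionProblem directly from arrays (protein kinds)."""
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    k = Z.shape[1]
    names = names or [f"c{j}" for j in range(k)]
    cols = [(Z[:, j] - Z[:, j].mean()) / Z[:, j].std() for j in range(k)]
    return RegressionProblem(
        target="T",
        y=y - y.mean(),
        candidates=names,
        kinds=["protein"] * k,
        prior_w=np.asarray(weights if weights is not None else [0.5] * k, dtype=float),
        Z=np.column_stack(cols) if k else np.zeros((len(y), 0)),
        g=float(g if g is not None else len(y)),
        sample_ids=[f"s{i}" for i in range(len(y))],
    )


class TestUpstreamCovariates:
    def _mats(self, mrna_vals, methyl_vals, mirna_vals=None):
        mrna = make_expression(mrna_vals, features=["G"], platform="mrna")
        methyl = make_expression(methyl_vals, features=["G"], platform="methylation")
        mirna = None
        if mirna_vals is not None:
            mirna = make_expression(
                mirna_vals,
                features=[f"G_MIR{i}" for i in range(mirna_vals.shape[1])],
                platform="mirna",
            )
        return mrna, methyl, mirna

    def test_orthogonal_methylation_puts_everything_in_independent(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        m = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x
        mrna, methyl, _ = self._mats(x[:, None], m[:, None])
        covs = pn.construct_upstream_covariates(mrna, methyl, None, "G")
        mod = next(c for c in covs if c.kind == "mrna-modulated")
        ind = next(c for c in covs if c.kind == "mrna-independent")
        np.testing.assert_allclose(mod.values - mod.values.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(ind.values, x - x.mean(), atol=1e-12)

    def test_proportional_mrna_leaves_zero_independent(self):
        m = np.array([0.5, 1.5, -1.0, 2.0])
        mrna, methyl, _ = self._mats((2.0 * m)[:, None], m[:, None])
        covs = pn.construct_upstream_covariates(mrna, methyl, None, "G")
        ind = next(c for c in covs if c.kind == "mrna-independent")
        np.testing.assert_allclose(ind.values, 0.0, atol=1e-10)

    def test_two_mirnas_give_k_of_four(self):
        rng = np.random.default_rng(0)
        mrna, methyl, mirna = self._mats(
            rng.standard_normal((10, 1)),
            rng.standard_normal((10, 1)),
            rng.standard_normal((10, 2)),
        )
        covs = pn.construct_upstream_covariates(
            mrna, methyl, mirna, "G", {"G": ["G_MIR0", "G_MIR1"]}
        )
        assert len(covs) == 4

    def test_gene_missing_from_mrna_falls_back_to_mirnas(self):
        rng = np.random.default_rng(0)
        mirna = make_expression(
            rng.standard_normal((10, 1)), features=["G_MIR0"], platform="mirna"
        )
        covs = pn.construct_upstream_covariates(
            None, None, mirna, "G", {"G": ["G_MIR0"]}
        )
        assert [c.kind for c in covs] == ["mirna"]
        assert pn.construct_upstream_covariates(None, None, None, "G", {}) == []


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    n = 20
    Z = rng.standard_normal((n, 2))
    y = 0.8 * Z[:, 0] + 0.7 * rng.standard_normal(n)
    return build_problem(y, Z, g=20.0)


class TestLogMarginalLikelihood:

    def test_empty_model_is_reference(self, toy):
        lm = log_marginal_likelihood(toy, ())
        n = toy.n
        expected = (
            -0.5 * n * math.log(2 * math.pi)
            + math.lgamma(n / 2)
            + (n / 2 - 1) * math.log(2)
            - 0.5 * n * math.log(toy._yty)
        )
        assert lm == pytest.approx(expected)

    def test_bayes_factor_invariant_to_response_scaling(self, toy):
        bf = log_marginal_likelihood(toy, (0,)) - log_marginal_likelihood(toy, ())
        scaled = build_problem(3.7 * (toy.y + 0.0), toy.Z, g=toy.g)
        bf_scaled = log_marginal_likelihood(scaled, (0,)) - log_marginal_likelihood(
            scaled, ()
        )
        assert bf == pytest.approx(bf_scaled, rel=1e-10)

    def test_matches_numerical_integration(self, toy):
        """Closed form vs adaptive quadrature of the (beta, sigma) integral."""
        lm = log_marginal_likelihood(toy, (0, 1))
        Z, y, g, n = toy.Z, toy.y, toy.g, toy.n
        cov = g * np.linalg.inv(Z.T @ Z)

        def integrand(b1, b2, s):
            beta = np.array([b1, b2])
            resid = y - Z @ beta
            loglik = -0.5 * resid @ resid / s**2 - n * math.log(
                s * math.sqrt(2 * math.pi)
            )
            prior = stats.multivariate_normal.pdf(beta, cov=s**2 * cov)
            return math.exp(loglik) * prior / s

        val, _ = integrate.tplquad(
            lambda s, b2, b1: integrand(b1, b2, s),
            -4, 4, -4, 4, 0.2, 4.0,
            epsabs=1e-12, epsrel=1e-7,
        )
        assert abs(lm - math.log(val)) / abs(lm) < 1e-3

    def test_oversized_model_rejected(self):
        rng = np.random.default_rng(1)
        prob = build_problem(rng.standard_normal(5), rng.standard_normal((5, 4)))
        with pytest.raises(ValueError):
            log_marginal_likelihood(prob, (0, 1, 2, 3))

    def test_collinear_model_handled(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        y = x + 0.1 * rng.standard_normal(30)
        prob = build_problem(y, np.column_stack([x, x]))  # exact duplicate
        lm = log_marginal_likelihood(prob, (0, 1))
        assert np.isfinite(lm)


class TestModelPosterior:
    def test_enumeration_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((40, 4))
        y = Z[:, 0] - 0.5 * Z[:, 2] + 0.5 * rng.standard_normal(40)
        fit = model_posterior(build_problem(y, Z), AnalysisConfig())
        assert fit.method == "enumeration"
        assert fit.model_probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_mandatory_candidate_has_pip_one(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        fit = model_posterior(
            build_problem(y, Z, weights=[1.0, 0.5, 0.5]), AnalysisConfig()
        )
        assert fit.pips[0] == pytest.approx(1.0)

    def test_pip_exactly_half_excluded_from_mpm(self):
        fit = NodeFit(
            target="T",
            candidates=["a"],
            kinds=["protein"],
            pips=np.array([0.5]),
            mpm=[c for c, p in zip(["a"], [0.5]) if p > 0.5],
            coefficients={},
            sigma2=1.0,
            method="enumeration",
        )
        assert fit.mpm == []

    def test_pips_invariant_to_candidate_ordering_with_flat_prior(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((50, 5))
        y = Z[:, 1] + 0.4 * rng.standard_normal(50)
        base = model_posterior(build_problem(y, Z), AnalysisConfig())
        perm = [3, 1, 4, 0, 2]
        flipped = model_posterior(build_problem(y, Z[:, perm]), AnalysisConfig())
        np.testing.assert_allclose(base.pips[perm], flipped.pips, atol=1e-10)

    def test_zero_candidates_gives_empty_fit(self):
        fit = model_posterior(
            build_problem(np.random.default_rng(0).standard_normal(20), np.zeros((20, 0))),
            AnalysisConfig(),
        )
        assert fit.mpm == [] and fit.pips.size == 0

    def test_mc3_matches_enumeration_on_small_problem(self):
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((60, 6))
        y = Z[:, 0] - 0.8 * Z[:, 3] + 0.5 * rng.standard_normal(60)
        prob = build_problem(y, Z)
        exact = model_posterior(prob, AnalysisConfig(enumeration_limit=6))
        sampled = model_posterior(
            prob,
            AnalysisConfig(enumeration_limit=1, mcmc_iters=30_000, seed=8),
        )
        assert sampled.method == "mc3"
        assert np.abs(exact.pips - sampled.pips).max() < 0.03

    def test_prior_monotonicity_for_true_regulator(self):
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((50, 4))
        y = 0.8 * Z[:, 0] + 0.6 * rng.standard_normal(50)
        pips = []
        for w0 in (0.2, 0.5, 0.9):
            fit = model_posterior(
                build_problem(y, Z, weights=[w0, 0.5, 0.5, 0.5]), AnalysisConfig()
            )
            pips.append(fit.pips[0])
        assert pips[0] <= pips[1] <= pips[2]


class TestIntegratedNetwork:
    def _fit(self, target, candidates, mpm, pips=None):
        pips = pips if pips is not None else [0.9 if c in mpm else 0.1 for c in candidates]
        return NodeFit(
            target=target,
            candidates=candidates,
            kinds=["protein"] * len(candidates),
            pips=np.asarray(pips, dtype=float),
            mpm=list(mpm),
            coefficients={},
            sigma2=1.0,
            method="enumeration",
        )

    def test_mutual_selection_becomes_correlative(self):
        fits = {
            "A": self._fit("A", ["B"], ["B"]),
            "B": self._fit("B", ["A"], ["A"]),
        }
        net = build_integrated_network(fits, proteins=["A", "B"])
        assert len(net.protein_edges) == 1
        edge = net.protein_edges[0]
        assert edge.kind == "correlative"
        assert net.out_degree == {"A": 1, "B": 1}

    def test_one_way_selection_becomes_regulatory(self):
        fits = {
            "A": self._fit("A", ["B"], []),
            "B": self._fit("B", ["A"], ["A"]),
        }
        net = build_integrated_network(fits, proteins=["A", "B"])
        (edge,) = net.protein_edges
        assert (edge.src, edge.dst, edge.kind) == ("A", "B", "regulatory")
        assert net.out_degree == {"A": 1, "B": 0}

    def test_empty_mpms_give_empty_network(self):
        fits = {p: self._fit(p, [q for q in "ABC" if q != p], []) for p in "ABC"}
        net = build_integrated_network(fits, proteins=list("ABC"))
        assert net.protein_edges == []
        assert all(c == 0 for c in net.out_degree.values())

    def test_correlative_edge_stores_max_pip_and_reverse(self):
        fits = {
            "A": self._fit("A", ["B"], ["B"], pips=[0.7]),
            "B": self._fit("B", ["A"], ["A"], pips=[0.95]),
        }
        net = build_integrated_network(fits, proteins=["A", "B"])
        (edge,) = net.protein_edges
        assert edge.pip == pytest.approx(0.95)
        assert edge.pip_reverse is not None

    def test_json_round_trip(self, small_fit):
        net = small_fit.network
        back = pn.IntegratedNetwork.from_json_dict(net.to_json_dict())
        assert back.proteins == net.proteins
        assert {(e.src, e.dst, e.kind) for e in back.protein_edges} == {
            (e.src, e.dst, e.kind) for e in net.protein_edges
        }
        assert back.out_degree == net.out_degree


def test_fit_pathway_network_recovers_strong_edges(small_cohort, small_fit):
    true_pairs = {frozenset((a, b)) for a, b, _ in small_cohort.truth_dags[0]}
    found_pairs = small_fit.network.edge_pairs()
    # all truth edges have |coef| >= 0.5 at noise 0.3: recall should be high
    assert len(true_pairs & found_pairs) >= 0.8 * len(true_pairs)
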