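import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import precisenet as pn
from precisenet.network import IntegratedNetwork, ProteinEdge
from precisenet.scoring import (
    PatientProbabilityTensor,
    _status_from_triple,
    _triple_from_t,
)

from conftest import make_expression


def make_tensor(probs, samples=None, proteins=None, delta=0.5):
    probs = np.asarray(probs, dtype=float)
    n, p, _ = probs.shape
    samples = samples or [f"s{i}" for i in range(n)]
    proteins = proteins or [f"P{j}" for j in range(p)]
    status = np.empty((n, p), dtype=object)
    for i in range(n):
        for j in range(p):
            status[i, j] = _status_from_triple(*probs[i, j])
    return PatientProbabilityTensor(samples, proteins, probs, status, delta)


def make_network(proteins, edges):
    """edges: list of (src, dst, kind)."""
    out_degree = {p: 0 for p in proteins}
    protein_edges = []
    for src, dst, kind in edges:
        protein_edges.append(ProteinEdge(src, dst, kind, 0.9))
        out_degree[src] += 1
        if kind == "correlative":
            out_degree[dst] += 1
    return IntegratedNetwork(
        cancer_type="SIM",
        pathway="pw",
        proteins=list(proteins),
        protein_edges=protein_edges,
        upstream_edges=[],
        out_degree=out_degree,
    )


class TestPredictiveProbabilities:
    def test_symmetric_predictive_balances_tails(self, small_fit):
        # location 0 by construction: empty-MPM fallback is centered at 0
        prot = next(iter(small_fit.fits))
        problem = small_fit.problems[prot]
        fit = small_fit.fits[prot]
        from precisenet.scoring import _predictive_params

        loc, scale, df = _predictive_params(problem, [], 0)
        assert loc == 0.0
        triple = _triple_from_t(loc, scale, df, 0.5)
        assert triple[0] == pytest.approx(triple[2], abs=1e-12)

    def test_huge_delta_forces_neutral(self, small_fit, small_tensor):
        prot = next(iter(small_fit.fits))
        triple = pn.predictive_probabilities(
            small_fit.fits[prot], small_fit.problems[prot], 0, delta=1e6
        )
        assert triple[1] == pytest.approx(1.0, abs=1e-9)

    def test_t_probability_against_quadrature(self):
        """p+ for a t predictive vs numerical integration of the density."""
        loc, scale, df, delta = 1.0, 0.5, 10, 0.5
        p_minus, p_zero, p_plus = _triple_from_t(loc, scale, df, delta)
        dens = lambda x: stats.t.pdf((x - loc) / scale, df) / scale
        num_plus, _ = integrate.quad(dens, delta, np.inf)
        num_minus, _ = integrate.quad(dens, -np.inf, -delta)
        assert p_plus == pytest.approx(num_plus, abs=1e-9)
        assert p_minus == pytest.approx(num_minus, abs=1e-9)
        assert p_plus == pytest.approx(stats.t.cdf(1.0, 10), abs=1e-12)

    def test_triples_normalised_across_cohort(self, small_tensor):
        sums = small_tensor.probs.sum(axis=2)
        assert np.abs(sums - 1.0).max() < 1e-12

    def test_model_averaging_close_to_mpm_when_posterior_concentrates(self, small_fit):
        prot = next(iter(small_fit.fits))
        fit, problem = small_fit.fits[prot], small_fit.problems[prot]
        if fit.model_masks is None:
            pytest.skip("sampled fit; no enumerated models")
        mpm = pn.predictive_probabilities(fit, problem, 3, delta=0.5)
        bma = pn.predictive_probabilities(
            fit, problem, 3, delta=0.5, model_averaging=True
        )
        assert np.abs(np.array(mpm) - np.array(bma)).max() < 0.2


class TestStatusRule:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.7, 0.2, 0.1), "suppressed"),
            ((0.1, 0.2, 0.7), "activated"),
            ((0.2, 0.6, 0.2), "neutral"),
            ((0.4, 0.2, 0.4), "neutral"),  # tie -> neutral
            ((1 / 3, 1 / 3, 1 / 3), "neutral"),
        ],
    )
    def test_argmax_with_tie_to_neutral(self, triple, expected):
        assert _status_from_triple(*triple) == expected


class TestPatientNetwork:
    def test_topology_shared_labels_differ(self, small_fit, small_tensor):
        net = small_fit.network
        d0 = pn.patient_network(net, small_tensor, small_tensor.sample_ids[0])
        d1 = pn.patient_network(net, small_tensor, small_tensor.sample_ids[1])
        assert d0["edges"] == d1["edges"]
        assert d0["patient"] != d1["patient"]

    def test_all_neutral_tensor_labels_all_neutral(self):
        probs = np.tile([0.0, 1.0, 0.0], (3, 2, 1))
        tensor = make_tensor(probs, proteins=["A", "B"])
        net = make_network(["A", "B"], [("A", "B", "regulatory")])
        d = pn.patient_network(net, tensor, "s0")
        statuses = [n["status"] for n in d["nodes"] if n["type"] == "protein"]
        assert statuses == ["neutral", "neutral"]

    def test_missing_protein_raises_with_name(self, small_fit):
        probs = np.tile([0.0, 1.0, 0.0], (2, 1, 1))
        tensor = make_tensor(probs, proteins=["OTHER"])
        with pytest.raises(ValueError, match=small_fit.network.proteins[0]):
            pn.patient_network(small_fit.network, tensor, "s0")


class TestPreciseScores:
    def test_forced_example_with_hub_weighting(self):
        # p=2, edge 1->2 so C = (1, 0); p+ = 1 for both proteins
        probs = np.tile([0.0, 0.0, 1.0], (1, 2, 1))
        tensor = make_tensor(probs, proteins=["P1", "P2"])
        net = make_network(["P1", "P2"], [("P1", "P2", "regulatory")])
        pw = pn.PathwayDefinition("pw", [("P1", "G1", 1), ("P2", "G2", 1)])
        scores = pn.precise_scores(tensor, net, pw)
        row = scores.iloc[0]
        assert row["kappa_plus"] == pytest.approx(1.5)
        assert row["kappa_minus"] == 0.0 and row["kappa_zero"] == 0.0
        assert row["status"] == "activated"

    def test_uniform_triples_equalise_kappas(self):
        probs = np.tile([1 / 3, 1 / 3, 1 / 3], (2, 3, 1))
        tensor = make_tensor(probs, proteins=["A", "B", "C"])
        net = make_network(["A", "B", "C"], [("A", "B", "correlative")])
        pw = pn.PathwayDefinition("pw", [(p, p, 1) for p in "ABC"])
        scores = pn.precise_scores(tensor, net, pw)
        assert np.allclose(scores["kappa_plus"], scores["kappa_minus"])
        assert np.allclose(scores["kappa_plus"], scores["kappa_zero"])
        assert (scores["status"] == "neutral").all()

    def test_kappa_sum_identity_random_fixture(self):
        rng = np.random.default_rng(31)
        p = 6
        proteins = [f"P{j}" for j in range(p)]
        raw = rng.dirichlet(np.ones(3), size=(4, p))
        tensor = make_tensor(raw, proteins=proteins)
        edges = [
            (proteins[i], proteins[j], "regulatory")
            for i in range(p)
            for j in range(i + 1, p)
            if rng.random() < 0.3
        ]
        net = make_network(proteins, edges)
        pw = pn.PathwayDefinition("pw", [(q, q, 1) for q in proteins])
        scores = pn.precise_scores(tensor, net, pw)
        # independent summation oracle with explicit loops
        expected = 0.0
        for prot in proteins:
            expected += net.out_degree[prot] + 1
        expected /= p
        total = scores["kappa_plus"] + scores["kappa_minus"] + scores["kappa_zero"]
        assert np.abs(total - expected).max() < 1e-10

    def test_empty_pathway_rejected(self, small_tensor, small_fit):
        pw = pn.PathwayDefinition("pw", [("NOT_THERE", "G", 1)])
        with pytest.raises(ValueError):
            pn.precise_scores(small_tensor, small_fit.network, pw)

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_normalisation_properties_hold_on_random_tensors(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(1, 5)), int(rng.integers(1, 6))
        proteins = [f"P{j}" for j in range(p)]
        tensor = make_tensor(rng.dirichlet(np.ones(3), size=(n, p)), proteins=proteins)
        assert np.abs(tensor.probs.sum(axis=2) - 1).max() < 1e-12
        edges = [
            (proteins[i], proteins[j], "regulatory")
            for i in range(p)
            for j in range(i + 1, p)
            if rng.random() < 0.4
        ]
        net = make_network(proteins, edges)
        pw = pn.PathwayDefinition("pw", [(q, q, 1) for q in proteins])
        scores = pn.precise_scores(tensor, net, pw)
        expected = sum(net.out_degree[q] + 1 for q in proteins) / p
        total = scores["kappa_plus"] + scores["kappa_minus"] + scores["kappa_zero"]
        assert np.abs(total - expected).max() < 1e-10
        assert (scores[["kappa_plus", "kappa_minus", "kappa_zero"]] >= 0).all().all()


class TestComparisonScores:
    def _protein(self):
        return make_expression(
            np.array([[2.0, 3.0, -1.0], [1.0, 1.0, 1.0]]),
            features=["A", "B", "C"],
        )

    def test_naive_is_plain_sum(self):
        pw = pn.PathwayDefinition("pw", [(p, p, 1) for p in "ABC"])
        scores = pn.naive_score(self._protein(), pw)
        assert scores.tolist() == [4.0, 3.0]

    def test_single_member_is_identity(self):
        pw = pn.PathwayDefinition("pw", [("B", "B", 1)])
        assert pn.naive_score(self._protein(), pw).tolist() == [3.0, 1.0]

    def test_native_signed_sum_and_reductions(self):
        protein = make_expression(np.array([[2.0, 3.0, 1.0]]), features=["A", "B", "C"])
        pw = pn.PathwayDefinition(
            "pw", [("A", "A", 1), ("B", "B", 1), ("C", "C", -1)]
        )
        assert pn.native_score(protein, pw).iloc[0] == pytest.approx(4.0)
        pw_pos = pn.PathwayDefinition("pw", [(p, p, 1) for p in "ABC"])
        assert (
            pn.native_score(protein, pw_pos).iloc[0]
            == pn.naive_score(protein, pw_pos).iloc[0]
        )
        pw_neg = pn.PathwayDefinition("pw", [(p, p, -1) for p in "ABC"])
        assert pn.native_score(protein, pw_neg).iloc[0] == pytest.approx(
            -pn.naive_score(protein, pw_pos).iloc[0]
        )

    def test_missing_members_dropped_empty_rejected(self):
        pw = pn.PathwayDefinition("pw", [("A", "A", 1), ("ZZ", "ZZ", 1)])
        assert pn.naive_score(self._protein(), pw).tolist() == [2.0, 1.0]
        pw_gone = pn.PathwayDefinition("pw", [("ZZ", "ZZ", 1)])
        with pytest.raises(ValueError):
            pn.naive_score(self._protein(), pw_gone)


class TestSubgroupRecovery:
    def test_shifted_subgroup_scores_activated(self):
        """Patients with a +1.5 pathway shift are called activated and their
        kappa+ exceeds the controls' on average."""
        spec = pn.SimulationSpec(
            n_samples=200,
            pathway_sizes=(8,),
            edge_density=0.2,
            noise_sd=0.3,
            subgroup_shifts=((0, 1.5),),
            seed=23,
        )
        cohort = pn.simulate_cohort(spec)
        from conftest import flat_prior

        cfg = pn.AnalysisConfig(seed=23)
        pf = pn.fit_pathway_network(
            cohort.matrices["protein"],
            cohort.pathways[0],
            flat_prior(cohort.matrices["protein"].feature_ids),
            cfg,
            mrna=cohort.matrices["mrna"],
            methylation=cohort.matrices["methylation"],
            mirna=cohort.matrices.get("mirna"),
            mirna_map=cohort.mirna_map,
        )
        tensor = pn.patient_probability_tensor(pf, delta=0.5)
        scores = pn.precise_scores(tensor, pf.network, cohort.pathways[0])
        shifted = cohort.labels.loc[cohort.labels["subgroup"] == 1, "sample"]
        controls = cohort.labels.loc[cohort.labels["subgroup"] == 0, "sample"]
        frac = (scores.loc[shifted, "status"] == "activated").mean()
        assert frac >= 0.9
        assert (
            scores.loc[shifted, "kappa_plus"].mean()
            > scores.loc[controls, "kappa_plus"].mean()
        )


def test_tensor_long_frame_round_trip(small_tensor):
    frame = small_tensor.to_long_frame()
    back = PatientProbabilityTensor.from_long_frame(frame, delta=small_tensor.delta)
    np.testing.assert_allclose(back.probs, small_tensor.probs)
    assert back.sample_ids == small_tensor.sample_ids
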