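"""Score functions: distance density, feature log-odds, network scores,
weights, and the maximum-likelihood updates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from conftest import toy_locus_set, toy_network
from signet.locus_model import GeneAssignment
from signet.sampler import update_parameters
from signet.scoring import (
    DistanceModel,
    FeatureModel,
    categorical_contribution,
    configuration_score,
    distance_log_density,
    feature_score,
    gene_total_score,
    locus_weights,
    network_log_likelihood_ratio,
    network_score,
    update_feature_counts,
    update_gamma,
)


def ga(symbol="A", x=0, **flags):
    from conftest import make_gene

    return GeneAssignment(gene=make_gene(symbol), locus_id="L0001", x=x, **flags)


class TestDistance:
    def test_unit_normalizer_at_zero(self):
        assert distance_log_density(0, 0.5) == pytest.approx(0.0)

    def test_closed_form_at_gamma(self):
        g = 1234.0
        assert distance_log_density(g, g) == pytest.approx(-math.log(2 * g) - 1)

    @pytest.mark.parametrize("gamma", [1e3, 2.7e4, 1.5e5, 1e6])
    def test_density_integrates_to_one(self, gamma):
        val, _ = quad(
            lambda x: math.exp(distance_log_density(x, gamma)),
            -50 * gamma,
            50 * gamma,
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_gamma_update_is_mean_absolute_distance(self):
        assert update_gamma([ga("A", 100), ga("B", -300)]) == pytest.approx(200)

    def test_gamma_update_is_stationary_point(self):
        """The refit gamma zeroes the derivative of the summed distance
        score (numeric differentiation)."""
        xs = [100.0, 300.0, 1250.0, 40.0]
        gamma_hat = update_gamma([ga(f"G{i}", x) for i, x in enumerate(xs)])

        def total(gam):
            return sum(distance_log_density(x, gam) for x in xs)

        h = 1e-3
        deriv = (total(gamma_hat + h) - total(gamma_hat - h)) / (2 * h)
        assert deriv == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_distances_floored(self):
        assert update_gamma([ga("A", 0), ga("B", 0)]) == 1.0

    def test_no_eligible_genes_keeps_previous(self):
        with pytest.warns(UserWarning):
            assert update_gamma([], previous=123.0) == 123.0


class TestFeatureScore:
    def test_full_data_worked_value(self):
        assert feature_score(941, 0, 214, 12, 1) == pytest.approx(4.04, abs=0.005)

    def test_scaled_counts_worked_value(self):
        assert feature_score(752.8, 0, 171.2, 9.6, 1) == pytest.approx(3.84, abs=0.005)

    def test_uninformative_feature_scores_zero(self):
        assert feature_score(10, 10, 10, 10) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.tuples(*[st.floats(0, 1e4, allow_nan=False) for _ in range(4)]),
        st.floats(0.1, 10),
    )
    def test_antisymmetry_under_feature_swap(self, counts, c):
        n00, n01, n10, n11 = counts
        s = feature_score(n00, n01, n10, n11, c)
        swapped = feature_score(n01, n00, n11, n10, c)
        assert swapped == pytest.approx(-s, rel=1e-9, abs=1e-12)

    def test_categorical_contribution_sums_flagged_features(self):
        fms = {
            "mendelian": FeatureModel("mendelian", 1, 0, 0, 13),  # ln14 - ln1 + ...
            "exome": FeatureModel("exome", 10, 10, 10, 10),
            "coloc": FeatureModel("coloc", 0, 0, 0, 0),
        }
        none = categorical_contribution(ga("A"), fms)
        assert sum(none.values()) == 0.0
        both = categorical_contribution(
            ga("A", has_mendelian=True, has_coloc=True), fms
        )
        assert sum(both.values()) == pytest.approx(
            fms["mendelian"].score + fms["coloc"].score
        )


class TestNetworkScore:
    def test_llr_at_zero_observed(self):
        assert network_log_likelihood_ratio(0, 1.0, 10) == pytest.approx(
            1 - math.log(11)
        )

    def test_llr_at_two_observed(self):
        assert network_log_likelihood_ratio(2, 1.0, 10) == pytest.approx(
            math.log(2) + 1 - math.log(11)
        )

    def test_llr_zero_zero_convention(self):
        assert network_log_likelihood_ratio(0, 0.0, 10) == pytest.approx(-math.log(11))

    def test_positive_e_with_zero_expectation_is_violation(self):
        with pytest.raises(ValueError):
            network_log_likelihood_ratio(1, 0.0, 10)

    def test_score_at_expectation_is_baseline(self):
        lam0 = network_log_likelihood_ratio(3.0, 3.0, 100)
        assert network_score(3, 3.0, 100) == pytest.approx(lam0)

    def test_enrichment_returns_lambda(self):
        # E > E0 and Lambda increasing there: reflection is the identity
        assert network_score(9, 2.0, 100) == pytest.approx(
            network_log_likelihood_ratio(9, 2.0, 100)
        )

    def test_depletion_reflected_below_baseline(self):
        lam0 = network_log_likelihood_ratio(3.0, 3.0, 100)
        lam = network_log_likelihood_ratio(0, 3.0, 100)
        assert network_score(0, 3.0, 100) == pytest.approx(2 * lam0 - lam)
        assert network_score(0, 3.0, 100) <= lam0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.01, 50), st.integers(60, 500))
    def test_monotone_in_observed_edges(self, e0, t):
        scores = [network_score(e, e0, t) for e in range(0, min(t, 40))]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.5, 30), st.integers(60, 500))
    def test_llr_minimum_near_expectation(self, e0, t):
        lam = [network_log_likelihood_ratio(e, e0, t) for e in range(0, 50)]
        argmin = lam.index(min(lam))
        assert abs(argmin - math.floor(e0)) <= 1


class TestWeights:
    def test_equal_scores_uniform(self):
        assert locus_weights([1.0] * 4) == pytest.approx([0.25] * 4)

    def test_closed_form_two_genes(self):
        assert locus_weights([0.0, math.log(3)]) == pytest.approx([0.25, 0.75])

    def test_shift_invariance(self):
        w1 = locus_weights([1.0, 2.0, 5.0])
        w2 = locus_weights([1.0 + 777, 2.0 + 777, 5.0 + 777])
        assert w1 == pytest.approx(w2)
        assert w1.sum() == pytest.approx(1.0)


class TestFeatureCounts:
    def test_toy_enumeration(self):
        ls = toy_locus_set(
            [[("A", 100, "m"), ("B", 500, "")], [("C", 100, "")]]
        )
        counts = update_feature_counts({"L0001": "A", "L0002": "C"}, ls)
        assert counts["mendelian"] == (1, 0, 1, 1)  # n00, n01, n10, n11

    def test_counts_partition_all_genes(self):
        ls = toy_locus_set(
            [[("A", 100, ""), ("B", 500, "c")], [("C", 100, "e"), ("D", 9, "")]]
        )
        counts = update_feature_counts({"L0001": "B", "L0002": "D"}, ls)
        for n00, n01, n10, n11 in counts.values():
            assert n00 + n01 + n10 + n11 == ls.G
            assert n10 + n11 == ls.L

    def test_singleton_loci_excluded(self):
        ls = toy_locus_set([[("A", 100, "m")], ("singleton", "SM1")])
        counts = update_feature_counts(
            {"L0001": "A", ls.singleton_loci[0].locus_id: "SM1"}, ls
        )
        assert sum(counts["mendelian"]) == 1  # only the GWAS-locus gene

    def test_all_flag_free_closed_form(self):
        ls = toy_locus_set([[("A", 100, ""), ("B", 500, "")]])
        counts = update_feature_counts({"L0001": "A"}, ls)
        n00, n01, n10, n11 = counts["coloc"]
        assert n01 == n11 == 0
        expected = math.log(1 / (n10 + 1)) - math.log(1 / (n00 + 1))
        assert feature_score(*counts["coloc"]) == pytest.approx(expected)


class TestGeneTotalScore:
    def test_component_isolation_no_evidence_no_edges(self):
        ls = toy_locus_set([[("A", 0, ""), ("B", 500, "")]])
        nets = {"ppi": toy_network([], ls), "gri": toy_network([], ls, directed=True)}
        dm = DistanceModel(gamma=1.0)
        fms = {n: FeatureModel(n) for n in ("mendelian", "exome", "coloc")}
        score = gene_total_score(
            ls.assignment("A"), ls.loci[0], {"L0001": "B"}, dm, fms, nets
        )
        assert score.distance == pytest.approx(-math.log(2))
        assert score.mendelian == score.exome == score.coloc == 0.0

    def test_edge_to_active_gene_raises_score(self):
        """Two otherwise-identical candidates: the one sharing a PPI edge
        with an active gene elsewhere scores strictly higher."""
        ls = toy_locus_set(
            [
                [("HUB", 100, "")],
                [("EDGE", 5000, ""), ("PLAIN", 5000, "")],
                [("C", 100, "")],
            ]
        )
        nets = {"ppi": toy_network([("HUB", "EDGE"), ("HUB", "C")], ls)}
        dm = DistanceModel(gamma=50_000)
        fms = {n: FeatureModel(n) for n in ("mendelian", "exome", "coloc")}
        config = {"L0001": "HUB", "L0002": "PLAIN", "L0003": "C"}
        locus = ls.locus_by_id("L0002")
        s_edge = gene_total_score(ls.assignment("EDGE"), locus, config, dm, fms, nets)
        s_plain = gene_total_score(ls.assignment("PLAIN"), locus, config, dm, fms, nets)
        assert s_edge.total > s_plain.total
        assert s_edge.distance == s_plain.distance

    def test_singleton_distance_term(self):
        ls = toy_locus_set([[("A", 100, "")], ("singleton", "SM1")])
        dm = DistanceModel(gamma=2.0)
        fms = {n: FeatureModel(n) for n in ("mendelian", "exome", "coloc")}
        sid = ls.singleton_loci[0].locus_id
        score = gene_total_score(
            ls.singleton_loci[0].member_genes[0],
            ls.singleton_loci[0],
            {"L0001": "A", sid: "SM1"},
            dm,
            fms,
            {},
        )
        assert score.distance == pytest.approx(-math.log(4))
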