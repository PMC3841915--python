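import itertools
import math

import numpy as np
import pytest

from otunet import clustering, network_aic
from otunet.io_seq import SequenceTypeTable
from otunet.network_aic import (
    AicCurve,
    AicResult,
    abundance_ll,
    abundance_ll_total,
    aic_curve,
    binary_aic,
    binary_ll,
    build_network,
    link_probability,
    select_optimal,
    weighted_aic,
)

from conftest import make_network, random_member_rows
from _oracles import (
    naive_binary_ll,
    naive_binomial_logpmf,
    naive_network_scores,
    naive_poisson_logpmf,
)


class TestBuildNetwork:
    def test_counts_links_sizes_and_abundance_sums(self):
        table = SequenceTypeTable(
            ["AAAA", "AAAT"], ["P1", "P2"], np.array([[3, 0], [1, 2]])
        )
        part = clustering.Partition(
            88, np.array([0, 0]), 1, np.array([0])
        )
        net = build_network(table, part)
        assert net.S_i.tolist() == [2]
        assert net.L_iq.tolist() == [[2, 1]]
        assert net.a_dot_iq.tolist() == [[4, 2]]
        assert net.L_total == 3

    def test_finest_partition_unit_otus(self, toy_table):
        part = clustering.Partition(
            99, np.arange(3), 3, np.arange(3)
        )
        net = build_network(toy_table, part)
        assert net.S_i.tolist() == [1, 1, 1]
        assert set(np.unique(net.L_iq)) <= {0, 1}

    def test_size_mismatch_rejected(self, toy_table):
        part = clustering.Partition(88, np.array([0, 0]), 1, np.array([0]))
        with pytest.raises(ValueError):
            build_network(toy_table, part)


class TestLinkProbability:
    def test_ratio_and_extremes(self):
        net = make_network([[[1, 1, 1, 0], [2, 0, 1, 0], [1, 1, 0, 0], [3, 0, 0, 0]]])
        assert link_probability(net, 0, 0) == 1.0
        assert link_probability(net, 0, 1) == 0.5
        assert link_probability(net, 0, 3) == 0.0


class TestBinaryLikelihood:
    def test_hand_value_checked_against_oracle_first(self):
        # S_i=4, L=3: oracle reproduces the hand computation, then the module
        expected = 3 * math.log(0.75) + math.log(0.25)
        assert naive_binary_ll(3, 4) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-2.249341, abs=1e-6)
        net = make_network([[[1], [1], [1], [0]]])
        assert binary_ll(net, 0, 0) == pytest.approx(expected, abs=1e-12)

    def test_zero_links_and_full_links_contribute_zero(self):
        net = make_network([[[0, 1], [0, 2]]])
        assert binary_ll(net, 0, 0) == 0.0  # L = 0
        assert binary_ll(net, 0, 1) == 0.0  # L = S_i

    def test_verbatim_sign_flips_second_term(self):
        net = make_network([[[1], [1], [1], [0]]])
        default = binary_ll(net, 0, 0)
        verbatim = binary_ll(net, 0, 0, verbatim_sign=True)
        assert verbatim == pytest.approx(3 * math.log(0.75) - math.log(0.25), abs=1e-12)
        assert verbatim > default


class TestBinaryAic:
    def test_two_types_one_link_hand_value(self):
        net = make_network([[[1], [0]]])
        assert binary_aic(net) == pytest.approx(6 - 2 * (2 * math.log(0.5)), abs=1e-9)
        assert binary_aic(net) == pytest.approx(8.772589, abs=1e-6)

    def test_finest_partition_closed_form(self):
        rows = [[[2, 0]], [[1, 3]], [[0, 5]]]  # three unit OTUs, r=2
        net = make_network(rows)
        assert binary_aic(net) == pytest.approx(2 * 3 * 2 + 2 * 3, abs=1e-12)

    def test_all_present_single_otu(self):
        net = make_network([[[1, 2], [3, 4]]])
        assert binary_aic(net) == pytest.approx(2 * 2 + 2 * 2, abs=1e-12)


class TestAbundanceLikelihood:
    def test_poisson_hand_value_via_oracle(self):
        expected = naive_poisson_logpmf(3, 2.0) + naive_poisson_logpmf(1, 2.0)
        assert expected == pytest.approx(-3.019171, abs=1e-6)
        net = make_network([[[3], [1]]])
        assert abundance_ll(net, 0, 0, "poisson") == pytest.approx(expected, abs=1e-9)

    def test_binomial_hand_value_via_oracle(self):
        expected = naive_binomial_logpmf(3, 4, 0.5) + naive_binomial_logpmf(1, 4, 0.5)
        assert expected == pytest.approx(-2.772589, abs=1e-6)
        net = make_network([[[3], [1]]])
        assert abundance_ll(net, 0, 0, "binomial") == pytest.approx(expected, abs=1e-9)

    def test_binomial_degenerate_single_member(self):
        net = make_network([[[7, 0]]])
        assert abundance_ll(net, 0, 0, "binomial") == 0.0
        assert abundance_ll(net, 0, 1, "binomial") == 0.0

    def test_poisson_zero_total_cell_contributes_zero(self):
        net = make_network([[[0, 2], [0, 2]]])
        assert abundance_ll(net, 0, 0, "poisson") == 0.0

    def test_unknown_model_rejected(self):
        net = make_network([[[1]]])
        with pytest.raises(ValueError):
            abundance_ll(net, 0, 0, "gamma")

    def test_poisson_maximal_at_equal_allocation(self):
        """Equal member abundances maximise the Poisson cell likelihood
        over all integer reallocations of the same total (exhaustive)."""
        for S_i in (2, 3):
            for total in range(0, 9, S_i):
                lam = total / S_i
                best = sum(
                    naive_poisson_logpmf(total // S_i, lam) for _ in range(S_i)
                )
                for combo in itertools.product(range(total + 1), repeat=S_i):
                    if sum(combo) != total:
                        continue
                    ll = sum(naive_poisson_logpmf(v, lam) for v in combo)
                    assert ll <= best + 1e-12


class TestWeightedAic:
    def test_algebraic_identity_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            net = make_network(random_member_rows(rng))
            for model in ("poisson", "binomial"):
                gap = weighted_aic(net, model) - binary_aic(net)
                expect = 2 * net.k * net.r - 2 * abundance_ll_total(net, model)
                assert gap == pytest.approx(expect, abs=1e-9)

    def test_single_otu_hand_value(self):
        net = make_network([[[3], [1]]])
        assert weighted_aic(net, "poisson") == pytest.approx(14.038342, abs=1e-6)

    def test_finest_partition_closed_form(self):
        rows = [[[2, 0]], [[1, 3]], [[0, 5]]]
        net = make_network(rows)
        ll = sum(
            naive_poisson_logpmf(v, v) for row in rows for v in row[0]
        )
        expect = 4 * 3 * 2 + 2 * 3 - 2 * ll
        assert weighted_aic(net, "poisson") == pytest.approx(expect, abs=1e-9)

    def test_sign_contract_default_mode(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            net = make_network(random_member_rows(rng))
            from otunet.network_aic import binary_ll_matrix

            assert (binary_ll_matrix(net) <= 1e-12).all()
            for model in ("poisson", "binomial"):
                assert abundance_ll_total(net, model) <= 1e-9
                assert weighted_aic(net, model) >= 4 * net.k * net.r - 1e-9


def scan_for(table, grid):
    dm = clustering.compute_distances(table)
    return clustering.scan(dm, table, grid)


class TestAicCurve:
    def planted(self):
        # 4 types in 2 planted pairs with distinct occupancy profiles
        return SequenceTypeTable(
            ["AAAAAAAA", "AAAAAAAT", "CCTTGGCC", "CCTTGGCA"],
            ["P1", "P2"],
            np.array([[9, 0], [7, 0], [0, 8], [0, 6]]),
        )

    def test_constant_offset_invariance_of_argmin(self):
        table = self.planted()
        curve = aic_curve(table, scan_for(table, range(74, 100)))
        scores = np.array([r.aic_weighted for r in curve.results])
        assert np.argmin(scores) == np.argmin(scores + 2 * table.n_types)

    def test_single_threshold_grid_is_optimal(self):
        table = self.planted()
        curve = aic_curve(table, scan_for(table, [88]))
        assert select_optimal(curve) == 88

    def test_tie_broken_toward_lower_threshold(self):
        results = [
            AicResult(74, 2, 0, 0, 5.0, 5.0, "poisson"),
            AicResult(75, 2, 0, 0, 5.0, 5.0, "poisson"),
            AicResult(76, 3, 0, 0, 7.0, 7.0, "poisson"),
        ]
        assert AicCurve(results).optimal_threshold == 74

    def test_identical_partitions_identical_aic(self):
        table = self.planted()
        curve = aic_curve(table, scan_for(table, [90, 91]))
        assert curve[0].aic_weighted == pytest.approx(curve[1].aic_weighted, abs=1e-12)
        assert select_optimal(curve) == 90

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            AicCurve([])

    def test_curve_write_round_trip(self, tmp_path):
        import pandas as pd

        table = self.planted()
        curve = aic_curve(table, scan_for(table, range(80, 95)))
        path = tmp_path / "curve.tsv"
        curve.write(path)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns) == [
            "threshold_pct", "k", "ll_binary", "ll_abund",
            "aic_binary", "aic_weighted", "model",
        ]
        assert len(frame) == 15


class TestNaiveOracleEquivalence:
    def test_random_networks_match_naive_reimplementation(self):
        """Direct-summation oracle agrees with the vectorised module to 1e-9
        on random networks (k<=10, r<=8, S<=40, abundances<=20)."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            rows = random_member_rows(rng)
            net = make_network(rows)
            for model in ("poisson", "binomial"):
                expect = naive_network_scores(rows, model)
                from otunet.network_aic import binary_ll_matrix

                assert binary_ll_matrix(net).sum() == pytest.approx(
                    expect["ll_binary"], abs=1e-9
                )
                assert abundance_ll_total(net, model) == pytest.approx(
                    expect["ll_abund"], abs=1e-9
                )
                assert binary_aic(net) == pytest.approx(expect["aic_binary"], abs=1e-9)
                assert weighted_aic(net, model) == pytest.approx(
                    expect["aic_weighted"], abs=1e-9
                )

    def test_verbatim_sign_matches_oracle(self):
        rng = np.random.default_rng(7)
        rows = random_member_rows(rng)
        net = make_network(rows)
        expect = naive_network_scores(rows, "poisson", verbatim_sign=True)
        from otunet.network_aic import binary_ll_matrix

        assert binary_ll_matrix(net, verbatim_sign=True).sum() == pytest.approx(
            expect["ll_binary"], abs=1e-9
        )
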