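"""Network construction and the quantitative network-level metrics."""

import math

import numpy as np
import pandas as pd
import pytest

import antplant as ap
from antplant.network import barber_q, ModulePartition
from conftest import census_frame, random_network


class TestBuildNetwork:
    def test_aggregates_counts(self, tiny_census):
        net = ap.build_network(tiny_census, 700.0)
        assert net.plant_labels == ("P1", "P2")
        assert net.ant_labels == ("A1", "A2")
        assert np.array_equal(net.counts, [[2, 0], [0, 1]])
        assert net.m == 3

    def test_all_unoccupied_gives_empty_network(self):
        census = census_frame([(700, "P1", 0, ""), (700, "P2", 0, "")])
        net = ap.build_network(census, 700.0)
        assert net.is_empty and net.m == 0

    def test_uncertain_exclusion_flag(self):
        census = census_frame([(800, "P1", 1, "uncertain")])
        assert ap.build_network(census, 800.0, exclude_uncertain=True).is_empty
        net = ap.build_network(census, 800.0, exclude_uncertain=False)
        assert np.array_equal(net.counts, [[1]])

    def test_labels_sorted_lexicographically(self):
        census = census_frame([(700, "Pz", 1, "Ab"), (700, "Pa", 1, "Aa")])
        net = ap.build_network(census, 700.0)
        assert net.plant_labels == ("Pa", "Pz")
        assert net.ant_labels == ("Aa", "Ab")

    def test_tsv_roundtrip(self, tiny_census, tmp_path):
        net = ap.build_network(tiny_census, 700.0)
        net.to_tsv(tmp_path / "net.tsv")
        back = ap.BipartiteNetwork.from_tsv(tmp_path / "net.tsv")
        assert back.plant_labels == net.plant_labels
        assert np.array_equal(back.counts, net.counts)

    def test_zero_row_rejected_in_direct_construction(self):
        with pytest.raises(ValueError):
            ap.BipartiteNetwork(("P1", "P2"), ("A1",),
                                np.array([[1], [0]]))


class TestConnectance:
    @pytest.mark.parametrize("counts,expected", [
        ([[1, 1], [1, 1]], 1.0),
        ([[2, 0], [0, 1]], 0.5),
        ([[1, 0], [1, 1]], 0.75),
    ])
    def test_examples(self, counts, expected):
        assert ap.connectance(ap.BipartiteNetwork.from_counts(counts)) == expected

    def test_empty_undefined(self):
        assert np.isnan(ap.connectance(ap.BipartiteNetwork.empty()))


class TestGeneralityVulnerability:
    def test_single_partner_columns_give_generality_one(self):
        net = ap.BipartiteNetwork.from_counts([[3, 0], [0, 2]])
        assert ap.generality(net) == pytest.approx(1.0)
        assert ap.vulnerability(net) == pytest.approx(1.0)

    def test_uniform_complete_matrix(self):
        net = ap.BipartiteNetwork.from_counts(np.full((3, 2), 4))
        assert ap.generality(net) == pytest.approx(3.0)
        assert ap.vulnerability(net) == pytest.approx(2.0)

    def test_hand_evaluated_entropy_formula(self):
        # independent scalar evaluation of the weighted exp-entropy formula
        net = ap.BipartiteNetwork.from_counts([[2, 1], [0, 3]])
        h_col2 = -(0.25 * math.log(0.25) + 0.75 * math.log(0.75))
        expected_gen = (2 / 6) * 1.0 + (4 / 6) * math.exp(h_col2)
        h_row1 = -((2 / 3) * math.log(2 / 3) + (1 / 3) * math.log(1 / 3))
        expected_vul = (3 / 6) * math.exp(h_row1) + (3 / 6) * 1.0
        assert ap.generality(net) == pytest.approx(expected_gen, abs=1e-12)
        assert ap.vulnerability(net) == pytest.approx(expected_vul, abs=1e-12)

    def test_symmetric_matrix_equates_both(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 5))
            tri = rng.integers(0, 4, size=(n, n))
            counts = tri + tri.T + np.eye(n, dtype=int)
            net = ap.BipartiteNetwork.from_counts(counts)
            assert ap.generality(net) == pytest.approx(ap.vulnerability(net))

    def test_permutation_invariance(self, rng):
        for _ in range(20):
            net = random_network(rng)
            perm_r = rng.permutation(net.n_plants)
            perm_c = rng.permutation(net.n_ants)
            shuffled = ap.BipartiteNetwork.from_counts(
                net.counts[np.ix_(perm_r, perm_c)])
            for metric in (ap.connectance, ap.generality, ap.vulnerability,
                           ap.h2_prime):
                a, b = metric(net), metric(shuffled)
                if np.isnan(a):
                    assert np.isnan(b)
                else:
                    assert a == pytest.approx(b, abs=1e-9)


class TestBarberQ:
    def test_single_module_is_zero(self, rng):
        for _ in range(10):
            net = random_network(rng)
            part = ModulePartition({l: 0 for l in net.plant_labels},
                                   {l: 0 for l in net.ant_labels})
            assert barber_q(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_blocks_give_half(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[:2, :2] = 1
        counts[2:, 2:] = 1
        net = ap.BipartiteNetwork.from_counts(counts)
        part = ModulePartition(
            {l: (0 if i < 2 else 1) for i, l in enumerate(net.plant_labels)},
            {l: (0 if j < 2 else 1) for j, l in enumerate(net.ant_labels)})
        assert barber_q(net, part) == pytest.approx(0.5)

    def test_bounds_hold_for_random_partitions(self, rng):
        for _ in range(30):
            net = random_network(rng)
            part = ModulePartition(
                {l: int(rng.integers(0, 3)) for l in net.plant_labels},
                {l: int(rng.integers(0, 3)) for l in net.ant_labels})
            q = barber_q(net, part)
            assert -0.5 - 1e-12 <= q <= 1.0 + 1e-12

    def test_uncovered_species_error(self, tiny_census):
        net = ap.build_network(tiny_census, 700.0)
        part = ModulePartition({"P1": 0}, {l: 0 for l in net.ant_labels})
        with pytest.raises(ValueError, match="P2"):
            barber_q(net, part)


class TestMetricSet:
    def test_composition(self):
        ms = ap.metric_set(ap.BipartiteNetwork.from_counts([[2, 0], [0, 1]]))
        assert (ms.plant_richness, ms.ant_richness) == (2, 2)
        assert ms.connectance == 0.5
        assert ms.generality == pytest.approx(1.0)
        assert ms.vulnerability == pytest.approx(1.0)

    def test_empty_network_all_undefined(self):
        ms = ap.metric_set(ap.BipartiteNetwork.empty())
        assert (ms.plant_richness, ms.ant_richness) == (0, 0)
        for value in (ms.connectance, ms.generality, ms.vulnerability,
                      ms.h2_prime, ms.modularity_q):
            assert np.isnan(value)

    def test_diagonal_matrix_fully_specialized(self):
        net = ap.BipartiteNetwork.from_counts(np.diag([4, 4, 4]))
        ms = ap.metric_set(net, seed=0)
        assert ms.h2_prime == pytest.approx(1.0)
        # three disconnected equal blocks: Q = 1 - 3*(1/3)^2 = 2/3
        assert ms.modularity_q == pytest.approx(2 / 3)


class TestHerbivoryOccupancy:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0, 0, 0), 0.0),
        ((0, 2, 2, 0), 10.75),
        ((0, 0, 0, 5), 66.5),
    ])
    def test_herbivory_index_examples(self, counts, expected):
        assert ap.herbivory_index(counts) == pytest.approx(expected)

    def test_zero_leaves_undefined(self):
        assert np.isnan(ap.herbivory_index((0, 0, 0, 0)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ap.herbivory_index((1, -1, 0, 0))

    def test_occupancy_examples(self):
        rows = [(700, "P1", 1, "A1")] * 18 + [(700, "P1", 0, "")] * 7
        assert ap.occupancy_rate(census_frame(rows), "P1") == pytest.approx(0.72)
        rows = [(700, "P2", 0, "")] * 5
        assert ap.occupancy_rate(census_frame(rows), "P2") == 0.0

    def test_uncertain_counts_as_occupied(self):
        rows = [(700, "P1", 1, "uncertain"), (700, "P1", 0, "")]
        assert ap.occupancy_rate(census_frame(rows), "P1") == 0.5

    def test_empty_scope_error(self, tiny_census):
        with pytest.raises(ValueError):
            ap.occupancy_rate(tiny_census, "PX")
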