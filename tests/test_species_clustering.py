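"""UPGMA agglomeration, group delimitation and mitotype structure, with an
independent naive average-linkage oracle and scipy as a cross-check."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from barcodeflora.config import ClassifierConfig
from barcodeflora.genetic_distance import DistanceMatrix, JC69, distance_matrix
from barcodeflora.species_clustering import (
    GeneticGroup,
    MATCHES_ATLANTIC,
    MATCHES_BOTH,
    UNDIFFERENTIATED,
    cut_tree,
    delimit_groups,
    regional_composition,
    upgma,
    within_group_structure,
)
from barcodeflora.specimen_io import AlignmentSet, Specimen


def make_dm(ids, mat):
    mat = np.asarray(mat, dtype=float)
    return DistanceMatrix(
        ids=tuple(ids),
        values=mat,
        model=JC69,
        comparable_sites=np.full_like(mat, 100, dtype=int),
    )


def naive_upgma_cophenetic(ids, mat):
    """Independent O(n^3) average-linkage oracle, returning the cophenetic
    distance matrix in input order."""
    clusters = {i: [i] for i in range(len(ids))}
    dist = {(i, j): mat[i][j] for i in range(len(ids)) for j in range(i + 1, len(ids))}
    coph = np.zeros((len(ids), len(ids)))
    nxt = len(ids)
    while len(clusters) > 1:
        (i, j), dmin = min(dist.items(), key=lambda kv: kv[1])
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = dmin
        merged = clusters[i] + clusters[j]
        del dist[(i, j)]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            w = (len(clusters[i]) * dik + len(clusters[j]) * djk) / len(merged)
            dist[(k, nxt)] = w
        del clusters[i], clusters[j]
        clusters[nxt] = merged
        nxt += 1
    return coph


class TestUpgma:
    def test_two_taxa_merge_at_half_distance(self):
        dm = make_dm(["A", "B"], [[0, 0.2], [0.2, 0]])
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(0.1)

    def test_three_taxon_worked_example(self):
        dm = make_dm(
            ["A", "B", "C"],
            [[0, 0.02, 0.10], [0.02, 0, 0.12], [0.10, 0.12, 0]],
        )
        tree = upgma(dm)
        ids, coph = tree.cophenetic_matrix()
        i = {s: k for k, s in enumerate(ids)}
        assert coph[i["A"], i["B"]] == pytest.approx(0.02)
        # ((A,B),C) joins at the average of 0.10 and 0.12
        assert coph[i["A"], i["C"]] == pytest.approx(0.11)
        assert tree.root.height == pytest.approx(0.055)

    @given(st.integers(0, 199))
    def test_oracle_equivalence_random_matrices(self, seed):
        """Cophenetic matrices match both a naive reference implementation
        and scipy average linkage on random 6-taxon matrices."""
        rng = np.random.default_rng(seed)
        n = 6
        cond = rng.uniform(0.01, 0.5, size=n * (n - 1) // 2)
        mat = squareform(cond)
        ids = [f"t{k}" for k in range(n)]
        tree = upgma(make_dm(ids, mat))
        got_ids, got = tree.cophenetic_matrix()
        order = [got_ids.index(i) for i in ids]
        got = got[np.ix_(order, order)]
        assert np.allclose(got, naive_upgma_cophenetic(ids, mat), atol=1e-12)
        scipy_coph = squareform(cophenet(linkage(cond, method="average")))
        assert np.allclose(got, scipy_coph, atol=1e-12)

    def test_output_is_ultrametric(self, rng):
        n = 8
        mat = squareform(rng.uniform(0.01, 0.4, size=n * (n - 1) // 2))
        tree = upgma(make_dm([f"t{k}" for k in range(n)], mat))
        assert tree.is_ultrametric()

    def test_tie_break_is_order_independent(self):
        # equidistant taxa: the pair with the smallest sorted ids merges first
        mat = [[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]]
        t1 = upgma(make_dm(["b", "a", "c"], mat))
        t2 = upgma(make_dm(["c", "b", "a"], mat))
        first1 = sorted(t1.merges[0][0] | t1.merges[0][1])
        first2 = sorted(t2.merges[0][0] | t2.merges[0][1])
        assert first1 == first2 == ["a", "b"]

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError):
            make_dm(["A", "B"], [[0, 0.2], [0.3, 0]])


class TestCutTree:
    @pytest.fixture
    def worked_tree(self):
        return upgma(
            make_dm(
                ["A", "B", "C"],
                [[0, 0.02, 0.10], [0.02, 0, 0.12], [0.10, 0.12, 0]],
            )
        )

    def test_above_root_yields_single_group(self, worked_tree):
        groups = cut_tree(worked_tree, 2.5 * worked_tree.root.height)
        assert groups == [("A", "B", "C")]

    def test_zero_threshold_groups_identical_sequences(self):
        aln = AlignmentSet(
            "COI-5P", {"a": "AAAA", "b": "AAAA", "c": "AATT"}, 4
        )
        tree = upgma(distance_matrix(aln))
        assert sorted(cut_tree(tree, 0.0)) == [("a", "b"), ("c",)]

    def test_worked_threshold(self, worked_tree):
        assert sorted(cut_tree(worked_tree, 0.04)) == [("A", "B"), ("C",)]

    def test_partitions_nested_in_threshold(self, rng):
        """Raising the threshold only merges groups, never splits them."""
        n = 10
        mat = squareform(rng.uniform(0.001, 0.3, size=n * (n - 1) // 2))
        tree = upgma(make_dm([f"t{k}" for k in range(n)], mat))
        prev = None
        for thr in np.linspace(0, 0.4, 30):
            groups = cut_tree(tree, thr)
            if prev is not None:
                assert len(groups) <= len(prev)
                # every previous group is contained in one current group
                lookup = {leaf: g for g in groups for leaf in g}
                for g in prev:
                    assert len({lookup[leaf] for leaf in g}) == 1
            prev = groups


def specimens_for(aln, regions):
    return [
        Specimen(
            specimen_id=sid,
            morpho_species="sp",
            genus="g",
            marker="COI-5P",
            region=regions[sid],
        )
        for sid in aln.records
    ]


class TestRegionalComposition:
    def test_counts_zero_filled_and_conserved(self):
        group = GeneticGroup("G1", ("c1", "c2", "c3"), "COI-5P")
        specs = [
            Specimen(f"c{i}", "sp", "g", "COI-5P", "churchill") for i in (1, 2, 3)
        ]
        comp = regional_composition(group, specs)
        assert comp == {"pacific": 0, "churchill": 3, "atlantic": 0}
        assert sum(comp.values()) == len(group.member_ids)

    def test_unknown_member_raises(self):
        group = GeneticGroup("G1", ("nope",), "COI-5P")
        with pytest.raises(KeyError):
            regional_composition(group, [])


class TestWithinGroupStructure:
    def test_churchill_carries_atlantic_signature(self, toy_alignment):
        regions = {"atl1": "atlantic", "atl2": "atlantic",
                   "pac1": "pacific", "pac2": "pacific", "chu1": "churchill"}
        specs = specimens_for(toy_alignment, regions)
        group = GeneticGroup("G1", tuple(toy_alignment.records), "COI-5P")
        regional_composition(group, specs)
        st_ = within_group_structure(group, toy_alignment, specs)
        assert st_.n_fixed_atl_vs_pac == 1
        assert st_.churchill_matches == MATCHES_ATLANTIC

    def test_identical_sequences_are_undifferentiated(self):
        aln = AlignmentSet(
            "COI-5P", {k: "ACGTACGT" for k in ("a", "p", "c")}, 8
        )
        regions = {"a": "atlantic", "p": "pacific", "c": "churchill"}
        specs = specimens_for(aln, regions)
        group = GeneticGroup("G1", ("a", "p", "c"), "COI-5P")
        regional_composition(group, specs)
        st_ = within_group_structure(aln=aln, group=group, specimens=specs)
        assert st_.churchill_matches == UNDIFFERENTIATED
        assert not st_.differentiated

    def test_split_churchill_specimens_match_both(self):
        aln = AlignmentSet(
            "COI-5P",
            {
                "atl1": "AATA", "atl2": "AATA",
                "pac1": "AACA", "pac2": "AACA",
                "chu1": "AATA", "chu2": "AACA",
            },
            4,
        )
        regions = {"atl1": "atlantic", "atl2": "atlantic", "pac1": "pacific",
                   "pac2": "pacific", "chu1": "churchill", "chu2": "churchill"}
        specs = specimens_for(aln, regions)
        group = GeneticGroup("G1", tuple(aln.records), "COI-5P")
        regional_composition(group, specs)
        st_ = within_group_structure(group, aln, specs)
        assert st_.churchill_matches == MATCHES_BOTH


class TestDelimitGroups:
    def test_synthetic_species_recovers_source_composition(self):
        """An Atlantic-source species sampled 5+5+5 splits into an
        Atlantic+Churchill group and a Pacific group at the default
        threshold."""
        from barcodeflora.synthetic_flora import SimulationParams, simulate_species

        params = SimulationParams(d_between=0.02, pi_within=0.002, d_churchill=0.002)
        rng = np.random.default_rng(7)
        aln, specs, _ = simulate_species(params, 0, rng, scenario="atlantic_source")
        cfg = ClassifierConfig()
        _, groups = delimit_groups(aln, cfg.delimit_threshold)
        for g in groups:
            regional_composition(g, specs)
        focal = [g for g in groups if g.composition["churchill"] > 0]
        assert len(focal) == 1
        assert focal[0].composition == {"pacific": 0, "churchill": 5, "atlantic": 5}
        assert focal[0].max_divergence <= 2 * 0.01
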