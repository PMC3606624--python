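"""Distance primitives: observed proportions, the JC69 correction, matrix
construction, and diagnostic-site scans, each checked against an
independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from barcodeflora.genetic_distance import (
    JC69,
    P_DISTANCE,
    SaturationError,
    UndefinedDistanceError,
    distance_matrix,
    fixed_differences,
    jc_distance,
    max_intragroup_divergence,
    p_distance,
)
from barcodeflora.specimen_io import AlignmentSet


_REFERENCE_60 = None


def mutated_barcode(rng, length, rate=0.1):
    """Random sequence near a shared reference, keeping pairwise p well
    below the JC saturation limit."""
    global _REFERENCE_60
    if _REFERENCE_60 is None or len(_REFERENCE_60) < length:
        _REFERENCE_60 = "".join(
            np.random.default_rng(0).choice(list("ACGT"), size=max(length, 60))
        )
    seq = list(_REFERENCE_60[:length])
    for i in range(length):
        if rng.random() < rate:
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(seq)


def naive_fixed_scan(seqs_a, seqs_b):
    """Exhaustive per-column oracle for fixed differences."""
    cols = []
    for c in range(len(seqs_a[0])):
        chars_a = {s[c] for s in seqs_a}
        chars_b = {s[c] for s in seqs_b}
        if not (chars_a | chars_b) <= set("ACGT"):
            continue
        if len(chars_a) == 1 and len(chars_b) == 1 and chars_a != chars_b:
            cols.append(c)
    return cols


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,p,n",
        [
            ("ACGT", "ACGT", 0.0, 4),
            ("ACGTACGTAC", "ACGTACGTTT", 0.2, 10),
            ("AC-T", "ACGT", 0.0, 3),
            ("ACNT", "ACGT", 0.0, 3),
        ],
    )
    def test_examples(self, a, b, p, n):
        assert p_distance(a, b) == (p, n)

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("--NN", "AC--")


class TestJCDistance:
    def test_identity_and_closed_form(self):
        assert jc_distance(0.0) == 0.0
        # independent closed-form evaluation of -0.75 ln(1 - 0.4/3)
        assert jc_distance(0.1) == pytest.approx(0.10732563273050497, abs=1e-12)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_distance(0.75)

    @given(st.floats(min_value=0, max_value=0.7499))
    def test_correction_never_shrinks(self, p):
        # up to floating-point rounding at vanishing p
        assert jc_distance(p) >= p * (1 - 1e-12)

    @given(
        st.floats(min_value=0, max_value=0.74),
        st.floats(min_value=1e-6, max_value=0.009),
    )
    def test_strictly_increasing(self, p, dp):
        if p + dp < 0.75:
            assert jc_distance(p + dp) > jc_distance(p)


class TestDistanceMatrix:
    def test_identical_records_give_zero_matrix(self):
        aln = AlignmentSet("COI-5P", {"a": "ACGT", "b": "ACGT"}, 4)
        dm = distance_matrix(aln, JC69)
        assert np.allclose(dm.values, 0)

    def test_three_taxa_offdiagonal_values(self):
        aln = AlignmentSet(
            "COI-5P",
            {"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGTTT"},
            10,
        )
        dm = distance_matrix(aln, JC69)
        expect = jc_distance(0.2)
        assert dm.get("a", "b") == 0
        assert dm.get("a", "c") == pytest.approx(expect)
        assert dm.get("b", "c") == pytest.approx(expect)

    def test_jc_matrix_is_elementwise_correction_of_p_matrix(self, rng):
        # oracle equivalence between the two model routes
        recs = {f"s{i}": mutated_barcode(rng, 60) for i in range(6)}
        aln = AlignmentSet("COI-5P", recs, 60)
        dp = distance_matrix(aln, P_DISTANCE)
        dj = distance_matrix(aln, JC69)
        expected = np.vectorize(jc_distance)(dp.values)
        assert np.allclose(dj.values, expected, atol=1e-12)

    def test_record_order_permutation_is_consistent(self):
        recs = {"x": "AAAA", "y": "AATA", "z": "ATTA"}
        dm1 = distance_matrix(AlignmentSet("COI-5P", recs, 4))
        dm2 = distance_matrix(
            AlignmentSet("COI-5P", {k: recs[k] for k in ("z", "x", "y")}, 4)
        )
        for a in recs:
            for b in recs:
                if a != b:
                    assert dm1.get(a, b) == dm2.get(a, b)


class TestFixedDifferences:
    def test_single_fixed_column(self):
        aln = AlignmentSet(
            "COI-5P",
            {"a1": "AAAA", "a2": "AAAA", "b1": "AATA", "b2": "AATA"},
            4,
        )
        rep = fixed_differences(aln, ["a1", "a2"], ["b1", "b2"])
        assert rep.n_fixed == 1
        assert rep.fixed_site_columns == (2,)

    def test_identical_partitions_have_none(self):
        aln = AlignmentSet("COI-5P", {"a": "AAAA", "b": "AAAA"}, 4)
        assert fixed_differences(aln, ["a"], ["b"]).n_fixed == 0

    def test_within_partition_polymorphism_blocks_fixation(self):
        aln = AlignmentSet(
            "COI-5P",
            {"a1": "AAAA", "a2": "AATA", "b1": "AATA", "b2": "AATA"},
            4,
        )
        assert fixed_differences(aln, ["a1", "a2"], ["b1", "b2"]).n_fixed == 0

    def test_overlapping_partitions_rejected(self):
        aln = AlignmentSet("COI-5P", {"a": "AAAA", "b": "AAAA"}, 4)
        with pytest.raises(ValueError, match="overlap"):
            fixed_differences(aln, ["a"], ["a", "b"])

    @given(st.data())
    def test_matches_exhaustive_scan_and_is_symmetric(self, data):
        n_a = data.draw(st.integers(1, 3))
        n_b = data.draw(st.integers(1, 3))
        length = data.draw(st.integers(1, 12))
        alphabet = "ACGT-N"
        seqs_a = [
            "".join(data.draw(st.sampled_from(alphabet)) for _ in range(length))
            for _ in range(n_a)
        ]
        seqs_b = [
            "".join(data.draw(st.sampled_from(alphabet)) for _ in range(length))
            for _ in range(n_b)
        ]
        recs = {f"a{i}": s for i, s in enumerate(seqs_a)}
        recs.update({f"b{i}": s for i, s in enumerate(seqs_b)})
        aln = AlignmentSet("COI-5P", recs, length)
        ids_a = [f"a{i}" for i in range(n_a)]
        ids_b = [f"b{i}" for i in range(n_b)]
        rep = fixed_differences(aln, ids_a, ids_b)
        assert list(rep.fixed_site_columns) == naive_fixed_scan(seqs_a, seqs_b)
        flipped = fixed_differences(aln, ids_b, ids_a)
        assert flipped.fixed_site_columns == rep.fixed_site_columns


class TestMaxIntragroupDivergence:
    def test_singleton_is_zero(self):
        aln = AlignmentSet("COI-5P", {"a": "ACGT"}, 4)
        assert max_intragroup_divergence(aln, ["a"]) == 0.0

    def test_barcode_scale_divergence(self):
        # two records differing at 5 of 625 sites: p = 0.008
        s1 = ("ACGT" * 157)[:625]
        s2 = s1[:5].translate(str.maketrans("ACGT", "CATG")) + s1[5:]
        aln = AlignmentSet("COI-5P", {"a": s1, "b": s2}, 625)
        p, n = p_distance(s1, s2)
        assert (p, n) == (0.008, 625)
        assert max_intragroup_divergence(aln, ["a", "b"]) == pytest.approx(
            jc_distance(0.008)
        )
        assert jc_distance(0.008) == pytest.approx(0.00804, abs=5e-6)

    def test_equals_max_of_restricted_matrix(self, rng):
        recs = {f"s{i}": mutated_barcode(rng, 40) for i in range(5)}
        aln = AlignmentSet("COI-5P", recs, 40)
        dm = distance_matrix(aln, JC69)
        ids = ["s0", "s2", "s4"]
        assert max_intragroup_divergence(aln, ids) == pytest.approx(
            dm.submatrix(ids).values.max()
        )


class TestEstimatorConsistency:
    def test_mean_jc_estimate_unbiased_for_true_divergence(self):
        """Simulated pairs at true divergence D: the mean JC estimate over
        200 replicates lies within 3 standard errors of D."""
        from barcodeflora.synthetic_flora import SimulationParams, simulate_species

        D, L, reps = 0.02, 664, 200
        params = SimulationParams(d_between=D, pi_within=0.0, d_churchill=0.0,
                                  seq_length=L, n_per_region=(1, 1, 1))
        vals = []
        master = np.random.SeedSequence(42)
        for i, child in enumerate(master.spawn(reps)):
            rngi = np.random.default_rng(child)
            _, _, truth = simulate_species(params, i, rngi, scenario="atlantic_source")
            vals.append(truth.realized_divergence)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(reps)
        assert abs(vals.mean() - D) < 3 * se
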