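import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodelim.distances import (
    SATURATED,
    distance_histogram,
    distance_matrix,
    evaluate_threshold,
    fmt_pct,
    k2p_distance,
    species_summaries,
    summarize_levels,
    threshold_curve,
)
from barcodelim.io_formats import Taxon

from conftest import make_alignment, make_matrix


def brute_force_k2p(a, b):
    """Independent per-pair oracle: explicit site loop, textbook formula."""
    ts = tv = n = 0
    purines = {"A", "G"}
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return P, Q, n, math.inf
    return P, Q, n, -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2P:
    def test_identical_sequences(self):
        pd = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (pd.P, pd.Q, pd.d) == (0.0, 0.0, 0.0)

    def test_closed_form_ten_transitions_in_hundred(self):
        a = "A" * 90 + "G" * 10
        b = "A" * 100
        pd = k2p_distance(a, b)
        assert pd.P == 0.1 and pd.Q == 0.0
        assert pd.d == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)

    def test_saturation_sentinel(self):
        # P=0.5, Q=0.1 -> 1-2P-Q = -0.1
        a = "A" * 50 + "C" * 10 + "T" * 40
        b = "G" * 50 + "A" * 10 + "T" * 40
        pd = k2p_distance(a, b)
        assert pd.P == 0.5 and pd.Q == pytest.approx(0.1)
        assert pd.saturated and pd.d == SATURATED

    def test_pairwise_deletion(self):
        pd = k2p_distance("ACGTN-", "ACGAAC")
        assert pd.n_valid == 4  # N and gap columns dropped
        assert pd.P == 0.0 and pd.Q == 0.25  # T vs A is a transversion
        P, Q, n, _ = brute_force_k2p("ACGTN-", "ACGAAC")
        assert (P, Q, n) == (pd.P, pd.Q, pd.n_valid)

    def test_min_valid_sites_error(self):
        with pytest.raises(ValueError, match="unambiguous"):
            k2p_distance("NNNA", "ANNN", min_valid_sites=2)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_k2p_at_least_p_distance(self, data):
        n = 200
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        a = "".join(rng.choice(list("ACGT"), n))
        b = "".join(rng.choice(list("ACGT"), n))
        pd = k2p_distance(a, b)
        p_dist = (pd.P + pd.Q)
        if not pd.saturated:
            assert pd.d >= p_dist - 1e-12
            if pd.d > 0:
                assert pd.d > p_dist or p_dist == 0

    def test_d_increasing_in_P_at_fixed_Q(self):
        ds = []
        for k in range(0, 30, 5):
            a = "A" * (100 - k) + "G" * k
            ds.append(k2p_distance(a, "A" * 100).d)
        assert all(x < y for x, y in zip(ds, ds[1:]))


class TestDistanceMatrix:
    def test_identical_records_all_zero(self):
        aln = make_alignment({"a": "ACGT" * 100, "b": "ACGT" * 100, "c": "ACGT" * 100})
        m = distance_matrix(aln, min_valid_sites=10)
        assert np.all(m.values == 0)

    def test_matches_per_pair_oracle(self, ten_species_dataset):
        aln, _, _, _ = ten_species_dataset
        m = distance_matrix(aln)
        seqs = {r.seq_id: r.sequence for r in aln.records}
        for i, a in enumerate(m.ids):
            for j in range(i + 1, len(m.ids)):
                b = m.ids[j]
                P, Q, n, d = brute_force_k2p(seqs[a], seqs[b])
                assert m.n_valid[i, j] == n
                assert m.values[i, j] == pytest.approx(d, abs=1e-12)

    def test_order_invariance_of_values(self, ten_species_dataset):
        aln, _, _, _ = ten_species_dataset
        m1 = distance_matrix(aln)
        from barcodelim.io_formats import AlignedMatrix

        rev = AlignedMatrix(list(reversed(aln.records)))
        m2 = distance_matrix(rev)
        for a, b, d in m1.pair_iter():
            assert m2.get(a, b) == pytest.approx(d, abs=0)

    def test_min_valid_sites_error_names_pair(self):
        aln = make_alignment({"a": "A" * 400 + "N" * 258, "b": "N" * 258 + "A" * 400})
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            distance_matrix(aln, min_valid_sites=300)


class TestSummaries:
    def test_level_means_hand_enumerated(self):
        # 2 species x 2 seqs, intra 0.01 / 0.02, the 4 inter pairs 0.2
        ids = ["s1", "s2", "s3", "s4"]
        m = make_matrix(ids, {("s1", "s2"): 0.01, ("s3", "s4"): 0.02}, default=0.2)
        meta = {
            "s1": Taxon("spA", "gen1", "fam1"),
            "s2": Taxon("spA", "gen1", "fam1"),
            "s3": Taxon("spB", "gen1", "fam1"),
            "s4": Taxon("spB", "gen1", "fam1"),
        }
        lv = summarize_levels(m, meta)
        assert lv["within_species"]["mean"] == pytest.approx(0.015)
        assert lv["within_species"]["n_pairs"] == 2
        assert lv["within_genus"]["mean"] == pytest.approx(0.2)
        assert lv["within_genus"]["n_pairs"] == 4
        assert lv["within_subfamily"]["n_pairs"] == 0
        assert lv["between_subfamily"]["n_pairs"] == 0

    def test_single_species_levels_empty(self):
        m = make_matrix(["a", "b"], {("a", "b"): 0.01})
        meta = {"a": Taxon("sp", "g", "f"), "b": Taxon("sp", "g", "f")}
        lv = summarize_levels(m, meta)
        assert lv["within_genus"]["n_pairs"] == 0
        assert lv["within_species"]["mean"] == pytest.approx(0.01)

    def test_saturated_pairs_counted_not_averaged(self):
        m = make_matrix(["a", "b", "c"], {("a", "b"): 0.01, ("a", "c"): math.inf,
                                          ("b", "c"): math.inf})
        meta = {k: Taxon("sp", "g", "f") for k in "abc"}
        lv = summarize_levels(m, meta)
        assert lv["within_species"]["mean"] == pytest.approx(0.01)
        assert lv["within_species"]["n_saturated"] == 2

    def test_species_summary_singleton(self):
        m = make_matrix(["a", "b", "c"], {("b", "c"): 0.01}, default=0.2)
        meta = {"a": Taxon("solo"), "b": Taxon("dup"), "c": Taxon("dup")}
        rows = {s.species: s for s in species_summaries(m, meta)}
        assert rows["solo"].max_intra is None
        assert rows["solo"].min_inter_nn == pytest.approx(0.2)
        assert rows["solo"].barcode_gap is None
        assert rows["dup"].barcode_gap == pytest.approx(0.2 - 0.01)

    def test_negative_barcode_gap(self):
        m = make_matrix(
            ["a1", "a2", "b1"], {("a1", "a2"): 0.12, ("a1", "b1"): 0.02, ("a2", "b1"): 0.15}
        )
        meta = {"a1": Taxon("A"), "a2": Taxon("A"), "b1": Taxon("B")}
        rows = {s.species: s for s in species_summaries(m, meta)}
        assert rows["A"].barcode_gap == pytest.approx(0.02 - 0.12)

    def test_nearest_neighbor_tie_lexicographic(self):
        m = make_matrix(
            ["x", "y", "z"], {("x", "y"): 0.1, ("x", "z"): 0.1, ("y", "z"): 0.3}
        )
        meta = {"x": Taxon("mid"), "y": Taxon("beta"), "z": Taxon("alpha")}
        rows = {s.species: s for s in species_summaries(m, meta)}
        assert rows["mid"].nearest_neighbor == "alpha"


class TestThreshold:
    def _summary(self, species, n_seqs, max_intra, min_inter):
        from barcodelim.distances import SpeciesDistanceSummary

        return SpeciesDistanceSummary(
            species, n_seqs, max_intra, max_intra, "other", min_inter,
            None if max_intra is None else min_inter - max_intra,
        )

    def test_defined_and_not_defined(self):
        s1 = self._summary("a", 5, 0.01, 0.05)
        s2 = self._summary("b", 5, 0.04, 0.05)
        r = evaluate_threshold([s1, s2], 0.03)
        assert r.n_species_defined == 1
        assert r.n_intra_below == 1
        assert r.n_inter_above == 2

    def test_fraction_on_constructed_ten_species(self):
        # 8 species with a clear gap at 3%, 2 species violating it
        rows = [self._summary(f"s{i}", 3, 0.01, 0.08) for i in range(8)]
        rows.append(self._summary("bad1", 3, 0.05, 0.08))  # intra too high
        rows.append(self._summary("bad2", 3, 0.01, 0.02))  # inter too low
        r = evaluate_threshold(rows, 0.03)
        assert r.fraction_defined == pytest.approx(0.8)

    def test_singletons_pass_intra_vacuously(self):
        r = evaluate_threshold([self._summary("a", 1, None, 0.05)], 0.03)
        assert r.n_species_defined == 1
        r2 = evaluate_threshold(
            [self._summary("a", 1, None, 0.05)], 0.03, include_singletons=False
        )
        assert r2.n_species == 0

    def test_curve_exposes_maximum(self):
        rows = [self._summary(f"s{i}", 3, 0.02, 0.06) for i in range(5)]
        results, best = threshold_curve(rows, [0.01, 0.03, 0.08])
        assert best.t == 0.03
        assert best.fraction_defined == 1.0


class TestHistogram:
    def test_binning_hand_case(self):
        m = make_matrix(["a", "b", "c"], {("a", "b"): 0.01, ("a", "c"): 0.011,
                                          ("b", "c"): 0.2})
        meta = {"a": Taxon("s1"), "b": Taxon("s1"), "c": Taxon("s1")}
        h = distance_histogram(m, meta, 0.05)
        assert h["intra"][0] == 2
        assert h["intra"][4] == 1  # [0.2, 0.25)
        assert h["intra"].sum() == 3

    def test_empty_inter_pool(self):
        m = make_matrix(["a", "b"], {("a", "b"): 0.01})
        meta = {"a": Taxon("s"), "b": Taxon("s")}
        h = distance_histogram(m, meta, 0.05)
        assert h["inter"].sum() == 0

    def test_counts_conserve_pool_sizes(self, ten_species_dataset):
        aln, meta, _, _ = ten_species_dataset
        m = distance_matrix(aln)
        h = distance_histogram(m, meta, 0.01)
        n = len(m.ids)
        assert h["intra"].sum() + h["inter"].sum() == n * (n - 1) // 2


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "x,decimals,expected",
        [
            (0.029, 2, "2.90"), (0.2226, 2, "22.26"), (0.110, 2, "11.00"),
            (212 / 255, 1, "83.1"), (112 / 255, 1, "43.9"), (0.0, 1, "0.0"),
            (0.005, 0, "1"),  # half away from zero
        ],
    )
    def test_round_half_away(self, x, decimals, expected):
        assert fmt_pct(x, decimals) == expected
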