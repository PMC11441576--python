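import math

import numpy as np
import pytest

from barcodelim.delimit_distance import (
    AbgdConfig,
    abgd_partition,
    abgd_stable_partition,
    asap_partition,
    motu_sweep,
    single_linkage_threshold,
)
from barcodelim.distances import DistanceMatrix, distance_matrix
from barcodelim.io_formats import AlignedMatrix, SequenceRecord

from conftest import make_matrix


# ---------------------------------------------------------------------------
# single-linkage vs an independent union-find oracle
# ---------------------------------------------------------------------------

class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def uf_components(matrix, cutoff):
    uf = UnionFind(matrix.ids)
    for a, b, d in matrix.pair_iter():
        if math.isfinite(d) and d <= cutoff:
            uf.union(a, b)
    groups = {}
    for x in matrix.ids:
        groups.setdefault(uf.find(x), set()).add(x)
    return frozenset(frozenset(g) for g in groups.values())


class TestSingleLinkage:
    def test_chaining_hand_case(self):
        m = make_matrix(["A", "B", "C"], {("A", "B"): 0.01, ("B", "C"): 0.02,
                                          ("A", "C"): 0.03})
        p1 = single_linkage_threshold(m, 0.015)
        assert p1.classes() == frozenset({frozenset({"A", "B"}), frozenset({"C"})})
        p2 = single_linkage_threshold(m, 0.025)  # chains A-B-C
        assert p2.n_motus() == 1

    def test_cutoff_zero_groups_identical(self):
        m = make_matrix(["a", "b", "c"], {("a", "b"): 0.0}, default=0.1)
        assert single_linkage_threshold(m, 0.0).classes() == frozenset(
            {frozenset({"a", "b"}), frozenset({"c"})}
        )

    def test_cutoff_above_max_single_motu(self):
        m = make_matrix(["a", "b", "c"], {})
        assert single_linkage_threshold(m, 1.0).n_motus() == 1

    def test_saturated_pairs_never_merge(self):
        m = make_matrix(["a", "b"], {("a", "b"): math.inf})
        assert single_linkage_threshold(m, 10.0).n_motus() == 2

    def test_matches_union_find_oracle_random(self):
        rng = np.random.default_rng(7)
        for rep in range(50):
            ids = [f"s{i:02d}" for i in range(12)]
            vals = rng.uniform(0, 0.3, size=(12, 12))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            m = DistanceMatrix(ids, vals, np.full((12, 12), 658), 1)
            cutoff = float(rng.uniform(0, 0.3))
            part = single_linkage_threshold(m, cutoff)
            assert part.classes() == uf_components(m, cutoff)


# ---------------------------------------------------------------------------
# base-cutoff sweep
# ---------------------------------------------------------------------------

def _two_cluster_alignment(L=658):
    """Intra pairs differ at exactly 2 sites, inter pairs at >= 30 sites."""
    rng = np.random.default_rng(3)
    base = rng.choice(list("ACGT"), L)
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transitions only

    def flip(seq, positions):
        out = seq.copy()
        for p in positions:
            out[p] = ts[out[p]]
        return out

    a1 = base
    a2 = flip(base, [0, 1])
    b1 = flip(base, range(100, 130))  # 30 sites
    b2 = flip(b1, [200, 201])
    return AlignedMatrix(
        [
            SequenceRecord(n, "".join(s), species=sp)
            for n, s, sp in [("a1", a1, "A"), ("a2", a2, "A"), ("b1", b1, "B"), ("b2", b2, "B")]
        ]
    )


class TestSweep:
    def test_constructed_two_cluster_counts(self):
        aln = _two_cluster_alignment()
        m = distance_matrix(aln)
        sweep = motu_sweep(m, aln.alignment_length)
        by_cutoff = dict(zip(sweep.cutoffs_bases, sweep.motu_counts))
        assert by_cutoff[1] == 4  # intra pairs differ at 2 sites
        for c in range(2, 30):
            assert by_cutoff[c] == 2, c
        for c in range(30, 51):
            assert by_cutoff[c] == 1, c

    def test_monotone_non_increasing(self, ten_species_dataset):
        aln, _, _, _ = ten_species_dataset
        m = distance_matrix(aln)
        sweep = motu_sweep(m, aln.alignment_length)
        assert all(
            a >= b for a, b in zip(sweep.motu_counts, sweep.motu_counts[1:])
        )

    def test_all_identical_single_motu(self):
        aln = AlignedMatrix(
            [SequenceRecord(f"s{i}", "ACGT" * 100) for i in range(4)]
        )
        m = distance_matrix(aln, min_valid_sites=10)
        sweep = motu_sweep(m, 400, cutoffs=[1])
        assert sweep.motu_counts == [1]

    def test_short_sequences_excluded(self):
        aln = _two_cluster_alignment()
        lengths = {sid: 658 for sid in aln.ids}
        lengths["b2"] = 500  # below 95% of 658
        m = distance_matrix(aln)
        sweep = motu_sweep(m, 658, ungapped_lengths=lengths)
        assert sweep.excluded_short == ["b2"]
        assert "b2" not in sweep.partitions[0].assignment


# ---------------------------------------------------------------------------
# barcode-gap recursion
# ---------------------------------------------------------------------------

class TestAbgd:
    def test_two_separated_clusters(self):
        rng = np.random.default_rng(0)
        ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        pairs = {}
        for i in range(10):
            for j in range(i + 1, 10):
                same = (i < 5) == (j < 5)
                pairs[(ids[i], ids[j])] = (
                    rng.uniform(0.001, 0.01) if same else rng.uniform(0.15, 0.18)
                )
        m = make_matrix(ids, pairs)
        parts = abgd_partition(m, AbgdConfig(prior_min=0.049, prior_max=0.051, n_priors=2))
        for p in parts:
            assert p.n_motus() == 2
            assert p.classes() == frozenset(
                {frozenset(ids[:5]), frozenset(ids[5:])}
            )

    def test_all_equal_distances_one_motu(self):
        m = make_matrix([f"s{i}" for i in range(5)], {}, default=0.1)
        parts = abgd_partition(m)
        assert all(p.n_motus() == 1 for p in parts)

    def test_prior_above_all_distances_one_motu(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(6)]
        pairs = {}
        for i in range(6):
            for j in range(i + 1, 6):
                pairs[(ids[i], ids[j])] = rng.uniform(0.001, 0.02)
        m = make_matrix(ids, pairs)
        parts = abgd_partition(m, AbgdConfig(prior_min=0.05, prior_max=0.09, n_priors=3))
        assert all(p.n_motus() == 1 for p in parts)

    def test_motu_count_monotone_in_prior(self, ten_species_dataset):
        aln, _, _, _ = ten_species_dataset
        m = distance_matrix(aln)
        parts = abgd_partition(m)
        counts = [p.n_motus() for p in parts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_partition_covers_all_ids(self, ten_species_dataset):
        aln, _, _, _ = ten_species_dataset
        m = distance_matrix(aln)
        for p in abgd_partition(m):
            assert sorted(p.assignment) == sorted(m.ids)

    def test_stable_partition_prefers_plateau(self, ten_species_dataset):
        aln, _, truth, _ = ten_species_dataset
        m = distance_matrix(aln)
        stable = abgd_stable_partition(abgd_partition(m))
        assert stable.same_partition(truth)


# ---------------------------------------------------------------------------
# ranked-score selection
# ---------------------------------------------------------------------------

class TestAsap:
    def test_two_clear_clusters(self):
        rng = np.random.default_rng(5)
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        pairs = {}
        for i in range(8):
            for j in range(i + 1, 8):
                same = (i < 4) == (j < 4)
                pairs[(ids[i], ids[j])] = (
                    rng.uniform(0.002, 0.012) if same else rng.uniform(0.15, 0.17)
                )
        m = make_matrix(ids, pairs)
        rows, best = asap_partition(m, seed=0)
        assert best.n_motus() == 2
        assert best.classes() == frozenset({frozenset(ids[:4]), frozenset(ids[4:])})

    def test_all_identical_one_motu(self):
        m = make_matrix([f"s{i}" for i in range(4)], {}, default=0.0)
        rows, best = asap_partition(m, seed=0)
        assert best.n_motus() == 1

    def test_one_row_per_distinct_merge_height(self, ten_species_dataset):
        aln, _, _, _ = ten_species_dataset
        m = distance_matrix(aln)
        rows, _ = asap_partition(m, seed=0)
        heights = [r.threshold for r in rows]
        assert len(heights) == len(set(heights))
        assert all(r.asap_score >= 1 for r in rows)

    def test_deterministic_for_fixed_seed(self, ten_species_dataset):
        aln, _, _, _ = ten_species_dataset
        m = distance_matrix(aln)
        _, b1 = asap_partition(m, seed=9)
        _, b2 = asap_partition(m, seed=9)
        assert b1.same_partition(b2)
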