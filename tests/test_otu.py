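import math

import numpy as np
import pytest

from cladeamp import otu
from cladeamp.errors import ValidationError
from cladeamp.otu import (
    DistanceMatrix,
    OtuAssignment,
    cluster_furthest_neighbor,
    k2p_distance,
    k2p_matrix,
    shared_otus,
)
from cladeamp.seqcore import NucleotideSequence


def naive_complete_linkage(D, cutoff):
    """Independent oracle: agglomerate greedily, recomputing every
    inter-cluster maximum from the original matrix at each step."""
    ids = list(D.ids)
    clusters = [[i] for i in range(len(ids))]

    def linkage(a, b):
        return max(D.values[i, j] for i in a for j in b)

    def tie_key(a, b):
        pair = sorted([min(ids[i] for i in a), min(ids[i] for i in b)])
        return tuple(pair)

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = linkage(clusters[x], clusters[y])
                if not np.isfinite(d) or d > cutoff:
                    continue
                cand = (d, tie_key(clusters[x], clusters[y]), x, y)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            break
        _, _, x, y = best
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    clusters.sort(key=lambda c: min(ids[i] for i in c))
    labels = {}
    for k, c in enumerate(clusters):
        for i in c:
            labels[ids[i]] = k
    return labels


def random_distance_matrix(rng, n, scale=0.05):
    ids = tuple(f"s{chr(97 + i)}" for i in range(n))
    v = rng.random((n, n)) * scale
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(ids, v)


class TestK2PDistance:
    def test_identical(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_transition_hand_value(self):
        # P=0.25, Q=0: d = -1/2 ln(0.5) = 0.34657
        assert k2p_distance("AAAA", "AGAA") == pytest.approx(0.3465735903, abs=5e-6)

    def test_single_transversion_hand_value(self):
        # P=0, Q=0.25: d = -1/2 ln(0.75 * sqrt(0.5)) = 0.31713
        expected = -0.5 * math.log(0.75 * math.sqrt(0.5))
        assert k2p_distance("AAAA", "ACAA") == pytest.approx(expected, abs=1e-9)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        # gapped/ambiguous columns drop out; remaining sites: one transition
        # among 5 valid -> same as a 5-site pair with one transition
        assert k2p_distance("A-ANAAG", "ATARAAA") == pytest.approx(
            k2p_distance("AAAAG", "AAAAA")
        )

    def test_saturated_pair_is_infinite(self):
        assert k2p_distance("AAAA", "GGGG") == math.inf

    def test_no_valid_sites(self):
        with pytest.raises(ValidationError):
            k2p_distance("----", "AAAA")

    def test_unequal_lengths(self):
        with pytest.raises(ValidationError):
            k2p_distance("AAA", "AAAA")

    def test_small_divergence_approximates_p_distance(self):
        # d -> P as P -> 0 with Q = 0
        a = "A" * 1000
        b = "G" + "A" * 999
        d = k2p_distance(a, b)
        assert d == pytest.approx(0.001, rel=0.01)

    def test_closed_form_on_random_pair(self):
        # count P and Q independently, evaluate the closed form by hand
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = list(a)
        for i in rng.choice(500, size=30, replace=False):
            b[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[i]]  # transitions
        for i in rng.choice(np.arange(500), size=10, replace=False):
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]  # transversions
        b = "".join(b)
        # recount what actually landed (overlapping picks can overwrite)
        P = sum(
            1 for x, y in zip(a, b)
            if x != y and (x in "AG") == (y in "AG")
        ) / 500
        Q = sum(
            1 for x, y in zip(a, b)
            if x != y and (x in "AG") != (y in "AG")
        ) / 500
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestClusterFurthestNeighbor:
    def test_all_far_apart_all_singletons(self):
        rng = np.random.default_rng(2)
        D = random_distance_matrix(rng, 6, scale=1.0)
        D = DistanceMatrix(D.ids, D.values + 0.5 - np.diag([0.5] * 6))
        a = cluster_furthest_neighbor(D, cutoff=0.01)
        assert a.n_otus == 6

    def test_cutoff_zero_groups_only_duplicates(self):
        seqs = [
            NucleotideSequence("a", "ACGTACGTAC"),
            NucleotideSequence("b", "ACGTACGTAC"),
            NucleotideSequence("c", "ACGTACGTAA"),
        ]
        a = cluster_furthest_neighbor(k2p_matrix(seqs), cutoff=0.0)
        assert a.labels["a"] == a.labels["b"] != a.labels["c"]
        assert a.n_otus == 2

    @pytest.mark.parametrize("trial", range(25))
    def test_agrees_with_naive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 9))
        D = random_distance_matrix(rng, n)
        got = cluster_furthest_neighbor(D, cutoff=0.03)
        assert dict(got.labels) == naive_complete_linkage(D, 0.03)

    def test_agrees_with_scipy_on_tie_free_matrix(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            D = random_distance_matrix(rng, n, scale=0.06)
            cutoff = 0.03
            ours = cluster_furthest_neighbor(D, cutoff)
            Z = linkage(squareform(D.values), method="complete")
            flat = fcluster(Z, t=cutoff, criterion="distance")
            # compare as partitions (label values are arbitrary)
            ours_part = {}
            for sid, k in ours.labels.items():
                ours_part.setdefault(k, set()).add(sid)
            scipy_part = {}
            for sid, k in zip(D.ids, flat):
                scipy_part.setdefault(k, set()).add(sid)
            assert set(map(frozenset, ours_part.values())) == set(
                map(frozenset, scipy_part.values())
            )

    def test_intra_otu_diameter_respects_cutoff(self):
        rng = np.random.default_rng(55)
        D = random_distance_matrix(rng, 15, scale=0.04)
        cutoff = 0.02
        a = cluster_furthest_neighbor(D, cutoff)
        idx = {sid: i for i, sid in enumerate(D.ids)}
        for members in a.members().values():
            for x in members:
                for y in members:
                    assert D.values[idx[x], idx[y]] <= cutoff + 1e-12

    def test_n_otus_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(66)
        D = random_distance_matrix(rng, 12, scale=0.05)
        counts = [
            cluster_furthest_neighbor(D, c).n_otus
            for c in (0.0, 0.005, 0.01, 0.02, 0.04, 0.08)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(88)
        D = random_distance_matrix(rng, 10, scale=0.03)
        base = cluster_furthest_neighbor(D, 0.015)
        perm = rng.permutation(10)
        D2 = DistanceMatrix(
            tuple(D.ids[i] for i in perm), D.values[np.ix_(perm, perm)]
        )
        again = cluster_furthest_neighbor(D2, 0.015)
        assert dict(base.labels) == dict(again.labels)

    def test_saturated_pairs_never_merge(self):
        v = np.array([[0.0, np.inf], [np.inf, 0.0]])
        D = DistanceMatrix(("a", "b"), v)
        assert cluster_furthest_neighbor(D, cutoff=1e9).n_otus == 2


class TestSharedOtus:
    def _assignment(self, labels):
        return OtuAssignment(cutoff=0.01, labels=labels)

    def test_published_style_accounting(self):
        # per-sample OTU counts 6,1,4,1 with exactly one OTU shared between
        # two samples -> 11 unique OTUs overall
        labels = {}
        samples = {"F": [], "B1": [], "B2": [], "M": []}
        otu_id = 0
        for sample, n in (("F", 6), ("B1", 1), ("B2", 4)):
            for k in range(n):
                sid = f"{sample}_seq{k}"
                labels[sid] = otu_id
                samples[sample].append(sid)
                otu_id += 1
        # M's single OTU is the one it shares with B1
        labels["M_seq0"] = labels[samples["B1"][0]]
        samples["M"].append("M_seq0")
        result = shared_otus(samples, self._assignment(labels))
        assert result.per_sample_counts == {"F": 6, "B1": 1, "B2": 4, "M": 1}
        assert result.n_unique_global == 11
        assert list(result.sharing_table.values()) == [("B1", "M")]

    def test_disjoint_singletons(self):
        labels = {f"s{i}": i for i in range(5)}
        samples = {"A": ["s0", "s1"], "B": ["s2", "s3", "s4"]}
        result = shared_otus(samples, self._assignment(labels))
        assert result.n_unique_global == 5
        assert result.sharing_table == {}

    def test_duplicate_membership_rejected(self):
        labels = {"s0": 0}
        with pytest.raises(ValidationError):
            shared_otus({"A": ["s0"], "B": ["s0"]}, self._assignment(labels))


class TestDistanceMatrixIO:
    def test_phylip_write(self, tmp_path):
        seqs = [
            NucleotideSequence("a", "ACGTACGTAC"),
            NucleotideSequence("b", "ACGTACGTAT"),
        ]
        D = k2p_matrix(seqs)
        path = tmp_path / "dist.phy"
        D.write_phylip(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("a")

    def test_symmetry_enforced(self):
        v = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), v)
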