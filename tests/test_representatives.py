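"""Representative selection (profile and centroid), %ID and evaluation metrics."""

import math

import numpy as np
import pytest

from seqspace import (
    EmbeddingMatrix,
    SequenceRecord,
    cluster_properties,
    evaluate_representative,
    global_identity,
    hmm_representative,
    vector_representative,
)
from seqspace.errors import CoverageError
from seqspace.io import AnnotationTable
from seqspace.representatives import AA20, build_profile


def rec(sid, seq):
    return SequenceRecord(id=sid, description="", residues=seq)


def star_cluster(rng, length=60, k=6, mut_rate=0.08):
    """One center sequence plus k single/multi-mutant satellites."""
    center = "".join(AA20[i] for i in rng.integers(20, size=length))
    members = [rec("center", center)]
    for m in range(k):
        chars = list(center)
        for pos in rng.choice(length, size=max(1, int(mut_rate * length)), replace=False):
            choices = [a for a in AA20 if a != chars[pos]]
            chars[pos] = choices[rng.integers(len(choices))]
        members.append(rec(f"mut{m}", "".join(chars)))
    return members


class TestGlobalIdentity:
    def test_identical_sequences_100(self):
        assert global_identity("MKLVAE", "MKLVAE") == 100.0

    def test_single_substitution_is_75_percent_of_4(self):
        # ACDE vs ACDX aligns without gaps: 3 of 4 columns identical
        assert global_identity("ACDE", "ACDX") == pytest.approx(75.0)

    def test_symmetric(self):
        a, b = "MKTAYIAKQRQISFVKSHFSRQ", "MKTAYIAKQKQISFVKAHFSRQLE"
        assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_gap_columns_count_in_denominator(self):
        # deletion of 2 residues: 8 identical columns over 10 alignment columns
        val = global_identity("ACDEFGHIKL", "ACDGHIKL")
        assert val == pytest.approx(80.0)


class TestFallbackProfile:
    def test_center_outscores_single_mutants_hand_enumerated(self):
        # 10-column toy MSA: center + 4 single mutants, each mutated at a
        # distinct column; scores enumerable from the count model by hand
        center = "ACDEFGHIKL"
        muts = ["YCDEFGHIKL", "AYDEFGHIKL", "ACYEFGHIKL", "ACDYFGHIKL"]
        rows = [center] + muts
        profile = build_profile(rows)
        scores = [profile.score(r) for r in rows]

        # independent enumeration from first principles
        def col_counts(col):
            counts = {aa: 1.0 for aa in AA20}
            for r in rows:
                counts[r[col]] += 1
            return counts

        expect = []
        for r in rows:
            total = 0.0
            for col in range(10):
                counts = col_counts(col)
                total += math.log((counts[r[col]] / (20 + 5)) / (1 / 20))
            expect.append(total)
        assert scores == pytest.approx(expect)
        assert int(np.argmax(scores)) == 0  # the center wins

    def test_identical_members_tie_to_smallest_id(self):
        members = [rec("b", "MKLV"), rec("a", "MKLV"), rec("c", "MKLV")]
        choice = hmm_representative(members, engine="fallback")
        assert choice.representative == "a"

    def test_singleton_returns_itself_score_zero(self):
        choice = hmm_representative([rec("solo", "MKLV")], engine="fallback")
        assert choice.representative == "solo" and choice.score == 0.0


class TestHmmerEngine:
    def test_star_center_selected(self):
        rng = np.random.default_rng(21)
        members = star_cluster(rng, mut_rate=0.10)
        choice = hmm_representative(members, engine="hmmer")
        assert choice.method == "hmm"
        assert choice.representative == "center"

    def test_fallback_agrees_on_star(self):
        rng = np.random.default_rng(22)
        members = star_cluster(rng, mut_rate=0.10)
        assert hmm_representative(members, engine="fallback").representative == "center"


class TestVectorRepresentative:
    def test_three_collinear_points_middle_wins(self):
        emb = EmbeddingMatrix(["a", "b", "c"], np.array([[-1.0], [0.0], [1.0]]))
        choice = vector_representative(["a", "b", "c"], emb)
        assert choice.representative == "b" and choice.score == pytest.approx(0.0)

    def test_matches_exhaustive_scan_on_random_clusters(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            X = rng.normal(size=(n, 8))
            ids = [f"v{i:03d}" for i in range(n)]
            emb = EmbeddingMatrix(ids, X)
            choice = vector_representative(ids, emb)
            dist = np.linalg.norm(X - X.mean(axis=0), axis=1)
            best = min(range(n), key=lambda i: (dist[i], ids[i]))
            assert choice.representative == ids[best]

    def test_singleton_at_distance_zero(self):
        emb = EmbeddingMatrix(["only"], np.array([[3.0, 4.0]]))
        choice = vector_representative(["only"], emb)
        assert choice.representative == "only" and choice.score == 0.0

    def test_missing_vector_rejected(self):
        emb = EmbeddingMatrix(["a"], np.zeros((1, 2)))
        with pytest.raises(CoverageError):
            vector_representative(["a", "ghost"], emb)


class TestEvaluateRepresentative:
    def test_identical_pair_all_metrics_trivial(self):
        members = [rec("a", "MKLVWY"), rec("b", "MKLVWY")]
        choice = hmm_representative(members, engine="fallback")
        out = evaluate_representative(members, choice, seed=0)
        assert out == {"delta_id": 0.0, "rank": 1.0, "length_delta": 0.0}

    def test_star_center_ranks_above_half(self):
        rng = np.random.default_rng(24)
        members = star_cluster(rng, k=8, mut_rate=0.12)
        choice = vector_rep = None
        choice = hmm_representative(members, engine="fallback")
        out = evaluate_representative(members, choice, seed=1)
        assert out["rank"] > 0.5
        assert out["delta_id"] >= 0.0

    def test_matches_exhaustive_reimplementation(self):
        rng = np.random.default_rng(25)
        members = star_cluster(rng, k=5, mut_rate=0.15)
        choice = hmm_representative(members, engine="fallback")
        out = evaluate_representative(members, choice, sample_pairs=10_000, seed=2)
        # independent brute force: all pairwise identities, medians by hand
        ids = [m.id for m in members]
        pid = {}
        for i, a in enumerate(members):
            for j, b in enumerate(members):
                if i != j:
                    pid[(a.id, b.id)] = global_identity(a, b)
        medians = {m: float(np.median([pid[(m, o)] for o in ids if o != m])) for m in ids}
        rep = choice.representative
        all_pairs = [pid[(a, b)] for i, a in enumerate(ids) for b in ids[i + 1:]]
        assert out["delta_id"] == pytest.approx(medians[rep] - float(np.median(all_pairs)))
        assert out["rank"] == pytest.approx(
            np.mean([medians[m] <= medians[rep] for m in ids]))
        assert out["length_delta"] == pytest.approx(
            len(rep_seq := next(m for m in members if m.id == rep)) -
            float(np.median([len(m) for m in members])))


class TestClusterProperties:
    def test_identical_sequence_clusters(self):
        seq_a, seq_b = "MKLVWYAETG" * 3, "ACDEFGHIKL" * 3
        seqs = {}
        clusters = {"A": set(), "B": set()}
        for i in range(5):
            seqs[f"a{i}"] = rec(f"a{i}", seq_a)
            seqs[f"b{i}"] = rec(f"b{i}", seq_b)
            clusters["A"].add(f"a{i}")
            clusters["B"].add(f"b{i}")
        table = cluster_properties(clusters, seqs, seed=0)
        assert (table.within_id_median == 100.0).all()
        cross = global_identity(seq_a, seq_b)
        assert table.between_id_median.tolist() == pytest.approx([cross, cross])

    def test_small_clusters_excluded(self):
        seqs = {f"x{i}": rec(f"x{i}", "MKLVWY") for i in range(7)}
        clusters = {"big": {f"x{i}" for i in range(5)}, "small": {"x5", "x6"}}
        table = cluster_properties(clusters, seqs, seed=0)
        assert table.cluster.tolist() == ["big"]

    def test_unannotated_cluster_zero_genera(self):
        seqs = {f"x{i}": rec(f"x{i}", "MKLVWY") for i in range(5)}
        clusters = {"c": set(seqs)}
        table = cluster_properties(clusters, seqs, annotations=AnnotationTable(), seed=0)
        assert table.n_genera.tolist() == [0]

    def test_genus_diversity_counted(self):
        seqs = {f"x{i}": rec(f"x{i}", "MKLVWY") for i in range(5)}
        ann = AnnotationTable({f"x{i}": {"taxon_genus": f"g{i % 3}"} for i in range(5)})
        table = cluster_properties({"c": set(seqs)}, seqs, annotations=ann, seed=0)
        assert table.n_genera.tolist() == [3]
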