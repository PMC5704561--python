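import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import AA, mutate, random_protein
from phyloscope.cluster_align import (
    Alignment,
    ClusterParams,
    build_profile,
    filter_columns,
    greedy_cluster,
    pairwise_identity,
    progressive_align,
)
from phyloscope.errors import EmptyProfileError, InvalidArgumentError
from phyloscope.sequence_io import SequenceRecord


def prot(i, seq):
    return SequenceRecord(f"s{i:03d}", f"G{i}", seq)


class TestPairwiseIdentity:
    def test_self_identity(self):
        a = prot(0, "MKVLITGGAGFIG")
        assert pairwise_identity(a, a) == (1.0, 1.0, 1.0)

    def test_nucleotide_three_of_four(self):
        a = SequenceRecord("a", "g", "AAAA", "rrna")
        b = SequenceRecord("b", "g", "AAAT", "rrna")
        ident, cov_a, cov_b = pairwise_identity(a, b)
        assert ident == pytest.approx(0.75)
        assert cov_a == cov_b == 1.0

    def test_symmetry(self, rng):
        for _ in range(5):
            a = prot(0, random_protein(rng, 40))
            b = prot(1, mutate(rng, a.residues, 0.3))
            ia, ca, cb = pairwise_identity(a, b)
            ib, cb2, ca2 = pairwise_identity(b, a)
            assert ia == pytest.approx(ib)
            assert (ca, cb) == pytest.approx((ca2, cb2))

    def test_empty_sequence(self):
        with pytest.raises(Exception):
            pairwise_identity(prot(0, "MK"), SequenceRecord("x", "g", "A").__class__("x", "g", ""))

    def test_against_nw_oracle(self, rng):
        """Identity must match some co-optimal alignment of an independent
        NW implementation, and the optimal scores must agree exactly."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score, aligner.extend_gap_score = -11.0, -1.0
        for _ in range(20):
            a = prot(0, random_protein(rng, int(rng.integers(15, 30))))
            b = prot(1, mutate(rng, a.residues, 0.4)[: int(rng.integers(10, 30))] or "M")
            score = aligner.align(a.residues, b.residues).score
            assert score == pytest.approx(
                oracles.nw_optimal_score(a.residues, b.residues), abs=1e-9
            )
            ident, cov_a, cov_b = pairwise_identity(a, b)
            options = {
                oracles.identity_coverage_of(sa, sb)
                for sa, sb in oracles.nw_all_optimal_alignments(a.residues, b.residues)
            }
            assert any(
                ident == pytest.approx(o[0]) and cov_a == pytest.approx(o[1])
                and cov_b == pytest.approx(o[2])
                for o in options
            )


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = [prot(i, "MKVLITGGAGFIGSHL") for i in range(4)]
        result = greedy_cluster(seqs, ClusterParams(0.5, 0.8))
        assert len(result) == 1
        assert result.clusters[0].size == 4

    def test_transitive_linkage(self, rng):
        # A-B and B-C pass, A-C does not: single linkage puts all three together
        base = random_protein(rng, 60)
        a = prot(0, base)
        b = prot(1, mutate(rng, base, 0.35))
        c = prot(2, mutate(rng, b.residues, 0.35))
        iab = pairwise_identity(a, b)[0]
        ibc = pairwise_identity(b, c)[0]
        iac = pairwise_identity(a, c)[0]
        thr = max(iac + 0.01, 0.5)
        if not (iab >= thr and ibc >= thr and iac < thr):
            pytest.skip("random draw did not produce the chain configuration")
        result = greedy_cluster([a, b, c], ClusterParams(thr, 0.0))
        assert len(result) == 1

    def test_threshold_is_inclusive(self):
        # 0.49 identity with threshold 0.50 -> two singletons
        a = SequenceRecord("a", "g", "A" * 49 + "C" * 51, "rrna")
        b = SequenceRecord("b", "g", "A" * 49 + "G" * 51, "rrna")
        ident = pairwise_identity(a, b)[0]
        assert ident == pytest.approx(0.49)
        result = greedy_cluster([a, b], ClusterParams(0.50, 0.0))
        assert len(result) == 2

    def test_matches_component_oracle(self, rng):
        for rep in range(10):
            n = int(rng.integers(5, 15))
            base = random_protein(rng, 50)
            seqs = [
                prot(i, mutate(rng, base, float(rng.uniform(0.1, 0.9)))) for i in range(n)
            ]
            params = ClusterParams(0.5, 0.8)
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    ident, ca, cb = pairwise_identity(seqs[i], seqs[j])
                    if ident >= 0.5 and min(ca, cb) >= 0.8:
                        edges.append((i, j))
            expected = {
                frozenset(seqs[i].id for i in comp)
                for comp in oracles.connected_components(n, edges)
            }
            got = {
                frozenset(c.member_ids()) for c in greedy_cluster(seqs, params).clusters
            }
            assert got == expected

    def test_input_order_invariance(self, rng):
        base = random_protein(rng, 50)
        seqs = [prot(i, mutate(rng, base, 0.3)) for i in range(8)]
        params = ClusterParams(0.5, 0.8)
        a = greedy_cluster(seqs, params)
        b = greedy_cluster(list(reversed(seqs)), params)
        assert [c.member_ids() for c in a.clusters] == [c.member_ids() for c in b.clusters]


class TestProgressiveAlign:
    def test_single_sequence(self):
        seq = prot(0, "MKVLIT")
        aln = progressive_align([seq])
        assert aln.rows[0].residues == "MKVLIT"

    def test_two_identical_no_gaps(self):
        seqs = [prot(0, "MKVLITGG"), prot(1, "MKVLITGG")]
        aln = progressive_align(seqs)
        assert all("-" not in r.residues for r in aln.rows)

    def test_deletion_produces_single_gap_block(self, rng):
        base = random_protein(rng, 60)
        deleted = base[:30] + base[33:]
        seqs = [prot(0, base), prot(1, base), prot(2, deleted)]
        aln = progressive_align(seqs)
        row = next(r.residues for r in aln.rows if r.id == "s002")
        assert row.count("-") == 3
        start = row.index("-")
        assert row[start : start + 3] == "---"

    def test_two_seq_score_equals_pairwise_nw(self, rng):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score, aligner.extend_gap_score = -11.0, -1.0
        for _ in range(10):
            a = prot(0, random_protein(rng, 50))
            b = prot(1, mutate(rng, a.residues, 0.3))
            aln = progressive_align([a, b])
            assert aln.score == pytest.approx(aligner.align(a.residues, b.residues).score)

    def test_ungap_invariant(self, rng):
        base = random_protein(rng, 50)
        seqs = [prot(i, mutate(rng, base, 0.3)) for i in range(6)]
        aln = progressive_align(seqs)
        originals = {s.id: s.residues for s in seqs}
        for row in aln.rows:
            assert row.residues.replace("-", "") == originals[row.id]


class TestFilterColumns:
    def make_alignment(self, rows):
        return Alignment(rows=[prot(i, r) for i, r in enumerate(rows)])

    def test_conserved_column_kept(self):
        aln = self.make_alignment(["A", "A", "A", "A"])
        out = filter_columns(aln)
        assert out.column_mask[0]
        assert out.gap_fraction[0] == 0.0
        assert out.homogeneity[0] == 1.0

    def test_gappy_column_removed(self):
        aln = self.make_alignment(["A", "-", "-", "-"])
        out = filter_columns(aln)
        assert not out.column_mask[0]
        assert out.gap_fraction[0] == pytest.approx(0.75)

    def test_heterogeneous_column_removed(self):
        aln = self.make_alignment(["A", "C", "D", "E", "F"])
        out = filter_columns(aln)
        assert out.homogeneity[0] == 0.0
        assert not out.column_mask[0]

    def test_boundary_gap_fraction_half_kept(self):
        # gap fraction exactly 0.5 is NOT > 0.5 -> kept (if homogeneous)
        aln = self.make_alignment(["A", "A", "-", "-"])
        out = filter_columns(aln)
        assert out.column_mask[0]

    def test_idempotent(self, rng):
        rows = ["".join(rng.choice(list(AA + "-"), 30)) for _ in range(6)]
        rows = [r if r.strip("-") else "A" * 30 for r in rows]
        aln = Alignment(rows=[prot(i, r) for i, r in enumerate(rows)])
        once = filter_columns(aln)
        twice = filter_columns(once)
        np.testing.assert_array_equal(once.column_mask, twice.column_mask)


class TestBuildProfile:
    def test_single_sequence_one_hot(self):
        aln = Alignment(rows=[prot(0, "AC")])
        profile = build_profile(aln)
        a_idx = "ACDEFGHIKLMNPQRSTVWY".index("A")
        assert profile.freqs[0, a_idx] == pytest.approx((1 + 0.05) / 2.0)

    def test_pseudocount_arithmetic(self):
        aln = Alignment(rows=[prot(i, c) for i, c in enumerate("AAAC")])
        profile = build_profile(aln)
        a_idx = "ACDEFGHIKLMNPQRSTVWY".index("A")
        c_idx = "ACDEFGHIKLMNPQRSTVWY".index("C")
        assert profile.freqs[0, a_idx] == pytest.approx((3 + 0.05) / 5.0)
        assert profile.freqs[0, c_idx] == pytest.approx((1 + 0.05) / 5.0)

    @given(data=st.data())
    @settings(max_examples=20, deadline=None)
    def test_frequencies_sum_to_one(self, data):
        n = data.draw(st.integers(2, 6))
        length = data.draw(st.integers(1, 20))
        rows = [
            data.draw(st.text(alphabet=AA + "-", min_size=length, max_size=length))
            for _ in range(n)
        ]
        if all(set(r) == {"-"} for r in rows):
            rows[0] = "A" * length
        aln = Alignment(rows=[prot(i, r) for i, r in enumerate(rows)])
        try:
            profile = build_profile(aln)
        except EmptyProfileError:
            return
        np.testing.assert_allclose(profile.freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_all_masked_raises(self):
        aln = Alignment(rows=[prot(0, "ACD")], column_mask=np.zeros(3, dtype=bool))
        with pytest.raises(EmptyProfileError):
            build_profile(aln)
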