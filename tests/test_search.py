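import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abcfam.alphabet import AA20, encode
from abcfam.errors import ValidationError
from abcfam.io_formats import DomainHit, ProteinRecord
from abcfam.search import (
    build_profile,
    count_nbds,
    filter_candidates,
    profile_from_sequence,
    read_profile,
    scan_protein,
    write_profile,
)
from abcfam.synthetic import make_family_archetypes, mutate

from ._oracles import oracle_local_score


def _dh(pid, full_e, ieval=1e-10, start=1, end=100, bits=50.0):
    return DomainHit(pid, "NBD", start, end, full_e, ieval, bits)


class TestFilterCandidates:
    def test_below_cutoff_retained(self):
        assert filter_candidates([_dh("p", 9.9)]) == {"p"}

    def test_cutoff_boundary_is_strict(self):
        assert filter_candidates([_dh("p", 10.0)]) == set()

    def test_empty(self):
        assert filter_candidates([]) == set()

    def test_best_evalue_decides(self):
        hits = [_dh("p", 50.0), _dh("p", 0.5)]
        assert filter_candidates(hits) == {"p"}


class TestBuildProfile:
    def test_requires_two_sequences(self):
        with pytest.raises(ValidationError):
            build_profile(["ACDEFGHIKLMN"])

    def test_identical_sequences_give_consensus_max(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        prof = build_profile([seq, seq], 0.1)
        for j, aa in enumerate(seq):
            assert prof.match_scores[j, AA20.index(aa)] == pytest.approx(
                prof.match_scores[j, :20].max()
            )

    def test_column_monotonicity(self):
        prof = build_profile(["G" * 12, "G" * 12, "G" * 12], 0.1)
        g, w = AA20.index("G"), AA20.index("W")
        assert prof.match_scores[0, g] > prof.match_scores[0, w]

    def test_gappy_columns_removed(self):
        # 20 columns; columns 3 and 7 (0-based) have 3/5 gaps -> removed
        base = "ACDEFGHIKLMNPQRSTVWY"
        seqs = []
        for i in range(5):
            s = list(base)
            if i < 3:
                s[3] = "-"
                s[7] = "-"
            seqs.append("".join(s))
        prof = build_profile(seqs, 0.5)
        assert prof.length == 18

    def test_roundtrip_serialization(self, tmp_path):
        prof = build_profile(["ACDEFGHIKLMN", "ACDEFGHIKLMN"], 0.3)
        write_profile(prof, tmp_path / "p.tsv")
        back = read_profile(tmp_path / "p.tsv")
        assert back.length == prof.length
        assert back.gap_open == prof.gap_open
        assert back.score_threshold == prof.score_threshold
        np.testing.assert_allclose(back.match_scores, prof.match_scores)


@pytest.fixture(scope="module")
def consensus_profile():
    """Profile over 5 mutated copies of a 60-residue core."""
    rng = np.random.default_rng(5)
    arch = make_family_archetypes(5)
    core = arch["C"][:60]
    seqs = [mutate(core, 0.05, rng) for _ in range(5)]
    prof = build_profile(seqs, 0.5, score_threshold=25.0)
    return prof


def _consensus(profile):
    return "".join(AA20[int(j)] for j in profile.match_scores[:, :20].argmax(axis=1))


def _random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


class TestScanProtein:
    def test_embedded_consensus_found_exactly(self, consensus_profile):
        rng = np.random.default_rng(0)
        cons = _consensus(consensus_profile)
        seq = _random_protein(rng, 50) + cons + _random_protein(rng, 40)
        hits = scan_protein(consensus_profile, ProteinRecord("p", "sp", seq))
        assert len(hits) == 1
        assert hits[0].interval == (50, 50 + len(cons))

    def test_random_protein_yields_no_hits(self, consensus_profile):
        rng = np.random.default_rng(1)
        rec = ProteinRecord("p", "sp", _random_protein(rng, 300))
        assert scan_protein(consensus_profile, rec) == []

    def test_two_copies_give_two_disjoint_hits(self, consensus_profile):
        rng = np.random.default_rng(2)
        cons = _consensus(consensus_profile)
        seq = (_random_protein(rng, 30) + cons + _random_protein(rng, 60)
               + cons + _random_protein(rng, 30))
        hits = scan_protein(consensus_profile, ProteinRecord("p", "sp", seq))
        assert len(hits) == 2
        (s1, e1), (s2, e2) = sorted(h.interval for h in hits)
        assert e1 <= s2

    def test_hits_sorted_best_first(self, consensus_profile):
        rng = np.random.default_rng(3)
        cons = _consensus(consensus_profile)
        degraded = mutate(cons, 0.1, rng)
        seq = (_random_protein(rng, 30) + degraded + _random_protein(rng, 60)
               + cons + _random_protein(rng, 30))
        hits = scan_protein(consensus_profile, ProteinRecord("p", "sp", seq))
        assert len(hits) == 2
        assert hits[0].bitscore >= hits[1].bitscore

    def test_matches_bruteforce_oracle(self, consensus_profile):
        """Best scan score equals exhaustive DP over proteins <= 200 aa."""
        prof = consensus_profile
        rng = np.random.default_rng(4)
        cons = _consensus(prof)
        for trial in range(20):
            length = int(rng.integers(30, 201))
            seq = _random_protein(rng, length)
            if trial % 2:  # half the trials contain signal
                pos = int(rng.integers(0, max(1, length - 60)))
                seq = seq[:pos] + mutate(cons, 0.15, rng)[: length - pos] + \
                    seq[pos + min(60, length - pos):]
                seq = seq[:length]
            S = prof.match_scores[:, encode(seq)].T.copy()
            expected = max(0.0, oracle_local_score(S, prof.gap_open, prof.gap_extend))
            hits = scan_protein(prof, ProteinRecord("p", "sp", seq))
            got = max((h.bitscore * 2 for h in hits), default=0.0)
            if expected / 2.0 >= prof.score_threshold:
                assert got == pytest.approx(expected, abs=1e-9)
            else:
                assert got == 0.0

    def test_score_decays_with_mutation_rate(self, consensus_profile):
        """Planted-domain score is monotone non-increasing in mutation rate."""
        from abcfam.search import best_local_score

        cons = _consensus(consensus_profile)
        means = []
        for rate in (0.0, 0.15, 0.3):
            scores = []
            for seed in range(20):
                rng = np.random.default_rng(100 + seed)
                seq = _random_protein(rng, 40) + mutate(cons, rate, rng) + \
                    _random_protein(rng, 40)
                scores.append(best_local_score(consensus_profile, seq))
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]


class TestCountNbds:
    def test_two_disjoint_hits(self):
        hits = [_dh("p", 1e-30, 1e-30, 1, 180), _dh("p", 1e-30, 1e-25, 250, 430)]
        assert count_nbds(hits).count == 2

    def test_single_hit(self):
        assert count_nbds([_dh("p", 1e-30, 1e-30, 1, 180)]).count == 1

    def test_heavy_overlap_collapses(self):
        hits = [_dh("p", 1e-30, 1e-30, 1, 100, bits=60),
                _dh("p", 1e-30, 1e-20, 11, 110, bits=50)]  # 90% of shorter
        assert count_nbds(hits).count == 1

    def test_insignificant_hits_ignored(self):
        assert count_nbds([_dh("p", 1.0, 0.5, 1, 100)]).count == 0

    def test_mixed_proteins_raise(self):
        with pytest.raises(ValidationError):
            count_nbds([_dh("a", 1e-30), _dh("b", 1e-30)])

    @given(st.permutations(range(4)))
    @settings(deadline=None, max_examples=24)
    def test_order_invariance(self, perm):
        hits = [
            _dh("p", 1e-30, 1e-30, 1, 180, bits=90),
            _dh("p", 1e-30, 1e-28, 240, 420, bits=80),
            _dh("p", 1e-30, 1e-10, 150, 330, bits=40),
            _dh("p", 1e-30, 5e-3, 500, 560, bits=20),
        ]
        shuffled = [hits[i] for i in perm]
        ref = count_nbds(hits)
        got = count_nbds(shuffled)
        assert got.count == ref.count
        assert got.intervals == ref.intervals

    def test_intervals_disjoint_beyond_overlap_limit(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            hits = [
                _dh("p", 1e-30, float(10.0 ** -rng.integers(5, 40)),
                    int(s := rng.integers(1, 400)), int(s + rng.integers(30, 200)),
                    bits=float(rng.integers(20, 90)))
                for _ in range(6)
            ]
            res = count_nbds(hits, max_overlap_frac=0.5)
            for a in range(len(res.intervals)):
                for b in range(a + 1, len(res.intervals)):
                    (s1, e1), (s2, e2) = res.intervals[a], res.intervals[b]
                    overlap = max(0, min(e1, e2) - max(s1, s2))
                    assert overlap <= 0.5 * min(e1 - s1, e2 - s2)


def test_planting_k_copies_yields_count_k(consensus_profile):
    """k non-overlapping consensus copies -> NBD count k, k in {1,2,3}."""
    rng = np.random.default_rng(6)
    cons = _consensus(consensus_profile)
    for k in (1, 2, 3):
        seq = _random_protein(rng, 40)
        for _ in range(k):
            seq += cons + _random_protein(rng, 70)
        hits = scan_protein(consensus_profile, ProteinRecord("p", "sp", seq))
        assert count_nbds(hits).count == k


def test_profile_from_sequence_matches_consensus():
    prof = profile_from_sequence("ACDEFGHIKLMN", 0.3)
    for j, aa in enumerate("ACDEFGHIKLMN"):
        assert prof.match_scores[j, :20].argmax() == AA20.index(aa)
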