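"""Identity, optimal copy matching, Jaccard and DSS."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, strategies as st

from gnevo.similarity import (
    AlignmentParams,
    DomainCopyProfile,
    all_vs_all,
    compare_profiles,
    dss_index,
    jaccard_index,
    match_domain_copies,
    optimal_assignment,
    pairwise_identity,
    trim_surplus,
)


def gotoh_score(a, b, matrix, gap_open, gap_extend):
    """Independent affine-gap global alignment score (full DP, three states)."""
    NEG = float("-inf")
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (vertical)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[la][lb], X[la][lb], Y[la][lb])


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKVLAWTQ", "MKVLAWTQ") == 100.0

    def test_fully_dissimilar_no_gap(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_score_matches_full_dp_oracle(self):
        # 12-residue pair; the aligner's optimal score must equal the
        # independent Gotoh DP under identical parameters
        a, b = "MKVLAWGHEDTQ", "MKILAWGQEDSQ"
        params = AlignmentParams()
        blosum = substitution_matrices.load("BLOSUM62")
        expect = gotoh_score(a, b, blosum, params.gap_open, params.gap_extend)
        from gnevo.similarity import _make_aligner

        got = _make_aligner(params).align(a, b).score
        assert got == pytest.approx(expect)
        # no-gap optimum here: identity = matches / columns, unique optimum
        matches = sum(x == y for x, y in zip(a, b))
        assert pairwise_identity(a, b) == pytest.approx(100.0 * matches / 12)

    @given(st.data())
    def test_score_oracle_on_random_pairs(self, data):
        alpha = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(data.draw(st.lists(st.sampled_from(alpha), min_size=1, max_size=9)))
        b = "".join(data.draw(st.lists(st.sampled_from(alpha), min_size=1, max_size=9)))
        params = AlignmentParams()
        blosum = substitution_matrices.load("BLOSUM62")
        from gnevo.similarity import _make_aligner

        assert _make_aligner(params).align(a, b).score == pytest.approx(
            gotoh_score(a, b, blosum, params.gap_open, params.gap_extend)
        )

    def test_symmetric_and_bounded(self):
        a, b = "MKVAWTTGHE", "MKVAWQPGHE"
        ab, ba = pairwise_identity(a, b), pairwise_identity(b, a)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 100.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MK")


def brute_force_assignment(matrix):
    """Maximum-total assignment by enumerating all permutations."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    best, best_pairs = float("-inf"), None
    for perm in itertools.permutations(range(matrix.shape[1]), n):
        total = sum(matrix[i, perm[i]] for i in range(n))
        if total > best:
            best, best_pairs = total, sorted(zip(range(n), perm))
    return best, best_pairs


class TestMatching:
    def test_single_pair(self):
        pairs = match_domain_copies(
            [("a", "M")], [("b", "M")], identity_matrix=np.array([[1.0]])
        )
        assert pairs == [(0, 0, 1.0)]

    def test_two_by_two_prefers_diagonal(self):
        M = np.array([[0.9, 0.2], [0.3, 0.8]])
        pairs = match_domain_copies(
            [("a1", ""), ("a2", "")], [("b1", ""), ("b2", "")], identity_matrix=M
        )
        assert [(i, j) for i, j, _ in pairs] == [(0, 0), (1, 1)]
        assert np.mean([p[2] for p in pairs]) == pytest.approx(0.85)

    @given(st.data())
    def test_hungarian_equals_brute_force(self, data):
        n = data.draw(st.integers(min_value=1, max_value=6))
        M = np.array(
            [[data.draw(st.floats(0, 1, width=32)) for _ in range(n)] for _ in range(n)]
        )
        best, _ = brute_force_assignment(M)
        pairs = optimal_assignment(M)
        assert sum(M[i, j] for i, j in pairs) == pytest.approx(best)

    def test_surplus_trim_then_assignment_equals_injection_oracle(self, rng):
        # 3 vs 2: drop the copy with the lowest best identity, then match;
        # oracle = best over all injections of 2 columns into 3 rows
        for _ in range(50):
            M = rng.random((3, 2))
            kept = trim_surplus(M, ["a", "b", "c"])
            assert len(kept) == 2
            dropped = ({0, 1, 2} - set(kept)).pop()
            assert M[dropped].max() == pytest.approx(M.max(axis=1).min())
            pairs = match_domain_copies(
                [("a", ""), ("b", ""), ("c", "")],
                [("x", ""), ("y", "")],
                identity_matrix=M,
            )
            total = sum(p[2] for p in pairs)
            Msub = M[kept]
            best, _ = brute_force_assignment(Msub.T)  # 2 rows into 2 cols
            assert total == pytest.approx(best)

    def test_tie_breaks_by_gene_id(self):
        M = np.array([[0.5, 0.5], [0.5, 0.5], [0.9, 0.9]])
        kept = trim_surplus(M, ["z_gene", "a_gene", "m_gene"])
        # rows 0 and 1 tie at 0.5; 'a_gene' (row 1) sorts first and is dropped
        assert kept == [0, 2]


def make_profile(gn_id, copies, extra_families=()):
    prof = DomainCopyProfile(gn_id=gn_id)
    for fam, seqs in copies.items():
        prof.copies[fam] = [(f"{gn_id}_{fam}{i}", s) for i, s in enumerate(seqs)]
        prof.families.add(fam)
    prof.families |= set(extra_families)
    return prof


class TestJaccardAndDss:
    def test_jaccard_worked_example(self):
        a = make_profile("a", {}, {"OSC", "CYP705A", "CYP708A", "ACT_IIIa"})
        b = make_profile("b", {}, {"OSC", "CYP705A", "ACT_IIIa"})
        assert jaccard_index(a, b) == pytest.approx(0.75)
        assert jaccard_index(a, a) == 1.0
        assert jaccard_index(
            make_profile("c", {}, {"X"}), make_profile("d", {}, {"Y"})
        ) == 0.0

    def test_self_comparison_is_exactly_one(self):
        prof = make_profile("a", {"f": ["MKVLAW", "MKVAAW"], "g": ["MCDEF"]})
        assert dss_index(prof, prof) == 1.0
        sim = compare_profiles(prof, prof)
        assert sim.jaccard == 1.0 and sim.avg_identity == pytest.approx(100.0)

    def test_dss_hand_expansion(self):
        # family f: 2 vs 1 copies (best identity 0.8), g: 1 vs 1 (0.6)
        # => (0.8 + 0.6) / (max(2,1) + max(1,1)) = 0.4667
        a = make_profile("a", {"f": ["x", "y"], "g": ["z"]})
        b = make_profile("b", {"f": ["w"], "g": ["v"]})
        idm = {("f"): np.array([[0.8], [0.2]]), ("g"): np.array([[0.6]])}

        num = 0.0
        for fam in ("f", "g"):
            pairs = match_domain_copies(a.copies[fam], b.copies[fam],
                                        identity_matrix=idm[fam])
            num += sum(p[2] for p in pairs)
        denom = max(2, 1) + max(1, 1)
        assert num / denom == pytest.approx((0.8 + 0.6) / 3)

    def test_no_shared_families_gives_zero_dss_undefined_identity(self):
        a = make_profile("a", {"f": ["MKVLAW"]})
        b = make_profile("b", {"g": ["MKVLAW"]})
        sim = compare_profiles(a, b)
        assert sim.dss == 0.0
        assert sim.avg_identity is None
        assert sim.n_shared_families == 0

    def test_symmetry_and_bounds(self):
        a = make_profile("a", {"f": ["MKVLAWHH", "MKVAAWHH"], "g": ["MCDEFKL"]})
        b = make_profile("b", {"f": ["MKILAWHY"], "h": ["MWWWQ"]})
        ab, ba = compare_profiles(a, b), compare_profiles(b, a)
        assert ab.dss == pytest.approx(ba.dss)
        assert ab.jaccard == pytest.approx(ba.jaccard)
        assert ab.avg_identity == pytest.approx(ba.avg_identity)
        assert 0.0 <= ab.dss <= 1.0 and 0.0 <= ab.jaccard <= 1.0
        assert ab.avg_identity <= 100.0

    def test_removing_private_family_never_lowers_similarity(self):
        a = make_profile("a", {"f": ["MKVLAWHH"], "g": ["MCDEFKL"]})
        b = make_profile("b", {"f": ["MKVLAWHY"]})
        with_private = compare_profiles(a, b)
        del a.copies["g"]
        a.families.discard("g")
        without = compare_profiles(a, b)
        assert without.jaccard >= with_private.jaccard
        assert without.dss >= with_private.dss


class TestAllVsAll:
    def test_bin_counts_recompute_from_pair_table(self, planted_dataset):
        ds, _ = planted_dataset
        from gnevo.neighbourhoods import extract_neighbourhoods

        gns = []
        for genome in ds.genomes:
            targets = [t for t in ds.target_ids if t in genome]
            gns.extend(extract_neighbourhoods(genome, targets))
        table, summary = all_vs_all(gns, ds.genomes)
        n = summary["n_gns"]
        assert summary["total_pairs"] == n * (n - 1) // 2 == len(table)
        assert summary["pairs_no_shared"] + summary["pairs_shared"] == len(table)
        shared = table[table.n_shared_families > 0]
        assert summary["pairs_jaccard_ge_0.5"] == int((shared.jaccard >= 0.5).sum())
        assert summary["pairs_identity_lt_50"] == int((shared.avg_identity < 50).sum())
        assert summary["pairs_dss_le_0.3"] == int((shared.dss <= 0.3).sum())

    def test_fewer_than_two_gns_errors(self, planted_dataset):
        ds, _ = planted_dataset
        genome = ds.genomes[0]
        from gnevo.neighbourhoods import extract_neighbourhoods

        targets = [t for t in ds.target_ids if t in genome]
        gns = extract_neighbourhoods(genome, targets)
        with pytest.raises(ValueError, match=">= 2"):
            all_vs_all(gns, [genome])
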