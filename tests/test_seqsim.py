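import numpy as np
import pytest

from ppinet.seqsim import (
    AMINO_ACIDS,
    BLOSUM_LEVELS,
    BenchmarkConfig,
    ProteinSequence,
    composition_features,
    load_blosum,
    make_benchmark,
    packaged_blosum,
    perturb_sequence,
    substitution_model,
    sw_identity,
)


@pytest.fixture(scope="module")
def blosum62():
    return packaged_blosum("BLOSUM62")


@pytest.fixture(scope="module")
def model62(blosum62):
    return substitution_model(blosum62)


class TestLoadBlosum:
    @pytest.mark.parametrize("name", ["BLOSUM30", "BLOSUM40", "BLOSUM62", "BLOSUM80"])
    def test_packaged_matrices_parse(self, name):
        B = packaged_blosum(name)
        assert len(B.symbols) == 24  # 20 aa + B, Z, X, *
        assert {"B", "Z", "X", "*"} <= set(B.symbols)

    def test_symmetry(self, blosum62):
        for a in blosum62.symbols:
            for b in blosum62.symbols:
                assert blosum62.score(a, b) == blosum62.score(b, a)

    def test_known_blosum62_values(self, blosum62):
        # spot checks against the published matrix
        assert blosum62.score("A", "A") == 4
        assert blosum62.score("W", "W") == 11
        assert blosum62.score("A", "W") == -3

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_blosum(tmp_path / "nope.txt")

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("AB C\n")
        with pytest.raises(ValueError):
            load_blosum(p)

    def test_asymmetric_rejected(self, tmp_path):
        p = tmp_path / "asym.txt"
        p.write_text("   A  R\nA  4 -1\nR -2  5\n")
        with pytest.raises(ValueError):
            load_blosum(p)


class TestSubstitutionModel:
    def test_rows_sum_to_one(self, model62):
        assert np.allclose(model62.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_diagonal(self, model62):
        assert np.all(np.diag(model62.probabilities) == 0.0)

    def test_monotone_in_score(self, blosum62, model62):
        # within a row, a higher BLOSUM score gives a higher probability
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                for k, c in enumerate(AMINO_ACIDS):
                    if j == i or k == i:
                        continue
                    if blosum62.score(a, b) > blosum62.score(a, c):
                        assert (
                            model62.probabilities[i, j] > model62.probabilities[i, k]
                        )


class TestPerturbSequence:
    def _seq(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return ProteinSequence("s", "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, n)]))

    def test_level_zero_identity(self, model62):
        s = self._seq(50)
        out = perturb_sequence(s, 0.0, model62, rng=np.random.default_rng(0))
        assert out.residues == s.residues

    def test_exact_fraction_blosum80_level(self, model62):
        s = self._seq(100)
        out, d = perturb_sequence(
            s, 0.20, model62, deletion_fraction=0.1,
            rng=np.random.default_rng(1), detail=True,
        )
        assert len(d["substituted"]) + len(d["deleted"]) == 20

    def test_no_deletions_preserves_length(self, model62):
        s = self._seq(100)
        out, d = perturb_sequence(
            s, 0.70, model62, deletion_fraction=0.0,
            rng=np.random.default_rng(2), detail=True,
        )
        assert len(out) == 100
        assert len(d["substituted"]) == 70
        diffs = sum(a != b for a, b in zip(s.residues, out.residues))
        assert diffs == 70  # substitutions always change the residue

    def test_deletion_count(self, model62):
        s = self._seq(200)
        out, d = perturb_sequence(
            s, 0.5, model62, deletion_fraction=0.2,
            rng=np.random.default_rng(3), detail=True,
        )
        assert len(d["deleted"]) == round(0.2 * 0.5 * 200)
        assert len(out) == 200 - len(d["deleted"])

    def test_sub_single_position_warning(self, model62):
        s = self._seq(10)
        with pytest.warns(UserWarning, match="fewer than one"):
            out = perturb_sequence(s, 0.01, model62, rng=np.random.default_rng(0))
        assert out.residues == s.residues

    def test_reproducible(self, model62):
        s = self._seq(80)
        a = perturb_sequence(s, 0.4, model62, rng=np.random.default_rng(9))
        b = perturb_sequence(s, 0.4, model62, rng=np.random.default_rng(9))
        assert a.residues == b.residues

    def test_invalid_level(self, model62):
        with pytest.raises(ValueError):
            perturb_sequence(self._seq(10), 1.5, model62)


class TestSwIdentity:
    def test_identical_sequences(self, blosum62):
        s = "MKTAYIAKQR"
        assert sw_identity(s, s, blosum62) == pytest.approx(100.0)

    def test_dissimilar_no_alignment(self, blosum62):
        assert sw_identity("AAAA", "WWWW", blosum62) == 0.0

    def test_symmetric(self, blosum62):
        a, b = "MKTAYIAKQR", "MKTAYIWKQR"
        assert sw_identity(a, b, blosum62) == pytest.approx(sw_identity(b, a, blosum62))

    def test_bounded(self, blosum62, rng):
        aa = np.array(list(AMINO_ACIDS))
        for _ in range(5):
            a = "".join(aa[rng.integers(0, 20, 30)])
            b = "".join(aa[rng.integers(0, 20, 30)])
            v = sw_identity(a, b, blosum62)
            assert 0.0 <= v <= 100.0

    def test_empty_rejected(self, blosum62):
        with pytest.raises(ValueError):
            sw_identity("", "AAA", blosum62)

    def test_short_pair_matches_dp_oracle(self, blosum62):
        # full Smith-Waterman DP with affine gaps and traceback, brute force
        def sw_oracle(s1, s2, go=10.0, ge=1.0):
            n1, n2 = len(s1), len(s2)
            NEG = -1e9
            M = np.full((n1 + 1, n2 + 1), 0.0)
            Ix = np.full((n1 + 1, n2 + 1), NEG)
            Iy = np.full((n1 + 1, n2 + 1), NEG)
            best = (0.0, 0, 0, None)
            for i in range(1, n1 + 1):
                for j in range(1, n2 + 1):
                    sub = blosum62.score(s1[i - 1], s2[j - 1])
                    Ix[i, j] = max(M[i - 1, j] - go - ge, Ix[i - 1, j] - ge)
                    Iy[i, j] = max(M[i, j - 1] - go - ge, Iy[i, j - 1] - ge)
                    M[i, j] = max(
                        0.0,
                        sub + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]),
                    )
                    if M[i, j] > best[0]:
                        best = (M[i, j], i, j, "M")
            # traceback for identity
            score, i, j, state = best
            if score <= 0:
                return 0.0, 0.0
            ident = length = 0
            while state is not None and (i > 0 and j > 0):
                if state == "M":
                    if M[i, j] == 0:
                        break
                    length += 1
                    if s1[i - 1] == s2[j - 1]:
                        ident += 1
                    prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
                    if prev == M[i - 1, j - 1]:
                        state = "M"
                    elif prev == Ix[i - 1, j - 1]:
                        state = "Ix"
                    else:
                        state = "Iy"
                    i, j = i - 1, j - 1
                    if state == "M" and M[i, j] == 0:
                        break
                elif state == "Ix":
                    length += 1
                    if Ix[i, j] == M[i - 1, j] - 11.0:
                        state = "M"
                    i -= 1
                else:
                    length += 1
                    if Iy[i, j] == M[i, j - 1] - 11.0:
                        state = "M"
                    j -= 1
            return score, 100.0 * ident / length if length else 0.0

        pairs = [("MKTAYI", "MKTAYI"), ("MKTAYI", "MKTWYI"), ("ACDEFG", "ACDFG"),
                 ("WWAAWW", "WWCCWW")]
        from Bio import Align

        for a, b in pairs:
            score, ident = sw_oracle(a, b)
            # cross-check the alignment score itself against the aligner
            aligner = Align.PairwiseAligner()
            aligner.mode = "local"
            aligner.substitution_matrix = blosum62.to_aligner_matrix()
            aligner.open_gap_score = -11.0
            aligner.extend_gap_score = -1.0
            assert aligner.score(a, b) == pytest.approx(score)
            assert sw_identity(a, b, blosum62) == pytest.approx(ident)


@pytest.fixture(scope="module")
def bench():
    return make_benchmark(
        n_proteins=24, n_modules=4, seq_len=60, seed=7,
        levels={"BLOSUM80": 0.20, "BLOSUM30": 0.70},
    )


class TestBenchmark:

    def test_reproducible(self, bench):
        again = make_benchmark(
            n_proteins=24, n_modules=4, seq_len=60, seed=7,
            levels={"BLOSUM80": 0.20, "BLOSUM30": 0.70},
        )
        assert [s.residues for s in again.sequences] == [
            s.residues for s in bench.sequences
        ]
        for lvl in bench.perturbed:
            assert [s.residues for s in again.perturbed[lvl]] == [
                s.residues for s in bench.perturbed[lvl]
            ]
        assert np.array_equal(again.features.values, bench.features.values)

    def test_module_clique_adjacency(self, bench):
        A = bench.network.adjacency
        expect = (bench.modules[:, None] == bench.modules[None, :]).astype(int)
        np.fill_diagonal(expect, 0)
        assert np.array_equal(A, expect)

    def test_identity_decreases_with_level(self, bench):
        mean_ident = {}
        for lvl in ("BLOSUM80", "BLOSUM30"):
            vals = [
                sw_identity(o, p)
                for o, p in zip(bench.sequences[:10], bench.perturbed[lvl][:10])
            ]
            mean_ident[lvl] = np.mean(vals)
        assert mean_ident["BLOSUM80"] > mean_ident["BLOSUM30"]

    def test_labels_carry_over(self, bench):
        for lvl, seqs in bench.perturbed.items():
            assert [s.id for s in seqs] == bench.protein_ids

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            BenchmarkConfig(n_proteins=4, n_modules=8)

    def test_default_levels(self):
        assert BLOSUM_LEVELS == {
            "BLOSUM30": 0.70, "BLOSUM40": 0.60, "BLOSUM62": 0.38, "BLOSUM80": 0.20,
        }


class TestCompositionFeatures:
    def test_frequencies_sum_to_one(self):
        seqs = [ProteinSequence("a", "ACDE"), ProteinSequence("b", "AAAA")]
        ft = composition_features(seqs, k=1)
        assert np.allclose(ft.values.sum(axis=1), 1.0)
        assert ft.values[1, 0] == pytest.approx(1.0)  # 'A' column

    def test_dipeptide_dimension(self):
        seqs = [ProteinSequence("a", "ACDEFG")]
        ft = composition_features(seqs, k=2)
        assert ft.values.shape == (1, 400)
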