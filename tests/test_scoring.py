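"""BLOSUM62/ESST lookup, the ESST text format, and the simplified estimator."""

import math

import numpy as np
import pytest

from _oracles import median_by_sort
from varstruct.annotate import StructuralEnvironment
from varstruct.scoring import (
    ESST,
    ESST_ALPHABET,
    SubstitutionTable,
    esst_lookup,
    estimate_esst,
    load_blosum62,
    lookup_score,
    negative_fraction,
    read_esst,
    score_variant_sets,
    write_esst,
)
from varstruct.variants import VariantRecord, VariantSet


@pytest.fixture(scope="module")
def blosum62():
    return load_blosum62()


class TestBlosum62:
    @pytest.mark.parametrize("pair,score", [
        (("G", "G"), 6), (("W", "R"), -3), (("A", "A"), 4), (("W", "W"), 11)])
    def test_known_entries(self, blosum62, pair, score):
        assert lookup_score(blosum62, *pair) == score

    def test_matches_published_matrix(self, blosum62):
        # entry-by-entry check against an independently shipped copy
        from Bio.Align import substitution_matrices

        reference = substitution_matrices.load("BLOSUM62")
        for a in ESST_ALPHABET:
            for b in ESST_ALPHABET:
                assert lookup_score(blosum62, a, b) == reference[a, b]

    def test_symmetry(self, blosum62):
        assert blosum62.is_symmetric

    def test_unknown_letter_named_in_error(self, blosum62):
        with pytest.raises(KeyError, match="J"):
            lookup_score(blosum62, "A", "J")


def constant_esst(codes_and_values):
    esst = ESST("toy")
    for code, value in codes_and_values:
        esst.tables[code] = SubstitutionTable(
            f"ENV{code}", ESST_ALPHABET, np.full((20, 20), float(value)))
    return esst


class TestEsstLookup:
    def test_environment_specificity(self):
        esst = constant_esst([(0, 1.0), (17, -2.0)])
        assert esst_lookup(esst, 0, "A", "V") == 1.0
        assert esst_lookup(esst, 17, "A", "V") == -2.0

    def test_undeclared_environment_errors(self):
        esst = constant_esst([(0, 1.0)])
        with pytest.raises(KeyError):
            esst_lookup(esst, 5, "A", "V")

    def test_blosum_replicated_everywhere_degenerates(self, blosum62):
        esst = ESST("blosum-everywhere")
        for code in range(64):
            esst.tables[code] = SubstitutionTable(
                f"ENV{code}", ESST_ALPHABET,
                np.array([[blosum62.score(a, b) for b in ESST_ALPHABET]
                          for a in ESST_ALPHABET]))
        for code in (0, 13, 63):
            for a, b in [("A", "V"), ("W", "R"), ("G", "G")]:
                assert esst_lookup(esst, code, a, b) == blosum62.score(a, b)

    def test_text_format_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        esst = ESST("rt")
        for code in (0, 7, 63):
            esst.tables[code] = SubstitutionTable(
                f"ENV{code}", ESST_ALPHABET,
                rng.integers(-9, 10, size=(20, 20)).astype(float))
        path = tmp_path / "esst.txt"
        write_esst(esst, path)
        again = read_esst(path)
        assert again.environments() == [0, 7, 63]
        for code in again.environments():
            assert np.array_equal(again.tables[code].scores,
                                  esst.tables[code].scores)


class TestEstimateEsst:
    def test_hand_computed_single_column(self):
        # one column A/A/V in environment 0: ordered pairs A->A x2,
        # A->V x2, V->A x2; background f(A)=2/3, f(V)=1/3
        esst = estimate_esst([(0, "AAV")])
        table = esst.tables[0]
        p_aa = 3 / 24          # (2+1) / (2+2+18*1 + 2)
        p_av = 3 / 24
        p_va = 3 / 22
        p_vv = 1 / 22
        assert table.score("A", "A") == round(2 * math.log2(p_aa / (2 / 3)))
        assert table.score("A", "V") == round(2 * math.log2(p_av / (1 / 3)))
        assert table.score("V", "A") == round(2 * math.log2(p_va / (2 / 3)))
        assert table.score("V", "V") == round(2 * math.log2(p_vv / (1 / 3)))

    def test_identical_columns_give_positive_diagonal(self):
        columns = [(0, aa * 6) for aa in "ACDEFGHIKLMNPQRSTVWY"] * 3
        esst = estimate_esst(columns)
        scores = esst.tables[0].scores
        assert (np.diag(scores) > 0).all()
        off = scores[~np.eye(20, dtype=bool)]
        assert (off <= 0).all()

    def test_environment_independent_process_gives_equal_tables(self):
        rng = np.random.default_rng(21)
        columns = []
        for _ in range(4000):
            aa = ESST_ALPHABET[rng.integers(20)]
            column = "".join(aa if rng.random() < 0.7
                             else ESST_ALPHABET[rng.integers(20)]
                             for _ in range(8))
            columns.append((int(rng.integers(2)), column))
        esst = estimate_esst(columns)
        # scores are integers, so cells whose true log-odds sit near a
        # half-integer flip by 1 between the two estimates; equality within
        # pseudocount/rounding noise means no cell differs by more than 2
        # and most cells agree exactly
        diff = np.abs(esst.tables[0].scores - esst.tables[1].scores)
        assert diff.max() <= 2.0
        assert (diff <= 1.0).mean() > 0.95

    def test_conserved_environment_scores_lower_off_diagonal(self):
        rng = np.random.default_rng(22)
        columns = []
        for _ in range(1500):
            aa = ESST_ALPHABET[rng.integers(20)]
            strict = "".join(aa if rng.random() < 0.98
                             else ESST_ALPHABET[rng.integers(20)]
                             for _ in range(8))
            loose = "".join(aa if rng.random() < 0.5
                            else ESST_ALPHABET[rng.integers(20)]
                            for _ in range(8))
            columns.append((1, strict))
            columns.append((2, loose))
        esst = estimate_esst(columns)
        mask = ~np.eye(20, dtype=bool)
        assert (esst.tables[1].scores[mask].mean()
                < esst.tables[2].scores[mask].mean())

    def test_unseen_environment_filled_from_pooled(self):
        esst = estimate_esst([(0, "AAV")], environments=[0, 1])
        assert esst.pooled_envs == {1}
        assert np.array_equal(esst.tables[1].scores, esst.tables[0].scores)


class TestScoreVariantSets:
    def variants(self):
        recs = [VariantRecord("P1", i + 1, wt, var, "SVD")
                for i, (wt, var) in enumerate(
                    [("G", "G") if False else ("G", "A"), ("W", "R"),
                     ("A", "V"), ("D", "E")])]
        return VariantSet("SVD", recs)

    def test_negative_fraction(self, blosum62):
        scores = score_variant_sets([self.variants()], blosum62)
        # BLOSUM62: G->A 0, W->R -3, A->V 0, D->E 2 -> 1 of 4 negative
        frac = negative_fraction(scores)
        assert frac["SVD"] == pytest.approx(0.25)

    def test_environment_stratified_medians_match_sort_oracle(self, blosum62):
        env_a = StructuralEnvironment("H", True, False, False, False)
        env_b = StructuralEnvironment("E", False, True, False, True)
        envs = {}
        recs = []
        rng = np.random.default_rng(4)
        wts = list(ESST_ALPHABET)
        for i in range(40):
            wt = wts[rng.integers(20)]
            var = wts[(wts.index(wt) + 1 + int(rng.integers(19))) % 20]
            if wt == var:
                var = wts[(wts.index(wt) + 2) % 20]
            rec = VariantRecord("P1", i + 1, wt, var, "SVD")
            recs.append(rec)
            envs[rec.key] = env_a if i % 2 else env_b
        scores = score_variant_sets([VariantSet("SVD", recs)], blosum62,
                                    environments=envs)
        for ss, group in scores.groupby("ss"):
            assert group["blosum62"].median() == pytest.approx(
                median_by_sort(group["blosum62"]))
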