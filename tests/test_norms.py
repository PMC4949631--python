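"""Feature- and concept-level statistics over property norms."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from semdyn import (
    NormsFormatError,
    PropertyNorms,
    concept_statistics,
    feature_correlations,
    feature_statistics,
    read_norms,
    sharedness_bands,
    write_norms,
)
from semdyn.norms import BAND_D, BAND_HIGH_S, BAND_LOW_S

from .conftest import make_norms


class TestIO:
    def test_round_trip_preserves_entries(self, toy_norms, tmp_path):
        path = tmp_path / "norms.tsv"
        write_norms(toy_norms, path)
        assert read_norms(path) == toy_norms

    def test_written_files_are_byte_identical(self, toy_norms, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_norms(toy_norms, p1)
        write_norms(toy_norms, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_toy_file_counts(self, toy_norms):
        assert len(toy_norms.concepts) == 3
        assert len(toy_norms.features) == 6

    @pytest.mark.parametrize(
        "body, message",
        [
            ("cat\tf1\t0\t0\n", "positive integer"),
            ("cat\tf1\tmany\t0\n", "positive integer"),
            ("cat\tf1\t3\t2\n", "taxonomic"),
            ("cat\tf1\t3\t0\ncat\tf1\t4\t0\n", "duplicate"),
        ],
    )
    def test_malformed_input_names_the_line(self, tmp_path, body, message):
        path = tmp_path / "bad.tsv"
        path.write_text("concept\tfeature\tprod_freq\ttaxonomic\n" + body)
        with pytest.raises(NormsFormatError, match=message):
            read_norms(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("concept\tfeature\tprod_freq\ncat\tf1\t3\n")
        with pytest.raises(NormsFormatError, match="taxonomic"):
            read_norms(path)

    def test_empty_norms_rejected(self):
        with pytest.raises(NormsFormatError):
            PropertyNorms(pd.DataFrame(columns=["concept", "feature",
                                                "prod_freq", "taxonomic"]))

    def test_concept_with_only_taxonomic_features_rejected(self):
        with pytest.raises(NormsFormatError, match="non-taxonomic"):
            make_norms([("cat", "is_animal", 5, True),
                        ("dog", "barks", 5, False)])


class TestFeatureStatistics:
    @pytest.mark.parametrize(
        "k, d, cls",
        [(1, 1.0, "distinguishing"), (2, 0.5, "distinguishing"), (3, 1 / 3, "shared")],
    )
    def test_distinctiveness_is_inverse_concept_count(self, k, d, cls):
        rows = [(f"c{i}", "probe", 5, False) for i in range(k)]
        rows += [(f"c{i}", f"u{i}", 5, False) for i in range(max(k, 3))]
        stats = feature_statistics(make_norms(rows))
        assert stats.loc["probe", "k"] == k
        assert stats.loc["probe", "distinctiveness"] == pytest.approx(d)
        assert stats.loc["probe", "feature_class"] == cls

    def test_toy_norms_statistics(self, toy_norms):
        stats = feature_statistics(toy_norms)
        assert stats.loc["f_pair", "distinctiveness"] == 0.5
        assert stats.loc["f_all", "feature_class"] == "shared"
        assert stats.loc["has_fur", "distinctiveness"] == 1.0

    @given(st.integers(min_value=1, max_value=40))
    def test_distinctiveness_decreases_with_k(self, k):
        assert 0 < 1.0 / (k + 1) < 1.0 / k <= 1.0

    def test_relabeling_leaves_statistics_unchanged(self, small_norms):
        stats = feature_statistics(small_norms)
        table = small_norms.table.copy()
        table["concept"] = "X_" + table["concept"]
        table["feature"] = "Y_" + table["feature"]
        renamed = feature_statistics(PropertyNorms(table))
        renamed.index = renamed.index.str.replace("^Y_", "", regex=True)
        pd.testing.assert_frame_equal(stats, renamed.sort_index())


class TestSharednessBands:
    @staticmethod
    def _norms_with_shared_ks(ks):
        rows = []
        for j, k in enumerate(ks):
            rows += [(f"c{i}", f"s{j}", 4, False) for i in range(k)]
        n = max(ks)
        rows += [(f"c{i}", f"u{i}", 4, False) for i in range(n)]
        return make_norms(rows)

    def test_median_split_on_distinctiveness(self):
        norms = self._norms_with_shared_ks([3, 4, 5, 6])
        stats = sharedness_bands(feature_statistics(norms))
        assert stats.loc["s0", "band"] == BAND_LOW_S  # k=3
        assert stats.loc["s1", "band"] == BAND_LOW_S  # k=4
        assert stats.loc["s2", "band"] == BAND_HIGH_S  # k=5
        assert stats.loc["s3", "band"] == BAND_HIGH_S  # k=6

    def test_ties_go_to_high_s(self):
        norms = self._norms_with_shared_ks([4, 4, 4])
        stats = sharedness_bands(feature_statistics(norms))
        shared = stats[stats["feature_class"] == "shared"]
        assert (shared["band"] == BAND_HIGH_S).all()

    def test_distinguishing_features_keep_band_d(self, small_norms):
        stats = sharedness_bands(feature_statistics(small_norms))
        dist = stats[stats["feature_class"] == "distinguishing"]
        assert (dist["band"] == BAND_D).all()

    def test_too_few_shared_features_rejected(self):
        norms = make_norms([("a", "u1", 3, False), ("b", "u2", 3, False),
                            ("c", "u3", 3, False)])
        with pytest.raises(ValueError, match="shared"):
            sharedness_bands(feature_statistics(norms))


class TestFeatureCorrelations:
    def test_identical_vectors_correlate_perfectly(self):
        rows = []
        for i, f in enumerate([3, 5, 9]):
            rows += [(f"c{i}", "s0", f, False), (f"c{i}", "s1", f, False)]
        rows += [(f"c{i}", f"u{i}", 2, False) for i in range(3)]
        corr = feature_correlations(make_norms(rows))
        pair = corr.set_index(["feature_i", "feature_j"]).loc[("s0", "s1")]
        assert pair["r"] == pytest.approx(1.0)
        assert pair["significant"]

    def test_hand_computed_pair(self):
        # production vectors (1,2,3,0) and (0,3,2,1) over four concepts
        a, b = [1, 2, 3, 0], [0, 3, 2, 1]
        rows = []
        for i in range(4):
            if a[i]:
                rows.append((f"c{i}", "sa", a[i], False))
            if b[i]:
                rows.append((f"c{i}", "sb", b[i], False))
            rows.append((f"c{i}", f"u{i}", 2, False))
        corr = feature_correlations(make_norms(rows))
        pair = corr.set_index(["feature_i", "feature_j"]).loc[("sa", "sb")]
        av, bv = np.array(a, float), np.array(b, float)
        expected = (
            ((av - av.mean()) * (bv - bv.mean())).sum()
            / np.sqrt(((av - av.mean()) ** 2).sum() * ((bv - bv.mean()) ** 2).sum())
        )
        assert pair["r"] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_gives_missing_r(self):
        # s_const has the same frequency in every concept: zero variance
        rows = []
        for i in range(4):
            rows += [(f"c{i}", "s_const", 5, False), (f"c{i}", "s_var", i + 1, False),
                     (f"c{i}", f"u{i}", 2, False)]
        corr = feature_correlations(make_norms(rows))
        pair = corr.set_index(["feature_i", "feature_j"]).loc[("s_const", "s_var")]
        assert np.isnan(pair["r"])
        assert not pair["significant"]

    def test_matches_brute_force_pearson(self, small_norms):
        corr = feature_correlations(small_norms, alpha=0.05, positive_only=False)
        mat = small_norms.frequency_matrix()
        for _, row in corr.iterrows():
            x = mat[row["feature_i"]].to_numpy(float)
            y = mat[row["feature_j"]].to_numpy(float)
            if np.isnan(row["r"]):
                assert x.std() == 0 or y.std() == 0
                continue
            r, p = sps.pearsonr(x, y)
            assert row["r"] == pytest.approx(r, abs=1e-10)
            assert row["p"] == pytest.approx(p, abs=1e-8)
            assert row["significant"] == (p < 0.05)

    def test_no_shared_features_warns_and_returns_empty(self):
        norms = make_norms([("a", "u1", 3, False), ("b", "u2", 3, False),
                            ("c", "u3", 3, False)])
        with pytest.warns(UserWarning, match="no shared"):
            corr = feature_correlations(norms)
        assert corr.empty


class TestConceptStatistics:
    def test_all_unique_features_give_mean_distinctiveness_one(self):
        rows = [("a", "u1", 3, False), ("a", "u2", 4, False),
                ("b", "u3", 3, False), ("c", "u4", 3, False)]
        cs = concept_statistics(make_norms(rows))
        assert cs.loc["a", "mean_distinctiveness"] == 1.0
        assert cs.loc["a", "nof"] == 2

    def test_mean_of_mixed_distinctiveness(self):
        rows = [("a", "u1", 3, False), ("a", "pair", 3, False),
                ("b", "pair", 3, False), ("b", "u2", 3, False),
                ("c", "u3", 3, False)]
        cs = concept_statistics(make_norms(rows))
        assert cs.loc["a", "mean_distinctiveness"] == pytest.approx(0.75)

    def test_single_significant_pair_mean_and_log(self, toy_norms):
        stats = feature_statistics(toy_norms)
        corr = pd.DataFrame(
            {
                "feature_i": ["f_all"],
                "feature_j": ["f_pair"],
                "r": [0.8],
                "p": [0.01],
                "significant": [True],
            }
        )
        cs = concept_statistics(toy_norms, stats, corr)
        assert cs.loc["cat", "mean_cs_raw"] == pytest.approx(0.8)
        assert cs.loc["cat", "mean_cs_log"] == pytest.approx(np.log(0.8))
        assert cs.loc["cat", "n_sig_pairs"] == 1
        # eel lacks f_pair, so the pair is not within-concept
        assert np.isnan(cs.loc["eel", "mean_cs_raw"])
        assert cs.loc["eel", "n_sig_pairs"] == 0

    def test_taxonomic_features_excluded(self, toy_norms):
        cs = concept_statistics(toy_norms)
        assert cs.loc["cat", "nof"] == 3  # is_animal not counted
        d = feature_statistics(toy_norms).loc[
            ["has_fur", "f_pair", "f_all"], "distinctiveness"
        ]
        assert cs.loc["cat", "mean_distinctiveness"] == pytest.approx(d.mean())

    def test_mean_distinctiveness_within_member_range(self, desk_norms, desk_stats):
        fstats, _, cstats = desk_stats
        t = desk_norms.table[~desk_norms.table["taxonomic"]]
        for concept, feats in t.groupby("concept")["feature"]:
            d = fstats.loc[list(feats), "distinctiveness"]
            m = cstats.loc[concept, "mean_distinctiveness"]
            assert d.min() - 1e-12 <= m <= d.max() + 1e-12
            assert 0 < m <= 1

    def test_disjoint_concept_leaves_pair_membership_unchanged(self, small_norms):
        def within_concept_pairs(norms):
            corr = feature_correlations(norms)
            feats = norms.table[~norms.table["taxonomic"]].groupby("concept")[
                "feature"
            ].agg(set)
            return {
                concept: {
                    (i, j)
                    for i, j in zip(corr["feature_i"], corr["feature_j"])
                    if i in members and j in members
                }
                for concept, members in feats.items()
            }

        before = within_concept_pairs(small_norms)
        extra = pd.concat(
            [
                small_norms.table,
                pd.DataFrame(
                    [("zzz_new", f"zzz_f{i}", 4, False) for i in range(5)],
                    columns=["concept", "feature", "prod_freq", "taxonomic"],
                ),
            ],
            ignore_index=True,
        )
        after = within_concept_pairs(PropertyNorms(extra))
        # r values may shift with the lengthened vectors, but each original
        # concept's candidate pair set must be identical
        for concept, pairs in before.items():
            assert after[concept] == pairs
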