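import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from microdyad.taxa import (
    AsvTable,
    TaxonomyTable,
    braycurtis_similarity,
    exclude_family,
    filter_nongut,
    jaccard_similarity,
    normalize_proportions,
    read_asv_biom,
    read_asv_tsv,
    read_taxonomy_tsv,
    remove_singletons,
    similarity_matrix,
    write_asv_tsv,
)
from .conftest import brute_force_braycurtis, brute_force_jaccard


class TestFilters:
    def test_nongut_removed_any_rank_case_insensitive(self, toy_asv, toy_taxonomy):
        out = filter_nongut(toy_asv, toy_taxonomy, ("cyanobacteria",))
        assert list(out.asv_ids) == ["ASV1", "ASV3"]

    def test_empty_exclusion_is_identity(self, toy_asv, toy_taxonomy):
        out = filter_nongut(toy_asv, toy_taxonomy, ())
        pd.testing.assert_frame_equal(out.data, toy_asv.data)

    def test_default_exclusions_hit_mitochondria(self, toy_asv):
        tax = TaxonomyTable(
            pd.DataFrame(
                {r: ["k__Bacteria", "f__mitochondria", "x"] for r in
                 ("kingdom", "phylum", "class", "order", "family", "genus")},
                index=["ASV1", "ASV2", "ASV3"],
            )
        )
        out = filter_nongut(toy_asv, tax)
        assert list(out.asv_ids) == ["ASV1", "ASV3"]

    def test_singleton_total_count_boundary(self):
        t = AsvTable(
            pd.DataFrame({"single": [1.0, 0.0], "pair": [2.0, 0.0], "split": [1.0, 1.0]},
                         index=["s1", "s2"])
        )
        out = remove_singletons(t)
        assert list(out.asv_ids) == ["pair", "split"]

    def test_singleton_single_sample_variant(self):
        t = AsvTable(
            pd.DataFrame({"one_sample": [5.0, 0.0], "two_samples": [1.0, 1.0]},
                         index=["s1", "s2"])
        )
        out = remove_singletons(t, definition="single_sample")
        assert list(out.asv_ids) == ["two_samples"]

    def test_singletons_require_counts_mode(self):
        t = AsvTable(pd.DataFrame({"a": [1.0], "b": [0.0]}, index=["s1"]), mode="proportions")
        with pytest.raises(ValueError, match="counts"):
            remove_singletons(t)

    def test_all_singletons_then_similarity_errors(self):
        t = AsvTable(pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}, index=["s1", "s2"]))
        empty = remove_singletons(t)
        assert empty.data.shape[1] == 0
        with pytest.raises(ValueError, match="empty"):
            similarity_matrix(empty, "jaccard")

    def test_normalize_rows(self):
        t = AsvTable(pd.DataFrame({"a": [2.0, 10.0], "b": [2.0, 0.0], "c": [0.0, 0.0]},
                                  index=["s1", "s2"]))
        out = normalize_proportions(t)
        assert out.mode == "proportions"
        np.testing.assert_allclose(out.data.loc["s1"], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(out.data.loc["s2"], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0)

    def test_normalize_names_empty_sample(self):
        t = AsvTable(pd.DataFrame({"a": [1.0, 0.0]}, index=["ok", "empty"]))
        with pytest.raises(ValueError, match="empty"):
            normalize_proportions(t)


class TestPairwiseSimilarity:
    def test_jaccard_examples(self):
        assert jaccard_similarity([1, 2, 0], [3, 5, 0]) == 1.0
        assert jaccard_similarity([1, 0], [0, 2]) == 0.0
        # {a,b,c} vs {b,c,d}: 2 shared / 4 union
        assert jaccard_similarity([1, 1, 1, 0], [0, 1, 1, 1]) == 0.5

    def test_jaccard_both_empty_errors(self):
        with pytest.raises(ValueError):
            jaccard_similarity([0, 0], [0, 0])

    def test_braycurtis_examples(self):
        assert braycurtis_similarity([0.2, 0.8], [0.2, 0.8]) == 1.0
        assert braycurtis_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0
        assert braycurtis_similarity([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.75)

    def test_braycurtis_both_empty_errors(self):
        with pytest.raises(ValueError):
            braycurtis_similarity([0.0], [0.0])

    @given(
        a=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        b=st.lists(st.floats(0, 1), min_size=4, max_size=4),
    )
    @hsettings(max_examples=50, deadline=None)
    def test_symmetry(self, a, b):
        if sum(a) + sum(b) == 0:
            return
        assert braycurtis_similarity(a, b) == pytest.approx(braycurtis_similarity(b, a))
        if any(a) or any(b):
            assert jaccard_similarity(a, b) == pytest.approx(jaccard_similarity(b, a))

    def test_oracle_equivalence_many_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = rng.integers(0, 4, size=12) * rng.uniform(0.1, 1.0, size=12)
            b = rng.integers(0, 4, size=12) * rng.uniform(0.1, 1.0, size=12)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert jaccard_similarity(a, b) == pytest.approx(brute_force_jaccard(a, b))
            assert braycurtis_similarity(a, b) == pytest.approx(brute_force_braycurtis(a, b))


class TestSimilarityMatrix:
    def test_matches_pairwise_and_symmetric(self, toy_asv):
        sim = similarity_matrix(toy_asv, "jaccard")
        for i in ("s1", "s2", "s3"):
            for j in ("s1", "s2", "s3"):
                if i != j:
                    expected = jaccard_similarity(
                        toy_asv.data.loc[i].to_numpy(), toy_asv.data.loc[j].to_numpy()
                    )
                    assert sim.data.at[i, j] == pytest.approx(expected)
        np.testing.assert_allclose(sim.data, sim.data.T)
        np.testing.assert_allclose(np.diag(sim.data), 1.0)

    def test_braycurtis_requires_proportions(self, toy_asv):
        with pytest.raises(ValueError, match="proportions"):
            similarity_matrix(toy_asv, "braycurtis")

    def test_unknown_metric(self, toy_asv):
        with pytest.raises(ValueError, match="metric"):
            similarity_matrix(toy_asv, "unifrac")

    def test_oracle_equivalence_on_random_table(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 3, size=(20, 50)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1.0
        t = AsvTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(20)],
                                  columns=[f"a{j}" for j in range(50)]))
        sim_j = similarity_matrix(t, "jaccard")
        props = normalize_proportions(t)
        sim_b = similarity_matrix(props, "braycurtis")
        for i in range(20):
            for j in range(i + 1, 20):
                assert sim_j.data.iat[i, j] == pytest.approx(
                    brute_force_jaccard(counts[i], counts[j])
                )
                assert sim_b.data.iat[i, j] == pytest.approx(
                    brute_force_braycurtis(props.data.iloc[i], props.data.iloc[j])
                )

    def test_jaccard_invariant_to_normalisation(self, toy_asv):
        before = similarity_matrix(toy_asv, "jaccard")
        after = similarity_matrix(normalize_proportions(toy_asv), "jaccard")
        pd.testing.assert_frame_equal(before.data, after.data)


class TestExcludeFamily:
    def test_absent_family_is_noop(self, toy_asv, toy_taxonomy):
        out = exclude_family(toy_asv, toy_taxonomy, "Bifidobacteriaceae")
        pd.testing.assert_frame_equal(out.data, toy_asv.data)

    def test_unassigned_family_never_removed(self, toy_asv, toy_taxonomy):
        out = exclude_family(toy_asv, toy_taxonomy, "Muribaculaceae")
        assert list(out.asv_ids) == ["ASV2", "ASV3"]

    def test_excluding_only_shared_family_zeroes_jaccard(self):
        t = AsvTable(pd.DataFrame({"f1": [1.0, 2.0], "x": [1.0, 0.0], "y": [0.0, 1.0]},
                                  index=["s1", "s2"]))
        tax = TaxonomyTable(
            pd.DataFrame(
                {"kingdom": "k", "phylum": "p", "class": "c", "order": "o",
                 "family": ["f__F", "f__G", "f__H"], "genus": pd.NA},
                index=["f1", "x", "y"],
            )
        )
        assert jaccard_similarity(t.data.loc["s1"], t.data.loc["s2"]) > 0
        out = exclude_family(t, tax, "F")
        assert jaccard_similarity(out.data.loc["s1"], out.data.loc["s2"]) == 0.0

    def test_excluding_all_families_empties_table(self, toy_asv, toy_taxonomy):
        out = exclude_family(toy_asv, toy_taxonomy, "Muribaculaceae")
        out = exclude_family(out, toy_taxonomy, "Lachnospiraceae")
        assert list(out.asv_ids) == ["ASV2"]  # unassigned family survives by design


class TestIO:
    def test_tsv_roundtrip(self, toy_asv, tmp_path):
        path = tmp_path / "asv.tsv"
        write_asv_tsv(toy_asv, path)
        back = read_asv_tsv(path)
        pd.testing.assert_frame_equal(back.data, toy_asv.data, check_names=False)

    def test_tsv_asvs_as_rows(self, toy_asv, tmp_path):
        path = tmp_path / "asv_t.tsv"
        toy_asv.data.T.to_csv(path, sep="\t", index_label="asv_id")
        back = read_asv_tsv(path, orientation="asvs_as_rows")
        pd.testing.assert_frame_equal(back.data, toy_asv.data, check_names=False)

    def test_biom_hdf5_roundtrip(self, toy_asv, tmp_path):
        import h5py
        from scipy.sparse import csr_matrix

        path = tmp_path / "table.biom"
        mat = csr_matrix(toy_asv.data.T.to_numpy())  # observations x samples
        with h5py.File(path, "w") as f:
            f.create_dataset("observation/ids", data=[s.encode() for s in toy_asv.asv_ids])
            f.create_dataset("sample/ids", data=[s.encode() for s in toy_asv.sample_ids])
            g = f.create_group("observation/matrix")
            g.create_dataset("data", data=mat.data)
            g.create_dataset("indices", data=mat.indices)
            g.create_dataset("indptr", data=mat.indptr)
        back = read_asv_biom(path)
        pd.testing.assert_frame_equal(back.data, toy_asv.data)

    def test_taxonomy_lineage_string(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "asv_id\tTaxon\n"
            "ASV1\tk__Bacteria; p__Bacteroidota; c__; o__; f__Muribaculaceae; g__\n"
        )
        tax = read_taxonomy_tsv(path)
        assert tax.family_of().loc["ASV1"] == "Muribaculaceae"
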