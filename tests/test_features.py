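import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxcys.features import (
    BLOCKS,
    FeatureSpec,
    build_design_matrix,
    cysteine_positions,
    encode_site,
    feature_dimension,
    feature_names,
    sequential_distances,
    window_slice,
)
from redoxcys.seqio import (
    AMINO_ACIDS,
    CysteineSite,
    FormatError,
    ProteinRecord,
    PSSMProfile,
    SiteTable,
    StructureAnnotation,
    pseudo_pssm,
)


class TestCysteinePositions:
    @pytest.mark.parametrize(
        "seq,expected",
        [("CACCAAC", [1, 3, 4, 7]), ("MKR", []), ("C", [1])],
    )
    def test_examples(self, seq, expected):
        assert cysteine_positions(seq) == expected

    def test_agrees_with_character_scan(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 60))))
            oracle = [i + 1 for i in range(len(seq)) if seq[i] == "C"]
            assert cysteine_positions(seq) == oracle


class TestSequentialDistances:
    def test_nearest_three(self):
        np.testing.assert_array_equal(
            sequential_distances("CACCAAC", 3, 3), [1, 2, 4]
        )

    def test_padding_uses_sequence_length(self):
        np.testing.assert_array_equal(
            sequential_distances("CACCAAC", 3, 6), [1, 2, 4, 7, 7, 7]
        )

    def test_lone_cysteine_all_sentinel(self):
        np.testing.assert_array_equal(sequential_distances("C", 1, 2), [1, 1])

    def test_non_cysteine_position_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            sequential_distances("CAC", 2, 1)

    def test_sorted_nondecreasing_property(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("CA"), size=int(rng.integers(2, 50))))
            pos = cysteine_positions(seq)
            if not pos:
                continue
            d = sequential_distances(seq, pos[0], 8)
            assert np.all(np.diff(d) >= 0)
            assert np.all(d >= 1)


class TestWindowSlice:
    def test_leading_padding(self):
        m = np.arange(6).reshape(3, 2) + 1.0
        out = window_slice(m, 1, 3)
        np.testing.assert_array_equal(out[0], [0, 0])
        np.testing.assert_array_equal(out[1:], m[:2])

    def test_identity_case(self):
        m = np.arange(6).reshape(3, 2) + 1.0
        np.testing.assert_array_equal(window_slice(m, 2, 3), m)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            window_slice(np.zeros((3, 2)), 1, 4)

    def test_window_one_reconstructs_matrix(self, rng):
        m = rng.normal(size=(7, 4))
        rebuilt = np.vstack([window_slice(m, p, 1) for p in range(1, 8)])
        np.testing.assert_array_equal(rebuilt, m)


class TestFeatureDimension:
    @pytest.mark.parametrize(
        "n,w,blocks,expected",
        [
            (6, 9, ("D", "PSSM", "SS"), 213),
            (6, 9, BLOCKS, 267),
            (1, 1, ("D",), 1),
            (0, 3, ("PSSM",), 60),
        ],
    )
    def test_examples(self, n, w, blocks, expected):
        assert feature_dimension(FeatureSpec(n, w, blocks)) == expected

    @settings(deadline=None, max_examples=60)
    @given(
        n=st.integers(0, 10),
        w=st.sampled_from([1, 3, 5, 9, 15, 25]),
        blocks=st.sets(st.sampled_from(BLOCKS), min_size=1).map(tuple),
    )
    def test_matches_encoded_length(self, n, w, blocks):
        spec = FeatureSpec(n, w, blocks)
        record = ProteinRecord("p", "MACMCWKCAAC")
        site = CysteineSite("p", 5, 1)
        fv = encode_site(
            site,
            spec,
            record,
            pssm=pseudo_pssm(record.sequence, protein_id="p"),
            annotation=StructureAnnotation("p", "CHHECCCEHHC", "EBEBEBEBEBE"),
        )
        assert len(fv.values) == feature_dimension(spec)
        assert len(set(fv.names)) == len(fv.names)


class TestEncodeSite:
    def _toy(self):
        record = ProteinRecord("p", "CCCCC")
        site = CysteineSite("p", 3, 1)
        pssm = PSSMProfile("p", np.zeros((5, 20)))
        ann = StructureAnnotation("p", "CCCCC", "EEEEE")
        return record, site, pssm, ann

    def test_zero_pssm_all_cys_hand_case(self):
        record, site, pssm, ann = self._toy()
        spec = FeatureSpec(n_neighbors=4, window=3, blocks=("D", "PSSM"))
        fv = encode_site(site, spec, record, pssm=pssm)
        np.testing.assert_array_equal(fv.values[:4], [1, 1, 2, 2])
        assert np.all(fv.values[4:] == 0)

    def test_block_order_is_fixed(self):
        record, site, pssm, ann = self._toy()
        spec = FeatureSpec(2, 3, blocks=("SS", "D", "PSSM"))  # given out of order
        assert spec.blocks == ("D", "PSSM", "SS")
        fv = encode_site(site, spec, record, pssm=pssm, annotation=ann)
        assert fv.names[0].startswith("D:") and fv.names[2].startswith("PSSM:")

    def test_missing_profile_is_descriptive(self):
        record, site, _, _ = self._toy()
        spec = FeatureSpec(2, 3, blocks=("PSSM",))
        with pytest.raises(FormatError, match="PSSM block.*'p'"):
            encode_site(site, spec, record)

    def test_missing_sa_string_is_descriptive(self):
        record, site, _, _ = self._toy()
        ann = StructureAnnotation("p", "CCCCC")
        spec = FeatureSpec(2, 3, blocks=("SA",))
        with pytest.raises(FormatError, match="SA block"):
            encode_site(site, spec, record, annotation=ann)

    def test_non_cysteine_site_rejected(self):
        record = ProteinRecord("p", "MCA")
        with pytest.raises(FormatError, match="not a cysteine"):
            encode_site(CysteineSite("p", 1, 1), FeatureSpec(1, 3, ("D",)), record)

    def test_deterministic_bitwise(self):
        record, site, pssm, ann = self._toy()
        spec = FeatureSpec(3, 3, BLOCKS)
        a = encode_site(site, spec, record, pssm=pssm, annotation=ann)
        b = encode_site(site, spec, record, pssm=pssm, annotation=ann)
        assert a.values.tobytes() == b.values.tobytes()

    def test_one_hot_window_content(self):
        record = ProteinRecord("p", "CAC")
        ann = StructureAnnotation("p", "HEC", "EBB")
        spec = FeatureSpec(0, 3, blocks=("SS",))
        fv = encode_site(CysteineSite("p", 1, 1), spec, record, annotation=ann)
        # offset -1 padded, offset 0 is H, offset +1 is E
        np.testing.assert_array_equal(fv.values, [0, 0, 0, 1, 0, 0, 0, 1, 0])


class TestDesignMatrix:
    def test_rows_match_per_site_encoding(self, small_dataset):
        records, pssms, anns = small_dataset.registries()
        spec = FeatureSpec()
        table = SiteTable(small_dataset.site_table.sites[:10])
        design = build_design_matrix(table, spec, records, pssms, anns)
        assert design.X.shape == (10, 213)
        for i, site in enumerate(table):
            fv = encode_site(
                site, spec, records[site.protein_id],
                pssm=pssms[site.protein_id], annotation=anns[site.protein_id],
            )
            np.testing.assert_array_equal(design.X[i], fv.values)

    def test_empty_table_gives_empty_matrix(self):
        design = build_design_matrix(SiteTable([]), FeatureSpec(), {})
        assert design.X.shape == (0, 213) and len(design.y) == 0

    def test_unknown_labels_routed_to_prediction_matrix(self):
        record = ProteinRecord("p", "CAC")
        table = SiteTable(
            [CysteineSite("p", 1, 1), CysteineSite("p", 3, 0)]
        )
        design = build_design_matrix(table, FeatureSpec(2, 3, ("D",)), {"p": record})
        assert design.X.shape == (1, 2) and design.X_unknown.shape == (1, 2)
        assert design.unknown_sites[0].position == 3

    def test_missing_record_aborts_with_identity(self):
        table = SiteTable([CysteineSite("ghost", 1, 1)])
        with pytest.raises(FormatError, match="ghost"):
            build_design_matrix(table, FeatureSpec(1, 3, ("D",)), {})


def test_positive_sites_have_longer_nearest_cysteine_distance(small_design):
    """The planted class signal mirrors the curated-data observation that
    redox-sensitive cysteines sit farther from their neighbours."""
    d1 = small_design.X[:, 0]
    y = small_design.y
    assert d1[y == 1].mean() > d1[y == -1].mean()
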