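import pytest

from selffi.manifest import (ImageRecord, ManifestError, PairExample,
                             build_pairs, read_manifest, write_manifest)
from conftest import make_record


class TestImageRecord:
    def test_rejects_unknown_enum_tokens(self):
        with pytest.raises(ManifestError, match="eye_side"):
            make_record(eye_side="both")
        with pytest.raises(ManifestError, match="modality"):
            make_record(modality="OCT")

    @pytest.mark.parametrize("labels", [(1, 0, 1), (0, 1, 0, 1, 0, 2)])
    def test_rejects_malformed_labels(self, labels):
        with pytest.raises(ManifestError, match="labels"):
            make_record(labels=labels)


class TestPairInvariants:
    def test_bilateral_requires_left_right_ufi(self):
        left = make_record("a", eye_side="left")
        right = make_record("b", eye_side="right")
        PairExample("bilateral", left, right)  # valid
        with pytest.raises(ManifestError):
            PairExample("bilateral", left, make_record("c", eye_side="left"))
        with pytest.raises(ManifestError):
            PairExample("bilateral", left,
                        make_record("d", eye_side="right", modality="CFI"))
        with pytest.raises(ManifestError, match="patients"):
            PairExample("bilateral", left,
                        make_record("e", patient_id="p2", eye_side="right"))

    def test_multimodal_requires_two_modalities_same_patient(self):
        ufi = make_record("a", modality="UFI")
        cfi = make_record("b", modality="CFI")
        PairExample("multimodal", ufi, cfi)  # valid
        with pytest.raises(ManifestError):
            PairExample("multimodal", ufi, make_record("c", modality="UFI"))

    def test_pair_instance_is_a_self_pair(self):
        rec = make_record("a")
        PairExample("pair_instance", rec, rec)  # valid
        with pytest.raises(ManifestError):
            PairExample("pair_instance", rec, make_record("b"))


class TestReadWrite:
    def test_well_formed_manifest_parses_identically(self, tmp_path):
        records = [
            make_record("i1", "p1", "left", "UFI", "a.png", (1, 0, 0, 0, 1, 0)),
            make_record("i2", "p1", "right", "UFI", "b.png", (0, 0, 0, 0, 0, 0)),
            make_record("i3", "p2", "left", "CFI", "c.png", (0, 1, 1, 0, 0, 0)),
            make_record("i4", "p2", "unknown", "UFI", "d.png", None),
        ]
        path = write_manifest(records, tmp_path / "m.csv")
        assert read_manifest(path) == records

    def test_round_trip_without_labels(self, tmp_path):
        records = [make_record("i1"), make_record("i2", "p2", "right")]
        path = write_manifest(records, tmp_path / "m.csv")
        assert read_manifest(path) == records

    def test_duplicate_image_id_names_both_rows(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "image_id,patient_id,eye_side,modality,path\n"
            "x,p1,left,UFI,a.png\n"
            "x,p2,right,UFI,b.png\n"
        )
        with pytest.raises(ManifestError, match="'x' at rows 2 and 3"):
            read_manifest(path)

    def test_missing_required_field_reports_row(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "image_id,patient_id,eye_side,modality,path\n"
            "x,p1,left,UFI,a.png\n"
            "y,,left,UFI,b.png\n"
        )
        with pytest.raises(ManifestError, match="row 3"):
            read_manifest(path)

    def test_synthetic_manifest_has_four_images_per_patient(self, small_records):
        assert len(small_records) == 40
        per_patient = {}
        for r in small_records:
            per_patient.setdefault(r.patient_id, []).append((r.eye_side, r.modality))
        for slots in per_patient.values():
            assert sorted(slots) == [("left", "CFI"), ("left", "UFI"),
                                     ("right", "CFI"), ("right", "UFI")]


class TestBuildPairs:
    def test_pair_counts_on_synthetic_cohort(self, small_records):
        assert len(build_pairs(small_records, "bilateral")) == 10
        assert len(build_pairs(small_records, "multimodal")) == 20
        assert len(build_pairs(small_records, "pair_instance")) == 20  # UFI only

    def test_pairs_satisfy_their_invariants(self, small_records):
        for strategy in ("pair_instance", "bilateral", "multimodal"):
            for pair in build_pairs(small_records, strategy, seed=3):
                assert pair.pair_type == strategy  # invariant checked in __post_init__

    def test_pair_count_bounds(self, small_records):
        n_ufi = sum(r.modality == "UFI" for r in small_records)
        n_cfi = sum(r.modality == "CFI" for r in small_records)
        assert len(build_pairs(small_records, "bilateral")) <= n_ufi // 2
        assert len(build_pairs(small_records, "multimodal")) <= min(n_ufi, n_cfi)

    def test_deterministic_order_given_seed(self, small_records):
        a = build_pairs(small_records, "multimodal", seed=7)
        b = build_pairs(small_records, "multimodal", seed=7)
        c = build_pairs(small_records, "multimodal", seed=8)
        assert a == b
        assert a != c and sorted(map(str, a)) == sorted(map(str, c))

    def test_missing_partner_raises_zero_pair_error(self):
        records = [make_record("a", eye_side="left")]
        with pytest.raises(ManifestError, match="left- and a right-eye"):
            build_pairs(records, "bilateral")

    def test_unknown_side_excluded_from_bilateral(self):
        records = [
            make_record("a", eye_side="unknown"),
            make_record("b", eye_side="right"),
            make_record("c", eye_side="left"),
        ]
        pairs = build_pairs(records, "bilateral")
        assert len(pairs) == 1
        assert {pairs[0].record_a.image_id, pairs[0].record_b.image_id} == {"b", "c"}

    def test_duplicate_slot_resolved_lexicographically(self):
        records = [
            make_record("z_late", eye_side="left"),
            make_record("a_early", eye_side="left"),
            make_record("m_right", eye_side="right"),
        ]
        (pair,) = build_pairs(records, "bilateral")
        assert pair.record_a.image_id == "a_early"

    def test_multimodal_per_patient_fallback(self):
        records = [
            make_record("u", eye_side="left", modality="UFI"),
            make_record("c", eye_side="right", modality="CFI"),
        ]
        with pytest.raises(ManifestError):
            build_pairs(records, "multimodal")  # per-eye: no match
        pairs = build_pairs(records, "multimodal", match_multimodal_per_eye=False)
        assert len(pairs) == 1
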