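"""Dataset assembly: capping, splitting, balancing, expansion, accounting.

The numeric anchors are the printed arithmetic of the study protocol:
class fractions of the imbalanced source set, 150-per-class capping,
80/20 pre-augmentation split, per-class auxiliary quotas, balancing to a
160-image training target, threefold blend expansion and 30-epoch
dynamic totals.
"""

import numpy as np
import pytest

from drgrade.dataset import (
    AssemblyPlan,
    AugmentationSpec,
    OrderingError,
    accounting,
    apply_augmentation,
    assemble_dataset,
    balance_augment,
    check_leakage,
    class_fractions,
    dynamic_stream,
    expand_blur_variants,
    merge_auxiliary,
    record_seed,
    select_balanced,
    stratified_split,
    ImageLoader,
)
from drgrade.io import DatasetManifest, write_manifest
from drgrade.synthetic import SyntheticSpec, generate_fundus

from conftest import make_records_manifest

MESSIDOR_COUNTS = [1017, 270, 347, 75, 35]
PLAN = AssemblyPlan()  # cap 150, 80/20, target 160, quotas {40,40,40,70,80}


class TestClassFractions:
    def test_severe_fraction_two_decimals(self):
        frame = class_fractions(MESSIDOR_COUNTS)
        assert frame.loc[3, "percent_2dec"] == 4.30

    def test_proliferative_fraction_integer(self):
        frame = class_fractions(MESSIDOR_COUNTS)
        assert frame.loc[4, "percent_int"] == 2

    def test_single_class_is_100_percent(self):
        frame = class_fractions([0, 0, 10, 0, 0])
        assert frame.loc[2, "percent"] == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            class_fractions([0] * 5)


class TestSelectBalanced:
    def test_cap_applied_only_above_cap(self, messidor_shaped_manifest):
        out = select_balanced(messidor_shaped_manifest, PLAN, seed=0)
        np.testing.assert_array_equal(out.class_counts(), [150, 150, 150, 75, 35])

    def test_all_below_cap_unchanged(self):
        m = make_records_manifest([10, 10, 10, 10, 10])
        out = select_balanced(m, PLAN, seed=0)
        assert out.records == m.records

    def test_different_seeds_pick_different_subsets(self, messidor_shaped_manifest):
        a = select_balanced(messidor_shaped_manifest, PLAN, seed=1)
        b = select_balanced(messidor_shaped_manifest, PLAN, seed=2)
        ids_a = {r.id for r in a.records if r.grade == 0}
        ids_b = {r.id for r in b.records if r.grade == 0}
        assert len(ids_a) == len(ids_b) == 150
        assert ids_a != ids_b

    def test_derived_records_rejected(self):
        m = make_records_manifest([2, 0, 0, 0, 0])
        m = stratified_split(m, 0.2, seed=0)
        m = expand_blur_variants(m)
        with pytest.raises(OrderingError):
            select_balanced(m, PLAN, seed=0)


class TestStratifiedSplit:
    @pytest.mark.parametrize("n,expected_train,expected_val", [(35, 28, 7), (150, 120, 30),
                                                               (75, 60, 15), (0, 0, 0)])
    def test_split_arithmetic(self, n, expected_train, expected_val):
        m = make_records_manifest([n, 0, 0, 0, 0])
        out = stratified_split(m, 0.2, seed=0)
        assert out.class_counts(split="train")[0] == expected_train
        assert out.class_counts(split="val")[0] == expected_val

    def test_rejects_manifest_with_augmented_records(self):
        m = make_records_manifest([5, 0, 0, 0, 0])
        m = stratified_split(m, 0.2, seed=0)
        m = balance_augment(m, AugmentationSpec(seed=0),
                            AssemblyPlan(train_class_target=6, auxiliary_quota=(0,) * 5))
        stripped = DatasetManifest([r.with_(split="unassigned") for r in m.records])
        with pytest.raises(OrderingError):
            stratified_split(stripped, 0.2, seed=0)

    def test_rejects_already_split_manifest(self):
        m = make_records_manifest([5, 0, 0, 0, 0], split="train")
        with pytest.raises(OrderingError):
            stratified_split(m, 0.2, seed=0)


class TestMergeAuxiliary:
    def test_quota_added_to_train_only(self):
        m = stratified_split(make_records_manifest([150] * 5), 0.2, seed=0)
        aux = make_records_manifest([100] * 5, prefix="aux")
        out = merge_auxiliary(m, aux, PLAN, seed=0)
        assert out.class_counts(split="train")[0] == 160  # 120 + 40
        assert out.class_counts(split="train", origins=["auxiliary"]).tolist() == [40, 40, 40, 70, 80]
        assert out.class_counts(split="val", origins=["auxiliary"]).sum() == 0

    def test_proliferative_train_total(self):
        m = stratified_split(make_records_manifest([35, 0, 0, 0, 0][::-1]), 0.2, seed=0)
        # class 4 has 35 records -> 28 train; quota 80 -> 108
        aux = make_records_manifest([0, 0, 0, 0, 100], prefix="aux")
        out = merge_auxiliary(m, aux, PLAN.__class__(auxiliary_quota=(0, 0, 0, 0, 80)), seed=0)
        assert out.class_counts(split="train")[4] == 108

    def test_zero_quota_is_noop(self):
        m = stratified_split(make_records_manifest([10] * 5), 0.2, seed=0)
        aux = make_records_manifest([5] * 5, prefix="aux")
        out = merge_auxiliary(m, aux, AssemblyPlan(auxiliary_quota=(0,) * 5), seed=0)
        assert out.records == m.records

    def test_quota_exceeding_pool_names_class(self):
        m = stratified_split(make_records_manifest([10] * 5), 0.2, seed=0)
        aux = make_records_manifest([5] * 5, prefix="aux")
        with pytest.raises(ValueError, match="Severe"):
            merge_auxiliary(m, aux, AssemblyPlan(auxiliary_quota=(0, 0, 0, 70, 0)), seed=0)


class TestBalanceAugment:
    def test_rarest_class_augmented_fraction(self):
        """28 primary + 80 auxiliary train images balanced to 160 need 52
        augmented copies: about a third of the final training pool."""
        m = stratified_split(make_records_manifest([0, 0, 0, 0, 35]), 0.2, seed=0)
        aux = make_records_manifest([0, 0, 0, 0, 100], prefix="aux")
        m = merge_auxiliary(m, aux, AssemblyPlan(auxiliary_quota=(0, 0, 0, 0, 80)), seed=0)
        out = balance_augment(m, AugmentationSpec(seed=1), PLAN)
        augmented = out.class_counts(split="train", origins=["augmented"])[4]
        assert augmented == 52
        assert augmented / out.class_counts(split="train")[4] == pytest.approx(0.325)

    def test_class_at_target_gains_nothing(self):
        m = stratified_split(make_records_manifest([200, 0, 0, 0, 0]), 0.2, seed=0)
        out = balance_augment(m, AugmentationSpec(seed=1), AssemblyPlan(train_class_target=160))
        assert out.class_counts(origins=["augmented"]).sum() == 0

    def test_augmented_parents_are_same_class_train_sources(self):
        m = stratified_split(make_records_manifest([0, 20, 0, 0, 0]), 0.2, seed=0)
        out = balance_augment(m, AugmentationSpec(seed=1), AssemblyPlan(train_class_target=30))
        by_id = out.by_id()
        for rec in out.records:
            if rec.origin == "augmented":
                parent = by_id[rec.parent_id]
                assert parent.grade == rec.grade
                assert parent.split == rec.split == "train"
                assert parent.origin == "primary"

    def test_requires_split_assignment(self):
        m = make_records_manifest([10] * 5)
        with pytest.raises(OrderingError):
            balance_augment(m, AugmentationSpec(seed=0), PLAN)

    def test_class_without_train_originals_raises(self):
        # only auxiliary train images: nothing eligible to augment from
        m = make_records_manifest([0, 10, 0, 0, 0], origin="auxiliary", split="train")
        with pytest.raises(ValueError, match="no train originals"):
            balance_augment(m, AugmentationSpec(seed=0), AssemblyPlan(train_class_target=20))


class TestApplyAugmentation:
    def test_augmentations_differ_from_parent(self):
        img, _ = generate_fundus(2, SyntheticSpec(side=64), seed=0)
        spec = AugmentationSpec(seed=0)
        changed = sum(
            not np.array_equal(apply_augmentation(img, spec, seed=s).pixels, img.pixels)
            for s in range(100)
        )
        assert changed >= 99

    def test_seeded_reproducibility(self):
        img, _ = generate_fundus(2, SyntheticSpec(side=64), seed=0)
        spec = AugmentationSpec(seed=0)
        a = apply_augmentation(img, spec, seed=7)
        b = apply_augmentation(img, spec, seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestExpandBlurVariants:
    def test_counts_triple_per_split_and_class(self):
        m = stratified_split(make_records_manifest([150] * 5), 0.2, seed=0)
        out = expand_blur_variants(m)
        np.testing.assert_array_equal(out.class_counts(split="train"), [360] * 5)
        np.testing.assert_array_equal(out.class_counts(split="val"), [90] * 5)
        assert all(r.origin == "blur_variant" for r in out.records)

    def test_populated_class_160_to_480(self):
        m = make_records_manifest([160, 0, 0, 0, 0], split="train")
        out = expand_blur_variants(m)
        assert out.class_counts(split="train")[0] == 480

    def test_empty_manifest_stays_empty(self):
        assert len(expand_blur_variants(DatasetManifest([]))) == 0


class TestDynamicStream:
    def _loader_and_manifest(self):
        spec = SyntheticSpec(side=32)
        records = make_records_manifest([2, 0, 0, 0, 0], split="train")
        images = {r.id: generate_fundus(0, spec, seed=i)[0] for i, r in enumerate(records)}
        loader = ImageLoader({r.id: r for r in records}, images)
        return records, loader

    def test_total_is_statics_times_epochs(self):
        manifest, loader = self._loader_and_manifest()
        stream, total = dynamic_stream(manifest, AugmentationSpec(seed=0), epochs=30,
                                       seed=0, loader=loader)
        assert total == len(manifest) * 30
        assert sum(1 for _ in stream) == total

    def test_table_scale_dynamic_totals(self):
        m = make_records_manifest([160, 0, 0, 0, 0], split="train")
        statics = expand_blur_variants(m)
        assert len(statics) * 30 == 14400
        mv = make_records_manifest([30, 0, 0, 0, 0], split="val")
        assert len(expand_blur_variants(mv)) * 30 == 2700

    def test_one_epoch_equals_static_count(self):
        manifest, loader = self._loader_and_manifest()
        _, total = dynamic_stream(manifest, AugmentationSpec(seed=0), epochs=1,
                                  seed=0, loader=loader)
        assert total == len(manifest)

    def test_zero_epochs_rejected(self):
        manifest, loader = self._loader_and_manifest()
        with pytest.raises(ValueError):
            dynamic_stream(manifest, AugmentationSpec(seed=0), epochs=0, seed=0, loader=loader)

    def test_stream_is_seed_reproducible(self):
        manifest, loader = self._loader_and_manifest()
        spec = AugmentationSpec(seed=0)
        a = [img.pixels for _, _, img in dynamic_stream(manifest, spec, 2, 5, loader)[0]]
        b = [img.pixels for _, _, img in dynamic_stream(manifest, spec, 2, 5, loader)[0]]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestAccounting:
    def test_artificial_per_real_ratio(self, messidor_shaped_manifest):
        table = accounting(messidor_shaped_manifest, PLAN)
        assert table.artificial_per_real == pytest.approx((1017 - 35) / 35)
        assert table.artificial_per_real > 28

    def test_full_assembly_reproduces_selection_table(self, messidor_shaped_manifest):
        aux = make_records_manifest([100] * 5, prefix="aux")
        res = assemble_dataset(messidor_shaped_manifest, PLAN, AugmentationSpec(seed=7),
                               seed=7, auxiliary=aux)
        t = accounting(res.stages["merged"], PLAN).per_class
        assert t["selected"].tolist() == [150, 150, 150, 75, 35]
        assert t["orig_train"].tolist() == [120, 120, 120, 60, 28]
        assert t["orig_val"].tolist() == [30, 30, 30, 15, 7]
        assert t["auxiliary_train"].tolist() == [40, 40, 40, 70, 80]

    def test_empty_manifest_all_zero(self):
        table = accounting(DatasetManifest([]), PLAN)
        assert table.per_class[["available", "blur_train"]].to_numpy().sum() == 0


class TestAssemblyInvariants:
    def _assembled(self, seed=7):
        primary = make_records_manifest([1017, 270, 347, 75, 35])
        aux = make_records_manifest([100] * 5, prefix="aux")
        return assemble_dataset(primary, PLAN, AugmentationSpec(seed=seed), seed=seed,
                                auxiliary=aux)

    def test_leakage_freedom(self):
        res = self._assembled()
        assert check_leakage(res.manifest)
        assert check_leakage(res.stages["balanced"])

    def test_identical_seeds_give_byte_identical_manifests(self, tmp_path):
        a = self._assembled(seed=11)
        b = self._assembled(seed=11)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_manifest(a.manifest, pa)
        write_manifest(b.manifest, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = self._assembled(seed=1)
        b = self._assembled(seed=2)
        assert [r.id for r in a.manifest.records] != [r.id for r in b.manifest.records]

    def test_final_counts_match_protocol_table(self):
        res = self._assembled()
        t = res.table.per_class
        assert t["blur_train"].tolist() == [480] * 5
        assert t["blur_val"].tolist() == [90, 90, 90, 45, 21]
        assert t["dynamic_train_total"].tolist() == [14400] * 5
        assert t["dynamic_val_total"].tolist() == [2700, 2700, 2700, 1350, 630]


class TestRecordSeed:
    def test_below_2_31(self):
        for s in (0, 1, 2**31 - 2):
            assert 0 <= record_seed(s, "some_id", "x") < 2**31
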