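"""Synthetic cohort generator: determinism, morphology and label signal."""

import numpy as np
import pytest

from lungrg.synthetic import (CohortSpec, generate_cohort, generate_patient,
                              load_cohort, manifest_hash, patient_digest,
                              save_cohort)

SPEC = CohortSpec(n_per_class=(2, 2, 2), seed=7)


def test_normal_patient_has_no_boxes_and_even_slices():
    p = generate_patient("Normal", SPEC, 0)
    assert len(p.boxes) == 0
    d = np.diff(p.slice_indices)
    assert (d > 0).all() and len(p.slice_indices) == 5
    # evenly spaced within one rounding step
    assert d.max() - d.min() <= 1


def test_same_arguments_reproduce_bitwise():
    a = generate_patient("SCLC", SPEC, 1)
    b = generate_patient("SCLC", SPEC, 1)
    assert (a.volume == b.volume).all()
    assert patient_digest(a) == patient_digest(b)


def test_sclc_lesion_is_central():
    spec = CohortSpec(n_per_class=(0, 1, 0), volume_depth=32, rows=64,
                      cols=64, seed=1)
    for i in range(4):
        p = generate_patient("SCLC", spec, i)
        k = int(p.slice_indices[2])
        r0, c0, r1, c1 = p.boxes[k]
        rc, cc = (r0 + r1) / 2, (c0 + c1) / 2
        assert 64 / 3 < rc < 2 * 64 / 3
        assert 64 / 3 < cc < 2 * 64 / 3


def test_nsclc_lesion_is_peripheral_and_heterogeneous():
    spec = CohortSpec(n_per_class=(0, 0, 1), volume_depth=32, rows=64,
                      cols=64, seed=2)
    for i in range(4):
        p = generate_patient("NSCLC", spec, i)
        k = int(p.slice_indices[2])
        r0, c0, r1, c1 = p.boxes[k]
        cc = (c0 + c1) / 2
        assert cc < 64 / 3 or cc > 2 * 64 / 3  # lateral third
        def core_std(q):
            kk = int(q.slice_indices[2])
            a0, b0, a1, b1 = q.boxes[kk]
            dr, dc = (a1 - a0) // 4, (b1 - b0) // 4
            return q.volume[kk, a0 + dr:a1 - dr, b0 + dc:b1 - dc] \
                .astype(float).std()
        # interior of the NSCLC blob is textured; the SCLC core is a plateau
        assert core_std(p) > core_std(generate_patient("SCLC", spec, i))


def test_malignant_boxes_positive_area_on_all_slices(small_cohort):
    for p in small_cohort:
        if p.label == "Normal":
            assert not p.boxes
            continue
        assert set(p.boxes) == set(int(k) for k in p.slice_indices)
        for r0, c0, r1, c1 in p.boxes.values():
            assert r1 > r0 and c1 > c0


def test_hu_range_and_slice_indices_valid(small_cohort):
    for p in small_cohort:
        assert p.volume.min() >= -1024 and p.volume.max() <= 3071
        assert (p.slice_indices >= 0).all()
        assert (p.slice_indices < p.volume.shape[0]).all()
        assert (np.diff(p.slice_indices) > 0).all()


def test_cohort_counts_and_unique_ids():
    c = generate_cohort(CohortSpec(n_per_class=(3, 2, 4), seed=0))
    labels = [p.label for p in c]
    assert labels.count("Normal") == 3
    assert labels.count("SCLC") == 2
    assert labels.count("NSCLC") == 4
    assert len({p.patient_id for p in c}) == 9


def test_study_scale_cohort_total():
    c = generate_cohort(CohortSpec(n_per_class=(256, 248, 263),
                                   volume_depth=12, rows=32, cols=32,
                                   seed=0))
    assert len(c) == 767


def test_empty_cohort():
    assert generate_cohort(CohortSpec(n_per_class=(0, 0, 0), seed=0)) == []


def test_manifest_hash_is_function_of_spec():
    s = CohortSpec(n_per_class=(2, 2, 2), seed=9)
    assert manifest_hash(generate_cohort(s)) == \
        manifest_hash(generate_cohort(s))
    other = CohortSpec(n_per_class=(2, 2, 2), seed=10)
    assert manifest_hash(generate_cohort(s)) != \
        manifest_hash(generate_cohort(other))


def test_too_small_volume_rejected():
    with pytest.raises(ValueError):
        generate_patient("SCLC",
                         CohortSpec(n_per_class=(0, 1, 0), volume_depth=6,
                                    rows=16, cols=16, seed=0), 0)


def test_mean_intensity_separates_normal_from_malignant():
    # the generator must encode learnable class signal
    from sklearn.linear_model import LogisticRegression
    c = generate_cohort(CohortSpec(n_per_class=(20, 20, 20), seed=3))
    X = np.array([[p.volume[p.slice_indices].mean()] for p in c])
    y = np.array([0 if p.label == "Normal" else 1 for p in c])
    assert LogisticRegression().fit(X, y).score(X, y) > 0.9


def test_save_load_roundtrip(tmp_path, small_cohort):
    save_cohort(small_cohort[:4], tmp_path / "cohort")
    back = load_cohort(tmp_path / "cohort")
    assert [p.patient_id for p in back] == \
        [p.patient_id for p in small_cohort[:4]]
    for a, b in zip(small_cohort[:4], back):
        assert (a.volume == b.volume).all()
        assert a.report_tr == b.report_tr
        assert a.boxes == b.boxes


def test_report_structure_and_parenchyma_sentence(small_cohort):
    for p in small_cohort:
        for rep, tag in ((p.report_en, "Lung Parenchyma"),
                         (p.report_tr, "Akciğer Parankimi")):
            lines = rep.splitlines()
            assert len(lines) == 8
            assert lines[5].startswith(tag + ":")
        if p.label != "Normal":
            k = int(p.slice_indices[2])
            r0, c0, r1, c1 = p.boxes[k]
            size_mm = str(int(round(max(r1 - r0, c1 - c0) * 3.0)))
            assert f"{size_mm} mm" in p.report_en.splitlines()[5]
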