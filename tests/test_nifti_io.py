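import dataclasses

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnseg.nifti_io import (
    FormatError,
    extract_patches,
    read_case,
    remap_labels,
    write_case,
    write_mask,
    zscore_normalize,
)
from attnseg.phantom import MODALITIES, generate_phantom


@pytest.fixture()
def case_on_disk(small_case, tmp_path):
    write_case(small_case, tmp_path)
    paths = {m: tmp_path / f"{small_case.case_id}_{m}.nii.gz" for m in MODALITIES}
    return paths, tmp_path / f"{small_case.case_id}_seg.nii.gz"


class TestReadWrite:
    def test_round_trip(self, small_case, case_on_disk):
        paths, seg = case_on_disk
        back = read_case(paths, seg, case_id=small_case.case_id)
        assert np.array_equal(back.mask.labels, small_case.mask.labels)
        for m in MODALITIES:
            assert np.allclose(back.modalities[m], small_case.modalities[m], atol=1e-5)
        assert np.allclose(back.affine, small_case.affine)

    def test_raw_label4_remapped_to_3(self, small_case, case_on_disk, tmp_path):
        paths, seg = case_on_disk
        raw = small_case.mask.labels.copy()
        raw[raw == 3] = 4  # BraTS native coding
        assert set(np.unique(raw)) == {0, 1, 2, 4}
        alt = tmp_path / "raw4_seg.nii.gz"
        nib.save(nib.Nifti1Image(raw.astype(np.uint8), small_case.affine), alt)
        back = read_case(paths, alt)
        assert set(np.unique(back.mask.labels)) == {0, 1, 2, 3}
        assert np.array_equal(back.mask.labels, small_case.mask.labels)

    def test_shape_mismatch_rejected(self, small_case, case_on_disk, tmp_path):
        paths, seg = case_on_disk
        small = nib.Nifti1Image(np.zeros((8, 8, 4), dtype=np.float32), np.eye(4))
        bad = tmp_path / "bad_flair.nii.gz"
        nib.save(small, bad)
        with pytest.raises(FormatError, match="shape mismatch"):
            read_case({**paths, "flair": bad}, None)

    def test_invalid_label_rejected(self, small_case, case_on_disk, tmp_path):
        paths, _ = case_on_disk
        labels = small_case.mask.labels.copy()
        labels.flat[0] = 7
        bad = tmp_path / "bad_seg.nii.gz"
        nib.save(nib.Nifti1Image(labels.astype(np.uint8), small_case.affine), bad)
        with pytest.raises(FormatError, match="label values"):
            read_case(paths, bad)

    def test_write_mask_dtype(self, small_case, tmp_path):
        p = write_mask(small_case.mask.labels, small_case.affine, tmp_path / "m.nii.gz")
        img = nib.load(p)
        assert img.get_data_dtype() == np.uint8


class TestRemap:
    @given(st.lists(st.sampled_from([0, 1, 2, 3, 4]), min_size=1, max_size=64))
    def test_bijective_on_observed_values(self, vals):
        arr = np.asarray(vals)
        out = remap_labels(arr)
        assert np.array_equal(out[arr != 4], arr[arr != 4])
        assert np.all(out[arr == 4] == 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            remap_labels(np.array([0, 5]))


class TestZscore:
    def test_hand_example_population_sd(self):
        vol = np.zeros((2, 2, 1))
        vol[0, 0, 0], vol[0, 1, 0] = 10.0, 20.0
        out = zscore_normalize(vol)
        assert out[0, 0, 0] == pytest.approx(-1.0)
        assert out[0, 1, 0] == pytest.approx(1.0)
        assert np.all(out[vol == 0] == 0)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(6, 6, 6))
        vol[vol == 0] = 0.1
        once = zscore_normalize(vol)
        assert np.allclose(zscore_normalize(once), once, atol=1e-6)

    def test_all_background_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(np.zeros((4, 4, 4)))

    def test_constant_region_rejected(self):
        vol = np.zeros((4, 4, 4))
        vol[:2] = 5.0
        with pytest.raises(ValueError, match="constant"):
            zscore_normalize(vol)

    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-5.0, max_value=5.0),
        seed=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=25, deadline=None)
    def test_shift_scale_equivariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        vol = np.zeros((5, 5, 2))
        support = rng.random(vol.shape) < 0.6
        support.flat[:2] = True
        vol[support] = rng.normal(10.0, 3.0, size=int(support.sum()))
        transformed = vol.copy()
        transformed[support] = a * vol[support] + b
        if np.any(transformed[support] == 0) or zscore_would_degenerate(vol, support):
            return
        assert np.allclose(
            zscore_normalize(transformed), zscore_normalize(vol), atol=1e-6
        )


def zscore_would_degenerate(vol, support) -> bool:
    vals = vol[support]
    return vals.size < 2 or vals.std() < 1e-9 or np.any(vals == 0)


class TestExtractPatches:
    def test_tumor_fraction_one_all_patches_have_tumor(self, small_case):
        ps = extract_patches(small_case, size=32, tumor_fraction=1.0, seed=0)
        assert all((m > 0).any() for m in ps.masks)

    def test_determinism(self, small_case):
        a = extract_patches(small_case, size=32, tumor_fraction=0.0, seed=9)
        b = extract_patches(small_case, size=32, tumor_fraction=0.0, seed=9)
        assert a.images.tobytes() == b.images.tobytes()
        assert a.provenance == b.provenance

    def test_provenance_restricted_to_tumor_slices(self, small_case):
        labels = small_case.mask.labels
        tumor_slices = {
            k for k in range(labels.shape[2]) if (labels[:, :, k] > 0).any()
        }
        ps = extract_patches(small_case, size=32, tumor_fraction=1.0, seed=1)
        assert {k for _, k in ps.provenance} <= tumor_slices

    def test_no_tumor_with_positive_fraction_rejected(self, small_spec):
        spec = dataclasses.replace(small_spec, noise_sd=0.0)
        case = generate_phantom(spec)
        empty = dataclasses.replace(
            case, mask=type(case.mask)(np.zeros_like(case.mask.labels))
        )
        with pytest.raises(ValueError, match="no tumor"):
            extract_patches(empty, size=32, tumor_fraction=0.5)

    def test_padding_to_larger_size(self, small_case):
        ps = extract_patches(small_case, size=64, tumor_fraction=1.0, seed=0)
        assert ps.images.shape[1:] == (64, 64, 4)
        assert ps.masks.shape[1:] == (64, 64)

    def test_flair_mask_centroid_alignment(self, clean_case):
        """Bright-edema centroid in FLAIR matches the mask centroid <= 1 voxel."""
        ps = extract_patches(
            clean_case, size=32, tumor_fraction=1.0, seed=0, normalize=False
        )
        flair = ps.images[..., 3]
        for img, mask in zip(flair, ps.masks):
            bright = img > 150.0  # between healthy (110) and edema (180)
            if not bright.any() or not (mask == 2).any():
                continue
            c_img = np.argwhere(bright).mean(axis=0)
            c_mask = np.argwhere(mask == 2).mean(axis=0)
            assert np.all(np.abs(c_img - c_mask) <= 1.0)
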