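"""Patch harvesting, flip/rotate/scale augmentation, mask implantation."""

import numpy as np
import pytest

import maskgan as mg
from maskgan.errors import EmptyInput, EmptyMask, OutOfBounds


def _bbox_oracle(mask, margin, shape):
    """Brute-force bounding box + margin, clipped to the image, via loops."""
    rows = [r for r in range(mask.shape[0]) if mask[r].any()]
    cols = [c for c in range(mask.shape[1]) if mask[:, c].any()]
    return (max(0, rows[0] - margin), min(shape[0], rows[-1] + 1 + margin),
            max(0, cols[0] - margin), min(shape[1], cols[-1] + 1 + margin))


def _dihedral_oracle(arr):
    """All 8 flip/rot90 images of a 2D array, via explicit index maps."""
    h, w = arr.shape
    out = []
    for flip in (False, True):
        base = np.empty_like(arr)
        for r in range(h):
            for c in range(w):
                base[r, c] = arr[r, w - 1 - c] if flip else arr[r, c]
        cur = base
        for _ in range(4):
            out.append(cur.copy())
            hh, ww = cur.shape
            nxt = np.empty((ww, hh), dtype=arr.dtype)
            for i in range(ww):
                for j in range(hh):
                    nxt[i, j] = cur[j, ww - 1 - i]  # 90-degree CCW
            cur = nxt
    return out


class TestHarvestPatches:
    def test_two_blobs_two_patches(self):
        mask = np.zeros((20, 20))
        mask[2:4, 2:4] = 1
        mask[10:13, 14:16] = 1
        slc = mg.CtSlice(np.arange(400).reshape(20, 20) % 4096)
        patches = mg.harvest_patches(slc, mg.TumorMask(mask), margin=1)
        assert len(patches) == 2

    def test_square_blob_margin(self):
        mask = np.zeros((16, 16))
        mask[6:9, 6:9] = 1  # 3x3 blob
        slc = mg.CtSlice(np.ones((16, 16)))
        (patch,) = mg.harvest_patches(slc, mg.TumorMask(mask), margin=1)
        assert patch.shape == (5, 5)
        assert patch.origin == (5, 5)

    def test_border_blob_clipped(self, rng):
        mask = np.zeros((16, 16))
        mask[0:3, 13:16] = 1  # touches top-right corner
        pixels = rng.integers(0, 4096, (16, 16)).astype(float)
        (patch,) = mg.harvest_patches(mg.CtSlice(pixels), mg.TumorMask(mask),
                                      margin=2)
        r0, r1, c0, c1 = _bbox_oracle(mask, 2, (16, 16))
        assert patch.shape == (r1 - r0, c1 - c0)
        np.testing.assert_array_equal(patch.pixels, pixels[r0:r1, c0:c1])

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMask):
            mg.harvest_patches(mg.CtSlice(np.ones((8, 8))),
                               mg.TumorMask(np.zeros((8, 8))), margin=1)

    def test_phantom_lesions_harvest(self, phantom64):
        slc, mask = phantom64
        patches = mg.harvest_patches(slc, mask, margin=2)
        assert len(patches) >= 1
        for p in patches:
            assert p.mask.sum() >= 1


class TestApplyTransform:
    def test_dihedral_group_matches_enumeration(self, rng):
        pixels = rng.integers(0, 4096, (2, 3)).astype(float)
        mask = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        patch = mg.TumorPatch(pixels, mask)
        produced = []
        for hflip in (False, True):
            for k in range(4):
                out = mg.apply_transform(patch, hflip=hflip, angle_deg=90.0 * k)
                produced.append(out.pixels)
        expected = _dihedral_oracle(pixels)
        got = sorted(p.tobytes() for p in produced)
        want = sorted(e.astype(float).tobytes() for e in expected)
        assert got == want

    def test_masks_stay_binary_under_continuous_transform(self, phantom64):
        slc, mask = phantom64
        (patch, *_) = mg.harvest_patches(slc, mask, margin=2)
        out = mg.apply_transform(patch, angle_deg=33.0, scale=1.2)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.mask.sum() >= 1

    def test_identity_transform(self, phantom64):
        slc, mask = phantom64
        (patch, *_) = mg.harvest_patches(slc, mask, margin=2)
        out = mg.apply_transform(patch)
        np.testing.assert_array_equal(out.pixels, patch.pixels)
        np.testing.assert_array_equal(out.mask, patch.mask)


class TestAugmentPatches:
    def _patches(self, rng, n=3):
        out = []
        for _ in range(n):
            mask = np.zeros((6, 6), dtype=np.uint8)
            mask[2:4, 2:4] = 1
            out.append(mg.TumorPatch(rng.integers(0, 4096, (6, 6)), mask))
        return out

    def test_exact_target_count(self, rng):
        patches = self._patches(rng)
        out, manifest = mg.augment_patches(patches, target_count=25, seed=0)
        assert len(out) == 25 and len(manifest) == 25

    def test_originals_returned_at_equal_target(self, rng):
        patches = self._patches(rng)
        out, manifest = mg.augment_patches(patches, target_count=3, seed=0)
        assert all(rec.is_identity for rec in manifest)
        for a, b in zip(out, patches):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_deterministic(self, rng):
        patches = self._patches(rng)
        a, ma = mg.augment_patches(patches, target_count=20, seed=42)
        b, mb = mg.augment_patches(patches, target_count=20, seed=42)
        assert ma == mb
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.pixels, pb.pixels)
            np.testing.assert_array_equal(pa.mask, pb.mask)

    def test_manifest_describes_outputs(self, rng):
        patches = self._patches(rng)
        out, manifest = mg.augment_patches(patches, target_count=10, seed=7)
        for rec, item in zip(manifest[3:], out[3:]):
            redo = mg.apply_transform(patches[rec.source_index], rec.hflip,
                                      rec.vflip, rec.angle_deg, rec.scale)
            np.testing.assert_array_equal(redo.pixels, item.pixels)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInput):
            mg.augment_patches([], target_count=5, seed=0)

    def test_target_below_source_rejected(self, rng):
        with pytest.raises(EmptyInput):
            mg.augment_patches(self._patches(rng), target_count=2, seed=0)


class TestImplantMask:
    def test_two_disjoint_implants_union(self, phantom64):
        slc, _ = phantom64
        stencil = np.ones((4, 4), dtype=np.uint8)
        am1, m1 = mg.implant_mask(slc, stencil, (5, 5))
        am2, m2 = mg.implant_mask(slc, stencil, (30, 30), existing_mask=m1)
        whitened = am2.pixels == mg.WHITE_VALUE
        expected = np.zeros(slc.shape, dtype=bool)
        expected[5:9, 5:9] = True
        expected[30:34, 30:34] = True
        assert m2.count == 32
        assert np.all(whitened[expected])
        assert np.array_equal(am2.pixels[~expected], slc.pixels[~expected])

    def test_empty_stencil_identity(self, phantom64):
        slc, _ = phantom64
        am, mask = mg.implant_mask(slc, np.zeros((3, 3), dtype=np.uint8), (10, 10))
        np.testing.assert_array_equal(am.pixels, slc.pixels)
        assert mask.count == 0

    def test_out_of_bounds(self, phantom64):
        slc, _ = phantom64
        with pytest.raises(OutOfBounds):
            mg.implant_mask(slc, np.ones((8, 8)), (60, 60))

    def test_reimplanting_harvested_mask_reproduces_attention_map(self, phantom64):
        slc, mask = phantom64
        patches = mg.harvest_patches(slc, mask, margin=2)
        am = None
        acc = None
        for p in patches:
            am, acc = mg.implant_mask(slc, p.mask, p.origin, existing_mask=acc)
        direct = mg.make_attention_map(slc, mask)
        np.testing.assert_array_equal(am.pixels, direct.pixels)
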