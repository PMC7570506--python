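import numpy as np
import pytest

from hsipix.core_io import (
    Hypercube, LabelImage, band_index, label_from_scene, read_cube, refold,
    unfold, write_cube,
)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_roundtrip_bitwise(self, tmp_path, rng, interleave):
        cube = Hypercube(rng.random((4, 5, 3)), [100.0, 110.0, 120.0])
        p = tmp_path / f"cube_{interleave}.raw"
        write_cube(cube, p, format="envi", interleave=interleave)
        back = read_cube(p, format="envi")
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)

    def test_interleaves_agree_on_handbuilt_payload(self, tmp_path):
        """BSQ and BIP files of one 4x5x3 array load identically; the BSQ
        payload is laid out by explicit index arithmetic, not the writer."""
        data = np.arange(60, dtype=np.float64).reshape(4, 5, 3)
        def hdr(ilv):
            return ("ENVI\nsamples = 5\nlines = 4\nbands = 3\ndata type = 5\n"
                    f"byte order = 0\ninterleave = {ilv}\n"
                    "wavelength = { 100, 110, 120 }\n")
        # BSQ: element (band b, line r, sample c) at index b*20 + r*5 + c
        bsq = np.empty(60)
        for b in range(3):
            for r in range(4):
                for c in range(5):
                    bsq[b * 20 + r * 5 + c] = data[r, c, b]
        (tmp_path / "a.raw").write_bytes(bsq.tobytes())
        (tmp_path / "a.raw.hdr").write_text(hdr("bsq"))
        # BIP: element (r, c, b) at index r*15 + c*3 + b
        bip = np.empty(60)
        for r in range(4):
            for c in range(5):
                for b in range(3):
                    bip[r * 15 + c * 3 + b] = data[r, c, b]
        (tmp_path / "b.raw").write_bytes(bip.tobytes())
        (tmp_path / "b.raw.hdr").write_text(hdr("bip"))
        a = read_cube(tmp_path / "a.raw")
        b = read_cube(tmp_path / "b.raw")
        np.testing.assert_array_equal(a.data, data)
        np.testing.assert_array_equal(a.data, b.data)

    def test_payload_size_mismatch_rejected(self, tmp_path):
        (tmp_path / "bad.raw").write_bytes(np.zeros(100).tobytes())
        (tmp_path / "bad.raw.hdr").write_text(
            "ENVI\nsamples = 5\nlines = 4\nbands = 101\ndata type = 5\n"
            "interleave = bsq\nwavelength = { " +
            ", ".join(str(900 + i) for i in range(101)) + " }\n")
        with pytest.raises(ValueError, match="payload"):
            read_cube(tmp_path / "bad.raw")

    def test_missing_wavelengths_named_in_error(self, tmp_path):
        (tmp_path / "c.raw").write_bytes(np.zeros(60).tobytes())
        (tmp_path / "c.raw.hdr").write_text(
            "ENVI\nsamples = 5\nlines = 4\nbands = 3\ndata type = 5\n"
            "interleave = bsq\n")
        with pytest.raises(ValueError, match="wavelength"):
            read_cube(tmp_path / "c.raw")

    def test_npz_roundtrip_with_mask(self, tmp_path, random_cube):
        cube = random_cube()
        p = tmp_path / "cube.npz"
        write_cube(cube, p)
        back = read_cube(p)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.mask, cube.mask)

    def test_npz_carries_optional_labels(self, tmp_path, random_cube):
        from hsipix.core_io import read_labels

        cube = random_cube()
        lab = label_from_scene(cube, 2, class_names=["a", "b"])
        p = tmp_path / "scene.npz"
        write_cube(cube, p, labels=lab)
        back = read_labels(p)
        np.testing.assert_array_equal(back.labels, lab.labels)
        assert list(back.class_names) == ["a", "b"]
        assert read_labels(self._plain(tmp_path, random_cube)) is None

    @staticmethod
    def _plain(tmp_path, random_cube):
        p = tmp_path / "plain.npz"
        write_cube(random_cube(), p)
        return p


class TestBandIndex:
    def test_known_grid_examples(self):
        wl = 943.0 + 7.0 * np.arange(101)
        assert band_index(wl, 957) == 2      # exact band center
        assert band_index(wl, 1496) == 79
        assert band_index(wl, 943) == 0

    def test_tie_breaks_to_lower_index(self):
        wl = np.array([100.0, 110.0, 120.0])
        assert band_index(wl, 105.0) == 0
        assert band_index(wl, 115.0) == 1

    def test_target_outside_range_rejected(self):
        wl = np.array([100.0, 110.0, 120.0])
        with pytest.raises(ValueError, match="outside"):
            band_index(wl, 131.0)
        with pytest.raises(ValueError, match="outside"):
            band_index(wl, 89.0)
        band_index(wl, 129.0)  # within one spacing: allowed

    def test_monotone_in_target(self, rng):
        wl = np.sort(rng.random(40)) * 500 + 900
        wl += np.arange(40) * 1e-6  # ensure strict increase
        targets = np.linspace(wl[0], wl[-1], 200)
        idx = [band_index(wl, t) for t in targets]
        assert all(a <= b for a, b in zip(idx, idx[1:]))


class TestUnfoldRefold:
    def test_enumeration_no_mask(self):
        data = np.arange(12, dtype=float).reshape(2, 2, 3)
        cube = Hypercube(data, [1.0, 2.0, 3.0])
        flat = unfold(cube, use_mask=False)
        assert flat.values.shape == (4, 3)
        np.testing.assert_array_equal(
            flat.coords, [[0, 0], [0, 1], [1, 0], [1, 1]])
        np.testing.assert_array_equal(flat.values[2], data[1, 0])

    def test_single_pixel_mask(self):
        data = np.arange(12, dtype=float).reshape(2, 2, 3)
        mask = np.zeros((2, 2), bool)
        mask[1, 0] = True
        cube = Hypercube(data, [1.0, 2.0, 3.0], mask=mask)
        flat = unfold(cube)
        assert flat.values.shape == (1, 3)
        np.testing.assert_array_equal(flat.values[0], data[1, 0])

    def test_empty_foreground_rejected(self):
        cube = Hypercube(np.zeros((2, 2, 3)), [1.0, 2.0, 3.0],
                         mask=np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="foreground"):
            unfold(cube)

    def test_roundtrip_identity_many_random_cubes(self, random_cube):
        """refold(unfold(cube)) restores the foreground and fills elsewhere,
        across 100 random shapes/masks/seeds."""
        base = np.random.default_rng(7)
        for trial in range(100):
            rows, cols, bands = base.integers(1, 9, size=3)
            cube = random_cube(int(rows), int(cols), int(bands),
                               seed=1000 + trial)
            flat = unfold(cube)
            img = refold(flat, fill=-7.0)
            np.testing.assert_array_equal(img[cube.mask], cube.data[cube.mask])
            assert np.all(img[~cube.mask] == -7.0)

    def test_refold_conservation(self, random_cube):
        cube = random_cube()
        flat = unfold(cube)
        vals = np.ones((flat.n_pixels, 2))
        img = refold(flat, vals, fill=0.0)
        assert img.sum() == pytest.approx(vals.sum())

    def test_refold_row_count_mismatch(self, random_cube):
        flat = unfold(random_cube())
        with pytest.raises(ValueError, match="rows"):
            refold(flat, np.zeros((flat.n_pixels + 1, 1)))

    def test_classification_map_from_predictions(self, random_cube):
        cube = random_cube()
        flat = unfold(cube)
        pred = np.full(flat.n_pixels, 3, dtype=np.int32)
        img = refold(flat, pred, fill=0)[:, :, 0]
        assert set(np.unique(img)) <= {0, 3}
        assert (img == 3).sum() == flat.n_pixels


class TestLabelFromScene:
    def test_constant_class_on_full_mask(self):
        cube = Hypercube(np.zeros((3, 3, 2)), [1.0, 2.0],
                         mask=np.ones((3, 3), bool))
        lab = label_from_scene(cube, 3, class_names=["a", "b", "c"])
        assert np.all(lab.labels == 3)

    def test_nonzero_count_matches_mask(self, random_cube):
        cube = random_cube()
        lab = label_from_scene(cube, 2, class_names=["a", "b"])
        assert (lab.labels > 0).sum() == cube.mask.sum()
        assert np.all((lab.labels == 2) == cube.mask)

    def test_background_class_id_rejected(self, random_cube):
        with pytest.raises(ValueError, match="class_id"):
            label_from_scene(random_cube(), 0)


class TestLabelImage:
    def test_label_exceeding_names_rejected(self):
        with pytest.raises(ValueError):
            LabelImage(np.full((2, 2), 3), class_names=["a", "b"])

    def test_negative_labels_rejected(self):
        with pytest.raises(ValueError):
            LabelImage(np.full((2, 2), -1))
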