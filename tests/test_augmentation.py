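import hashlib

import numpy as np
import pytest

from sorghumnet import (
    AugmentConfig,
    DensityMapConfig,
    ImageRecord,
    PointSet,
    ValidationError,
    augment_pair,
    build_density_map,
    expand_dataset,
    rescale_points,
    split_dataset,
)
from sorghumnet.augmentation import _rotate_pair
from sorghumnet.density_maps import count_from_density


def photometric_only(**kw):
    base = dict(p_rotate=0, p_hflip=0, p_vflip=0, p_hue_sat=1, p_noise=1,
                p_blur=1, p_invert=0, p_contrast=1, p_additive=1)
    base.update(kw)
    return AugmentConfig(**base)


def geometric_only(**kw):
    base = dict(p_rotate=0, p_hflip=0, p_vflip=0, p_hue_sat=0, p_noise=0,
                p_blur=0, p_invert=0, p_contrast=0, p_additive=0)
    base.update(kw)
    return AugmentConfig(**base)


@pytest.fixture
def sample(rng):
    img = ImageRecord("s", rng.integers(0, 255, (60, 40, 3), dtype=np.uint8))
    pts = np.array([[5.0, 7.0], [30.5, 50.25], [0.0, 0.0], [39.0, 59.0]])
    return img, PointSet("s", 40, 60, pts)


class TestAugmentPair:
    def test_horizontal_flip_formula(self, sample, rng):
        img, ps = sample
        cfg = geometric_only(p_hflip=1)
        aimg, aps = augment_pair(img, ps, cfg, rng)
        np.testing.assert_allclose(aps.points[:, 0], 39 - ps.points[:, 0])
        np.testing.assert_allclose(aps.points[:, 1], ps.points[:, 1])
        np.testing.assert_array_equal(aimg.pixels, img.pixels[:, ::-1])

    def test_double_flip_restores_coordinates(self, sample, rng):
        img, ps = sample
        cfg = geometric_only(p_hflip=1, p_vflip=1)
        a_img, a_ps = augment_pair(img, ps, cfg, rng)
        b_img, b_ps = augment_pair(a_img, a_ps, cfg, rng)
        np.testing.assert_allclose(b_ps.points, ps.points)
        np.testing.assert_array_equal(b_img.pixels, img.pixels)

    def test_photometric_leaves_annotation_unchanged(self, sample, rng):
        img, ps = sample
        aimg, aps = augment_pair(img, ps, photometric_only(), rng)
        np.testing.assert_array_equal(aps.points, ps.points)
        assert not np.array_equal(aimg.pixels, img.pixels)

    def test_rotation_matches_rotation_matrix_oracle(self):
        """90-degree rotation of a corner point, checked against the 2-D
        rotation matrix applied about the image centre."""
        img = np.zeros((11, 11, 3), dtype=np.uint8)
        pts = np.array([[1.0, 2.0]])
        _, _, rotated = _rotate_pair(img, None, pts, 90.0)
        cx = cy = 5.0
        theta = np.pi / 2
        rel = pts[0] - [cx, cy]
        expected = [
            cx + rel[0] * np.cos(theta) - rel[1] * np.sin(theta),
            cy + rel[0] * np.sin(theta) + rel[1] * np.cos(theta),
        ]
        np.testing.assert_allclose(rotated[0], expected, atol=1e-9)

    def test_rotation_keeps_image_and_points_consistent(self, rng):
        """A single bright pixel and its annotation must land on the same
        spot after rotation."""
        img = np.zeros((41, 41, 3), dtype=np.uint8)
        img[10, 28] = 255
        rec = ImageRecord("r", img)
        ps = PointSet("r", 41, 41, np.array([[28.0, 10.0]]))
        cfg = geometric_only(p_rotate=1, rotation_range=25)
        aimg, aps = augment_pair(rec, ps, cfg, rng)
        assert aps.n_points == 1
        x, y = aps.points[0]
        bright = np.unravel_index(aimg.pixels[..., 0].argmax(), (41, 41))
        assert abs(bright[0] - y) <= 1.0 and abs(bright[1] - x) <= 1.0

    def test_size_mismatch_rejected(self, sample, rng):
        img, _ = sample
        ps = PointSet("s", 30, 30, np.array([[1.0, 1.0]]))
        with pytest.raises(ValidationError):
            augment_pair(img, ps, AugmentConfig(), rng)

    def test_density_regenerated_after_augmentation_conserves_count(self, sample, rng):
        img, ps = sample
        cfg = AugmentConfig(seed=3)
        aimg, aps = augment_pair(img, ps, cfg, rng)
        scaled = rescale_points(aps, (112, 112))
        dm = build_density_map(scaled, DensityMapConfig(target_size=(112, 112)))
        assert abs(count_from_density(dm) - aps.n_points) < 1e-6


def _write_source(tmp_path, rng, n=2):
    from sorghumnet.annotations_io import ManifestRecord, DatasetManifest, save_image, write_point_annotations
    records = []
    for i in range(n):
        iid = f"src{i}"
        save_image(rng.integers(0, 255, (48, 32, 3), dtype=np.uint8),
                   tmp_path / f"{iid}.png")
        ps = PointSet(iid, 32, 48, rng.uniform(0, 30, (5, 2)))
        write_point_annotations(ps, tmp_path / f"{iid}.json")
        records.append(ManifestRecord(iid, f"{iid}.png", f"{iid}.json",
                                      "", "A", f"p{i}", 100))
    return DatasetManifest(records=records, root=tmp_path)


def _tree_hash(directory):
    h = hashlib.sha256()
    for p in sorted(directory.iterdir()):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


class TestExpandDataset:
    def test_variant_count(self, tmp_path, rng):
        man = _write_source(tmp_path, rng, n=2)
        out = expand_dataset(man, AugmentConfig(variants_per_image=3, seed=0),
                             tmp_path / "aug")
        assert len(out.records) == 6
        # originals are not kept
        assert all("_aug" in r.image_id for r in out.records)

    def test_single_variant(self, tmp_path, rng):
        man = _write_source(tmp_path, rng, n=1)
        out = expand_dataset(man, AugmentConfig(variants_per_image=1, seed=0),
                             tmp_path / "aug")
        assert len(out.records) == 1

    def test_same_seed_byte_identical(self, tmp_path, rng):
        man = _write_source(tmp_path, rng, n=2)
        cfg = AugmentConfig(variants_per_image=2, seed=42)
        expand_dataset(man, cfg, tmp_path / "a1")
        expand_dataset(man, cfg, tmp_path / "a2")
        assert _tree_hash(tmp_path / "a1") == _tree_hash(tmp_path / "a2")

    def test_missing_annotation_names_record(self, tmp_path, rng):
        man = _write_source(tmp_path, rng, n=1)
        man.records[0].annotation = ""
        with pytest.raises(ValidationError, match="src0"):
            expand_dataset(man, AugmentConfig(variants_per_image=1), tmp_path / "aug")


class TestSplitDataset:
    def test_record_level_counts(self, tmp_path, rng):
        man = _write_source(tmp_path, rng, n=2)
        out = expand_dataset(man, AugmentConfig(variants_per_image=5, seed=0),
                             tmp_path / "aug")
        train, test = split_dataset(out, 0.8, level="record", seed=0)
        assert len(train.records) == 8 and len(test.records) == 2

    def test_source_level_keeps_variants_together(self, tmp_path, rng):
        man = _write_source(tmp_path, rng, n=4)
        out = expand_dataset(man, AugmentConfig(variants_per_image=3, seed=0),
                             tmp_path / "aug")
        train, test = split_dataset(out, 0.75, level="source", seed=1)
        def sources(m):
            return {r.image_id.split("_aug")[0] for r in m.records}
        assert sources(train).isdisjoint(sources(test))
        assert len(sources(train)) == 3 and len(sources(test)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_partition_is_disjoint_and_exhaustive(self, tmp_path, rng, seed):
        man = _write_source(tmp_path, rng, n=5)
        train, test = split_dataset(man, 0.6, level="record", seed=seed)
        ids_train = {r.image_id for r in train.records}
        ids_test = {r.image_id for r in test.records}
        assert ids_train.isdisjoint(ids_test)
        assert ids_train | ids_test == {r.image_id for r in man.records}

    def test_single_group_rejected(self, tmp_path, rng):
        man = _write_source(tmp_path, rng, n=1)
        with pytest.raises(ValidationError):
            split_dataset(man, 0.8, level="source", seed=0)
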