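import numpy as np
import pytest
from scipy import stats

from perifw import patch_budget, sample_patches, augment_patches
from perifw.patches import (PATCH_SIZE, Patch, PatchSet,
                            augmentation_admissible)
from perifw.tensor import ScalarMap


def _box_masks(shape=(48, 48, 6)):
    """Rectangular edema slab inside an all-brain grid, no tumor."""
    brain = np.ones(shape, bool)
    tumor = np.zeros(shape, bool)
    edema = np.zeros(shape, bool)
    edema[8:40, 8:40, :] = True
    return {"brain": brain, "tumor": tumor, "edema": edema}


def _map_for(masks, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.random(masks["brain"].shape)
    return ScalarMap(values=vals, kind="FW-VF", mask=masks["brain"])


class TestPatchBudget:
    @pytest.mark.parametrize("n_voxels, expected", [
        (2560, 10), (256, 1), (100, 1), (511, 1), (512, 2), (0, 0)])
    def test_budget_formula(self, n_voxels, expected):
        mask = np.zeros(4000, bool)
        mask[:n_voxels] = True
        assert patch_budget(mask.reshape(20, 20, 10)) == expected


class TestSamplePatches:
    def test_zero_request_gives_empty_set(self):
        masks = _box_masks()
        ps = sample_patches(_map_for(masks), masks, 0, seed=0)
        assert len(ps) == 0

    def test_deterministic_given_seed(self):
        masks = _box_masks()
        m = _map_for(masks)
        a = sample_patches(m, masks, 10, seed=5)
        b = sample_patches(m, masks, 10, seed=5)
        assert [p.origin for p in a] == [p.origin for p in b]
        assert np.array_equal(a.to_array(), b.to_array())

    def test_patch_shape_and_rules(self):
        masks = _box_masks()
        ps = sample_patches(_map_for(masks), masks, 20, seed=1,
                            label="metastasis")
        assert len(ps) == 20
        for p in ps:
            x, y, z = p.origin
            assert p.values.shape == (16, 16)
            assert not masks["tumor"][x:x + 16, y:y + 16, z].any()
            assert masks["brain"][x:x + 16, y:y + 16, z].all()
            assert masks["edema"][x + 8, y + 8, z]   # center voxel in edema
            assert p.label == "metastasis"

    def test_thin_shell_adjacent_to_tumor_never_includes_tumor(self):
        """A 1-voxel-thick edema ring around a tumor: every candidate window
        covering the ring overlaps near the tumor, so the rejection rule is
        exercised hard; any returned patch must still have zero tumor
        voxels under its footprint."""
        shape = (48, 48, 3)
        brain = np.ones(shape, bool)
        tumor = np.zeros(shape, bool)
        tumor[20:28, 20:28, 1] = True
        edema = np.zeros(shape, bool)
        edema[19:29, 19:29, 1] = True
        edema &= ~tumor
        masks = {"brain": brain, "tumor": tumor, "edema": edema}
        ps = sample_patches(_map_for(masks), masks, 10, seed=2)
        for p in ps:
            x, y, z = p.origin
            assert tumor[x:x + 16, y:y + 16, z].sum() == 0

    def test_infeasible_placement_returns_subset_with_warning(self, caplog):
        # edema exists but no 16x16 brain window fits in a 10-wide grid
        shape = (10, 10, 2)
        masks = {"brain": np.ones(shape, bool),
                 "tumor": np.zeros(shape, bool),
                 "edema": np.ones(shape, bool)}
        with caplog.at_level("WARNING"):
            ps = sample_patches(_map_for(masks), masks, 5, seed=0)
        assert len(ps) == 0
        assert any("rejection cap" in r.message or "placed" in r.message
                   for r in caplog.records)

    def test_center_coverage_uniform_on_symmetric_phantom(self):
        """Over many draws, deep-interior edema centers are hit uniformly
        (chi-square goodness of fit, p > 0.01)."""
        masks = _box_masks((64, 64, 1))
        masks["edema"][:] = False
        masks["edema"][12:52, 12:52, :] = True
        m = _map_for(masks)
        counts = np.zeros((64, 64))
        ps = sample_patches(m, masks, 10_000, seed=3)
        for p in ps:
            counts[p.origin[0] + 8, p.origin[1] + 8] += 1
        interior = counts[20:44, 20:44].ravel()   # >= 8 voxels from edges
        chi2, p = stats.chisquare(interior)
        assert p > 0.01

    def test_multichannel_patches(self):
        masks = _box_masks()
        m1 = _map_for(masks, 0)
        m2 = ScalarMap(values=np.full(masks["brain"].shape, 1.5e-3),
                       kind="MD", mask=masks["brain"])
        ps = sample_patches([m1, m2], masks, 4, seed=0)
        assert ps.map_kind == "FW-VF+MD"
        assert ps.to_array().shape == (4, 16, 16, 2)
        # diffusivity channel scaled by its physical range
        assert np.allclose(ps.to_array()[..., 1], 0.5)


class TestAugmentation:
    def test_zero_shift_reproduces_source(self):
        masks = _box_masks()
        m = _map_for(masks)
        ps = sample_patches(m, masks, 1, seed=0)
        src = ps.patches[0]
        assert augmentation_admissible(src.origin, (0, 0), masks)

    def test_healthy_overlap_boundary_51_vs_52(self):
        """51 of 256 healthy-brain voxels is admissible, 52 is not."""
        shape = (40, 40, 1)
        brain = np.ones(shape, bool)
        tumor = np.zeros(shape, bool)
        edema = np.ones(shape, bool)
        # carve exactly k healthy voxels into the shifted footprint at (4,4)
        origin = (4, 4, 0)
        for k, ok in ((51, True), (52, False)):
            ed = edema.copy()
            window = np.zeros((16, 16), bool)
            window.ravel()[:k] = True
            ed[4:20, 4:20] &= ~window[..., None]
            masks = {"brain": brain, "tumor": tumor, "edema": ed}
            assert augmentation_admissible(origin, (0, 0), masks) is ok

    def test_tumor_under_shifted_footprint_rejected(self):
        masks = _box_masks()
        masks["tumor"][30:32, 30:32, 0] = True
        masks["edema"] &= ~masks["tumor"]
        assert not augmentation_admissible((20, 20, 0), (0, 0), masks)

    def test_augmented_patches_flagged_and_admissible(self):
        masks = _box_masks()
        m = _map_for(masks)
        ps = sample_patches(m, masks, 8, seed=1)
        aug = augment_patches(ps, m, masks, n_aug=2, seed=2)
        assert len(aug) == 3 * len(ps)
        healthy = masks["brain"] & ~masks["edema"] & ~masks["tumor"]
        for p in aug:
            x, y, z = p.origin
            assert not masks["tumor"][x:x + 16, y:y + 16, z].any()
            assert healthy[x:x + 16, y:y + 16, z].sum() <= 51
        assert sum(p.augmented for p in aug) == 2 * len(ps)

    def test_no_admissible_shift_keeps_source_unaugmented(self, caplog):
        # tumor everywhere except the exact source window: no shift admissible
        shape = (40, 40, 1)
        tumor = np.ones(shape, bool)
        tumor[10:26, 10:26, 0] = False
        edema = ~tumor
        masks = {"brain": np.ones(shape, bool), "tumor": tumor, "edema": edema}
        m = _map_for(masks)
        src = PatchSet([Patch(values=m.normalized()[10:26, 10:26, 0],
                              origin=(10, 10, 0), subject_id="s",
                              label="glioblastoma", map_kind="FW-VF")],
                       "FW-VF")
        with caplog.at_level("WARNING"):
            aug = augment_patches(src, m, masks, n_aug=1, seed=0)
        # only shift (0,0) is admissible, so any accepted augmentation
        # duplicates the source footprint
        for p in aug:
            assert p.origin == (10, 10, 0)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        masks = _box_masks()
        ps = sample_patches(_map_for(masks), masks, 6, seed=4)
        ps.save(tmp_path / "train_fwvf")
        back = PatchSet.load(tmp_path / "train_fwvf")
        assert back.map_kind == ps.map_kind
        assert np.array_equal(back.to_array(), ps.to_array())
        assert [p.origin for p in back] == [p.origin for p in ps]
        df = back.index_frame()
        assert set(df.columns) >= {"subject_id", "label", "x", "y", "z",
                                   "augmented"}

    def test_mixed_map_kind_rejected(self):
        p1 = Patch(values=np.zeros((16, 16)), origin=(0, 0, 0),
                   subject_id="s", label="glioblastoma", map_kind="FA")
        p2 = Patch(values=np.zeros((16, 16)), origin=(0, 0, 0),
                   subject_id="s", label="glioblastoma", map_kind="MD")
        with pytest.raises(ValueError, match="map kind"):
            PatchSet([p1, p2], "FA")
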