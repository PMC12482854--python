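import numpy as np
import pandas as pd
import pytest

import atnquant as aq
from conftest import random_label_volume, tiny_dictionary


def brute_force_stats(pet, labels):
    """Naive per-voxel accumulation oracle for region_stats."""
    sums, counts = {}, {}
    nx, ny, nz = labels.labels.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                lid = int(labels.labels[i, j, k])
                v = float(pet.data[i, j, k])
                if lid == 0:
                    continue
                if np.isfinite(v) and v >= 0:
                    sums[lid] = sums.get(lid, 0.0) + v
                    counts[lid] = counts.get(lid, 0) + 1
    return {lid: sums[lid] / counts[lid] for lid in sums}


class TestRegionStats:
    def test_uniform_region(self):
        labels = random_label_volume(1)
        pet = aq.ImageVolume(np.where(labels.labels == 3, 2.0, 0.5),
                             labels.affine)
        stats = aq.region_stats(pet, labels)
        row = stats.table.set_index("id").loc[3]
        assert row["mean"] == pytest.approx(2.0)
        assert row["voxels"] == int((labels.labels == 3).sum())

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        labels = random_label_volume(seed)
        rng = np.random.default_rng(seed + 1000)
        pet = aq.ImageVolume(rng.random(labels.labels.shape), labels.affine)
        stats = aq.region_stats(pet, labels)
        expected = brute_force_stats(pet, labels)
        got = stats.table.set_index("id")["mean"]
        for lid, mean in expected.items():
            assert got.loc[lid] == pytest.approx(mean, abs=1e-12)

    def test_nan_and_negative_excluded(self):
        labels = random_label_volume(2)
        data = np.ones(labels.labels.shape)
        sel = labels.labels == 1
        idx = np.argwhere(sel)
        data[tuple(idx[0])] = np.nan
        data[tuple(idx[1])] = -5.0
        stats = aq.region_stats(aq.ImageVolume(data, labels.affine), labels)
        row = stats.table.set_index("id").loc[1]
        assert row["excluded"] == 2
        assert row["mean"] == pytest.approx(1.0)

    def test_absent_label_flagged_not_dropped(self):
        labels = random_label_volume(3)
        labels.labels[labels.labels == 5] = 0  # erase label 5
        pet = aq.ImageVolume(np.ones(labels.labels.shape), labels.affine)
        stats = aq.region_stats(pet, labels)
        row = stats.table.set_index("id").loc[5]
        assert row["voxels"] == 0 and np.isnan(row["mean"])

    def test_grid_mismatch_rejected(self, pet_phantom):
        labels = random_label_volume(4)
        with pytest.raises(ValueError, match="grid mismatch"):
            aq.region_stats(pet_phantom, labels)


class TestReferenceAndSuvr:
    def test_pooled_reference_is_volume_weighted(self):
        # two labels, means 1.0 / 3.0 with a 1:3 voxel ratio -> 2.5
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[:2, :4, :4] = 1   # 32 voxels
        labels[2:8, :4, :4] = 2  # 96 voxels
        d = tiny_dictionary(2)
        lv = aq.LabelVolume(labels, np.eye(4), d)
        pet = aq.ImageVolume(np.where(labels == 1, 1.0, 3.0) * (labels > 0),
                             np.eye(4))
        stats = aq.region_stats(pet, lv)
        ref = aq.CompositeMask("ref", frozenset({1, 2}))
        assert aq.reference_uptake(stats, ref) == pytest.approx(2.5)

    def test_single_label_reference(self):
        labels = random_label_volume(5)
        pet = aq.ImageVolume(np.full(labels.labels.shape, 1.7), labels.affine)
        stats = aq.region_stats(pet, labels)
        ref = aq.CompositeMask("ref", frozenset({2}))
        assert aq.reference_uptake(stats, ref) == pytest.approx(1.7)

    def test_empty_reference_rejected(self):
        labels = random_label_volume(6, n_labels=3)
        labels.labels[labels.labels == 2] = 0
        pet = aq.ImageVolume(np.ones(labels.labels.shape), labels.affine)
        stats = aq.region_stats(pet, labels)
        with pytest.raises(ValueError, match="empty reference"):
            aq.reference_uptake(stats, aq.CompositeMask("r", frozenset({2})))

    def test_full_phantom_yields_122_rows(self, pet_phantom, label_phantom,
                                          dictionary, masks):
        stats = aq.region_stats(pet_phantom, label_phantom)
        ref = aq.resolve_mask("whole_cerebellum", masks, dictionary)
        table = aq.suvr_table(stats, ref, dictionary)
        assert len(table) == 122
        assert set(table.table["tissue"]) == {"GM"}

    def test_reference_suvr_is_one(self, pet_phantom, label_phantom,
                                   dictionary, masks):
        stats = aq.region_stats(pet_phantom, label_phantom)
        ref = aq.resolve_mask("cerebellar_gm", masks, dictionary)
        table = aq.suvr_table(stats, ref, dictionary)
        suvr = table.as_series()
        ids = [i for i in ref.structure_ids if i in suvr.index]
        sub = stats.table.set_index("id").loc[ids]
        pooled = ((sub["mean"] * sub["included"]).sum()
                  / sub["included"].sum()) / table.reference_uptake
        assert pooled == pytest.approx(1.0, abs=1e-9)

    def test_zero_reference_rejected(self):
        labels = random_label_volume(7)
        pet = aq.ImageVolume(np.zeros(labels.labels.shape), labels.affine)
        stats = aq.region_stats(pet, labels)
        with pytest.raises(ValueError, match="reference"):
            aq.suvr_table(stats, aq.CompositeMask("r", frozenset({1})),
                          labels.dictionary)


class TestCompositeSuvr:
    def test_mask_equal_reference_is_one(self, pet_phantom, label_phantom,
                                         dictionary, masks):
        stats = aq.region_stats(pet_phantom, label_phantom)
        ref = aq.resolve_mask("whole_cerebellum", masks, dictionary)
        assert aq.composite_suvr(stats, ref, ref) == pytest.approx(1.0)

    def test_two_region_weighted_mean(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[:4, :, :] = 1
        labels[4:, :, :] = 2
        d = tiny_dictionary(3)
        labels[0, 0, 0] = 3  # reference voxel
        lv = aq.LabelVolume(labels, np.eye(4), d)
        data = np.where(labels == 1, 1.2, 1.8)
        data[0, 0, 0] = 1.0
        stats = aq.region_stats(aq.ImageVolume(data, np.eye(4)), lv)
        mask = aq.CompositeMask("m", frozenset({1, 2}))
        ref = aq.CompositeMask("ref", frozenset({3}))
        got = aq.composite_suvr(stats, mask, ref)
        n1 = int((labels == 1).sum())
        n2 = int((labels == 2).sum())
        assert got == pytest.approx((1.2 * n1 + 1.8 * n2) / (n1 + n2))

    def test_unknown_mask_id_rejected(self, dictionary):
        with pytest.raises(ValueError, match="absent"):
            aq.CompositeMask("bad", frozenset({9999})).validate(dictionary)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aq.CompositeMask("m", frozenset())


def _suvr_tables_with_effects(n_per_group, effect_ids, seed):
    """Two cohorts of SuvrTables: effect_ids separated by ~3 SD."""
    rng = np.random.default_rng(seed)
    ids = list(range(1, 9))
    out = ([], [])
    for g, shift in enumerate((0.0, 1.0)):
        for _ in range(n_per_group):
            suvr = 1.0 + 0.1 * rng.standard_normal(len(ids))
            for lid in effect_ids:
                suvr[ids.index(lid)] += shift * 0.3
            df = pd.DataFrame({"id": ids, "name": [f"R{i}" for i in ids],
                               "tissue": "GM", "mean": suvr, "voxels": 100,
                               "volume_mm3": 800.0, "suvr": suvr})
            out[g].append(aq.SuvrTable(df, "ref", 1.0))
    return out


class TestDiscriminativeSelection:
    @pytest.mark.parametrize("criterion", ["effect_size", "auc"])
    def test_planted_structures_found(self, criterion):
        a, b = _suvr_tables_with_effects(30, effect_ids=[2, 5], seed=0)
        res = aq.select_discriminative_structures(a, b, criterion, top_k=2)
        assert res.mask.structure_ids == {2, 5}
        assert res.stable

    def test_identical_groups_unstable(self):
        a, _ = _suvr_tables_with_effects(10, effect_ids=[], seed=1)
        res = aq.select_discriminative_structures(a, list(a), top_k=3)
        assert not res.stable

    def test_single_subject_rejected(self):
        a, b = _suvr_tables_with_effects(3, effect_ids=[1], seed=2)
        with pytest.raises(ValueError, match="2 subjects"):
            aq.select_discriminative_structures(a[:1], b)

    def test_mismatched_labels_rejected(self):
        a, b = _suvr_tables_with_effects(3, effect_ids=[1], seed=3)
        b[0].table.drop(index=0, inplace=True)
        with pytest.raises(ValueError, match="mismatched"):
            aq.select_discriminative_structures(a, b)


class TestPvc:
    @staticmethod
    def _two_region_phantom():
        labels = np.zeros((40, 40, 40), dtype=np.int32)
        labels[8:20, 8:32, 8:32] = 1
        labels[20:32, 8:32, 8:32] = 2
        d = tiny_dictionary(2)
        grid = aq.SpaceSpec.isotropic((40, 40, 40), 2.0)
        lv = aq.LabelVolume(labels, grid.affine, d)
        truth = {1: 1.0, 2: 3.0}
        blurred = aq.make_pet_phantom(lv, truth, psf_fwhm=6.0)
        return lv, blurred, truth

    def _region_means(self, vol, lv):
        stats = aq.region_stats(vol, lv)
        return stats.table.set_index("id")["mean"]

    def test_recovers_means_within_2_percent(self):
        lv, blurred, truth = self._two_region_phantom()
        corrected = aq.pvc_region_based(blurred, lv, psf_fwhm=6.0,
                                        iterations=5)
        means = self._region_means(corrected, lv)
        for lid, t in truth.items():
            assert means.loc[lid] == pytest.approx(t, rel=0.02)

    def test_error_decreases_over_first_iterations(self):
        lv, blurred, truth = self._two_region_phantom()
        errs = []
        for it in range(1, 4):
            corrected = aq.pvc_region_based(blurred, lv, psf_fwhm=6.0,
                                            iterations=it)
            means = self._region_means(corrected, lv)
            errs.append(sum(abs(means.loc[lid] - t)
                            for lid, t in truth.items()))
        base = self._region_means(blurred, lv)
        err0 = sum(abs(base.loc[lid] - t) for lid, t in truth.items())
        assert errs[0] < err0
        assert errs[0] > errs[1] > errs[2]

    def test_vanishing_psf_is_identity_limit(self):
        lv, blurred, _ = self._two_region_phantom()
        out = aq.pvc_region_based(blurred, lv, psf_fwhm=1e-6, iterations=3)
        np.testing.assert_allclose(out.data, blurred.data, atol=1e-9)

    def test_total_uptake_approximately_conserved(self):
        # phantom without background spill: the two regions tile the grid
        labels = np.zeros((40, 40, 40), dtype=np.int32)
        labels[:20] = 1
        labels[20:] = 2
        grid = aq.SpaceSpec.isotropic((40, 40, 40), 2.0)
        lv = aq.LabelVolume(labels, grid.affine, tiny_dictionary(2))
        blurred = aq.make_pet_phantom(lv, {1: 1.0, 2: 3.0}, psf_fwhm=6.0)
        prev = blurred.data.sum()
        for it in range(1, 4):
            cur = aq.pvc_region_based(blurred, lv, psf_fwhm=6.0,
                                      iterations=it).data.sum()
            assert abs(cur - prev) / prev < 0.01
            prev = cur

    def test_nonpositive_fwhm_rejected(self):
        lv, blurred, _ = self._two_region_phantom()
        with pytest.raises(ValueError, match="psf_fwhm"):
            aq.pvc_region_based(blurred, lv, psf_fwhm=0.0)


class TestVolumeTable:
    def test_arithmetic(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels.reshape(-1)[:1000] = 1
        d = tiny_dictionary(2)
        lv = aq.LabelVolume(labels, np.eye(4), d)  # 1 mm3 voxels
        vt = aq.volume_table(lv, icv=1.5e6)
        row = vt.table.set_index("id").loc[1]
        assert row["native_mm3"] == pytest.approx(1000.0)
        assert row["icv_fraction"] == pytest.approx(6.667e-4, rel=1e-3)

    def test_empty_label_zero_volume(self):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        lv = aq.LabelVolume(labels, np.eye(4), tiny_dictionary(2))
        vt = aq.volume_table(lv, icv=1e6)
        assert vt.table.set_index("id").loc[2, "native_mm3"] == 0.0

    def test_zero_icv_rejected(self):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        lv = aq.LabelVolume(labels, np.eye(4), tiny_dictionary(1))
        with pytest.raises(ValueError, match="icv"):
            aq.volume_table(lv, icv=0.0)

    def test_fractions_sum_below_one(self, label_phantom):
        vt = aq.volume_table(label_phantom, aq.estimate_icv(label_phantom))
        frac = vt.table["icv_fraction"]
        assert ((frac >= 0) & (frac < 1)).all()
        assert frac.sum() <= 1.0 + 1e-9
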