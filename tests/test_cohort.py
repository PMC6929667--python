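"""Synthetic cohort generator: determinism, composition, planted effects."""

import numpy as np
import pytest

import painconn as pc
from painconn.cohort import choose_disjoint_pairs


def test_same_config_same_seed_is_bitwise_identical(small_cohort):
    cfg, recs = small_cohort
    again = pc.generate_cohort(cfg)
    assert len(again) == len(recs)
    for a, b in zip(recs, again):
        assert a.subject_id == b.subject_id
        assert a.group == b.group and a.sex == b.sex
        assert np.array_equal(a.timeseries, b.timeseries)
        assert np.array_equal(a.confounds, b.confounds)
        assert a.artifact_flags == b.artifact_flags


def test_cohort_composition_follows_proportions():
    cfg = pc.CohortConfig(n_subjects=140, artifact_rate=0.0, seed=1)
    recs = pc.generate_cohort(cfg)
    groups = [r.group for r in recs]
    sexes = [r.sex for r in recs]
    # largest-remainder apportionment of the 98:60 and 124:34 ratios
    assert groups.count("control") == 87
    assert groups.count("chronic_pain") == 53
    assert sexes.count("female") == 110
    assert sexes.count("male") == 30
    assert all(r.timeseries.shape == (16, 235) for r in recs)
    assert not any(np.isnan(r.timeseries).any() for r in recs)


@pytest.mark.parametrize("bad", [
    dict(group_proportions=(0.6, 0.5)),
    dict(sex_proportions=(0.5, 0.4)),
    dict(lag_effect=80, n_timepoints=80),
    dict(ar_coefficient=1.0),
    dict(corr_effect=3.0),
    dict(affected_edges=frozenset({(0, 99)})),
])
def test_invalid_configs_are_rejected(bad):
    with pytest.raises(ValueError):
        pc.CohortConfig(**bad).validate()


def test_corr_effect_realized_in_patient_group():
    """Monte-Carlo check of the generating covariance on one edge."""
    cfg = pc.CohortConfig(n_subjects=24, n_regions=6, n_timepoints=5000,
                          affected_edges=frozenset({(0, 3)}),
                          base_coupling=0.4, corr_effect=0.4,
                          artifact_rate=0.0, confound_amplitude=0.0, seed=9)
    recs = pc.generate_cohort(cfg)
    by_group = {"control": [], "chronic_pain": []}
    for r in recs:
        by_group[r.group].append(np.corrcoef(r.timeseries[0], r.timeseries[3])[0, 1])
    assert abs(np.mean(by_group["chronic_pain"]) - 0.8) < 0.05
    assert abs(np.mean(by_group["control"]) - 0.4) < 0.05


def test_sex_assignment_independent_of_effect_parameters():
    """Changing signal effects must not perturb the sex (or group) labels."""
    edges = frozenset({(0, 3)})
    base = pc.CohortConfig(n_subjects=40, n_regions=6, n_timepoints=60,
                           affected_edges=edges, seed=4)
    alt = pc.CohortConfig(n_subjects=40, n_regions=6, n_timepoints=60,
                          affected_edges=edges, corr_effect=0.5, seed=4)
    a = pc.generate_cohort(base)
    b = pc.generate_cohort(alt)
    assert [r.sex for r in a] == [r.sex for r in b]
    assert [r.group for r in a] == [r.group for r in b]


def test_null_cohort_permutation_pvalues_uniform():
    """With no planted effect, per-edge permutation p-values are ~U(0,1)."""
    from scipy.stats import kstest

    cfg = pc.CohortConfig(n_subjects=40, n_regions=10, n_timepoints=120,
                          affected_edges=frozenset(), corr_effect=0.0,
                          artifact_rate=0.0, seed=17)
    recs = pc.generate_cohort(cfg)
    fs = pc.cohort_features(recs, "correlation")
    y = fs.group_labels
    obs = fs.vectors[y == 1].mean(axis=0) - fs.vectors[y == 0].mean(axis=0)
    rng = np.random.default_rng(0)
    n_perm = 200
    exceed = np.zeros(fs.vectors.shape[1])
    for _ in range(n_perm):
        yp = rng.permutation(y)
        diff = fs.vectors[yp == 1].mean(axis=0) - fs.vectors[yp == 0].mean(axis=0)
        exceed += np.abs(diff) >= np.abs(obs)
    pvals = (exceed + 1) / (n_perm + 1)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_lag_only_groups_match_in_correlation():
    """The lag construction leaves instantaneous correlation group-matched."""
    edges = choose_disjoint_pairs(12, 5, seed=3)
    cfg = pc.CohortConfig(n_subjects=120, n_regions=12, n_timepoints=235,
                          affected_edges=edges, base_coupling=0.4,
                          corr_effect=0.0, lag_effect=5, artifact_rate=0.0,
                          seed=23)
    recs = pc.generate_cohort(cfg)
    fs = pc.cohort_features(recs, "correlation")
    y = fs.group_labels
    iu = list(zip(*np.triu_indices(12, 1)))
    aff = np.array([tuple(e) in {tuple(sorted(p)) for p in edges} for e in iu])
    gap = abs(fs.vectors[y == 1][:, aff].mean() - fs.vectors[y == 0][:, aff].mean())
    assert gap < 0.1  # z-scored units; planted lag is invisible to correlation


def test_artifact_flags_mark_spiked_volumes():
    cfg = pc.CohortConfig(n_subjects=10, n_regions=6, n_timepoints=200,
                          artifact_rate=0.05, seed=2)
    recs = pc.generate_cohort(cfg)
    flagged = [r for r in recs if r.artifact_flags]
    assert flagged, "expected some artifact volumes at rate 0.05"
    rec = flagged[0]
    t = next(iter(rec.artifact_flags))
    clean_scale = np.abs(np.delete(rec.timeseries, list(rec.artifact_flags), axis=1)).mean()
    assert np.abs(rec.timeseries[:, t]).mean() > 2 * clean_scale


class TestToyAtlas:
    def test_zero_overlap_is_one_hot_partition(self):
        atlas = pc.generate_toy_atlas(50, 7, overlap=0.0, seed=1)
        assert atlas.weights.shape == (50, 7)
        assert set(np.unique(atlas.weights)) == {0.0, 1.0}
        assert np.array_equal(atlas.weights.sum(axis=1), np.ones(50))
        assert (atlas.weights.sum(axis=0) >= 1).all()

    def test_39_regions_full_rank_any_seed(self):
        for seed in (0, 1, 2):
            atlas = pc.generate_toy_atlas(300, 39, overlap=0.25, seed=seed)
            assert atlas.n_regions == 39
            assert np.linalg.matrix_rank(atlas.weights) == 39

    def test_overlap_produces_multiregion_voxels(self):
        atlas = pc.generate_toy_atlas(200, 10, overlap=0.3, seed=5)
        per_voxel = (atlas.weights > 0).sum(axis=1)
        assert (per_voxel >= 2).any()
        assert (atlas.weights >= 0).all()
        # dominant home region per construction
        assert (atlas.weights.max(axis=1) == 1.0).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pc.generate_toy_atlas(5, 10, 0.0, 0)
        with pytest.raises(ValueError):
            pc.generate_toy_atlas(50, 10, 1.0, 0)


class TestVoxelVolume:
    def test_noiseless_volume_inverts_exactly(self, small_cohort):
        _, recs = small_cohort
        atlas = pc.generate_toy_atlas(120, 10, overlap=0.3, seed=2)
        vox = pc.generate_voxel_volume(recs[0], atlas, noise_sd=0.0, seed=0)
        rec = pc.extract_region_signals(vox, atlas)
        assert np.abs(rec - recs[0].timeseries).max() < 1e-8

    def test_one_hot_atlas_copies_region_series(self, small_cohort):
        _, recs = small_cohort
        atlas = pc.generate_toy_atlas(40, 10, overlap=0.0, seed=3)
        vox = pc.generate_voxel_volume(recs[0], atlas, noise_sd=0.0, seed=0)
        home = atlas.weights.argmax(axis=1)
        for v in range(0, 40, 7):
            assert np.allclose(vox[v], recs[0].timeseries[home[v]])

    def test_noisy_recovery_correlates(self, small_cohort):
        _, recs = small_cohort
        atlas = pc.generate_toy_atlas(2000, 10, overlap=0.3, seed=4)
        vox = pc.generate_voxel_volume(recs[0], atlas, noise_sd=1.0, seed=5)
        rec = pc.extract_region_signals(vox, atlas)
        for r in range(10):
            assert np.corrcoef(rec[r], recs[0].timeseries[r])[0, 1] > 0.95

    def test_dimension_mismatch_raises(self, small_cohort):
        _, recs = small_cohort
        atlas = pc.generate_toy_atlas(40, 7, overlap=0.0, seed=0)
        with pytest.raises(ValueError):
            pc.generate_voxel_volume(recs[0], atlas, 0.0, 0)


def test_nifti_roundtrip(tmp_path, small_cohort):
    import nibabel as nib

    from painconn.cohort import (atlas_to_nifti, nifti_to_voxel_series,
                                 voxel_series_to_nifti)

    _, recs = small_cohort
    atlas = pc.generate_toy_atlas(60, 10, overlap=0.2, seed=6)
    vox = pc.generate_voxel_volume(recs[0], atlas, noise_sd=0.1, seed=1)
    img = voxel_series_to_nifti(vox, (3, 4, 5))
    p = tmp_path / "func.nii"
    nib.save(img, p)
    back = nifti_to_voxel_series(nib.load(p))
    assert np.allclose(back, vox, atol=1e-4)  # float32 storage
    aimg = atlas_to_nifti(atlas, (3, 4, 5))
    assert aimg.shape == (3, 4, 5, 10)
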