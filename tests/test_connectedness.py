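import numpy as np
import pytest

from connmap.connectedness import connectedness_map, find_hotspots
from connmap.stats import fisher_z
from connmap.volumes import NetworkMask

from conftest import box_mask, make_run


def dense_connectedness_oracle(data_2d, include_self=False, z_before_average=False):
    """O(V^2) reference: full correlation matrix row means (off-diagonal)."""
    V = data_2d.shape[0]
    R = np.corrcoef(data_2d)
    out = np.empty(V)
    for v in range(V):
        row = R[v] if include_self else np.delete(R[v], v)
        if z_before_average:
            out[v] = np.arctanh(np.clip(row, -1 + 1e-7, 1 - 1e-7)).mean()
        else:
            out[v] = np.arctanh(np.clip(row.mean(), -1 + 1e-7, 1 - 1e-7))
    return out


class TestConnectednessMap:
    @pytest.mark.parametrize("include_self", [False, True])
    def test_matches_dense_oracle(self, rng, include_self):
        data = rng.standard_normal((4, 4, 3, 60))
        run = make_run(data)
        mask = box_mask(run.geometry, 0, 4, 0, 4, 0, 2)  # 32 voxels
        cmap = connectedness_map(run, mask, include_self=include_self)
        got = cmap.values[mask.indicator]
        flat = data[mask.indicator]
        expected = dense_connectedness_oracle(flat, include_self=include_self)
        assert np.allclose(got, expected, atol=1e-10)

    def test_z_before_average_matches_oracle(self, rng):
        data = rng.standard_normal((3, 3, 3, 50))
        run = make_run(data)
        mask = box_mask(run.geometry, 0, 3, 0, 3, 0, 3)
        cmap = connectedness_map(run, mask, z_before_average=True)
        expected = dense_connectedness_oracle(data[mask.indicator], z_before_average=True)
        assert np.allclose(cmap.values[mask.indicator], expected, atol=1e-9)

    def test_two_identical_voxels_clip_with_warning(self, rng):
        series = rng.standard_normal(40)
        data = np.zeros((2, 1, 1, 40))
        data[0, 0, 0] = series
        data[1, 0, 0] = series
        run = make_run(data)
        mask = box_mask(run.geometry, 0, 2, 0, 1, 0, 1)
        cmap = connectedness_map(run, mask)
        vals = cmap.values[mask.indicator]
        assert np.all(np.isfinite(vals))
        assert np.all(vals > 8.0)  # arctanh of the clipped r = 1

    def test_orthogonal_series_give_near_zero(self, rng):
        T = 400
        data = rng.standard_normal((3, 3, 1, T))
        run = make_run(data)
        mask = box_mask(run.geometry, 0, 3, 0, 3, 0, 1)
        cmap = connectedness_map(run, mask)
        assert np.all(np.abs(cmap.values[mask.indicator]) < 3.0 / np.sqrt(T))

    def test_invariant_to_per_voxel_affine_rescaling(self, rng):
        data = rng.standard_normal((3, 3, 2, 50))
        run = make_run(data)
        mask = box_mask(run.geometry, 0, 3, 0, 3, 0, 2)
        scales = rng.uniform(0.5, 4.0, size=(3, 3, 2, 1))
        offsets = rng.uniform(-10, 10, size=(3, 3, 2, 1))
        run2 = make_run(data * scales + offsets)
        a = connectedness_map(run, mask).values
        b = connectedness_map(run2, mask).values
        assert np.allclose(a[mask.indicator], b[mask.indicator], atol=1e-10)

    def test_censored_frames_excluded(self, rng):
        data = rng.standard_normal((2, 2, 1, 50))
        full = make_run(data.copy())
        mask = box_mask(full.geometry, 0, 2, 0, 2, 0, 1)
        censored_data = data.copy()
        censored_data[..., [0, 7]] = 0.0
        cens = make_run(censored_data, censored=(0, 7))
        manual = make_run(data[..., [i for i in range(50) if i not in (0, 7)]])
        a = connectedness_map(cens, mask).values
        b = connectedness_map(manual, mask).values
        assert np.allclose(a[mask.indicator], b[mask.indicator], atol=1e-12)

    def test_constant_voxel_excluded_with_warning(self, rng):
        data = rng.standard_normal((3, 1, 1, 40))
        data[1, 0, 0] = 5.0  # constant series
        run = make_run(data)
        mask = box_mask(run.geometry, 0, 3, 0, 1, 0, 1)
        with pytest.warns(UserWarning, match="constant"):
            cmap = connectedness_map(run, mask)
        vals = cmap.values
        assert np.isnan(vals[1, 0, 0])
        expected = fisher_z(np.corrcoef(data[0, 0, 0], data[2, 0, 0])[0, 1])
        assert vals[0, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_network_smaller_than_two_rejected(self, rng):
        run = make_run(rng.standard_normal((3, 3, 3, 30)))
        mask = box_mask(run.geometry, 0, 1, 0, 1, 0, 1)
        with pytest.raises(ValueError, match="2 voxels"):
            connectedness_map(run, mask)


class TestFindHotspots:
    def test_identical_conditions_give_no_hotspots(self, tiny_study):
        runs = tiny_study.condition_runs("sham")
        res = find_hotspots(runs, [r for r in runs], tiny_study.masks["net"], seed=1)
        assert len(res) == 0

    def test_swapping_conditions_flips_signs(self, tiny_study):
        mask = tiny_study.masks["net"]
        a = tiny_study.condition_runs("cTBS")
        b = tiny_study.condition_runs("sham")
        fwd = find_hotspots(a, b, mask, voxel_z=1.0, n_perm=20, seed=9)
        rev = find_hotspots(b, a, mask, voxel_z=1.0, n_perm=20, seed=9)
        fwd_sets = {(c.voxels, c.sign) for c in fwd}
        rev_sets = {(c.voxels, -c.sign) for c in rev}
        assert fwd_sets == rev_sets

    def test_records_carry_contrast_and_role(self, tiny_study):
        mask = tiny_study.masks["net"]
        res = find_hotspots(
            tiny_study.condition_runs("cTBS"),
            tiny_study.condition_runs("sham"),
            mask,
            voxel_z=0.5,
            n_perm=10,
            seed=2,
        )
        assert res.contrast == ("cTBS", "sham")
        for rec in res:
            assert rec.role == "hotspot"
            assert rec.contrast == ("cTBS", "sham")
            assert rec.volume_mm3 == pytest.approx(rec.size * 8.0)

    def test_subject_misalignment_rejected(self, tiny_study):
        a = tiny_study.condition_runs("cTBS")
        b = list(reversed(tiny_study.condition_runs("sham")))
        with pytest.raises(ValueError, match="aligned"):
            find_hotspots(a, b, tiny_study.masks["net"], seed=0)
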