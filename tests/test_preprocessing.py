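"""Midline estimation, reflection, and mirror imputation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from craniomorph.preprocessing import (MidlineEstimationError, MidlinePlane,
                                       estimate_midline,
                                       impute_missing_bilateral,
                                       reflect_configuration, reflect_points,
                                       subset_complete)
from craniomorph.io import AnnotatedDataset, SiteInfo
from craniomorph.superimposition import centroid_size
from craniomorph.synthetic import make_template_skull
from conftest import record_from, random_rotation


@pytest.fixture
def symmetric_record(neuro_template):
    return record_from(neuro_template, specimen_id="sym")


YZ_PLANE = MidlinePlane(point=np.zeros(3), normal=np.array([1.0, 0.0, 0.0]))


class TestReflect:
    def test_involution(self, symmetric_record, neuro_spec, rng):
        plane = MidlinePlane(rng.normal(size=3), rng.normal(size=3))
        once = reflect_configuration(symmetric_record, neuro_spec, plane)
        twice = reflect_configuration(once, neuro_spec, plane)
        assert np.allclose(twice.coords, symmetric_record.coords, atol=1e-12)

    def test_symmetric_configuration_is_fixed_point(self, symmetric_record, neuro_spec):
        out = reflect_configuration(symmetric_record, neuro_spec, YZ_PLANE)
        assert np.allclose(out.coords, symmetric_record.coords, atol=1e-12)

    def test_centroid_size_preserved(self, neuro_spec, rng):
        rec = record_from(rng.normal(size=(9, 3)) * 30)
        plane = MidlinePlane(rng.normal(size=3), rng.normal(size=3))
        out = reflect_configuration(rec, neuro_spec, plane)
        assert centroid_size(out.coords) == pytest.approx(
            centroid_size(rec.coords), abs=1e-12)


class TestEstimateMidline:
    def test_exactly_symmetric_template(self, symmetric_record, neuro_spec):
        plane = estimate_midline(symmetric_record, neuro_spec)
        assert abs(abs(plane.normal[0]) - 1.0) < 1e-9
        assert abs(plane.point @ np.array([1.0, 0, 0])) < 1e-9

    def test_equivariance_under_rigid_motion(self, neuro_template, neuro_spec, rng):
        # the fitted plane must be the transformed analytic plane
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        t = np.array([5.0, 2.0, 1.0])
        moved = neuro_template @ R.T + t
        plane = estimate_midline(record_from(moved), neuro_spec)
        expected_normal = R @ np.array([1.0, 0.0, 0.0])
        align = abs(plane.normal @ expected_normal)
        assert align == pytest.approx(1.0, abs=1e-9)
        # plane passes through the transformed midline
        assert abs((plane.point - t) @ expected_normal) < 1e-9

    def test_no_symmetry_information_raises(self, neuro_template, neuro_spec):
        present = np.ones(9, bool)
        present[list(neuro_spec.midline_indices)] = False
        for li, ri in neuro_spec.bilateral_pairs:
            present[li] = False  # delete all left-side landmarks
        rec = record_from(neuro_template, present)
        with pytest.raises(MidlineEstimationError):
            estimate_midline(rec, neuro_spec)


class TestImpute:
    def test_exact_recovery_on_symmetric_template(self, neuro_template, neuro_spec):
        li, ri = neuro_spec.bilateral_pairs[0]
        present = np.ones(9, bool)
        present[ri] = False
        rec = record_from(neuro_template, present)
        out, rep = impute_missing_bilateral(rec, neuro_spec)
        assert rep.n_imputed == 1 and not rep.excluded
        assert out.imputed[ri]
        assert np.allclose(out.coords[ri], neuro_template[ri], atol=1e-9)

    def test_more_than_three_missing_excluded_unchanged(self, cf_template, cf_spec):
        present = np.ones(37, bool)
        present[[10, 12, 14, 16]] = False  # four missing: not imputed
        rec = record_from(cf_template, present)
        out, rep = impute_missing_bilateral(rec, cf_spec)
        assert rep.excluded and rep.n_imputed == 0
        assert np.array_equal(out.present, present)

    @pytest.mark.parametrize("n_missing,excluded", [(0, False), (3, False), (4, True)])
    def test_exclusion_rule_boundary(self, cf_template, cf_spec, n_missing, excluded):
        present = np.ones(37, bool)
        present[1:1 + n_missing] = False
        _, rep = impute_missing_bilateral(record_from(cf_template, present), cf_spec)
        assert rep.excluded == excluded

    def test_missing_midline_and_missing_pairs_not_imputed(self, neuro_template, neuro_spec):
        present = np.ones(9, bool)
        present[neuro_spec.midline_indices[0]] = False
        li, ri = neuro_spec.bilateral_pairs[0]
        present[[li, ri]] = False
        rec = record_from(neuro_template, present)
        out, rep = impute_missing_bilateral(rec, neuro_spec)
        assert rep.n_imputed == 0 and rep.n_missing_after == 3

    def test_isometry_equivariance_zero_error(self, cf_template, cf_spec, rng):
        # symmetric template under rigid motion + scaling: recovery is exact
        R = random_rotation(rng)
        moved = 1.7 * cf_template @ R.T + rng.normal(size=3) * 50
        li, ri = cf_spec.bilateral_pairs[3]
        present = np.ones(37, bool)
        present[li] = False
        out, _ = impute_missing_bilateral(record_from(moved, present), cf_spec)
        assert np.allclose(out.coords[li], moved[li], atol=1e-9)

    def test_reimputation_fixed_point(self, cf_template, cf_spec):
        li, ri = cf_spec.bilateral_pairs[5]
        present = np.ones(37, bool)
        present[ri] = False
        out1, _ = impute_missing_bilateral(record_from(cf_template, present), cf_spec)
        # delete the imputed point again and re-impute
        pres2 = out1.present.copy()
        pres2[ri] = False
        out2, _ = impute_missing_bilateral(
            record_from(out1.coords, pres2), cf_spec)
        assert np.allclose(out1.coords[ri], out2.coords[ri], atol=1e-9)

    def test_noisy_imputation_rmse_close_to_known_plane_oracle(self, cf_template, cf_spec, rng):
        """Monte Carlo: estimated-midline imputation should perform within
        20% (RMSE) of an oracle that reflects through the true plane."""
        li, ri = cf_spec.bilateral_pairs[2]
        err_est, err_oracle = [], []
        for _ in range(500):
            noisy = cf_template + rng.normal(scale=0.5, size=cf_template.shape)
            present = np.ones(37, bool)
            present[li] = False
            rec = record_from(noisy, present)
            out, _ = impute_missing_bilateral(rec, cf_spec)
            err_est.append(np.linalg.norm(out.coords[li] - cf_template[li]))
            oracle_pt = reflect_points(noisy[ri], YZ_PLANE)
            err_oracle.append(np.linalg.norm(oracle_pt - cf_template[li]))
        rmse_est = np.sqrt(np.mean(np.square(err_est)))
        rmse_oracle = np.sqrt(np.mean(np.square(err_oracle)))
        assert rmse_est <= 1.2 * rmse_oracle


@settings(max_examples=30, derandomize=True)
@given(missing=st.sets(st.integers(min_value=0, max_value=36), max_size=8))
def test_excluded_iff_more_than_three_missing(missing):
    from craniomorph.landmark_sets import default_set
    spec = default_set("craniofacial")
    template = make_template_skull(spec)
    present = np.ones(37, bool)
    present[list(missing)] = False
    if not present.any():
        return
    _, rep = impute_missing_bilateral(record_from(template, present), spec)
    assert rep.excluded == (len(missing) >= 4)


class TestSubsetComplete:
    def _dataset(self, cf_spec, cf_template, masks):
        sites = [SiteInfo("Yoshigo", "CCH")]
        recs = [record_from(cf_template, m, f"s{i}", site="Yoshigo")
                for i, m in enumerate(masks)]
        return AnnotatedDataset(cf_spec, recs, sites)

    def test_incomplete_specimens_dropped(self, cf_spec, cf_template):
        from craniomorph.landmark_sets import default_set
        facial = default_set("facial")
        pos = facial.positions_in(cf_spec)
        masks = [np.ones(37, bool) for _ in range(10)]
        for i in range(3):
            masks[i] = masks[i].copy()
            masks[i][pos[0]] = False
        ds = self._dataset(cf_spec, cf_template, masks)
        out = subset_complete(ds, facial)
        assert len(out.specimens) == 7

    def test_projection_matches_parent_rows(self, cf_spec, cf_template):
        from craniomorph.landmark_sets import default_set
        facial = default_set("facial")
        ds = self._dataset(cf_spec, cf_template, [np.ones(37, bool)])
        out = subset_complete(ds, facial)
        pos = list(facial.positions_in(cf_spec))
        assert np.array_equal(out.specimens[0].coords, cf_template[pos])

    def test_complete_dataset_identity_membership(self, cf_spec, cf_template):
        ds = self._dataset(cf_spec, cf_template, [np.ones(37, bool)] * 4)
        out = subset_complete(ds, cf_spec)
        assert [r.specimen_id for r in out.specimens] == \
               [r.specimen_id for r in ds.specimens]

    def test_empty_result_warns(self, cf_spec, cf_template):
        from craniomorph.landmark_sets import default_set
        facial = default_set("facial")
        mask = np.ones(37, bool)
        mask[facial.positions_in(cf_spec)[0]] = False
        ds = self._dataset(cf_spec, cf_template, [mask])
        with pytest.warns(UserWarning, match="complete"):
            out = subset_complete(ds, facial)
        assert not out.specimens
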