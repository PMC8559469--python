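"""Masking core: shell, influence, intensity distribution, fill rules."""

import numpy as np
import pytest
import trimesh
from scipy import ndimage
from scipy.stats import ks_2samp

from geodeface import (
    ControlPoint,
    ControlPointSet,
    TriMesh,
    VolumeGrid,
    anonymize,
    apply_influence,
    build_shell,
    deface,
    fit_distribution,
)
from geodeface.errors import GeometryError, ValidationError


def _sphere_mesh(radius):
    m = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    return TriMesh(m.vertices, m.faces, "sphere")


@pytest.fixture(scope="module")
def sphere_grid():
    aff = np.eye(4)
    aff[:3, 3] = -49.5
    v = VolumeGrid(np.zeros((100, 100, 100), dtype=np.float32), aff)
    return v


class TestBuildShell:
    def test_concentric_sphere_shell_closed_form(self, sphere_grid):
        shell = build_shell(sphere_grid, _sphere_mesh(40), _sphere_mesh(30))
        analytic = 4 / 3 * np.pi * (40**3 - 30**3)
        assert shell.shell.sum() == pytest.approx(analytic, rel=0.03)

    def test_identical_meshes_are_degenerate(self, sphere_grid):
        with pytest.raises(GeometryError):
            build_shell(sphere_grid, _sphere_mesh(30), _sphere_mesh(30))

    def test_non_nested_meshes_rejected(self, sphere_grid):
        outside = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
        outside.apply_translation([35.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="nested"):
            build_shell(
                sphere_grid,
                _sphere_mesh(30),
                TriMesh(outside.vertices, outside.faces, "skull"),
            )

    def test_phantom_shell_excludes_brain(self, quick_anonymized, quick_phantom):
        _, truth = quick_phantom
        _, report = quick_anonymized
        shell = report.artifacts["shell"]
        assert not np.any(shell.shell & truth.mask("brain"))


class TestApplyInfluence:
    def test_single_nose_point_covers_nose_feature(
        self, quick_phantom, quick_anonymized
    ):
        v, truth = quick_phantom
        _, report = quick_anonymized
        shell = report.artifacts["shell"]
        nose_tip = truth.landmarks.by_label("face")[0]
        one = apply_influence(
            shell, ControlPointSet([nose_tip], "subject")
        )
        nose_in_shell = truth.feature_masks["nose"] & shell.shell
        covered = np.mean(one.active[nose_in_shell])
        assert covered >= 0.95

    def test_vanishing_radius_empties_the_mask(self, quick_anonymized):
        _, report = quick_anonymized
        shell = report.artifacts["shell"]
        cps = report.artifacts["control_points"]
        tiny = ControlPointSet(
            [ControlPoint(p.label, p.position, 1e-6) for p in cps.points],
            "subject",
        )
        with pytest.warns(UserWarning, match="0 active"):
            out = apply_influence(shell, tiny)
        assert out.active.sum() == 0

    def test_two_ear_points_give_two_components(
        self, quick_phantom, quick_anonymized
    ):
        _, truth = quick_phantom
        _, report = quick_anonymized
        shell = report.artifacts["shell"]
        ears = ControlPointSet(
            truth.landmarks.by_label("ear_L")
            + truth.landmarks.by_label("ear_R"),
            "subject",
        )
        out = apply_influence(shell, ears)
        _, n = ndimage.label(out.active, structure=np.ones((3, 3, 3), bool))
        assert n == 2


class TestIntensityDistribution:
    def test_constant_shell_samples_constant(self, sphere_grid):
        v = VolumeGrid(
            np.full(sphere_grid.shape, 42.0, dtype=np.float32),
            sphere_grid.affine,
        )
        shell = build_shell(v, _sphere_mesh(40), _sphere_mesh(30))
        dist = fit_distribution(v, shell)
        rng = np.random.default_rng(0)
        assert np.all(dist.sample(1000, rng) == 42.0)

    def test_pool_mean_matches_label_weighted_mixture(
        self, quick_phantom, quick_anonymized
    ):
        v, truth = quick_phantom
        _, report = quick_anonymized
        dist = report.artifacts["distribution"]
        shell = report.artifacts["shell"].shell
        labels = truth.compartment_labels[shell]
        from geodeface.phantom import DEFAULT_TISSUE_MEANS, LABEL_NAMES

        mix = np.mean(
            [DEFAULT_TISSUE_MEANS[LABEL_NAMES[c]] for c in labels]
        )
        n = len(dist.sample_pool)
        assert dist.summary["mean"] == pytest.approx(
            mix, abs=2 * dist.summary["sd"] / np.sqrt(n) + 0.5
        )

    def test_fresh_draws_match_pool_distribution(self, quick_anonymized):
        _, report = quick_anonymized
        dist = report.artifacts["distribution"]
        rng = np.random.default_rng(1)
        draws = dist.sample(10_000, rng)
        assert ks_2samp(draws, dist.sample_pool).statistic < 0.05


class TestDeface:
    def test_fill_and_zero_rules(self, quick_phantom, quick_anonymized):
        v, truth = quick_phantom
        out, report = quick_anonymized
        shell = report.artifacts["shell"]
        # rule (ii): strictly outside the skin model -> exact zero
        assert not np.any(out.data[~shell.inside_skin])
        # rule (iii): untouched voxels bitwise equal
        untouched = shell.inside_skin & ~shell.active
        assert np.array_equal(out.data[untouched], v.data[untouched])
        # brain strictly preserved
        brain = truth.mask("brain")
        assert np.array_equal(out.data[brain], v.data[brain])

    def test_active_values_follow_shell_distribution(self, quick_anonymized):
        out, report = quick_anonymized
        shell = report.artifacts["shell"]
        dist = report.artifacts["distribution"]
        vals = out.data[shell.active]
        rng = np.random.default_rng(2)
        sub = vals[rng.integers(0, len(vals), 10_000)]
        assert ks_2samp(sub, dist.sample_pool).statistic < 0.05

    def test_deterministic_under_seed(self, quick_phantom):
        v, truth = quick_phantom
        a, _ = anonymize(v, truth.landmarks, seed=5)
        b, _ = anonymize(v, truth.landmarks, seed=5)
        c, _ = anonymize(v, truth.landmarks, seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_grid_mismatch_rejected(self, quick_anonymized, sphere_grid):
        _, report = quick_anonymized
        shell = report.artifacts["shell"]
        dist = report.artifacts["distribution"]
        with pytest.raises(GeometryError, match="grid"):
            deface(sphere_grid, shell, dist, report.artifacts["skin"], seed=0)

    def test_reanonymization_keeps_brain_bitwise(self, quick_phantom,
                                                 quick_anonymized):
        v, truth = quick_phantom
        out, _ = quick_anonymized
        again, _ = anonymize(out, truth.landmarks, seed=3)
        brain = truth.mask("brain")
        assert np.array_equal(again.data[brain], v.data[brain])


class TestAnonymize:
    def test_nose_voxels_replaced_and_report_complete(
        self, quick_phantom, quick_anonymized
    ):
        v, truth = quick_phantom
        out, report = quick_anonymized
        changed = out.data != v.data
        feat = np.zeros(v.shape, bool)
        for m in truth.feature_masks.values():
            feat |= m
        assert np.mean(changed[feat]) >= 0.95
        assert report.counts["active_voxels"] > 0
        assert report.seed == 3
        assert len(report.landmarks) == len(truth.landmarks.points)
        assert "segment" in report.timings_s

    def test_manual_points_must_be_subject_space(self, quick_phantom):
        v, truth = quick_phantom
        cps = ControlPointSet(truth.landmarks.points, "template")
        with pytest.raises(ValidationError):
            anonymize(v, cps, seed=0)

    def test_qa_report_serializes(self, quick_anonymized, tmp_path):
        _, report = quick_anonymized
        text = report.to_json(tmp_path / "qa.json")
        import json

        doc = json.loads(text)
        assert doc["seed"] == 3
        assert doc["params"]["zero_exterior"] == "global"
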