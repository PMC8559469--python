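"""Evaluation battery: Jaccard, Hausdorff, usability, pair comparison."""

import numpy as np
import pytest
import trimesh

from geodeface import TriMesh, hausdorff, jaccard, screen_usability
from geodeface.errors import GeometryError
from geodeface.metrics import (
    cochran_q,
    compare_pair,
    holm_bonferroni,
    mcnemar,
    pairwise_wilcoxon,
)


def _jaccard_oracle(a, b):
    inter = union = 0
    for x, y in zip(a.reshape(-1), b.reshape(-1)):
        if x and y:
            inter += 1
        if x or y:
            union += 1
    return 1.0 if union == 0 else inter / union


class TestJaccard:
    def test_matches_counting_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(0.2, 0.8)
            a = rng.random((8, 8, 8)) < p
            b = rng.random((8, 8, 8)) < p
            assert jaccard(a, b) == pytest.approx(_jaccard_oracle(a, b), abs=0)
            assert jaccard(a, b) == jaccard(b, a)

    def test_shifted_cube_is_exactly_half(self):
        a = np.zeros((8, 8, 8), bool)
        a[2:5, 2:5, 2:5] = True
        b = np.roll(a, 1, axis=0)
        assert jaccard(a, b) == 18 / 36

    def test_edge_conventions(self):
        a = np.zeros((4, 4, 4), bool)
        assert jaccard(a, a) == 1.0  # both empty: identical by convention
        a[0, 0, 0] = True
        b = np.zeros((4, 4, 4), bool)
        b[3, 3, 3] = True
        assert jaccard(a, b) == 0.0
        assert jaccard(a, a) == 1.0
        with pytest.raises(GeometryError):
            jaccard(a, np.zeros((3, 3, 3), bool))


def _sphere(radius, subdivisions=4):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(m.vertices, m.faces, "sphere")


def _patch(z):
    verts = np.array(
        [[0, 0, z], [1, 0, z], [1, 1, z], [0, 1, z]], dtype=float
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriMesh(verts, faces, "patch")


class TestHausdorff:
    def test_identical_mesh_distance_zero(self):
        s = _sphere(20)
        h = hausdorff(s, s, n_samples=500)
        assert h.symmetric == pytest.approx(0.0, abs=1e-12)

    def test_parallel_patches_closed_form(self):
        h = hausdorff(_patch(0.0), _patch(3.0), n_samples=2000)
        assert h.directed_12 == pytest.approx(3.0, abs=1e-9)
        assert h.directed_21 == pytest.approx(3.0, abs=1e-9)
        assert h.symmetric == 3.0

    def test_concentric_spheres_closed_form(self):
        h = hausdorff(_sphere(30), _sphere(40), n_samples=5000)
        # icosphere facets dip slightly inside the ideal sphere
        assert h.symmetric == pytest.approx(10.0, abs=0.2)
        assert h.symmetric == max(h.directed_12, h.directed_21)

    def test_more_samples_never_decrease_the_distance(self):
        m1 = _sphere(30, subdivisions=2)
        m2 = _sphere(40, subdivisions=3)
        coarse = hausdorff(m1, m2, n_samples=0)  # vertices only
        fine = hausdorff(m1, m2, n_samples=8000)
        assert fine.symmetric >= coarse.symmetric

    def test_triangle_inequality_spot_check(self):
        meshes = [_sphere(r, subdivisions=3) for r in (20, 28, 37)]
        h01 = hausdorff(meshes[0], meshes[1], 2000).symmetric
        h12 = hausdorff(meshes[1], meshes[2], 2000).symmetric
        h02 = hausdorff(meshes[0], meshes[2], 2000).symmetric
        assert h02 <= h01 + h12 + 0.05

    def test_point_filter_restricts_the_maximum(self):
        # two spheres differing only near the north pole
        base = _sphere(30, subdivisions=3)
        bumped = trimesh.creation.icosphere(subdivisions=3, radius=30.0)
        top = bumped.vertices[:, 2] > 25
        bumped.vertices[top] *= 1.2
        bm = TriMesh(bumped.vertices, bumped.faces, "bumped")
        full = hausdorff(base, bm, 3000).symmetric
        south = hausdorff(
            base, bm, 3000, point_filter=lambda p: p[:, 2] < 0
        ).symmetric
        assert full > 3.0
        assert south < 0.5

    def test_empty_mesh_rejected(self):
        with pytest.raises(GeometryError):
            hausdorff(
                TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)),
                _sphere(10),
            )


class TestUsability:
    def test_clean_truth_surface_is_usable(self, quick_phantom):
        _, truth = quick_phantom
        skin = truth.surfaces["skin"]
        status, reasons = screen_usability(skin, expected_volume=skin.volume)
        assert status == "usable"
        assert reasons == []

    def test_randomly_displaced_vertices_flag_distorted(self, quick_phantom):
        _, truth = quick_phantom
        skin = truth.surfaces["skin"]
        rng = np.random.default_rng(0)
        verts = skin.vertices.copy()
        pick = rng.random(len(verts)) < 0.3
        verts[pick] += rng.normal(scale=10.0 / np.sqrt(3), size=(pick.sum(), 3))
        crumpled = TriMesh(verts, skin.faces, "skin")
        status, reasons = screen_usability(
            crumpled, expected_volume=skin.volume
        )
        assert status == "distorted"
        assert reasons

    def test_missing_mesh_is_failed(self):
        status, reasons = screen_usability(None)
        assert status == "failed"

    def test_handles_flag_distorted(self):
        t = trimesh.creation.torus(major_radius=20, minor_radius=5)
        status, reasons = screen_usability(TriMesh(t.vertices, t.faces))
        assert status == "distorted"
        assert any("genus" in r for r in reasons)

    def test_volume_out_of_range_flagged(self):
        s = _sphere(20)
        status, reasons = screen_usability(s, expected_volume=s.volume * 2)
        assert status == "distorted"
        assert any("volume" in r for r in reasons)


def test_compare_pair_self_is_neutral(quick_phantom):
    v, _ = quick_phantom
    report = compare_pair(v, v, n_samples=1500)
    assert report.jaccard == 1.0
    for label, entry in report.usability.items():
        assert entry["status"] == "usable", (label, entry)
    for label, h in report.hausdorff_per_surface.items():
        assert h["symmetric"] == pytest.approx(0.0, abs=1e-12)
    assert "Jaccard" in report.summary()


class TestStatsUtilities:
    def test_holm_bonferroni_known_case(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_pairwise_wilcoxon_tidy(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        for s in range(12):
            base = rng.normal()
            rows += [
                {"subject": s, "method": "a", "value": base},
                {"subject": s, "method": "b", "value": base + 1.0},
            ]
        res = pairwise_wilcoxon(pd.DataFrame(rows), "value", "method", "subject")
        assert len(res) == 1
        assert res[0]["p_value"] < 0.01
        assert res[0]["p_adjusted"] >= res[0]["p_value"]

    def test_cochran_and_mcnemar_detect_asymmetry(self):
        rng = np.random.default_rng(0)
        a = np.ones(40, bool)
        b = rng.random(40) < 0.4
        q, pq = cochran_q(np.column_stack([a, b]).astype(float))
        stat, pm = mcnemar(a, b)
        assert pq < 0.01 and pm < 0.01
        assert mcnemar(a, a) == (0.0, 1.0)
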