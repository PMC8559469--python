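"""Control points: file formats, templates, registration, transfer."""

import json

import numpy as np
import pytest

from geodeface import (
    ControlPoint,
    ControlPointSet,
    VolumeGrid,
    read_points,
    register,
    transfer_points,
    write_points,
)
from geodeface.errors import ConvergenceError, ValidationError
from geodeface.landmarks import (
    SpatialTransform,
    load_template,
    make_template,
)


@pytest.fixture
def seven_points():
    pts = [
        ControlPoint("face", (0.0, 84.0, -8.0), 25.0),
        ControlPoint("face", (-20.0, 70.0, 10.0), 25.0),
        ControlPoint("face", (20.0, 70.0, 10.0), 25.0),
        ControlPoint("face", (0.0, 75.0, -35.0), 22.5),
        ControlPoint("face", (0.0, 70.0, 30.0), 25.0),
        ControlPoint("ear_L", (-80.0, -5.0, 0.0), 20.0),
        ControlPoint("ear_R", (80.0, -5.0, 0.0), 20.0),
    ]
    return ControlPointSet(pts, "subject")


class TestPointFiles:
    @pytest.mark.parametrize("ext", ["fcsv", "json"])
    def test_round_trip_identity(self, seven_points, tmp_path, ext):
        p = tmp_path / f"pts.{ext}"
        write_points(seven_points, p)
        back = read_points(p, space="subject")
        assert [q.label for q in back.points] == [
            q.label for q in seven_points.points
        ]
        assert np.allclose(back.positions(), seven_points.positions())
        assert [q.radius for q in back.points] == [
            q.radius for q in seven_points.points
        ]

    def test_fcsv_lps_positions_convert_to_ras(self, tmp_path):
        lines = [
            "# Markups fiducial file version = 4.11",
            "# CoordinateSystem = LPS",
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,assoc",
        ]
        for i, (x, y, z, label) in enumerate(
            [(10, 20, 30, "face"), (11, 21, 31, "face"), (12, 22, 32, "face"),
             (60, 0, 0, "ear_L"), (-60, 0, 0, "ear_R")]
        ):
            lines.append(f"F_{i},{x},{y},{z},0,0,0,1,1,1,0,{label},,")
        p = tmp_path / "pts.fcsv"
        p.write_text("\n".join(lines))
        cps = read_points(p)
        assert np.allclose(cps.points[0].position, [-10, -20, 30])

    def test_missing_coordinate_system_assumes_lps_with_warning(self, tmp_path):
        lines = ["# Markups fiducial file version = 4.11"]
        for i in range(3):
            lines.append(f"F_{i},1,2,3,0,0,0,1,1,1,0,face,,")
        lines.append("E,5,0,0,0,0,0,1,1,1,0,ear_L,,")
        lines.append("E2,-5,0,0,0,0,0,1,1,1,0,ear_R,,")
        p = tmp_path / "pts.fcsv"
        p.write_text("\n".join(lines))
        with pytest.warns(UserWarning, match="LPS"):
            cps = read_points(p)
        assert np.allclose(cps.points[0].position, [-1, -2, 3])

    def test_incomplete_point_set_rejected(self, tmp_path):
        lines = [
            "# CoordinateSystem = LPS",
            "A,1,2,3,0,0,0,1,1,1,0,ear_L,,",
            "B,4,5,6,0,0,0,1,1,1,0,ear_R,,",
        ]
        p = tmp_path / "noface.fcsv"
        p.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="face"):
            read_points(p)

    def test_unknown_label_lists_allowed(self, tmp_path):
        p = tmp_path / "bad.fcsv"
        p.write_text(
            "# CoordinateSystem = LPS\nA,1,2,3,0,0,0,1,1,1,0,nostril,,\n"
        )
        with pytest.raises(ValidationError, match="ear_L"):
            read_points(p)

    def test_json_declares_coordinate_convention(self, seven_points, tmp_path):
        p = tmp_path / "pts.json"
        write_points(seven_points, p)
        doc = json.loads(p.read_text())
        assert doc["coordinate_system"] == "RAS"


class TestTemplateBundle:
    def _volume(self):
        rng = np.random.default_rng(0)
        aff = np.diag([4.0, 4.0, 4.0, 1.0])
        aff[:3, 3] = -94.0
        return VolumeGrid(rng.normal(size=(48, 48, 48)).astype(np.float32), aff)

    def test_bundle_round_trip(self, seven_points, tmp_path):
        make_template(self._volume(), seven_points, tmp_path / "tpl",
                      name="phantom-template")
        bundle = load_template(tmp_path / "tpl")
        assert bundle.name == "phantom-template"
        assert bundle.control_points.space == "template"
        assert len(bundle.control_points) == 7

    def test_checksum_tamper_detected(self, seven_points, tmp_path):
        make_template(self._volume(), seven_points, tmp_path / "tpl")
        pts = tmp_path / "tpl" / "points.fcsv"
        pts.write_text(pts.read_text().replace("84", "48"))
        with pytest.raises(ValidationError, match="checksum"):
            load_template(tmp_path / "tpl")

    def test_out_of_fov_point_rejected(self, seven_points, tmp_path):
        pts = seven_points.points + [
            ControlPoint("face", (500.0, 0.0, 0.0), 25.0)
        ]
        with pytest.raises(ValidationError, match="field of view"):
            make_template(
                self._volume(), ControlPointSet(pts, "subject"),
                tmp_path / "tpl",
            )


class TestTransfer:
    def test_points_on_skin_are_fixed_under_identity(self, quick_phantom):
        _, truth = quick_phantom
        cps = ControlPointSet(truth.landmarks.points, "template")
        out = transfer_points(
            cps, SpatialTransform(np.eye(4)), truth.surfaces["skin"]
        )
        assert out.space == "subject"
        resid = np.linalg.norm(
            out.positions() - truth.landmarks.positions(), axis=1
        )
        assert resid.max() < 0.5

    def test_normal_perturbation_projects_back(self, quick_phantom):
        _, truth = quick_phantom
        skin = truth.surfaces["skin"]
        pts = []
        for p in truth.landmarks.points:
            n = p.position / np.linalg.norm(p.position)
            pts.append(ControlPoint(p.label, p.position + 3.0 * n, p.radius))
        out = transfer_points(
            ControlPointSet(pts, "template"), SpatialTransform(np.eye(4)), skin
        )
        d, _ = skin.distance_query().query(out.positions())
        assert d.max() < 1e-6  # exactly on the surface
        # projection pulled each point back near its origin
        resid = np.linalg.norm(
            out.positions() - truth.landmarks.positions(), axis=1
        )
        assert resid.max() < 3.5

    def test_unreliable_transfer_recommends_manual_points(self, quick_phantom):
        _, truth = quick_phantom
        t = SpatialTransform(np.eye(4))
        t.affine_part = t.affine_part.copy()
        t.affine_part[:3, 3] = [500.0, 500.0, 500.0]
        with pytest.raises(ConvergenceError, match="manual"):
            transfer_points(
                ControlPointSet(truth.landmarks.points, "template"),
                t,
                truth.surfaces["skin"],
            )


class TestRegistration:
    def test_self_registration_is_identity(self, quick_phantom):
        v, truth = quick_phantom
        t = register(v, v)
        pts = truth.landmarks.positions()
        moved = t.apply(pts)
        assert np.abs(moved - pts).max() < v.voxel_size.max()

    def test_known_translation_recovered(self, quick_phantom):
        v, truth = quick_phantom
        aff = v.affine.copy()
        aff[:3, 3] += [10.0, -5.0, 3.0]
        shifted = VolumeGrid(v.data, aff)
        t = register(shifted, v)  # template=v, subject=shifted
        pts = truth.landmarks.positions()
        recovered = (t.apply(pts) - pts).mean(axis=0)
        assert np.abs(recovered - [10.0, -5.0, 3.0]).max() < 1.0

    def test_unknown_mode_rejected(self, quick_phantom):
        v, _ = quick_phantom
        with pytest.raises(ValidationError):
            register(v, v, mode="deformable-spline")
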