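"""Face/ear control points: file formats, templates, registration, transfer.

Control points are labeled world-mm landmarks (``face``, ``ear_L``,
``ear_R``) with a per-point influence radius. They arrive either manually
(3D Slicer markups FCSV or a JSON schema) or automatically, by registering
the subject's MRI to a template volume on which the points were marked
once and mapping them across. After mapping, every point is projected to
the nearest point of the subject's extracted skin surface, so the mask is
anchored to the subject's actual anatomy no matter how good or bad the
registration was — registration error only moves points tangentially
along the skin.

Registration itself is delegated to SimpleITK (multi-resolution
intensity-based affine with a correlation metric, principal-moments
initialization, optional diffeomorphic-demons refinement). SimpleITK works
in LPS coordinates; this module converts at the boundary so everything the
package sees is RAS.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import ConvergenceError, ValidationError, VolumeIOError
from .surfaces import TriMesh
from .volume_io import VolumeGrid, read_volume, write_volume

__all__ = [
    "ControlPoint",
    "ControlPointSet",
    "TemplateBundle",
    "SpatialTransform",
    "read_points",
    "write_points",
    "register",
    "transfer_points",
    "make_template",
    "load_template",
]

ALLOWED_LABELS = ("face", "ear_L", "ear_R")
DEFAULT_RADII = {"face": 25.0, "ear_L": 20.0, "ear_R": 20.0}

_LPS_FLIP = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class ControlPoint:
    label: str
    position: np.ndarray
    radius: float

    def __post_init__(self):
        if self.label not in ALLOWED_LABELS:
            raise ValidationError(
                f"unknown control-point label {self.label!r}; "
                f"allowed: {', '.join(ALLOWED_LABELS)}"
            )
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"non-finite position for {self.label}")
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValidationError(f"non-positive radius for {self.label}")


@dataclass
class ControlPointSet:
    """Labeled landmark set in either template or subject space."""

    points: list[ControlPoint]
    space: str = "subject"  # template | subject

    def __post_init__(self):
        if self.space not in ("template", "subject"):
            raise ValidationError(f"unknown space {self.space!r}")

    def __len__(self):
        return len(self.points)

    def by_label(self, label: str) -> list[ControlPoint]:
        return [p for p in self.points if p.label == label]

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=np.float64)

    def validate_complete(self) -> None:
        """A usable set needs >= 3 face points and >= 1 per ear."""
        n_face = len(self.by_label("face"))
        if n_face < 3:
            raise ValidationError(f"need >= 3 face points, got {n_face}")
        for ear in ("ear_L", "ear_R"):
            if not self.by_label(ear):
                raise ValidationError(f"missing {ear} control point")

    def with_radii(self, face: float | None = None,
                   ear: float | None = None) -> "ControlPointSet":
        pts = []
        for p in self.points:
            r = p.radius
            if p.label == "face" and face is not None:
                r = face
            if p.label.startswith("ear") and ear is not None:
                r = ear
            pts.append(ControlPoint(p.label, p.position.copy(), r))
        return ControlPointSet(pts, self.space)


# ---------------------------------------------------------------------------
# point file I/O


def _parse_fcsv_radius(description: str, label: str) -> float:
    for token in description.replace(";", ",").split(","):
        token = token.strip()
        if token.startswith("radius="):
            try:
                return float(token.split("=", 1)[1])
            except ValueError:
                pass
    return DEFAULT_RADII[label]


def read_points(path, space: str = "subject") -> ControlPointSet:
    """Read control points from Slicer markups FCSV or package JSON.

    FCSV positions are interpreted per the file's ``# CoordinateSystem``
    header (``LPS``/``1`` or ``RAS``/``0``) and converted to RAS; a missing
    declaration assumes LPS — Slicer's default — with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"points file not found: {path}")
    if path.suffix.lower() == ".json":
        return _read_points_json(path, space)
    return _read_points_fcsv(path, space)


def _read_points_fcsv(path: Path, space: str) -> ControlPointSet:
    coordinate_system = None
    rows = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line:
                    coordinate_system = line.split("=")[-1].strip()
                continue
            rows.append(next(csv.reader([line])))
    if coordinate_system is None:
        warnings.warn(
            f"{path}: no CoordinateSystem header; assuming LPS (Slicer default)",
            stacklevel=2,
        )
        coordinate_system = "LPS"
    lps = coordinate_system.upper() in ("LPS", "1")

    points = []
    for row in rows:
        if len(row) < 4:
            raise ValidationError(f"{path}: malformed FCSV row {row!r}")
        try:
            pos = np.array([float(row[1]), float(row[2]), float(row[3])])
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric position in {row!r}") from exc
        if lps:
            pos[0] = -pos[0]
            pos[1] = -pos[1]
        label = row[11].strip() if len(row) > 11 else "face"
        desc = row[12] if len(row) > 12 else ""
        if label not in ALLOWED_LABELS:
            raise ValidationError(
                f"{path}: unknown label {label!r}; allowed: "
                f"{', '.join(ALLOWED_LABELS)}"
            )
        points.append(ControlPoint(label, pos, _parse_fcsv_radius(desc, label)))
    cps = ControlPointSet(points, space)
    cps.validate_complete()
    return cps


def _read_points_json(path: Path, space: str) -> ControlPointSet:
    with open(path) as fh:
        doc = json.load(fh)
    coords = doc.get("coordinate_system", "RAS").upper()
    points = []
    for entry in doc["points"]:
        pos = np.asarray(entry["position"], dtype=np.float64)
        if coords == "LPS":
            pos = pos * np.array([-1.0, -1.0, 1.0])
        elif coords != "RAS":
            raise ValidationError(f"{path}: unknown coordinate_system {coords!r}")
        points.append(
            ControlPoint(
                entry["label"], pos,
                float(entry.get("radius", DEFAULT_RADII.get(entry["label"], 25.0))),
            )
        )
    cps = ControlPointSet(points, doc.get("space", space))
    cps.validate_complete()
    return cps


def write_points(cps: ControlPointSet, path) -> None:
    """Write FCSV (LPS, Slicer dialect) or JSON (RAS) by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "coordinate_system": "RAS",
            "space": cps.space,
            "points": [
                {
                    "label": p.label,
                    "position": p.position.tolist(),
                    "radius": p.radius,
                }
                for p in cps.points
            ],
        }
        path.write_text(json.dumps(doc, indent=2))
        return
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = LPS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, p in enumerate(cps.points):
        x, y, z = -p.position[0], -p.position[1], p.position[2]
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{x:.6f},{y:.6f},{z:.6f},"
            f"0,0,0,1,1,1,0,{p.label},radius={p.radius:g},"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# registration


@dataclass
class SpatialTransform:
    """Maps template-space RAS points to subject-space RAS points."""

    affine_part: np.ndarray
    displacement: np.ndarray | None = None  # (nx,ny,nz,3) mm on template grid
    displacement_affine: np.ndarray | None = None
    metric_history: list = field(default_factory=list)

    def __post_init__(self):
        self.affine_part = np.asarray(self.affine_part, dtype=np.float64)
        if abs(np.linalg.det(self.affine_part[:3, :3])) < 1e-12:
            raise ValidationError("transform affine is singular")
        if self.displacement is not None and not np.all(
            np.isfinite(self.displacement)
        ):
            raise ValidationError("displacement field contains non-finite values")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if self.displacement is not None:
            from scipy.ndimage import map_coordinates

            inv = np.linalg.inv(self.displacement_affine)
            idx = (pts @ inv[:3, :3].T + inv[:3, 3]).T
            disp = np.stack(
                [
                    map_coordinates(self.displacement[..., k], idx, order=1,
                                    mode="nearest")
                    for k in range(3)
                ],
                axis=1,
            )
            pts = pts + disp
        return pts @ self.affine_part[:3, :3].T + self.affine_part[:3, 3]


def _to_sitk(v: VolumeGrid) -> sitk.Image:
    """VolumeGrid (RAS affine) -> SimpleITK image (LPS geometry)."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(v.data.astype(np.float32), (2, 1, 0)))
    )
    lps = _LPS_FLIP @ v.affine
    spacing = np.linalg.norm(lps[:3, :3], axis=0)
    direction = lps[:3, :3] / spacing
    img.SetSpacing(tuple(spacing))
    img.SetDirection(tuple(direction.ravel()))
    img.SetOrigin(tuple(lps[:3, 3]))
    return img


def _affine_to_ras_matrix(tx: sitk.AffineTransform) -> np.ndarray:
    a = np.asarray(tx.GetMatrix(), dtype=np.float64).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=np.float64)
    t = np.asarray(tx.GetTranslation(), dtype=np.float64)
    m = np.eye(4)
    m[:3, :3] = a
    m[:3, 3] = c + t - a @ c
    return _LPS_FLIP @ m @ _LPS_FLIP


def register(
    subject: VolumeGrid,
    template: VolumeGrid,
    mode: str = "affine",
    sampling_fraction: float = 0.2,
    seed: int = 12345,
) -> SpatialTransform:
    """Estimate the template -> subject spatial mapping.

    ``mode`` is ``"affine"`` or ``"affine+demons"``. The affine stage is a
    three-level multi-resolution optimization of a correlation metric,
    initialized by image moments; demons refinement adds a dense
    displacement field on the template grid. The per-level metric history
    is kept on the returned transform for QA; a non-improving metric
    raises a warning, not an error (the best-effort transform is still
    returned, and the skin projection downstream absorbs residual error).
    """
    if mode not in ("affine", "affine+demons"):
        raise ValidationError(f"unknown registration mode {mode!r}")
    fixed = _to_sitk(template)
    moving = _to_sitk(subject)

    initial = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(sampling_fraction, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=150,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=True)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

    history: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent,
                   lambda: history.append(float(reg.GetMetricValue())))
    final = reg.Execute(fixed, moving)

    if history and history[-1] >= history[0]:
        warnings.warn(
            "registration metric did not improve; returning best-effort "
            f"transform (start {history[0]:.4f}, end {history[-1]:.4f})",
            stacklevel=2,
        )

    affine_ras = _affine_to_ras_matrix(sitk.AffineTransform(final))

    displacement = None
    disp_affine = None
    if mode == "affine+demons":
        aligned = sitk.Resample(moving, fixed, final, sitk.sitkLinear, 0.0)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(30)
        demons.SetStandardDeviations(2.0)
        field = demons.Execute(fixed, aligned)
        # field maps template LPS point -> displacement in LPS mm
        arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3) LPS components
        arr = np.transpose(arr, (2, 1, 0, 3)).astype(np.float64)
        arr[..., 0] *= -1.0
        arr[..., 1] *= -1.0
        displacement = arr
        disp_affine = template.affine.copy()

    return SpatialTransform(
        affine_part=affine_ras,
        displacement=displacement,
        displacement_affine=disp_affine,
        metric_history=history,
    )


def transfer_points(
    cps: ControlPointSet,
    t: SpatialTransform,
    skin: TriMesh,
    max_projection_mm: float = 15.0,
) -> ControlPointSet:
    """Map template points into subject space and pin them to the skin.

    Each mapped point is replaced by its exact nearest point on the skin
    mesh, so the output always satisfies the on-surface invariant. Points
    whose projection travelled more than ``max_projection_mm`` are flagged
    in the per-point report; if more than half are flagged the transfer
    fails with a recommendation to place points manually.
    """
    if cps.space != "template":
        raise ValidationError("transfer_points expects template-space points")
    mapped = t.apply(cps.positions())
    dist, projected = skin.distance_query().query(mapped)
    flagged = dist > max_projection_mm
    if len(cps) and flagged.sum() / len(cps) > 0.5:
        raise ConvergenceError(
            f"{int(flagged.sum())}/{len(cps)} transferred points projected "
            f"more than {max_projection_mm} mm to reach the skin; "
            "registration looks unreliable — place control points manually"
        )
    points = [
        ControlPoint(p.label, projected[i], p.radius)
        for i, p in enumerate(cps.points)
    ]
    out = ControlPointSet(points, "subject")
    out.projection_distances = dist  # type: ignore[attr-defined]
    out.flagged = flagged  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# template bundles


@dataclass
class TemplateBundle:
    volume: VolumeGrid
    control_points: ControlPointSet
    name: str = "template"
    version: str = "1"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _in_fov(v: VolumeGrid, positions: np.ndarray) -> np.ndarray:
    idx = v.world_to_index(positions)
    shape = np.asarray(v.shape)
    return np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=1)


def make_template(volume: VolumeGrid, cps: ControlPointSet, out,
                  name: str = "template", version: str = "1") -> TemplateBundle:
    """Write a template bundle directory (volume + points + manifest)."""
    cps.validate_complete()
    in_fov = _in_fov(volume, cps.positions())
    if not np.all(in_fov):
        raise ValidationError(
            f"{int((~in_fov).sum())} control points fall outside the "
            "template volume's field of view"
        )
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    vol_path = out / "template.nii.gz"
    pts_path = out / "points.fcsv"
    write_volume(volume, vol_path)
    write_points(ControlPointSet(cps.points, "template"), pts_path)
    manifest = {
        "name": name,
        "version": version,
        "files": {
            "template.nii.gz": _sha256(vol_path),
            "points.fcsv": _sha256(pts_path),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return TemplateBundle(volume, ControlPointSet(cps.points, "template"),
                          name, version)


def load_template(path) -> TemplateBundle:
    """Load and integrity-check a template bundle directory."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise VolumeIOError(f"no manifest.json in template bundle {path}")
    manifest = json.loads(manifest_path.read_text())
    for fname, digest in manifest.get("files", {}).items():
        fpath = path / fname
        if not fpath.exists():
            raise VolumeIOError(f"template bundle missing {fname}")
        if _sha256(fpath) != digest:
            raise ValidationError(
                f"template bundle checksum mismatch for {fname}"
            )
    volume = read_volume(path / "template.nii.gz")
    cps = read_points(path / "points.fcsv", space="template")
    return TemplateBundle(volume, cps, manifest.get("name", "template"),
                          str(manifest.get("version", "1")))
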