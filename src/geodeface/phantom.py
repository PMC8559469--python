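"""Synthetic layered head phantoms with analytic ground truth.

The phantom is a nested-ellipsoid head in a T1-like contrast regime:
bright scalp and brain, dark skull and CSF, dark background. A nose
(half-protruding anterior ellipsoid) and two lateral ear bumps give the
face mask nontrivial geometry to remove. Because every compartment
boundary is an analytic quadric, the phantom carries exact ground truth:
marching-cubes meshes of the analytic surfaces, a label volume, face/ear
landmarks guaranteed to lie on the skin surface, and masks of the
protruding identity-bearing feature voxels.

Compartments, inside out: brain, CSF (brain-to-inner-skull gap), skull
(inner-to-outer-skull band), scalp (outer-skull-to-skin shell plus
features), background. The CSF gap carries its own intensity so that the
inner-skull boundary is recoverable from image intensity alone — the
shape-prior machinery a clinical hybrid watershed would bring to bear is
deliberately out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ValidationError
from .landmarks import ControlPoint, ControlPointSet
from .surfaces import TriMesh
from .volume_io import VolumeGrid

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "degrade_like"]

LABEL_NAMES = {0: "background", 1: "scalp", 2: "skull", 3: "csf", 4: "brain"}

DEFAULT_TISSUE_MEANS = {
    "background": 0.0,
    "skull": 30.0,
    "csf": 60.0,
    "scalp": 90.0,
    "brain": 120.0,
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head.

    Radii are ellipsoid semi-axes in mm and must be strictly nested.
    ``tissue_means`` must be pairwise separated by at least 5x
    ``noise_sd`` so that segmentation on the phantom is a well-posed
    problem, and background must be the darkest compartment. The default
    grid (128^3 at 1.5 mm) keeps a full pipeline run on one phantom in
    the tens of seconds.
    """

    shape: tuple = (128, 128, 128)
    voxel_size: tuple = (1.5, 1.5, 1.5)
    brain_radii: tuple = (50.0, 64.0, 44.0)
    inner_skull_radii: tuple = (56.0, 70.0, 50.0)
    outer_skull_radii: tuple = (62.0, 76.0, 56.0)
    skin_radii: tuple = (70.0, 85.0, 65.0)
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sd: float = 4.0
    with_nose: bool = True
    nose_length: float = 15.0
    with_ears: bool = True
    ear_bump: float = 12.0
    center: tuple = (0.0, -8.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        radii = [self.brain_radii, self.inner_skull_radii,
                 self.outer_skull_radii, self.skin_radii]
        for inner, outer in zip(radii[:-1], radii[1:]):
            if not all(0 < ri < ro for ri, ro in zip(inner, outer)):
                raise ValidationError(
                    "compartment semi-axes must be strictly nested "
                    f"(got {inner} vs {outer})"
                )
        means = sorted(self.tissue_means.values())
        if self.tissue_means.get("background") != means[0]:
            raise ValidationError("background must be the darkest tissue mean")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.noise_sd > 0:
            gap = min(b - a for a, b in zip(means[:-1], means[1:]))
            if gap < 5 * self.noise_sd:
                raise ValidationError(
                    f"tissue means separated by {gap:g} < 5 x noise_sd "
                    f"({5 * self.noise_sd:g}); segmentation would be ill-posed"
                )
        # the head (plus features) must fit inside the field of view,
        # with one voxel of margin so analytic surfaces close properly
        half_fov = np.asarray(self.shape) * np.asarray(self.voxel_size) / 2
        margin = np.asarray(self.voxel_size, dtype=float)
        c = np.asarray(self.center, dtype=float)
        hi = c + np.asarray(self.skin_radii, dtype=float)
        lo = c - np.asarray(self.skin_radii, dtype=float)
        if self.with_ears:
            hi[0] += self.ear_bump
            lo[0] -= self.ear_bump
        if self.with_nose:
            hi[1] += self.nose_length
        if np.any(hi >= half_fov - margin) or np.any(lo <= -half_fov + margin):
            raise ValidationError("head does not fit in the field of view")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.voxel_size)
        a[:3, 3] = -(np.asarray(self.shape) - 1) * np.asarray(self.voxel_size) / 2
        return a


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom."""

    surfaces: dict  # label -> TriMesh for brain/inner_skull/outer_skull/skin
    landmarks: ControlPointSet
    compartment_labels: np.ndarray
    feature_masks: dict  # nose / ear_L / ear_R -> protruding-voxel masks

    def mask(self, name: str) -> np.ndarray:
        code = {v: k for k, v in LABEL_NAMES.items()}[name]
        return self.compartment_labels == code

    def filled_mask(self, surface: str) -> np.ndarray:
        """Union of compartments inside the named analytic surface."""
        inside = {
            "brain": ("brain",),
            "inner_skull": ("brain", "csf"),
            "outer_skull": ("brain", "csf", "skull"),
            "skin": ("brain", "csf", "skull", "scalp"),
        }[surface]
        out = np.zeros(self.compartment_labels.shape, dtype=bool)
        for name in inside:
            out |= self.mask(name)
        return out


def _on_ellipsoid(direction, radii) -> np.ndarray:
    """Point on an origin-centred ellipsoid along the given direction."""
    d = np.asarray(direction, dtype=np.float64)
    r = np.asarray(radii, dtype=np.float64)
    return d / np.sqrt(np.sum((d / r) ** 2))


def _quadric(coords, center, radii):
    """f < 0 inside the ellipsoid, 0 on it, > 0 outside."""
    x, y, z = coords
    cx, cy, cz = center
    rx, ry, rz = radii
    return (
        ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 - 1.0
    )


class _Geometry:
    """Analytic feature geometry shared by labels, meshes and landmarks."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.center = np.asarray(spec.center, dtype=np.float64)
        a, b, c = spec.skin_radii
        self.nose_center = None
        self.nose_radii = None
        if spec.with_nose:
            z0 = -0.12 * c
            y0 = b * np.sqrt(1 - (z0 / c) ** 2)
            self.nose_center = self.center + np.array([0.0, y0, z0])
            self.nose_radii = np.array([9.0, spec.nose_length, 11.0])
        self.ear_centers = {}
        # footprint kept within the default 20 mm ear influence radius
        self.ear_radii = np.array([spec.ear_bump, 14.0, 15.0])
        if spec.with_ears:
            for side, sx in (("ear_L", -1.0), ("ear_R", 1.0)):
                self.ear_centers[side] = self.center + _on_ellipsoid(
                    (sx, -0.05, 0.0), spec.skin_radii
                )

    def skin_field(self, coords):
        f = _quadric(coords, self.center, self.spec.skin_radii)
        if self.nose_center is not None:
            f = np.minimum(f, _quadric(coords, self.nose_center, self.nose_radii))
        for center in self.ear_centers.values():
            f = np.minimum(f, _quadric(coords, center, self.ear_radii))
        return f

    def landmark_set(self) -> ControlPointSet:
        spec = self.spec
        pts = []
        if self.nose_center is not None:
            tip = self.nose_center + np.array([0.0, spec.nose_length, 0.0])
            pts.append(ControlPoint("face", tip, 25.0))
        for d in ((0.0, 0.9, 0.35), (0.0, 0.8, -0.55),
                  (-0.45, 0.8, -0.2), (0.45, 0.8, -0.2)):
            pts.append(
                ControlPoint(
                    "face", self.center + _on_ellipsoid(d, spec.skin_radii),
                    25.0,
                )
            )
        for side, sx in (("ear_L", -1.0), ("ear_R", 1.0)):
            if side in self.ear_centers:
                apex = self.ear_centers[side] + np.array(
                    [sx * spec.ear_bump, 0.0, 0.0]
                )
            else:
                apex = self.center + _on_ellipsoid(
                    (sx, -0.05, 0.0), spec.skin_radii
                )
            pts.append(ControlPoint(side, apex, 20.0))
        return ControlPointSet(pts, "subject")


def _field_mesh(f: np.ndarray, affine: np.ndarray, label: str) -> TriMesh:
    verts, faces, _, _ = measure.marching_cubes(f, level=0.0)
    verts = verts @ affine[:3, :3].T + affine[:3, 3]
    import trimesh as _tm

    mesh = _tm.Trimesh(vertices=verts, faces=faces, process=True)
    _tm.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return TriMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces),
                   label=label,
                   diagnostics={"watertight": bool(mesh.is_watertight),
                                "analytic": True})


def make_phantom(spec: PhantomSpec | None = None) -> tuple[VolumeGrid, PhantomTruth]:
    """Generate the intensity volume and its analytic ground truth.

    Bit-reproducible for a fixed ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    geom = _Geometry(spec)
    affine = spec.affine

    idx = [np.arange(n, dtype=np.float64) for n in spec.shape]
    grid = np.meshgrid(*idx, indexing="ij")
    coords = tuple(
        affine[i, i] * grid[i] + affine[i, 3] for i in range(3)
    )  # diagonal affine by construction

    f_brain = _quadric(coords, spec.center, spec.brain_radii)
    f_inner = _quadric(coords, spec.center, spec.inner_skull_radii)
    f_outer = _quadric(coords, spec.center, spec.outer_skull_radii)
    f_skin = geom.skin_field(coords)

    labels = np.zeros(spec.shape, dtype=np.int8)
    labels[f_skin <= 0] = 1
    labels[f_outer <= 0] = 2
    labels[f_inner <= 0] = 3
    labels[f_brain <= 0] = 4

    means = spec.tissue_means
    lut = np.array(
        [means["background"], means["scalp"], means["skull"],
         means.get("csf", (means["skull"] + means["scalp"]) / 2),
         means["brain"]],
        dtype=np.float64,
    )
    data = lut[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + spec.noise_sd * rng.standard_normal(spec.shape)
    volume = VolumeGrid(data.astype(np.float32), affine)

    surfaces = {
        "brain": _field_mesh(f_brain, affine, "brain"),
        "inner_skull": _field_mesh(f_inner, affine, "inner_skull"),
        "outer_skull": _field_mesh(f_outer, affine, "outer_skull"),
        "skin": _field_mesh(f_skin, affine, "skin"),
    }

    feature_masks = {}
    base_skin = _quadric(coords, spec.center, spec.skin_radii)
    if geom.nose_center is not None:
        feature_masks["nose"] = (
            (_quadric(coords, geom.nose_center, geom.nose_radii) <= 0)
            & (base_skin > 0)
        )
    for side, center in geom.ear_centers.items():
        feature_masks[side] = (
            (_quadric(coords, center, geom.ear_radii) <= 0) & (base_skin > 0)
        )

    truth = PhantomTruth(
        surfaces=surfaces,
        landmarks=geom.landmark_set(),
        compartment_labels=labels,
        feature_masks=feature_masks,
    )
    return volume, truth


def degrade_like(
    v: VolumeGrid,
    truth: PhantomTruth,
    mode: str,
    blur_sd_mm: float = 8.0,
) -> VolumeGrid:
    """Surrogate competitor-defaced phantom for exercising the metrics.

    ``blank-face`` zeroes the landmark-defined face region outright, the
    way template-matching face removal leaves the face area empty; the
    region is the union of face control-point balls restricted to outside
    the outer skull, so face removal deletes the face but leaves the
    cranial content untouched. ``blur-face`` Gaussian-smooths the
    unrestricted ball region, the way masking-by-blurring bleeds across
    tissue boundaries and dissolves them. These surrogates exist only so
    the evaluation battery has known-worse comparison points.
    """
    if mode not in ("blank-face", "blur-face"):
        raise ValidationError(f"unknown degradation mode {mode!r}")
    region = np.zeros(v.shape, dtype=bool)
    shape = np.asarray(v.shape)
    inv = np.linalg.inv(v.affine)
    idx_grids = None
    for p in truth.landmarks.by_label("face"):
        center_idx = v.world_to_index(p.position)[0]
        r_vox = p.radius / v.voxel_size
        lo = np.maximum(np.floor(center_idx - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(center_idx + r_vox).astype(int) + 1, shape)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        local = np.meshgrid(
            *[np.arange(l, h, dtype=np.float64) for l, h in zip(lo, hi)],
            indexing="ij",
        )
        d2 = sum(
            ((local[i] - center_idx[i]) * v.voxel_size[i]) ** 2 for i in range(3)
        )
        region[sl] |= d2 <= p.radius**2
    del idx_grids, inv

    out = np.array(v.data, copy=True)
    if mode == "blank-face":
        region &= ~truth.filled_mask("outer_skull")
        out[region] = 0
    else:
        if blur_sd_mm > 0:
            blurred = ndimage.gaussian_filter(
                np.asarray(v.data, dtype=np.float64),
                sigma=blur_sd_mm / v.voxel_size,
            )
            out[region] = blurred[region].astype(out.dtype)
    return VolumeGrid(out, v.affine.copy())
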