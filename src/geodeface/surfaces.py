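"""Head segmentation and triangulated surface extraction.

The first stage of the deidentification procedure: a marker-based
watershed on the gradient-magnitude image separates head from background,
then intensity-band classification inside the head recovers the dark
skull band, the CSF gap and the bright brain, yielding the four nested
compartment masks (brain, inner skull, outer skull, skin) from which the
BEM-style surfaces are extracted by marching cubes. These are the same
surfaces used for EEG/MEG forward head models, which is precisely why
preserving them is the point of the masking stage downstream.

Band thresholds are the midpoints between 1-D k-means tissue centers
estimated from head-interior intensities, snapped to a coarse scale-free
grid. Snapping makes the segmentation reproducible under intensity
perturbations that preserve the head's intensity distribution (such as
the distribution-matched noise fill applied by the defacing stage), so a
brain mask segmented from a defaced volume is voxel-identical to the
original's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed as _watershed

from ._geometry import MeshDistanceQuery, rasterize_mesh
from .errors import GeometryError, SegmentationError
from .volume_io import VolumeGrid

__all__ = [
    "TriMesh",
    "SegmentationParams",
    "SegmentationResult",
    "segment_head",
    "extract_surface",
    "extract_bem_set",
]

SURFACE_LABELS = ("brain", "inner_skull", "outer_skull", "skin")


@dataclass
class TriMesh:
    """Triangulated closed surface in world mm."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = "surface"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (M, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise GeometryError("faces index nonexistent vertices")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @property
    def volume(self) -> float:
        return float(self.as_trimesh().volume)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def distance_query(self) -> MeshDistanceQuery:
        return MeshDistanceQuery(self.vertices, self.faces)

    def to_mask(self, affine: np.ndarray, shape) -> np.ndarray:
        """Rasterize the closed surface to an inside/outside voxel mask."""
        return rasterize_mesh(self.vertices, self.faces, affine, shape)

    def export(self, path) -> None:
        self.as_trimesh().export(str(path))


@dataclass
class SegmentationParams:
    """Tunables of the watershed + band segmentation.

    grad_sigma_mm: Gaussian scale of the gradient-magnitude image the
        watershed floods. marker_erosion controls the
        bright head marker, which by default is every tissue brighter than
        the CSF|scalp threshold (scalp and brain both), so the head basin
        owns all bright tissue from the start; marker_quantile optionally
        replaces that threshold with a bright-intensity quantile. band_init_quantiles seed the 3-class 1-D
        k-means (CSF, scalp, brain) on above-background intensities;
        dark_init_quantiles seed the 2-class one (background, skull) on
        the rest. skull_quantile, if set, overrides the estimated
        skull/CSF threshold with a fixed head-interior quantile.
        skull_reach_mm bounds how far outside the inner-skull surface the
        dark skull band is sought. snap_divisions sets the threshold
        snapping grid to roughly range/snap_divisions, rounded to a power
        of two.
    """

    grad_sigma_mm: float = 1.5
    marker_quantile: float | None = None
    marker_erosion: int = 2
    boundary_band: int = 2
    band_init_quantiles: tuple = (0.08, 0.35, 0.80)
    dark_init_quantiles: tuple = (0.40, 0.99)
    skull_quantile: float | None = None
    skull_reach_mm: float = 8.0
    closing_radius: int = 1
    snap_divisions: int = 64
    min_side_fraction: float = 1e-3


@dataclass
class SegmentationResult:
    """Nested boolean compartment masks on the input grid."""

    head_mask: np.ndarray
    skull_mask: np.ndarray
    brain_mask: np.ndarray
    inner_skull_mask: np.ndarray
    outer_skull_mask: np.ndarray
    thresholds: dict
    diagnostics: dict

    def mask_for(self, label: str) -> np.ndarray:
        return {
            "brain": self.brain_mask,
            "inner_skull": self.inner_skull_mask,
            "outer_skull": self.outer_skull_mask,
            "skin": self.head_mask,
        }[label]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return mask
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def _kmeans_1d(x: np.ndarray, init: np.ndarray, max_iter: int = 80) -> np.ndarray:
    """Deterministic Lloyd iteration for sorted 1-D centers."""
    centers = np.sort(np.asarray(init, dtype=np.float64))
    for _ in range(max_iter):
        edges = (centers[:-1] + centers[1:]) / 2.0
        assign = np.searchsorted(edges, x)
        new = np.empty_like(centers)
        for k in range(len(centers)):
            sel = assign == k
            if not np.any(sel):
                raise SegmentationError(
                    "intensity band collapsed during tissue clustering",
                    {"empty_band": k, "centers": centers.tolist()},
                )
            new[k] = x[sel].mean()
        if np.allclose(new, centers, rtol=0, atol=1e-10):
            centers = new
            break
        centers = new
    return centers


def _snap(value: float, grid: float) -> float:
    return float(np.round(value / grid) * grid)


def segment_head(v: VolumeGrid, params: SegmentationParams | None = None) -> SegmentationResult:
    """Segment head, skull band, inner-skull cavity and brain.

    Raises :class:`SegmentationError` with diagnostic counts when the
    contrast is degenerate (uniform volume, empty or touching marker
    sets, collapsed intensity bands).
    """
    params = params or SegmentationParams()
    data = np.asarray(v.data, dtype=np.float64)
    diag: dict = {}

    if np.ptp(data) == 0:
        raise SegmentationError("uniform-intensity volume: no separable markers",
                                {"ptp": 0.0})

    t_bg = float(threshold_otsu(data))
    frac_head = float(np.mean(data > t_bg))
    diag["otsu_background_threshold"] = t_bg
    diag["head_fraction"] = frac_head
    if min(frac_head, 1 - frac_head) < params.min_side_fraction:
        raise SegmentationError(
            "background/head split degenerate", diag
        )

    # --- intensity bands, estimated globally so that inner compartments do
    # not depend on head-mask topology (a defaced input can open a mouth in
    # the scalp through which the watershed background flood enters).
    bright = data > t_bg
    vals_bright = data[bright]
    p1, p99 = np.percentile(vals_bright, [1, 99])
    if p99 <= p1:
        raise SegmentationError("tissue intensities have no spread", diag)
    grid = 2.0 ** np.round(np.log2((p99 - p1) / params.snap_divisions))
    c3 = _kmeans_1d(
        vals_bright, np.quantile(vals_bright, params.band_init_quantiles)
    )  # csf, scalp, brain centers
    if np.min(np.diff(c3)) < (p99 - p1) / 1e4:
        raise SegmentationError(
            "tissue intensity bands are not separable",
            {**diag, "centers": c3.tolist()},
        )
    vals_dark = data[~bright]
    c_bgk = _kmeans_1d(vals_dark, np.quantile(vals_dark, params.dark_init_quantiles))
    skull_center = float(c_bgk[-1])

    t1 = _snap((skull_center + c3[0]) / 2, grid)  # skull | csf
    t2 = _snap((c3[0] + c3[1]) / 2, grid)  # csf | scalp
    t3 = _snap((c3[1] + c3[2]) / 2, grid)  # scalp | brain
    if params.skull_quantile is not None:
        t1 = float(np.quantile(data[data > t_bg], params.skull_quantile))
    thresholds = {
        "background": t_bg,
        "skull_csf": t1,
        "csf_scalp": t2,
        "scalp_brain": t3,
        "snap_grid": float(grid),
        "centers": [skull_center] + c3.tolist(),
    }

    sigma_vox = params.grad_sigma_mm / v.voxel_size
    grad = ndimage.gaussian_gradient_magnitude(data, sigma=sigma_vox)

    border = np.zeros(v.shape, dtype=bool)
    border[:2], border[-2:] = True, True
    border[:, :2], border[:, -2:] = True, True
    border[:, :, :2], border[:, :, -2:] = True, True
    bg_marker = border & (data <= t_bg)

    # scalp and brain are both marked as head, so the background basin can
    # never win a tie for scalp through a ridge opened by prior defacing
    if params.marker_quantile is not None:
        bright_cut = float(
            np.quantile(data[data > t_bg], params.marker_quantile)
        )
    else:
        bright_cut = t2
    head_marker = data >= bright_cut
    if params.marker_erosion > 0:
        eroded = ndimage.binary_erosion(
            head_marker, iterations=params.marker_erosion
        )
        if np.any(eroded):
            head_marker = eroded
    diag["n_bg_marker"] = int(bg_marker.sum())
    diag["n_head_marker"] = int(head_marker.sum())
    if not np.any(bg_marker) or not np.any(head_marker):
        raise SegmentationError("empty watershed marker set", diag)
    if np.any(bg_marker & head_marker):
        raise SegmentationError("watershed markers touch", diag)

    markers = np.zeros(v.shape, dtype=np.int32)
    markers[bg_marker] = 1
    markers[head_marker] = 2
    ws = _watershed(grad, markers)
    head = ws == 2

    # correct the watershed line by intensity inside a thin boundary band:
    # the flooding splits the background/scalp gradient ridge arbitrarily
    # within a voxel or two; the threshold decides exactly there.
    r = params.boundary_band
    band = ndimage.binary_dilation(head, iterations=r) & ~ndimage.binary_erosion(
        head, iterations=r
    )
    head = (head & ~band) | (band & (data > t_bg))

    brain = ndimage.binary_fill_holes(_largest_component(data >= t3))

    csf_band = (data >= t1) & (data < t2)
    inner = _largest_component(csf_band | brain)
    inner = ndimage.binary_fill_holes(inner)

    # the dark skull band hugs the inner-skull surface: search for it only
    # within a fixed reach of that surface so the background (equally dark)
    # can never be captured, even through a defaced opening in the scalp
    gap_mm = ndimage.distance_transform_edt(~inner, sampling=tuple(v.voxel_size))
    near_inner = gap_mm <= params.skull_reach_mm
    skull_dark = (data < t1) & near_inner & ~inner
    structure = ndimage.generate_binary_structure(3, 1)
    closed = ndimage.binary_closing(
        skull_dark, structure=structure, iterations=params.closing_radius
    )
    # closing may only add voxels that are not scalp/brain-bright; this
    # bridges noise gaps in the dark band without inflating its outer rim
    skull_dark = skull_dark | (closed & near_inner & (data < t2))

    outer = ndimage.binary_fill_holes(_largest_component(inner | skull_dark))

    # the head is the watershed result plus everything the outer skull
    # encloses; the union happens before the largest-component reduction
    # because a defaced opening can disconnect scalp from brain inside the
    # watershed result, and the outer skull is the bridge between them
    head = ndimage.binary_fill_holes(_largest_component(head | outer))
    diag["n_head"] = int(head.sum())

    # enforce nesting; report any trimming
    inner &= outer
    brain_in = brain & inner
    diag["n_brain_trimmed"] = int(brain.sum() - brain_in.sum())
    brain = brain_in
    outer &= head

    skull_mask = outer & ~inner
    diag.update(
        n_brain=int(brain.sum()),
        n_inner_skull=int(inner.sum()),
        n_outer_skull=int(outer.sum()),
        n_skull_band=int(skull_mask.sum()),
    )
    if not (np.any(brain) and np.any(skull_mask)):
        raise SegmentationError("empty compartment after segmentation", diag)

    return SegmentationResult(
        head_mask=head,
        skull_mask=skull_mask,
        brain_mask=brain,
        inner_skull_mask=inner,
        outer_skull_mask=outer,
        thresholds=thresholds,
        diagnostics=diag,
    )


def extract_surface(
    mask: np.ndarray,
    affine: np.ndarray,
    label: str = "surface",
    smooth_iters: int = 10,
    presmooth_sd: float = 0.5,
) -> TriMesh:
    """Marching-cubes isosurface of a boolean mask, in world mm.

    The mask is optionally Gaussian-smoothed (``presmooth_sd`` in voxels)
    before contouring at 0.5, which turns the binary staircase into a
    sub-voxel-accurate surface; Taubin smoothing then relaxes the
    remaining lattice ripple without shrinking the mesh. The largest
    connected component is kept, holes are closed, and the orientation is
    fixed outward. A mesh that still fails watertightness after repair is
    returned with ``diagnostics['watertight'] = False`` rather than
    raising, so downstream usability screening can record the failure.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise GeometryError(f"cannot extract {label} surface from empty mask")

    vol = mask.astype(np.float32)
    if presmooth_sd > 0:
        vol = ndimage.gaussian_filter(vol, presmooth_sd)
        # keep the level set inside regions the smoothing washed out
        vol[mask & (vol < 0.55)] = 0.55
    vol = np.pad(vol, 1, mode="constant")

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5)
    verts -= 1.0  # undo padding offset
    affine = np.asarray(affine, dtype=np.float64)
    verts = verts @ affine[:3, :3].T + affine[:3, 3]

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: len(m.faces))
    trimesh.repair.fill_holes(mesh)
    trimesh.repair.fix_normals(mesh)
    if smooth_iters > 0:
        trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=-0.53,
                                        iterations=smooth_iters)
    if mesh.volume < 0:
        mesh.invert()

    watertight = bool(mesh.is_watertight)
    if not watertight:
        warnings.warn(f"{label} surface not watertight after repair", stacklevel=2)
    return TriMesh(
        np.asarray(mesh.vertices),
        np.asarray(mesh.faces),
        label=label,
        diagnostics={
            "watertight": watertight,
            "n_components_removed": int(len(parts) - 1) if len(parts) > 1 else 0,
            "n_vertices": int(len(mesh.vertices)),
        },
    )


def check_nesting(inner: TriMesh, outer: TriMesh, affine: np.ndarray, shape,
                  tol_fraction: float = 1e-3) -> bool:
    """True when (almost) all inner-mesh vertices lie inside the outer mesh."""
    outer_mask = outer.to_mask(affine, shape)
    inv = np.linalg.inv(np.asarray(affine, dtype=np.float64))
    idx = np.round(
        inner.vertices @ inv[:3, :3].T + inv[:3, 3]
    ).astype(np.int64)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    inside = outer_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(np.mean(~inside)) <= tol_fraction


def extract_bem_set(
    v: VolumeGrid,
    params: SegmentationParams | None = None,
    smooth_iters: int = 10,
    segmentation: SegmentationResult | None = None,
) -> list[TriMesh]:
    """Extract the four nested BEM surfaces (brain ... skin).

    Pairwise nesting is checked by voxelized containment; a violation is
    flagged on the outer mesh's diagnostics (``nested=False``) rather than
    raised, because a distorted reconstruction is an outcome the usability
    screen is meant to measure.
    """
    seg = segmentation if segmentation is not None else segment_head(v, params)
    meshes = []
    for label in SURFACE_LABELS:
        meshes.append(
            extract_surface(seg.mask_for(label), v.affine, label=label,
                            smooth_iters=smooth_iters)
        )
    for inner_m, outer_m in zip(meshes[:-1], meshes[1:]):
        ok = check_nesting(inner_m, outer_m, v.affine, v.shape)
        inner_m.diagnostics.setdefault("nested", True)
        inner_m.diagnostics["nested"] = inner_m.diagnostics["nested"] and ok
        if not ok:
            warnings.warn(
                f"{inner_m.label} not nested inside {outer_m.label}",
                stacklevel=2,
            )
    meshes[-1].diagnostics.setdefault("nested", True)
    return meshes
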