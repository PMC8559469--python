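"""The masking stage: skull-to-skin shell, noise fill, exterior zeroing.

The subject-specific mask is the intersection of the control-point
influence regions (Euclidean balls around each face/ear point) with the
skull-to-skin shell — the scalp and facial soft tissue between the outer
skull surface and the skin surface. Voxels in that intersection are
replaced by independent draws from the empirical intensity distribution
of the whole shell; voxels strictly outside the skin surface are set to
zero; everything else — brain, skull, unmasked scalp — is bitwise
untouched. Because the fill follows the shell's own distribution and the
skin surface itself is never moved, re-running surface extraction on the
output reproduces the original head geometry.

The fill RNG is a counter-based Philox generator keyed by the seed, and
draws are assigned to active voxels in fixed C order, so identical
inputs and seed give bitwise-identical output regardless of platform or
iteration strategy.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import GeometryError, ValidationError
from .landmarks import (
    ControlPointSet,
    SpatialTransform,
    TemplateBundle,
    register,
    transfer_points,
)
from .surfaces import (
    SegmentationParams,
    TriMesh,
    extract_surface,
    segment_head,
)
from .volume_io import VolumeGrid, to_canonical

__all__ = [
    "ShellMask",
    "IntensityDistribution",
    "DefaceParams",
    "QAReport",
    "build_shell",
    "apply_influence",
    "fit_distribution",
    "deface",
    "anonymize",
]


@dataclass
class ShellMask:
    """Skull-to-skin shell and its control-point-active subset."""

    shell: np.ndarray
    active: np.ndarray | None
    affine: np.ndarray
    inside_skin: np.ndarray = None  # cached rasterization for exterior zeroing

    def __post_init__(self):
        self.shell = np.asarray(self.shell, dtype=bool)
        if self.active is not None:
            self.active = np.asarray(self.active, dtype=bool)
            if self.active.shape != self.shell.shape:
                raise GeometryError("active/shell grid mismatch")
            if np.any(self.active & ~self.shell):
                raise GeometryError("active mask extends outside the shell")


@dataclass
class IntensityDistribution:
    """Empirical distribution of shell voxel intensities."""

    sample_pool: np.ndarray
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_pool = np.asarray(self.sample_pool).ravel()
        if len(self.sample_pool) == 0:
            raise ValidationError("empty intensity pool")
        if not self.summary:
            q = np.percentile(self.sample_pool, [5, 25, 50, 75, 95])
            self.summary = {
                "n": int(len(self.sample_pool)),
                "mean": float(self.sample_pool.mean()),
                "sd": float(self.sample_pool.std()),
                "quantiles": {str(p): float(v)
                              for p, v in zip([5, 25, 50, 75, 95], q)},
            }

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw with replacement from the pool."""
        return self.sample_pool[rng.integers(0, len(self.sample_pool), size=n)]


def build_shell(v: VolumeGrid, skin: TriMesh, outer_skull: TriMesh) -> ShellMask:
    """Voxels inside the skin surface but outside the outer skull.

    Membership is decided by voxelized even-odd containment of voxel
    centers; centers exactly on the skin surface count as inside, so the
    skin boundary voxels stay in the preserved region.
    """
    in_skin = skin.to_mask(v.affine, v.shape)
    in_skull = outer_skull.to_mask(v.affine, v.shape)
    n_outside = int(np.count_nonzero(in_skull & ~in_skin))
    if n_outside > max(16, 0.005 * in_skull.sum()):
        raise GeometryError(
            f"outer skull not nested inside skin ({n_outside} voxels outside)"
        )
    shell = in_skin & ~in_skull
    if not np.any(shell):
        raise GeometryError("empty skull-to-skin shell (degenerate surfaces)")
    return ShellMask(shell=shell, active=None, affine=np.asarray(v.affine),
                     inside_skin=in_skin)


def apply_influence(shell: ShellMask, cps: ControlPointSet) -> ShellMask:
    """Intersect the shell with the union of control-point balls."""
    if cps.space != "subject":
        raise ValidationError("control points must be in subject space")
    shape = np.asarray(shell.shell.shape)
    affine = np.asarray(shell.affine, dtype=np.float64)
    inv = np.linalg.inv(affine)
    voxel_size = np.linalg.norm(affine[:3, :3], axis=0)

    region = np.zeros(tuple(shape), dtype=bool)
    for p in cps.points:
        center_idx = (inv[:3, :3] @ p.position + inv[:3, 3])
        r_vox = p.radius / voxel_size
        lo = np.maximum(np.floor(center_idx - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(center_idx + r_vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
        local = np.meshgrid(
            *[np.arange(l, h, dtype=np.float64) for l, h in zip(lo, hi)],
            indexing="ij",
        )
        d2 = sum(
            ((local[i] - center_idx[i]) * voxel_size[i]) ** 2 for i in range(3)
        )
        region[sl] |= d2 <= p.radius**2

    active = shell.shell & region
    if not np.any(active):
        import warnings

        warnings.warn(
            "control-point influence misses the shell entirely "
            "(0 active voxels)", stacklevel=2,
        )
    return ShellMask(shell=shell.shell, active=active, affine=shell.affine,
                     inside_skin=shell.inside_skin)


def fit_distribution(v: VolumeGrid, shell: ShellMask) -> IntensityDistribution:
    """Empirical multiset of all shell voxel intensities."""
    if not np.any(shell.shell):
        raise GeometryError("cannot fit distribution on empty shell")
    return IntensityDistribution(sample_pool=np.array(v.data[shell.shell]))


def deface(
    v: VolumeGrid,
    mask: ShellMask,
    dist: IntensityDistribution,
    skin: TriMesh,
    seed: int,
    zero_exterior: str = "global",
) -> VolumeGrid:
    """Apply the mask: fill active voxels, zero outside the skin.

    Output voxel value is (i) a fresh draw from ``dist`` if the voxel is
    in ``mask.active``; (ii) 0 if strictly outside the skin surface (per
    ``zero_exterior``: ``global`` everywhere, ``face-only`` restricted to
    the control-point influence region, ``off`` never); (iii) the
    original value otherwise.
    """
    if mask.shell.shape != v.shape:
        raise GeometryError("mask grid does not match volume grid")
    if zero_exterior not in ("global", "face-only", "off"):
        raise ValidationError(f"unknown zero_exterior mode {zero_exterior!r}")
    if mask.active is None:
        raise ValidationError("shell mask has no active region; "
                              "run apply_influence first")

    inside_skin = (
        mask.inside_skin
        if mask.inside_skin is not None
        else skin.to_mask(v.affine, v.shape)
    )

    out = np.array(v.data, copy=True)
    if zero_exterior == "global":
        out[~inside_skin] = 0
    elif zero_exterior == "face-only":
        dilated = _influence_region_like(mask)
        out[~inside_skin & dilated] = 0

    rng = np.random.Generator(np.random.Philox(key=seed))
    n_active = int(mask.active.sum())
    draws = dist.sample(n_active, rng)
    if np.issubdtype(out.dtype, np.integer):
        draws = np.rint(draws)
    out[mask.active] = draws.astype(out.dtype)
    return VolumeGrid(out, v.affine.copy())


def _influence_region_like(mask: ShellMask) -> np.ndarray:
    # face-only exterior zeroing: zero outside skin within a dilation of
    # the active region, leaving remote background untouched
    from scipy import ndimage

    return ndimage.binary_dilation(mask.active, iterations=3)


@dataclass
class DefaceParams:
    """All tunables of the end-to-end anonymization run."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    smooth_iters: int = 10
    registration_mode: str = "affine"
    radius_face: float | None = None
    radius_ear: float | None = None
    max_projection_mm: float = 15.0
    zero_exterior: str = "global"

    def resolved(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class QAReport:
    """Structured record of one anonymization run.

    Everything needed to reproduce the run bitwise: the resolved
    parameters, the seed, per-stage voxel counts and timings, and the
    landmark projection report.
    """

    seed: int
    params: dict
    counts: dict
    timings_s: dict
    thresholds: dict
    landmarks: list
    renders: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        import json

        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _render_qa(v_out: VolumeGrid, skin: TriMesh, qa_dir: Path) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qa_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, axes = plt.subplots(1, 3, figsize=(10, 4))
    mids = [s // 2 for s in v_out.shape]
    slices = [
        v_out.data[mids[0], :, :].T,
        v_out.data[:, mids[1], :].T,
        v_out.data[:, :, mids[2]].T,
    ]
    for ax, sl, name in zip(axes, slices, ["sagittal", "coronal", "axial"]):
        ax.imshow(sl, cmap="gray", origin="lower")
        ax.set_title(name)
        ax.axis("off")
    fig.tight_layout()
    p = qa_dir / "slices.png"
    fig.savefig(p, dpi=90)
    plt.close(fig)
    paths.append(str(p))

    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, projection="3d")
    step = max(1, len(skin.faces) // 4000)
    ax.plot_trisurf(
        skin.vertices[:, 0], skin.vertices[:, 1],
        triangles=skin.faces[::step], Z=skin.vertices[:, 2],
        color="tan", edgecolor="none",
    )
    ax.set_axis_off()
    p = qa_dir / "skin_surface.png"
    fig.savefig(p, dpi=90)
    plt.close(fig)
    paths.append(str(p))
    return paths


def anonymize(
    v: VolumeGrid,
    template_or_points: TemplateBundle | ControlPointSet,
    params: DefaceParams | None = None,
    seed: int = 0,
    qa_dir=None,
    return_artifacts: bool = False,
) -> tuple[VolumeGrid, QAReport]:
    """Full pipeline: segment, extract surfaces, locate landmarks, mask.

    ``template_or_points`` is either a template bundle (automatic mode:
    register and transfer its control points, then project them onto the
    subject's skin) or a subject-space :class:`ControlPointSet` (manual
    mode: points are projected onto the skin but otherwise trusted).
    """
    params = params or DefaceParams()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def _stage(name):
        class _T:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()

            def __exit__(self_t, *exc):
                timings[name] = round(time.perf_counter() - self_t.t0, 3)

        return _T()

    with _stage("canonicalize"):
        v = to_canonical(v)

    with _stage("segment"):
        seg = segment_head(v, params.segmentation)
    counts["head_voxels"] = int(seg.head_mask.sum())
    counts["brain_voxels"] = int(seg.brain_mask.sum())

    with _stage("surfaces"):
        skin = extract_surface(seg.head_mask, v.affine, "skin",
                               smooth_iters=params.smooth_iters)
        outer_skull = extract_surface(seg.outer_skull_mask, v.affine,
                                      "outer_skull",
                                      smooth_iters=params.smooth_iters)

    with _stage("landmarks"):
        if isinstance(template_or_points, TemplateBundle):
            bundle = template_or_points
            transform = register(v, bundle.volume,
                                 mode=params.registration_mode)
            cps = transfer_points(
                bundle.control_points, transform, skin,
                max_projection_mm=params.max_projection_mm,
            )
        elif isinstance(template_or_points, ControlPointSet):
            cps = template_or_points
            cps.validate_complete()
            if cps.space != "subject":
                raise ValidationError(
                    "manual control points must be in subject space"
                )
            identity = SpatialTransform(np.eye(4))
            cps = transfer_points(
                ControlPointSet(cps.points, "template"), identity, skin,
                max_projection_mm=params.max_projection_mm,
            )
        else:
            raise ValidationError(
                "template_or_points must be a TemplateBundle or ControlPointSet"
            )
        proj_mm = getattr(cps, "projection_distances", np.zeros(len(cps)))
        proj_flagged = getattr(cps, "flagged", np.zeros(len(cps), dtype=bool))
        cps = cps.with_radii(face=params.radius_face, ear=params.radius_ear)

    with _stage("shell"):
        shell = build_shell(v, skin, outer_skull)
        shell = apply_influence(shell, cps)
    counts["shell_voxels"] = int(shell.shell.sum())
    counts["active_voxels"] = int(shell.active.sum())

    with _stage("fill"):
        dist = fit_distribution(v, shell)
        out = deface(v, shell, dist, skin, seed=seed,
                     zero_exterior=params.zero_exterior)
    counts["zeroed_voxels"] = int(np.count_nonzero(
        (out.data == 0) & (v.data != 0)
    ))

    renders = []
    if qa_dir is not None:
        with _stage("qa_render"):
            renders = _render_qa(out, skin, Path(qa_dir))

    report = QAReport(
        seed=seed,
        params=params.resolved(),
        counts=counts,
        timings_s=timings,
        thresholds=seg.thresholds,
        landmarks=[
            {
                "label": p.label,
                "position": [round(float(x), 4) for x in p.position],
                "radius": p.radius,
                "projection_mm": round(float(d), 4),
                "flagged": bool(f),
            }
            for p, d, f in zip(cps.points, proj_mm, proj_flagged)
        ],
        renders=renders,
    )
    if return_artifacts:
        report.artifacts = {  # type: ignore[attr-defined]
            "segmentation": seg,
            "skin": skin,
            "outer_skull": outer_skull,
            "shell": shell,
            "distribution": dist,
            "control_points": cps,
        }
    return out, report
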