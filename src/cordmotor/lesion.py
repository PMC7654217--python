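"""Spared-tissue quantification from template-space cord and lesion masks.

A chronic spinal cord injury leaves a lesion inside the cord whose axial
footprint, accumulated over the superior-inferior (S-I) extent of the
damage, determines how much of each white-matter region is still intact.
The procedure implemented here:

1. (optionally) align each axial slice of a subject's cord mask onto a
   template cord cross-section by centroid translation and area-matching
   isotropic scaling (a simplified slicewise registration stand-in;
   nonlinear template registration is delegated to external tooling and
   inputs are normally assumed to already be in template space);
2. project the 3-D lesion mask along the S-I axis into a single composite
   axial image (logical union);
3. score the percentage of spared (non-lesioned) tissue in the whole cord
   and in the anterior, posterior, left-lateral and right-lateral
   white-matter regions of an axial atlas.

Region atlases carry per-pixel nonnegative weights so probabilistic tract
atlases can be consumed directly; binary masks are the special case of
weights in {0, 1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "REGIONS",
    "LesionStudy",
    "AxialRegionAtlas",
    "SparedTissueProfile",
    "SlicewiseTransform",
    "slicewise_align",
    "project_lesion_axial",
    "compute_spared_fraction",
    "spared_profile",
    "load_study",
    "save_study",
    "load_atlas",
    "save_atlas",
    "profiles_to_csv",
    "plot_projection",
]

logger = logging.getLogger(__name__)

#: Canonical axial white-matter region names, in reporting order.
REGIONS = ("anterior", "posterior", "left", "right")


@dataclass
class LesionStudy:
    """Template-space 3-D cord and lesion masks with grid metadata.

    Parameters
    ----------
    cord_mask, lesion_mask
        Boolean 3-D volumes on a common grid. The cord mask includes the
        lesion (the lesion is intramedullary), so ``lesion_mask`` must be
        a subset of ``cord_mask``.
    voxel_size
        Physical voxel size in mm per axis.
    si_axis
        Index of the superior-inferior axis (the axis collapsed by the
        axial projection). Default 2 (last axis).
    """

    cord_mask: np.ndarray
    lesion_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    si_axis: int = 2
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.cord_mask = np.asarray(self.cord_mask, dtype=bool)
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.cord_mask.ndim != 3:
            raise ValueError("cord_mask must be 3-D")
        if self.cord_mask.shape != self.lesion_mask.shape:
            raise ValueError(
                f"mask shapes differ: cord {self.cord_mask.shape} vs "
                f"lesion {self.lesion_mask.shape}"
            )
        if not self.si_axis in (0, 1, 2):
            raise ValueError("si_axis must be 0, 1 or 2")
        if np.any(self.lesion_mask & ~self.cord_mask):
            raise ValueError("lesion_mask must be contained in cord_mask")

    @property
    def axial_shape(self) -> tuple[int, int]:
        shape = list(self.cord_mask.shape)
        shape.pop(self.si_axis)
        return tuple(shape)  # type: ignore[return-value]


@dataclass
class AxialRegionAtlas:
    """Per-pixel region weights and a whole-cord mask on one axial grid.

    ``region_weights`` maps each of :data:`REGIONS` to a nonnegative 2-D
    weight image; weight support must lie inside ``cord_mask_2d`` and each
    region must have positive total weight.
    """

    region_weights: dict[str, np.ndarray]
    cord_mask_2d: np.ndarray

    def __post_init__(self) -> None:
        self.cord_mask_2d = np.asarray(self.cord_mask_2d, dtype=bool)
        missing = set(REGIONS) - set(self.region_weights)
        if missing:
            raise ValueError(f"atlas missing regions: {sorted(missing)}")
        for name, w in self.region_weights.items():
            w = np.asarray(w, dtype=float)
            self.region_weights[name] = w
            if w.shape != self.cord_mask_2d.shape:
                raise ValueError(f"region {name!r} grid differs from cord mask")
            if np.any(w < 0):
                raise ValueError(f"region {name!r} has negative weights")
            if w.sum() <= 0:
                raise ValueError(f"region {name!r} has zero total weight")
            if np.any((w > 0) & ~self.cord_mask_2d):
                raise ValueError(f"region {name!r} support outside cord mask")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.cord_mask_2d.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SparedTissueProfile:
    """The five spared-tissue percentages used as MRI outcome variables."""

    spared_total: float
    spared_anterior: float
    spared_posterior: float
    spared_left: float
    spared_right: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (-1e-9 <= value <= 100 + 1e-9):
                raise ValueError(f"{name}={value} outside [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {
            "spared_total": self.spared_total,
            "spared_anterior": self.spared_anterior,
            "spared_posterior": self.spared_posterior,
            "spared_left": self.spared_left,
            "spared_right": self.spared_right,
        }

    def as_array(self) -> np.ndarray:
        return np.array(list(self.as_dict().values()))


@dataclass(frozen=True)
class SlicewiseTransform:
    """Per-slice rigid translation plus isotropic scale.

    ``dx, dy`` is the translation that carries the subject slice centroid
    onto the template centroid; ``scale`` is the per-axis linear factor
    that matches the subject cord area to the template area
    (``scale = sqrt(template_area / subject_area)``).
    """

    dx: float
    dy: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")


def project_lesion_axial(study: LesionStudy) -> np.ndarray:
    """Collapse the lesion along the S-I axis into one composite axial image.

    A pixel (x, y) is lesioned iff any voxel (x, y, z) along the S-I axis
    is lesioned (logical union). An empty lesion yields an all-zero image.
    """
    return np.moveaxis(study.lesion_mask, study.si_axis, -1).any(axis=-1)


def compute_spared_fraction(projected_lesion: np.ndarray, region_weights: np.ndarray) -> float:
    """Percent of a region's weight lying outside the projected lesion.

    Returns ``100 * sum(weights over non-lesioned pixels) / sum(weights)``.
    """
    projected_lesion = np.asarray(projected_lesion, dtype=bool)
    w = np.asarray(region_weights, dtype=float)
    if w.shape != projected_lesion.shape:
        raise ValueError("projected lesion and region grids differ")
    total = w.sum()
    if total <= 0:
        raise ValueError("region has zero total weight; spared fraction undefined")
    return float(100.0 * w[~projected_lesion].sum() / total)


def spared_profile(study: LesionStudy, atlas: AxialRegionAtlas) -> SparedTissueProfile:
    """The five spared-tissue percentages (total + four regions).

    The total is scored against the whole-cord axial mask; the four
    regions against their weight maps. The study's axial grid must match
    the atlas grid (run :func:`slicewise_align` first if it does not).
    """
    if study.axial_shape != atlas.grid_shape:
        raise ValueError(
            f"study axial grid {study.axial_shape} does not match atlas "
            f"grid {atlas.grid_shape}"
        )
    proj = project_lesion_axial(study)
    total = compute_spared_fraction(proj, atlas.cord_mask_2d.astype(float))
    regional = {
        name: compute_spared_fraction(proj, atlas.region_weights[name])
        for name in REGIONS
    }
    return SparedTissueProfile(
        spared_total=total,
        spared_anterior=regional["anterior"],
        spared_posterior=regional["posterior"],
        spared_left=regional["left"],
        spared_right=regional["right"],
    )


def _slice_centroid_area(mask2d: np.ndarray) -> tuple[np.ndarray, float]:
    area = float(mask2d.sum())
    centroid = np.array(ndimage.center_of_mass(mask2d)) if area else np.zeros(2)
    return centroid, area


def slicewise_align(
    study: LesionStudy, template_cord_2d: np.ndarray
) -> tuple[LesionStudy, list[SlicewiseTransform]]:
    """Align each axial slice onto a template cord cross-section.

    Per slice, the cord centroid is translated onto the template centroid
    and the cord area matched by an isotropic scale; the same transform is
    applied to the lesion slice (nearest-neighbour resampling). Empty cord
    slices get the identity transform and are logged.

    This is a deliberately simple stand-in for slicewise template
    registration, intended for phantom testing; real nonlinear
    registration is out of scope and assumed done upstream.
    """
    template_cord_2d = np.asarray(template_cord_2d, dtype=bool)
    if template_cord_2d.shape != study.axial_shape:
        raise ValueError("template grid does not match study axial grid")
    t_centroid, t_area = _slice_centroid_area(template_cord_2d)
    if t_area == 0:
        raise ValueError("template cord mask is empty")

    cord = np.moveaxis(study.cord_mask, study.si_axis, -1)
    lesion = np.moveaxis(study.lesion_mask, study.si_axis, -1)
    new_cord = np.zeros_like(cord)
    new_lesion = np.zeros_like(lesion)
    transforms: list[SlicewiseTransform] = []

    for z in range(cord.shape[-1]):
        c_centroid, c_area = _slice_centroid_area(cord[..., z])
        if c_area == 0:
            logger.info("slice %d: empty cord slice, identity transform", z)
            transforms.append(SlicewiseTransform(0.0, 0.0, 1.0))
            continue
        s = float(np.sqrt(t_area / c_area))
        # output(x) = input(c_subject + (x - c_template) / s)
        matrix = np.eye(2) / s
        offset = c_centroid - t_centroid / s
        new_cord[..., z] = ndimage.affine_transform(
            cord[..., z].astype(np.uint8), matrix, offset=offset, order=0
        ).astype(bool)
        new_lesion[..., z] = ndimage.affine_transform(
            lesion[..., z].astype(np.uint8), matrix, offset=offset, order=0
        ).astype(bool)
        shift = t_centroid - c_centroid
        transforms.append(SlicewiseTransform(float(shift[0]), float(shift[1]), s))

    aligned = LesionStudy(
        cord_mask=np.moveaxis(new_cord, -1, study.si_axis),
        lesion_mask=np.moveaxis(new_lesion, -1, study.si_axis) & np.moveaxis(new_cord, -1, study.si_axis),
        voxel_size=study.voxel_size,
        si_axis=study.si_axis,
        subject_id=study.subject_id,
    )
    return aligned, transforms


# ---------------------------------------------------------------------------
# I/O

def save_study(study: LesionStudy, cord_path, lesion_path) -> None:
    """Write cord and lesion masks as NIfTI volumes (voxel size in the affine)."""
    affine = np.diag(list(study.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(study.cord_mask.astype(np.uint8), affine), str(cord_path))
    nib.save(nib.Nifti1Image(study.lesion_mask.astype(np.uint8), affine), str(lesion_path))


def load_study(cord_path, lesion_path, si_axis: int = 2, subject_id: str = "") -> LesionStudy:
    cord_img = nib.load(str(cord_path))
    lesion_img = nib.load(str(lesion_path))
    voxel = tuple(float(v) for v in cord_img.header.get_zooms()[:3])
    return LesionStudy(
        cord_mask=np.asarray(cord_img.dataobj) > 0.5,
        lesion_mask=np.asarray(lesion_img.dataobj) > 0.5,
        voxel_size=voxel,  # type: ignore[arg-type]
        si_axis=si_axis,
        subject_id=subject_id,
    )


def save_atlas(atlas: AxialRegionAtlas, directory) -> None:
    """Write the atlas as one NIfTI per region plus the whole-cord mask."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for name in REGIONS:
        img = nib.Nifti1Image(
            atlas.region_weights[name][..., None].astype(np.float32), affine
        )
        nib.save(img, str(directory / f"region_{name}.nii"))
    nib.save(
        nib.Nifti1Image(atlas.cord_mask_2d[..., None].astype(np.uint8), affine),
        str(directory / "cord_mask.nii"),
    )


def load_atlas(directory) -> AxialRegionAtlas:
    from pathlib import Path

    directory = Path(directory)
    weights = {}
    for name in REGIONS:
        img = nib.load(str(directory / f"region_{name}.nii"))
        weights[name] = np.asarray(img.dataobj, dtype=float)[..., 0]
    cord = np.asarray(nib.load(str(directory / "cord_mask.nii")).dataobj)[..., 0] > 0.5
    return AxialRegionAtlas(region_weights=weights, cord_mask_2d=cord)


def profiles_to_csv(profiles: dict[str, SparedTissueProfile], path) -> pd.DataFrame:
    """Write spared-tissue rows (percent) keyed by subject id; returns the frame."""
    rows = []
    for subject_id, prof in profiles.items():
        row = {"subject_id": subject_id}
        row.update(prof.as_dict())
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def plot_projection(study: LesionStudy, atlas: AxialRegionAtlas, path) -> None:
    """QC figure: projected lesion over the region atlas."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = project_lesion_axial(study)
    label = np.zeros(atlas.grid_shape)
    for k, name in enumerate(REGIONS, start=1):
        label[atlas.region_weights[name] > 0] = k
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(label.T, origin="lower", cmap="Pastel1", interpolation="nearest")
    ys, xs = np.nonzero(proj.T)
    ax.scatter(xs, ys, s=6, c="crimson", label="projected lesion")
    ax.set_title(study.subject_id or "projected lesion")
    ax.legend(loc="upper right", fontsize=7)
    fig.savefig(path, dpi=100)
    plt.close(fig)
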