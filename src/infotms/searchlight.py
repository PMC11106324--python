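"""Mask-constrained spherical searchlight decoding and target selection.

A sphere (default radius 3 voxels = 7.5 mm at 2.5 mm isotropic voxels) is
centered on every voxel of a constraint mask; the voxels inside the sphere and
the brain mask form the feature set for leave-one-run-out decoding, and the
mean cross-validated AUC is assigned to the center voxel.  The unthresholded
map's peak defines the individualized stimulation target, around which a 5 mm
ROI is drawn for subsequent pattern extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import ClassifierSpec, crossval_auc

__all__ = [
    "SphereSpec",
    "SearchlightMap",
    "TargetSelection",
    "sphere_offsets",
    "roi_offsets",
    "run_searchlight",
    "select_target",
]


@dataclass(frozen=True)
class SphereSpec:
    radius_voxels: float = 3.0

    def __post_init__(self) -> None:
        if self.radius_voxels < 0:
            raise ValueError("radius must be >= 0")


@dataclass
class SearchlightMap:
    score_volume: np.ndarray  # per-voxel AUC, NaN outside the constraint mask
    mask_used: np.ndarray
    spec: SphereSpec


@dataclass
class TargetSelection:
    center: tuple[int, int, int]
    score: float
    roi_mask: np.ndarray  # boolean volume
    roi_radius_mm: float


def sphere_offsets(radius_voxels: float) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius, in lexicographic order."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius_voxels))
    offs = [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if i * i + j * j + k * k <= radius_voxels * radius_voxels
    ]
    return np.array(sorted(offs), dtype=int).reshape(-1, 3)


def roi_offsets(radius_mm: float, voxel_size: float) -> np.ndarray:
    """Integer offsets whose centers lie strictly within ``radius_mm``."""
    r = int(np.floor(radius_mm / voxel_size))
    offs = [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if (i * i + j * j + k * k) * voxel_size**2 < radius_mm**2
    ]
    return np.array(sorted(offs), dtype=int).reshape(-1, 3)


def run_searchlight(
    trial_betas_volume: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    brain_mask: np.ndarray,
    constraint_mask: np.ndarray,
    spec: SphereSpec = SphereSpec(),
    classifier_spec: ClassifierSpec = ClassifierSpec(),
) -> SearchlightMap:
    """Decode every sphere centered on the constraint mask; map AUC to centers.

    ``trial_betas_volume``: (n_trials, nx, ny, nz) beta images.  Spheres are
    clipped at grid and brain-mask borders.  The returned map is
    unthresholded.
    """
    betas = np.asarray(trial_betas_volume, dtype=float)
    if betas.ndim != 4:
        raise ValueError("trial_betas_volume must be (n_trials, nx, ny, nz)")
    grid = betas.shape[1:]
    brain_mask = np.asarray(brain_mask, dtype=bool)
    constraint_mask = np.asarray(constraint_mask, dtype=bool)
    if brain_mask.shape != grid or constraint_mask.shape != grid:
        raise ValueError("masks must match the beta volume grid")
    offs = sphere_offsets(spec.radius_voxels)
    centers = np.argwhere(constraint_mask)
    if centers.size == 0:
        raise ValueError("constraint mask is empty")
    flat = betas.reshape(betas.shape[0], -1)
    brain_flat = brain_mask.ravel()
    score = np.full(grid, np.nan)
    for cx, cy, cz in centers:
        vox = offs + (cx, cy, cz)
        ok = ((vox >= 0) & (vox < grid)).all(axis=1)
        vox = vox[ok]
        idx = np.ravel_multi_index(vox.T, grid)
        idx = idx[brain_flat[idx]]
        if idx.size == 0:
            raise ValueError(f"empty sphere at center {(cx, cy, cz)}")
        res = crossval_auc(flat[:, idx], labels, runs, classifier_spec)
        score[cx, cy, cz] = res.mean_auc
    return SearchlightMap(score_volume=score, mask_used=constraint_mask, spec=spec)


def select_target(
    sl_map: SearchlightMap,
    brain_mask: np.ndarray | None = None,
    roi_radius_mm: float = 5.0,
    voxel_size: float = 2.5,
) -> TargetSelection:
    """Peak of the unthresholded map; ties break to the smallest linear index.

    The target ROI is the set of voxels within ``roi_radius_mm`` of the peak,
    intersected with the brain mask.
    """
    score = sl_map.score_volume
    if not np.isfinite(score).any():
        raise ValueError("searchlight map is empty")
    flat = score.ravel()
    flat = np.where(np.isnan(flat), -np.inf, flat)
    center_flat = int(np.argmax(flat))  # first (smallest linear index) maximum
    center = np.unravel_index(center_flat, score.shape)
    offs = roi_offsets(roi_radius_mm, voxel_size)
    vox = offs + center
    ok = ((vox >= 0) & (vox < score.shape)).all(axis=1)
    vox = vox[ok]
    roi = np.zeros(score.shape, dtype=bool)
    roi[tuple(vox.T)] = True
    if brain_mask is not None:
        roi &= np.asarray(brain_mask, dtype=bool)
    return TargetSelection(
        center=tuple(int(c) for c in center),
        score=float(score[center]),
        roi_mask=roi,
        roi_radius_mm=roi_radius_mm,
    )
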