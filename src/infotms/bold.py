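"""Synthetic 4D BOLD runs with planted, parameterized ground truth.

Each trial contributes an HRF-convolved 500 ms boxcar scaled by a per-voxel
amplitude.  Ground truth plants

* an action-goal (Go vs No-Go) multivoxel pattern in the ``goal_pattern``
  region, with class-mean distance ``(1 - alpha) * pattern_separation *
  noise_sd`` along a zero-mean unit direction (so univariate activation is
  independent of the attenuation factor alpha);
* a valence (Negative vs Positive) pattern in the ``valence_pattern`` region
  and, along a second orthogonal direction, inside ``goal_pattern`` — valence
  information is never attenuated, providing the specificity control;
* a seed region driven by the task plus a slow stochastic fluctuation, and a
  remote region coupled to the seed with baseline strength ``coupling_base``
  plus an extra ``(1 - alpha) * coupling_modulation`` during negative-cue
  processing (the psychophysiological interaction ground truth);
* AR(1) temporal noise, spatially smoothed with a Gaussian kernel and scaled
  to ``noise_sd`` marginal standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

from . import hrf as _hrf
from .design import NEGATIVE, NEUTRAL, POSITIVE, TrialEvent

__all__ = [
    "RegionLayout",
    "GroundTruthSpec",
    "PatternBasis",
    "BOLDRun",
    "default_layout",
    "make_pattern_basis",
    "synthesize_run",
    "save_run_nifti",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RegionLayout:
    """Voxel-grid geometry and role -> coordinate-set map.

    Roles: ``goal_pattern`` (action-goal coding cortex, inside
    ``anatomical_mask``), ``valence_pattern``, ``seed``, ``remote``,
    ``anatomical_mask`` (searchlight constraint) and ``brain_mask``.
    Regions are pairwise disjoint except ``anatomical_mask ⊇ goal_pattern``;
    ``brain_mask`` contains everything.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: float = 2.5
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = np.asarray(self.grid_shape)
        for role, coords in self.regions.items():
            coords = np.asarray(coords, dtype=int)
            if coords.ndim != 2 or coords.shape[1] != 3:
                raise ValueError(f"region {role!r} must be an (n, 3) coordinate array")
            if coords.size and ((coords < 0).any() or (coords >= shape).any()):
                raise ValueError(f"region {role!r} has coordinates outside the grid")
            self.regions[role] = coords
        exempt = {"anatomical_mask", "brain_mask"}
        flat = {
            role: set(map(tuple, self.regions[role]))
            for role in self.regions
            if role not in exempt
        }
        roles = sorted(flat)
        for i, a in enumerate(roles):
            for b in roles[i + 1 :]:
                if flat[a] & flat[b]:
                    raise ValueError(f"regions {a!r} and {b!r} overlap")
        if "goal_pattern" in self.regions and "anatomical_mask" in self.regions:
            anat = set(map(tuple, self.regions["anatomical_mask"]))
            if not set(map(tuple, self.regions["goal_pattern"])) <= anat:
                raise ValueError("goal_pattern must lie inside anatomical_mask")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def flat_indices(self, role: str) -> np.ndarray:
        coords = self.regions[role]
        if coords.size == 0:
            raise ValueError(f"region {role!r} is empty")
        return np.ravel_multi_index(coords.T, self.grid_shape)

    def mask_volume(self, role: str) -> np.ndarray:
        vol = np.zeros(self.grid_shape, dtype=bool)
        coords = self.regions[role]
        if coords.size:
            vol[tuple(coords.T)] = True
        return vol


def _ball(center: tuple[int, int, int], radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    offs = np.array(
        [
            (i, j, k)
            for i in range(-r, r + 1)
            for j in range(-r, r + 1)
            for k in range(-r, r + 1)
            if i * i + j * j + k * k <= radius * radius
        ]
    )
    return offs + np.asarray(center)


def _box(lo: tuple[int, int, int], hi: tuple[int, int, int]) -> np.ndarray:
    grid = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return grid.reshape(3, -1).T


def default_layout(grid_shape: tuple[int, int, int] = (14, 14, 10)) -> RegionLayout:
    """Compact layout: goal blob inside a box-shaped anatomical mask, plus
    valence, seed and remote blobs elsewhere in the grid."""
    nx, ny, nz = grid_shape
    if min(grid_shape) < 8:
        raise ValueError("grid too small for the default layout")
    anat = _box((2, ny // 2, 3), (min(8, nx - 2), min(ny - 1, ny // 2 + 6), min(8, nz - 2)))
    goal = _ball((5, ny // 2 + 3, 5), 2.0)
    valence = _ball((nx - 4, 3, nz // 2), 2.0)
    seed = _ball((nx - 4, ny - 4, nz // 2), 1.0)
    remote = _ball((3, 3, nz // 2), 1.0)
    brain = _box((0, 0, 0), grid_shape)
    return RegionLayout(
        grid_shape=grid_shape,
        regions={
            "goal_pattern": goal,
            "valence_pattern": valence,
            "seed": seed,
            "remote": remote,
            "anatomical_mask": anat,
            "brain_mask": brain,
        },
    )


@dataclass(frozen=True)
class GroundTruthSpec:
    """Simulation knobs for the planted signals.

    ``pattern_separation`` (d_sep) is the distance between the Go and No-Go
    mean pattern vectors in units of the BOLD noise SD; ``tms_attenuation``
    (alpha, 0-1) multiplies d_sep and the coupling modulation — alpha = 1
    simulates full cTBS-like abolition, alpha = 0 leaves patterns untouched.
    """

    pattern_separation: float = 0.6
    valence_separation: float = 0.6
    coupling_base: float = 0.5
    coupling_modulation: float = 0.8
    tms_attenuation: float = 0.0
    ar1_phi: float = 0.3
    spatial_fwhm: float = 2.5
    noise_sd: float = 1.0
    mean_response: float = 1.0
    seed_fluctuation_sd: float = 1.0
    noise_sd_jitter: float = 0.0
    spike_probability: float = 0.0
    spike_amplitude: float = 8.0

    def __post_init__(self) -> None:
        if self.pattern_separation < 0 or self.valence_separation < 0:
            raise ValueError("pattern separations must be >= 0")
        if not 0 <= self.tms_attenuation <= 1:
            raise ValueError("tms_attenuation must lie in [0, 1]")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.noise_sd < 0 or self.spatial_fwhm < 0 or self.noise_sd_jitter < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.spike_probability < 1:
            raise ValueError("spike_probability must lie in [0, 1)")


@dataclass(frozen=True)
class PatternBasis:
    """Per-subject pattern directions, fixed across runs and sessions.

    Each is a zero-sum unit vector over its region's voxels; the two goal-region
    directions (action goal and valence) are orthogonal.
    """

    goal_direction: np.ndarray
    goal_valence_direction: np.ndarray
    valence_direction: np.ndarray


def _zero_sum_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    v -= v.mean()
    return v / np.linalg.norm(v)


def make_pattern_basis(layout: RegionLayout, rng: np.random.Generator) -> PatternBasis:
    n_goal = len(layout.regions["goal_pattern"])
    n_val = len(layout.regions["valence_pattern"])
    if n_goal < 3 or n_val < 2:
        raise ValueError("pattern regions too small for zero-sum orthogonal directions")
    u_goal = _zero_sum_unit(rng, n_goal)
    w = _zero_sum_unit(rng, n_goal)
    w -= u_goal * (u_goal @ w)
    u_goal_val = w / np.linalg.norm(w)
    u_val = _zero_sum_unit(rng, n_val)
    return PatternBasis(u_goal, u_goal_val, u_val)


@dataclass
class BOLDRun:
    """One run's voxels x timepoints data plus geometry and ground truth."""

    data: np.ndarray  # (n_voxels, n_timepoints), C-ordered flat grid
    layout: RegionLayout
    tr: float
    design: list[TrialEvent]
    truth: GroundTruthSpec
    seed_used: int | None = None
    spike_volumes: list[int] = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def volume4d(self) -> np.ndarray:
        return self.data.reshape(*self.layout.grid_shape, self.n_timepoints)

    def region_data(self, role: str) -> np.ndarray:
        """(n_region_voxels, n_timepoints) view for one region role."""
        return self.data[self.layout.flat_indices(role)]


def _smoothing_norm(sigma_vox: float, grid_shape: tuple[int, int, int]) -> float:
    """L2 norm of the discrete Gaussian smoothing kernel (variance shrink factor)."""
    if sigma_vox <= 0:
        return 1.0
    size = min(int(8 * sigma_vox) * 2 + 1, *grid_shape)
    imp = np.zeros((size, size, size))
    imp[size // 2, size // 2, size // 2] = 1.0
    k = ndimage.gaussian_filter(imp, sigma_vox, mode="constant")
    return float(np.sqrt((k**2).sum()))


def _ar1_noise(
    rng: np.random.Generator, n_voxels: int, n_timepoints: int, phi: float
) -> np.ndarray:
    white = rng.standard_normal((n_voxels, n_timepoints))
    if phi == 0:
        return white
    # lfilter implements x_t = phi x_{t-1} + e_t; scale to unit marginal SD
    out = signal.lfilter([1.0], [1.0, -phi], white, axis=1)
    return out * np.sqrt(1.0 - phi**2)


def _valence_sign(trial: TrialEvent) -> float:
    return {NEGATIVE: 1.0, POSITIVE: -1.0, NEUTRAL: 0.0}[trial.valence]


def synthesize_run(
    run_design: list[TrialEvent],
    layout: RegionLayout,
    truth: GroundTruthSpec,
    hrf_params: _hrf.HRFParams = _hrf.HRFParams(),
    rng: np.random.Generator | None = None,
    basis: PatternBasis | None = None,
    n_timepoints: int = 222,
    tr: float = 2.0,
    oversampling: int = 20,
    attenuation_mask: np.ndarray | None = None,
) -> BOLDRun:
    """Forward-model one AGNG run into a (voxels, 222) BOLD array.

    ``basis`` fixes the planted pattern directions; if omitted, a layout-seeded
    deterministic basis is used so that repeated calls share directions.
    ``attenuation_mask`` (flat voxel indices) restricts the pattern attenuation
    to a sub-region — the in-silico analogue of stimulating the individualized
    site rather than the whole pattern-coding region; coupling modulation is
    always attenuated globally.  By default attenuation covers the full
    goal-pattern region.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not run_design:
        raise ValueError("run_design is empty")
    for role in ("goal_pattern", "valence_pattern", "seed", "remote", "brain_mask"):
        if role not in layout.regions or len(layout.regions[role]) == 0:
            raise ValueError(f"layout error: region {role!r} is missing or empty")
    if basis is None:
        basis = make_pattern_basis(layout, np.random.default_rng(layout.n_voxels))

    alpha = truth.tms_attenuation
    onsets = np.array([t.onset for t in run_design])
    duration = run_design[0].duration
    data = np.zeros((layout.n_voxels, n_timepoints))

    def regressor(sel_onsets: np.ndarray, amplitudes: np.ndarray | None = None) -> np.ndarray:
        return _hrf.event_regressor(
            sel_onsets, duration, n_timepoints, tr, hrf_params, oversampling, amplitudes
        )

    # --- planted multivoxel patterns -------------------------------------
    goal_idx = layout.flat_indices("goal_pattern")
    goal_sign = np.array([1.0 if t.action_goal == "Go" else -1.0 for t in run_design])
    val_sign = np.array([_valence_sign(t) for t in run_design])
    atten = np.full(goal_idx.size, 1.0 - alpha)
    if attenuation_mask is not None:
        masked = np.isin(goal_idx, np.asarray(attenuation_mask).ravel())
        atten = np.where(masked, 1.0 - alpha, 1.0)
    # separations are in noise-SD units; unit reference in the noiseless limit
    ref_sd = truth.noise_sd if truth.noise_sd > 0 else 1.0
    sep_goal = atten * truth.pattern_separation * ref_sd
    sep_val = truth.valence_separation * ref_sd

    x_all = regressor(onsets)
    x_goal = regressor(onsets, goal_sign)
    x_val = regressor(onsets, val_sign)

    data[goal_idx] += (
        truth.mean_response * x_all
        + np.outer(0.5 * sep_goal * basis.goal_direction, x_goal)
        + 0.5 * sep_val * np.outer(basis.goal_valence_direction, x_val)
    )
    val_idx = layout.flat_indices("valence_pattern")
    data[val_idx] += truth.mean_response * x_all + 0.5 * sep_val * np.outer(
        basis.valence_direction, x_val
    )

    # --- seed drive and valence-modulated coupling to the remote region --
    fluct = _ar1_noise(rng, 1, n_timepoints, 0.8)[0] * truth.seed_fluctuation_sd
    seed_signal = truth.mean_response * x_all + fluct
    data[layout.flat_indices("seed")] += seed_signal
    neg_onsets = onsets[val_sign > 0]
    psych_neg = (
        regressor(neg_onsets) if neg_onsets.size else np.zeros(n_timepoints)
    )
    coupling = truth.coupling_base + (1.0 - alpha) * truth.coupling_modulation * psych_neg
    data[layout.flat_indices("remote")] += coupling * seed_signal

    # --- AR(1) + spatially smooth noise ----------------------------------
    if truth.noise_sd > 0:
        noise = _ar1_noise(rng, layout.n_voxels, n_timepoints, truth.ar1_phi)
        sigma_vox = truth.spatial_fwhm * _FWHM_TO_SIGMA / layout.voxel_size
        if sigma_vox > 0:
            vol = noise.reshape(*layout.grid_shape, n_timepoints)
            vol = ndimage.gaussian_filter(vol, sigma=(sigma_vox,) * 3 + (0.0,))
            noise = vol.reshape(layout.n_voxels, n_timepoints)
            noise /= _smoothing_norm(sigma_vox, layout.grid_shape)
        scale = truth.noise_sd
        if truth.noise_sd_jitter > 0:
            scale = scale * np.exp(
                truth.noise_sd_jitter * rng.standard_normal(layout.n_voxels)
            )[:, None]
        data += noise * scale

    # --- optional motion-like spike volumes -------------------------------
    spike_volumes: list[int] = []
    if truth.spike_probability > 0:
        flags = rng.random(n_timepoints) < truth.spike_probability
        spike_volumes = [int(i) for i in np.flatnonzero(flags)]
        for i in spike_volumes:
            data[:, i] += truth.spike_amplitude * truth.noise_sd * rng.choice([-1.0, 1.0])

    if not np.isfinite(data).all():
        raise FloatingPointError("non-finite values in synthesized run")
    return BOLDRun(
        data=data,
        layout=layout,
        tr=tr,
        design=list(run_design),
        truth=truth,
        spike_volumes=spike_volumes,
    )


def save_run_nifti(run: BOLDRun, out_dir, prefix: str = "run") -> dict[str, str]:
    """Write the run and its region masks as NIfTI-1, plus a ground-truth JSON."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([run.layout.voxel_size] * 3 + [1.0])
    written: dict[str, str] = {}
    bold_path = out_dir / f"{prefix}_bold.nii"
    nib.save(nib.Nifti1Image(run.volume4d().astype(np.float32), affine), bold_path)
    written["bold"] = str(bold_path)
    for role in run.layout.regions:
        p = out_dir / f"{prefix}_mask-{role}.nii"
        nib.save(
            nib.Nifti1Image(run.layout.mask_volume(role).astype(np.uint8), affine), p
        )
        written[role] = str(p)
    sidecar = out_dir / f"{prefix}_truth.json"
    with open(sidecar, "w") as fh:
        json.dump(asdict(run.truth), fh, indent=2, sort_keys=True)
    written["truth"] = str(sidecar)
    return written
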