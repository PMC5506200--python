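"""Synthetic multi-subject ROI BOLD generator with planted coupling.

Emulates the study conditions downstream stages are tested against:
18 subjects, 28 motor regions, a ~390 s alternating block design at
TR = 2 s, with controllable homotopic / intra-hemispheric / other
inter-regional coupling, HRF-convolved task modulation, low-frequency
drift, motion-correlated nuisance signal, and white measurement noise.

The correlated noise is produced by applying the matrix square root of the
target correlation matrix to white Gaussian noise, so the population
correlation of the noise component equals the requested structure exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .design import TaskParadigm, condition_regressor, default_paradigm
from .nodes import NodeSet, default_nodeset

__all__ = [
    "CouplingModel",
    "SubjectTimeSeries",
    "InvalidModelError",
    "InvalidGeometryError",
    "build_covariance",
    "simulate_subject",
    "simulate_group",
    "render_volumes",
    "default_nodeset",
]


class InvalidModelError(ValueError):
    """The requested coupling structure has no valid correlation matrix."""


class InvalidGeometryError(ValueError):
    """Node spheres overlap or fall outside the voxel grid."""


# Fraction of noise_sd injected as independent white measurement noise on
# top of the structured noise component.
_WHITE_FRACTION = 0.25

# Task gain multipliers by laterality of a region relative to the moved
# foot: motor responses are strongest contralaterally, present but weaker
# ipsilaterally, intermediate for midline structures.
_GAIN_CONTRA = 1.0
_GAIN_IPSI = 0.5
_GAIN_MIDLINE = 0.75

_PSD_FLOOR = 1e-8
_REPAIR_TOL = 0.1  # max entrywise drift a PSD repair may introduce


@dataclass(frozen=True)
class CouplingModel:
    """Planted inter-regional coupling plus nuisance amplitudes.

    ``r_homotopic`` / ``r_intra`` / ``r_other`` are the target noise
    correlations for homotopic pairs, same-hemisphere pairs, and everything
    else.  Midline regions carry ``r_intra`` toward both hemispheres (a
    midline structure such as the cerebellar vermis interacts with both
    sides).  Amplitudes are in units of the noise standard deviation.
    """

    r_homotopic: float = 0.6
    r_intra: float = 0.3
    r_other: float = 0.1
    task_gain: float = 0.5
    noise_sd: float = 1.0
    drift_amp: float = 0.5
    motion_coupling: float = 0.3

    def __post_init__(self) -> None:
        for name in ("r_homotopic", "r_intra", "r_other"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.task_gain < 0:
            raise ValueError("task_gain must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.drift_amp < 0:
            raise ValueError("drift_amp must be >= 0")
        if self.motion_coupling < 0:
            raise ValueError("motion_coupling must be >= 0")


@dataclass
class SubjectTimeSeries:
    """Region x scan BOLD matrix with its TR and nuisance confound table."""

    data: np.ndarray  # (n_regions, n_scans)
    tr_s: float
    confounds: pd.DataFrame  # (n_scans, 8): 6 motion + wm + csf
    subject_id: str = "sub-01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D region x scan matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if len(self.confounds) != self.data.shape[1]:
            raise ValueError(
                f"confound rows ({len(self.confounds)}) must match scan "
                f"count ({self.data.shape[1]})"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]


def build_covariance(
    nodes: NodeSet, model: CouplingModel
) -> tuple[np.ndarray, dict]:
    """Target region-correlation matrix for the structured noise component.

    Returns the (possibly PSD-repaired) correlation matrix and a metadata
    dict recording whether repair was applied.  Raises
    :class:`InvalidModelError` if repair would move any entry by more than
    0.1 from its requested value.
    """
    n = nodes.n_nodes
    C = np.full((n, n), model.r_other)
    hemi = nodes.hemisphere
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if hemi[i] == hemi[j] or "M" in (hemi[i], hemi[j]):
                C[i, j] = model.r_intra
    for i, j in nodes.pair_map:
        C[i, j] = C[j, i] = model.r_homotopic
    np.fill_diagonal(C, 1.0)

    eigvals = np.linalg.eigvalsh(C)
    meta = {"repaired": False, "min_eigenvalue": float(eigvals[0])}
    if eigvals[0] < -1e-10:
        w, V = np.linalg.eigh(C)
        w = np.clip(w, _PSD_FLOOR, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        if np.max(np.abs(R - C)) > _REPAIR_TOL:
            raise InvalidModelError(
                "coupling structure is not positive semi-definite and PSD "
                f"repair moves entries by {np.max(np.abs(R - C)):.3f} > {_REPAIR_TOL}"
            )
        C = R
        meta["repaired"] = True
    return C, meta


def _condition_gains(nodes: NodeSet, condition: str) -> np.ndarray:
    """Per-region task gain for a movement condition (contralateral max)."""
    contra = {"left": "R", "right": "L"}.get(condition)
    gains = np.empty(nodes.n_nodes)
    for i, h in enumerate(nodes.hemisphere):
        if h == "M" or contra is None:
            gains[i] = _GAIN_MIDLINE
        elif h == contra:
            gains[i] = _GAIN_CONTRA
        else:
            gains[i] = _GAIN_IPSI
    return gains


def _motion_traces(rng: np.random.Generator, n_scans: int) -> np.ndarray:
    """Six smoothed-random-walk motion traces (3 translation, 3 rotation)."""
    steps = rng.standard_normal((6, n_scans))
    walks = np.cumsum(steps, axis=1)
    walks = gaussian_filter1d(walks, sigma=3.0, axis=1)
    walks -= walks.mean(axis=1, keepdims=True)
    sd = walks.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return walks / sd

def _slow_series(rng: np.random.Generator, n_scans: int, k: int = 1) -> np.ndarray:
    """Low-frequency random series (WM / CSF nuisance stand-ins)."""
    x = gaussian_filter1d(rng.standard_normal((k, n_scans)), sigma=10.0, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


_CONFOUND_COLUMNS = [
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "wm", "csf",
]


def simulate_subject(
    nodes: NodeSet,
    model: CouplingModel,
    paradigm: TaskParadigm,
    seed: int,
    subject_id: str = "sub-01",
) -> SubjectTimeSeries:
    """Simulate one subject's region x scan BOLD matrix.

    The signal is the sum of HRF-convolved task responses (laterality
    weighted), correlated Gaussian noise with the :func:`build_covariance`
    structure, slow sinusoidal+linear drift below 0.008 Hz, motion- and
    WM/CSF-coupled nuisance, and white noise.  The returned confound table
    contains exactly the motion and WM/CSF series that were injected.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    n = nodes.n_nodes
    n_scans = paradigm.n_scans
    t = np.arange(n_scans) * paradigm.tr_s

    C, _ = build_covariance(nodes, model)
    w, V = np.linalg.eigh(C)
    sqrtC = (V * np.sqrt(np.clip(w, 0, None))) @ V.T
    data = model.noise_sd * (sqrtC @ rng.standard_normal((n, n_scans)))
    data += _WHITE_FRACTION * model.noise_sd * rng.standard_normal((n, n_scans))

    for cond in paradigm.conditions:
        reg = condition_regressor(paradigm, cond).raw
        data += model.task_gain * np.outer(_condition_gains(nodes, cond), reg)

    if model.drift_amp > 0:
        freqs = rng.uniform(0.002, 0.006, size=n)
        phases = rng.uniform(0, 2 * np.pi, size=n)
        drift = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        drift += rng.uniform(-1, 1, size=(n, 1)) * np.linspace(-1, 1, n_scans)
        data += model.drift_amp * drift

    motion = _motion_traces(rng, n_scans)
    wmcsf = _slow_series(rng, n_scans, k=2)
    nuisance = np.vstack([motion, wmcsf])  # (8, n_scans)
    if model.motion_coupling > 0:
        loadings = rng.uniform(-1, 1, size=(n, 8)) / np.sqrt(8)
        data += model.motion_coupling * (loadings @ nuisance)

    confounds = pd.DataFrame(nuisance.T, columns=_CONFOUND_COLUMNS)
    return SubjectTimeSeries(
        data=data, tr_s=paradigm.tr_s, confounds=confounds, subject_id=subject_id
    )


def simulate_group(
    nodes: NodeSet | None = None,
    model: CouplingModel | None = None,
    paradigm: TaskParadigm | None = None,
    n_subjects: int = 18,
    seed: int = 0,
) -> list[SubjectTimeSeries]:
    """Simulate a cohort (default 18 subjects) with independent noise but a
    shared coupling model; per-subject seeds are spawned from ``seed``."""
    nodes = nodes if nodes is not None else default_nodeset()
    model = model if model is not None else CouplingModel()
    paradigm = paradigm if paradigm is not None else default_paradigm()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    return [
        simulate_subject(
            nodes, model, paradigm, int(s), subject_id=f"sub-{k + 1:02d}"
        )
        for k, s in enumerate(child_seeds)
    ]


def render_volumes(
    ts: SubjectTimeSeries,
    nodes: NodeSet,
    radius_mm: float = 3.0,
    voxel_mm: float = 2.0,
    margin_mm: float = 8.0,
    background_sd: float = 0.05,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    affine: np.ndarray | None = None,
):
    """Paint each region's time course into a sphere of voxels, returning a
    4D NIfTI image whose affine maps voxel indices to MNI millimeters.

    Voxel membership uses the voxel-center-in-sphere rule, the same rule the
    extraction stage applies, so a render -> extract round trip recovers each
    series up to the added background noise.
    """
    import nibabel as nib

    centers = nodes.centers_mm
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 2 * radius_mm:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise InvalidGeometryError(
            f"node spheres overlap: {nodes.labels[i]} and {nodes.labels[j]} "
            f"are {d[i, j]:.1f} mm apart (radius {radius_mm} mm)"
        )

    if shape is None or affine is None:
        lo = centers.min(axis=0) - margin_mm
        hi = centers.max(axis=0) + margin_mm
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / voxel_mm)) + 1 for k in range(3))
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = lo
    else:
        shape = tuple(int(s) for s in shape)
        affine = np.asarray(affine, dtype=float)

    rng = np.random.default_rng(seed)
    vol = rng.normal(0.0, background_sd, size=shape + (ts.n_scans,))
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    homog = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
    vox_mm = homog @ affine.T[:, :3]
    for r, c in enumerate(centers):
        mask = np.linalg.norm(vox_mm - c[None, None, None, :], axis=-1) <= radius_mm
        if not mask.any():
            raise InvalidGeometryError(
                f"sphere for node {nodes.labels[r]} contains no voxel centers"
            )
        vol[mask, :] += ts.data[r][None, :]
    return nib.Nifti1Image(vol.astype(np.float32), affine)
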