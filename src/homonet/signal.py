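"""ROI time-series extraction and denoising.

The fixed order of operations is extraction -> bandpass -> nuisance
regression.  Confounds are bandpassed with the same filter before being
regressed out, so the regression cannot reintroduce frequencies the filter
removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "RoiSpec",
    "EmptyRoiError",
    "CollinearityError",
    "InvalidBandError",
    "extract_roi_timeseries",
    "bandpass",
    "regress_nuisance",
    "denoise",
]


class EmptyRoiError(ValueError):
    """A node's sphere contains no voxel centers."""


class CollinearityError(ValueError):
    """The nuisance design matrix is rank deficient."""


class InvalidBandError(ValueError):
    """The requested passband is infeasible at this TR."""


@dataclass(frozen=True)
class RoiSpec:
    """Spherical ROIs: one MNI center per node, common radius (default 3 mm)."""

    centers_mm: np.ndarray  # (n, 3)
    radius_mm: float = 3.0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers_mm, dtype=float))
        object.__setattr__(self, "centers_mm", centers)
        if self.radius_mm <= 0:
            raise ValueError(f"radius_mm must be positive, got {self.radius_mm}")
        if not np.all(np.isfinite(centers)):
            raise ValueError("centers_mm contains non-finite values")


def extract_roi_timeseries(image, roi: RoiSpec) -> np.ndarray:
    """Mean time course per spherical ROI from a 4D image.

    A voxel belongs to a sphere when its center lies within ``radius_mm``
    (Euclidean, millimeter space) of the node center.  Returns a
    region x scan matrix.  Raises :class:`EmptyRoiError`, naming the node,
    if any sphere covers no voxel center.
    """
    affine = np.asarray(image.affine, dtype=float)
    data = np.asarray(image.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data.shape}")
    shape = data.shape[:3]
    inv = np.linalg.inv(affine)

    out = np.empty((len(roi.centers_mm), data.shape[3]))
    for r, c in enumerate(roi.centers_mm):
        # candidate voxel box around the center, then exact distance test
        c_vox = (inv @ np.append(c, 1.0))[:3]
        span = roi.radius_mm / np.min(np.abs(np.diag(affine)[:3])) + 1
        lo = np.maximum(np.floor(c_vox - span).astype(int), 0)
        hi = np.minimum(np.ceil(c_vox + span).astype(int) + 1, shape)
        if np.any(lo >= hi):
            _raise_empty(roi, r)
        ii, jj, kk = np.meshgrid(
            *(np.arange(lo[k], hi[k]) for k in range(3)), indexing="ij"
        )
        homog = np.stack(
            [ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)], axis=0
        )
        mm = (affine @ homog)[:3].T
        inside = np.linalg.norm(mm - c[None, :], axis=1) <= roi.radius_mm
        if not inside.any():
            _raise_empty(roi, r)
        vi, vj, vk = ii.ravel()[inside], jj.ravel()[inside], kk.ravel()[inside]
        out[r] = data[vi, vj, vk, :].mean(axis=0)
    return out


def _raise_empty(roi: RoiSpec, r: int) -> None:
    name = roi.labels[r] if roi.labels else f"node {r}"
    raise EmptyRoiError(f"sphere for {name} contains no voxel centers")


def bandpass(
    ts: np.ndarray,
    tr_s: float,
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the scan axis.

    ``ts`` is region x scan.  Forward-backward filtering (no phase lag)
    with an order-``order`` Butterworth design; DC is removed, the passband
    gain stays within 10% and power at twice the band edges is attenuated
    by at least a factor of 10.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    nyq = 0.5 / tr_s
    if not 0 <= low_hz < high_hz < nyq:
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz infeasible at TR {tr_s} s "
            f"(Nyquist {nyq} Hz)"
        )
    if ts.shape[1] < 16:
        raise ValueError(f"need at least 16 scans, got {ts.shape[1]}")
    sos = sps.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_s, output="sos"
    )
    ntaps = 2 * sos.shape[0] + 1
    padlen = min(3 * ntaps, ts.shape[1] - 1)
    return sps.sosfiltfilt(sos, ts, axis=1, padlen=padlen)


def _design_matrix(
    confounds: pd.DataFrame, add_derivatives: bool, derivative_columns
) -> tuple[np.ndarray, list[str]]:
    cols = list(confounds.columns)
    X = [np.ones(len(confounds))]
    names = ["intercept"]
    for c in cols:
        X.append(confounds[c].to_numpy(dtype=float))
        names.append(str(c))
    if add_derivatives:
        if derivative_columns is None:
            derivative_columns = [
                c for c in cols if any(k in str(c).lower() for k in ("wm", "csf"))
            ]
        for c in derivative_columns:
            d = np.gradient(confounds[c].to_numpy(dtype=float))
            X.append(d)
            names.append(f"{c}_derivative")
    return np.column_stack(X), names


def regress_nuisance(
    ts: np.ndarray,
    confounds: pd.DataFrame,
    add_derivatives: bool = True,
    derivative_columns: list[str] | None = None,
) -> np.ndarray:
    """Residualize each region's series against the nuisance design.

    The design is [intercept, confound columns, first derivatives of the
    WM/CSF columns] (derivatives of other columns only if listed in
    ``derivative_columns``).  Residuals are orthogonal to every design
    column.  Raises :class:`CollinearityError` naming the offending columns
    when the design is rank deficient.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if len(confounds) != ts.shape[1]:
        raise ValueError(
            f"confound rows ({len(confounds)}) do not match scans ({ts.shape[1]})"
        )
    X, names = _design_matrix(confounds, add_derivatives, derivative_columns)
    # incremental rank check to name the offending columns
    offending = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for k in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, k]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            offending.append(names[k])
    if offending:
        raise CollinearityError(
            f"rank-deficient nuisance design; offending columns: {offending}"
        )
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def denoise(
    ts: np.ndarray,
    confounds: pd.DataFrame,
    tr_s: float,
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    add_derivatives: bool = True,
) -> np.ndarray:
    """Bandpass then nuisance-regress a region x scan matrix.

    Confounds are bandpassed with the same filter before regression; the
    intercept and WM/CSF derivatives are built from the filtered columns.
    """
    filtered = bandpass(ts, tr_s, low_hz, high_hz)
    conf_filtered = pd.DataFrame(
        bandpass(confounds.to_numpy(dtype=float).T, tr_s, low_hz, high_hz).T,
        columns=confounds.columns,
    )
    return regress_nuisance(filtered, conf_filtered, add_derivatives=add_derivatives)
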