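"""Condition-specific weighted connectivity and group edge inference.

Per subject, edge weights are weighted Pearson correlations of denoised
region time courses, the per-scan weights being the HRF-convolved block
regressor of the condition (clipped at zero).  Subject correlations are
Fisher-transformed (z = atanh r) and tested edgewise across subjects with
a one-sample two-sided t-test (random-effects analysis); the edge set is
thresholded at P < 0.05 after Benjamini-Hochberg FDR correction, and the
surviving positive-mean edges carry weight W = tanh(mean z), the
back-transformed group correlation in (0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubjectConnectivity",
    "GroupNetwork",
    "DegenerateSeriesError",
    "weighted_correlation",
    "fisher_z",
    "subject_connectivity",
    "group_edge_test",
    "fdr_bh",
    "build_group_network",
]


class DegenerateSeriesError(ValueError):
    """A series has zero weighted variance; its correlation is undefined."""


@dataclass
class SubjectConnectivity:
    """Symmetric matrix of Fisher-transformed correlations for one subject."""

    z: np.ndarray
    condition: str
    subject_id: str = "sub-01"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be a square matrix")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z contains non-finite entries")
        np.fill_diagonal(z, 0.0)
        self.z = z


@dataclass
class GroupNetwork:
    """Thresholded group network: weights plus per-edge statistics.

    ``W[i, j] > 0`` exactly on edges whose group mean Fisher score is
    positive and survives FDR.  Significant negative-mean edges are kept in
    ``negative_mask`` for transparency but excluded from ``W``.
    """

    W: np.ndarray
    mean_z: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray  # bool, FDR-surviving (any sign)
    negative_mask: np.ndarray  # bool, FDR-surviving with negative mean
    n_subjects: int
    condition: str
    flags: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, 1) > 0))


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with non-negative per-scan weights.

    Moments are computed with the weights normalized to sum to one; with
    constant weights this reduces to the ordinary Pearson coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y and w must have identical shapes")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.count_nonzero(w) < 3:
        raise ValueError("need at least 3 scans with positive weight")
    wn = w / w.sum()
    mx, my = wn @ x, wn @ y
    cov = wn @ ((x - mx) * (y - my))
    vx = wn @ ((x - mx) ** 2)
    vy = wn @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise DegenerateSeriesError("zero weighted variance")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def fisher_z(r, clip: bool = False):
    """Fisher transform z = 1/2 ln((1+r)/(1-r)) = atanh(r).

    With ``clip=True``, |r| is first clipped to 1 - 1e-7 (for degenerate
    perfectly correlated series); otherwise |r| >= 1 raises.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    elif np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1 is outside the Fisher transform domain")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def subject_connectivity(
    ts: np.ndarray,
    weights: np.ndarray,
    condition: str = "task",
    subject_id: str = "sub-01",
) -> SubjectConnectivity:
    """All-pairs weighted correlation of a denoised region x scan matrix,
    Fisher transformed (perfect correlations clipped at 1 - 1e-7)."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape != (ts.shape[1],):
        raise ValueError(
            f"weights must have one entry per scan ({ts.shape[1]}), got {w.shape}"
        )
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.count_nonzero(w) < 3:
        raise ValueError("need at least 3 scans with positive weight")
    wn = w / w.sum()
    centered = ts - (ts @ wn)[:, None]
    cov = (centered * wn[None, :]) @ centered.T
    var = np.diag(cov).copy()
    if np.any(var <= 0):
        bad = int(np.argmax(var <= 0))
        raise DegenerateSeriesError(f"zero weighted variance at region {bad}")
    r = cov / np.sqrt(np.outer(var, var))
    r = np.clip(r, -1.0, 1.0)
    z = fisher_z(r, clip=True)
    np.fill_diagonal(z, 0.0)
    return SubjectConnectivity(z=z, condition=condition, subject_id=subject_id)


def _check_stack(subjects: list[SubjectConnectivity]) -> np.ndarray:
    if len(subjects) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(subjects)}")
    conds = {s.condition for s in subjects}
    if len(conds) > 1:
        raise ValueError(f"subjects mix conditions: {sorted(conds)}")
    shapes = {s.z.shape for s in subjects}
    if len(shapes) > 1:
        raise ValueError(f"subjects mix node counts: {sorted(shapes)}")
    return np.stack([s.z for s in subjects])


def group_edge_test(
    subjects: list[SubjectConnectivity],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edgewise one-sample two-sided t-test of Fisher scores against zero.

    Returns (mean_z, t, p) as full symmetric matrices, df = n_subjects - 1.
    Edges with zero across-subject variance but nonzero mean get p = 0 with
    a warning (the test statistic diverges); zero-mean zero-variance edges
    get t = 0, p = 1.
    """
    zs = _check_stack(subjects)
    n = zs.shape[0]
    mean_z = zs.mean(axis=0)
    sd = zs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_z / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    if np.any(zero_var & (mean_z != 0)):
        warnings.warn(
            "edges with zero across-subject variance and nonzero mean: "
            "p set to 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        t[zero_var & (mean_z != 0)] = np.inf * np.sign(mean_z[zero_var & (mean_z != 0)])
        p[zero_var & (mean_z != 0)] = 0.0
    t[zero_var & (mean_z == 0)] = 0.0
    p[zero_var & (mean_z == 0)] = 1.0
    np.fill_diagonal(t, 0.0)
    np.fill_diagonal(p, 1.0)
    return mean_z, t, p


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if q <= 0:
        return np.zeros(p.shape, dtype=bool)
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def build_group_network(
    subjects: list[SubjectConnectivity],
    q: float = 0.05,
    weight_convention: str = "tanh-mean-z",
) -> GroupNetwork:
    """Threshold the group random-effects test into a weighted network.

    FDR correction runs over the n(n-1)/2 unique edges.  Surviving
    positive-mean edges carry W = tanh(mean z) (or mean z itself under the
    ``"mean-z"`` convention); surviving negative-mean edges are recorded in
    ``negative_mask`` but excluded from W.
    """
    if weight_convention not in ("tanh-mean-z", "mean-z"):
        raise ValueError(f"unknown weight convention {weight_convention!r}")
    mean_z, t, p = group_edge_test(subjects)
    n = mean_z.shape[0]
    iu = np.triu_indices(n, k=1)
    mask_flat = fdr_bh(p[iu], q=q)

    # BH-adjusted q-values for reporting
    if iu[0].size:
        _, q_flat, *_ = multipletests(p[iu], alpha=max(q, 1e-12), method="fdr_bh")
    else:
        q_flat = np.zeros(0)
    q_value = np.ones_like(p)
    q_value[iu] = q_flat
    q_value.T[iu] = q_flat

    significant = np.zeros((n, n), dtype=bool)
    significant[iu] = mask_flat
    significant |= significant.T

    positive = significant & (mean_z > 0)
    negative = significant & (mean_z < 0)
    W = np.zeros((n, n))
    src = np.tanh(mean_z) if weight_convention == "tanh-mean-z" else mean_z
    W[positive] = src[positive]
    np.fill_diagonal(W, 0.0)

    return GroupNetwork(
        W=W,
        mean_z=mean_z,
        t_stat=t,
        p_value=p,
        q_value=q_value,
        significant=significant,
        negative_mask=negative,
        n_subjects=len(subjects),
        condition=subjects[0].condition,
        flags={"weight_convention": weight_convention},
    )
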