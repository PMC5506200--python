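"""Block-design task paradigm and HRF-convolved condition regressors.

The motor paradigm alternates left- and right-foot movement blocks separated
by rest.  Condition regressors are boxcars convolved with a canonical
double-gamma hemodynamic response function (HRF) sampled at the repetition
time (TR); the clipped, non-negative version of a regressor serves as the
per-scan weight vector for condition-specific weighted correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Block",
    "TaskParadigm",
    "HrfKernel",
    "ConditionRegressor",
    "default_paradigm",
    "canonical_hrf",
    "condition_regressor",
]


@dataclass(frozen=True)
class Block:
    """One task block: onset and duration in seconds plus a condition label."""

    onset_s: float
    duration_s: float
    condition: str


@dataclass(frozen=True)
class TaskParadigm:
    """An ordered list of task blocks over a fixed-duration run.

    Parameters
    ----------
    blocks:
        Task blocks (rest is implicit: any time not covered by a block).
    total_duration_s:
        Run length in seconds; must cover every block.
    tr_s:
        Repetition time (seconds per scan).
    metadata:
        Free-form annotations (e.g. the nominal experiment duration when it
        differs from the sum of the stated segments).
    """

    blocks: tuple[Block, ...]
    total_duration_s: float
    tr_s: float
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        for b in self.blocks:
            if b.onset_s < 0:
                raise ValueError(f"block onset must be >= 0, got {b.onset_s}")
            if b.duration_s <= 0:
                raise ValueError(f"block duration must be > 0, got {b.duration_s}")
            if b.onset_s + b.duration_s > self.total_duration_s + 1e-9:
                raise ValueError(
                    f"block at {b.onset_s}s (+{b.duration_s}s) exceeds "
                    f"total duration {self.total_duration_s}s"
                )
        # blocks of the same condition must not overlap
        by_cond: dict[str, list[Block]] = {}
        for b in self.blocks:
            by_cond.setdefault(b.condition, []).append(b)
        for cond, bs in by_cond.items():
            bs = sorted(bs, key=lambda b: b.onset_s)
            for a, b in zip(bs, bs[1:]):
                if a.onset_s + a.duration_s > b.onset_s + 1e-9:
                    raise ValueError(f"overlapping blocks in condition {cond!r}")

    @property
    def n_scans(self) -> int:
        return int(round(self.total_duration_s / self.tr_s))

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.blocks:
            if b.condition not in seen:
                seen.append(b.condition)
        return tuple(seen)


@dataclass(frozen=True)
class HrfKernel:
    """Sampled HRF: unitless amplitude per time step of ``dt_s`` seconds."""

    samples: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt_s <= 0:
            raise ValueError(f"dt_s must be positive, got {self.dt_s}")
        if samples.size < 1:
            raise ValueError("HRF kernel must have at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("HRF kernel contains non-finite values")
        if samples.sum() * self.dt_s <= 0:
            raise ValueError("HRF kernel must integrate to a positive value")


@dataclass(frozen=True)
class ConditionRegressor:
    """HRF-convolved condition regressor sampled once per scan.

    ``raw`` is the plain convolution output (it can dip below zero in the
    HRF undershoot); ``weights`` is the same vector clipped at zero, the
    form used as per-scan weights in weighted correlation.
    """

    raw: np.ndarray
    condition: str
    tr_s: float

    @property
    def weights(self) -> np.ndarray:
        return np.clip(self.raw, 0.0, None)


# --- default motor paradigm -------------------------------------------------

TASK_S = 16.0
REST_S = 20.0
INITIAL_REST_S = 26.0
FINAL_REST_S = 22.0
N_CYCLES = 10
NOMINAL_DURATION_S = 396.0  # the nominal experiment length; the stated
# segments total 388 s, so the paradigm is built from the segments and the
# nominal figure is kept as metadata only.


def default_paradigm(tr_s: float = 2.0, first_condition: str = "left") -> TaskParadigm:
    """Alternating left/right foot-movement block paradigm.

    Ten 16 s movement blocks separated by 20 s rests, preceded by a 26 s
    initial rest and followed by a 22 s final rest.  Conditions alternate
    starting from ``first_condition`` ("left" by default, matching the
    odd-numbered-subject sequence).
    """
    other = "right" if first_condition == "left" else "left"
    blocks = []
    onset = INITIAL_REST_S
    for k in range(N_CYCLES):
        cond = first_condition if k % 2 == 0 else other
        blocks.append(Block(onset_s=onset, duration_s=TASK_S, condition=cond))
        onset += TASK_S
        if k < N_CYCLES - 1:
            onset += REST_S
    total = onset + FINAL_REST_S
    return TaskParadigm(
        blocks=tuple(blocks),
        total_duration_s=total,
        tr_s=tr_s,
        metadata={
            "nominal_duration_s": NOMINAL_DURATION_S,
            "lead_in_s": 4.0,
            "note": "total derived from segment durations; nominal 396 s kept as metadata",
        },
    )


# --- canonical HRF ----------------------------------------------------------

_HRF_SUPPORT_S = 32.0
_PEAK_DELAY_S = 6.0
_UNDERSHOOT_DELAY_S = 16.0
_DISPERSION_S = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def _double_gamma(t: np.ndarray) -> np.ndarray:
    """Difference of two gamma densities (peak ~5 s, undershoot ~15 s)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gamma_pdf(x: np.ndarray, shape: float, scale: float) -> np.ndarray:
        return np.exp(
            (shape - 1) * np.log(x)
            - x / scale
            - gammaln(shape)
            - shape * np.log(scale)
        )

    peak = gamma_pdf(tp, _PEAK_DELAY_S / _DISPERSION_S, _DISPERSION_S)
    under = gamma_pdf(tp, _UNDERSHOOT_DELAY_S / _DISPERSION_S, _DISPERSION_S)
    out[pos] = peak - _UNDERSHOOT_RATIO * under
    return out


def canonical_hrf(dt_s: float) -> HrfKernel:
    """Canonical double-gamma HRF sampled every ``dt_s`` seconds over 32 s.

    Peak amplitude is normalized to 1 on a dense reference grid so that the
    kernel's scale does not depend on the sampling step.
    """
    if not 0 < dt_s <= 4:
        raise ValueError(f"dt_s must be in (0, 4], got {dt_s}")
    dense = _double_gamma(np.arange(0, _HRF_SUPPORT_S + 1e-9, 0.001))
    scale = dense.max()
    t = np.arange(0, _HRF_SUPPORT_S + 1e-9, dt_s)
    return HrfKernel(samples=_double_gamma(t) / scale, dt_s=dt_s)


def condition_regressor(
    paradigm: TaskParadigm,
    condition: str,
    hrf: HrfKernel | None = None,
) -> ConditionRegressor:
    """Boxcar-convolve the HRF for one condition, sampled per scan.

    The HRF time step must equal the TR or an integer subdivision of it; the
    boxcar is built at the HRF resolution, convolved, then read out at scan
    onsets and truncated to ``paradigm.n_scans`` samples.
    """
    if condition not in paradigm.conditions:
        raise KeyError(
            f"condition {condition!r} not present in paradigm "
            f"(has {list(paradigm.conditions)})"
        )
    if hrf is None:
        hrf = canonical_hrf(paradigm.tr_s)
    sub = paradigm.tr_s / hrf.dt_s
    if abs(sub - round(sub)) > 1e-9 or sub < 1 - 1e-9:
        raise ValueError(
            f"hrf.dt_s ({hrf.dt_s}) must equal the TR ({paradigm.tr_s}) "
            "or an integer subdivision of it"
        )
    sub = int(round(sub))
    n_fine = paradigm.n_scans * sub
    t_fine = np.arange(n_fine) * hrf.dt_s
    boxcar = np.zeros(n_fine)
    for b in paradigm.blocks:
        if b.condition == condition:
            boxcar[(t_fine >= b.onset_s - 1e-9) & (t_fine < b.onset_s + b.duration_s - 1e-9)] = 1.0
    conv = np.convolve(boxcar, hrf.samples)[:n_fine]
    return ConditionRegressor(raw=conv[::sub].copy(), condition=condition, tr_s=paradigm.tr_s)
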