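"""Plate-reader trace containers and processing.

Raw kinetic reads come off the instrument as relative fluorescence units
(RFU) per well.  Analysis requires three steps before any fitting:
background subtraction against negative-control wells, conversion of RFU to
uM of cleaved reporter using the fully-processed-control plateau, and
initial-velocity extraction by the maximum-slope sliding-window method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "KineticTrace",
    "ConcentrationTrace",
    "VelocityEstimate",
    "FmaxEstimate",
    "subtract_background",
    "estimate_fmax",
    "to_concentration",
    "max_slope_velocity",
    "trim_settling",
    "endpoint_signal",
]

#: Recognised well roles.  ``sample`` wells contain the full coupled
#: reaction; ``negative_tc`` the intact reporter without deaminase;
#: ``endoq_tdu_control`` the pre-deaminated reporter with endonuclease only
#: (cleavage not rate-limited by deamination); ``inhibited_sample`` the full
#: reaction plus inhibitor; ``buffer_blank`` reporter-free buffer.
ROLES = frozenset(
    {"sample", "negative_tc", "endoq_tdu_control", "inhibited_sample", "buffer_blank"}
)

#: Relative tolerance on the scan interval (instrument jitter allowance, s).
_GRID_ATOL = 1e-3


@dataclass
class KineticTrace:
    """One well's raw fluorescence time series.

    ``times`` are absolute seconds from scan start, strictly increasing on a
    uniform grid (constant interval to within 1 ms); ``values`` are RFU.
    ``meta`` carries layout metadata: reporter ("TC"/"TdU"), reporter_uM,
    deaminase_uM, endoq_uM, inhibitor_nM, dilution.
    """

    well_id: str
    times: np.ndarray
    values: np.ndarray
    role: str = "sample"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 10:
            raise ValueError(f"trace {self.well_id}: need >= 10 time points, got {len(self.times)}")
        if self.times[0] < 0:
            raise ValueError(f"trace {self.well_id}: times must start at >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.well_id}: non-finite RFU values")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError(f"trace {self.well_id}: times must be strictly increasing")
        if np.ptp(dt) > _GRID_ATOL:
            raise ValueError(f"trace {self.well_id}: scan interval not constant (to 1 ms)")

    @property
    def interval(self) -> float:
        """Scan interval in seconds."""
        return float(self.times[1] - self.times[0])


@dataclass
class ConcentrationTrace:
    """A trace converted to uM of cleaved (product) reporter."""

    well_id: str
    times: np.ndarray
    product: np.ndarray
    fmax_ref: float
    a0: float
    role: str = "sample"
    meta: dict = field(default_factory=dict)
    n_clipped: int = 0

    @property
    def values(self) -> np.ndarray:
        """Alias so slope/endpoint operations work on either trace type."""
        return self.product


@dataclass(frozen=True)
class VelocityEstimate:
    """Initial velocity from the maximum-slope window.

    ``v`` is in the units of the input trace per second (RFU/s for raw
    traces, uM/s for concentration traces).
    """

    v: float
    window_start_index: int
    window_length: int
    r2_window: float


@dataclass(frozen=True)
class FmaxEstimate:
    """Reference fluorescence of fully processed reporter (RFU)."""

    value: float
    at_plateau: bool
    per_control: tuple


def _same_grid(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and np.allclose(a, b, rtol=0, atol=_GRID_ATOL)


def subtract_background(
    trace: KineticTrace, negatives: list, interpolate: bool = False
) -> KineticTrace:
    """Subtract the mean negative-control trace point-by-point.

    Subtracting the full negative trace (rather than a scalar baseline)
    removes both the quenched-reporter background and the early settling
    transient, which the negative controls share with the samples.  Small
    negative values after subtraction are expected noise and retained.
    """
    if not negatives:
        raise ValueError("at least one negative-control trace is required")
    cols = []
    for neg in negatives:
        if _same_grid(neg.times, trace.times):
            cols.append(neg.values)
        elif interpolate:
            cols.append(np.interp(trace.times, neg.times, neg.values))
        else:
            raise ValueError(
                f"negative control {neg.well_id} is not on the time grid of "
                f"{trace.well_id}; pass interpolate=True to resample"
            )
    background = np.mean(cols, axis=0)
    return replace(trace, values=trace.values - background, meta=dict(trace.meta))


def _tail_plateau(trace, frac: float = 0.1, min_points: int = 5):
    """Mean of the last ``frac`` of points (>= min_points) and its flatness."""
    n = len(trace.times)
    ntail = max(min_points, int(np.ceil(frac * n)))
    t_tail = trace.times[-ntail:]
    y_tail = trace.values[-ntail:]
    level = float(np.mean(y_tail))
    slope = float(np.polyfit(t_tail, y_tail, 1)[0])
    # flat if extrapolating the tail slope over the whole scan moves < 2 %
    span = trace.times[-1] - trace.times[0]
    flat = abs(slope) * span <= 0.02 * abs(level) if level != 0 else slope == 0
    return level, flat


def _exp_plateau(trace) -> float:
    """Plateau from a free one-phase association fit to a control trace.

    Unbiased when the control truly follows plateau*(1-e^(-kt)); preferred
    over the tail mean when the scan may end before full processing.
    """
    from scipy.optimize import curve_fit

    t, y = trace.times, trace.values
    ymax = float(np.max(y))
    if ymax <= 0:
        return float(np.mean(y[-5:]))
    # crude rate guess from time to half max
    above = np.nonzero(y >= 0.5 * ymax)[0]
    t_half = t[above[0]] if len(above) and t[above[0]] > 0 else t[-1] / 4
    p0 = [ymax, np.log(2) / max(t_half, t[1] - t[0])]
    popt, _ = curve_fit(
        lambda tt, plat, k: plat * -np.expm1(-k * tt), t, y, p0=p0, maxfev=10000
    )
    return float(popt[0])


def estimate_fmax(controls: list, method: str = "plateau_mean") -> FmaxEstimate:
    """Reference RFU of the fully processed reporter, from cleavage controls.

    Parameters
    ----------
    controls
        Background-subtracted ``endoq_tdu_control`` traces.
    method
        ``plateau_mean`` (default): mean of each control's last 10 % of
        points (>= 5), averaged across controls.  ``max``: single maximum
        observed RFU per control.  ``exp_fit``: plateau of a free one-phase
        association fit per control (exact when the control follows the
        cleavage kinetics; used by the analysis pipelines).

    A control whose tail still rises (extrapolated tail slope > 2 % of the
    plateau over the scan) clears the ``at_plateau`` flag on the result.
    """
    if not controls:
        raise ValueError("at least one cleavage-control trace is required")
    if method not in {"plateau_mean", "max", "exp_fit"}:
        raise ValueError(f"unknown fmax method {method!r}")
    per, flat_all = [], True
    for ctl in controls:
        level, flat = _tail_plateau(ctl)
        if method == "max":
            level = float(np.max(ctl.values))
        elif method == "exp_fit":
            level = _exp_plateau(ctl)
        per.append(level)
        flat_all &= flat
    value = float(np.mean(per))
    if not flat_all:
        logger.warning("cleavage control(s) not at plateau; fmax may be underestimated")
    return FmaxEstimate(value=value, at_plateau=flat_all, per_control=tuple(per))


def to_concentration(trace: KineticTrace, fmax_ref: float, a0: float) -> ConcentrationTrace:
    """Convert background-subtracted RFU to uM cleaved reporter.

    product(t) = a0 * value(t) / fmax_ref, clipped to [0, 1.05 * a0]
    (5 % headroom for noise); any clipping is counted and logged.
    """
    if not fmax_ref > 0:
        raise ValueError(f"fmax_ref must be > 0, got {fmax_ref}")
    if not a0 > 0:
        raise ValueError(f"a0 must be > 0, got {a0}")
    raw = a0 * trace.values / fmax_ref
    clipped = np.clip(raw, 0.0, 1.05 * a0)
    n_clipped = int(np.sum(raw != clipped))
    if n_clipped:
        logger.warning(
            "well %s: %d/%d points clipped to [0, 1.05*A0] during RFU->uM conversion",
            trace.well_id, n_clipped, len(raw),
        )
    return ConcentrationTrace(
        well_id=trace.well_id,
        times=trace.times.copy(),
        product=clipped,
        fmax_ref=float(fmax_ref),
        a0=float(a0),
        role=trace.role,
        meta=dict(trace.meta),
        n_clipped=n_clipped,
    )


def max_slope_velocity(trace, window_points: int = 10, search_from: float = 0.0) -> VelocityEstimate:
    """Initial velocity as the maximal OLS slope over a sliding window.

    Every contiguous window of ``window_points`` points starting at or after
    ``search_from`` is fit by ordinary least squares; the steepest (largest
    positive slope) window wins, ties broken by earliest start.  Works on
    raw (RFU) or concentration (uM) traces; the velocity is per second.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.values, dtype=float)
    if window_points < 3:
        raise ValueError("window must span at least 3 points")
    start0 = int(np.searchsorted(t, search_from))
    n_avail = len(t) - start0
    if n_avail < window_points:
        raise ValueError(
            f"only {n_avail} points at or after t={search_from}; window needs {window_points}"
        )
    tw = np.lib.stride_tricks.sliding_window_view(t[start0:], window_points)
    yw = np.lib.stride_tricks.sliding_window_view(y[start0:], window_points)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = np.sum((tw - tm) ** 2, axis=1)
    sxy = np.sum((tw - tm) * (yw - ym), axis=1)
    slopes = sxy / sxx
    best = int(np.argmax(slopes))  # argmax takes the earliest tie
    syy = np.sum((yw - ym) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 1.0)
    return VelocityEstimate(
        v=float(slopes[best]),
        window_start_index=start0 + best,
        window_length=window_points,
        r2_window=float(r2[best]),
    )


def trim_settling(trace: KineticTrace, t_cut: float = 300.0) -> KineticTrace:
    """Drop the early settling transient: remove points with t < t_cut.

    Plate reads show a small signal rise over roughly the first five
    minutes before a stable baseline; trimming those points avoids biasing
    slope and background estimates.  ``t_cut = 0`` is the identity.
    """
    if t_cut <= 0:
        return replace(trace, meta=dict(trace.meta))
    if t_cut >= trace.times[-1]:
        raise ValueError(f"t_cut={t_cut} would remove the entire trace")
    keep = trace.times >= t_cut
    return replace(trace, times=trace.times[keep], values=trace.values[keep], meta=dict(trace.meta))


def endpoint_signal(trace, t_end: float) -> float:
    """Signal at the last scan at or before ``t_end`` (e.g. the 1 h read)."""
    t = np.asarray(trace.times, dtype=float)
    if t_end < t[0]:
        raise ValueError(f"t_end={t_end} precedes the first scan at t={t[0]}")
    idx = int(np.searchsorted(t, t_end, side="right")) - 1
    return float(np.asarray(trace.values)[idx])
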