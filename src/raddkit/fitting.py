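"""Nonlinear parameter inference for reporter-assay kinetics.

Three fit families, all unweighted least squares with asymptotic
(t-distribution) 95 % confidence intervals:

* single-rate progress-curve fits — one-phase association for the
  cleavage-only control, and the consecutive-reaction product curve with
  the cleavage rate fixed, combined in the two-stage single-turnover
  procedure (stage 1 estimates k2 from cleavage controls, stage 2 fixes it
  and estimates the deamination rate k1 from the full reaction);
* Michaelis-Menten fits of an initial-velocity-vs-substrate table;
* constrained variable-slope IC50 fits (top = 100 %, bottom = 0 %) in
  log10-concentration space.

Replicates are pooled as individual points rather than averaged first, which
preserves degrees of freedom.  Rate fits use bounded least squares with
three log-spaced starts to avoid local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .models import (
    DoseResponseParams,
    SequentialParams,
    dose_response,
    one_phase_association,
    sequential_product,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitError",
    "RateFit",
    "SequentialFitResult",
    "MMFitResult",
    "DoseResponseFit",
    "fit_one_phase",
    "fit_sequential",
    "two_stage_single_turnover",
    "fit_mm",
    "percent_activity",
    "fit_ic50",
    "confidence_interval",
]

#: Bounds on fitted rate constants, 1/s.  The upper bound corresponds to a
#: sub-second reaction, far faster than any plate-scan-resolvable process;
#: a fit pinned there indicates the step is not rate-limiting in the data.
RATE_BOUNDS = (1e-9, 10.0)


#: Tight scipy.least_squares tolerances: parameters span many decades
#: (rates ~1e-3/s, velocities ~1e-4 uM/s), so default tolerances stop
#: visibly short of the optimum on exact data.
_LSQ_OPTS = {"ftol": 1e-14, "xtol": 1e-14, "gtol": 1e-14}


class FitError(RuntimeError):
    """A fit failed to converge; carries the last iterate for diagnosis."""

    def __init__(self, message: str, last_params: dict | None = None):
        super().__init__(message)
        self.last_params = last_params or {}


@dataclass
class RateFit:
    """A fitted first-order rate constant with uncertainty."""

    model: str  # "one_phase" or "sequential"
    k: float  # 1/s
    k_stderr: float
    k_ci: tuple  # 95 % (lo, hi), 1/s
    fixed: dict  # constrained parameters (plateau, a0, k2, ...)
    r2: float
    n_traces: int
    n_points: int
    at_bound: bool = False  # k pinned at a bound: step not identifiable


@dataclass
class SequentialFitResult:
    """Output of the two-stage single-turnover procedure."""

    endoq_fit: RateFit  # stage 1: cleavage rate k2
    deaminase_fit: RateFit  # stage 2: deamination rate k1 (k2 fixed)
    single_turnover: bool  # True when [E] >> Km and [E] > A0, so k1 ~ kcat

    @property
    def rate_label(self) -> str:
        """'kcat' under single-turnover conditions, else 'kobs'."""
        return "kcat" if self.single_turnover else "kobs"


@dataclass
class MMFitResult:
    km: float  # uM
    km_ci: tuple
    vmax: float  # uM/s
    vmax_ci: tuple
    kcat: float  # 1/s == vmax / enzyme
    enzyme: float  # uM
    r2: float
    n_points: int
    range_warning: bool = False  # max S < km/2: substrate range too low
    unidentifiable: bool = False  # flat velocities: Km unresolved below min S


@dataclass
class DoseResponseFit:
    ic50: float  # nM
    ic50_ci: tuple
    hill: float
    hill_stderr: float
    r2: float
    n_points: int
    constraints: dict = field(default_factory=lambda: {"top": 100.0, "bottom": 0.0})
    extrapolated: bool = False  # responses do not straddle 50 %
    in_span: bool = True  # fitted ic50 lies within the tested range


def confidence_interval(
    value: float,
    stderr: float,
    dof: int,
    level: float = 0.95,
    lower_bound: float = -np.inf,
) -> tuple:
    """Asymptotic CI: value +/- t(dof, (1+level)/2) * stderr, truncated.

    ``lower_bound`` truncates at physical limits (e.g. rates > 0).  A
    zero-residual fit has stderr 0 and a zero-width interval.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if dof < 1:
        return (max(lower_bound, -np.inf), np.inf)
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    half = tcrit * stderr
    return (max(value - half, lower_bound), value + half)


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def _pool(traces) -> tuple:
    t = np.concatenate([np.asarray(tr.times, float) for tr in traces])
    y = np.concatenate([np.asarray(tr.values, float) for tr in traces])
    return t, y


def _rate_starts(t: np.ndarray, y: np.ndarray, plateau: float, n_starts: int = 3):
    """Log-spaced initial rate guesses around a half-rise heuristic."""
    ymax = np.max(y)
    target = 0.5 * min(plateau, ymax) if ymax > 0 else 0.5 * plateau
    above = np.nonzero(y >= target)[0]
    if len(above) and t[above[0]] > 0:
        k0 = np.log(2.0) / t[above[0]]
    else:
        k0 = 1.0 / max(t[-1], 1.0)
    return k0 * np.logspace(-1, 1, n_starts)


def _fit_single_rate(traces, model_fn, model_name, fixed, ci_level=0.95) -> RateFit:
    """Shared machinery: bounded 1-parameter LS with multi-start."""
    if not traces:
        raise ValueError("at least one trace is required")
    t, y = _pool(traces)
    plateau = fixed.get("plateau", fixed.get("a0", 1.0))

    def residual(params):
        return model_fn(t, params["k"].value) - y

    best = None
    for k0 in _rate_starts(t, y, plateau):
        params = Parameters()
        params.add("k", value=float(np.clip(k0, *RATE_BOUNDS)), min=RATE_BOUNDS[0], max=RATE_BOUNDS[1])
        try:
            res = minimize(residual, params, method="least_squares", **_LSQ_OPTS)
        except Exception:  # singular jacobian etc.; try next start
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        last = {"k": float(best.params["k"].value)} if best is not None else {}
        raise FitError(f"{model_name} fit did not converge", last_params=last)
    k = float(best.params["k"].value)
    stderr = best.params["k"].stderr
    at_bound = k <= RATE_BOUNDS[0] * 1.01 or k >= RATE_BOUNDS[1] * 0.99
    if stderr is None:
        # covariance unavailable (boundary or degenerate data)
        stderr = np.nan
        at_bound = True
        logger.warning("%s fit: no parameter covariance; k may be at a bound", model_name)
    dof = max(len(y) - 1, 1)
    ci = confidence_interval(k, stderr, dof, level=ci_level, lower_bound=0.0)
    return RateFit(
        model=model_name,
        k=k,
        k_stderr=float(stderr),
        k_ci=ci,
        fixed=dict(fixed),
        r2=_r2(y, best.residual),
        n_traces=len(traces),
        n_points=len(y),
        at_bound=at_bound,
    )


def fit_one_phase(traces, plateau: float = 1.0, ci_level: float = 0.95) -> RateFit:
    """Fit plateau*(1 - e^(-k t)) with the plateau fixed, pooled replicates."""
    if not plateau > 0:
        raise ValueError(f"plateau must be > 0, got {plateau}")
    return _fit_single_rate(
        traces,
        lambda t, k: one_phase_association(t, k, plateau),
        "one_phase",
        {"plateau": plateau},
        ci_level,
    )


def fit_one_phase_free(traces, ci_level: float = 0.95):
    """Joint (k, plateau) one-phase fit to raw (RFU) control traces.

    Used for calibration: the fitted plateau is the fluorescence of fully
    processed reporter, and because k and the plateau are estimated
    jointly, the rate's standard error includes the scale uncertainty that
    a fixed-plateau fit on pre-normalised data would ignore.

    Returns ``(rate_fit, plateau, plateau_stderr)``.
    """
    if not traces:
        raise ValueError("at least one trace is required")
    t, y = _pool(traces)
    ymax = float(np.max(y))
    if ymax <= 0:
        raise FitError("calibration fit needs a positive signal")

    def residual(params):
        return params["plateau"].value * -np.expm1(-params["k"].value * t) - y

    best = None
    for k0 in _rate_starts(t, y, ymax):
        params = Parameters()
        params.add("k", value=float(np.clip(k0, *RATE_BOUNDS)), min=RATE_BOUNDS[0], max=RATE_BOUNDS[1])
        params.add("plateau", value=ymax, min=1e-12)
        try:
            res = minimize(residual, params, method="least_squares", **_LSQ_OPTS)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise FitError("free-plateau one-phase fit did not converge")
    k = float(best.params["k"].value)
    k_se = best.params["k"].stderr
    plat = float(best.params["plateau"].value)
    plat_se = best.params["plateau"].stderr
    dof = max(len(y) - 2, 1)
    fit = RateFit(
        model="one_phase",
        k=k,
        k_stderr=float(k_se) if k_se is not None else np.nan,
        k_ci=confidence_interval(k, k_se if k_se is not None else np.nan, dof, ci_level, 0.0),
        fixed={},
        r2=_r2(y, best.residual),
        n_traces=len(traces),
        n_points=len(y),
        at_bound=k_se is None,
    )
    return fit, plat, float(plat_se) if plat_se is not None else np.nan


def fit_sequential(traces, k2: float, a0: float = 1.0, ci_level: float = 0.95) -> RateFit:
    """Fit the consecutive-reaction product curve for k1, with k2 and A0 fixed.

    ``k2`` comes from the cleavage-only control (stage 1).  A k1 colliding
    with k2 is handled by the analytic equal-rate limit of the model.
    """
    if not k2 > 0:
        raise ValueError(f"k2 must be > 0, got {k2}")
    if not a0 > 0:
        raise ValueError(f"a0 must be > 0, got {a0}")
    return _fit_single_rate(
        traces,
        lambda t, k: sequential_product(t, SequentialParams(k1=k, k2=k2, a0=a0)),
        "sequential",
        {"k2": k2, "a0": a0},
        ci_level,
    )


def two_stage_single_turnover(
    tdu_controls,
    sample_traces,
    a0: float = 1.0,
    enzyme_uM: float | None = None,
    km_uM: float | None = None,
    ci_level: float = 0.95,
    k2_fit: RateFit | None = None,
) -> SequentialFitResult:
    """Two-stage rate inference from one normalised plate.

    Stage 1 fits the one-phase association (plateau = A0) to the
    pre-deaminated-reporter controls to obtain the cleavage rate k2; stage 2
    fixes k2 and fits the sequential product model to the full-reaction
    samples for the deamination rate k1.  Both trace sets must already be in
    uM on the same plate.  A precomputed stage-1 result (e.g. the joint
    calibration fit of :func:`fit_one_phase_free`) can be passed as
    ``k2_fit`` to replace the constrained stage-1 fit.

    Because stage 2 conditions on the stage-1 estimate, the reported k1
    standard error adds the first-order propagated stage-1 uncertainty,
    (dk1/dk2)^2 * se(k2)^2, with the sensitivity evaluated by refitting at
    a perturbed k2.

    The ``single_turnover`` flag is set when the deaminase is in excess over
    the substrate and at or above Km, so most substrate is enzyme-bound and
    k1 reports the turnover number kcat; otherwise k1 is an observed rate
    kobs.
    """
    if not tdu_controls and k2_fit is None:
        raise ValueError("stage 1 requires at least one endoq_tdu_control trace")
    if not sample_traces:
        raise ValueError("stage 2 requires at least one sample trace")
    if k2_fit is not None:
        endoq_fit = k2_fit
    else:
        try:
            endoq_fit = fit_one_phase(tdu_controls, plateau=a0, ci_level=ci_level)
        except FitError as err:
            raise FitError(f"stage 1 (cleavage control) failed: {err}", err.last_params) from err
    try:
        deaminase_fit = fit_sequential(sample_traces, k2=endoq_fit.k, a0=a0, ci_level=ci_level)
    except FitError as err:
        raise FitError(
            f"stage 2 (deamination) failed after stage 1 k2={endoq_fit.k:.4g}: {err}",
            err.last_params,
        ) from err
    if np.isfinite(endoq_fit.k_stderr) and endoq_fit.k_stderr > 0 and not deaminase_fit.at_bound:
        # first-order propagation of the stage-1 uncertainty into k1
        dk2 = 0.01 * endoq_fit.k
        k1_pert = fit_sequential(
            sample_traces, k2=endoq_fit.k + dk2, a0=a0, ci_level=ci_level
        ).k
        sens = (k1_pert - deaminase_fit.k) / dk2
        se_total = float(
            np.sqrt(deaminase_fit.k_stderr**2 + (sens * endoq_fit.k_stderr) ** 2)
        )
        dof = max(deaminase_fit.n_points - 1, 1)
        deaminase_fit.k_stderr = se_total
        deaminase_fit.k_ci = confidence_interval(
            deaminase_fit.k, se_total, dof, level=ci_level, lower_bound=0.0
        )
    if deaminase_fit.at_bound:
        logger.warning(
            "deamination rate pinned at a bound (k=%.3g/s): deamination is not "
            "rate-limiting in these traces",
            deaminase_fit.k,
        )
    single = (
        enzyme_uM is not None
        and enzyme_uM > a0
        and (km_uM is None or enzyme_uM >= km_uM)
    )
    return SequentialFitResult(
        endoq_fit=endoq_fit, deaminase_fit=deaminase_fit, single_turnover=bool(single)
    )


def fit_mm(table, enzyme: float, ci_level: float = 0.95) -> MMFitResult:
    """Michaelis-Menten fit of an initial-velocity table.

    ``table`` is a DataFrame with columns ``substrate_uM`` and ``v_uM_per_s``
    (optionally ``replicate``); all replicate points are fit individually.
    Requires >= 4 distinct substrate concentrations.  kcat = Vmax / enzyme.
    """
    if not enzyme > 0:
        raise ValueError(f"enzyme concentration must be > 0, got {enzyme}")
    s = np.asarray(table["substrate_uM"], dtype=float)
    v = np.asarray(table["v_uM_per_s"], dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be > 0")
    if len(np.unique(s)) < 4:
        raise ValueError("Michaelis-Menten fitting needs >= 4 distinct substrate levels")

    def residual(params):
        return params["vmax"].value * s / (params["km"].value + s) - v

    params = Parameters()
    params.add("km", value=float(np.median(s)), min=1e-9)
    params.add("vmax", value=float(max(np.max(v), 1e-12) * 1.2), min=1e-15)
    res = minimize(residual, params, method="least_squares", **_LSQ_OPTS)
    if not res.success:
        raise FitError("Michaelis-Menten fit did not converge",
                       {p: float(res.params[p].value) for p in res.params})
    km = float(res.params["km"].value)
    vmax = float(res.params["vmax"].value)
    dof = max(len(v) - 2, 1)
    km_se = res.params["km"].stderr
    vmax_se = res.params["vmax"].stderr
    # velocities flat across substrate: any Km well below min(S) fits
    # equally, so Km is only bounded from above and the CI is unbounded
    unidentifiable = np.ptp(v) <= 1e-12 * np.max(np.abs(v)) or km < np.min(s) / 1e3
    if km_se is None or vmax_se is None or unidentifiable:
        if unidentifiable:
            logger.warning("Michaelis-Menten fit: velocities flat; Km unidentifiable")
        else:
            logger.warning("Michaelis-Menten fit: unbounded parameter covariance")
        km_ci = (0.0, np.inf)
        vmax_ci = (0.0, np.inf) if vmax_se is None else confidence_interval(
            vmax, vmax_se, dof, ci_level, lower_bound=0.0
        )
    else:
        km_ci = confidence_interval(km, km_se, dof, ci_level, lower_bound=0.0)
        vmax_ci = confidence_interval(vmax, vmax_se, dof, ci_level, lower_bound=0.0)
    range_warning = float(np.max(s)) < km / 2.0
    if range_warning:
        logger.warning("max substrate (%.3g uM) < Km/2 (%.3g uM): Km poorly bounded",
                       np.max(s), km / 2.0)
    return MMFitResult(
        km=km, km_ci=km_ci, vmax=vmax, vmax_ci=vmax_ci,
        kcat=vmax / enzyme, enzyme=float(enzyme),
        r2=_r2(v, res.residual), n_points=len(v), range_warning=range_warning,
        unidentifiable=bool(unidentifiable),
    )


def percent_activity(v_inhibited, v_uninhibited: float):
    """Velocities as percent of the uninhibited reaction: 100 * v / v0."""
    if not v_uninhibited > 0:
        raise ValueError(f"uninhibited velocity must be > 0, got {v_uninhibited}")
    return 100.0 * np.asarray(v_inhibited, dtype=float) / v_uninhibited


def fit_ic50(points, ci_level: float = 0.95) -> DoseResponseFit:
    """Constrained variable-slope IC50 fit of (inhibitor nM, % activity) pairs.

    Top and bottom are fixed at 100 % and 0 %; the fit is performed in
    log10-concentration space for (log10 IC50, hill).  The IC50 CI is
    back-transformed from the log scale (hence positive by construction).
    Responses that do not straddle 50 % set the ``extrapolated`` flag.
    """
    conc = np.asarray([p[0] for p in points], dtype=float)
    resp = np.asarray([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("inhibitor concentrations must be > 0")
    if len(np.unique(conc)) < 4:
        raise ValueError("IC50 fitting needs >= 4 distinct inhibitor concentrations")
    extrapolated = bool(np.all(resp > 50.0) or np.all(resp < 50.0))
    if extrapolated:
        logger.warning("all responses on one side of 50%%: IC50 is an extrapolation")

    def residual(params):
        p = DoseResponseParams(ic50=10.0 ** params["log_ic50"].value, hill=params["hill"].value)
        return dose_response(conc, p) - resp

    # start at the concentration whose response is nearest 50 %
    x0 = float(np.log10(conc[np.argmin(np.abs(resp - 50.0))]))
    params = Parameters()
    params.add("log_ic50", value=x0, min=np.log10(conc.min()) - 4, max=np.log10(conc.max()) + 4)
    params.add("hill", value=1.0, min=1e-3, max=100.0)
    res = minimize(residual, params, method="least_squares", **_LSQ_OPTS)
    if not res.success:
        raise FitError("IC50 fit did not converge",
                       {p: float(res.params[p].value) for p in res.params})
    log_ic50 = float(res.params["log_ic50"].value)
    ic50 = 10.0 ** log_ic50
    dof = max(len(resp) - 2, 1)
    se = res.params["log_ic50"].stderr
    if se is None:
        ic50_ci = (0.0, np.inf)
    else:
        lo, hi = confidence_interval(log_ic50, se, dof, ci_level)
        ic50_ci = (10.0 ** lo, 10.0 ** hi)
    hill_se = res.params["hill"].stderr
    return DoseResponseFit(
        ic50=ic50,
        ic50_ci=ic50_ci,
        hill=float(res.params["hill"].value),
        hill_stderr=float(hill_se) if hill_se is not None else np.nan,
        r2=_r2(resp, res.residual),
        n_points=len(resp),
        extrapolated=extrapolated,
        in_span=bool(conc.min() <= ic50 <= conc.max()),
    )
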