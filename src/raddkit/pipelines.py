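"""End-to-end plate analyses: from raw traces to fitted reports.

Each analysis mirrors one characterisation experiment:

* :func:`analyze_single_turnover` — two-stage rate inference (cleavage rate
  from the pre-deaminated-reporter controls, then the deamination rate with
  the cleavage rate fixed);
* :func:`analyze_mm` — max-slope initial velocities across a substrate
  dilution series, fit to the Michaelis-Menten model;
* :func:`analyze_ic50` — percent-activity of inhibited wells against the
  uninhibited velocity, fit to the constrained variable-slope logistic;
* :func:`analyze_qc` — endpoint screening-window statistics (Z', S:N, S:B).

All consume a list of :class:`~raddkit.traces.KineticTrace` (e.g. from
:func:`raddkit.io.read_plate` or :func:`raddkit.simulate.simulate_plate`)
plus a :class:`~raddkit.config.RunConfig`.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .fitting import (
    DoseResponseFit,
    MMFitResult,
    SequentialFitResult,
    fit_ic50,
    fit_mm,
    fit_one_phase,
    fit_one_phase_free,
    fit_sequential,
    percent_activity,
    two_stage_single_turnover,
)
from .screening import ScreenStats, screen_summary
from .traces import estimate_fmax, max_slope_velocity, subtract_background, to_concentration

logger = logging.getLogger(__name__)

__all__ = [
    "split_roles",
    "prepare_concentration",
    "analyze_single_turnover",
    "analyze_mm",
    "analyze_ic50",
    "analyze_qc",
    "as_report",
]


def split_roles(traces) -> dict:
    groups: dict = {}
    for tr in traces:
        groups.setdefault(tr.role, []).append(tr)
    return groups


def _a0_of(trace) -> float:
    return float(trace.meta.get("reporter_uM", 1.0))


def prepare_concentration(traces, config: RunConfig | None = None) -> dict:
    """Background-subtract, calibrate fmax, and convert a plate to uM.

    Negative-control wells define the per-timepoint background (which also
    carries the settling transient); cleavage-only controls define the
    fluorescence of fully processed reporter per uM.  Wells with differing
    reporter loads are scaled by their own reporter concentration.

    Returns ``{"samples": [...], "inhibited": [...], "controls": [...],
    "fmax_per_uM": float}`` with concentration traces.
    """
    config = config or RunConfig()
    groups = split_roles(traces)
    negatives = groups.get("negative_tc", [])
    if not negatives:
        raise ValueError("plate has no negative_tc wells for background subtraction")
    controls = groups.get("endoq_tdu_control", [])
    if not controls:
        raise ValueError("plate has no endoq_tdu_control wells for fmax calibration")
    controls_bg = [subtract_background(tr, negatives) for tr in controls]
    fmax = estimate_fmax(controls_bg, method=config.plateau_method)
    a0_ctrl = _a0_of(controls[0])
    fmax_per_uM = fmax.value / a0_ctrl
    out = {"samples": [], "inhibited": [], "controls": [], "fmax_per_uM": fmax_per_uM}
    for tr in controls_bg:
        out["controls"].append(to_concentration(tr, fmax_per_uM * _a0_of(tr), _a0_of(tr)))
    for role, key in (("sample", "samples"), ("inhibited_sample", "inhibited")):
        for tr in groups.get(role, []):
            bg = subtract_background(tr, negatives)
            out[key].append(to_concentration(bg, fmax_per_uM * _a0_of(bg), _a0_of(bg)))
    return out


def _maybe_average(conc_traces, config: RunConfig):
    """Optionally collapse replicates to one mean trace (config switch)."""
    if not config.average_replicates or len(conc_traces) < 2:
        return conc_traces
    first = conc_traces[0]
    mean = np.mean([ct.product for ct in conc_traces], axis=0)
    avg = dataclasses.replace(first, well_id="mean", product=mean)
    return [avg]


def _inflate_shared_background(rate_fit, n_traces: int, n_neg: int, ci_level: float) -> None:
    """Widen a pooled-fit SE for the background trace shared across wells.

    Subtracting the same mean-negative trace from every well correlates
    residuals across wells at each timepoint (iid across time), so a pooled
    fit that assumes independent points understates the parameter variance
    by (1 + n_traces/n_neg) / (1 + 1/n_neg).  The factor is sqrt(1.5) for
    the standard 3-replicate, 3-negative design.
    """
    from .fitting import confidence_interval

    infl = np.sqrt((1.0 + n_traces / n_neg) / (1.0 + 1.0 / n_neg))
    if np.isfinite(rate_fit.k_stderr):
        rate_fit.k_stderr *= infl
        dof = max(rate_fit.n_points - 2, 1)
        rate_fit.k_ci = confidence_interval(
            rate_fit.k, rate_fit.k_stderr, dof, level=ci_level, lower_bound=0.0
        )


def analyze_single_turnover(traces, config: RunConfig | None = None) -> SequentialFitResult:
    """Two-stage rate inference on one plate of raw traces.

    Stage 1 is the joint free-plateau calibration fit to the
    background-subtracted cleavage controls: its rate is k2 and its plateau
    is the fmax used to normalise the plate, so the k2 standard error
    already carries the normalisation uncertainty.  Stage 2 fits the
    deamination rate on the normalised samples with k2 fixed, with the
    stage-1 uncertainty propagated into the k1 interval.
    """
    config = config or RunConfig()
    groups = split_roles(traces)
    negatives = groups.get("negative_tc", [])
    if not negatives:
        raise ValueError("plate has no negative_tc wells for background subtraction")
    controls = groups.get("endoq_tdu_control", [])
    if not controls:
        raise ValueError("plate has no endoq_tdu_control wells for fmax calibration")
    samples = groups.get("sample", [])
    if not samples:
        raise ValueError("plate has no sample wells to fit")
    controls_bg = [subtract_background(tr, negatives) for tr in controls]
    k2_fit, fmax, _ = fit_one_phase_free(controls_bg, ci_level=config.ci_level)
    _inflate_shared_background(k2_fit, len(controls), len(negatives), config.ci_level)
    fmax_per_uM = fmax / _a0_of(controls[0])
    samples_conc = [
        to_concentration(subtract_background(tr, negatives), fmax_per_uM * _a0_of(tr), _a0_of(tr))
        for tr in samples
    ]
    controls_conc = [
        to_concentration(tr, fmax_per_uM * _a0_of(tr), _a0_of(tr)) for tr in controls_bg
    ]
    a0 = samples_conc[0].a0
    enzyme = samples_conc[0].meta.get("deaminase_uM")
    result = two_stage_single_turnover(
        _maybe_average(controls_conc, config),
        _maybe_average(samples_conc, config),
        a0=a0,
        enzyme_uM=float(enzyme) if enzyme is not None else None,
        ci_level=config.ci_level,
        k2_fit=k2_fit,
    )
    return result


def velocity_table(conc_traces, config: RunConfig | None = None) -> pd.DataFrame:
    """Max-slope initial velocities, one row per well (uM/s)."""
    config = config or RunConfig()
    rows = []
    for i, ct in enumerate(conc_traces):
        est = max_slope_velocity(
            ct, window_points=config.slope_window, search_from=config.search_from
        )
        rows.append(
            {
                "well_id": ct.well_id,
                "substrate_uM": ct.a0,
                "v_uM_per_s": est.v,
                "r2_window": est.r2_window,
                "replicate": i,
            }
        )
    return pd.DataFrame(rows)


def _common_window_slope(ct, start: int, n: int) -> float:
    t = ct.times[start : start + n]
    y = ct.product[start : start + n]
    return float(np.polyfit(t, y, 1)[0])


def mm_velocity_table(conc_traces, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-replicate initial velocities for a substrate dilution series.

    The steepest window is located on the replicate-mean trace of each
    substrate level, then each replicate's slope is evaluated on that
    common window.  Selecting the window on the mean suppresses the upward
    bias that taking each noisy replicate's own maximum would introduce,
    while keeping one velocity point per replicate for the fit.  The
    window spans one third of the scan unless ``mm_window_points`` is set:
    these progress curves are slow, so long windows lose little signal and
    greatly reduce slope variance.
    """
    config = config or RunConfig()
    groups: dict = {}
    for ct in conc_traces:
        groups.setdefault(ct.a0, []).append(ct)
    rows = []
    for a0, cts in sorted(groups.items()):
        n_pts = len(cts[0].times)
        window = config.mm_window_points or max(config.slope_window, n_pts // 3)
        mean_trace = dataclasses.replace(
            cts[0], well_id=f"mean_{a0}uM", product=np.mean([c.product for c in cts], axis=0)
        )
        est = max_slope_velocity(mean_trace, window_points=window, search_from=config.search_from)
        for i, ct in enumerate(cts):
            rows.append(
                {
                    "well_id": ct.well_id,
                    "substrate_uM": a0,
                    "v_uM_per_s": _common_window_slope(ct, est.window_start_index, window),
                    "r2_window": est.r2_window,
                    "replicate": i,
                }
            )
    return pd.DataFrame(rows)


def analyze_mm(traces, config: RunConfig | None = None, enzyme_uM: float | None = None) -> MMFitResult:
    """Michaelis-Menten parameters from a substrate-dilution-series plate."""
    config = config or RunConfig()
    prep = prepare_concentration(traces, config)
    if not prep["samples"]:
        raise ValueError("plate has no sample wells to fit")
    table = mm_velocity_table(prep["samples"], config)
    if enzyme_uM is None:
        enzyme_uM = prep["samples"][0].meta.get("deaminase_uM")
        if enzyme_uM is None:
            raise ValueError("enzyme concentration not given and absent from the plate layout")
    return fit_mm(table, enzyme=float(enzyme_uM), ci_level=config.ci_level)


def analyze_ic50(traces, config: RunConfig | None = None) -> DoseResponseFit:
    """Inhibitor potency from an inhibition-series plate.

    Uninhibited ``sample`` wells define 100 % activity; each
    ``inhibited_sample`` well contributes one (inhibitor nM, % activity)
    point.  With the default ``activity_metric='rate_fit'`` a well's
    velocity is k1 * A0 from a sequential-model fit (the cleavage rate
    coming from the plate's own controls), which corrects for substrate
    depletion over the progress curve; ``'max_slope'`` uses the raw
    sliding-window velocity instead.
    """
    config = config or RunConfig()
    prep = prepare_concentration(traces, config)
    if not prep["inhibited"]:
        raise ValueError("plate has no inhibited_sample wells")
    if not prep["samples"]:
        raise ValueError("plate has no uninhibited sample wells to define 100% activity")
    if config.activity_metric == "rate_fit":
        k2 = fit_one_phase(prep["controls"], plateau=prep["controls"][0].a0).k

        def vel(ct):
            return fit_sequential([ct], k2=k2, a0=ct.a0).k * ct.a0

    else:

        def vel(ct):
            return max_slope_velocity(ct, config.slope_window, config.search_from).v

    v0 = float(np.mean([vel(ct) for ct in prep["samples"]]))
    points = []
    for ct in prep["inhibited"]:
        inh = ct.meta.get("inhibitor_nM")
        if inh is None:
            raise ValueError(f"well {ct.well_id}: inhibited_sample without inhibitor_nM in layout")
        points.append((float(inh), float(percent_activity([vel(ct)], v0)[0])))
    return fit_ic50(points, ci_level=config.ci_level)


def analyze_qc(traces, config: RunConfig | None = None) -> ScreenStats:
    """Endpoint screening statistics from raw positive/negative wells."""
    config = config or RunConfig()
    return screen_summary(
        traces, t_end=config.endpoint_time, snr_method=config.snr_method
    )


def as_report(result) -> dict:
    """JSON-serialisable dict of any analysis result dataclass."""
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, float) and not np.isfinite(obj):
            return None if np.isnan(obj) else ("Infinity" if obj > 0 else "-Infinity")
        return obj

    return convert(result)
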