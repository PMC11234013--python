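"""Seeded synthetic plates emulating the real-time deamination assay.

The generator composes the closed-form reaction kinetics with the FRET
readout: a quenched baseline, a fluorescence window opened by reporter
cleavage, a small early settling transient shared by all wells, and
additive Gaussian read noise:

    F(t) = F_bg + (F_max - F_bg) * P(t) / A0
         + amp * (1 - e^(-t / tau)) + eps(t),   eps ~ N(0, noise_sd)

where P(t) follows the consecutive two-step model for full-reaction wells,
one-phase association at the cleavage rate for pre-deaminated-reporter
controls (the substrate is already deaminated, so only the endonuclease
step remains), and 0 for negative controls and blanks.

Presets encode the assay designs used to characterise the method: a
substrate dilution series for Michaelis-Menten kinetics, a single-turnover
plate, a 18+18-well screening-window plate, an inhibitor dilution series,
and a lysate dilution series.  Every well draws from an independent RNG
substream keyed by (seed, well id), so editing a plate design never
perturbs the other wells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .models import SequentialParams, one_phase_association, sequential_product
from .traces import KineticTrace

__all__ = [
    "SimulationScenario",
    "WellSpec",
    "PlateDesign",
    "simulate_trace",
    "simulate_plate",
    "hill_inhibition",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Generator settings for one well (or a plate's shared baseline).

    Defaults correspond to the standard assay design: 1 uM reporter read
    every 30 s for 1 h, deamination at 5.5e-3/s (deaminase in excess) and
    cleavage at 2.97e-3/s, with a ~2000-RFU quenched baseline opening to
    ~10000 RFU at full cleavage, a small settling rise over the first
    minutes, and ~1 % read noise.
    """

    k1: float = 5.5e-3  # deamination rate, 1/s (0 for negative controls)
    k2: float = 2.97e-3  # cleavage rate, 1/s
    a0: float = 1.0  # reporter, uM
    f_bg: float = 2000.0  # quenched baseline, RFU
    f_max: float = 10000.0  # RFU at full cleavage of a0
    transient_amp: float = 150.0  # settling transient amplitude, RFU
    transient_tau: float = 60.0  # settling time constant, s
    noise_sd: float = 80.0  # additive read noise, RFU
    duration: float = 3600.0  # s
    interval: float = 30.0  # s (30 or 60 on the instrument)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.f_max > self.f_bg >= 0:
            raise ValueError(f"need f_max > f_bg >= 0, got f_max={self.f_max}, f_bg={self.f_bg}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.k1 < 0 or self.k2 <= 0:
            raise ValueError(f"need k1 >= 0 and k2 > 0, got k1={self.k1}, k2={self.k2}")
        if not self.a0 > 0:
            raise ValueError(f"a0 must be > 0, got {self.a0}")
        if self.duration / self.interval < 9:
            raise ValueError("duration/interval must yield >= 10 scan points")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 0.5 * self.interval, self.interval)


@dataclass(frozen=True)
class WellSpec:
    """One well of a plate design: role plus scenario overrides."""

    well_id: str
    role: str = "sample"
    overrides: dict = field(default_factory=dict)  # scenario field -> value
    meta: dict = field(default_factory=dict)  # layout metadata (reporter_uM, inhibitor_nM, ...)


@dataclass(frozen=True)
class PlateDesign:
    wells: tuple

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate well ids in design: {dupes}")
        if self.wells and not any(w.role == "negative_tc" for w in self.wells):
            raise ValueError("a non-empty plate design needs >= 1 negative_tc well")


def _well_rng(seed: int, well_id: str) -> np.random.Generator:
    """Independent, reproducible substream for one well."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(well_id.encode())])


def _product_curve(t: np.ndarray, s: SimulationScenario, role: str) -> np.ndarray:
    if role in ("negative_tc", "buffer_blank") or s.k1 == 0:
        return np.zeros_like(t)
    if role == "endoq_tdu_control":
        return one_phase_association(t, s.k2, s.a0)
    return sequential_product(t, SequentialParams(k1=s.k1, k2=s.k2, a0=s.a0))


def simulate_trace(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    role: str = "sample",
    well_id: str = "A1",
    meta: dict | None = None,
) -> KineticTrace:
    """Simulate one well's fluorescence trace; deterministic given the rng seed."""
    if rng is None:
        rng = _well_rng(scenario.seed, well_id)
    t = scenario.times
    p = _product_curve(t, scenario, role)
    f = (
        scenario.f_bg
        + (scenario.f_max - scenario.f_bg) * p / scenario.a0
        + scenario.transient_amp * -np.expm1(-t / scenario.transient_tau)
    )
    if scenario.noise_sd > 0:
        f = f + rng.normal(0.0, scenario.noise_sd, size=t.shape)
    base_meta = {"reporter_uM": scenario.a0}
    if meta:
        base_meta.update(meta)
    return KineticTrace(well_id=well_id, times=t, values=f, role=role, meta=base_meta)


def simulate_plate(design: PlateDesign, base: SimulationScenario, seed: int) -> list:
    """Simulate every well of a design from per-well RNG substreams."""
    traces = []
    for well in design.wells:
        scenario = replace(base, **well.overrides) if well.overrides else base
        rng = _well_rng(seed, well.well_id)
        traces.append(
            simulate_trace(scenario, rng=rng, role=well.role, well_id=well.well_id, meta=dict(well.meta))
        )
    return traces


def hill_inhibition(k1: float, inhibitor_nM: float, ic50_nM: float, hill: float = 1.0) -> float:
    """Effective deamination rate under Hill-type inhibitor occupancy.

    k1_eff = k1 * (1 - [I]^n / ([I]^n + IC50^n)); at [I] = IC50 the rate is
    halved, matching the constrained logistic the potency fit assumes.
    """
    if inhibitor_nM < 0 or ic50_nM <= 0:
        raise ValueError("inhibitor >= 0 and ic50 > 0 required")
    occ = inhibitor_nM**hill / (inhibitor_nM**hill + ic50_nM**hill)
    return k1 * (1.0 - occ)


def _wells_grid(n: int, start_row: str = "A", ncol: int = 12):
    rows = "ABCDEFGH"
    r0 = rows.index(start_row)
    for i in range(n):
        yield f"{rows[r0 + i // ncol]}{i % ncol + 1}"


# ---------------------------------------------------------------------------
# Presets: the characterisation designs, as (PlateDesign, SimulationScenario)

#: Michaelis-Menten reference parameters for the preset substrate series
#: (catalytic-domain deaminase at 100 nM).
_MM_KM_UM = 4.390
_MM_VMAX_UM_S = 5.1397e-4
_MM_ENZYME_UM = 0.1

#: Reference inhibitor potency used by the inhibition preset, nM.
_IC50_NM = 226.4


def _preset_single_turnover():
    """Excess deaminase (5 uM) over 1 uM reporter: k1 reports the turnover number."""
    base = SimulationScenario()  # defaults are this design
    wells = [
        WellSpec(f"A{i+1}", "sample", meta={"deaminase_uM": 5.0, "endoq_uM": 2.0})
        for i in range(base.n_replicates)
    ]
    wells += [
        WellSpec(f"B{i+1}", "endoq_tdu_control", meta={"reporter": "TdU", "endoq_uM": 2.0})
        for i in range(base.n_replicates)
    ]
    wells += [WellSpec(f"C{i+1}", "negative_tc", meta={"endoq_uM": 2.0}) for i in range(base.n_replicates)]
    return PlateDesign(tuple(wells)), base


def _preset_mm_series():
    """Half dilution series 16 -> 1 uM reporter, N = 3, 100 nM deaminase.

    Deamination is pseudo-first-order, k1(S) = Vmax / (Km + S), so that the
    initial product-formation velocity k1 * S follows the Michaelis-Menten
    curve.  The fluorescence window scales with the reporter amount.
    """
    base = SimulationScenario()
    f_per_uM = base.f_max - base.f_bg
    wells = []
    row = iter("ABCDE")
    for s_uM in (16.0, 8.0, 4.0, 2.0, 1.0):
        r = next(row)
        k1 = _MM_VMAX_UM_S / (_MM_KM_UM + s_uM)
        over = {"k1": k1, "a0": s_uM, "f_max": base.f_bg + f_per_uM * s_uM}
        meta = {"reporter_uM": s_uM, "deaminase_uM": _MM_ENZYME_UM, "endoq_uM": 2.0}
        wells += [WellSpec(f"{r}{i+1}", "sample", over, meta) for i in range(3)]
    wells += [
        WellSpec(f"F{i+1}", "endoq_tdu_control", meta={"reporter": "TdU", "endoq_uM": 2.0})
        for i in range(3)
    ]
    wells += [WellSpec(f"G{i+1}", "negative_tc", meta={"endoq_uM": 2.0}) for i in range(3)]
    return PlateDesign(tuple(wells)), base


def _preset_zprime():
    """Screening-window plate: 18 positive and 18 negative wells, 1 h endpoint.

    Positive wells (100 nM deaminase, ~complete processing at 1 h) carry
    larger well-to-well endpoint scatter than negatives, as enzyme-bearing
    wells do in practice; the amplitudes are chosen to give the strong
    (Z' ~ 0.7, S:B ~ 5) separation typical of this assay.
    """
    base = SimulationScenario(k1=5.9e-3, f_bg=2000.0, f_max=10200.0, noise_sd=100.0)
    wells = [
        WellSpec(w, "sample", {"noise_sd": 580.0}, {"deaminase_uM": 0.1, "endoq_uM": 2.0})
        for w in _wells_grid(18, "A")
    ]
    wells += [WellSpec(w, "negative_tc", meta={"endoq_uM": 2.0}) for w in _wells_grid(18, "C")]
    return PlateDesign(tuple(wells)), base


def _preset_inhibition_series():
    """Inhibitor dilution series 78-620 nM against 500 nM deaminase, N = 3.

    The inhibitor maps to an effective deamination rate via Hill occupancy
    with the reference IC50, so the potency fit round-trips in expectation.
    """
    k1_free = 4.8e-4  # 500 nM deaminase on 1 uM reporter, below saturation
    base = SimulationScenario(k1=k1_free)
    wells = [
        WellSpec(f"A{i+1}", "sample", meta={"deaminase_uM": 0.5, "endoq_uM": 2.0, "inhibitor_nM": 0.0})
        for i in range(3)
    ]
    row = iter("BCDEF")
    for inh in (78.0, 155.0, 310.0, 450.0, 620.0):
        r = next(row)
        over = {"k1": hill_inhibition(k1_free, inh, _IC50_NM)}
        meta = {"deaminase_uM": 0.5, "endoq_uM": 2.0, "inhibitor_nM": inh}
        wells += [WellSpec(f"{r}{i+1}", "inhibited_sample", over, meta) for i in range(3)]
    wells += [
        WellSpec(f"G{i+1}", "endoq_tdu_control", meta={"reporter": "TdU", "endoq_uM": 2.0})
        for i in range(3)
    ]
    wells += [WellSpec(f"H{i+1}", "negative_tc", meta={"endoq_uM": 2.0}) for i in range(3)]
    return PlateDesign(tuple(wells)), base


def _preset_lysate_dilution():
    """Cell-lysate series: undiluted, 1:2 and 1:4, N = 3 each.

    Lysate activity is lower than purified enzyme; dilution scales the
    deamination rate by the dilution factor.
    """
    k1_lysate = 5.0e-4
    base = SimulationScenario(k1=k1_lysate)
    wells = []
    for r, dil in zip("ABC", (1.0, 2.0, 4.0)):
        over = {"k1": k1_lysate / dil}
        meta = {"dilution": dil, "endoq_uM": 2.0}
        wells += [WellSpec(f"{r}{i+1}", "sample", over, meta) for i in range(3)]
    wells += [
        WellSpec(f"D{i+1}", "endoq_tdu_control", meta={"reporter": "TdU", "endoq_uM": 2.0})
        for i in range(3)
    ]
    wells += [WellSpec(f"E{i+1}", "negative_tc", {"k1": 0.0}, {"dilution": 1.0, "endoq_uM": 2.0})
              for i in range(3)]
    return PlateDesign(tuple(wells)), base


_PRESETS = {
    "single_turnover": _preset_single_turnover,
    "mm_series": _preset_mm_series,
    "zprime": _preset_zprime,
    "inhibition_series": _preset_inhibition_series,
    "lysate_dilution": _preset_lysate_dilution,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str):
    """Named assay design -> (PlateDesign, SimulationScenario)."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}") from None
    return builder()
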