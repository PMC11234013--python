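"""Closed-form kinetic models for the coupled deaminase-endonuclease reporter assay.

The assay couples two irreversible (pseudo-)first-order steps acting on a
self-quenched fluorescent ssDNA reporter:

    S --k1--> I --k2--> P

where S is the intact target-cytosine reporter, I the deaminated (uridine)
intermediate, and P the cleaved, fluorescent product.  Deamination by the
cytosine deaminase proceeds at rate ``k1`` and cleavage adjacent to the
uridine by the coupling endonuclease at rate ``k2``.  All times are seconds,
concentrations micromolar (umol/L) except inhibitor concentrations, which
follow the field convention of nanomolar.

These functions are pure and vectorised over time / concentration arrays;
everything downstream (simulation, fitting) is built on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SequentialParams",
    "MMParams",
    "DoseResponseParams",
    "sequential_species",
    "sequential_product",
    "intermediate_peak_time",
    "one_phase_association",
    "mm_velocity",
    "kcat_from_vmax",
    "dose_response",
]

#: Relative |k1 - k2| threshold below which the equal-rate limit form is used
#: to avoid catastrophic cancellation in the (k2 - k1) denominator.
EQUAL_RATE_RTOL = 1e-6


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time values must be nonnegative")
    return t


@dataclass(frozen=True)
class SequentialParams:
    """Parameters of the consecutive two-step first-order reaction.

    Attributes
    ----------
    k1 : float
        First-step (deamination) rate constant, 1/s.
    k2 : float
        Second-step (endonuclease cleavage) rate constant, 1/s.
    a0 : float
        Initial substrate (reporter) concentration, uM.  The published
        analysis constrains this to 1.00 uM after normalisation.
    """

    k1: float
    k2: float
    a0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0 and self.a0 > 0):
            raise ValueError(
                f"SequentialParams requires k1, k2, a0 > 0; "
                f"got k1={self.k1}, k2={self.k2}, a0={self.a0}"
            )


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters.

    ``km`` in uM, ``vmax`` in uM/s, ``enzyme`` (total enzyme concentration)
    in uM.  The turnover number ``kcat`` is derived as vmax / enzyme.
    """

    km: float
    vmax: float
    enzyme: float | None = None

    def __post_init__(self) -> None:
        if not (self.km > 0 and self.vmax > 0):
            raise ValueError(f"MMParams requires km, vmax > 0; got km={self.km}, vmax={self.vmax}")
        if self.enzyme is not None and not self.enzyme > 0:
            raise ValueError(f"enzyme concentration must be > 0, got {self.enzyme}")

    @property
    def kcat(self) -> float:
        """Turnover number vmax / [E], 1/s."""
        if self.enzyme is None:
            raise ValueError("enzyme concentration not set; cannot derive kcat")
        return self.vmax / self.enzyme


@dataclass(frozen=True)
class DoseResponseParams:
    """Constrained variable-slope (four-parameter logistic) dose-response.

    ``ic50`` in nM; ``hill`` > 0 gives the inhibition orientation (response
    decreasing with concentration).  The published analysis constrains
    ``top`` = 100 % and ``bottom`` = 0 %.
    """

    ic50: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50}")
        if not self.top > self.bottom:
            raise ValueError(f"top ({self.top}) must exceed bottom ({self.bottom})")


def sequential_species(t, p: SequentialParams):
    """Species concentrations of the consecutive reaction S -> I -> P.

    Returns ``(S, I, P)`` in uM at time(s) ``t`` (seconds):

        S(t) = A0 e^(-k1 t)
        I(t) = A0 k1/(k2-k1) (e^(-k1 t) - e^(-k2 t))
        P(t) = A0 - S(t) - I(t)

    When k1 and k2 coincide to within :data:`EQUAL_RATE_RTOL` the analytic
    limit with k = (k1+k2)/2 is used instead:

        I(t) = A0 k t e^(-k t),   P(t) = A0 (1 - (1 + k t) e^(-k t))

    All three species are nonnegative and sum to A0 (mass conservation).
    """
    t = _check_time(t)
    k1, k2, a0 = p.k1, p.k2, p.a0
    if abs(k1 - k2) < EQUAL_RATE_RTOL * max(k1, k2):
        k = 0.5 * (k1 + k2)
        e = np.exp(-k * t)
        s = a0 * e
        i = a0 * k * t * e
    else:
        s = a0 * np.exp(-k1 * t)
        i = a0 * (k1 / (k2 - k1)) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    prod = np.maximum(a0 - s - i, 0.0)
    return s, i, prod


def sequential_product(t, p: SequentialParams):
    """Cleaved-product concentration P(t) of the consecutive reaction, uM.

    P is nondecreasing in t, 0 at t=0, and approaches A0.
    """
    return sequential_species(t, p)[2]


def intermediate_peak_time(p: SequentialParams) -> float:
    """Time of maximal intermediate concentration: ln(k1/k2)/(k1-k2) s.

    In the equal-rate limit this reduces to 1/k with k = (k1+k2)/2.
    """
    k1, k2 = p.k1, p.k2
    if abs(k1 - k2) < EQUAL_RATE_RTOL * max(k1, k2):
        return 2.0 / (k1 + k2)
    return float(np.log(k1 / k2) / (k1 - k2))


def one_phase_association(t, k: float, plateau: float = 1.0):
    """Single-exponential approach to a plateau: plateau * (1 - e^(-k t)).

    Used for the cleavage-only (pre-deaminated reporter + endonuclease)
    control, whose product formation is a single first-order step.
    """
    if not k > 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    if not plateau > 0:
        raise ValueError(f"plateau must be > 0, got {plateau}")
    t = _check_time(t)
    return plateau * -np.expm1(-k * t)


def mm_velocity(s, p: MMParams):
    """Michaelis-Menten initial velocity v = Vmax * S / (Km + S), uM/s."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be nonnegative")
    return p.vmax * s / (p.km + s)


def kcat_from_vmax(vmax: float, enzyme: float) -> float:
    """Turnover number kcat = Vmax / [E] (1/s), for [E] in uM and Vmax in uM/s."""
    if not enzyme > 0:
        raise ValueError(f"enzyme concentration must be > 0, got {enzyme}")
    if vmax < 0:
        raise ValueError(f"vmax must be nonnegative, got {vmax}")
    return vmax / enzyme


def dose_response(conc, p: DoseResponseParams):
    """Percent activity at inhibitor concentration(s) ``conc`` (nM).

    Variable-slope logistic in log10-concentration space,

        response = bottom + (top - bottom) / (1 + 10^((log10 c - log10 IC50) * hill))

    oriented so that response decreases with concentration for hill > 0;
    response(IC50) = (top + bottom) / 2, and response -> top as c -> 0.
    At hill = 1 this coincides with the hyperbolic form
    bottom + (top - bottom) * IC50 / (IC50 + c).
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("inhibitor concentrations must be > 0 (log-scale model)")
    x = (np.log10(conc) - np.log10(p.ic50)) * p.hill
    return p.bottom + (p.top - p.bottom) / (1.0 + 10.0 ** x)
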