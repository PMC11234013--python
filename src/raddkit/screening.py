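"""Plate-level assay-quality statistics for screening readiness.

From endpoint fluorescence of positive (full reaction) and negative (no
deaminase) wells:

* Z'-factor = 1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg|;  >= 0.5 marks an
  assay as excellent for high-throughput screening,
* signal-to-noise = (mu_pos - mu_neg) / sd_neg,
* signal-to-background = mu_pos / mu_neg.

Sample standard deviations (n - 1) throughout, since screening plates use
small well groups.  An alternative pooled-noise S:N,
(mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2), is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import endpoint_signal

__all__ = ["ScreenStats", "z_prime", "signal_to_noise", "signal_to_background", "screen_summary"]


@dataclass(frozen=True)
class ScreenStats:
    mu_pos: float
    mu_neg: float
    sd_pos: float
    sd_neg: float
    n_pos: int
    n_neg: int
    z_prime: float
    snr: float
    sbr: float
    #: mean +/- 3 SD bands per group, as drawn on screening-window plots
    pos_band: tuple = ()
    neg_band: tuple = ()


def _group(values, name: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"{name} group needs >= 2 wells, got {v.size}")
    return v


def z_prime(pos, neg) -> float:
    """Screening-window coefficient; 1 for perfectly separated groups."""
    p, n = _group(pos, "positive"), _group(neg, "negative")
    mu_p, mu_n = p.mean(), n.mean()
    if mu_p == mu_n:
        raise ValueError("Z' undefined: positive and negative means are equal")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / abs(mu_p - mu_n))


def signal_to_noise(pos, neg, method: str = "background_sd") -> float:
    """(mu_pos - mu_neg) / sd_neg, or pooled-SD variant with method='pooled'."""
    p, n = _group(pos, "positive"), _group(neg, "negative")
    delta = p.mean() - n.mean()
    if method == "background_sd":
        sd = n.std(ddof=1)
    elif method == "pooled":
        sd = np.sqrt(p.std(ddof=1) ** 2 + n.std(ddof=1) ** 2)
    else:
        raise ValueError(f"unknown S:N method {method!r}")
    if sd == 0:
        raise ValueError("S:N undefined: zero noise standard deviation")
    return float(delta / sd)


def signal_to_background(pos, neg) -> float:
    """mu_pos / mu_neg."""
    p, n = _group(pos, "positive"), _group(neg, "negative")
    if n.mean() <= 0:
        raise ValueError("S:B undefined: nonpositive background mean")
    return float(p.mean() / n.mean())


def screen_summary(
    traces,
    t_end: float = 3600.0,
    positive_role: str = "sample",
    negative_role: str = "negative_tc",
    snr_method: str = "background_sd",
) -> ScreenStats:
    """All screening metrics from endpoint reads of a plate's well groups."""
    pos = [endpoint_signal(tr, t_end) for tr in traces if tr.role == positive_role]
    neg = [endpoint_signal(tr, t_end) for tr in traces if tr.role == negative_role]
    p, n = _group(pos, "positive"), _group(neg, "negative")
    mu_p, mu_n = float(p.mean()), float(n.mean())
    sd_p, sd_n = float(p.std(ddof=1)), float(n.std(ddof=1))
    return ScreenStats(
        mu_pos=mu_p,
        mu_neg=mu_n,
        sd_pos=sd_p,
        sd_neg=sd_n,
        n_pos=p.size,
        n_neg=n.size,
        z_prime=z_prime(p, n),
        snr=signal_to_noise(p, n, method=snr_method),
        sbr=signal_to_background(p, n),
        pos_band=(mu_p - 3 * sd_p, mu_p + 3 * sd_p),
        neg_band=(mu_n - 3 * sd_n, mu_n + 3 * sd_n),
    )
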