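"""Synthetic study calibration curve (synthetic data — not a measured dataset).

Bayesian chronological modelling of pedigrees is sensitive to the *shape* of
the calibration curve, not to its absolute values.  This module generates a
deterministic, fully synthetic curve that emulates the structural regimes a
real atmospheric curve exhibits, so that sampler behaviour (bracketing,
inversion resolution, plateau cut-offs, anchor points) can be exercised and
tested without shipping any measured calibration dataset:

* a long **plateau** between 770 and 400 cal BC with two sub-plateaus split at
  540 cal BC and two down-wiggles (troughs) in its first half — dates falling
  in a trough calibrate to wide, multi-modal ranges and appear inverted;
* a **steep** stretch at 7600–7500 cal BC followed by a wiggle at 7470–7330
  cal BC — dates on the steep part calibrate to very narrow ranges;
* a **mixed** stretch at 2040–1770 cal BC: two wiggle packets separated by a
  short steep section, emulating an ordinary Bronze-Age-like curve section;
* a steep **anchor** approach at 810–770 cal BC immediately before the
  plateau, so a single early date can pin down a whole pedigree;
* slope ~1 BP per calendar year everywhere else.

The curve is piecewise linear between 5-year knots; the curve uncertainty
varies mildly around 10 BP.  All feature positions are calendar-year
parameters of this generator, fixed here as the package's study conditions.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .calcurve import CalCurve

__all__ = ["study_curve", "linear_curve"]

# (end_year, slope) segments, oldest to youngest; slope = -d(mu)/d(year) in BP/yr.
_SEGMENTS: list[tuple[float, float]] = [
    (-7600, 1.0),   # background
    (-7500, 2.2),   # steep section
    (-7470, 1.0),
    (-7400, 0.1),   # wiggle shelf after the steep section
    (-7330, 0.5),
    (-2040, 1.05),  # background
    (-1940, 0.25),  # mixed: first wiggle packet (sine added below)
    (-1880, 1.8),   # mixed: short steep section
    (-1770, 0.2),   # mixed: second wiggle packet (sine added below)
    (-810, 1.0),    # background
    (-770, 2.5),    # steep anchor approach into the plateau
    (-745, 1.2),    # plateau shoulder
    (-720, 0.2),
    (-700, 1.8),    # trough A falling limb
    (-680, -1.8),   # trough A rising limb (inversion)
    (-660, 1.1),    # trough B falling limb
    (-650, 0.5),    # trough B bottom (around 655 cal BC)
    (-625, -1.0),   # trough B rising limb (inversion)
    (-560, 0.15),   # first sub-plateau
    (-540, 2.3),    # sub-plateau split at 540 cal BC
    (-420, 0.08),   # second sub-plateau
    (-400, 1.2),    # plateau exit
    (-200, 1.0),    # background
]
_START_YEAR = -8000.0
_START_MU = 9950.0
# (start, end, amplitude BP, cycles): zero-at-edges sine packets in the mixed section
_WIGGLES = [(-2040.0, -1940.0, 12.0, 2), (-1880.0, -1770.0, 12.0, 2)]


def _mu_at(years: np.ndarray) -> np.ndarray:
    # integrate the piecewise slope from the oldest end
    breaks = [_START_YEAR] + [e for e, _ in _SEGMENTS]
    mus = [_START_MU]
    for (end, slope), start in zip(_SEGMENTS, breaks):
        mus.append(mus[-1] - slope * (end - start))
    mu = np.empty_like(years, dtype=float)
    for i, y in enumerate(np.asarray(years, dtype=float)):
        j = int(np.searchsorted(breaks, y, side="right")) - 1
        j = min(max(j, 0), len(_SEGMENTS) - 1)
        slope = _SEGMENTS[j][1]
        mu[i] = mus[j] - slope * (y - breaks[j])
    for a, b, amp, cycles in _WIGGLES:
        inside = (years >= a) & (years <= b)
        mu[inside] += amp * np.sin(2 * np.pi * cycles * (years[inside] - a) / (b - a))
    return mu


@lru_cache(maxsize=4)
def study_curve(knot_step: float = 5.0) -> CalCurve:
    """The synthetic study curve on 5-year knots over 8000–200 cal BC."""
    years = np.arange(_START_YEAR, -200.0 + 0.5 * knot_step, knot_step)
    mu = _mu_at(years)
    sigma = 10.0 + 2.0 * np.sin(years / 150.0)
    return CalCurve(name="synthetic-study", knots_cal=years, mu=mu, sigma_curve=sigma)


def linear_curve(
    start: float = -3000.0,
    end: float = -1000.0,
    slope: float = 1.0,
    mu_start: float | None = None,
    sigma: float = 10.0,
    knot_step: float = 10.0,
    name: str = "synthetic-linear",
) -> CalCurve:
    """A strictly linear synthetic curve: mu = mu_start - slope*(year-start).

    Used for closed-form checks — on an affine curve the calibrated posterior
    is a (transformed) normal distribution.
    """
    years = np.arange(start, end + 0.5 * knot_step, knot_step)
    if mu_start is None:
        mu_start = 1950.0 - start
    mu = mu_start - slope * (years - start)
    sig = np.full_like(years, float(sigma))
    return CalCurve(name=name, knots_cal=years, mu=mu, sigma_curve=sig)
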