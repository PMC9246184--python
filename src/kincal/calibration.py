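"""Single-date calibration: calendar posterior, HPD ranges, span accounting.

A conventional radiocarbon determination ``x +- sigma`` (years BP) is mapped
through a calibration curve ``mu(theta), sigma_curve(theta)`` to a posterior
density over calendar years ``theta``::

    p(theta | x)  propto  exp( -(x - mu(theta))^2 / (2 (sigma^2 + sigma_curve(theta)^2)) )

evaluated on a uniform calendar grid (default 1 year) and normalised to sum
to 1.  Measurement and curve uncertainties combine in quadrature.  Highest-
posterior-density (HPD) regions at 68.2% / 95.4% are extracted by threshold
search over the grid; the *outer span* of a set of HPD sub-ranges is the
distance from the oldest to the youngest bound with the gaps between
sub-ranges ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calcurve import CalCurve

__all__ = [
    "C14Determination",
    "CalendarPDF",
    "HPDRange",
    "HPDRanges",
    "calibrate",
    "hpd",
    "outer_span",
    "sweep_spans",
]

TWO_SIGMA = 0.954
ONE_SIGMA = 0.682
_SUPPORT_EPS = 1e-12


@dataclass(frozen=True)
class C14Determination:
    """One measured or simulated radiocarbon date.

    ``hbco_offset`` is the human bone collagen offset in years (0-25), the lag
    between carbon incorporation into collagen and death; it is *not* applied
    by :func:`calibrate` — see :func:`kincal.pedigree_model.apply_hbco`.
    """

    id: str
    age: float
    err: float
    hbco_offset: float = 0.0
    cn_ratio: float | None = None
    hbco_applied: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.age):
            raise ValueError(f"{self.id}: age must be finite")
        if self.err <= 0:
            raise ValueError(f"{self.id}: err must be > 0")
        if not (0.0 <= self.hbco_offset <= 25.0):
            raise ValueError(f"{self.id}: hbco_offset must lie in [0, 25]")


@dataclass(frozen=True)
class CalendarPDF:
    """Probability distribution over calendar years on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    edge_warning: bool = False

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if grid.size != dens.size or grid.size < 1:
            raise ValueError("grid/density mismatch")
        if np.any(dens < 0):
            raise ValueError("density must be >= 0")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", dens)

    @property
    def step(self) -> float:
        if self.grid.size < 2:
            return 1.0
        return float(self.grid[1] - self.grid[0])

    def normalised(self) -> "CalendarPDF":
        total = float(self.density.sum())
        if total <= 0:
            raise ValueError("cannot normalise an all-zero density")
        return replace(self, density=self.density / total)

    def mean(self) -> float:
        return float(np.sum(self.grid * self.density) / np.sum(self.density))

    def median(self) -> float:
        c = np.cumsum(self.density) / np.sum(self.density)
        return float(self.grid[np.searchsorted(c, 0.5)])


@dataclass(frozen=True)
class HPDRange:
    """One contiguous HPD sub-range; bounds are signed years, old -> young."""

    older: float
    younger: float
    mass: float

    @property
    def width(self) -> float:
        return self.younger - self.older


@dataclass(frozen=True)
class HPDRanges:
    level: float
    ranges: tuple[HPDRange, ...] = field(default_factory=tuple)

    @property
    def outer_span(self) -> float:
        return outer_span(self)

    @property
    def oldest(self) -> float:
        return self.ranges[0].older

    @property
    def youngest(self) -> float:
        return self.ranges[-1].younger

    def contains(self, year: float) -> bool:
        return any(r.older <= year <= r.younger for r in self.ranges)


def calibrate(det: C14Determination, curve: CalCurve, resolution: float = 1.0) -> CalendarPDF:
    """Calibrate a single determination against a curve.

    The result is restricted to the contiguous window where the density
    exceeds ``1e-12`` of its maximum and normalised to sum to 1.  If the
    density peaks at the very edge of the curve support the result carries
    ``edge_warning=True`` (the date reaches beyond the curve).
    """
    grid, mu, sig = curve.sampled(resolution)
    var = det.err**2 + sig**2
    dens = np.exp(-((det.age - mu) ** 2) / (2.0 * var))
    peak = int(np.argmax(dens))
    edge = peak in (0, grid.size - 1)
    keep = np.nonzero(dens > _SUPPORT_EPS * dens[peak])[0]
    lo, hi = int(keep[0]), int(keep[-1])
    pdf = CalendarPDF(grid=grid[lo : hi + 1], density=dens[lo : hi + 1], edge_warning=edge)
    return pdf.normalised()


def hpd(pdf: CalendarPDF, level: float = TWO_SIGMA) -> HPDRanges:
    """Highest-posterior-density region of cumulative mass ``level``.

    Grid cells are admitted in decreasing order of density until the target
    mass is reached (ties broken toward older cells, so output is
    deterministic), then assembled into maximal contiguous runs.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    dens = pdf.density / pdf.density.sum()
    # stable sort on -density: ties keep grid order, i.e. older cells first
    order = np.argsort(-dens, kind="stable")
    csum = np.cumsum(dens[order])
    n_take = int(np.searchsorted(csum, level)) + 1
    n_take = min(n_take, dens.size)
    mask = np.zeros(dens.size, dtype=bool)
    mask[order[:n_take]] = True
    ranges: list[HPDRange] = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            ranges.append(
                HPDRange(
                    older=float(pdf.grid[i]),
                    younger=float(pdf.grid[j]),
                    mass=float(dens[i : j + 1].sum()),
                )
            )
            i = j + 1
        else:
            i += 1
    return HPDRanges(level=level, ranges=tuple(ranges))


def outer_span(ranges: HPDRanges) -> float:
    """Oldest bound minus youngest bound across all sub-ranges (gaps ignored)."""
    if not ranges.ranges:
        raise ValueError("empty HPD range set")
    return float(ranges.ranges[-1].younger - ranges.ranges[0].older)


def sweep_spans(
    curve: CalCurve,
    bp_start: float,
    bp_end: float,
    step: float = 5.0,
    err: float = 25.0,
    level: float = TWO_SIGMA,
    resolution: float = 1.0,
) -> pd.DataFrame:
    """Outer 2-sigma span of simulated ages swept across the curve.

    Ages run from ``bp_start`` down to ``bp_end`` (exclusive of anything below)
    in steps of ``step`` BP, each calibrated with uncertainty ``err``.  Ages
    whose posterior piles up at the curve edge are skipped (flagged in the
    ``skipped`` column of the returned frame).
    """
    if bp_start <= bp_end:
        raise ValueError("bp_start must exceed bp_end")
    if step <= 0:
        raise ValueError("step must be > 0")
    rows = []
    n = int(np.floor((bp_start - bp_end) / step)) + 1
    for k in range(n):
        age = bp_start - k * step
        det = C14Determination(id=f"sim_{age:g}", age=age, err=err)
        pdf = calibrate(det, curve, resolution=resolution)
        if pdf.edge_warning:
            rows.append((age, np.nan, np.nan, np.nan, True))
            continue
        r = hpd(pdf, level)
        rows.append((age, outer_span(r), r.oldest, r.youngest, False))
    return pd.DataFrame(rows, columns=["age_bp", "span", "oldest", "youngest", "skipped"])
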