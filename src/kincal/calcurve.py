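"""Radiocarbon calibration curves: loading, interpolation, reverse lookup.

A calibration curve maps calendar age to the expected conventional radiocarbon
age (in years BP, referenced to AD 1950) together with a 1-sigma curve
uncertainty.  Calendar time is stored internally as a *signed* year on a
continuous axis with ``calAD = 1950 - calBP``; negative years are displayed as
"N cal BC" with ``N = -year`` (so 2500 cal BP corresponds to -550, shown as
550 cal BC).  No year-zero correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CalCurve",
    "CurveFormatError",
    "CurveRangeError",
    "load_curve",
    "write_curve",
    "format_year",
]


class CurveFormatError(ValueError):
    """A curve file failed to parse or violated a curve invariant."""


class CurveRangeError(ValueError):
    """A calendar year fell outside the curve's support."""


def format_year(year: float) -> str:
    """Render a signed calendar year in cal BC / cal AD notation."""
    y = round(float(year))
    if y < 0:
        return f"{-y} cal BC"
    return f"{y} cal AD"


@dataclass(frozen=True)
class CalCurve:
    """A calibration curve defined by knots (calendar year, mu, sigma).

    Parameters
    ----------
    name:
        Text label, e.g. ``"intcal13"``.
    knots_cal:
        Signed calendar years at the knots, strictly increasing.
    mu:
        Conventional radiocarbon age (BP) at each knot.
    sigma_curve:
        1-sigma curve uncertainty (BP) at each knot, strictly positive.
    """

    name: str
    knots_cal: np.ndarray
    mu: np.ndarray
    sigma_curve: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots_cal, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sig = np.asarray(self.sigma_curve, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise CurveFormatError(f"curve {self.name!r}: needs at least 2 knots")
        if knots.size != mu.size or knots.size != sig.size:
            raise CurveFormatError(f"curve {self.name!r}: column length mismatch")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sig)) and np.all(np.isfinite(knots))):
            raise CurveFormatError(f"curve {self.name!r}: non-finite values")
        if np.any(np.diff(knots) <= 0):
            raise CurveFormatError(
                f"curve {self.name!r}: knots not strictly monotone in calendar age"
            )
        if np.any(sig <= 0):
            raise CurveFormatError(f"curve {self.name!r}: sigma_curve must be > 0")
        object.__setattr__(self, "knots_cal", knots)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma_curve", sig)

    @property
    def support(self) -> tuple[float, float]:
        """(oldest, youngest) signed calendar year covered by the curve."""
        return float(self.knots_cal[0]), float(self.knots_cal[-1])

    def _check_support(self, year: float) -> None:
        lo, hi = self.support
        if not (lo <= year <= hi):
            raise CurveRangeError(
                f"year {year} outside curve {self.name!r} support [{lo}, {hi}]"
            )

    def mu_sigma_at(self, year: float) -> tuple[float, float]:
        """Piecewise-linear interpolation of (mu, sigma_curve) at ``year``.

        Exact at knots; raises :class:`CurveRangeError` outside the support.
        """
        self._check_support(float(year))
        m = float(np.interp(year, self.knots_cal, self.mu))
        s = float(np.interp(year, self.knots_cal, self.sigma_curve))
        return m, s

    def reverse_lookup(self, yod: float) -> float:
        """Conventional age BP the curve assigns to a year-of-death.

        Evaluates the curve mean at ``yod`` and rounds to 0.1 BP; no
        measurement noise is added (simulated ages equal the curve value).
        """
        m, _ = self.mu_sigma_at(yod)
        return round(m, 1)

    def sampled(self, resolution: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Curve evaluated on a uniform calendar grid at ``resolution`` years.

        Returns ``(grid, mu, sigma)`` arrays covering the full support; the
        grid is aligned so that integer-resolution grids land on integer years.
        """
        lo, hi = self.support
        start = np.ceil(lo / resolution) * resolution
        grid = np.arange(start, hi + 0.5 * resolution, resolution)
        mu = np.interp(grid, self.knots_cal, self.mu)
        sig = np.interp(grid, self.knots_cal, self.sigma_curve)
        return grid, mu, sig


def load_curve(path: str | Path, dialect: str = "intcal", name: str | None = None) -> CalCurve:
    """Read a calibration curve from an IntCal ``.14c`` text file.

    The ``intcal`` dialect has '#'-prefixed header lines followed by records
    ``calBP, 14C age, error[, Delta14C, sigma]``, comma- or whitespace-
    separated; only the first three columns are consumed.  Records are
    re-sorted into increasing signed calendar year (``calAD = 1950 - calBP``).
    """
    if dialect != "intcal":
        raise ValueError(f"unknown curve dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) < 3:
                raise CurveFormatError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                calbp, age, err = (float(parts[0]), float(parts[1]), float(parts[2]))
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{lineno}: malformed record: {stripped!r}") from exc
            rows.append((calbp, age, err))
    if len(rows) < 2:
        raise CurveFormatError(f"{path}: fewer than 2 data records")
    # signed year; sort old -> young
    rows.sort(key=lambda r: 1950.0 - r[0])
    years = np.array([1950.0 - r[0] for r in rows])
    mu = np.array([r[1] for r in rows])
    sig = np.array([r[2] for r in rows])
    return CalCurve(name=name or path.stem, knots_cal=years, mu=mu, sigma_curve=sig)


def write_curve(curve: CalCurve, path: str | Path, comment: str = "") -> None:
    """Write a curve in the IntCal ``.14c`` three-column dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {curve.name}\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# CAL BP, 14C age, error\n")
        for year, m, s in zip(curve.knots_cal[::-1], curve.mu[::-1], curve.sigma_curve[::-1]):
            fh.write(f"{1950.0 - year:.1f},{m:.1f},{s:.1f}\n")
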