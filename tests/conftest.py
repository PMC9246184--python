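import numpy as np
import pytest
from hypothesis import settings

import kincal as kc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def curve():
    """The synthetic study curve shared across tests."""
    return kc.study_curve()


@pytest.fixture(scope="session")
def linear():
    """A strictly linear curve with known closed-form posteriors."""
    return kc.linear_curve(start=-3000, end=-1000, slope=1.0, sigma=10, knot_step=10)


@pytest.fixture()
def tiny_14c(tmp_path):
    """Write a 3-knot IntCal-dialect file and return its path."""
    path = tmp_path / "tiny.14c"
    path.write_text(
        "# synthetic 3-knot curve\n"
        "# CAL BP, 14C age, error\n"
        "2000,2100,10\n"
        "2005,2110,10\n"
        "2010,2120,10\n"
    )
    return path


def total_variation(a: kc.CalendarPDF, b: kc.CalendarPDF) -> float:
    """TV distance between two pdfs on equally-stepped, aligned grids."""
    res = a.step
    assert abs(res - b.step) < 1e-9
    lo = min(a.grid[0], b.grid[0])
    hi = max(a.grid[-1], b.grid[-1])
    grid = np.arange(lo, hi + 0.5 * res, res)

    def embed(p):
        out = np.zeros(grid.size)
        i0 = int(round((p.grid[0] - lo) / res))
        out[i0 : i0 + p.grid.size] = p.density / p.density.sum()
        return out

    return 0.5 * float(np.abs(embed(a) - embed(b)).sum())
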