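"""Emit and parse a restricted OxCal-style model dialect.

Only the constructs needed for contiguous ordered-phase pedigree models are
covered: ``Plot``, ``Sequence``, ``Boundary``, ``Phase``, ``R_Date`` and
``Interval(N(mean,sd))``.  The emitted text round-trips through the parser to
an equivalent model, and can be pasted into OxCal for cross-checking.
"""

from __future__ import annotations

import re

from .calibration import C14Determination
from .constraint_engine import ModelSpec

__all__ = ["to_oxcal", "parse_oxcal"]


def to_oxcal(spec: ModelSpec, dates: dict[str, C14Determination]) -> str:
    """Render a model as OxCal-dialect code (Sequence/Boundary/Phase nesting)."""
    names = spec.names()
    out: list[str] = ["Plot()", "{", " Sequence()", " {"]
    out.append(f'  Boundary("Start {names[0]}");')
    for j, phase in enumerate(spec.phases):
        out.append(f'  Phase("{names[j]}")')
        out.append("  {")
        for did in phase:
            det = dates[did]
            out.append(f'   R_Date("{did}",{det.age:g},{det.err:g});')
        out.append("  };")
        if j in spec.intervals:
            mean, sd = spec.intervals[j]
            out.append(f"  Interval(N({mean:g},{sd:g}));")
        if j < spec.n_gen - 1:
            out.append(f'  Boundary("{j + 1}/{j + 2}");')
    out.append(f'  Boundary("End {names[-1]}");')
    out.append(" };")
    out.append("};")
    return "\n".join(out) + "\n"


_TOKEN = re.compile(
    r"""\s*(?:
        (?P<str>"[^"]*")
      | (?P<num>-?\d+(?:\.\d+)?)
      | (?P<name>[A-Za-z_][A-Za-z_0-9]*)
      | (?P<punct>[(){};,])
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ValueError(f"cannot tokenize OxCal code at: {text[pos:pos + 30]!r}")
        tokens.append(m.group().strip())
        pos = m.end()
    return tokens


def parse_oxcal(text: str) -> tuple[ModelSpec, list[C14Determination]]:
    """Parse the restricted dialect back into a model spec plus its dates."""
    toks = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return toks[pos] if pos < len(toks) else None

    def take(expected: str | None = None) -> str:
        nonlocal pos
        if pos >= len(toks):
            raise ValueError("unexpected end of OxCal code")
        tok = toks[pos]
        pos += 1
        if expected is not None and tok != expected:
            raise ValueError(f"expected {expected!r}, got {tok!r}")
        return tok

    phases: list[tuple[str, ...]] = []
    phase_names: list[str] = []
    intervals: dict[int, tuple[float, float]] = {}
    dates: list[C14Determination] = []

    def parse_block() -> None:
        take("{")
        while peek() != "}":
            parse_statement()
        take("}")
        if peek() == ";":
            take(";")

    def parse_statement() -> None:
        name = take()
        if name == "Boundary":
            take("(")
            take()  # label
            take(")")
            take(";")
        elif name in ("Plot", "Sequence"):
            take("(")
            take(")")
            parse_block()
        elif name == "Phase":
            take("(")
            label = take().strip('"')
            take(")")
            members: list[str] = []
            take("{")
            while peek() != "}":
                kw = take("R_Date")
                take("(")
                did = take().strip('"')
                take(",")
                age = float(take())
                take(",")
                err = float(take())
                take(")")
                take(";")
                assert kw == "R_Date"
                members.append(did)
                dates.append(C14Determination(id=did, age=age, err=err))
            take("}")
            take(";")
            phases.append(tuple(members))
            phase_names.append(label)
        elif name == "Interval":
            take("(")
            take("N")
            take("(")
            mean = float(take())
            take(",")
            sd = float(take())
            take(")")
            take(")")
            take(";")
            intervals[len(phases) - 1] = (mean, sd)
        else:
            raise ValueError(f"unsupported OxCal construct {name!r}")

    parse_statement()
    if not phases:
        raise ValueError("no Phase() blocks found")
    spec = ModelSpec(
        phases=tuple(phases),
        contiguous=True,
        intervals=intervals,
        phase_names=tuple(phase_names),
    )
    return spec, dates
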