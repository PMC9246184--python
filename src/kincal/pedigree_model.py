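"""Pedigrees into chronological models: HBCO, QC, model building, caps.

Generation-levelled pedigrees (from ancient-DNA kinship analysis) are turned
into ordered-phase model specs: one phase per generation level, sequenced
oldest to youngest.  Sibling birth order within a level is never constrained.
This module also applies the human bone collagen offset (HBCO) correction,
the collagen C:N quality gate, and post-hoc year-of-death separation caps on
modelled ranges (a maximum number of years between the deaths of consecutive
generations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import TWO_SIGMA, C14Determination, CalendarPDF, HPDRanges, hpd
from .constraint_engine import ModelSpec, PosteriorSummary

__all__ = [
    "Individual",
    "Pedigree",
    "apply_hbco",
    "cn_qc",
    "build_model",
    "pairwise_death_order_models",
    "separation_cap",
    "yod_separation_cap",
    "load_date_table",
    "load_pedigree",
    "bundled_path",
]

CN_RANGE = (2.9, 3.6)


@dataclass(frozen=True)
class Individual:
    """One pedigree member with anthropological age-at-death bounds."""

    id: str
    generation_level: int
    aad_min: float
    aad_max: float
    yod: float | None = None  # known year-of-death (simulations only)
    det_id: str | None = None

    def __post_init__(self) -> None:
        if self.generation_level < 1:
            raise ValueError(f"{self.id}: generation_level must be >= 1")
        if self.aad_min > self.aad_max:
            raise ValueError(f"{self.id}: aad_min > aad_max")

    @property
    def date_id(self) -> str:
        return self.det_id or self.id


@dataclass(frozen=True)
class Pedigree:
    individuals: tuple[Individual, ...]
    edges: tuple[tuple[str, str], ...] = ()
    strands: dict[str, tuple[str, ...]] | None = None
    name: str = "pedigree"

    def __post_init__(self) -> None:
        ids = {i.id for i in self.individuals}
        by_id = {i.id: i for i in self.individuals}
        for parent, child in self.edges:
            if parent not in ids or child not in ids:
                raise ValueError(f"edge ({parent},{child}) references unknown individual")
            if by_id[child].generation_level != by_id[parent].generation_level + 1:
                raise ValueError(
                    f"edge ({parent},{child}): child's generation level must be parent's + 1"
                )
        # acyclicity (levels increase along edges, but check explicitly anyway)
        children: dict[str, list[str]] = {}
        for p, c in self.edges:
            children.setdefault(p, []).append(c)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in children.get(node, []):
                if state.get(nxt) == 1:
                    raise ValueError("pedigree edge graph contains a cycle")
                if state.get(nxt, 0) == 0:
                    visit(nxt)
            state[node] = 2

        for i in self.individuals:
            if state.get(i.id, 0) == 0:
                visit(i.id)

    def by_id(self, ind_id: str) -> Individual:
        for i in self.individuals:
            if i.id == ind_id:
                return i
        raise KeyError(ind_id)

    def levels(self) -> list[int]:
        return sorted({i.generation_level for i in self.individuals})


def apply_hbco(det: C14Determination) -> C14Determination:
    """Subtract the HBCO offset from the conventional age (once only).

    Subtracting the offset lowers the BP age, which moves the calibrated
    distribution *younger* — the measured collagen predates death.
    """
    if det.hbco_applied:
        raise ValueError(f"{det.id}: HBCO correction already applied")
    return replace(det, age=det.age - det.hbco_offset, hbco_applied=True)


def cn_qc(ratio: float) -> bool:
    """Collagen C:N quality gate: pass iff 2.9 <= ratio <= 3.6 (inclusive)."""
    if ratio <= 0:
        raise ValueError("C:N ratio must be positive")
    return CN_RANGE[0] <= ratio <= CN_RANGE[1]


def build_model(
    ped: Pedigree,
    dates: dict[str, C14Determination],
    use_intervals: bool = False,
    interval_means: dict[int, float] | None = None,
    interval_sd: float = 10.0,
    use_hbco: bool = False,
    level_merge: dict[int, int] | None = None,
    include: set[str] | None = None,
) -> tuple[ModelSpec, list[C14Determination]]:
    """One phase per (merged) generation level, ordered oldest to youngest.

    ``level_merge`` remaps raw generation levels onto model levels; by default
    missing levels are collapsed (e.g. levels 1,2,4 become phases 1,2,3).  A
    collapsed gap that is known to hide a missing generation can be given an
    interval prior instead via ``interval_means``, keyed by the 0-based gap
    index between consecutive *collapsed* phases.
    """
    members = [i for i in ped.individuals if include is None or i.id in include]
    undated = [i.id for i in members if i.date_id not in dates]
    if undated:
        raise ValueError(f"individuals without a date: {undated}")
    if level_merge is None:
        raw = sorted({i.generation_level for i in members})
        level_merge = {lvl: k + 1 for k, lvl in enumerate(raw)}
    phases_map: dict[int, list[str]] = {}
    for ind in members:
        lvl = level_merge[ind.generation_level]
        phases_map.setdefault(lvl, []).append(ind.date_id)
    model_levels = sorted(phases_map)
    if model_levels != list(range(model_levels[0], model_levels[0] + len(model_levels))):
        raise ValueError(
            f"generation levels not contiguous after merge: {model_levels}; "
            "supply level_merge or interval_means"
        )
    phases = tuple(tuple(phases_map[lvl]) for lvl in model_levels)
    intervals: dict[int, tuple[float, float]] = {}
    if use_intervals and interval_means:
        intervals = {g: (m, interval_sd) for g, m in interval_means.items()}
    spec = ModelSpec(
        phases=phases,
        contiguous=True,
        intervals=intervals,
        phase_names=tuple(f"Gen {lvl}" for lvl in model_levels),
    )
    used = [dates[i.date_id] for lvl in model_levels for i in members
            if level_merge[i.generation_level] == lvl]
    if use_hbco:
        used = [apply_hbco(d) if not d.hbco_applied and d.hbco_offset > 0 else d for d in used]
    return spec, used


def pairwise_death_order_models(
    parent: Individual,
    child: Individual,
    dates: dict[str, C14Determination],
    scenarios: list[tuple[tuple[str, str], float, float]],
) -> list[tuple[str, ModelSpec, list[C14Determination]]]:
    """Two-phase death-order models for a parent/child pair.

    Each scenario is ``((first_id, second_id), interval_mean, interval_sd)``:
    the first individual died before or simultaneously with the second (the
    gap can be 0 or more years), with a normal prior on the gap.  Returns one
    labelled model per scenario for agreement-index comparison.
    """
    if not scenarios:
        raise ValueError("empty scenario list")
    pair = {parent.id: parent, child.id: child}
    out = []
    for (first, second), mean, sd in scenarios:
        if first not in pair or second not in pair:
            raise KeyError(f"scenario references unknown individual ({first}, {second})")
        d_first, d_second = pair[first].date_id, pair[second].date_id
        if d_first not in dates or d_second not in dates:
            raise ValueError("both individuals must be dated")
        spec = ModelSpec(
            phases=((d_first,), (d_second,)),
            contiguous=True,
            intervals={0: (mean, sd)},
            phase_names=(first, second),
        )
        label = f"{first} before {second} ({mean:g}+-{sd:g})"
        out.append((label, spec, [dates[d_first], dates[d_second]]))
    return out


def separation_cap(
    end_gen1_year: float,
    generation: int,
    sep: float,
    gaps: list[float] | None = None,
) -> float:
    """Youngest admissible year for generation ``k`` (1-based) under a
    year-of-death separation cap.

    ``end_gen1_year`` is the youngest 2-sigma bound of the first generation
    (signed year).  Each of the ``k-1`` gaps contributes ``min(sep, gap)``
    when the between-generation gap is known, else ``sep``.
    """
    if sep <= 0:
        raise ValueError("sep must be > 0")
    if generation < 1:
        raise ValueError("generation is 1-based")
    total = 0.0
    for g in range(generation - 1):
        gap = gaps[g] if gaps is not None and g < len(gaps) else sep
        total += min(sep, gap)
    return end_gen1_year + total


def yod_separation_cap(
    summary: PosteriorSummary,
    sep: float,
    gaps: list[float] | None = None,
    cap_older: bool = False,
) -> dict[str, HPDRanges]:
    """Truncate modelled 2-sigma ranges by cumulative death-separation caps.

    For a date in phase ``k`` (1-based) the younger bound is capped at
    ``end(gen 1) + sum of min(sep, gap)`` over the preceding gaps; masses are
    renormalised within the cap.  Older-end caps (from the last generation
    backwards, unclipped) are applied only on request — they only bind when
    between-generation gaps exceed ``sep``.  Capping never widens a range and
    never changes the phase order.
    """
    if sep <= 0:
        raise ValueError("sep must be > 0")
    k_phases = summary.spec.n_gen
    out: dict[str, HPDRanges] = {}
    if k_phases == 1:
        return {did: summary.ranges2[did] for did in summary.spec.date_ids}
    end_gen1 = max(summary.ranges2[d].youngest for d in summary.spec.phases[0])
    start_last = min(summary.ranges2[d].oldest for d in summary.spec.phases[-1])
    for j, phase in enumerate(summary.spec.phases):
        young_cap = separation_cap(end_gen1, j + 1, sep, gaps)
        old_cap = start_last - (k_phases - 1 - j) * sep if cap_older else -np.inf
        for did in phase:
            pdf = summary.marginals[did]
            keep = (pdf.grid <= young_cap) & (pdf.grid >= old_cap)
            if not np.any(keep):
                out[did] = HPDRanges(level=TWO_SIGMA, ranges=())
                continue
            capped = CalendarPDF(grid=pdf.grid[keep], density=pdf.density[keep]).normalised()
            out[did] = hpd(capped, TWO_SIGMA)
    return out


# ---------------------------------------------------------------------------
# bundled fixtures (case-study date table and pedigree files)
# ---------------------------------------------------------------------------

def bundled_path(*parts: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(resources.files("kincal").joinpath("data", *parts))  # type: ignore[arg-type]


def load_date_table(path: str | Path | None = None, site: str | None = None) -> pd.DataFrame:
    """Read a delimited date table (default: the bundled case-study table).

    Columns: site, feature, id, generation_level, c14_age, err, aad_min,
    aad_max, hbco.  ``site`` filters to one site abbreviation.
    """
    path = Path(path) if path is not None else bundled_path("table1.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    if site is not None:
        df = df[df["site"] == site].reset_index(drop=True)
    return df


def determinations_from_table(df: pd.DataFrame) -> dict[str, C14Determination]:
    return {
        row["id"]: C14Determination(
            id=row["id"],
            age=float(row["c14_age"]),
            err=float(row["err"]),
            hbco_offset=float(row["hbco"]),
        )
        for _, row in df.iterrows()
    }


def load_pedigree(site_or_path: str | Path) -> Pedigree:
    """Load a pedigree file: an individuals table with an optional edge list.

    The file holds '#' comments, a block of individual rows
    ``id<TAB>generation_level<TAB>aad_min<TAB>aad_max`` and, after a line
    ``[edges]``, rows ``parent_id<TAB>child_id``.  Site abbreviations
    (``post``, ``post_grandfather``, ``obkr``, ``aiti``) resolve to bundled
    fixtures.
    """
    path = Path(site_or_path)
    if not path.exists():
        path = bundled_path("pedigrees", f"{str(site_or_path).lower()}.tsv")
    individuals: list[Individual] = []
    edges: list[tuple[str, str]] = []
    in_edges = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[edges]":
            in_edges = True
            continue
        parts = line.split("\t")
        if in_edges:
            edges.append((parts[0], parts[1]))
        else:
            individuals.append(
                Individual(
                    id=parts[0],
                    generation_level=int(parts[1]),
                    aad_min=float(parts[2]),
                    aad_max=float(parts[3]),
                )
            )
    return Pedigree(
        individuals=tuple(individuals), edges=tuple(edges), name=path.stem
    )
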