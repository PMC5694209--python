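"""Tabulations over a final MTF set.

Reproduces the field's standard summary views: a family x species count
matrix, per-family totals (leaderboard), the TM-count distribution with
percentages, and the location-pattern breakdown for single- and
double-span proteins.  All percentages are conventional half-up rounding
at one decimal; raw (unrounded) percents within one denominator group sum
to 100 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import ClassifyParams, pattern_code
from .model import MtfRecord, MtfscanError
from ._util import round_half_up

__all__ = [
    "SummaryBundle",
    "family_species_matrix",
    "family_totals",
    "tm_count_percentages",
    "location_percentages",
    "summarize_mtfs",
    "render_bundle",
]


@dataclass(frozen=True)
class SummaryBundle:
    """All summary tables for one MTF set."""

    family_species: pd.DataFrame
    tm_count_hist: dict[int, tuple[int, float]]
    location_1tm: dict[str, tuple[int, float]]
    location_2tm: dict[str, tuple[int, float]]
    species_totals: dict[str, int]
    n_mtfs: int


def family_species_matrix(mtfs: list[MtfRecord]) -> pd.DataFrame:
    """Integer count matrix, family rows x species columns, both sorted.

    Absent combinations are 0.  Every record must carry a family label
    (records read without an annotation table carry "NA", which is a
    label like any other; a genuinely empty label is an error).
    """
    for m in mtfs:
        if not m.protein.family:
            raise MtfscanError(f"{m.protein.id}: missing family label")
    if not mtfs:
        return pd.DataFrame(dtype=int)
    df = pd.DataFrame(
        {"family": [m.protein.family for m in mtfs], "species": [m.protein.species for m in mtfs]}
    )
    mat = pd.crosstab(df["family"], df["species"])
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = "family"
    mat.columns.name = "species"
    return mat


def family_totals(matrix: pd.DataFrame) -> list[tuple[str, int]]:
    """Row sums sorted descending, ties broken alphabetically."""
    if matrix.empty:
        return []
    sums = matrix.sum(axis=1)
    return sorted(
        ((fam, int(total)) for fam, total in sums.items()),
        key=lambda t: (-t[1], t[0]),
    )


def tm_count_percentages(mtfs: list[MtfRecord]) -> dict[int, tuple[int, float]]:
    """tm_count -> (protein count, percent of all MTFs to 1 decimal)."""
    if not mtfs:
        raise MtfscanError("tm_count_percentages requires >=1 MTF")
    total = len(mtfs)
    counts: dict[int, int] = {}
    for m in mtfs:
        counts[m.tm_count] = counts.get(m.tm_count, 0) + 1
    return {
        k: (c, round_half_up(100.0 * c / total, 1)) for k, c in sorted(counts.items())
    }


def location_percentages(
    mtfs: list[MtfRecord], params: ClassifyParams | None = None
) -> tuple[dict[str, tuple[int, float]], dict[str, tuple[int, float]]]:
    """Location breakdowns for 1-TM and 2-TM proteins.

    For 1-TM proteins: counts and percents per class letter {N, C, M},
    denominator the 1-TM total.  For 2-TM proteins: per pattern
    {NN, CC, NC, others}, denominator the 2-TM total.  Patterns are
    recomputed from spans under *params* so the breakdown stays
    consistent with the configured zone fractions.
    """
    if not mtfs:
        raise MtfscanError("location_percentages requires >=1 MTF")
    params = params or ClassifyParams()
    one = [m for m in mtfs if m.tm_count == 1]
    two = [m for m in mtfs if m.tm_count == 2]

    loc1: dict[str, tuple[int, float]] = {}
    if one:
        counts1 = {"N": 0, "C": 0, "M": 0}
        for m in one:
            counts1[pattern_code(list(m.spans), len(m.protein), params)] += 1
        loc1 = {
            k: (c, round_half_up(100.0 * c / len(one), 1)) for k, c in counts1.items()
        }

    loc2: dict[str, tuple[int, float]] = {}
    if two:
        counts2 = {"NN": 0, "CC": 0, "NC": 0, "others": 0}
        for m in two:
            pat = pattern_code(list(m.spans), len(m.protein), params)
            counts2[pat if pat in counts2 else "others"] += 1
        loc2 = {
            k: (c, round_half_up(100.0 * c / len(two), 1)) for k, c in counts2.items()
        }
    return loc1, loc2


def summarize_mtfs(
    mtfs: list[MtfRecord], params: ClassifyParams | None = None
) -> SummaryBundle:
    """Build the full summary bundle (empty input yields empty tables)."""
    matrix = family_species_matrix(mtfs)
    species_totals = (
        {sp: int(t) for sp, t in matrix.sum(axis=0).items()} if not matrix.empty else {}
    )
    if mtfs:
        hist = tm_count_percentages(mtfs)
        loc1, loc2 = location_percentages(mtfs, params)
    else:
        hist, loc1, loc2 = {}, {}, {}
    return SummaryBundle(
        family_species=matrix,
        tm_count_hist=hist,
        location_1tm=loc1,
        location_2tm=loc2,
        species_totals=species_totals,
        n_mtfs=len(mtfs),
    )


def render_bundle(bundle: SummaryBundle, params: ClassifyParams | None = None) -> str:
    """Aligned-text rendering of every table in a bundle."""
    params = params or ClassifyParams()
    parts = [
        f"# MTF summary ({bundle.n_mtfs} MTFs; zone fractions "
        f"n={params.n_frac:.3f}, c={params.c_frac:.3f}; coordinates 1-based inclusive)",
        "",
        "## Family x species matrix",
        bundle.family_species.to_string() if not bundle.family_species.empty else "(empty)",
        "",
        "## Family totals",
    ]
    for fam, tot in family_totals(bundle.family_species):
        parts.append(f"{fam}\t{tot}")
    parts += ["", "## TM-count distribution"]
    for k, (c, pct) in bundle.tm_count_hist.items():
        parts.append(f"{k} TM\t{c}\t{pct}%")
    parts += ["", "## Location of single-TM proteins"]
    for k, (c, pct) in bundle.location_1tm.items():
        parts.append(f"{k}\t{c}\t{pct}%")
    parts += ["", "## Location patterns of double-TM proteins"]
    for k, (c, pct) in bundle.location_2tm.items():
        parts.append(f"{k}\t{c}\t{pct}%")
    return "\n".join(parts) + "\n"
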