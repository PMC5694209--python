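"""Built-in hydrophobicity-profile transmembrane predictor.

This is the classic sliding-window hydropathy approach to TM helix
detection: each residue is scored by a trapezoid-weighted window average
of a hydropathy scale, candidate helices are maximal profile runs above a
lower cutoff, and the topology (which loops face the cytoplasm) is set by
the positive-inside rule — loops richer in Lys/Arg face inside.

Two scales ship as plain-text resources: ``GES`` (Goldman-Engelman-Steitz
transfer free energies, kcal/mol, hydrophobic positive — the default, with
the conventional certain/putative cutoffs 1.0/0.6) and ``KD``
(Kyte-Doolittle).  X scores 0 on both scales.

The profile run above the lower cutoff is systematically narrower than
the physical helix: with a 21-residue window and sharply hydrophilic
flanks, smoothing erodes roughly the wedge width from each end of the
run (more against strongly charged flanks).  The minimum segment length
therefore applies to the *run* and defaults to 9, corresponding to a
physical helix of roughly 15-17 or more residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .model import (
    Certainty,
    ProteinRecord,
    SequenceError,
    TmSpan,
    TopologyPrediction,
    states_from_spans,
)

__all__ = [
    "HydroParams",
    "HydroProfile",
    "load_scale",
    "hydropathy_profile",
    "find_tm_segments",
    "orient_topology",
    "predict_topology_hydro",
    "BUILTIN_PREDICTOR",
]

BUILTIN_PREDICTOR = "hydro-builtin"

_SCALE_CACHE: dict[str, dict[str, float]] = {}


def load_scale(name: str) -> dict[str, float]:
    """Load a bundled hydropathy scale ("KD" or "GES") as residue -> value."""
    key = name.upper()
    if key in _SCALE_CACHE:
        return _SCALE_CACHE[key]
    try:
        text = (
            resources.files("mtfscan.data").joinpath(f"{key.lower()}.tsv").read_text()
        )
    except FileNotFoundError:
        raise ValueError(f"unknown hydropathy scale {name!r} (available: KD, GES)")
    scale: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        scale[aa] = float(value)
    _SCALE_CACHE[key] = scale
    return scale


@dataclass(frozen=True)
class HydroParams:
    """Parameters of the hydropathy predictor.

    The trapezoid window spans ``core_len + 2*wedge_len`` residues: weight
    1.0 across the core, decaying linearly to ``1/(wedge_len+1)`` at the
    window edge.  Cutoffs are in scale units (GES kcal/mol by default): a
    run's peak >= ``upper_cutoff`` grades it certain, else putative.
    """

    scale: str = "GES"
    core_len: int = 11
    wedge_len: int = 5
    upper_cutoff: float = 1.0
    lower_cutoff: float = 0.6
    min_helix_len: int = 9
    min_loop_len: int = 2
    loop_charge_window: int = 15

    def __post_init__(self) -> None:
        if self.core_len < 1 or self.core_len % 2 == 0:
            raise ValueError("core_len must be odd and >= 1")
        if self.wedge_len < 0:
            raise ValueError("wedge_len must be >= 0")
        if self.lower_cutoff > self.upper_cutoff:
            raise ValueError("lower_cutoff must be <= upper_cutoff")
        if self.min_helix_len < 1:
            raise ValueError("min_helix_len must be >= 1")

    @property
    def half_window(self) -> int:
        return (self.core_len - 1) // 2 + self.wedge_len

    def window_weight(self, offset: int) -> float:
        """Trapezoid weight at a signed offset from the window center."""
        d = abs(offset)
        half_core = (self.core_len - 1) // 2
        if d <= half_core:
            return 1.0
        j = d - half_core
        if j > self.wedge_len:
            return 0.0
        return 1.0 - j / (self.wedge_len + 1)


@dataclass(frozen=True)
class HydroProfile:
    """Per-residue trapezoid-window hydropathy values (one per residue)."""

    values: tuple[float, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.values)


def hydropathy_profile(seq: str, params: HydroParams | None = None) -> HydroProfile:
    """Trapezoid-weighted windowed hydropathy, one value per residue.

    Windows are truncated at the sequence ends and renormalized by the
    weights actually applied, so short sequences are still scored (a
    single residue scores its raw scale value).
    """
    params = params or HydroParams()
    scale = load_scale(params.scale)
    try:
        raw = [scale[aa] for aa in seq]
    except KeyError as exc:
        raise SequenceError(f"residue {exc.args[0]!r} missing from scale {params.scale}")
    n = len(raw)
    w = params.half_window
    weights = [params.window_weight(d) for d in range(-w, w + 1)]
    values: list[float] = []
    for p in range(n):
        num = 0.0
        den = 0.0
        lo = max(0, p - w)
        hi = min(n - 1, p + w)
        for q in range(lo, hi + 1):
            wt = weights[q - p + w]
            num += wt * raw[q]
            den += wt
        values.append(num / den)
    return HydroProfile(tuple(values))


def find_tm_segments(profile: HydroProfile, params: HydroParams | None = None) -> list[TmSpan]:
    """Call TM segments from a hydropathy profile.

    Candidates are maximal runs with value >= ``lower_cutoff``; runs
    separated by a gap shorter than ``min_loop_len`` are merged, then runs
    shorter than ``min_helix_len`` are dropped.  A surviving run whose
    maximum reaches ``upper_cutoff`` is graded certain, else putative.
    """
    params = params or HydroParams()
    vals = profile.values
    runs: list[tuple[int, int]] = []  # 1-based inclusive
    start = None
    for pos, v in enumerate(vals, start=1):
        if v >= params.lower_cutoff:
            if start is None:
                start = pos
        elif start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, len(vals)))

    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < params.min_loop_len:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    spans: list[TmSpan] = []
    for s, e in merged:
        if e - s + 1 < params.min_helix_len:
            continue
        peak = max(vals[s - 1 : e])
        cert = Certainty.CERTAIN if peak >= params.upper_cutoff else Certainty.PUTATIVE
        spans.append(TmSpan(s, e, cert))
    return spans


def orient_topology(
    seq: str,
    spans: list[TmSpan],
    loop_charge_window: int = 15,
    protein_id: str = "",
    predictor: str = BUILTIN_PREDICTOR,
) -> TopologyPrediction:
    """Assign loop sides by the positive-inside rule.

    Both alternating orientations (first loop inside vs outside) are
    scored by counting K+R in the loops labeled 'i', considering at most
    *loop_charge_window* loop residues adjacent to each membrane span; the
    orientation with the larger inside count wins, ties going to
    first-loop-inside.  With no spans the protein is soluble and all
    residues are labeled 'i'.
    """
    n = len(seq)
    for sp in spans:
        if sp.end > n:
            raise SequenceError(f"span ({sp.start}, {sp.end}) out of range for length {n}")
    if not spans:
        return TopologyPrediction.from_states(protein_id, "i" * n, predictor)

    # loops as (start, end) 1-based inclusive; empty loops allowed
    bounds = [0] + [b for sp in spans for b in (sp.start, sp.end)] + [n + 1]
    loops = [(bounds[2 * k] + 1, bounds[2 * k + 1] - 1) for k in range(len(spans) + 1)]

    def charge(loop: tuple[int, int], k: int) -> int:
        s, e = loop
        if s > e:
            return 0
        positions: set[int] = set()
        if k > 0:  # residues adjacent to the preceding span
            positions.update(range(s, min(e, s + loop_charge_window - 1) + 1))
        if k < len(spans):  # residues adjacent to the following span
            positions.update(range(max(s, e - loop_charge_window + 1), e + 1))
        return sum(1 for p in positions if seq[p - 1] in "KR")

    loop_charges = [charge(lp, k) for k, lp in enumerate(loops)]
    inside_first = sum(c for k, c in enumerate(loop_charges) if k % 2 == 0)
    outside_first = sum(c for k, c in enumerate(loop_charges) if k % 2 == 1)
    first_loop = "i" if inside_first >= outside_first else "o"
    states = states_from_spans(n, list(spans), first_loop=first_loop)
    return TopologyPrediction(
        protein_id=protein_id,
        predictor=predictor,
        states=states,
        spans=tuple(spans),
    )


def predict_topology_hydro(
    rec: ProteinRecord, params: HydroParams | None = None
) -> TopologyPrediction:
    """Full built-in prediction: profile -> segments -> orientation."""
    params = params or HydroParams()
    profile = hydropathy_profile(rec.seq, params)
    spans = find_tm_segments(profile, params)
    return orient_topology(
        rec.seq,
        spans,
        loop_charge_window=params.loop_charge_window,
        protein_id=rec.id,
        predictor=BUILTIN_PREDICTOR,
    )
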