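"""Core domain types for the MTF identification pipeline.

Coordinate convention: residue coordinates are 1-based and inclusive on
both ends (the convention of TMHMM-style reports); a span ``(10, 30)``
covers 21 residues.  Topology strings use the alphabet ``{i, M, o}``:
``i`` = inside/cytoplasmic loop, ``M`` = membrane, ``o`` = outside loop.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ALLOWED_RESIDUES",
    "MtfscanError",
    "FormatError",
    "SequenceError",
    "Certainty",
    "ProteinRecord",
    "TmSpan",
    "TopologyPrediction",
    "AnnotationRow",
    "AnnotationTable",
    "DomainInterval",
    "MtfRecord",
    "spans_from_states",
    "states_from_spans",
]

#: The 20 standard amino acids plus X (unknown, hydropathy-neutral).
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class MtfscanError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MtfscanError):
    """Malformed input file or report (parse error)."""


class SequenceError(MtfscanError):
    """Invalid sequence content or coordinates."""


class Certainty(str, enum.Enum):
    """Confidence grade of a predicted TM span."""

    CERTAIN = "certain"
    PUTATIVE = "putative"


@dataclass(frozen=True)
class ProteinRecord:
    """One transcription-factor protein.

    ``locus``, ``species`` and ``family`` default to ``"NA"`` when no
    annotation table is supplied; ``family`` is a TF-family label such as
    ``"NAC"`` or ``"bZIP"`` (classification by DNA-binding domain).
    """

    id: str
    seq: str
    locus: str = "NA"
    species: str = "NA"
    family: str = "NA"

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein id must be non-empty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        for pos, aa in enumerate(seq, start=1):
            if aa not in ALLOWED_RESIDUES:
                raise SequenceError(
                    f"record {self.id!r}: disallowed residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class TmSpan:
    """A transmembrane segment as a 1-based inclusive residue interval."""

    start: int
    end: int
    certainty: Certainty = Certainty.CERTAIN

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SequenceError(f"invalid span ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "TmSpan") -> int:
        """Number of residues shared with *other* (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def spans_from_states(states: str) -> list[TmSpan]:
    """Maximal runs of 'M' in a topology string, as sorted spans."""
    spans: list[TmSpan] = []
    start = None
    for pos, ch in enumerate(states, start=1):
        if ch == "M":
            if start is None:
                start = pos
        elif start is not None:
            spans.append(TmSpan(start, pos - 1))
            start = None
    if start is not None:
        spans.append(TmSpan(start, len(states)))
    return spans


def states_from_spans(length: int, spans: list[TmSpan], first_loop: str = "i") -> str:
    """Build an alternating topology string from sorted, non-overlapping spans.

    Loops alternate starting from *first_loop*; with no spans the whole
    string is *first_loop* (the soluble default).
    """
    if first_loop not in ("i", "o"):
        raise ValueError("first_loop must be 'i' or 'o'")
    out: list[str] = []
    loop = first_loop
    prev_end = 0
    for sp in spans:
        if sp.start <= prev_end:
            raise SequenceError("spans must be sorted and separated by >=1 residue")
        if sp.end > length:
            raise SequenceError(f"span ({sp.start}, {sp.end}) exceeds length {length}")
        out.append(loop * (sp.start - 1 - prev_end))
        out.append("M" * len(sp))
        loop = "o" if loop == "i" else "i"
        prev_end = sp.end
    out.append(loop * (length - prev_end))
    return "".join(out)


@dataclass(frozen=True)
class TopologyPrediction:
    """Per-residue topology and derived TM spans for one protein/predictor.

    Invariant: ``spans`` are exactly the maximal runs of 'M' in ``states``.
    ``valid_alternation`` is False when the loop labels between consecutive
    spans fail to alternate i/o (accepted as-written from external
    predictors, but flagged).
    """

    protein_id: str
    predictor: str
    states: str
    spans: tuple[TmSpan, ...] = field(default=())
    span_confidence: tuple[float, ...] | None = None
    valid_alternation: bool = True

    def __post_init__(self) -> None:
        if not self.states:
            raise SequenceError(f"{self.protein_id}: empty topology string")
        bad = set(self.states) - {"i", "M", "o"}
        if bad:
            raise FormatError(
                f"{self.protein_id}: illegal topology characters {sorted(bad)}"
            )
        expected = tuple(spans_from_states(self.states))
        if tuple(self.spans) != expected:
            raise SequenceError(
                f"{self.protein_id}: spans do not match maximal M-runs of states"
            )
        if self.span_confidence is not None and len(self.span_confidence) != len(
            self.spans
        ):
            raise SequenceError(
                f"{self.protein_id}: span_confidence length mismatch"
            )

    @classmethod
    def from_states(
        cls,
        protein_id: str,
        states: str,
        predictor: str = "generic",
        span_confidence: tuple[float, ...] | None = None,
    ) -> "TopologyPrediction":
        spans = tuple(spans_from_states(states))
        return cls(
            protein_id=protein_id,
            predictor=predictor,
            states=states,
            spans=spans,
            span_confidence=span_confidence,
            valid_alternation=_loops_alternate(states),
        )

    @classmethod
    def from_spans(
        cls,
        protein_id: str,
        length: int,
        spans: list[TmSpan] | tuple[TmSpan, ...],
        predictor: str = "generic",
        first_loop: str = "i",
    ) -> "TopologyPrediction":
        states = states_from_spans(length, list(spans), first_loop=first_loop)
        return cls(
            protein_id=protein_id,
            predictor=predictor,
            states=states,
            spans=tuple(spans),
        )

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_spans(self) -> int:
        return len(self.spans)

    @property
    def first_loop(self) -> str:
        """State of the N-terminal loop ('i' or 'o'); 'i' for an all-M string."""
        for ch in self.states:
            if ch != "M":
                return ch
        return "i"


def _loops_alternate(states: str) -> bool:
    """True iff consecutive loop segments alternate between i and o."""
    loops: list[str] = []
    prev = None
    for ch in states:
        if ch != "M":
            if prev != ch:
                loops.append(ch)
            prev = ch
        else:
            prev = None
    return all(a != b for a, b in zip(loops, loops[1:]))


@dataclass(frozen=True)
class AnnotationRow:
    locus: str
    species: str
    family: str


class AnnotationTable:
    """Mapping protein id -> (locus, species, family); ids unique."""

    def __init__(self, rows: Mapping[str, AnnotationRow] | None = None) -> None:
        self._rows: dict[str, AnnotationRow] = {}
        if rows:
            for pid, row in rows.items():
                self.add(pid, row)

    def add(self, protein_id: str, row: AnnotationRow) -> None:
        if protein_id in self._rows:
            raise FormatError(f"duplicate protein id in annotation table: {protein_id!r}")
        if not row.family:
            raise FormatError(f"{protein_id}: empty family label")
        self._rows[protein_id] = row

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._rows

    def __getitem__(self, protein_id: str) -> AnnotationRow:
        return self._rows[protein_id]

    def get(self, protein_id: str) -> AnnotationRow | None:
        return self._rows.get(protein_id)

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self) -> Iterator[str]:
        return iter(self._rows)


@dataclass(frozen=True)
class DomainInterval:
    """1-based inclusive coordinates of the DNA-binding (TF) domain."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"{self.protein_id}: invalid domain interval ({self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MtfRecord:
    """A final membrane-bound transcription factor call.

    ``provenance`` records which branch of the workflow called it: a
    non-empty subset of ``{"consensus", "tmhmm"}``.
    """

    protein: ProteinRecord
    spans: tuple[TmSpan, ...]
    location_pattern: str
    provenance: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.spans) < 1:
            raise SequenceError(f"{self.protein.id}: MTF record requires >=1 span")
        if not self.provenance or not set(self.provenance) <= {"consensus", "tmhmm"}:
            raise SequenceError(
                f"{self.protein.id}: provenance must be a non-empty subset of "
                "{'consensus', 'tmhmm'}"
            )

    @property
    def tm_count(self) -> int:
        return len(self.spans)
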