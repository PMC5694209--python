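"""TM-span location classification.

Each span is assigned to the N-terminal, central or C-terminal zone of
its protein by the position of its midpoint relative to configurable
length fractions (default: terminal thirds).  Midpoints exactly on a zone
boundary resolve toward the terminal class.  A protein's location pattern
is the concatenation of per-span class letters in sequence order, e.g.
"N", "NC", "MMM" (M = central).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .model import SequenceError, TmSpan

__all__ = ["LocationClass", "ClassifyParams", "classify_span_location", "pattern_code"]


class LocationClass(str, enum.Enum):
    N_TERMINAL = "N"
    CENTRAL = "M"
    C_TERMINAL = "C"


@dataclass(frozen=True)
class ClassifyParams:
    """Zone boundaries as fractions of protein length."""

    n_frac: float = 1 / 3
    c_frac: float = 1 / 3

    def __post_init__(self) -> None:
        if not (0 < self.n_frac < 1 and 0 < self.c_frac < 1):
            raise ValueError("n_frac and c_frac must be in (0, 1)")
        if self.n_frac + self.c_frac > 1:
            raise ValueError("n_frac + c_frac must be <= 1")


def classify_span_location(
    span: TmSpan, length: int, params: ClassifyParams | None = None
) -> LocationClass:
    """Zone of a span's midpoint: N if m <= n_frac*L, C if m > (1-c_frac)*L."""
    params = params or ClassifyParams()
    if span.end > length:
        raise SequenceError(f"span ({span.start}, {span.end}) out of range for length {length}")
    m = span.midpoint
    if m <= params.n_frac * length:
        return LocationClass.N_TERMINAL
    if m > (1 - params.c_frac) * length:
        return LocationClass.C_TERMINAL
    return LocationClass.CENTRAL


def pattern_code(
    spans: list[TmSpan], length: int, params: ClassifyParams | None = None
) -> str:
    """Concatenated class letters of all spans, in sequence order."""
    if not spans:
        raise SequenceError("pattern_code requires >=1 span")
    return "".join(
        classify_span_location(sp, length, params).value for sp in sorted(spans)
    )
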