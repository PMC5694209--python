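"""Parsers for external topology-predictor output.

The pipeline never executes third-party predictor binaries; it consumes
their reports.  Three formats are supported:

* TMHMM long-format reports (``<id> TMHMM2.0 TMhelix <start> <end>`` plus
  inside/outside lines),
* TMHMM per-residue posterior files (plp-style: index, residue letter,
  then state probabilities with a membrane column),
* a generic one-topology-per-line format ``id<TAB>topology-string`` over
  the alphabet {i, M, o}, which any predictor can be converted to.

Integration contract for directory input: one report file per predictor
per proteome, named ``<predictor>.<ext>`` with extension ``.tmhmm`` (long
format), ``.plp`` (posteriors) or ``.topo`` (generic strings).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

from .model import FormatError, TmSpan, TopologyPrediction

__all__ = [
    "PosteriorTrack",
    "parse_tmhmm_long",
    "parse_posterior_track",
    "parse_topology_string",
    "parse_generic_file",
    "read_predictor_dir",
]


@dataclass(frozen=True)
class PosteriorTrack:
    """Per-residue membrane-state posterior probabilities for one protein."""

    protein_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        for v in self.values:
            if not (0.0 <= v <= 1.0):
                raise FormatError(
                    f"{self.protein_id}: posterior {v} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.values)


_TMHMM_STATES = {"inside": "i", "TMhelix": "M", "outside": "o"}


def parse_tmhmm_long(text: str) -> list[TopologyPrediction]:
    """Parse a TMHMM long-format report into one prediction per protein.

    Segment lines look like ``P1  TMHMM2.0  TMhelix  10  30``; the
    segments of one protein must be contiguous (grouped in a block),
    ordered and non-overlapping, and together tile positions 1..length.
    Comment lines start with '#'.
    """
    segments: dict[str, list[tuple[str, int, int]]] = {}
    order: list[str] = []
    last_id: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FormatError(f"TMHMM report line {lineno}: expected 5 fields")
        pid, _tag, state, start_s, end_s = parts
        if state not in _TMHMM_STATES:
            raise FormatError(f"TMHMM report line {lineno}: unknown state {state!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"TMHMM report line {lineno}: non-integer coordinates")
        if pid not in segments:
            segments[pid] = []
            order.append(pid)
        elif pid != last_id:
            raise FormatError(
                f"TMHMM report line {lineno}: interleaved blocks for {pid!r}"
            )
        segments[pid].append((state, start, end))
        last_id = pid

    preds: list[TopologyPrediction] = []
    for pid in order:
        segs = segments[pid]
        pos = 1
        states_parts: list[str] = []
        for state, start, end in segs:
            if start != pos or end < start:
                raise FormatError(
                    f"TMHMM report for {pid!r}: segments unordered, overlapping "
                    f"or gapped at position {start}"
                )
            states_parts.append(_TMHMM_STATES[state] * (end - start + 1))
            pos = end + 1
        preds.append(
            TopologyPrediction.from_states(pid, "".join(states_parts), predictor="TMHMM")
        )
    return preds


def parse_posterior_track(text: str, protein_id: str = "") -> PosteriorTrack:
    """Parse a plp-style per-residue posterior file.

    Data lines carry: residue index (1-based, consecutive), residue
    letter, then state probabilities.  The membrane column is taken from
    a ``#`` header naming the columns (one of them ``M`` or ``TMhelix``)
    when present, else it defaults to the last probability column.
    """
    mem_col: int | None = None
    values: list[float] = []
    expected = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            cols = stripped.lstrip("#").split()
            for k, name in enumerate(cols):
                if name in ("M", "TMhelix", "membrane"):
                    # probability columns start after index+residue fields
                    mem_col = k
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise FormatError(f"posterior line {lineno}: expected index, residue, probabilities")
        try:
            idx = int(parts[0])
        except ValueError:
            raise FormatError(f"posterior line {lineno}: non-integer residue index")
        if idx != expected:
            raise FormatError(
                f"posterior line {lineno}: residue index {idx}, expected {expected} (gap)"
            )
        expected += 1
        probs = parts[2:]
        col = mem_col if mem_col is not None and mem_col < len(probs) else len(probs) - 1
        try:
            v = float(probs[col])
        except ValueError:
            raise FormatError(f"posterior line {lineno}: non-numeric probability")
        if not (0.0 <= v <= 1.0):
            raise FormatError(f"posterior line {lineno}: probability {v} outside [0, 1]")
        values.append(v)
    return PosteriorTrack(protein_id=protein_id, values=tuple(values))


def parse_topology_string(protein_id: str, s: str, predictor: str = "generic") -> TopologyPrediction:
    """Build a prediction from a raw {i, M, o} topology string.

    Non-alternating loop labels (e.g. ``iMi``) are accepted as written
    but flagged via ``valid_alternation=False``.
    """
    if not s:
        raise FormatError(f"{protein_id}: empty topology string")
    return TopologyPrediction.from_states(protein_id, s, predictor=predictor)


def parse_generic_file(text: str, predictor: str = "generic") -> list[TopologyPrediction]:
    """Parse the one-topology-per-line format ``id<TAB>topology-string``."""
    preds: list[TopologyPrediction] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"topology file line {lineno}: expected id<TAB>string")
        preds.append(parse_topology_string(parts[0], parts[1], predictor=predictor))
    return preds


def read_predictor_dir(
    path: str | os.PathLike,
) -> tuple[dict[str, list[TopologyPrediction]], dict[str, PosteriorTrack]]:
    """Load all predictor reports from a directory.

    Returns (predictions by predictor name, TMHMM posterior tracks by
    protein id).  File naming: ``<predictor>.tmhmm`` (long format),
    ``<predictor>.plp`` (posterior track for a single protein is not
    supported here — .plp files hold one block per protein separated by
    ``>`` id lines), ``<predictor>.topo`` (generic strings).
    """
    preds: dict[str, list[TopologyPrediction]] = {}
    tracks: dict[str, PosteriorTrack] = {}
    for p in sorted(Path(path).iterdir()):
        if p.suffix == ".tmhmm":
            preds[p.stem] = parse_tmhmm_long(p.read_text())
        elif p.suffix == ".topo":
            preds[p.stem] = parse_generic_file(p.read_text(), predictor=p.stem)
        elif p.suffix == ".plp":
            for pid, block in _split_plp_blocks(p.read_text()):
                tracks[pid] = parse_posterior_track(block, protein_id=pid)
    return preds, tracks


def _split_plp_blocks(text: str) -> list[tuple[str, str]]:
    """Split a multi-protein plp file on '>' id lines."""
    blocks: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        if line.startswith(">"):
            blocks.append((line[1:].strip().split()[0], []))
        elif blocks:
            blocks[-1][1].append(line)
        elif line.strip() and not line.startswith("#"):
            raise FormatError("plp file: data before first '>' id line")
    return [(pid, "\n".join(lines)) for pid, lines in blocks]
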