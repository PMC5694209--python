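"""Alternative-splicing (ALS) activation screen.

Some MTF loci produce splice isoforms that keep the DNA-binding domain
but lose the TM-encoding block; such isoforms are constitutively nuclear,
so the locus can be activated without proteolysis.  The screen flags a
locus when at least one variant isoform (a) is predicted soluble by the
hydropathy predictor and (b) retains the reference's TF domain nearly
intact, measured as the identity fraction of domain positions in a global
alignment of variant against reference.

Alignment scoring: match/mismatch substitution with affine gaps, where a
gap run of length k costs ``gap_open + k * gap_extend`` (defaults
2 / -1 / -5 / -1).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .hydropathy import HydroParams, predict_topology_hydro
from .model import DomainInterval, MtfscanError, ProteinRecord, SequenceError
from ._util import round_half_up

__all__ = [
    "IsoformSet",
    "AlsCall",
    "AlignmentResult",
    "align_global",
    "domain_coverage",
    "screen_isoforms",
    "als_fraction",
]


@dataclass(frozen=True)
class IsoformSet:
    """Per-locus isoforms: the membrane-bound reference plus variants.

    The reference is the isoform with predicted TM spans (if several
    have spans, callers pick the longest); ``domain`` is the TF-domain
    interval on the reference.
    """

    locus: str
    reference: ProteinRecord
    variants: tuple[ProteinRecord, ...]
    domain: DomainInterval

    def __post_init__(self) -> None:
        if self.domain.end > len(self.reference):
            raise SequenceError(
                f"{self.locus}: domain interval exceeds reference length"
            )


@dataclass(frozen=True)
class AlsCall:
    """Screen verdict for one locus."""

    locus: str
    qualifying_variants: tuple[str, ...]

    @property
    def flagged(self) -> bool:
        return len(self.qualifying_variants) > 0


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment as gapped strings plus its score."""

    a_gapped: str
    b_gapped: str
    score: float


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # library convention charges open on the first gap position; ours
    # charges open + extend per position, hence the shift
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment of *a* and *b* under affine gap scoring.

    Deterministic: among co-optimal alignments the first in the
    aligner's fixed enumeration order is returned.
    """
    if not a or not b:
        raise MtfscanError("align_global requires two non-empty sequences")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return AlignmentResult(a_gapped=aln[0], b_gapped=aln[1], score=float(aln.score))


def domain_coverage(alignment: AlignmentResult, domain: DomainInterval) -> float:
    """Fraction of domain positions aligned to an identical residue.

    The domain interval refers to the first (reference) sequence of the
    alignment; gapped and mismatched domain positions count as uncovered.
    """
    a_len = sum(1 for ch in alignment.a_gapped if ch != "-")
    if domain.end > a_len:
        raise SequenceError(
            f"{domain.protein_id}: domain interval exceeds aligned sequence length {a_len}"
        )
    covered = 0
    a_pos = 0
    for ca, cb in zip(alignment.a_gapped, alignment.b_gapped):
        if ca == "-":
            continue
        a_pos += 1
        if domain.start <= a_pos <= domain.end and ca == cb:
            covered += 1
    return covered / len(domain)


def screen_isoforms(
    iso: IsoformSet,
    hydro: HydroParams | None = None,
    coverage_min: float = 0.9,
) -> AlsCall:
    """Screen one locus for ALS-based activation.

    A variant qualifies iff the hydropathy predictor finds no TM span in
    it and its domain coverage against the reference is >= *coverage_min*.
    """
    hydro = hydro or HydroParams()
    qualifying: list[str] = []
    for var in iso.variants:
        pred = predict_topology_hydro(var, hydro)
        if pred.n_spans != 0:
            continue
        aln = align_global(iso.reference.seq, var.seq)
        if domain_coverage(aln, iso.domain) >= coverage_min:
            qualifying.append(var.id)
    return AlsCall(locus=iso.locus, qualifying_variants=tuple(qualifying))


def als_fraction(calls: list[AlsCall]) -> tuple[int, int, int]:
    """(flagged loci, total loci, percent rounded half-up to 0 decimals)."""
    if not calls:
        raise MtfscanError("als_fraction requires >=1 call")
    flagged = sum(1 for c in calls if c.flagged)
    total = len(calls)
    return flagged, total, int(round_half_up(100.0 * flagged / total, 0))
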