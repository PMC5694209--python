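"""Consensus and branch-merge decision logic.

The workflow runs two branches per protein and unions their calls:

1. a *consensus* branch over the non-TMHMM predictors — predictions are
   greedily clustered into agreement classes and the largest class wins;
2. a *TMHMM* branch in which helices are kept only when their mean
   per-residue membrane posterior exceeds a probability threshold
   (strictly > 0.90 by default).

A protein enters the final MTF set iff either branch calls at least one
TM span; when both fire, the consensus spans are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .adapters import PosteriorTrack
from .classify import ClassifyParams, pattern_code
from .model import (
    MtfRecord,
    MtfscanError,
    ProteinRecord,
    TopologyPrediction,
)

__all__ = [
    "DEFAULT_PRIORITY",
    "ConsensusResult",
    "topologies_agree",
    "consensus_topology",
    "filter_tmhmm",
    "merge_branches",
]

#: Fixed predictor priority used for deterministic greedy clustering and
#: tie-breaking: the six non-TMHMM predictors of the workflow, then the
#: built-in hydropathy predictor, then anything else.
DEFAULT_PRIORITY = (
    "HMMTOP",
    "PHOBIUS",
    "S-TMHMM",
    "TOPPRED",
    "SCAMPI",
    "MEMSAT",
    "hydro-builtin",
)


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of agreement clustering for one protein.

    ``classes`` partitions the input predictor names into agreement
    classes (each a tuple of predictor names, representative first);
    ``support`` is the size of the winning class.
    """

    protein_id: str
    winner: TopologyPrediction
    support: int
    classes: tuple[tuple[str, ...], ...]


def topologies_agree(
    a: TopologyPrediction, b: TopologyPrediction, min_overlap: int = 5
) -> bool:
    """Do two predictions for the same protein agree?

    Agreement requires the same span count, pairwise overlap of at least
    *min_overlap* residues between corresponding spans (capped by the
    shorter span's length, so degenerate short spans keep the relation
    reflexive), and — when both predictions have spans — the same
    N-terminal loop state.  Span-free (soluble) predictions agree with
    each other regardless of loop label.  Reflexive and symmetric by
    construction.
    """
    if len(a.states) != len(b.states):
        raise MtfscanError(
            f"length mismatch between predictions for {a.protein_id!r}/{b.protein_id!r}"
        )
    if a.n_spans != b.n_spans:
        return False
    if a.n_spans == 0:
        return True
    if a.first_loop != b.first_loop:
        return False
    return all(
        sa.overlap(sb) >= min(min_overlap, len(sa), len(sb))
        for sa, sb in zip(a.spans, b.spans)
    )


def _priority_key(predictor: str, priority: Sequence[str]) -> tuple[int, str]:
    try:
        return (priority.index(predictor), predictor)
    except ValueError:
        return (len(priority), predictor)


def consensus_topology(
    preds: Sequence[TopologyPrediction],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    min_overlap: int = 5,
) -> ConsensusResult:
    """Greedy agreement clustering; the largest class's representative wins.

    Predictions are visited in *priority* order (unknown predictors last,
    alphabetically); each joins the first existing class whose
    representative (founder) it agrees with, else founds a new class.
    Ties between equally large classes go to the class whose
    representative ranks first in priority.  The winner may be a 0-span
    topology (consensus "soluble").
    """
    if not preds:
        raise MtfscanError("consensus_topology requires >=1 prediction")
    pids = {p.protein_id for p in preds}
    if len(pids) != 1:
        raise MtfscanError(f"predictions for multiple proteins: {sorted(pids)}")
    ordered = sorted(preds, key=lambda p: _priority_key(p.predictor, priority))
    classes: list[list[TopologyPrediction]] = []
    for p in ordered:
        for cls in classes:
            if topologies_agree(cls[0], p, min_overlap=min_overlap):
                cls.append(p)
                break
        else:
            classes.append([p])
    # largest class; ties by representative priority (= founding order)
    best = max(classes, key=lambda c: (len(c), -classes.index(c)))
    return ConsensusResult(
        protein_id=ordered[0].protein_id,
        winner=best[0],
        support=len(best),
        classes=tuple(tuple(p.predictor for p in cls) for cls in classes),
    )


def filter_tmhmm(
    pred: TopologyPrediction,
    track: PosteriorTrack | None,
    threshold: float = 0.90,
    statistic: str = "mean",
) -> TopologyPrediction:
    """Posterior-filter a TMHMM prediction.

    A span is retained iff its per-residue membrane posterior summary
    (*statistic*: "mean" or "min" over the span) is strictly greater than
    *threshold*; states are rebuilt from the surviving spans.  With no
    track the prediction passes unfiltered (callers log a warning).
    """
    if track is None:
        return pred
    if len(track) != len(pred.states):
        raise MtfscanError(
            f"{pred.protein_id}: posterior track length {len(track)} != "
            f"protein length {len(pred.states)}"
        )
    if statistic not in ("mean", "min"):
        raise ValueError("statistic must be 'mean' or 'min'")
    kept = []
    for sp in pred.spans:
        window = track.values[sp.start - 1 : sp.end]
        score = sum(window) / len(window) if statistic == "mean" else min(window)
        if score > threshold:
            kept.append(sp)
    return TopologyPrediction.from_spans(
        pred.protein_id,
        len(pred.states),
        kept,
        predictor=pred.predictor,
        first_loop=pred.first_loop,
    )


def merge_branches(
    proteins: Mapping[str, ProteinRecord],
    consensus: Mapping[str, ConsensusResult],
    tmhmm: Mapping[str, TopologyPrediction],
    classify_params: ClassifyParams | None = None,
) -> list[MtfRecord]:
    """Union the consensus and TMHMM branches into the final MTF set.

    A protein is an MTF iff its consensus winner has >=1 span OR its
    (filtered) TMHMM prediction has >=1 span.  Spans come from the
    consensus winner when that branch called membrane, else from TMHMM;
    provenance records every branch that fired.  Output ordered by
    protein id.
    """
    classify_params = classify_params or ClassifyParams()
    out: list[MtfRecord] = []
    for pid in sorted(proteins):
        cons = consensus.get(pid)
        tm = tmhmm.get(pid)
        cons_hit = cons is not None and cons.winner.n_spans > 0
        tm_hit = tm is not None and tm.n_spans > 0
        if not (cons_hit or tm_hit):
            continue
        prov = set()
        if cons_hit:
            prov.add("consensus")
        if tm_hit:
            prov.add("tmhmm")
        spans = cons.winner.spans if cons_hit else tm.spans
        protein = proteins[pid]
        pattern = pattern_code(list(spans), len(protein), classify_params)
        out.append(
            MtfRecord(
                protein=protein,
                spans=tuple(spans),
                location_pattern=pattern,
                provenance=frozenset(prov),
            )
        )
    return out
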