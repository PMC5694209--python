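"""End-to-end orchestration of the MTF identification workflow.

``run_scan`` implements the two-branch decision: external predictor
reports (plus the built-in hydropathy predictor) feed the consensus
branch, TMHMM reports feed the posterior-filtered branch, and the union
of both branches is the final MTF set.  Without external reports the
built-in predictor alone feeds both branches (a degenerate consensus of
one), which is logged as a notice.

Every run directory receives the MTF TSV report, the rendered summary
tables, a run log and the fully resolved configuration.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from pathlib import Path

from .adapters import read_predictor_dir
from .als import AlsCall, IsoformSet, screen_isoforms
from .config import PipelineConfig, dump_config
from .consensus import (
    ConsensusResult,
    consensus_topology,
    filter_tmhmm,
    merge_branches,
)
from .hydropathy import predict_topology_hydro
from .io import read_annotation_table, read_fasta, write_mtf_report
from .model import (
    DomainInterval,
    MtfRecord,
    MtfscanError,
    ProteinRecord,
    TopologyPrediction,
)
from .summarize import SummaryBundle, render_bundle, summarize_mtfs

__all__ = ["ScanResult", "run_scan", "build_isoform_sets", "run_als_screen"]

logger = logging.getLogger("mtfscan")


@dataclass(frozen=True)
class ScanResult:
    mtfs: list[MtfRecord]
    bundle: SummaryBundle
    consensus: dict[str, ConsensusResult]
    tmhmm: dict[str, TopologyPrediction]


def _is_tmhmm(name: str) -> bool:
    return name.replace("-", "").replace("_", "").upper().startswith("TMHMM")


def run_scan(
    fasta: str | os.PathLike,
    annotations: str | os.PathLike | None = None,
    predictor_reports: str | os.PathLike | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> ScanResult:
    """Scan a TF proteome for membrane-bound members.

    Ids present in the FASTA but missing from the annotation table get
    "NA" labels with a warning (never a failure).  When *out_dir* is
    given, writes ``mtf_report.tsv``, ``summary.txt``, ``config.yaml``
    and ``run.log`` there.
    """
    config = config or PipelineConfig()
    log_records: list[str] = []

    def note(msg: str) -> None:
        logger.warning(msg)
        log_records.append(msg)

    table = read_annotation_table(annotations) if annotations is not None else None
    records = read_fasta(fasta, table)
    if table is not None:
        for rec in records:
            if rec.id not in table:
                note(f"no annotation for {rec.id}; using NA labels")
    proteins = {rec.id: rec for rec in records}

    builtin = {rec.id: predict_topology_hydro(rec, config.hydro) for rec in records}

    ext_preds: dict[str, list[TopologyPrediction]] = {}
    tracks = {}
    if predictor_reports is not None:
        ext_preds, tracks = read_predictor_dir(predictor_reports)
    else:
        note(
            "no external predictor reports supplied; built-in hydropathy "
            "predictor feeds both branches (degenerate consensus of one)"
        )

    # group external predictions per protein, splitting off the TMHMM branch
    per_protein: dict[str, list[TopologyPrediction]] = {pid: [] for pid in proteins}
    tmhmm_raw: dict[str, TopologyPrediction] = {}
    for predictor, preds in ext_preds.items():
        for p in preds:
            if p.protein_id not in proteins:
                note(f"{predictor}: prediction for unknown protein {p.protein_id}; skipped")
                continue
            if len(p.states) != len(proteins[p.protein_id]):
                raise MtfscanError(
                    f"{predictor}: prediction length {len(p.states)} != protein "
                    f"length {len(proteins[p.protein_id])} for {p.protein_id}"
                )
            if _is_tmhmm(predictor):
                tmhmm_raw[p.protein_id] = p
            else:
                per_protein[p.protein_id].append(p)

    consensus: dict[str, ConsensusResult] = {}
    for pid, preds in per_protein.items():
        consensus[pid] = consensus_topology(
            preds + [builtin[pid]],
            priority=config.predictor_priority,
            min_overlap=config.min_overlap,
        )

    tmhmm_branch: dict[str, TopologyPrediction] = {}
    if predictor_reports is not None:
        for pid, pred in tmhmm_raw.items():
            track = tracks.get(pid)
            if track is None and pred.n_spans > 0:
                note(f"no posterior track for {pid}; TMHMM helices accepted unfiltered")
            tmhmm_branch[pid] = filter_tmhmm(
                pred,
                track,
                threshold=config.tmhmm_threshold,
                statistic=config.tmhmm_statistic,
            )
    else:
        tmhmm_branch = dict(builtin)

    mtfs = merge_branches(proteins, consensus, tmhmm_branch, config.classify)
    bundle = summarize_mtfs(mtfs, config.classify)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mtf_report(mtfs, out / "mtf_report.tsv")
        (out / "summary.txt").write_text(render_bundle(bundle, config.classify))
        dump_config(config, out / "config.yaml")
        (out / "run.log").write_text("".join(line + "\n" for line in log_records))
    return ScanResult(mtfs=mtfs, bundle=bundle, consensus=consensus, tmhmm=tmhmm_branch)


def build_isoform_sets(
    records: list[ProteinRecord],
    domains: dict[str, DomainInterval],
    config: PipelineConfig | None = None,
    locus_pattern: str = r"^(.*)\.\d+$",
) -> list[IsoformSet]:
    """Group isoform records by locus and pick each locus's MTF reference.

    The locus is captured by group 1 of *locus_pattern* applied to the
    protein id (falling back to the record's locus annotation).  The
    reference is the isoform with predicted TM spans; when several have
    spans the longest wins (ties by id).  Loci whose reference lacks a
    domain interval, or with no membrane-bound isoform, or with no
    variants, are skipped with a warning.
    """
    config = config or PipelineConfig()
    pat = re.compile(locus_pattern)
    groups: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        m = pat.match(rec.id)
        locus = m.group(1) if m else (rec.locus if rec.locus != "NA" else rec.id)
        groups.setdefault(locus, []).append(rec)

    out: list[IsoformSet] = []
    for locus in sorted(groups):
        members = groups[locus]
        with_spans = [
            rec
            for rec in members
            if predict_topology_hydro(rec, config.hydro).n_spans > 0
        ]
        if not with_spans:
            logger.warning("locus %s: no membrane-bound isoform; skipped", locus)
            continue
        # longest membrane-bound isoform; ties broken by smallest id
        reference = sorted(with_spans, key=lambda r: (-len(r), r.id))[0]
        variants = tuple(r for r in members if r.id != reference.id)
        if not variants:
            logger.warning("locus %s: no variant isoforms; skipped", locus)
            continue
        if reference.id not in domains:
            logger.warning("locus %s: no domain interval for reference %s; skipped",
                           locus, reference.id)
            continue
        out.append(
            IsoformSet(
                locus=locus,
                reference=reference,
                variants=variants,
                domain=domains[reference.id],
            )
        )
    return out


def run_als_screen(
    sets: list[IsoformSet], config: PipelineConfig | None = None
) -> list[AlsCall]:
    """Screen every locus; deterministic locus order."""
    config = config or PipelineConfig()
    return [
        screen_isoforms(iso, config.hydro, coverage_min=config.als_coverage_min)
        for iso in sorted(sets, key=lambda s: s.locus)
    ]
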