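"""Deterministic synthetic TF proteomes and isoform sets with known truth.

These fixtures emulate the *computational* shape of a TF-proteome screen
— hydrophilic background sequence with planted hydrophobic helix blocks
of 19-23 residues — not real TF biology (no NAC/bZIP motifs).  Decoys are
adversarially resampled below the detection cutoff of the default
hydropathy parameters, so the expected false-positive count is exactly
zero and sensitivity/specificity checks are sharp assertions.

All generation is seeded; the seed is recorded in FASTA headers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .als import IsoformSet
from .classify import LocationClass
from .hydropathy import HydroParams, hydropathy_profile, predict_topology_hydro
from .model import (
    AnnotationRow,
    AnnotationTable,
    DomainInterval,
    MtfscanError,
    ProteinRecord,
    TmSpan,
)

__all__ = [
    "HYDROPHILIC",
    "HYDROPHOBIC",
    "FixtureTruth",
    "TruthEntry",
    "plant_tm_protein",
    "soluble_decoy",
    "isoform_fixture",
    "genome_fixture",
]

#: Background alphabet: strongly polar/charged plus helix breakers.
HYDROPHILIC = "STNQDEKRGP"
#: Planted-helix alphabet.
HYDROPHOBIC = "LIVFAM"

DEFAULT_FAMILIES = ("NAC", "bZIP", "SBP", "C2H2", "MYB-related", "bHLH")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one synthetic protein."""

    protein_id: str
    is_mtf: bool
    spans: tuple[TmSpan, ...]
    family: str
    species: str


@dataclass
class FixtureTruth:
    """Ground truth for a whole synthetic proteome / isoform collection."""

    proteins: dict[str, TruthEntry] = field(default_factory=dict)
    als_flagged: dict[str, bool] = field(default_factory=dict)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#id\tspecies\tfamily\tis_mtf\tspans\n")
            for pid in sorted(self.proteins):
                t = self.proteins[pid]
                spans = ";".join(f"{s.start}-{s.end}" for s in t.spans)
                fh.write(
                    f"{pid}\t{t.species}\t{t.family}\t{int(t.is_mtf)}\t{spans}\n"
                )


def _hydrophilic_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(HYDROPHILIC), size=length))


_ZONES = {
    LocationClass.N_TERMINAL: (0.0, 1 / 3),
    LocationClass.CENTRAL: (1 / 3, 2 / 3),
    LocationClass.C_TERMINAL: (2 / 3, 1.0),
}

#: Minimum gap between planted spans (keeps profile runs well separated).
_MIN_GAP = 25
#: Keep planted midpoints this far inside their zone so window smoothing
#: cannot push the predicted midpoint across a zone boundary.
_ZONE_MARGIN = 5


def plant_tm_protein(
    n_tm: int,
    locations: list[LocationClass],
    length: int,
    seed: int,
    protein_id: str = "synth",
) -> tuple[ProteinRecord, tuple[TmSpan, ...]]:
    """A hydrophilic-background protein with planted hydrophobic helices.

    Each helix is a contiguous block of 19-23 residues from the
    hydrophobic alphabet, centered inside the requested zone (terminal
    thirds by default classification).  Returns the record and the truth
    spans.  Raises when the requested zones cannot host non-overlapping
    spans.
    """
    if n_tm != len(locations):
        raise MtfscanError("n_tm must equal len(locations)")
    if length < 40 * max(n_tm, 1):
        raise MtfscanError(f"length {length} too short for {n_tm} spans")
    rng = np.random.default_rng(seed)
    seq = _hydrophilic_seq(rng, length)
    spans: list[TmSpan] = []
    order = sorted(range(n_tm), key=lambda k: _ZONES[locations[k]][0])
    placed: list[tuple[int, int]] = []
    for k in order:
        lo_f, hi_f = _ZONES[locations[k]]
        span_len = int(rng.integers(19, 24))
        half = span_len // 2
        lo = max(int(lo_f * length) + 1 + _ZONE_MARGIN, half + 1)
        hi = min(int(hi_f * length) - _ZONE_MARGIN, length - (span_len - half) + 1)
        for _attempt in range(200):
            center = int(rng.integers(lo, hi + 1)) if hi >= lo else None
            if center is None:
                break
            start = center - half
            end = start + span_len - 1
            if all(
                start > pe + _MIN_GAP or end < ps - _MIN_GAP for ps, pe in placed
            ):
                placed.append((start, end))
                break
        else:
            center = None
        if center is None:
            raise MtfscanError(
                f"cannot place span {k + 1}/{n_tm} in zone {locations[k].name} "
                f"of a length-{length} protein"
            )
        for p in range(start - 1, end):
            seq[p] = str(rng.choice(list(HYDROPHOBIC)))
        spans.append(TmSpan(start, end))
    spans.sort()
    rec = ProteinRecord(id=protein_id, seq="".join(seq))
    return rec, tuple(spans)


def soluble_decoy(
    length: int, seed: int, protein_id: str = "decoy", params: HydroParams | None = None
) -> ProteinRecord:
    """A decoy guaranteed below the detection cutoff of *params*.

    Hydrophilic background; any window whose profile value reaches the
    lower cutoff is resampled (after repeated bad luck, from the strongly
    hydrophilic letters only) until the whole profile sits strictly below
    the cutoff.
    """
    if length < 30:
        raise MtfscanError("soluble_decoy requires length >= 30")
    params = params or HydroParams()
    rng = np.random.default_rng(seed)
    seq = _hydrophilic_seq(rng, length)
    w = params.half_window
    for round_ in range(200):
        profile = hydropathy_profile("".join(seq), params)
        bad = [i for i, v in enumerate(profile.values) if v >= params.lower_cutoff]
        if not bad:
            break
        alphabet = list(HYDROPHILIC) if round_ < 50 else list("DEKR")
        touched: set[int] = set()
        for i in bad:
            touched.update(range(max(0, i - w), min(length, i + w + 1)))
        for p in sorted(touched):
            seq[p] = str(rng.choice(alphabet))
    else:
        raise MtfscanError("soluble_decoy failed to converge")  # pragma: no cover
    return ProteinRecord(id=protein_id, seq="".join(seq))


def isoform_fixture(
    locus: str,
    drop_tm: bool,
    drop_domain: bool,
    seed: int,
) -> IsoformSet:
    """A per-locus isoform pair with controlled TM/domain loss.

    The reference (``<locus>.1``) is a soluble-decoy background of 279
    residues with a 21-residue hydrophobic block inserted after position
    180 (occupying 181-201 of the 300-residue reference) and a 60-residue
    TF-domain interval at 40-99.  The variant (``<locus>.2``) is the
    reference with the TM block excised when *drop_tm* and/or domain
    residues 40-69 excised when *drop_domain*.
    """
    rng = np.random.default_rng(seed)
    bg_seed = int(rng.integers(0, 2**31 - 1))
    bg = soluble_decoy(279, bg_seed, protein_id="bg").seq
    block = "".join(rng.choice(list(HYDROPHOBIC), size=21))
    ref_seq = bg[:180] + block + bg[180:]
    reference = ProteinRecord(id=f"{locus}.1", seq=ref_seq, locus=locus)
    if predict_topology_hydro(reference).n_spans < 1:  # pragma: no cover
        raise MtfscanError(f"{locus}: reference lost its planted span")

    var_seq = ref_seq
    if drop_tm:
        var_seq = var_seq[:180] + var_seq[201:]
    if drop_domain:
        var_seq = var_seq[:39] + var_seq[69:]
    variant = ProteinRecord(id=f"{locus}.2", seq=var_seq, locus=locus)
    return IsoformSet(
        locus=locus,
        reference=reference,
        variants=(variant,),
        domain=DomainInterval(reference.id, 40, 99),
    )


def genome_fixture(
    n_species: int,
    n_tf_per_species: int,
    mtf_fraction: float,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    seed: int = 0,
    out_dir: str | os.PathLike = ".",
) -> tuple[Path, AnnotationTable, FixtureTruth]:
    """A multi-species synthetic TF proteome with planted MTFs.

    Per species, ``round(mtf_fraction * n_tf_per_species)`` proteins get
    1-2 planted helices (single-span with probability 0.7, matching the
    dominance of 1-TM proteins in real MTF sets) at uniformly drawn zone
    locations; the rest are adversarially soluble decoys.  Writes
    ``proteome.fasta``, ``annotations.tsv`` and ``truth.tsv`` under
    *out_dir* and returns (FASTA path, annotation table, truth).
    """
    if not (0.0 <= mtf_fraction <= 1.0):
        raise MtfscanError("mtf_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = FixtureTruth()
    table = AnnotationTable()
    fasta_path = out / "proteome.fasta"
    n_mtf = int(round(mtf_fraction * n_tf_per_species))
    zones = list(_ZONES)
    with open(fasta_path, "w") as fh:
        for s in range(n_species):
            species = f"sp{s + 1:02d}"
            for t in range(n_tf_per_species):
                pid = f"{species}_tf{t + 1:04d}"
                family = str(rng.choice(list(families)))
                child = int(rng.integers(0, 2**31 - 1))
                if t < n_mtf:
                    n_tm = 1 if rng.random() < 0.7 else 2
                    # distinct zones for multi-span proteins so spans always fit
                    locs = [
                        zones[int(z)]
                        for z in rng.choice(3, size=n_tm, replace=False)
                    ]
                    length = int(rng.integers(250, 501))
                    rec, spans = plant_tm_protein(
                        n_tm, locs, length, child, protein_id=pid
                    )
                else:
                    length = int(rng.integers(150, 401))
                    rec = soluble_decoy(length, child, protein_id=pid)
                    spans = ()
                fh.write(f">{pid} seed={seed}\n")
                for i in range(0, len(rec.seq), 60):
                    fh.write(rec.seq[i : i + 60] + "\n")
                table.add(pid, AnnotationRow(locus=pid, species=species, family=family))
                truth.proteins[pid] = TruthEntry(
                    protein_id=pid,
                    is_mtf=bool(spans),
                    spans=spans,
                    family=family,
                    species=species,
                )
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("#id\tlocus\tspecies\tfamily\n")
        for pid in table:
            row = table[pid]
            fh.write(f"{pid}\t{row.locus}\t{row.species}\t{row.family}\n")
    truth.write(out / "truth.tsv")
    return fasta_path, table, truth
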