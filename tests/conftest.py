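from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from hypothesis import strategies as st

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from mtfscan.model import ProteinRecord, TmSpan, MtfRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@st.composite
def topology_strings(draw, min_len: int = 1, max_len: int = 80):
    """Random {i, M, o} strings (arbitrary, including non-alternating)."""
    n = draw(st.integers(min_len, max_len))
    return "".join(draw(st.sampled_from("iMo")) for _ in range(n))


@st.composite
def alternating_topologies(draw, min_len: int = 10, max_len: int = 120):
    """Well-formed topologies: alternating loops around >=0 M-runs."""
    n = draw(st.integers(min_len, max_len))
    n_spans = draw(st.integers(0, max(0, (n - 2) // 8)))
    loop = draw(st.sampled_from("io"))
    # carve the length into loop/span/loop/span/... pieces
    cuts = sorted(draw(st.lists(st.integers(1, n - 1), min_size=2 * n_spans,
                                max_size=2 * n_spans, unique=True)))
    pieces = []
    prev = 0
    for c in cuts + [n]:
        pieces.append(c - prev)
        prev = c
    states = []
    for k, size in enumerate(pieces):
        if k % 2 == 1:
            states.append("M" * size)
        else:
            states.append(loop * size)
            loop = "o" if loop == "i" else "i"
    return "".join(states)


def random_protein_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def make_mtf(pid: str, length: int, spans: list[tuple[int, int]],
             family: str = "NAC", species: str = "spA",
             provenance: frozenset = frozenset({"consensus"})) -> MtfRecord:
    """A minimal MtfRecord with an inert sequence; pattern recomputed later."""
    from mtfscan.classify import pattern_code

    rec = ProteinRecord(id=pid, seq="S" * length, family=family, species=species,
                        locus=pid)
    tm = [TmSpan(s, e) for s, e in spans]
    return MtfRecord(protein=rec, spans=tuple(tm),
                     location_pattern=pattern_code(tm, length),
                     provenance=provenance)


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """A 3-species x 40-TF synthetic proteome shared across tests."""
    from mtfscan.fixtures import genome_fixture

    out = tmp_path_factory.mktemp("genome")
    fasta, table, truth = genome_fixture(3, 40, 0.15, seed=11, out_dir=out)
    return fasta, table, truth
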