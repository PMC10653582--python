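import numpy as np
import pytest

from mutland.msa_io import Alignment, AMINO_ACIDS


def make_alignment(rows, ids=None, taxon="unknown"):
    """Build an Alignment from a list of equal-length strings (row 0 = query)."""
    if ids is None:
        ids = [f"s{i}" for i in range(len(rows))]
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return Alignment(query_id=ids[0], sequence_ids=list(ids), matrix=matrix,
                     taxon=taxon)


def random_alignment(rng, n, L, gap_frac=0.0):
    """Random alignment over the canonical alphabet; query row is gap-free."""
    aa = np.array(list(AMINO_ACIDS))
    matrix = aa[rng.integers(20, size=(n, L))]
    if gap_frac > 0 and n > 1:
        mask = rng.random(size=(n - 1, L)) < gap_frac
        matrix[1:][mask] = "-"
    ids = [f"s{i}" for i in range(n)]
    return Alignment(query_id="s0", sequence_ids=ids, matrix=matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def clade_fixture():
    """Query plus two 4-sequence clades; position 5 (1-based) segregates by
    clade (clade 1 all G, clade 2 all H), position 6 has the same symbol
    composition shuffled across clades.  Every non-query row is exactly 4
    mismatches from the query."""
    rows = [
        "AAAAAA",            # query
        "CCAAGG", "CCAAGH", "CCAAGG", "CCAAGH",   # clade 1: pos5 G
        "DDAAHH", "DDAAHG", "DDAAHH", "DDAAHG",   # clade 2: pos5 H
    ]
    return make_alignment(rows)
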