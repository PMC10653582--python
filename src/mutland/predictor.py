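"""Mutational-landscape prediction.

Combines three alignment-derived ingredients into a full L x 20 matrix of
predicted substitution effects:

* per-position conservation levels c_i on the sequence tree,
* evolutionary distances delta(i, b): the minimal conservation-weighted
  Hamming distance between the query and any aligned sequence displaying
  residue b at position i (the minimum amount of change that accommodates
  the substitution),
* weighted amino-acid frequencies computed with a reduced physicochemical
  alphabet, which back up positions where a substitution was never observed.

For an observed substitution the raw effect is delta(i, b) itself.  When b
is absent from column i but another member of its reduced class is present,
the class-minimal distance plus a penalty kappa stands in; when the whole
class is absent, the landscape-wide maximum observed distance plus kappa is
used.  Final scores are S(i, b) = -c_i * raw(i, b), rescaled so the
landscape minimum is exactly -1 and every wild-type cell exactly 0: scores
are non-positive, 0 = neutral, more negative = more deleterious.  Only the
ranking of scores is meaningful (evaluation is rank-based), so the sign and
scale conventions are free choices.

Multi-substitution variants ("A25G:F33L") score additively over their
single substitutions.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa_io import Alignment, AMINO_ACIDS, GAP
from .conservation import ConservationProfile

AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}

#: 11-class reduced alphabet grouping the 20 amino acids by physicochemistry:
#: tiny (A,G), hydroxyl (S,T), proline, cysteine, acidic (D,E), amide (N,Q),
#: histidine, basic (K,R), aliphatic-hydrophobic (I,L,M,V), aromatic (F,Y),
#: tryptophan.
REDUCED_ALPHABET_11 = (
    "AG", "ST", "P", "C", "DE", "NQ", "H", "KR", "ILMV", "FY", "W",
)

#: default pseudocount per class in frequency estimation
LAMBDA_DEFAULT = 1.0
#: default unobserved-substitution penalty, as a fraction of the maximum
#: observed distance
KAPPA_FRACTION_DEFAULT = 0.2
#: default frequency-blend weight (0 = purely distance-driven)
ALPHA_DEFAULT = 0.0

_MUTANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

logger = logging.getLogger(__name__)


class VariantError(ValueError):
    """Malformed or query-inconsistent mutation string."""


def reduced_class_map(groups: tuple[str, ...] = REDUCED_ALPHABET_11) -> dict[str, int]:
    """Map each amino acid to its reduced-class index; validates coverage."""
    mapping: dict[str, int] = {}
    for k, grp in enumerate(groups):
        for aa in grp:
            mapping[aa] = k
    if sorted(mapping) != sorted(AMINO_ACIDS):
        raise ValueError("reduced alphabet must partition the 20 amino acids")
    return mapping


@dataclass
class FrequencyTables:
    """Per-column weighted frequencies: reduced classes and full 20 letters."""

    reduced: np.ndarray      # L x K
    full: np.ndarray         # L x 20
    groups: tuple[str, ...]
    pseudocount: float


@dataclass
class Landscape:
    """L x 20 matrix of substitution effect scores.

    ``scores[i, k]`` is the predicted effect of mutating position i+1 of the
    query into amino acid ``AMINO_ACIDS[k]``; wild-type cells are 0 and the
    most deleterious cell is -1.
    """

    scores: np.ndarray
    query: str
    alphabet: str = AMINO_ACIDS
    provenance: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, mut: str) -> float:
        """Score of a single substitution at 1-based ``position``."""
        return float(self.scores[position - 1, AA_INDEX[mut]])

    def to_wide_frame(self) -> pd.DataFrame:
        idx = [f"{wt}{i + 1}" for i, wt in enumerate(self.query)]
        return pd.DataFrame(self.scores, index=idx, columns=list(self.alphabet))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, wt in enumerate(self.query):
            for aa in self.alphabet:
                if aa == wt:
                    continue
                rows.append((f"{wt}{i + 1}{aa}", self.scores[i, AA_INDEX[aa]]))
        return pd.DataFrame(rows, columns=["mutant", "score"])

    def write_wide_tsv(self, path) -> None:
        self.to_wide_frame().to_csv(path, sep="\t", float_format="%.6f")

    def write_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False, float_format="%.6f")


@dataclass
class SubstitutionQuery:
    """A parsed variant: one or more (1-based position, wt, mut) triples."""

    substitutions: list[tuple[int, str, str]]

    def __iter__(self):
        return iter(self.substitutions)

    def __len__(self):
        return len(self.substitutions)


# ---------------------------------------------------------------------------
# frequencies


def reduced_frequencies(
    aln: Alignment,
    weights: np.ndarray | None = None,
    pseudocount: float = LAMBDA_DEFAULT,
    groups: tuple[str, ...] = REDUCED_ALPHABET_11,
) -> FrequencyTables:
    """Weighted per-column frequencies over the reduced alphabet.

    Gap symbols are excluded from the denominator; a pseudocount is added
    per class (and per letter in the full-20 table).  An all-gap column
    falls back to the uniform distribution.
    """
    if weights is None:
        weights = np.ones(aln.n)
    weights = np.asarray(weights, dtype=float)
    cmap = reduced_class_map(groups)
    K = len(groups)
    L = aln.L
    red = np.zeros((L, K))
    full = np.zeros((L, 20))
    for i in range(L):
        col = aln.matrix[:, i]
        for sym, w in zip(col, weights):
            if sym == GAP:
                continue
            red[i, cmap[sym]] += w
            full[i, AA_INDEX[sym]] += w
    tot = red.sum(axis=1, keepdims=True)
    all_gap = tot[:, 0] == 0
    if all_gap.any():
        logger.warning(
            "all-gap column(s) at positions %s: using uniform frequencies",
            [int(i) + 1 for i in np.nonzero(all_gap)[0]],
        )
    red = (red + pseudocount) / (tot + K * pseudocount)
    full = (full + pseudocount) / (full.sum(axis=1, keepdims=True) + 20 * pseudocount)
    if pseudocount == 0 and all_gap.any():
        red[all_gap] = 1.0 / K
        full[all_gap] = 1.0 / 20
    return FrequencyTables(reduced=red, full=full, groups=groups, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# evolutionary distances


def _query_distances(aln: Alignment, levels: np.ndarray) -> np.ndarray:
    """Conservation-weighted Hamming distance from the query to every row.

    d_s = sum_j c_j * [x_j(s) != q_j] / sum_j c_j, over query positions;
    a gap against a query residue counts as a mismatch.
    """
    c = np.asarray(levels, dtype=float)
    denom = c.sum()
    if denom == 0:
        # degenerate: no conserved signal anywhere; fall back to uniform
        c = np.ones_like(c)
        denom = c.sum()
    mismatch = aln.matrix != aln.matrix[0]
    return mismatch @ c / denom


def evolutionary_distance(
    aln: Alignment,
    cons: ConservationProfile,
    i: int,
    b: str,
) -> float:
    """delta(i, b): minimal conservation-weighted Hamming distance between
    the query and any row displaying ``b`` at 0-based position ``i``.

    Returns NaN when no row displays ``b`` there ("unobserved").  The query
    is its own witness, so delta(i, wild-type) = 0.
    """
    if not 0 <= i < aln.L:
        raise IndexError(f"position {i} outside [0, {aln.L})")
    if b not in AA_INDEX:
        raise ValueError(f"not a canonical amino acid: {b!r}")
    d = _query_distances(aln, cons.levels)
    witnesses = aln.matrix[:, i] == b
    if not witnesses.any():
        return float("nan")
    return float(d[witnesses].min())


def distance_table(aln: Alignment, cons: ConservationProfile) -> np.ndarray:
    """L x 20 table of delta(i, b); NaN marks unobserved substitutions."""
    d = _query_distances(aln, cons.levels)
    L = aln.L
    table = np.full((L, 20), np.nan)
    for i in range(L):
        col = aln.matrix[:, i]
        for k, aa in enumerate(AMINO_ACIDS):
            mask = col == aa
            if mask.any():
                table[i, k] = d[mask].min()
    return table


# ---------------------------------------------------------------------------
# landscape assembly


def single_landscape(
    aln: Alignment,
    cons: ConservationProfile,
    freqs: FrequencyTables | None = None,
    kappa: float | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> Landscape:
    """Assemble the full single-substitution landscape.

    ``kappa`` is the penalty added to class-fallback and fully unobserved
    distances (default 0.2 x the maximum observed distance); ``alpha``
    blends in a frequency term (default 0, distance-dominant).
    """
    if aln.L == 0:
        raise ValueError("empty alignment")
    if freqs is None:
        freqs = reduced_frequencies(aln)
    cmap = reduced_class_map(freqs.groups)
    delta = distance_table(aln, cons)
    c = np.asarray(cons.levels, dtype=float)
    if c.max() == 0.0:
        # profile carries no signal at all; weight positions uniformly so the
        # distance structure still produces a ranked landscape
        c = np.ones_like(c)
    wt_idx = np.array([AA_INDEX[aa] for aa in aln.matrix[0]])

    observed = ~np.isnan(delta)
    delta_max = float(np.nanmax(delta)) if observed.any() else 0.0
    if delta_max == 0.0:
        delta_max = 1.0  # no variability in the MSA: nominal scale
    if kappa is None:
        kappa = KAPPA_FRACTION_DEFAULT * delta_max

    # class-minimal observed distance per (position, class); the wild-type
    # cell is masked out -- the query's own residue is no evidence that its
    # physicochemical class tolerates substitution
    K = len(freqs.groups)
    delta_subst = delta.copy()
    delta_subst[np.arange(aln.L), wt_idx] = np.nan
    class_min = np.full((aln.L, K), np.nan)
    for k, aa in enumerate(AMINO_ACIDS):
        cls = cmap[aa]
        col = delta_subst[:, k]
        cur = class_min[:, cls]
        class_min[:, cls] = np.where(
            np.isnan(cur), col, np.where(np.isnan(col), cur, np.minimum(cur, col))
        )

    raw = delta.copy()
    for k, aa in enumerate(AMINO_ACIDS):
        cls = cmap[aa]
        fallback = np.where(
            np.isnan(class_min[:, cls]), delta_max + kappa, class_min[:, cls] + kappa
        )
        raw[:, k] = np.where(observed[:, k], raw[:, k], fallback)

    if alpha > 0.0:
        # optional blend: rarity of b's reduced class, on the distance scale
        class_of = np.array([cmap[aa] for aa in AMINO_ACIDS])
        rarity = (1.0 - freqs.reduced[:, class_of]) * delta_max
        raw = (1.0 - alpha) * raw + alpha * rarity
    scores = -c[:, None] * raw

    # pin wild-type cells to exactly 0, then rescale the minimum to -1
    scores[np.arange(aln.L), wt_idx] = 0.0
    smin = scores.min()
    if smin < 0:
        scores = scores / (-smin)

    provenance = {
        "kappa": kappa,
        "alpha": alpha,
        "pseudocount": freqs.pseudocount,
        "reduced_alphabet": list(freqs.groups),
        "m_min": cons.m_min,
        "linkage": cons.linkage_method,
        "msa_digest": hashlib.sha256(aln.matrix.tobytes()).hexdigest()[:16],
    }
    return Landscape(scores=scores, query=aln.query, provenance=provenance)


# ---------------------------------------------------------------------------
# variants


def parse_mutant(s: str, query: str, offset: int = 0) -> SubstitutionQuery:
    """Parse a ProteinGym-style mutant string ("A25G", "A25G:F33L").

    ``offset`` shifts DMS numbering onto 1-based query numbering (query
    position = reported position - offset).  Wild-type letters are checked
    against the query; duplicate positions within one variant are rejected.
    """
    if not s or not s.strip():
        raise VariantError("empty mutant string")
    subs: list[tuple[int, str, str]] = []
    seen: set[int] = set()
    for token in s.strip().split(":"):
        m = _MUTANT_RE.match(token.strip())
        if m is None:
            raise VariantError(f"malformed mutation token {token!r}")
        wt, pos_str, mut = m.group(1), m.group(2), m.group(3)
        if wt not in AA_INDEX or mut not in AA_INDEX:
            raise VariantError(f"non-canonical amino acid in token {token!r}")
        pos = int(pos_str) - offset
        if not 1 <= pos <= len(query):
            raise VariantError(
                f"position {pos} of token {token!r} outside query range 1..{len(query)}"
            )
        if query[pos - 1] != wt:
            raise VariantError(
                f"wild-type mismatch at position {pos}: token says {wt}, "
                f"query has {query[pos - 1]}"
            )
        if pos in seen:
            raise VariantError(f"duplicate position {pos} in variant {s!r}")
        seen.add(pos)
        subs.append((pos, wt, mut))
    return SubstitutionQuery(substitutions=subs)


def combined_score(landscape: Landscape, q: SubstitutionQuery) -> float:
    """Additive score of a (possibly multi-substitution) variant."""
    return float(sum(landscape.score(pos, mut) for pos, _wt, mut in q))
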