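"""Alignment depth: sequence weights, Neff and the shallow/deep classification.

The effective number of sequences is the standard redundancy-corrected depth

    Neff = sum_s pi_s,      pi_s = 1 / #{ t : D_H(x(s), x(t)) < theta_ID }

where D_H is the normalized Hamming distance between aligned rows and
theta_ID a divergence neighborhood (0.2 for cellular proteins, 0.01 for
viral ones, i.e. 80% / 99% identity).  Alignments are classed by the ratio
of Neff to the number of well-covered positions Lcov (columns with under
30% gaps): ratio < 1 is "low" (shallow), ratio > 100 is "high" (deep),
anything between is "medium".  Both Neff/Lcov and Neff/L are reported.

Gap conventions: a gap aligned against a residue is a mismatch; a gap
aligned against a gap is a match, which keeps D_H(s, s) = 0 for every row.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .msa_io import Alignment, GAP

#: divergence threshold by taxon (fraction of positions allowed to differ)
THETA_BY_TAXON = {
    "human": 0.2,
    "eukaryote": 0.2,
    "prokaryote": 0.2,
    "unknown": 0.2,
    "virus": 0.01,
}

#: rows per block in the pairwise-distance sweep; results are independent of
#: this value (pure chunking of an exact computation)
WEIGHT_CHUNK_ROWS = 2048


@dataclass
class DepthReport:
    weights: np.ndarray
    neff: float
    L: int
    Lcov: int
    theta_id: float
    depth_class: str

    @property
    def ratio_L(self) -> float:
        return self.neff / self.L

    @property
    def ratio_Lcov(self) -> float:
        return self.neff / self.Lcov if self.Lcov else float("inf")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = [float(w) for w in self.weights]
        d["ratio_L"] = self.ratio_L
        d["ratio_Lcov"] = self.ratio_Lcov
        return d


def hamming_norm(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Normalized Hamming distance between two aligned rows.

    Gap/residue counts as a mismatch, gap/gap as a match.
    """
    a = np.asarray(list(a) if isinstance(a, str) else a, dtype="<U1")
    b = np.asarray(list(b) if isinstance(b, str) else b, dtype="<U1")
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("rows must be 1-D, non-empty and of equal length")
    return float(np.mean(a != b))


def _encoded(aln: Alignment) -> np.ndarray:
    # map symbols to small ints for fast pairwise comparison
    return aln.matrix.view(np.uint32).reshape(aln.n, aln.L)


def pairwise_hamming(aln: Alignment) -> np.ndarray:
    """Full N x N matrix of normalized Hamming distances."""
    enc = _encoded(aln)
    n = aln.n
    out = np.empty((n, n), dtype=float)
    for start in range(0, n, WEIGHT_CHUNK_ROWS):
        block = enc[start : start + WEIGHT_CHUNK_ROWS]
        out[start : start + WEIGHT_CHUNK_ROWS] = (
            (block[:, None, :] != enc[None, :, :]).mean(axis=2)
        )
    return out


def sequence_weights(aln: Alignment, theta_id: float) -> np.ndarray:
    """Per-sequence weights pi_s = 1 / #{t : D_H(s,t) < theta_id}.

    The neighborhood count uses a strict inequality and always includes the
    sequence itself (self-distance 0), so every weight lies in [1/N, 1].
    """
    if not 0.0 < theta_id < 1.0:
        raise ValueError("theta_id must lie strictly between 0 and 1")
    if aln.n == 0:
        raise ValueError("empty alignment")
    enc = _encoded(aln)
    n, L = enc.shape
    counts = np.zeros(n, dtype=np.int64)
    for start in range(0, n, WEIGHT_CHUNK_ROWS):
        block = enc[start : start + WEIGHT_CHUNK_ROWS]
        mism = (block[:, None, :] != enc[None, :, :]).sum(axis=2)
        # divide before comparing so the strict test agrees bit-for-bit with
        # hamming_norm(s, t) < theta_id
        counts[start : start + WEIGHT_CHUNK_ROWS] = (mism / L < theta_id).sum(axis=1)
    return 1.0 / counts


def neff(aln: Alignment, theta_id: float) -> float:
    """Effective number of sequences: the sum of the weights."""
    return float(sequence_weights(aln, theta_id).sum())


def default_theta(taxon: str) -> float:
    """Divergence threshold theta_ID by taxon: 0.01 for viral proteins
    (99% identity), 0.2 otherwise (80% identity)."""
    try:
        return THETA_BY_TAXON[taxon]
    except KeyError:
        raise ValueError(f"unknown taxon label {taxon!r}") from None


def coverage_length(aln: Alignment, max_gap_frac: float = 0.30) -> int:
    """Number of query positions whose column gap fraction (over all rows)
    is strictly below ``max_gap_frac``."""
    if not 0.0 < max_gap_frac <= 1.0:
        raise ValueError("max_gap_frac must lie in (0, 1]")
    gap_frac = (aln.matrix == GAP).mean(axis=0)
    return int(np.sum(gap_frac < max_gap_frac))


def classify_depth(ratio: float) -> str:
    """Depth class from a Neff ratio: < 1 low, > 100 high, else medium.

    The boundaries themselves fall in "medium" because the shallow and deep
    definitions are strict inequalities.
    """
    if ratio < 1.0:
        return "low"
    if ratio > 100.0:
        return "high"
    return "medium"


def depth_report(
    aln: Alignment,
    theta_id: float | None = None,
    max_gap_frac: float = 0.30,
    classify_on: str = "ratio_Lcov",
) -> DepthReport:
    """Compute the full depth report for an alignment.

    ``classify_on`` selects which ratio drives the class label
    ("ratio_Lcov", the benchmark convention, or "ratio_L").
    """
    if theta_id is None:
        theta_id = default_theta(aln.taxon)
    w = sequence_weights(aln, theta_id)
    ne = float(w.sum())
    lcov = coverage_length(aln, max_gap_frac)
    report = DepthReport(
        weights=w, neff=ne, L=aln.L, Lcov=lcov, theta_id=theta_id, depth_class=""
    )
    if classify_on not in ("ratio_Lcov", "ratio_L"):
        raise ValueError("classify_on must be 'ratio_Lcov' or 'ratio_L'")
    report.depth_class = classify_depth(getattr(report, classify_on))
    return report
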