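"""Synthetic alignments and DMS tables with known ground truth.

Sequences are evolved down a simulated pure-birth (Yule) tree from a random
root sequence, which also serves as the query.  Each site carries a
constraint kappa_i in [0, 1]: every proposed substitution at site i is
rejected with probability kappa_i, so kappa_i = 1 keeps the column
monomorphic and kappa_i = 0 lets it drift freely.  Substitutions are
proposed per site as a Poisson process along each branch and draw the
replacement uniformly from the 19 alternative amino acids.  There are no
indels, so the simulated sequences are already aligned and every column has
full coverage.

Matched synthetic DMS tables score each substitution at site i as
-kappa_i * effect_size plus Gaussian noise, giving a measurement whose
noise-free version is an exact monotone function of the ground-truth
constraint.

All randomness flows through a single seed: the tree uses a
``random.Random`` and everything else a numpy ``Generator``, both derived
from it, so a fixed seed reproduces the FASTA output byte for byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
from dendropy.simulate import treesim

from .msa_io import Alignment, AMINO_ACIDS
from .evaluation import DMSTable

AA_ARRAY = np.array(list(AMINO_ACIDS))


class GenerationError(RuntimeError):
    """A preset failed its post-generation regime check; re-seed and retry."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study condition."""

    n_sequences: int = 200
    length: int = 50
    birth_rate: float = 1.0
    kappa: np.ndarray | None = None     # per-site constraint; None = U(0,1)
    branch_scale: float = 1.0           # expected proposals per site per unit length
    dms_noise_sd: float = 0.1
    effect_size: float = 1.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be positive")
        if self.birth_rate <= 0 or self.branch_scale < 0:
            raise ValueError("birth_rate must be positive, branch_scale >= 0")
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)
            if self.kappa.shape != (self.length,):
                raise ValueError("kappa must have one entry per site")
            if np.any((self.kappa < 0) | (self.kappa > 1)):
                raise ValueError("kappa entries must lie in [0, 1]")


@dataclass
class GroundTruth:
    tree_newick: str
    kappa: np.ndarray
    root_sequence: str


def _evolve(seq: np.ndarray, t: float, kappa: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve one sequence along a branch of (scaled) length t."""
    out = seq.copy()
    n_prop = rng.poisson(t, size=len(seq))
    for i in np.nonzero(n_prop)[0]:
        for _ in range(n_prop[i]):
            if rng.random() < kappa[i]:
                continue  # constrained site rejects this proposal
            alternatives = [aa for aa in AMINO_ACIDS if aa != out[i]]
            out[i] = alternatives[rng.integers(19)]
    return out


def simulate_msa(spec: SyntheticSpec) -> tuple[Alignment, GroundTruth]:
    """Simulate an alignment down a pure-birth tree.

    Row 0 is the query (= the root sequence); the remaining rows are the
    tree's leaves in stable label order.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    kappa = spec.kappa if spec.kappa is not None else rng.uniform(0, 1, spec.length)
    root_seq = AA_ARRAY[rng.integers(20, size=spec.length)]

    if spec.n_sequences == 1:
        matrix = root_seq[None, :]
        ids = ["query"]
        newick = "query;"
    else:
        tree = treesim.birth_death_tree(
            birth_rate=spec.birth_rate,
            death_rate=0.0,
            num_extant_tips=spec.n_sequences,
            rng=random.Random(spec.seed + 1),
        )
        seqs: dict[int, np.ndarray] = {}
        leaf_rows: list[tuple[str, np.ndarray]] = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                seqs[id(node)] = root_seq
            else:
                t = (node.edge.length or 0.0) * spec.branch_scale
                seqs[id(node)] = _evolve(seqs[id(node.parent_node)], t, kappa, rng)
            if node.is_leaf():
                leaf_rows.append((node.taxon.label, seqs[id(node)]))
        leaf_rows.sort(key=lambda kv: kv[0])
        ids = ["query"] + [label.replace(" ", "_") for label, _ in leaf_rows]
        matrix = np.stack([root_seq] + [s for _, s in leaf_rows])
        newick = tree.as_string(schema="newick").strip()

    aln = Alignment(
        query_id="query",
        sequence_ids=ids,
        matrix=matrix,
        taxon="unknown",
        source_protocol=f"synthetic:{spec.name or 'custom'}",
    )
    truth = GroundTruth(tree_newick=newick, kappa=kappa, root_sequence="".join(root_seq))
    return aln, truth


def simulate_dms(
    kappa: np.ndarray,
    query: str,
    spec: SyntheticSpec,
    n_multi: int = 0,
) -> DMSTable:
    """Synthetic DMS matched to per-site constraints.

    Every single substitution at site i measures
    ``-kappa_i * effect_size + Normal(0, dms_noise_sd)``; higher values are
    more functional, so strongly constrained sites score low.  ``n_multi``
    optional double mutants add their single-site effects plus one noise
    draw.  Deterministic per seed (a distinct stream from the MSA's).
    """
    kappa = np.asarray(kappa, dtype=float)
    rng = np.random.default_rng(spec.seed + 2)
    mutants: list[str] = []
    values: list[float] = []
    for i, wt in enumerate(query):
        for aa in AMINO_ACIDS:
            if aa == wt:
                continue
            mutants.append(f"{wt}{i + 1}{aa}")
            values.append(
                -kappa[i] * spec.effect_size + rng.normal(0, spec.dms_noise_sd)
            )
    L = len(query)
    made: set[str] = set()
    for _ in range(n_multi):
        i, j = sorted(rng.choice(L, size=2, replace=False))
        mi = AA_ARRAY[AA_ARRAY != query[i]][rng.integers(19)]
        mj = AA_ARRAY[AA_ARRAY != query[j]][rng.integers(19)]
        s = f"{query[i]}{i + 1}{mi}:{query[j]}{j + 1}{mj}"
        if s in made or s in mutants:
            continue
        made.add(s)
        mutants.append(s)
        values.append(
            -(kappa[i] + kappa[j]) * spec.effect_size
            + rng.normal(0, spec.dms_noise_sd)
        )
    return DMSTable(
        experiment_id=f"synthetic_dms_seed{spec.seed}",
        target_id=f"synthetic_target_seed{spec.seed}",
        taxon="unknown",
        mutants=mutants,
        measurements=np.array(values),
    )


def depth_regimes(seed: int = 0) -> dict[str, SyntheticSpec]:
    """Presets whose realized Neff/Lcov falls in the low / medium / high
    depth bands (< 1, between 1 and 100, > 100); each preset is verified
    at generation time by :func:`verify_regime`."""
    return {
        "low": SyntheticSpec(
            n_sequences=40, length=60, branch_scale=0.3, seed=seed, name="low"
        ),
        "medium": SyntheticSpec(
            n_sequences=300, length=50, branch_scale=2.0, seed=seed, name="medium"
        ),
        "high": SyntheticSpec(
            n_sequences=1500, length=10, branch_scale=5.0, seed=seed, name="high"
        ),
    }


def verify_regime(spec: SyntheticSpec, theta_id: float = 0.2) -> float:
    """Simulate the preset and return its realized Neff/Lcov ratio.

    Raises GenerationError when the ratio misses the preset's band.
    """
    from .depth_metrics import classify_depth, coverage_length, neff

    aln, _ = simulate_msa(spec)
    ratio = neff(aln, theta_id) / coverage_length(aln)
    if spec.name in ("low", "medium", "high") and classify_depth(ratio) != spec.name:
        raise GenerationError(
            f"preset {spec.name!r} realized Neff/Lcov = {ratio:.3g} outside its "
            "band; re-seed and regenerate"
        )
    return ratio
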