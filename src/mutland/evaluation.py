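"""Scoring landscapes against deep-mutational-scanning measurements.

The accuracy metric is the Spearman rank correlation between predicted
substitution effects and experimental measurements, computed per DMS
experiment over the variants whose positions fall in the evaluated region
(when comparing protocols with different coverage, the calculation is
restricted to their common positions).  Aggregation is two-stage: DMS
experiments are first averaged within their target protein, then target
means are averaged within each group (taxon, depth class), mirroring how
benchmark tables weight proteins rather than experiments; the flat per-DMS
mean is reported alongside.

A redundancy filter de-duplicates benchmark proteins from precomputed
pairwise alignment records: a pair is redundant when its identity reaches
the cutoff, except that alignments shorter than 50 residues are ignored
for pairs of sequences that are both at least 180 residues long, so that
spurious short local alignments cannot knock out long proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .predictor import Landscape, VariantError, combined_score, parse_mutant

logger = logging.getLogger(__name__)

#: default sequence-identity cutoff above which two benchmark proteins are
#: considered redundant (UniqueProt-style HVAL0 neighborhood, configurable)
REDUNDANCY_IDENTITY_DEFAULT = 0.2
#: alignments shorter than this many residues are exempt from the filter...
SHORT_ALIGNMENT_RESIDUES = 50
#: ...when both sequences are at least this long
LONG_SEQUENCE_RESIDUES = 180


class EvaluationError(ValueError):
    pass


class UndefinedCorrelationError(EvaluationError):
    """Raised when a rank correlation is undefined (constant input)."""


class InsufficientDataError(EvaluationError):
    pass


class PairingError(EvaluationError):
    pass


@dataclass
class DMSTable:
    """One DMS experiment: mutant strings with a functional measurement.

    Higher measurements are assumed more functional; use ``flip=True`` at
    load time for assays where lower is better.
    """

    experiment_id: str
    target_id: str
    taxon: str
    mutants: list[str]
    measurements: np.ndarray
    multiple_mutants: bool = False

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=float)
        if len(self.mutants) != len(self.measurements):
            raise EvaluationError("mutants and measurements differ in length")
        if len(set(self.mutants)) != len(self.mutants):
            raise EvaluationError("duplicate mutant strings in DMS table")
        if not np.all(np.isfinite(self.measurements)):
            raise EvaluationError("non-finite measurement in DMS table")
        self.multiple_mutants = any(":" in m for m in self.mutants)


@dataclass
class EvaluationResult:
    experiment_id: str
    target_id: str
    rho: float
    n_variants: int
    n_excluded: int
    position_range: tuple[int, int]
    taxon: str = "unknown"
    depth_class: str = ""
    protocol: str = ""


def read_dms_csv(
    path,
    measurement_column: str,
    experiment_id: str = "",
    target_id: str = "",
    taxon: str = "unknown",
    mutant_column: str = "mutant",
    flip: bool = False,
) -> DMSTable:
    """Load a ProteinGym-style CSV with ``mutant`` and measurement columns."""
    df = pd.read_csv(path)
    for col in (mutant_column, measurement_column):
        if col not in df.columns:
            raise EvaluationError(f"column {col!r} missing from {path}")
    meas = df[measurement_column].to_numpy(dtype=float)
    if flip:
        meas = -meas
    return DMSTable(
        experiment_id=experiment_id or str(path),
        target_id=target_id or experiment_id or str(path),
        taxon=taxon,
        mutants=df[mutant_column].astype(str).tolist(),
        measurements=meas,
    )


def spearman(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties).

    Raises UndefinedCorrelationError for constant input rather than
    returning 0: an undefined correlation is reported as missing.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise EvaluationError("inputs must be equal-length 1-D with n >= 2")
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        raise UndefinedCorrelationError("constant input: rank correlation undefined")
    rho = stats.spearmanr(pred, obs).statistic
    return float(rho)


def evaluate(
    landscape: Landscape,
    dms: DMSTable,
    region: Iterable[int] | None = None,
    offset: int = 0,
    depth_class: str = "",
    protocol: str = "",
) -> EvaluationResult:
    """Correlate landscape scores with one DMS experiment.

    ``region`` is an optional set of 1-based query positions; variants
    touching any position outside it, and unparseable variants, are
    excluded (and counted), never silently scored.
    """
    region_set = None if region is None else set(region)
    preds: list[float] = []
    obs: list[float] = []
    positions: list[int] = []
    excluded = 0
    for mut, meas in zip(dms.mutants, dms.measurements):
        try:
            q = parse_mutant(mut, landscape.query, offset=offset)
        except VariantError as exc:
            logger.warning("excluding variant %r: %s", mut, exc)
            excluded += 1
            continue
        pos = [p for p, _w, _m in q]
        if region_set is not None and not all(p in region_set for p in pos):
            excluded += 1
            continue
        preds.append(combined_score(landscape, q))
        obs.append(float(meas))
        positions.extend(pos)
    if len(preds) < 2:
        raise InsufficientDataError(
            f"only {len(preds)} scoreable variant(s) in {dms.experiment_id}"
        )
    rho = spearman(preds, obs)
    return EvaluationResult(
        experiment_id=dms.experiment_id,
        target_id=dms.target_id,
        rho=rho,
        n_variants=len(preds),
        n_excluded=excluded,
        position_range=(min(positions), max(positions)),
        taxon=dms.taxon,
        depth_class=depth_class,
        protocol=protocol,
    )


def aggregate(
    results: Sequence[EvaluationResult],
    by: Sequence[str] = (),
) -> dict[str, pd.DataFrame]:
    """Two-stage averages of Spearman rho, plus flat per-DMS means.

    Experiments are averaged within each target first, then target means
    within each group keyed by ``by`` (subset of {"taxon", "depth_class"}).
    When results carry exactly two protocol labels, the paired per-target
    mean difference is included as well (second label minus first, in
    order of appearance; the pairing key is the target id).
    """
    if not results:
        raise EvaluationError("no results to aggregate")
    bad = set(by) - {"taxon", "depth_class"}
    if bad:
        raise EvaluationError(f"cannot aggregate by {sorted(bad)}")
    df = pd.DataFrame(
        {
            "experiment_id": [r.experiment_id for r in results],
            "target_id": [r.target_id for r in results],
            "taxon": [r.taxon for r in results],
            "depth_class": [r.depth_class for r in results],
            "protocol": [r.protocol for r in results],
            "rho": [r.rho for r in results],
            "n_variants": [r.n_variants for r in results],
        }
    )
    keys = list(by)
    group_keys = keys if keys else []

    per_target = (
        df.groupby(["protocol", "target_id"] + keys, dropna=False, sort=True)
        .agg(rho_target=("rho", "mean"), n_dms=("rho", "size"))
        .reset_index()
    )
    if group_keys:
        two_stage = (
            per_target.groupby(["protocol"] + group_keys, sort=True)
            .agg(mean_rho=("rho_target", "mean"), n_targets=("rho_target", "size"))
            .reset_index()
        )
        flat = (
            df.groupby(["protocol"] + group_keys, sort=True)
            .agg(mean_rho_flat=("rho", "mean"), n_dms=("rho", "size"))
            .reset_index()
        )
    else:
        two_stage = (
            per_target.groupby("protocol", sort=True)
            .agg(mean_rho=("rho_target", "mean"), n_targets=("rho_target", "size"))
            .reset_index()
        )
        flat = (
            df.groupby("protocol", sort=True)
            .agg(mean_rho_flat=("rho", "mean"), n_dms=("rho", "size"))
            .reset_index()
        )
    out = {"per_target": per_target, "two_stage": two_stage, "flat": flat}

    protocols = list(dict.fromkeys(df["protocol"]))
    if len(protocols) == 2:
        a, b = protocols
        pa = per_target[per_target["protocol"] == a].set_index("target_id")
        pb = per_target[per_target["protocol"] == b].set_index("target_id")
        orphans = sorted(set(pa.index) ^ set(pb.index))
        if orphans:
            raise PairingError(
                f"targets present under only one protocol: {orphans}"
            )
        diff = (pb["rho_target"] - pa["rho_target"]).rename("delta_rho").reset_index()
        if group_keys:
            meta = per_target[per_target["protocol"] == a][["target_id"] + group_keys]
            diff = diff.merge(meta, on="target_id")
            delta = (
                diff.groupby(group_keys)
                .agg(mean_delta_rho=("delta_rho", "mean"), n_targets=("delta_rho", "size"))
                .reset_index()
            )
        else:
            delta = pd.DataFrame(
                {
                    "mean_delta_rho": [diff["delta_rho"].mean()],
                    "n_targets": [len(diff)],
                }
            )
        delta.attrs["comparison"] = f"{b} - {a}"
        out["delta"] = delta
    return out


@dataclass
class PairwiseRecord:
    """Precomputed alignment between two benchmark sequences."""

    id_a: str
    id_b: str
    alignment_length: int
    identity: float
    len_a: int
    len_b: int


def redundancy_filter(
    ids: Sequence[str],
    pairwise: Iterable[PairwiseRecord | tuple],
    threshold: float = REDUNDANCY_IDENTITY_DEFAULT,
) -> list[str]:
    """Greedy de-duplication of benchmark sequences.

    A pair is redundant iff identity >= threshold, unless the alignment is
    shorter than 50 residues while both sequences are at least 180 residues
    long (short local hits must not remove long proteins).  Ids are kept in
    input order, dropping any id redundant to an already-retained one.
    """
    records = [
        r if isinstance(r, PairwiseRecord) else PairwiseRecord(*r) for r in pairwise
    ]
    redundant_with: dict[str, set[str]] = {i: set() for i in ids}
    for r in records:
        exempt = (
            r.alignment_length < SHORT_ALIGNMENT_RESIDUES
            and min(r.len_a, r.len_b) >= LONG_SEQUENCE_RESIDUES
        )
        if r.identity >= threshold and not exempt:
            redundant_with.setdefault(r.id_a, set()).add(r.id_b)
            redundant_with.setdefault(r.id_b, set()).add(r.id_a)
    retained: list[str] = []
    for i in ids:
        if any(j in redundant_with.get(i, ()) for j in retained):
            continue
        retained.append(i)
    return retained
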