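"""End-to-end orchestration: preprocess -> depth -> conserve -> predict -> evaluate.

A run is fully described by a flat :class:`RunConfig`, serialized to YAML;
every run writes its resolved config next to its outputs so that the config
file alone reproduces the run.  Policy gates applied before prediction:

* queries of at most ``min_query_len`` residues (default 20) are skipped as
  too short to be treated as proteins;
* alignments with fewer than ``shallow_msa_threshold`` sequences (default
  200) trigger an advisory to regenerate the MSA without the diversity
  filter — regeneration needs the external search tool, so the flag is
  recorded in the report rather than acted on.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import depth_metrics, msa_io
from .conservation import conservation_profile
from .evaluation import read_dms_csv, evaluate
from .predictor import (
    ALPHA_DEFAULT,
    LAMBDA_DEFAULT,
    REDUCED_ALPHABET_11,
    reduced_frequencies,
    single_landscape,
)

logger = logging.getLogger("mutland")


def setup_logging(level: int = logging.INFO) -> None:
    """Structured stage logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("mutland")
    root.handlers[:] = [handler]
    root.setLevel(level)


@dataclass
class RunConfig:
    """Flat, YAML-serializable description of one pipeline run."""

    msa_path: str = ""
    msa_format: str = "fasta"
    taxon: str = "unknown"
    theta_id: float | None = None        # None = taxon default
    min_query_len: int = 20
    shallow_msa_threshold: int = 200
    linkage: str = "average"
    reduced_alphabet: list[str] = field(
        default_factory=lambda: list(REDUCED_ALPHABET_11)
    )
    kappa: float | None = None           # None = 0.2 x max observed distance
    pseudocount: float = LAMBDA_DEFAULT
    alpha: float = ALPHA_DEFAULT
    dms_path: str = ""
    dms_measurement_column: str = "DMS_score"
    dms_flip: bool = False
    offset: int = 0
    region: str = ""                     # "start-end", 1-based inclusive
    seed: int = 0
    out_dir: str = "mutland_out"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _parse_region(region: str) -> set[int] | None:
    if not region:
        return None
    start, end = region.split("-")
    return set(range(int(start), int(end) + 1))


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) a machine-readable report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "resolved_config.yaml")
    report: dict = {"config": asdict(config), "stages": {}, "status": "incomplete"}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 3)}
        return report["stages"][name]

    try:
        s = stage("preprocess")
        aln = msa_io.read_alignment(
            config.msa_path, format=config.msa_format, taxon=config.taxon
        )
        aln, changes = msa_io.preprocess_undefined(aln)
        msa_io.write_change_log(changes, out_dir / "changes.tsv")
        s.update(n_sequences=aln.n, length=aln.L, n_edits=len(changes))

        verdict = msa_io.check_query_length(aln, config.min_query_len)
        report["query_length_verdict"] = verdict
        if verdict == "skip":
            report["status"] = "skipped"
            report["skip_reason"] = (
                f"query length {aln.L} <= min_query_len {config.min_query_len}"
            )
            return _finish(report, out_dir)
        if aln.n < config.shallow_msa_threshold:
            report["shallow_msa_advisory"] = (
                f"MSA has {aln.n} sequences (< {config.shallow_msa_threshold}); "
                "recommend regenerating the alignment without the filter step"
            )

        s = stage("depth")
        dr = depth_metrics.depth_report(aln, theta_id=config.theta_id)
        depth_dict = dr.to_dict()
        with open(out_dir / "depth.json", "w") as fh:
            json.dump(depth_dict, fh, indent=1)
        report["depth"] = {k: v for k, v in depth_dict.items() if k != "weights"}
        s.update(neff=dr.neff, depth_class=dr.depth_class)

        s = stage("conserve")
        cons = conservation_profile(aln, method=config.linkage)
        with open(out_dir / "conservation.tsv", "w") as fh:
            fh.write("position\tresidue\tlevel\n")
            for i, (wt, lev) in enumerate(zip(aln.query, cons.levels)):
                fh.write(f"{i + 1}\t{wt}\t{lev:.6f}\n")
        s.update(mean_level=float(np.mean(cons.levels)))

        s = stage("predict")
        freqs = reduced_frequencies(
            aln,
            weights=dr.weights,
            pseudocount=config.pseudocount,
            groups=tuple(config.reduced_alphabet),
        )
        scape = single_landscape(
            aln, cons, freqs, kappa=config.kappa, alpha=config.alpha
        )
        scape.write_wide_tsv(out_dir / "landscape.tsv")
        scape.write_long_csv(out_dir / "landscape.csv")
        s.update(min_score=float(scape.scores.min()))

        if config.dms_path:
            s = stage("evaluate")
            dms = read_dms_csv(
                config.dms_path,
                measurement_column=config.dms_measurement_column,
                taxon=config.taxon,
                flip=config.dms_flip,
            )
            res = evaluate(
                scape,
                dms,
                region=_parse_region(config.region),
                offset=config.offset,
                depth_class=dr.depth_class,
            )
            report["evaluation"] = {
                "experiment_id": res.experiment_id,
                "rho": res.rho,
                "n_variants": res.n_variants,
                "n_excluded": res.n_excluded,
                "position_range": list(res.position_range),
            }
            s.update(rho=res.rho)

        report["status"] = "complete"
    except Exception as exc:
        failed = list(report["stages"])[-1] if report["stages"] else "init"
        report["status"] = "error"
        report["error"] = {"stage": failed, "cause": str(exc)}
        _finish(report, out_dir)
        raise
    return _finish(report, out_dir)


def _finish(report: dict, out_dir: Path) -> dict:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
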