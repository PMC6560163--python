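"""End-to-end synthetic pipeline: simulate -> score -> chemogram -> concordance.

Given a run configuration (YAML or dict) the pipeline simulates a labelled
cohort and its drug plates (or loads user-supplied tables), averages
technical replicates, scores the signature, fits dose-response curves, and
compares AUC between the called subgroups.  Every run writes a provenance
record (input checksums, configuration, seed, package version) next to its
outputs, and identical configuration + seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemogram import compare_groups, cross_drug_correlation, fit_table
from .expression import average_replicates, normalize_housekeeping, read_counts, read_sample_meta, write_counts
from .signature import DEFAULT_SIGNATURE, SignatureDefinition, score_cohort, score_table
from .synthetic import CohortSimConfig, PlateSimConfig, simulate_cohort, simulate_plate

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the exit code the CLI should use."""

    def __init__(self, message: str, exit_code: int = 2):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    When ``counts_path`` is None a synthetic cohort is simulated from
    ``cohort`` and drug plates from ``plates`` (one entry per drug).
    """

    out_dir: str = "mycsig_run"
    seed: int = 0
    counts_path: str | None = None
    meta_path: str | None = None
    viability_paths: dict[str, str] = field(default_factory=dict)
    signature_path: str | None = None
    normalize_hk: bool = True
    cohort: dict = field(default_factory=dict)
    plates: dict[str, dict] = field(default_factory=lambda: {"JQ1": {}, "NHWD-870": {}})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages and return the report directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = (
        SignatureDefinition.from_yaml(cfg.signature_path)
        if cfg.signature_path
        else DEFAULT_SIGNATURE
    )
    provenance: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in vars(cfg).items()},
        "inputs": {},
    }

    # ---- stage 1: obtain cohort -------------------------------------------
    if cfg.counts_path:
        counts_file = Path(cfg.counts_path)
        if not counts_file.exists():
            raise PipelineError(f"counts file not found: {counts_file}", exit_code=2)
        meta = read_sample_meta(cfg.meta_path) if cfg.meta_path else None
        matrix = read_counts(counts_file, sample_meta=meta,
                             signature_genes=list(sig.signature_genes))
        provenance["inputs"][str(counts_file)] = _sha256(counts_file)
        truth = None
    else:
        cohort_cfg = CohortSimConfig(seed=cfg.seed, **cfg.cohort)
        matrix, truth = simulate_cohort(cohort_cfg, sig)
        truth.to_yaml(str(out / "truth.yaml"))

    if matrix.sample_meta is not None and "replicate_group" in matrix.sample_meta.columns:
        matrix = average_replicates(matrix)
    if cfg.normalize_hk:
        matrix = normalize_housekeeping(matrix, list(sig.housekeeping_genes))
    write_counts(matrix, out / "counts_processed.tsv")

    # ---- stage 2: signature scoring ---------------------------------------
    try:
        results = score_cohort(matrix, sig)
    except Exception as exc:
        raise PipelineError(f"scoring failed: {exc}", exit_code=3) from exc
    table, summary = score_table(results)
    table.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.10g")
    summary.to_csv(out / "score_summary.tsv", sep="\t", index=False)
    labels = {r.sample: r.label for r in results}

    # ---- stage 3: chemograms ----------------------------------------------
    auc_by_drug: dict[str, dict[str, float]] = {}
    comparisons: dict[str, dict] = {}
    if cfg.viability_paths:
        plates = {}
        for drug, path in cfg.viability_paths.items():
            p = Path(path)
            if not p.exists():
                raise PipelineError(f"viability file not found: {p}", exit_code=2)
            plates[drug] = pd.read_csv(p, sep="\t")
            provenance["inputs"][str(p)] = _sha256(p)
    elif truth is not None:
        # one independent stream per drug, all derived from the run seed
        drug_seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.plates))
        plates = {
            drug: simulate_plate(
                PlateSimConfig(seed=int(ss.generate_state(1)[0] % 2**31), **plate_cfg),
                truth, drug=drug,
            )
            for (drug, plate_cfg), ss in zip(cfg.plates.items(), drug_seeds)
        }
    else:
        plates = {}

    for drug, plate in plates.items():
        fits = fit_table(plate)
        fits.to_csv(out / f"chemogram_{drug}.tsv", sep="\t", index=False,
                    float_format="%.10g")
        auc_by_drug[drug] = dict(zip(fits["sample"], fits["auc"]))
        try:
            comparisons[drug] = compare_groups(auc_by_drug[drug], labels)
        except ValueError:
            comparisons[drug] = {"note": "subgroup comparison unavailable (one group empty)"}
    if len(auc_by_drug) >= 2:
        d1, d2 = list(auc_by_drug)[:2]
        comparisons["cross_drug"] = cross_drug_correlation(auc_by_drug[d1], auc_by_drug[d2])
    if comparisons:
        with open(out / "group_comparisons.json", "w", encoding="utf-8") as fh:
            json.dump(comparisons, fh, indent=2, sort_keys=True)

    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out
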