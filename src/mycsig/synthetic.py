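"""Synthetic nCounter-style cohorts and drug-screen plates with known truth.

The cohort generator draws per-gene, per-sample counts from a negative
binomial whose mean encodes the MYC state of the sample: in MYC-high samples
up-regulated signature genes are shifted up by ``effect_size`` and
down-regulated genes down by the same factor (symmetric on the log scale);
housekeeping genes are unaffected by the label.  Dispersion follows the
var = mu + dispersion * mu**2 convention, so dispersion 0 degrades to
Poisson.  The plate generator draws triplicate viability readings from a
four-parameter log-logistic curve whose IC50 depends on the MYC label, with
additive Gaussian noise truncated at zero and vehicle (dose 0) wells at a
mean of 100.

A single seed drives a splittable generator, so cohort and plate draws are
independent streams but jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .signature import DEFAULT_SIGNATURE, MYC_HIGH, MYC_LOW, SignatureDefinition

__all__ = [
    "CohortSimConfig",
    "PlateSimConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_plate",
]

DEFAULT_DOSES_UM = tuple(np.round(np.logspace(np.log10(0.003), np.log10(100.0), 8), 6))


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters for a simulated NanoString-style cohort.

    Defaults mirror the study design the package targets: 24 organoid
    samples split 11 MYC-high / 13 MYC-low, moderate baseline counts and
    overdispersion, and a two-fold signature shift.
    """

    n_high: int = 11
    n_low: int = 13
    effect_size: float = 2.0
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_low < 0 or self.n_high + self.n_low < 1:
            raise ValueError("need n_high + n_low >= 1 with both non-negative")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1 (fold change)")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class PlateSimConfig:
    """Generative parameters for a simulated dose-response viability plate.

    Doses are in µM; the default ladder is eight log-spaced points spanning
    0.003–100 µM, plus a vehicle well at dose 0 used only for normalization.
    ``ic50_high`` applies to MYC-high samples, ``ic50_low`` to MYC-low.
    Viability is in percent of vehicle.  ``noise_sd`` is the Gaussian noise
    level: with ``noise_model="additive"`` it is an SD in percentage points
    applied uniformly; with ``"proportional"`` it is a coefficient of
    variation in percent (readout noise scales with the signal, as for
    fluorescence-based viability reagents).
    """

    doses: tuple[float, ...] = DEFAULT_DOSES_UM
    replicates: int = 3
    ic50_high: float = 0.1
    ic50_low: float = 10.0
    hill: float = 1.0
    floor: float = 20.0
    noise_sd: float = 5.0
    noise_model: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [d for d in self.doses if d > 0]
        if len(set(positive)) < 3:
            raise ValueError("doses must contain at least 3 distinct positive values")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 <= self.floor <= 100):
            raise ValueError("floor must lie in [0, 100]")
        if self.ic50_high <= 0 or self.ic50_low <= 0:
            raise ValueError("IC50 values must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("additive", "proportional"):
            raise ValueError("noise_model must be 'additive' or 'proportional'")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth labels plus the generative parameters that produced them."""

    labels: dict[str, str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.labels.items() if l not in (MYC_HIGH, MYC_LOW)}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"labels": self.labels, "params": self.params}, fh, sort_keys=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu**2."""
    if dispersion == 0:
        return rng.poisson(mean).astype(float)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(float)


def simulate_cohort(
    cfg: CohortSimConfig,
    sig: SignatureDefinition = DEFAULT_SIGNATURE,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a labelled cohort of signature + housekeeping gene counts.

    Column names encode sample and replicate (``P01_r1``); all replicates of
    a sample share a ``replicate_group`` in the metadata.  Identical
    (cfg, sig) pairs produce bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[0])
    n = cfg.n_high + cfg.n_low
    labels = [MYC_HIGH] * cfg.n_high + [MYC_LOW] * cfg.n_low
    patients = [f"P{i + 1:02d}" for i in range(n)]
    genes = list(sig.all_genes)
    fold = np.ones((len(genes), n))
    is_high = np.array([l == MYC_HIGH for l in labels])
    for i, g in enumerate(genes):
        if g in sig.up_genes:
            fold[i, is_high] = cfg.effect_size
        elif g in sig.down_genes:
            fold[i, is_high] = 1.0 / cfg.effect_size
    means = cfg.baseline_mean * fold

    columns, col_groups = [], []
    draws = []
    for r in range(cfg.n_replicates):
        draws.append(_nb_draw(rng, means, cfg.dispersion))
    for j, p in enumerate(patients):
        for r in range(cfg.n_replicates):
            columns.append(f"{p}_r{r + 1}" if cfg.n_replicates > 1 else p)
            col_groups.append(p)
    data = np.empty((len(genes), n * cfg.n_replicates))
    k = 0
    for j in range(n):
        for r in range(cfg.n_replicates):
            data[:, k] = draws[r][:, j]
            k += 1
    meta = pd.DataFrame(
        {"replicate_group": col_groups},
        index=pd.Index(columns, name="sample"),
    )
    matrix = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=columns), meta)
    truth = SyntheticTruth(
        labels=dict(zip(patients, labels)),
        params={
            "n_high": cfg.n_high,
            "n_low": cfg.n_low,
            "effect_size": cfg.effect_size,
            "baseline_mean": cfg.baseline_mean,
            "dispersion": cfg.dispersion,
            "n_replicates": cfg.n_replicates,
            "seed": cfg.seed,
        },
    )
    return matrix, truth


def simulate_plate(
    cfg: PlateSimConfig,
    truth: SyntheticTruth,
    drug: str = "BETi",
) -> pd.DataFrame:
    """Simulate a viability table for every labelled sample against one drug.

    Returns a long-format DataFrame with columns sample, drug, dose_uM,
    replicate, viability_pct.  Mean viability follows
    ``floor + (100 - floor) / (1 + (dose / ic50)**hill)`` with the label's
    IC50; vehicle wells (dose 0) have mean 100.  Readings are truncated at 0.
    """
    if not truth.labels:
        raise ValueError("truth carries no labelled samples")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    rows = []
    doses = list(cfg.doses)
    if 0.0 not in doses:
        doses = [0.0] + doses
    for sample, label in truth.labels.items():
        ic50 = cfg.ic50_high if label == MYC_HIGH else cfg.ic50_low
        for dose in doses:
            if dose == 0:
                mean = 100.0
            else:
                mean = cfg.floor + (100.0 - cfg.floor) / (1.0 + (dose / ic50) ** cfg.hill)
            if cfg.noise_sd == 0:
                noise = np.zeros(cfg.replicates)
            elif cfg.noise_model == "proportional":
                noise = mean * rng.normal(0.0, cfg.noise_sd / 100.0, size=cfg.replicates)
            else:
                noise = rng.normal(0.0, cfg.noise_sd, size=cfg.replicates)
            for r in range(cfg.replicates):
                rows.append(
                    {
                        "sample": sample,
                        "drug": drug,
                        "dose_uM": float(dose),
                        "replicate": r + 1,
                        "viability_pct": max(0.0, mean + noise[r]),
                    }
                )
    return pd.DataFrame(rows)
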