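"""The 16-gene MYC-activity score and MYC-high / MYC-low classification.

The score works on a cohort of pancreatic-cancer expression profiles.  Ten
transcripts known to be induced by c-MYC (up genes) and six known to be
repressed (down genes) are first put on a common cohort-relative scale: each
signature gene's values are rescaled so the gene's sum across all samples in
the cohort equals 100.  For every sample, every up/down gene pair then yields
a ratio (normalized up value divided by normalized down value) — 60 ratios
for the default signature — and the sample's score is the median of those
ratios.  A score above 1 means the MYC-induced arm dominates the
MYC-repressed arm relative to the cohort: the sample is called MYC-high;
otherwise MYC-low.

The score is cohort-relative by construction.  To place a new sample on an
existing cohort's scale, pass that cohort's per-gene sums as
``reference_sums`` to :func:`score_cohort`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix, ExpressionValidationError

__all__ = [
    "SignatureDefinition",
    "DEFAULT_SIGNATURE",
    "MycScoreResult",
    "MYC_HIGH",
    "MYC_LOW",
    "cohort_normalize",
    "score_cohort",
    "classify",
    "score_table",
]

MYC_HIGH = "MYC-high"
MYC_LOW = "MYC-low"


@dataclass(frozen=True)
class SignatureDefinition:
    """Ordered up-regulated, down-regulated and housekeeping gene lists.

    The default is the published 16-gene MYC signature (10 up, 6 down) with
    its five reference housekeeping genes; all three lists are configurable
    but must be non-empty and pairwise disjoint.
    """

    up_genes: tuple[str, ...] = (
        "CAD", "CCT4", "CDC20", "KPNA2", "MAD2L1",
        "MCM2", "PLK1", "RFC4", "RUVBL2", "SRM",
    )
    down_genes: tuple[str, ...] = (
        "BCL2L15", "CTSE", "ERN2", "RAB25", "TXNIP", "VSIG2",
    )
    housekeeping_genes: tuple[str, ...] = ("SDHA", "CLTC", "TBP", "GUSB", "RPL19")

    def __post_init__(self) -> None:
        for name, genes in (
            ("up_genes", self.up_genes),
            ("down_genes", self.down_genes),
            ("housekeeping_genes", self.housekeeping_genes),
        ):
            if not genes:
                raise ValueError(f"{name} must be non-empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"{name} contains duplicates")
        up, down, hk = map(set, (self.up_genes, self.down_genes, self.housekeeping_genes))
        overlap = (up & down) | (up & hk) | (down & hk)
        if overlap:
            raise ValueError(f"gene lists must be disjoint; shared: {sorted(overlap)}")

    @property
    def signature_genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes + self.housekeeping_genes

    @property
    def n_ratios(self) -> int:
        return len(self.up_genes) * len(self.down_genes)

    @classmethod
    def from_yaml(cls, path: str) -> "SignatureDefinition":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            up_genes=tuple(cfg["up_genes"]),
            down_genes=tuple(cfg["down_genes"]),
            housekeeping_genes=tuple(cfg.get("housekeeping_genes", cls.housekeeping_genes)),
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "up_genes": list(self.up_genes),
                    "down_genes": list(self.down_genes),
                    "housekeeping_genes": list(self.housekeeping_genes),
                },
                fh,
                sort_keys=False,
            )


DEFAULT_SIGNATURE = SignatureDefinition()


@dataclass(frozen=True)
class MycScoreResult:
    """Per-sample outcome of signature scoring.

    ``ratios`` holds all up/down ratios in up-gene-major order (first up gene
    against every down gene, then the second up gene, ...), ``score`` is
    their median and ``label`` the MYC-high / MYC-low call.
    """

    sample: str
    ratios: tuple[float, ...]
    score: float
    label: str

    def __post_init__(self) -> None:
        if not np.isclose(self.score, float(np.median(self.ratios)), rtol=0, atol=1e-12):
            raise ValueError("score must equal the median of the ratios")


def cohort_normalize(
    m: ExpressionMatrix,
    sig: SignatureDefinition = DEFAULT_SIGNATURE,
    reference_sums: pd.Series | None = None,
) -> ExpressionMatrix:
    """Rescale every signature gene so its across-sample sum equals 100.

    The output is restricted to the signature genes (up then down, in
    signature order).  When ``reference_sums`` is given (per-gene sums of a
    previously scored cohort) the rescaling divisor is taken from it instead
    of from ``m`` — this places new samples on the stored cohort's scale.
    """
    genes = list(sig.signature_genes)
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        raise ExpressionValidationError(f"signature genes absent: {missing}")
    sub = m.data.loc[genes].astype(float)
    if reference_sums is not None:
        missing_ref = [g for g in genes if g not in reference_sums.index]
        if missing_ref:
            raise ExpressionValidationError(
                f"reference sums missing genes: {missing_ref}"
            )
        sums = reference_sums.loc[genes].astype(float)
    else:
        sums = sub.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ExpressionValidationError(
            f"non-positive across-sample sum for gene(s): {list(zero.index)}"
        )
    scaled = sub.div(sums, axis=0) * 100.0
    return ExpressionMatrix(scaled, m.sample_meta)


def classify(score: float, threshold: float = 1.0) -> str:
    """MYC-high when the score exceeds the threshold, MYC-low otherwise.

    A score exactly at the threshold is called MYC-low (the conservative
    side for treatment selection) and a boundary warning is emitted.
    """
    if not score > 0:
        raise ValueError(f"score must be positive, got {score}")
    if score == threshold:
        warnings.warn(
            f"score exactly at threshold {threshold}; assigning {MYC_LOW}",
            UserWarning,
            stacklevel=2,
        )
        return MYC_LOW
    return MYC_HIGH if score > threshold else MYC_LOW


def score_cohort(
    m: ExpressionMatrix,
    sig: SignatureDefinition = DEFAULT_SIGNATURE,
    threshold: float = 1.0,
    reference_sums: pd.Series | None = None,
) -> list[MycScoreResult]:
    """Score every sample of a cohort and assign MYC-high / MYC-low labels.

    Applies :func:`cohort_normalize`, forms all up/down ratios per sample in
    up-gene-major order, takes their median (even counts: mean of the two
    central order statistics) and compares it to ``threshold``.  Results are
    returned in the matrix's sample order.
    """
    norm = cohort_normalize(m, sig, reference_sums=reference_sums)
    up = norm.data.loc[list(sig.up_genes)].to_numpy()        # (n_up, n_samples)
    down = norm.data.loc[list(sig.down_genes)].to_numpy()    # (n_down, n_samples)
    if (down <= 0).any():
        i, j = np.argwhere(down <= 0)[0]
        raise ExpressionValidationError(
            f"non-positive normalized value for down gene {sig.down_genes[i]!r} "
            f"in sample {norm.samples[j]!r}; ratios undefined"
        )
    # ratios[s] laid out up-major: up_1/down_1, up_1/down_2, ..., up_2/down_1, ...
    ratios = (up[:, np.newaxis, :] / down[np.newaxis, :, :]).reshape(
        sig.n_ratios, -1
    )
    scores = np.median(ratios, axis=0)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # boundary warned per cohort below
        for j, sample in enumerate(norm.samples):
            results.append(
                MycScoreResult(
                    sample=sample,
                    ratios=tuple(ratios[:, j]),
                    score=float(scores[j]),
                    label=classify(float(scores[j]), threshold),
                )
            )
    at_boundary = [r.sample for r in results if r.score == threshold]
    if at_boundary:
        warnings.warn(
            f"samples scored exactly at threshold {threshold} (assigned {MYC_LOW}): "
            f"{at_boundary}",
            UserWarning,
            stacklevel=2,
        )
    return results


def score_table(results: list[MycScoreResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate scores (descending) plus subgroup counts and percentages.

    Returns ``(table, summary)``: the table has columns sample/score/label/
    n_ratios ordered by descending score; the summary has one row per label
    with count and percentage (1-decimal rounding).
    """
    if not results:
        raise ValueError("score_table requires at least one result")
    table = pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "score": [r.score for r in results],
            "label": [r.label for r in results],
            "n_ratios": [len(r.ratios) for r in results],
        }
    ).sort_values("score", ascending=False, kind="mergesort", ignore_index=True)
    counts = table["label"].value_counts()
    summary = pd.DataFrame(
        {
            "label": [MYC_HIGH, MYC_LOW],
            "n": [int(counts.get(MYC_HIGH, 0)), int(counts.get(MYC_LOW, 0))],
        }
    )
    summary["percent"] = (100.0 * summary["n"] / len(results)).round(1)
    return table, summary
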