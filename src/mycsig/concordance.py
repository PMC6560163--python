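"""PDTX-organoid concordance on the 16-gene signature.

A :class:`PairedCohort` holds expression for patients measured in two model
systems — a patient-derived xenograft (PDTX) and the organoid derived from
the same tumor.  Agreement between models is quantified by the Pearson
correlation of subgroup-averaged log2 expression profiles, a PCA embedding
of the samples, and hierarchical-clustering orderings (average linkage on
1 - Pearson distance) for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, log2_transform
from .signature import MYC_HIGH, MYC_LOW

__all__ = [
    "PairedCohort",
    "subgroup_mean_profiles",
    "pearson",
    "pca_embed",
    "hclust_order",
]


@dataclass(frozen=True)
class PairedCohort:
    """Signature expression for patients profiled as both PDTX and organoid.

    ``pairing`` maps each patient to its (PDTX sample id, organoid sample
    id); ``labels`` maps each patient to MYC-high / MYC-low.
    """

    expression: ExpressionMatrix
    pairing: dict[str, tuple[str, str]]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        samples = set(self.expression.samples)
        seen: set[str] = set()
        for patient, (pdtx, org) in self.pairing.items():
            for sid in (pdtx, org):
                if sid not in samples:
                    raise ValueError(f"paired sample {sid!r} absent from matrix")
                if sid in seen:
                    raise ValueError(f"sample {sid!r} paired to more than one patient")
                seen.add(sid)
            if patient not in self.labels:
                raise ValueError(f"patient {patient!r} has no label")
        bad = {p: l for p, l in self.labels.items() if l not in (MYC_HIGH, MYC_LOW)}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def patients_with_label(self, label: str) -> list[str]:
        return [p for p in self.pairing if self.labels[p] == label]


def subgroup_mean_profiles(
    pc: PairedCohort,
    label: str,
    pseudocount: float = 1.0,
) -> tuple[pd.Series, pd.Series]:
    """Per-gene mean log2 expression of a subgroup, separately per model.

    Returns ``(pdtx_mean, organoid_mean)``: each is one value per gene,
    averaged on the log2 scale across the subgroup's patients.
    """
    patients = pc.patients_with_label(label)
    if not patients:
        raise ValueError(f"no patients labelled {label!r}")
    logm = (
        pc.expression
        if pc.expression.log_scale
        else log2_transform(pc.expression, pseudocount)
    )
    pdtx_cols = [pc.pairing[p][0] for p in patients]
    org_cols = [pc.pairing[p][1] for p in patients]
    return (
        logm.data[pdtx_cols].mean(axis=1),
        logm.data[org_cols].mean(axis=1),
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError(f"need >= 3 points, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pca_embed(
    m: ExpressionMatrix,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the principal components of gene space.

    The matrix is centered per gene (across samples) and decomposed by SVD.
    Returns sample coordinates (samples x components) and the explained-
    variance fractions.  Component signs follow the convention that each
    component's largest-magnitude gene loading is positive.
    """
    n_samples = len(m.samples)
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_comp = min(len(m.genes), n_samples - 1)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    X = m.values.T                      # samples x genes
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u[:, :n_components] * s[:n_components]
    var = s ** 2 / (n_samples - 1)
    frac = (var / var.sum())[:n_components] if var.sum() > 0 else np.zeros(n_components)
    out = pd.DataFrame(
        coords,
        index=pd.Index(m.samples, name="sample"),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return out, frac


def correlation_distance_matrix(m: ExpressionMatrix, axis: str) -> np.ndarray:
    """Pairwise 1 - Pearson distances between rows (genes) or columns (samples)."""
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    X = m.values if axis == "genes" else m.values.T
    ids = m.genes if axis == "genes" else m.samples
    sds = X.std(axis=1)
    if (sds == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant {axis[:-1]}(s) make correlation undefined: {bad}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def hclust_order(
    m: ExpressionMatrix,
    axis: str = "samples",
    method: str = "average",
) -> tuple[list[str], np.ndarray]:
    """Hierarchical-clustering leaf order on 1 - Pearson distance.

    Returns the ordered identifiers along the chosen axis and the SciPy
    linkage matrix.  Average linkage by default (the common heatmap
    convention); ties resolve to the lower original index first, so the
    ordering is deterministic.
    """
    ids = m.genes if axis == "genes" else m.samples
    if len(ids) < 2:
        raise ValueError(f"need >= 2 items on axis {axis!r}")
    dist = correlation_distance_matrix(m, axis)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    leaves = hierarchy.leaves_list(Z)
    return [ids[i] for i in leaves], Z
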