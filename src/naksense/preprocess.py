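"""RMA-style preprocessing and PCA sample mapping.

The chain mirrors the three RMA stages — background adjustment, quantile
normalization, and median-polish summarization of probe-level values — with
one deliberate simplification: the normal+exponential convolution
background model is replaced by an offset subtraction with a positivity
floor. All downstream analyses are threshold- and set-based, which this
simplification does not perturb; the exact convolution model would be a
drop-in extension of :func:`background_adjust`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ProbeMap, Scale

__all__ = [
    "background_adjust",
    "quantile_normalize",
    "log2_transform",
    "linear_transform",
    "median_polish_summarize",
    "median_polish",
    "pca",
    "PCAResult",
]


def background_adjust(
    m: ExpressionMatrix, offset: float, floor: float = 1.0
) -> ExpressionMatrix:
    """Subtract a constant background, clamping at a positive floor.

    values' = max(values − offset, floor). Monotone and positivity
    preserving; offset 0 is the identity (values are already ≥ floor on any
    matrix that came off a scanner).
    """
    if m.scale is not Scale.LINEAR:
        raise ValueError("background adjustment expects a linear-scale matrix")
    if offset < 0:
        raise ValueError("background offset must be non-negative")
    if floor <= 0:
        raise ValueError("floor must be positive")
    adjusted = np.maximum(m.values.to_numpy() - offset, floor)
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=m.values.index, columns=m.values.columns),
        Scale.LINEAR,
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the mean-of-order-statistics reference distribution.

    Each column is replaced rank-for-rank by the across-column mean of order
    statistics, so all columns share one empirical distribution while
    within-column rank order is preserved. Ties are placed by sorted
    position with input order as tie-breaker (stable argsort).
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = m.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = reference
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.scale,
    )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log₂; flips the scale flag."""
    if m.scale is not Scale.LINEAR:
        raise ValueError("matrix is already on the log2 scale")
    x = m.values.to_numpy()
    if not np.all(x > 0):
        raise ValueError("log2 transform requires strictly positive values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(x), index=m.values.index, columns=m.values.columns),
        Scale.LOG2,
    )


def linear_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform`."""
    if m.scale is not Scale.LOG2:
        raise ValueError("matrix is already on the linear scale")
    return ExpressionMatrix(
        pd.DataFrame(
            np.exp2(m.values.to_numpy()),
            index=m.values.index,
            columns=m.values.columns,
        ),
        Scale.LINEAR,
    )


def median_polish(
    block: np.ndarray, max_iter: int = 10, tol: float = 0.01
):
    """Tukey median polish of one probes × samples block.

    Fits value ≈ overall + row(probe) effect + column(sample) effect by
    alternating median sweeps, rows first, stopping when the total absolute
    residual changes by less than ``tol`` or after ``max_iter`` iterations.
    Returns (overall, row_effects, col_effects, residuals).
    """
    residual = np.asarray(block, dtype=float).copy()
    overall = 0.0
    row_eff = np.zeros(residual.shape[0])
    col_eff = np.zeros(residual.shape[1])
    last_total = np.abs(residual).sum()
    for _ in range(max_iter):
        row_med = np.median(residual, axis=1)
        row_eff += row_med
        residual -= row_med[:, None]
        shift = np.median(row_eff)
        row_eff -= shift
        overall += shift

        col_med = np.median(residual, axis=0)
        col_eff += col_med
        residual -= col_med[None, :]
        shift = np.median(col_eff)
        col_eff -= shift
        overall += shift

        total = np.abs(residual).sum()
        if abs(last_total - total) < tol:
            break
        last_total = total
    return overall, row_eff, col_eff, residual


def median_polish_summarize(
    m: ExpressionMatrix, probe_map: ProbeMap, max_iter: int = 10,
    tol: float = 0.01,
) -> ExpressionMatrix:
    """Collapse a probe-level log₂ matrix to gene level via median polish.

    Gene expression per sample = overall + sample effect; probe affinity
    differences are absorbed by the probe (row) effects, so shifting one
    probe by a constant leaves the summary unchanged.
    """
    if m.scale is not Scale.LOG2:
        raise ValueError("median polish expects a log2-scale matrix")
    unmapped = [p for p in m.gene_ids if p not in probe_map.mapping]
    if unmapped:
        raise ValueError(f"unmapped probes: {unmapped[:5]}")
    gene_of = probe_map.mapping
    groups: dict[str, list[str]] = {}
    for probe in m.gene_ids:
        groups.setdefault(gene_of[probe], []).append(probe)
    out = {}
    for gene, probes in groups.items():
        block = m.values.loc[probes].to_numpy()
        overall, _, col_eff, _ = median_polish(block, max_iter, tol)
        out[gene] = overall + col_eff
    summary = pd.DataFrame.from_dict(out, orient="index",
                                     columns=m.values.columns)
    return ExpressionMatrix(summary.sort_index(), Scale.LOG2)


@dataclasses.dataclass
class PCAResult:
    """Sample scores and variance fractions of a PCA of the sample profiles."""

    scores: pd.DataFrame            # samples × components
    variance_fraction: np.ndarray   # per retained component
    total_top3: float               # summed fraction of the top 3 components

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if np.any(vf < -1e-12) or np.any(vf > 1 + 1e-12):
            raise ValueError("variance fractions must lie in [0, 1]")
        if np.any(np.diff(vf) > 1e-9):
            raise ValueError("variance fractions must be non-increasing")
        self.variance_fraction = vf


def pca(m: ExpressionMatrix, k: int = 3) -> PCAResult:
    """Principal component analysis of samples in gene space.

    Genes are centered across samples (not scaled — the data are already on
    the log₂ scale); the SVD of the centered sample × gene matrix gives the
    per-sample scores and the variance fraction of each component.
    """
    if m.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= k <= m.n_samples - 1:
        raise ValueError("k must lie in [1, n_samples - 1]")
    x = m.values.to_numpy(dtype=float)
    centered = (x - x.mean(axis=1, keepdims=True)).T  # samples × genes
    total_var = (centered ** 2).sum()
    if total_var <= 0:
        raise ValueError("constant matrix: zero total variance")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    fractions = s ** 2 / (s ** 2).sum()
    scores = pd.DataFrame(
        (u * s)[:, :k],
        index=m.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(
        scores=scores,
        variance_fraction=fractions[:k],
        total_top3=float(fractions[:3].sum()),
    )
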