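"""Per-gene treatment-vs-control contrasts, signed folds, and FDR control.

Each contrast compares one treatment (ouabain or K⁺-free) to control within
a (cell type, calcium condition) design cell: a two-sample t-test per gene
on the log₂ values (Welch by default; with n = 4 per group it is the
conservative equivalent of the two-group ANOVA, and a pooled-variance
option is available). p-values are adjusted within each contrast by the
Benjamini–Hochberg step-up.

Fold convention: signed folds as printed in array studies — 2^log2fc for
up-regulation, −2^(−log2fc) for down-regulation, so |fold| ≥ 1 and
fold = 1 means no change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    Calcium,
    Config,
    ExpressionMatrix,
    SampleDesign,
    Scale,
    Treatment,
)

__all__ = [
    "fold_from_log2fc",
    "log2fc_from_fold",
    "contrast_test",
    "bh_adjust",
    "de_table",
]

#: relative slack when comparing |fold| against the threshold, so that an
#: effect of exactly log2(1.2) survives the 2**log2(…) round trip
FOLD_EPS = 1e-9


def fold_from_log2fc(log2fc):
    """Signed fold from a log₂ fold change (vectorized).

    0 → 1.0; 1 → 2.0; −1 → −2.0. The sign of the fold matches the sign of
    the log₂ change and |fold| ≥ 1 always.
    """
    x = np.asarray(log2fc, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log2fc must be finite")
    out = np.where(x >= 0, np.exp2(x), -np.exp2(-x))
    return float(out) if np.isscalar(log2fc) or out.ndim == 0 else out


def log2fc_from_fold(fold):
    """Inverse of :func:`fold_from_log2fc`."""
    f = np.asarray(fold, dtype=float)
    if np.any(np.abs(f) < 1 - FOLD_EPS):
        raise ValueError("signed folds must have |fold| >= 1")
    out = np.where(f >= 0, np.log2(np.maximum(np.abs(f), 1.0)),
                   -np.log2(np.maximum(np.abs(f), 1.0)))
    return float(out) if np.isscalar(fold) or out.ndim == 0 else out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q(i) = min over j ≥ i of m·p(j)/j on the sorted p-values, capped at 1,
    mapped back to the input order. Invariant under input permutation.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _welch_rows(treated: np.ndarray, control: np.ndarray, equal_var: bool):
    """Per-gene two-sample t-test with explicit zero-variance handling.

    Returns (log2fc, p, degenerate). Zero variance in both groups:
    p = 1 when the means agree, p = 0 otherwise (flagged degenerate) — this
    keeps zero-noise simulations free of NaNs without inventing evidence.
    """
    mean_t = treated.mean(axis=1)
    mean_c = control.mean(axis=1)
    log2fc = mean_t - mean_c
    var_t = treated.var(axis=1, ddof=1)
    var_c = control.var(axis=1, ddof=1)
    degenerate = (var_t <= 0) & (var_c <= 0)

    p = np.ones(treated.shape[0])
    ok = ~degenerate
    if ok.any():
        res = stats.ttest_ind(
            treated[ok], control[ok], axis=1, equal_var=equal_var
        )
        p[ok] = res.pvalue
    equal_means = np.isclose(mean_t, mean_c, rtol=0.0, atol=0.0)
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return log2fc, p, degenerate


def contrast_test(
    m: ExpressionMatrix,
    design: SampleDesign,
    cell_type: str,
    calcium,
    treatment,
    equal_var: bool = False,
) -> pd.DataFrame:
    """One treatment-vs-control contrast; returns per-gene rows.

    Columns: gene, cell_type, calcium, treatment, log2fc, fold, p,
    degenerate. log2fc = mean(treated) − mean(control) on the log₂ scale;
    p two-sided.
    """
    if m.scale is not Scale.LOG2:
        raise ValueError("contrasts are computed on the log2 scale")
    design.check_matches(m)
    treatment = Treatment(str(treatment).lower())
    if treatment is Treatment.CONTROL:
        raise ValueError("treatment contrast cannot be control vs control")
    calcium = Calcium(str(calcium).lower())
    treated_ids = design.samples_for(cell_type, calcium, treatment)
    control_ids = design.samples_for(cell_type, calcium, Treatment.CONTROL)
    for label, ids in (("treated", treated_ids), ("control", control_ids)):
        if len(ids) < 2:
            raise ValueError(
                f"design cell ({cell_type}, {calcium.value}, "
                f"{treatment.value if label == 'treated' else 'control'}) has "
                f"{len(ids)} replicates; need at least 2"
            )
    treated = m.values[treated_ids].to_numpy(dtype=float)
    control = m.values[control_ids].to_numpy(dtype=float)
    log2fc, p, degenerate = _welch_rows(treated, control, equal_var)
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "cell_type": str(cell_type).lower(),
            "calcium": calcium.value,
            "treatment": treatment.value,
            "log2fc": log2fc,
            "fold": fold_from_log2fc(log2fc),
            "p": p,
            "degenerate": degenerate,
        }
    )


def de_table(
    m: ExpressionMatrix,
    design: SampleDesign,
    config: Config | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """All treatment-vs-control contrasts present in the design.

    Adds BH q-values (adjusted within each contrast) and a direction label
    using the configured fold threshold and significance rule: ``up`` /
    ``down`` for genes that would be called differential, ``none``
    otherwise.
    """
    config = config or Config()
    pieces = []
    cells = design.table[["cell_type", "calcium", "treatment"]].drop_duplicates()
    for cell, ca, tr in cells.itertuples(index=False):
        if tr == Treatment.CONTROL.value:
            continue
        rows = contrast_test(m, design, cell, ca, tr, equal_var=equal_var)
        rows["q"] = bh_adjust(rows["p"].to_numpy())
        pieces.append(rows)
    if not pieces:
        raise ValueError("design contains no treatment groups")
    de = pd.concat(pieces, ignore_index=True)
    sig = de["q"] if config.use_adjusted_p else de["p"]
    passing = (np.abs(de["fold"]) * (1 + FOLD_EPS) >= config.threshold) & (
        sig < config.alpha
    )
    de["direction"] = np.where(
        passing, np.where(de["log2fc"] > 0, "up", "down"), "none"
    )
    return de
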