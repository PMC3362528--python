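"""The dual-stimulus classification calculus.

A gene is *Na⁺ᵢ/K⁺ᵢ-sensitive* in a (cell type, calcium condition) context
when it is called differential — |fold| ≥ 1.2 and significant — under BOTH
pump inhibitors (ouabain and K⁺-free medium) with the same direction. From
the per-context sensitive sets the module derives:

* the *ubiquitous* set: genes sensitive with a consistent direction in
  every cell type;
* the three-way *calcium partition* of sensitive genes into
  Ca²⁺-containing-only / both-conditions / Ca²⁺-depleted-only;
* the cross-treatment *fold correlation* (Pearson on signed log₂ folds);
* *functional-category summaries* over the five category codes
  (t, d, f, i, o) and *top tables* of the most strongly regulated genes.

All operations run identically on DE tables produced by the pipeline and
on the packaged fixture transcriptions of the printed tables.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Config, load_fixture
from .diffexpr import FOLD_EPS, log2fc_from_fold

__all__ = [
    "SensitiveSet",
    "CaPartition",
    "CorrelationReport",
    "CategorySummary",
    "call_differential",
    "concordant_sensitive",
    "ubiquitous_set",
    "ca_partition",
    "fold_correlation",
    "category_summary",
    "top_table",
    "sensitive_sets_from_fixture",
    "classify_experiment",
    "CATEGORY_CODES",
    "CATEGORY_LABELS",
]

CATEGORY_CODES = ("t", "d", "f", "i", "o")
CATEGORY_LABELS = {
    "t": "transcription/translation, RNA processing and degradation",
    "d": "cell adhesion, migration, proliferation, differentiation and death",
    "f": "protein folding and ubiquitination",
    "i": "inflammation and immune response",
    "o": "other or unknown function",
}


@dataclasses.dataclass
class SensitiveSet:
    """Genes responding concordantly to both pump inhibitors in one context.

    ``table`` has one row per member gene with columns gene, direction,
    ouabain_fold, kfree_fold. ``discordant`` counts genes that were called
    under both treatments but with opposite directions (excluded from the
    set, reported rather than silently dropped).
    """

    cell_type: str
    calcium: str
    table: pd.DataFrame
    discordant: int = 0

    @property
    def genes(self) -> set:
        return set(self.table["gene"])

    def direction_of(self) -> dict:
        return dict(zip(self.table["gene"], self.table["direction"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclasses.dataclass
class CaPartition:
    """Three-way split of sensitive genes by calcium condition.

    The labels partition the union of the two conditions' sensitive sets;
    a direction flip between conditions sets the gene's concordance flag to
    False but does not reassign it.
    """

    scope: str
    ca_containing_only: set
    both_conditions: set
    ca_depleted_only: set
    direction_concordant: dict

    def label_of(self) -> dict:
        out = {}
        for g in self.ca_containing_only:
            out[g] = "ca_containing_only"
        for g in self.both_conditions:
            out[g] = "both_conditions"
        for g in self.ca_depleted_only:
            out[g] = "ca_depleted_only"
        return out


@dataclasses.dataclass
class CorrelationReport:
    """Pearson correlation of ouabain vs K⁺-free log₂ folds."""

    cell_type: str
    calcium: str
    n_genes: int
    r: float
    r_squared: float
    p: float

    def __post_init__(self) -> None:
        if not math.isclose(self.r_squared, self.r ** 2, abs_tol=1e-9):
            raise ValueError("R² must equal r²")

    @property
    def positive(self) -> bool:
        return self.r > 0


@dataclasses.dataclass
class CategorySummary:
    """Counts and integer percentages per functional-category code."""

    counts: dict
    percentages: dict
    empty: bool = False


def call_differential(
    de_rows: pd.DataFrame,
    threshold: float = 1.2,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Differential calls from one contrast's DE rows.

    A gene is called when |fold| ≥ threshold (inclusive, with a 1e-9
    relative slack for floating-point round trips) AND its significance
    value (q when ``use_adjusted``, else raw p) is below alpha. Returns the
    passing rows with a ``direction`` column.
    """
    if threshold < 1:
        raise ValueError("fold threshold must be >= 1")
    sig_col = "q" if use_adjusted else "p"
    if sig_col not in de_rows.columns:
        raise ValueError(f"DE rows lack a {sig_col!r} column")
    fold = de_rows["fold"].to_numpy(dtype=float)
    sig = de_rows[sig_col].to_numpy(dtype=float)
    passing = (np.abs(fold) * (1 + FOLD_EPS) >= threshold) & (sig < alpha)
    calls = de_rows.loc[passing].copy()
    calls["direction"] = np.where(calls["fold"] > 0, "up", "down")
    return calls.reset_index(drop=True)


def _context_of(calls: pd.DataFrame):
    cells = calls["cell_type"].unique() if "cell_type" in calls else ["?"]
    cas = calls["calcium"].unique() if "calcium" in calls else ["?"]
    if len(cells) > 1 or len(cas) > 1:
        raise ValueError(
            "differential calls mix contexts: "
            f"cell types {list(cells)}, calcium {list(cas)}"
        )
    return str(cells[0]), str(cas[0])


def concordant_sensitive(
    ouabain_calls: pd.DataFrame, kfree_calls: pd.DataFrame
) -> SensitiveSet:
    """Intersect the two treatments' calls, requiring a shared direction.

    Symmetric in its arguments. Genes called under both treatments with
    opposite directions are excluded and counted in ``discordant``.
    """
    cell_o, ca_o = _context_of(ouabain_calls)
    cell_k, ca_k = _context_of(kfree_calls)
    if (cell_o, ca_o) != (cell_k, ca_k) and "?" not in (cell_o, ca_o):
        raise ValueError(
            f"calls come from different contexts: ({cell_o}, {ca_o}) vs "
            f"({cell_k}, {ca_k})"
        )
    o = ouabain_calls.set_index("gene")
    k = kfree_calls.set_index("gene")
    common = o.index.intersection(k.index)
    same = [g for g in common if o.loc[g, "direction"] == k.loc[g, "direction"]]
    table = pd.DataFrame(
        {
            "gene": same,
            "direction": [o.loc[g, "direction"] for g in same],
            "ouabain_fold": [float(o.loc[g, "fold"]) for g in same],
            "kfree_fold": [float(k.loc[g, "fold"]) for g in same],
        }
    ).sort_values("gene", ignore_index=True)
    return SensitiveSet(
        cell_type=cell_o,
        calcium=ca_o,
        table=table,
        discordant=len(common) - len(same),
    )


def ubiquitous_set(sets: list) -> pd.DataFrame:
    """Genes present in every cell type's sensitive set with one direction.

    Input sets must come from the same calcium condition and at least two
    cell types. Returns one row per ubiquitous gene with per-cell folds
    (columns ``<cell>_ouabain`` / ``<cell>_kfree``).
    """
    if len(sets) < 2:
        raise ValueError("ubiquity needs sensitive sets from >= 2 cell types")
    calciums = {s.calcium for s in sets}
    if len(calciums) > 1:
        raise ValueError(f"sets mix calcium conditions: {sorted(calciums)}")
    cells = [s.cell_type for s in sets]
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate cell types among input sets")
    shared = set.intersection(*(s.genes for s in sets))
    directions = [s.direction_of() for s in sets]
    rows = []
    for gene in sorted(shared):
        dirs = {d[gene] for d in directions}
        if len(dirs) != 1:
            continue  # sign-inconsistent across cell types
        row = {"gene": gene, "direction": dirs.pop()}
        for s in sets:
            sub = s.table.set_index("gene")
            row[f"{s.cell_type}_ouabain"] = float(sub.loc[gene, "ouabain_fold"])
            row[f"{s.cell_type}_kfree"] = float(sub.loc[gene, "kfree_fold"])
        rows.append(row)
    return pd.DataFrame(rows)


def ca_partition(plus_set: SensitiveSet, minus_set: SensitiveSet) -> CaPartition:
    """Partition the union of the two calcium conditions' sensitive sets."""
    if plus_set.calcium == minus_set.calcium:
        raise ValueError("need one set per calcium condition")
    if plus_set.cell_type != minus_set.cell_type:
        raise ValueError(
            f"scope mismatch: {plus_set.cell_type} vs {minus_set.cell_type}"
        )
    plus, minus = plus_set.genes, minus_set.genes
    both = plus & minus
    dir_plus, dir_minus = plus_set.direction_of(), minus_set.direction_of()
    concordant = {g: dir_plus[g] == dir_minus[g] for g in both}
    return CaPartition(
        scope=plus_set.cell_type,
        ca_containing_only=plus - minus,
        both_conditions=both,
        ca_depleted_only=minus - plus,
        direction_concordant=concordant,
    )


def fold_correlation(
    sset: SensitiveSet, use_log2: bool = True
) -> CorrelationReport:
    """Pearson correlation between the two treatments' fold responses.

    By default folds are mapped to signed log₂ space
    (sign(fold)·log₂|fold|), which linearizes the multiplicative response;
    ``use_log2=False`` correlates the raw signed folds instead.
    """
    if len(sset) < 3:
        raise ValueError("correlation needs at least 3 genes")
    x = sset.table["ouabain_fold"].to_numpy(dtype=float)
    y = sset.table["kfree_fold"].to_numpy(dtype=float)
    if use_log2:
        x = np.sign(x) * np.log2(np.abs(x))
        y = np.sign(y) * np.log2(np.abs(y))
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a fold vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationReport(
        cell_type=sset.cell_type,
        calcium=sset.calcium,
        n_genes=len(sset),
        r=float(r),
        r_squared=float(r) ** 2,
        p=float(p),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def category_summary(genes, annotation: dict) -> CategorySummary:
    """Counts and integer percentages per functional category.

    Unannotated genes fall into category ``o``. Percentages are rounded
    half-up to whole percent; an empty input is reported as all-zero with
    the ``empty`` flag set.
    """
    genes = list(genes)
    counts = {c: 0 for c in CATEGORY_CODES}
    for g in genes:
        code = annotation.get(g, "o")
        if code not in counts:
            code = "o"
        counts[code] += 1
    if not genes:
        return CategorySummary(counts=counts,
                               percentages={c: 0 for c in CATEGORY_CODES},
                               empty=True)
    percentages = {
        c: _round_half_up(100.0 * n / len(genes)) for c, n in counts.items()
    }
    return CategorySummary(counts=counts, percentages=percentages)


def top_table(rows: pd.DataFrame, min_abs_fold: float = 4.0) -> pd.DataFrame:
    """Strongly regulated genes, ranked by |fold| (K⁺-free, then ouabain).

    Keeps genes whose larger |fold| across the two treatments reaches
    ``min_abs_fold``; sorts by descending |kfree_fold| with |ouabain_fold|
    as tie-breaker.
    """
    needed = {"gene", "ouabain_fold", "kfree_fold"}
    if not needed <= set(rows.columns):
        raise ValueError(f"top_table needs columns {sorted(needed)}")
    kabs = rows["kfree_fold"].abs()
    oabs = rows["ouabain_fold"].abs()
    keep = np.maximum(kabs, oabs) >= min_abs_fold
    out = rows.loc[keep].copy()
    out["_k"] = out["kfree_fold"].abs()
    out["_o"] = out["ouabain_fold"].abs()
    out = out.sort_values(["_k", "_o"], ascending=False, ignore_index=True)
    return out.drop(columns=["_k", "_o"])


# ---------------------------------------------------------------------------
# Fixture adapters
# ---------------------------------------------------------------------------

def sensitive_sets_from_fixture(
    name: str = "table3", calcium: str = "plus"
) -> list:
    """Reinterpret the ubiquitous-gene fixture as three per-cell sensitive sets.

    Every fixture row carries the six printed folds, so each cell type's
    set is simply the fixture genes with that cell's (ouabain, kfree) fold
    pair and the printed direction.
    """
    fx = load_fixture(name)
    if name != "table3":
        raise ValueError("only the ubiquitous-gene table maps to sensitive sets")
    sets = []
    for cell in ("hela", "huvec", "rvsmc"):
        table = pd.DataFrame(
            {
                "gene": fx["gene"],
                "direction": fx["direction"],
                "ouabain_fold": fx[f"{cell}_ouabain"].astype(float),
                "kfree_fold": fx[f"{cell}_kfree"].astype(float),
            }
        )
        sets.append(SensitiveSet(cell_type=cell, calcium=calcium, table=table))
    return sets


def fixture_annotation(name: str = "table3") -> dict:
    """gene → functional-category code from a fixture's category column."""
    fx = load_fixture(name)
    if "category" not in fx.columns:
        raise ValueError(f"fixture {name!r} carries no category codes")
    return dict(zip(fx["gene"], fx["category"]))


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClassificationResult:
    """Everything the classification stage derives from one DE table."""

    sensitive: dict           # (cell_type, calcium) -> SensitiveSet
    ubiquitous: dict          # calcium -> DataFrame of ubiquitous genes
    partitions: dict          # cell_type -> CaPartition
    correlations: list        # CorrelationReport per context


def classify_experiment(
    de: pd.DataFrame, config: Config | None = None
) -> ClassificationResult:
    """Run calls → concordance → ubiquity → calcium partition → correlation."""
    config = config or Config()
    sensitive = {}
    contexts = de[["cell_type", "calcium"]].drop_duplicates()
    for cell, ca in contexts.itertuples(index=False):
        sub = de[(de["cell_type"] == cell) & (de["calcium"] == ca)]
        calls = {
            tr: call_differential(
                sub[sub["treatment"] == tr],
                threshold=config.threshold,
                alpha=config.alpha,
                use_adjusted=config.use_adjusted_p,
            )
            for tr in ("ouabain", "kfree")
        }
        if any(len(sub[sub["treatment"] == tr]) == 0 for tr in calls):
            continue  # context lacks one of the two stimuli
        sensitive[(cell, ca)] = concordant_sensitive(
            calls["ouabain"], calls["kfree"]
        )
    ubiquitous = {}
    for ca in {k[1] for k in sensitive}:
        sets = [s for (c, cca), s in sensitive.items() if cca == ca]
        if len(sets) >= 2:
            ubiquitous[ca] = ubiquitous_set(sets)
    partitions = {}
    for cell in {k[0] for k in sensitive}:
        if (cell, "plus") in sensitive and (cell, "minus") in sensitive:
            partitions[cell] = ca_partition(
                sensitive[(cell, "plus")], sensitive[(cell, "minus")]
            )
    correlations = []
    for sset in sensitive.values():
        if len(sset) >= 3:
            try:
                correlations.append(fold_correlation(sset))
            except ValueError:
                pass  # degenerate fold vectors carry no correlation
    return ClassificationResult(
        sensitive=sensitive,
        ubiquitous=ubiquitous,
        partitions=partitions,
        correlations=correlations,
    )
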