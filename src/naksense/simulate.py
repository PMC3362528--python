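"""Factorial expression simulator with planted effect classes.

Emulates the study design — 3 cell types × {control, ouabain, K⁺-free} ×
{Ca²⁺-containing, Ca²⁺-depleted} × 4 replicates — on the log₂ scale that an
RMA-processed matrix lives on. Each gene is assigned one effect class:

``null``
    no treatment effect anywhere.
``ubiquitous``
    same-sign effect in every cell type, both treatments, both calcium
    conditions.
``cell_specific``
    effect in exactly one cell type (both calcium conditions).
``ca_dependent``
    effect in every cell type but only in Ca²⁺-containing medium.
``ca_only``
    effect only in Ca²⁺-depleted medium.
``ca_independent``
    effect in every cell type under both calcium conditions; together with
    ``ubiquitous`` it maps to the "both conditions" label of the calcium
    partition.

The ouabain effect of a non-null gene is a signed log₂ shift whose
magnitude is floored at log2(1.2) so every planted gene clears the study's
fold filter by construction; the K⁺-free effect is ``kfree_gain`` times the
ouabain effect plus a log₂ jitter, reflecting the observation that K⁺-free
medium drives larger Na⁺ᵢ gain / K⁺ᵢ loss than ouabain in human cells.
Residual noise is Gaussian on the log₂ scale with no mean–variance trend —
a deliberate simplification relative to real array data.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Calcium, ExpressionMatrix, ProbeMap, SampleDesign, Scale, Treatment

__all__ = [
    "GeneratorConfig",
    "TruthTable",
    "generate_dataset",
    "summarize_truth",
    "allocate_classes",
    "CLASS_NAMES",
]

CLASS_NAMES = (
    "null",
    "ubiquitous",
    "cell_specific",
    "ca_dependent",
    "ca_only",
    "ca_independent",
)

#: log2 of the study's 1.2-fold filter; planted effect magnitudes never fall
#: below this.
MIN_EFFECT = float(np.log2(1.2))

_DEFAULT_FRACTIONS = {
    "null": 0.70,
    "ubiquitous": 0.05,
    "cell_specific": 0.10,
    "ca_dependent": 0.05,
    "ca_only": 0.05,
    "ca_independent": 0.05,
}


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic factorial experiment.

    All effect parameters are in log₂ units. Defaults: 4 replicates per
    design cell as in the study; effect magnitudes ~ |N(2.0, 0.6)| floored
    at log2(1.2); K⁺-free gain 1.5 with jitter s.d. 0.3; residual s.d. 0.25.
    """

    n_genes: int = 2000
    n_replicates: int = 4
    cell_types: Sequence[str] = ("hela", "huvec", "rvsmc")
    class_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    effect_mean: float = 2.0
    effect_sd: float = 0.6
    kfree_gain: float = 1.5
    treatment_noise_sd: float = 0.3
    noise_sd: float = 0.25
    prob_up: float = 0.75
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    probes_per_gene: int = 1
    probe_affinity_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        for name in ("effect_sd", "treatment_noise_sd", "noise_sd",
                     "probe_affinity_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kfree_gain <= 0:
            raise ValueError("kfree_gain must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per design cell")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")


@dataclasses.dataclass
class TruthTable:
    """Planted ground truth: per-gene class and per-context log₂ effects.

    ``classes`` maps gene → class label; ``effects`` is a long DataFrame
    with columns (gene, cell_type, calcium, treatment, effect, direction).
    Control contexts carry no rows (their effect is identically zero).
    """

    classes: pd.Series
    effects: pd.DataFrame

    def effect_lookup(self) -> dict:
        """(gene, cell_type, calcium, treatment) → planted log₂ effect."""
        return {
            (r.gene, r.cell_type, r.calcium, r.treatment): r.effect
            for r in self.effects.itertuples()
        }

    def planted_set(self, cell_type: str, calcium: str) -> set:
        """Genes with a planted effect under BOTH treatments in this context."""
        e = self.effects
        sel = e[(e["cell_type"] == cell_type) & (e["calcium"] == calcium)]
        by_treatment = sel.groupby("gene")["treatment"].nunique()
        return set(by_treatment[by_treatment == 2].index)


def allocate_classes(n_genes: int, fractions: dict) -> list:
    """Deterministic largest-remainder allocation of genes to classes.

    Counts depend only on ``n_genes`` and ``fractions`` (never on the seed);
    classes are laid out in the fixed ``CLASS_NAMES`` order.
    """
    names = [c for c in CLASS_NAMES if fractions.get(c, 0.0) > 0]
    quotas = np.array([fractions[c] * n_genes for c in names])
    counts = np.floor(quotas).astype(int)
    short = n_genes - counts.sum()
    # ties broken by class order, matching the stable argsort
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    labels = []
    for name, k in zip(names, counts):
        labels.extend([name] * int(k))
    return labels


def _plant_effects(config: GeneratorConfig, classes, rng) -> pd.DataFrame:
    """Draw signed log₂ effects for every non-null (gene, context)."""
    cells = list(config.cell_types)
    rows = []
    for g, cls in enumerate(classes):
        if cls == "null":
            continue
        gene = f"g{g:05d}"
        sign = 1.0 if rng.random() < config.prob_up else -1.0
        magnitude = max(
            abs(rng.normal(config.effect_mean, config.effect_sd)), MIN_EFFECT
        )
        base = sign * magnitude
        if cls == "cell_specific":
            active_cells = [cells[rng.integers(len(cells))]]
        else:
            active_cells = cells
        if cls == "ca_dependent":
            active_ca = [Calcium.PLUS.value]
        elif cls == "ca_only":
            active_ca = [Calcium.MINUS.value]
        else:
            active_ca = [Calcium.PLUS.value, Calcium.MINUS.value]
        for cell in active_cells:
            for ca in active_ca:
                ouabain = base
                kfree = config.kfree_gain * ouabain + rng.normal(
                    0.0, config.treatment_noise_sd
                )
                # keep the planted truth internally consistent: same sign as
                # the ouabain effect and above the fold-filter floor
                kfree = sign * max(abs(kfree), MIN_EFFECT) if kfree * sign > 0 \
                    else sign * MIN_EFFECT
                rows.append((gene, cell, ca, Treatment.OUABAIN.value, ouabain,
                             "up" if sign > 0 else "down"))
                rows.append((gene, cell, ca, Treatment.KFREE.value, kfree,
                             "up" if sign > 0 else "down"))
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "calcium", "treatment", "effect",
                 "direction"],
    )


def generate_dataset(config: GeneratorConfig | None = None):
    """Generate (ExpressionMatrix, SampleDesign, TruthTable[, ProbeMap]).

    Sample value = baseline + planted effect(cell, calcium, treatment)
    + probe offset + N(0, noise_sd), all on the log₂ scale. Deterministic
    given ``config.seed`` (one documented RNG stream, no hidden state).
    With ``probes_per_gene > 1`` the matrix is probe-level and a ProbeMap is
    returned; otherwise the probe map is ``None``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    classes = allocate_classes(config.n_genes, config.class_fractions)
    effects = _plant_effects(config, classes, rng)
    truth = TruthTable(
        classes=pd.Series(classes, index=genes, name="class"), effects=effects
    )

    design_rows = []
    for cell in config.cell_types:
        for ca in (Calcium.PLUS.value, Calcium.MINUS.value):
            for tr in (Treatment.CONTROL.value, Treatment.OUABAIN.value,
                       Treatment.KFREE.value):
                for rep in range(1, config.n_replicates + 1):
                    design_rows.append(
                        (f"{cell}_{ca}_{tr}_{rep}", cell, tr, ca, rep)
                    )
    design = SampleDesign(
        pd.DataFrame(
            design_rows,
            columns=["sample_id", "cell_type", "treatment", "calcium",
                     "replicate"],
        )
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    lookup = truth.effect_lookup()

    n_probes = config.probes_per_gene
    probe_offsets = (
        rng.normal(0.0, config.probe_affinity_sd,
                   size=(config.n_genes, n_probes))
        if n_probes > 1
        else np.zeros((config.n_genes, 1))
    )

    n_rows = config.n_genes * n_probes
    sample_ids = design.sample_ids
    values = np.empty((n_rows, len(sample_ids)))
    for j, row in enumerate(design.table.itertuples()):
        shift = np.array([
            lookup.get((g, row.cell_type, row.calcium, row.treatment), 0.0)
            for g in genes
        ])
        mean = baseline + shift
        block = mean[:, None] + probe_offsets  # genes × probes
        noise = rng.normal(0.0, config.noise_sd, size=block.shape) \
            if config.noise_sd > 0 else 0.0
        values[:, j] = (block + noise).reshape(-1)

    if n_probes > 1:
        row_ids = [f"{g}_p{k}" for g in genes for k in range(n_probes)]
        probe_map = ProbeMap({f"{g}_p{k}": g for g in genes
                              for k in range(n_probes)})
    else:
        row_ids = genes
        probe_map = None

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=row_ids, columns=sample_ids), Scale.LOG2
    )
    return matrix, design, truth, probe_map


def summarize_truth(truth: TruthTable) -> dict:
    """Per-class gene counts and per-(cell, calcium) planted DE sets."""
    counts = truth.classes.value_counts().to_dict()
    contexts = (
        truth.effects[["cell_type", "calcium"]].drop_duplicates().itertuples(
            index=False)
    )
    planted = {
        (cell, ca): truth.planted_set(cell, ca) for cell, ca in contexts
    }
    return {"class_counts": counts, "planted_sets": planted}
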