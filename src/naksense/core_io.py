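"""Data model and file I/O shared by all pipeline stages.

The pipeline works on two in-memory containers built on pandas:

* :class:`ExpressionMatrix` — a genes × samples numeric matrix tagged with
  its scale (``linear`` intensities or ``log2``).
* :class:`SampleDesign` — the per-sample factor table of the factorial
  experiment (cell type × treatment × calcium condition × replicate).

Interchange is plain TSV throughout: the study's raw arrays are not
deposited, so there is nothing proprietary to parse, and TSV keeps every
intermediate human-readable. Transcriptions of the printed result tables
(total differentially expressed transcript counts, the ubiquitous-gene
list, and the strongly regulated HeLa genes) ship with the package as
fixtures and are loaded with :func:`load_fixture`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "Treatment",
    "Calcium",
    "ExpressionMatrix",
    "SampleDesign",
    "ProbeMap",
    "Config",
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_de_table",
    "write_de_table",
    "load_fixture",
    "write_results",
    "FIXTURE_NAMES",
]


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


class Scale(str, enum.Enum):
    LINEAR = "linear"
    LOG2 = "log2"


class Treatment(str, enum.Enum):
    CONTROL = "control"
    OUABAIN = "ouabain"
    KFREE = "kfree"


class Calcium(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"


def _coerce_enum(cls, value, field: str):
    """Case-insensitive enum parsing; all internal labels are lowercase."""
    if isinstance(value, cls):
        return value
    try:
        return cls(str(value).strip().lower())
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ParseError(
            f"unknown {field} value {value!r}; allowed: {allowed}"
        ) from None


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes × samples numeric matrix with a scale flag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. All entries must be finite; on the linear scale they
        must additionally be strictly positive.
    scale
        ``Scale.LINEAR`` or ``Scale.LOG2``.
    """

    values: pd.DataFrame
    scale: Scale = Scale.LOG2

    def __post_init__(self) -> None:
        self.scale = _coerce_enum(Scale, self.scale, "scale")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric entries")
        if arr.size and not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        if self.scale is Scale.LINEAR and arr.size and not np.all(arr > 0):
            r, c = np.argwhere(arr <= 0)[0]
            raise ParseError(
                f"non-positive value on linear scale at gene "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale)


_DESIGN_COLUMNS = ["sample_id", "cell_type", "treatment", "calcium", "replicate"]


@dataclasses.dataclass
class SampleDesign:
    """Per-sample factors of the factorial experiment."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParseError(f"design table missing columns: {missing}")
        t = self.table[_DESIGN_COLUMNS].copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["cell_type"] = t["cell_type"].astype(str).str.strip().str.lower()
        t["treatment"] = [
            _coerce_enum(Treatment, v, "treatment").value for v in t["treatment"]
        ]
        t["calcium"] = [
            _coerce_enum(Calcium, v, "calcium").value for v in t["calcium"]
        ]
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] <= 0).any():
            raise ParseError("replicate numbers must be positive integers")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ParseError(f"duplicate sample_id {dup!r}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    @property
    def cell_types(self) -> list:
        return sorted(self.table["cell_type"].unique())

    def samples_for(
        self, cell_type: str, calcium, treatment
    ) -> list:
        """Sample ids of one design cell."""
        calcium = _coerce_enum(Calcium, calcium, "calcium").value
        treatment = _coerce_enum(Treatment, treatment, "treatment").value
        t = self.table
        sel = (
            (t["cell_type"] == str(cell_type).lower())
            & (t["calcium"] == calcium)
            & (t["treatment"] == treatment)
        )
        return list(t.loc[sel, "sample_id"])

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        design_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if design_ids != matrix_ids:
            raise ParseError(
                "design/matrix sample mismatch: "
                f"only-in-design={sorted(design_ids - matrix_ids)[:5]}, "
                f"only-in-matrix={sorted(matrix_ids - design_ids)[:5]}"
            )


@dataclasses.dataclass
class ProbeMap:
    """Many-to-one probe → gene mapping."""

    mapping: dict

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        if not self.mapping:
            raise ParseError("empty probe map")

    @property
    def genes(self) -> list:
        return sorted(set(self.mapping.values()))

    def probes_for(self, gene: str) -> list:
        return [p for p, g in self.mapping.items() if g == gene]


@dataclasses.dataclass
class Config:
    """Run-level analysis parameters with the study's defaults.

    threshold
        Minimum |fold| for a differential call (inclusive). 1.2 reproduces
        the study's 20%-modulation filter.
    alpha
        Significance level for the per-contrast test.
    use_adjusted_p
        If True (default) significance is judged on BH-adjusted q-values;
        if False on raw p-values, matching the literal "p<0.05" wording.
    """

    threshold: float = 1.2
    alpha: float = 0.05
    use_adjusted_p: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("fold threshold must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "Config":
        """Read key=value overrides (``#`` comments allowed)."""
        kwargs = {}
        casts = {
            "threshold": float,
            "alpha": float,
            "use_adjusted_p": lambda s: s.strip().lower() in ("1", "true", "yes"),
            "seed": int,
        }
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"config line without '=': {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in casts:
                raise ParseError(f"unknown config key {key!r}")
            kwargs[key] = casts[key](value.strip())
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, scale="log2") -> ExpressionMatrix:
    """Read a genes × samples TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.columns.size == 0:
        raise ParseError(f"{path}: no sample columns")
    numeric = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (df[col].str.strip() == "")
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric or missing value at gene {gene!r}, "
                f"sample {col!r}"
            )
        numeric[col] = converted.to_numpy(dtype=float)
    return ExpressionMatrix(numeric, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


_DE_COLUMNS = [
    "gene", "cell_type", "calcium", "treatment",
    "log2fc", "fold", "p", "q", "direction",
]


def write_de_table(de: pd.DataFrame, path) -> None:
    cols = [c for c in _DE_COLUMNS if c in de.columns]
    extra = [c for c in de.columns if c not in cols]
    de[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DE table missing columns {missing}")
    return df


def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: probe map needs probe_id and gene_id columns")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ParseError(f"{path}: probe {dup!r} mapped more than once")
    return ProbeMap(dict(zip(probes, genes)))


def write_probe_map(pm: ProbeMap, path) -> None:
    pd.DataFrame(
        {"probe_id": list(pm.mapping), "gene_id": list(pm.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table2", "table3", "table4")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged verbatim table transcriptions.

    ``table2`` — per cell type and direction, the total numbers of
    differentially expressed transcripts under each pump inhibitor and the
    maximal folds, in Ca²⁺-containing medium.
    ``table3`` — the 80 ubiquitous Na⁺ᵢ/K⁺ᵢ-sensitive genes with folds for
    all six (cell type, treatment) contrasts and functional-category codes.
    ``table4`` — HeLa genes altered by more than 4-fold, with folds and
    per-contrast p-values.

    Folds are signed decimals exactly as printed (negative = inhibition);
    standard errors are kept in separate ``*_se`` columns.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("naksense.fixtures").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# Result bundles
# ---------------------------------------------------------------------------

def write_results(
    out_dir,
    *,
    de_table: pd.DataFrame | None = None,
    tables: Mapping[str, pd.DataFrame] | None = None,
    summary: Mapping | None = None,
    config: Config | None = None,
) -> Path:
    """Write result TSVs plus one JSON run summary; returns the summary path.

    The JSON records set sizes, the filter parameters, and the seed so a run
    can be audited without re-opening the TSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if de_table is not None:
        write_de_table(de_table, out_dir / "de.tsv")
    counts = {}
    for name, df in (tables or {}).items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.12g")
        counts[name] = int(len(df))
    config = config or Config()
    payload = {
        "counts": counts,
        "parameters": {
            "threshold": config.threshold,
            "alpha": config.alpha,
            "use_adjusted_p": config.use_adjusted_p,
        },
        "seed": config.seed,
    }
    if summary:
        payload.update(summary)
    summary_path = out_dir / "run_summary.json"
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return summary_path
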