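# naksense

Analysis toolkit for the **Na⁺ᵢ/K⁺ᵢ-sensitive transcriptome** — the set of
genes whose expression changes when the intracellular sodium/potassium
ratio rises after Na⁺,K⁺-ATPase inhibition.

## The scientific problem

The Na⁺,K⁺-ATPase keeps intracellular K⁺ high and Na⁺ low. Inhibiting the
pump — either with the cardiotonic steroid **ouabain** or by removing
extracellular K⁺ (**K⁺-free medium**) — dissipates that gradient and
triggers broad changes in gene expression. Because the two stimuli act
through unrelated side-effect profiles, a gene that responds *concordantly
to both* can be attributed to the [Na⁺]ᵢ/[K⁺]ᵢ signal itself rather than
to either perturbation's off-target effects. Running the same design in
several cell types, and with or without Ca²⁺-mediated signaling
(Ca²⁺-depleted medium with chelators), separates

* **sensitive genes** per (cell type, calcium condition): |fold| ≥ 1.2 and
  significant under *both* inhibitors, same direction;
* the **ubiquitous set**: sensitive with one consistent direction in every
  cell type;
* the **calcium partition**: sensitive genes detected only with Ca²⁺,
  under both conditions, or only without Ca²⁺.

`naksense` implements that inference chain end to end: RMA-style
preprocessing (background adjustment, quantile normalization, median-polish
probe summarization, PCA), per-contrast differential expression (Welch or
pooled t-tests with Benjamini–Hochberg FDR control, signed folds), the
dual-stimulus classification calculus, the closed-form wet-lab assay
formulas that accompany such experiments (fura-2 calcium, radiotracer
cation content, ¹⁴C-urea space, intracellular BAPTA, ΔΔCt qPCR folds), and
a synthetic factorial-experiment generator with planted effect classes for
recovery testing. Verbatim transcriptions of the published result tables
ship as TSV fixtures so the classification operations can be exercised on
real printed data. See `docs/methods.md` for the model and all parameter
choices.

## Worked example

```python
import naksense as nk

# 1. Classification on the packaged ubiquitous-gene table
sets = nk.sensitive_sets_from_fixture("table3")
ubiq = nk.ubiquitous_set(sets)
print(len(ubiq))                                  # 80
print((ubiq["direction"] == "up").sum())          # 61
print((ubiq["direction"] == "down").sum())        # 19

report = nk.fold_correlation(sets[0])             # HeLa: ouabain vs K+-free
print(round(report.r, 3), round(report.r_squared, 3))   # 0.934 0.873

summary = nk.category_summary(ubiq["gene"], nk.fixture_annotation("table3"))
print(summary.percentages)   # {'t': 49, 'd': 24, 'f': 3, 'i': 6, 'o': 19}

# 2. Closed-form assays
print(nk.fura2_ca(1.5))                 # 224.0  (nM, calibration midpoint)
print(nk.bapta_concentration(260, 2))   # 130.0  (µM)

# 3. Synthetic experiment -> differential expression -> classification
cfg = nk.GeneratorConfig(n_genes=2000, seed=1)
matrix, design, truth, _ = nk.generate_dataset(cfg)
print(matrix.n_genes, "x", matrix.n_samples)      # 2000 x 72

de = nk.de_table(matrix, design)                  # 24000 contrast rows
result = nk.classify_experiment(de)
print(len(result.ubiquitous["plus"]))             # 284 detected ubiquitous
sset = result.sensitive[("hela", "plus")]
print(len(sset))                                  # 357 sensitive genes
print(round(nk.fold_correlation(sset).r_squared, 3))    # 0.983
```

The same stages are available from the command line:

```bash
naksense simulate --n-genes 2000 --seed 1 --out sim/
naksense de --matrix sim/matrix.tsv --design sim/design.tsv --out de.tsv
naksense classify --de de.tsv --out results/
naksense classify --fixture table3 --out fixture_results/
naksense assay fura2 --r 1.5          # {"ca_nm": 224.0}
```

## Layout

```
src/naksense/      core_io, simulate, preprocess, diffexpr, classify,
                   assays, cli  (+ fixtures/*.tsv)
tests/             unit, property-based, integration and acceptance tests
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameters, limitations
```
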