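# immunoscape

Spatial scoring of lymphocytic infiltration in tumour sections, from
classified cell coordinates to prognosis.

Histopathology image analysis can reduce an H&E whole-tumour section to a
table of cell positions and types (cancer / lymphocyte / stromal).  This
package takes such cell maps and quantifies *where* the lymphocytes sit
relative to the cancer, for pathology-informatics and tumour-immunology
groups who need reproducible, observer-independent infiltration scores:

1. **Cancer-density landscape** — a quartic-kernel intensity surface
   f(p) = h⁻² Σᵢ K((p − xᵢ)/h) over the cancer cells; each lymphocyte's
   proximity to cancer is sᵢ = f(yᵢ), evaluated exactly at its position.
2. **Lymphocyte classes** — a univariate Gaussian mixture on the pooled sᵢ
   (EM, K chosen by BIC = 2L − d·log N with subsampling stability) separates
   **ITL** (intratumour), **ATL** (adjacent-tumour) and **DTL**
   (distal-tumour) lymphocytes; per-cell labels come from the crossing
   points of adjacent component densities.
3. **Scores** — per tumour, the intratumour lymphocyte ratio
   **ITLR = n_ITL / n_cancer** plus ATLR, DTLR and the class-agnostic
   Lym ratio; spatial-arrangement descriptors d_min (nearest cancer cell)
   and d_centroid (centroid of the convex hull of the 5 nearest cancer
   cells) characterize the classes physically.
4. **Survival** — percentile cut-off scan (20th–80th, step 1.5) with
   discovery/validation discipline, Kaplan–Meier/log-rank, uni- and
   multivariate Cox (high-score group coded 1, so HR < 1 means high
   infiltration is protective), patient-bootstrap robustness and cross-cohort
   cut-off consistency.
5. **Molecular correlates** — per-gene Pearson correlation with the score,
   Storey q-values (λ = 0.75), co-expression module discovery
   (100-cluster cut, mean |r| > 0.75, size ≥ 6), hypergeometric gene-set
   enrichment, and paired score-vs-gene Cox comparisons.

A synthetic-data module generates tumour sections (Thomas-process cancer
nests with geometrically planted lymphocyte regimes), survival tables
(Weibull proportional hazards with a planted hazard ratio) and expression
matrices (planted correlated genes and modules) so every stage is testable
against known ground truth.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import numpy as np
from immunoscape import (
    TumorSimParams, simulate_tumor, KernelSpec, proximity_to_cancer,
    fit_gmm, class_thresholds, assign_classes, compute_scores,
)

params = TumorSimParams(
    window=(4000.0, 4000.0), nest_rate=1.25, offspring_mean=300.0,
    nest_sd=60.0, stromal_rate=25.0, lymph_counts=(500, 500, 500),
    adjacent_offset=120.0, regime_jitter=10.0, seed=5000,
)
cell_map, regimes = simulate_tumor(params, "T00")
prox = proximity_to_cancer(cell_map, KernelSpec(bandwidth=80.0))
model = fit_gmm(prox.values, k=3, seed=42)
labels = assign_classes(class_thresholds(model), prox.values)
scores = compute_scores(labels, cell_map.n_cancer, "T00")
print("component means:", np.sort(model.means))
print("counts:", labels.counts())
print(f"ITLR = {scores.itlr:.4f}   Lym = {scores.lym:.4f}")
```

Output:

```
component means: [2.31638591e-11 3.21307832e-04 6.93802744e-03]
counts: {'ITL': 561, 'ATL': 393, 'DTL': 546}
ITLR = 0.1679   Lym = 0.4488
```

The three component means are the low/medium/high cancer-density regimes the
mixture discovered (cells/μm²: distal lymphocytes see essentially zero cancer
density, adjacent ones an intermediate level, intratumour ones ~20× more).
On a single small section the class split is noisier than on a pooled cohort
— here 561/393/546 against the planted 500/500/500; pooling many sections
before the mixture fit (as `immunoscape classify` does) sharpens it.  ITLR is
the number of intratumour lymphocytes per cancer cell: this simulated section
has ≈ 17 intratumour lymphocytes per 100 cancer cells.

The same flow runs from the shell:

```bash
immunoscape simulate tumor --seed 5000 --out sim/
immunoscape classify --cells-dir sim/ --h 80 --out out/
immunoscape score --labels-dir out/labels --out scores.csv
immunoscape survival scores.csv clinical.tsv --discovery 1 --validation 2 \
    --boot 1000 --seed 7 --out survival_report.json
immunoscape run --config run.yaml        # full pipeline from one config
```

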