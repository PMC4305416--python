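"""Synthetic tumour sections, survival tables and expression matrices.

Every downstream stage of the package is testable without access to real
histology because this module plants known ground truth:

* :func:`simulate_tumor` draws cancer cells from a Thomas-type
  parent–offspring ("nest") process and places lymphocytes in three
  geometric regimes — inside nests (``intra``), at a fixed offset on the
  outward side of a nest (``adjacent``), and far from every nest
  (``distal``).  The regimes are geometric constructions, not density
  thresholds, so recovery tests of the density/mixture pipeline are
  non-circular.
* :func:`simulate_survival` draws Weibull proportional-hazards event times
  with a planted hazard ratio between score-defined groups, independent
  exponential censoring, and administrative censoring at 120 months
  (10-year disease-specific follow-up).
* :func:`simulate_expression` plants score-correlated genes at a target
  Pearson correlation and latent-factor co-expression modules at a target
  within-module correlation.

All generators are pure functions of their parameters (including ``seed``).
Default parameters emulate a whole-tumour TNBC section at full scale
(~8×10⁴ cancer cells, ~1.5×10⁴ lymphocytes in a 1 cm² window) and a
181-patient cohort; tests use smaller windows/counts passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_tables import CellMap

REGIMES = ("intra", "adjacent", "distal")
#: planted regime -> the lymphocyte class it should be recovered as
REGIME_TO_CLASS = {"intra": "ITL", "adjacent": "ATL", "distal": "DTL"}


@dataclass
class TumorSimParams:
    """Parameters of the nested tumour-section point process.

    Defaults produce a full-scale whole-tumour section: a 10×10 mm window with
    2 nests/mm² of 400 cancer cells each (≈8×10⁴ cancer cells), 140
    stromal cells/mm² (≈1.4×10⁴) and 15 000 lymphocytes split by the
    average observed class composition (32% ITL / 47% ATL / 21% DTL).
    """

    window: tuple[float, float] = (10_000.0, 10_000.0)  # μm × μm
    nest_rate: float = 2.0  # nest parents per mm²
    offspring_mean: float = 400.0  # cancer cells per nest
    nest_sd: float = 75.0  # μm, Gaussian nest spread
    stromal_rate: float = 140.0  # per mm²
    lymph_counts: tuple[int, int, int] = (4800, 7050, 3150)  # (intra, adjacent, distal)
    adjacent_offset: float = 150.0  # μm from an anchor cancer cell, outward
    regime_jitter: float = 20.0  # μm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nest_rate, self.offspring_mean, self.stromal_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.adjacent_offset <= 0:
            raise ValueError("adjacent_offset must be positive")
        if min(self.lymph_counts) < 0:
            raise ValueError("lymphocyte counts must be non-negative")


@dataclass
class SurvSimParams:
    """Weibull proportional-hazards survival generator settings.

    ``hazard_ratio`` is the hazard of the *high*-score group relative to the
    low-score group (the ``low_fraction`` of patients with the smallest
    scores); HR < 1 plants the observed clinical direction, low infiltration
    scores carrying the worse prognosis.  Baseline Weibull shape/scale are in
    months and describe the low-score group; the default scale gives the
    low group ≈49% 5-year survival.  Censoring is exponential at
    ``censor_rate`` per month, with administrative censoring at 120 months.
    """

    n_patients: int = 181
    shape: float = 1.1
    scale: float = 82.0  # months
    hazard_ratio: float = 0.36
    low_fraction: float = 0.2
    censor_rate: float = 0.002  # per month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 < self.low_fraction < 1:
            raise ValueError("low_fraction must lie in (0, 1)")
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")


@dataclass
class ExprSimParams:
    """Expression-matrix generator settings.

    ``n_correlated`` genes follow ``r_target·z + √(1−r²)·ε`` on the
    standardized score ``z`` (population correlation exactly ``r_target``);
    ``n_negative`` of the same construction at ``−r_target``.  Each entry of
    ``module_spec`` plants one co-expression module: ``size`` genes sharing a
    latent factor with pairwise population correlation ``rho``.  Remaining
    genes are i.i.d. noise.
    """

    n_genes: int = 2000
    n_correlated: int = 100
    r_target: float = 0.6
    n_negative: int = 0
    module_spec: list = field(default_factory=list)  # [(size, within-correlation), ...]
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.r_target) >= 1:
            raise ValueError("|r_target| must be < 1 (r_target = ±1 leaves no noise)")
        for size, rho in self.module_spec:
            if size < 2:
                raise ValueError("module sizes must be ≥ 2")
            if not 0 <= rho < 1:
                raise ValueError("within-module correlation must lie in [0, 1)")
        if self.n_correlated + self.n_negative + sum(s for s, _ in self.module_spec) > self.n_genes:
            raise ValueError("planted genes exceed n_genes")


# ---------------------------------------------------------------------------
# tumour sections
# ---------------------------------------------------------------------------

def simulate_tumor(params: TumorSimParams, tumour_id: str = "sim") -> tuple[CellMap, np.ndarray]:
    """Generate one tumour section with planted lymphocyte regimes.

    Returns the :class:`CellMap` and an array of regime labels
    (``intra``/``adjacent``/``distal``), aligned with the lymphocyte rows of
    the map in order.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.window
    area_mm2 = w * h / 1e6

    n_parents = rng.poisson(params.nest_rate * area_mm2)
    parents = rng.uniform((0, 0), (w, h), size=(n_parents, 2))

    # cancer: Gaussian offspring around each parent, clipped into the window
    n_off = rng.poisson(params.offspring_mean, size=n_parents)
    parent_of = np.repeat(np.arange(n_parents), n_off)
    cancer = parents[parent_of] + rng.normal(0.0, params.nest_sd, size=(parent_of.size, 2))
    cancer = np.clip(cancer, [0, 0], [w, h])

    n_stromal = rng.poisson(params.stromal_rate * area_mm2)
    stromal = rng.uniform((0, 0), (w, h), size=(n_stromal, 2))

    n_intra, n_adj, n_distal = params.lymph_counts
    if (n_intra or n_adj) and cancer.shape[0] == 0:
        raise RuntimeError("no cancer cells generated; cannot anchor intra/adjacent lymphocytes")

    lymph_parts, labels = [], []

    if n_intra:
        anchor = rng.integers(0, cancer.shape[0], size=n_intra)
        pts = cancer[anchor] + rng.normal(0.0, params.regime_jitter, size=(n_intra, 2))
        lymph_parts.append(np.clip(pts, [0, 0], [w, h]))
        labels += ["intra"] * n_intra

    if n_adj:
        anchor = rng.integers(0, cancer.shape[0], size=n_adj)
        out = cancer[anchor] - parents[parent_of[anchor]]
        norm = np.linalg.norm(out, axis=1, keepdims=True)
        rand_dir = rng.normal(size=(n_adj, 2))
        rand_dir /= np.linalg.norm(rand_dir, axis=1, keepdims=True)
        out = np.where(norm > 1e-9, out / np.where(norm > 1e-9, norm, 1.0), rand_dir)
        pts = (
            cancer[anchor]
            + out * params.adjacent_offset
            + rng.normal(0.0, params.regime_jitter, size=(n_adj, 2))
        )
        lymph_parts.append(np.clip(pts, [0, 0], [w, h]))
        labels += ["adjacent"] * n_adj

    if n_distal:
        min_dist = 3.0 * params.nest_sd
        kept: list[np.ndarray] = []
        n_kept = 0
        max_draws = max(10_000, 1000 * n_distal)
        drawn = 0
        while n_kept < n_distal:
            batch = max(n_distal - n_kept, 1000)
            if drawn + batch > max_draws:
                raise RuntimeError(
                    "window too crowded to place distal lymphocytes "
                    f"≥{min_dist:.0f} μm from every nest parent"
                )
            cand = rng.uniform((0, 0), (w, h), size=(batch, 2))
            drawn += batch
            if n_parents:
                d2 = ((cand[:, None, :] - parents[None, :, :]) ** 2).sum(axis=2).min(axis=1)
                cand = cand[d2 >= min_dist**2]
            if len(cand):
                kept.append(cand)
                n_kept += len(cand)
        pts = np.concatenate(kept)[:n_distal]
        lymph_parts.append(pts)
        labels += ["distal"] * n_distal

    lymph = np.concatenate(lymph_parts) if lymph_parts else np.empty((0, 2))

    df = pd.DataFrame(
        {
            "x": np.concatenate([cancer[:, 0], lymph[:, 0], stromal[:, 0]]),
            "y": np.concatenate([cancer[:, 1], lymph[:, 1], stromal[:, 1]]),
            "class": (
                ["cancer"] * cancer.shape[0]
                + ["lymphocyte"] * lymph.shape[0]
                + ["stromal"] * stromal.shape[0]
            ),
        }
    )
    cell_map = CellMap(tumour_id, df, (0.0, 0.0, w, h))
    return cell_map, np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

ADMIN_CENSOR_MONTHS = 120.0


def simulate_survival(scores: np.ndarray, params: SurvSimParams) -> pd.DataFrame:
    """Clinical table (time in months, event flag, node, size) for given scores.

    Patients with scores below the ``low_fraction`` quantile form the
    low-score group; their hazard is ``1/hazard_ratio`` times the rest.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != params.n_patients:
        raise ValueError(
            f"scores length {scores.size} != n_patients {params.n_patients}"
        )
    rng = np.random.default_rng(params.seed)
    cut = np.quantile(scores, params.low_fraction)
    high = (scores >= cut).astype(int)  # 1 = high-score group

    # Weibull PH: S(t|z) = exp(-(t/scale)^shape · HR^z), baseline = low group
    u = rng.uniform(size=scores.size)
    hr = params.hazard_ratio**high
    t_event = params.scale * (-np.log(u) / hr) ** (1.0 / params.shape)
    if params.censor_rate > 0:
        t_cens = rng.exponential(1.0 / params.censor_rate, size=scores.size)
    else:
        t_cens = np.full(scores.size, np.inf)
    observed = np.minimum(np.minimum(t_event, t_cens), ADMIN_CENSOR_MONTHS)
    event = (t_event <= t_cens) & (t_event <= ADMIN_CENSOR_MONTHS)

    node = rng.binomial(1, 0.35, size=scores.size)
    size_cm = np.round(rng.lognormal(mean=np.log(2.2), sigma=0.35, size=scores.size), 2)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(scores.size)],
            "time_months": np.maximum(observed, 1e-6),
            "event": event.astype(int),
            "node": node,
            "size": size_cm,
            "score": scores,
            "true_group_high": high,
        }
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    scores: np.ndarray, params: ExprSimParams
) -> tuple[pd.DataFrame, dict]:
    """Genes × samples expression matrix with planted truth.

    Returns ``(expr, truth)`` where ``truth`` records the planted
    positively/negatively correlated gene ids and module memberships.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    z = (scores - scores.mean()) / scores.std(ddof=0)
    rng = np.random.default_rng(params.seed)

    gene_ids = [f"gene_{i:05d}" for i in range(params.n_genes)]
    X = np.empty((params.n_genes, n))
    r = params.r_target
    row = 0
    pos_genes = gene_ids[row : row + params.n_correlated]
    for _ in range(params.n_correlated):
        X[row] = r * z + np.sqrt(1 - r**2) * rng.normal(size=n)
        row += 1
    neg_genes = gene_ids[row : row + params.n_negative]
    for _ in range(params.n_negative):
        X[row] = -r * z + np.sqrt(1 - r**2) * rng.normal(size=n)
        row += 1
    modules = []
    for size, rho in params.module_spec:
        f = rng.normal(size=n)
        members = gene_ids[row : row + size]
        for _ in range(size):
            X[row] = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
            row += 1
        modules.append(members)
    n_null = params.n_genes - row
    null_genes = gene_ids[row:]
    X[row:] = rng.normal(size=(n_null, n))
    X *= params.noise_sd

    expr = pd.DataFrame(X, index=gene_ids, columns=[f"S{i:04d}" for i in range(n)])
    truth = {
        "positive_genes": pos_genes,
        "negative_genes": neg_genes,
        "modules": modules,
        "null_genes": null_genes,
    }
    return expr, truth
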