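"""Score dichotomization and survival modelling.

A continuous infiltration score is dichotomized by scanning candidate
cut-offs at the score's 20th–80th percentiles in steps of 1.5 percentile
points (41 candidates) and keeping the cut-off with the smallest log-rank
p-value in a *discovery* cohort; the chosen cut-off is then frozen and
applied to a *validation* cohort.  The scan optimizes over 41 tests, so its
raw minimum p-value is anti-conservative by construction — validation in an
independent cohort is the guard, exactly as the discovery/validation split
enforces.

Kaplan–Meier estimation, the log-rank test and Cox proportional-hazards
models (Efron tie handling) are provided by lifelines behind this module's
interface.  The high-score group is coded 1 throughout, so a hazard ratio
below one means high scores are protective.  Survival times are
disease-specific and administratively censored at 120 months on ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

ADMIN_CENSOR_MONTHS = 120.0
ALPHA = 0.05

TIME_COL = "time_months"
EVENT_COL = "event"


def prepare_clinical(clinical: pd.DataFrame, censor_at: float = ADMIN_CENSOR_MONTHS) -> pd.DataFrame:
    """Validate a clinical table and apply 10-year administrative censoring."""
    df = clinical.copy()
    for col in (TIME_COL, EVENT_COL):
        if col not in df.columns:
            raise ValueError(f"clinical table is missing column {col!r}")
    if (df[TIME_COL] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df[EVENT_COL].isin([0, 1]).all():
        raise ValueError("event flags must be 0/1")
    over = df[TIME_COL] > censor_at
    df.loc[over, EVENT_COL] = 0
    df.loc[over, TIME_COL] = censor_at
    return df


def km_logrank(groups: np.ndarray, clinical: pd.DataFrame) -> dict:
    """Kaplan–Meier curves per group plus the log-rank comparison.

    Returns ``{"km": {group: survival function DataFrame}, "statistic", "p"}``.
    If every subject in every group is censored the test statistic is
    undefined and reported as NaN.
    """
    groups = np.asarray(groups)
    t = clinical[TIME_COL].to_numpy(dtype=float)
    e = clinical[EVENT_COL].to_numpy(dtype=int)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    km = {}
    for g in uniq:
        sel = groups == g
        fitter = KaplanMeierFitter()
        fitter.fit(t[sel], e[sel], label=str(g))
        km[g] = fitter.survival_function_
    if e.sum() == 0:
        warnings.warn("all subjects censored; log-rank p undefined", stacklevel=2)
        return {"km": km, "statistic": float("nan"), "p": float("nan")}
    if len(uniq) == 2:
        res = logrank_test(
            t[groups == uniq[0]], t[groups == uniq[1]],
            e[groups == uniq[0]], e[groups == uniq[1]],
        )
    else:
        res = multivariate_logrank_test(t, groups, e)
    return {"km": km, "statistic": float(res.test_statistic), "p": float(res.p_value)}


@dataclass
class CutoffResult:
    """Outcome of the percentile cut-off scan."""

    percentiles: np.ndarray
    cutoffs: np.ndarray
    pvalues: np.ndarray
    chosen_percentile: float
    chosen_cutoff: float
    n_low: int
    n_high: int
    logrank_p: float
    hr: float = float("nan")
    hr_ci: tuple = (float("nan"), float("nan"))
    km: dict = field(default_factory=dict, repr=False)


def scan_cutoff(
    score: np.ndarray,
    clinical: pd.DataFrame,
    lo: float = 20.0,
    hi: float = 80.0,
    step: float = 1.5,
) -> CutoffResult:
    """Percentile scan for the most prognostic dichotomizing cut-off.

    Candidates are the score percentiles ``lo, lo+step, …, hi`` (the default
    grid has 41 candidates).  Groups are score < cut-off versus ≥ cut-off;
    the candidate with the smallest log-rank p wins, ties resolving to the
    lower percentile.  Candidates yielding an empty group are skipped.
    """
    score = np.asarray(score, dtype=float)
    if score.size < 20:
        raise ValueError("need at least 20 patients for the cut-off scan")
    if np.ptp(score) == 0:
        raise ValueError("score is constant; no cut-off can stratify")
    clinical = prepare_clinical(clinical)
    n_steps = int(np.floor((hi - lo) / step + 1e-9))
    pctl = lo + step * np.arange(n_steps + 1)
    cutoffs = np.percentile(score, pctl)
    pvals = np.full(pctl.size, np.nan)
    for i, c in enumerate(cutoffs):
        high = score >= c
        if high.all() or not high.any():
            continue
        pvals[i] = km_logrank(high.astype(int), clinical)["p"]
    if np.isnan(pvals).all():
        raise ValueError("no candidate cut-off produced two non-empty groups")
    best = int(np.nanargmin(pvals))  # first minimum -> lower percentile on ties
    chosen = float(cutoffs[best])
    high = (score >= chosen).astype(int)
    kmres = km_logrank(high, clinical)
    cox = cox_model(clinical.assign(score_high=high), terms=["score_high"])
    row = cox["table"].iloc[0]
    return CutoffResult(
        percentiles=pctl,
        cutoffs=cutoffs,
        pvalues=pvals,
        chosen_percentile=float(pctl[best]),
        chosen_cutoff=chosen,
        n_low=int((~high.astype(bool)).sum()),
        n_high=int(high.sum()),
        logrank_p=float(pvals[best]),
        hr=float(row["hr"]),
        hr_ci=(float(row["ci_low"]), float(row["ci_high"])),
        km=kmres["km"],
    )


def cox_model(clinical: pd.DataFrame, terms: list[str]) -> dict:
    """Cox proportional-hazards fit (Efron ties) for the given covariates.

    Returns ``{"table": DataFrame(term, hr, ci_low, ci_high, p),
    "concordance", "converged"}``.  Non-convergence (e.g. monotone
    likelihood) is flagged rather than raised, matching the convention of
    reporting a failed fit as 0 (0–Inf).
    """
    df = prepare_clinical(clinical)[[TIME_COL, EVENT_COL, *terms]]
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col=TIME_COL, event_col=EVENT_COL)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        table = pd.DataFrame(
            {
                "term": terms,
                "hr": 0.0,
                "ci_low": 0.0,
                "ci_high": float("inf"),
                "p": float("nan"),
            }
        )
        return {"table": table, "concordance": float("nan"), "converged": False,
                "error": str(exc)}
    summ = fitter.summary
    with np.errstate(over="ignore"):
        table = _summary_table(summ)
    return {
        "table": table,
        "concordance": float(fitter.concordance_index_),
        "converged": True,
    }


def _summary_table(summ: pd.DataFrame) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "term": summ.index,
            "hr": summ["exp(coef)"].to_numpy(),
            "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
            "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
            "coef": summ["coef"].to_numpy(),
            "se": summ["se(coef)"].to_numpy(),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return table


@dataclass
class BootstrapStability:
    frac_significant_uni: float
    frac_significant_multi: float
    n_failed_uni: int
    n_failed_multi: int
    n_boot: int
    alpha: float


def bootstrap_stability(
    clinical: pd.DataFrame,
    group: np.ndarray,
    covariates: tuple = ("node", "size"),
    n_boot: int = 1000,
    alpha: float = ALPHA,
    seed: int | None = None,
) -> BootstrapStability:
    """Patient-bootstrap robustness of the score's prognostic significance.

    Resamples patients with replacement ``n_boot`` times, refits the
    univariate (score group only) and multivariate (group + covariates) Cox
    models, and reports the fraction of resamples in which the group term has
    p < ``alpha``.  Resamples where a model fails to converge count as
    non-significant and are tallied separately.
    """
    df = prepare_clinical(clinical).reset_index(drop=True)
    df = df.assign(score_high=np.asarray(group, dtype=int))
    rng = np.random.default_rng(seed)
    n = len(df)
    sig_uni = sig_multi = fail_uni = fail_multi = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        for terms, is_multi in ((["score_high"], False), (["score_high", *covariates], True)):
            res = cox_model(boot, terms)
            if not res["converged"]:
                if is_multi:
                    fail_multi += 1
                else:
                    fail_uni += 1
                continue
            p = res["table"].set_index("term").loc["score_high", "p"]
            if np.isfinite(p) and p < alpha:
                if is_multi:
                    sig_multi += 1
                else:
                    sig_uni += 1
    return BootstrapStability(
        frac_significant_uni=sig_uni / n_boot,
        frac_significant_multi=sig_multi / n_boot,
        n_failed_uni=fail_uni,
        n_failed_multi=fail_multi,
        n_boot=n_boot,
        alpha=alpha,
    )


def cutoff_consistency(
    sig1: np.ndarray, cutoff1: float, sig2: np.ndarray, cutoff2: float
) -> dict:
    """Compare optimal cut-offs of one signature across two cohorts.

    Each cohort's signature values are centred at 0 and scaled to unit
    standard deviation; the cut-offs are mapped by the same affine transform,
    making the comparison invariant to per-cohort affine rescaling.
    """
    out = []
    for sig, cut in ((sig1, cutoff1), (sig2, cutoff2)):
        sig = np.asarray(sig, dtype=float)
        sd = sig.std(ddof=0)
        if sd == 0:
            raise ValueError("zero-variance cohort: standardized cut-off undefined")
        out.append((cut - sig.mean()) / sd)
    z1, z2 = out
    return {"z_cutoff_1": float(z1), "z_cutoff_2": float(z2), "abs_difference": float(abs(z1 - z2))}


def discovery_validation(
    score_disc: np.ndarray,
    clin_disc: pd.DataFrame,
    score_val: np.ndarray,
    clin_val: pd.DataFrame,
    lo: float = 20.0,
    hi: float = 80.0,
    step: float = 1.5,
) -> dict:
    """Scan the discovery cohort, freeze the cut-off, test in validation.

    The validation cohort applies the discovery cut-off at the same score
    *percentile* (the scan is percentile-based, so the frozen quantity is the
    percentile; the absolute cut-off is also reported for both cohorts).
    """
    disc = scan_cutoff(score_disc, clin_disc, lo=lo, hi=hi, step=step)
    score_val = np.asarray(score_val, dtype=float)
    cut_val = float(np.percentile(score_val, disc.chosen_percentile))
    high_val = (score_val >= cut_val).astype(int)
    km_val = km_logrank(high_val, prepare_clinical(clin_val))
    cox_val = cox_model(prepare_clinical(clin_val).assign(score_high=high_val), ["score_high"])
    return {
        "discovery": disc,
        "validation_cutoff": cut_val,
        "validation_logrank_p": km_val["p"],
        "validation_cox": cox_val,
        "consistency": cutoff_consistency(
            score_disc, disc.chosen_cutoff, score_val, cut_val
        ),
    }
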