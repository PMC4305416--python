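"""Lymphocyte class discovery: univariate Gaussian mixtures on proximity values.

Lymphocytes pooled across tumours are clustered on their proximity-to-cancer
values s with a univariate Gaussian mixture fitted by
expectation–maximization.  The number of components is chosen by the
Bayesian information criterion in the higher-is-better convention

    BIC = 2·L − d·log N,        d = 3K − 1,

and the robustness of the chosen K is assessed by repeated subsampling.
The three recovered classes, ordered by decreasing mean proximity, are the
intratumour (ITL), adjacent-tumour (ATL) and distal-tumour (DTL)
lymphocytes.  Per-lymphocyte assignment uses the two crossing points of the
weighted component densities between adjacent means, which yields contiguous
intervals on s even with unequal variances; maximum-posterior assignment is
available as an option.

Everything here is scale-free: multiplying all s by a positive constant
shifts means, variances and thresholds consistently and leaves labels
unchanged.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

LYMPHOCYTE_CLASSES = ("ITL", "ATL", "DTL")  # decreasing proximity to cancer

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureModel:
    """A fitted univariate Gaussian mixture.

    Components are stored sorted by mean in *descending* order (ITL first
    when K = 3).  ``bic`` uses the higher-is-better convention
    ``2·loglik − d·log(n)`` with ``d = 3K − 1`` free parameters.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    n: int
    n_iter: int
    restarts: int
    seed: int | None
    loglik_trace: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def d(self) -> int:
        return 3 * self.k - 1

    @property
    def bic(self) -> float:
        return 2.0 * self.loglik - self.d * np.log(self.n)

    def logpdf_components(self, s: np.ndarray) -> np.ndarray:
        """(n, K) array of log w_k + log N(s; μ_k, σ_k²)."""
        s = np.asarray(s, dtype=float)[:, None]
        return (
            np.log(self.weights)[None, :]
            - 0.5 * (_LOG2PI + np.log(self.variances))[None, :]
            - 0.5 * (s - self.means[None, :]) ** 2 / self.variances[None, :]
        )

    def posteriors(self, s: np.ndarray) -> np.ndarray:
        lp = self.logpdf_components(s)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n": self.n,
            "n_iter": self.n_iter,
            "restarts": self.restarts,
            "seed": self.seed,
        }


class EMCollapseError(RuntimeError):
    """All EM restarts collapsed (a component weight vanished)."""


try:  # compiled EM inner loop; the numpy implementation below is the fallback
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _em_core(x, w0, mu0, var0, tol, max_iter, var_floor):  # pragma: no cover
        n = x.size
        k = w0.size
        w, mu, var = w0.copy(), mu0.copy(), var0.copy()
        lp = np.empty(k)
        nk = np.empty(k)
        s1 = np.empty(k)
        s2 = np.empty(k)
        trace = np.empty(max_iter)
        ll_old = -np.inf
        n_iter = 0
        for it in range(max_iter):
            logw = np.log(w)
            logv = np.log(var)
            for j in range(k):
                nk[j] = 0.0
                s1[j] = 0.0
                s2[j] = 0.0
            ll = 0.0
            for i in range(n):
                mx = -np.inf
                for j in range(k):
                    d = x[i] - mu[j]
                    lp[j] = logw[j] - 0.5 * (_LOG2PI + logv[j]) - 0.5 * d * d / var[j]
                    if lp[j] > mx:
                        mx = lp[j]
                tot = 0.0
                for j in range(k):
                    tot += np.exp(lp[j] - mx)
                lse = mx + np.log(tot)
                ll += lse
                for j in range(k):
                    r = np.exp(lp[j] - lse)
                    nk[j] += r
                    s1[j] += r * x[i]
                    s2[j] += r * x[i] * x[i]
            trace[it] = ll
            n_iter = it + 1
            if it > 0 and ll - ll_old <= tol * abs(ll_old):
                break
            ll_old = ll
            for j in range(k):
                if nk[j] < max(1e-10 * n, 1e-300):
                    return w, mu, var, ll, n_iter, trace[:n_iter], 1
                w[j] = nk[j] / n
                mu[j] = s1[j] / nk[j]
                v = s2[j] / nk[j] - mu[j] * mu[j]
                var[j] = v if v > var_floor else var_floor
        return w, mu, var, trace[n_iter - 1], n_iter, trace[:n_iter], 0

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _em_run(
    s: np.ndarray,
    mu0: np.ndarray,
    var0: np.ndarray,
    w0: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, np.ndarray] | None:
    """One EM run; returns None on component collapse."""
    if _HAVE_NUMBA:
        w, mu, var, ll, n_iter, trace, status = _em_core(
            s, w0.astype(float), mu0.astype(float), var0.astype(float),
            tol, max_iter, var_floor,
        )
        if status != 0:
            return None
        return w, mu, var, float(ll), int(n_iter), trace
    n = s.size
    k = mu0.size
    w, mu, var = w0.copy(), mu0.copy(), var0.copy()
    x = s[:, None]
    ll_old = -np.inf
    trace = []
    for it in range(max_iter):
        lp = (
            np.log(w)[None, :]
            - 0.5 * (_LOG2PI + np.log(var))[None, :]
            - 0.5 * (x - mu[None, :]) ** 2 / var[None, :]
        )
        lse = logsumexp(lp, axis=1)
        ll = float(lse.sum())
        trace.append(ll)
        if ll - ll_old <= tol * abs(ll_old) and it > 0:
            break
        ll_old = ll
        resp = np.exp(lp - lse[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < max(1e-10 * n, 1e-300)):
            return None  # collapse -> caller restarts
        w = nk / n
        mu = (resp * x).sum(axis=0) / nk
        var = (resp * (x - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
    return w, mu, var, ll, it + 1, np.asarray(trace)


def fit_gmm(
    s: np.ndarray,
    k: int,
    seed: int | None = None,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    var_floor_frac: float = 1e-12,
) -> MixtureModel:
    """EM fit of a K-component univariate Gaussian mixture to pooled s values.

    The best of ``restarts`` quantile-spread initializations is kept: the
    first restart seeds means at evenly spaced quantiles, the rest at sorted
    random quantile levels.  Each restart is first run briefly (30
    iterations at relaxed tolerance); only the best short run is polished to
    ``tol``, which matches the standard short-EM strategy for mixture fits.
    Convergence is a relative log-likelihood change below ``tol``; the
    log-likelihood trace is non-decreasing (EM ascent).

    Requires ``len(s) ≥ 10·(3K−1)`` observations.
    """
    s = np.asarray(s, dtype=float).ravel()
    n = s.size
    d = 3 * k - 1
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if n < 10 * d:
        raise ValueError(f"need at least {10 * d} observations for K={k}, got {n}")

    if k == 1:  # closed-form MLE
        mu = float(s.mean())
        var = float(s.var(ddof=0))
        if var <= 0:
            raise ValueError("zero-variance sample")
        ll = float(-0.5 * n * (_LOG2PI + np.log(var) + 1.0))
        return MixtureModel(
            1, np.array([1.0]), np.array([mu]), np.array([var]),
            ll, n, 1, 1, seed, np.array([ll]),
        )

    sample_var = float(s.var(ddof=0))
    if sample_var <= 0:
        raise ValueError("zero-variance sample")
    var_floor = var_floor_frac * sample_var
    rng = np.random.default_rng(seed)

    short = []
    for r in range(max(restarts, 1)):
        if r == 0:
            q = (np.arange(k) + 0.5) / k
        else:
            q = np.sort(rng.uniform(0.02, 0.98, size=k))
        mu0 = np.quantile(s, q)
        var0 = np.full(k, sample_var / k**2 + var_floor)
        w0 = np.full(k, 1.0 / k)
        res = _em_run(s, mu0, var0, w0, max(tol, 1e-6), 30, var_floor)
        if res is not None:
            short.append(res)
    if not short:
        raise EMCollapseError(f"all {restarts} EM restarts collapsed for K={k}")
    w, mu, var, ll, it0, trace0 = max(short, key=lambda r: r[3])
    res = _em_run(s, mu, var, w, tol, max_iter, var_floor)
    if res is None:
        # polishing collapsed; fall back to the best surviving short run
        res = (w, mu, var, ll, it0, trace0)
    w, mu, var, ll, n_iter, trace = res

    order = np.argsort(mu)[::-1]  # descending mean: ITL component first
    return MixtureModel(
        k, w[order], mu[order], var[order], ll, n,
        int(n_iter), restarts, seed, trace,
    )


@dataclass
class KSelection:
    """BIC-based choice of the number of mixture components."""

    best_k: int
    ks: np.ndarray
    bics: np.ndarray
    models: dict

    @property
    def best_model(self) -> MixtureModel:
        return self.models[self.best_k]


def select_k(
    s: np.ndarray,
    k_max: int = 5,
    seed: int | None = None,
    **fit_kwargs,
) -> KSelection:
    """Fit K = 1..k_max and return the BIC-argmax (higher BIC is better).

    BIC ties within 1e-6 resolve to the smaller K.
    """
    rng = np.random.default_rng(seed)
    models = {}
    for k in range(1, k_max + 1):
        child = int(rng.integers(0, 2**31 - 1))
        models[k] = fit_gmm(s, k, seed=child, **fit_kwargs)
    ks = np.arange(1, k_max + 1)
    bics = np.array([models[k].bic for k in ks])
    return KSelection(best_k_by_bic(ks, bics), ks, bics, models)


def best_k_by_bic(ks: np.ndarray, bics: np.ndarray, tol: float = 1e-6) -> int:
    """Argmax of BIC; ties within ``tol`` resolve to the smaller K."""
    best = 0
    for i in range(1, len(ks)):
        if bics[i] > bics[best] + tol:
            best = i
    return int(ks[best])


@dataclass
class StabilityReport:
    """Subsampling stability of the mixture solution.

    ``means_k3`` holds, per repetition, the K = 3 component means sorted
    ascending (DTL, ATL, ITL order, matching how cluster means are usually
    quoted).
    """

    best_k: np.ndarray  # (reps,)
    means_k3: np.ndarray  # (reps, 3), ascending
    modal_k: int
    frac_modal: float
    median_means: np.ndarray
    sd_means: np.ndarray

    def to_dict(self) -> dict:
        return {
            "modal_k": self.modal_k,
            "frac_modal": self.frac_modal,
            "best_k_counts": {int(k): int(v) for k, v in Counter(self.best_k).items()},
            "median_means": self.median_means.tolist(),
            "sd_means": self.sd_means.tolist(),
        }


def stability_analysis(
    pooled_s: np.ndarray,
    sample_size: int = 100_000,
    reps: int = 200,
    k_max: int = 5,
    seed: int | None = None,
    **fit_kwargs,
) -> StabilityReport:
    """Repeatedly subsample s (without replacement) and re-select K.

    Each repetition draws ``sample_size`` values, runs :func:`select_k` and
    records the winning K and the sorted means of the K = 3 fit.  Reports the
    modal K, the fraction of repetitions choosing it, and the median/s.d. of
    each sorted K = 3 mean across repetitions.
    """
    pooled_s = np.asarray(pooled_s, dtype=float).ravel()
    if sample_size > pooled_s.size:
        warnings.warn(
            f"sample_size {sample_size} exceeds pool size {pooled_s.size}; clipping",
            stacklevel=2,
        )
        sample_size = pooled_s.size
    rng = np.random.default_rng(seed)
    best_k = np.empty(reps, dtype=int)
    means_k3 = np.empty((reps, 3))
    for rep in range(reps):
        idx = rng.choice(pooled_s.size, size=sample_size, replace=False)
        child = int(rng.integers(0, 2**31 - 1))
        sel = select_k(pooled_s[idx], k_max=k_max, seed=child, **fit_kwargs)
        best_k[rep] = sel.best_k
        means_k3[rep] = np.sort(sel.models[3].means)
    modal_k, modal_n = Counter(best_k).most_common(1)[0]
    return StabilityReport(
        best_k=best_k,
        means_k3=means_k3,
        modal_k=int(modal_k),
        frac_modal=modal_n / reps,
        median_means=np.median(means_k3, axis=0),
        sd_means=means_k3.std(axis=0, ddof=1),
    )


# ---------------------------------------------------------------------------
# thresholds and assignment
# ---------------------------------------------------------------------------

def _crossing(wa, ma, va, wb, mb, vb) -> float | None:
    """Crossing point of two weighted normal densities between their means.

    Solves log(w_a·N(t; m_a, v_a)) = log(w_b·N(t; m_b, v_b)), a quadratic in
    t; returns the root strictly between the two means, or None.
    """
    lo, hi = sorted((ma, mb))
    A = 0.5 * (1.0 / vb - 1.0 / va)
    B = ma / va - mb / vb
    C = (
        np.log(wa) - np.log(wb)
        - 0.5 * np.log(va) + 0.5 * np.log(vb)
        - 0.5 * ma**2 / va + 0.5 * mb**2 / vb
    )
    if abs(A) < 1e-300:  # equal variances -> linear equation
        if abs(B) < 1e-300:
            return None
        t = -C / B
        return float(t) if lo < t < hi else None
    disc = B**2 - 4 * A * C
    if disc < 0:
        return None
    roots = ((-B + np.sqrt(disc)) / (2 * A), (-B - np.sqrt(disc)) / (2 * A))
    inside = [t for t in roots if lo < t < hi]
    return float(inside[0]) if inside else None


def class_thresholds(model: MixtureModel) -> tuple[float, float]:
    """Decision thresholds (t_low, t_high) from a K = 3 mixture.

    t_high separates ITL from ATL (crossing of the two top components'
    weighted densities between their means); t_low separates ATL from DTL.
    A pathological fit with no crossing falls back to the midpoint of the
    two means with a warning.  Always μ_DTL < t_low < μ_ATL < t_high < μ_ITL.
    """
    if model.k != 3:
        raise ValueError(f"thresholds require a 3-component model, got K={model.k}")
    m = np.sort(model.means)  # ascending: DTL, ATL, ITL
    order = np.argsort(model.means)
    w = model.weights[order]
    v = model.variances[order]
    ts = []
    for a, b in ((0, 1), (1, 2)):
        t = _crossing(w[a], m[a], v[a], w[b], m[b], v[b])
        if t is None:
            warnings.warn(
                "no density crossing between adjacent component means; "
                "falling back to the midpoint",
                stacklevel=2,
            )
            t = 0.5 * (m[a] + m[b])
        ts.append(t)
    return float(ts[0]), float(ts[1])


@dataclass
class ClassifiedLymphocytes:
    """ITL/ATL/DTL labels with the thresholds and mixture posteriors used."""

    labels: np.ndarray  # values in LYMPHOCYTE_CLASSES
    t_low: float
    t_high: float
    posteriors: np.ndarray | None = None  # (m, 3), columns ITL/ATL/DTL

    def counts(self) -> dict:
        return {c: int((self.labels == c).sum()) for c in LYMPHOCYTE_CLASSES}


def assign_classes(
    thresholds: tuple[float, float],
    s: np.ndarray,
    model: MixtureModel | None = None,
    method: str = "threshold",
) -> ClassifiedLymphocytes:
    """Label lymphocytes by their proximity values.

    ``threshold`` (default): s ≥ t_high → ITL; t_low ≤ s < t_high → ATL;
    s < t_low → DTL.  ``posterior``: maximum mixture posterior (requires
    ``model``); may produce non-contiguous regions with unequal variances.
    """
    s = np.asarray(s, dtype=float).ravel()
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds must satisfy t_low < t_high")
    if method == "threshold":
        labels = np.where(s >= t_high, "ITL", np.where(s >= t_low, "ATL", "DTL"))
    elif method == "posterior":
        if model is None:
            raise ValueError("posterior assignment requires the mixture model")
        post = model.posteriors(s)  # components sorted mean-descending = ITL,ATL,DTL
        labels = np.array(LYMPHOCYTE_CLASSES, dtype=object)[post.argmax(axis=1)]
    else:
        raise ValueError(f"unknown method {method!r}")
    post = model.posteriors(s) if model is not None else None
    return ClassifiedLymphocytes(np.asarray(labels, dtype=object), t_low, t_high, post)


def mixture_density(model: MixtureModel, s: np.ndarray) -> np.ndarray:
    """Mixture pdf Σ_k w_k·N(s; μ_k, σ_k²)."""
    s = np.asarray(s, dtype=float)
    return sum(
        w * norm.pdf(s, m, np.sqrt(v))
        for w, m, v in zip(model.weights, model.means, model.variances)
    )
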