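"""Mixed-effects discomfort models and rank-correlation machinery.

Ratings are ordinal 1–5 discomfort codes treated as numeric responses in
a Gaussian linear mixed model: image-level metrics enter as fixed
effects, observers as random effects (random intercept plus, by default,
a correlated random slope per covariate — observers differ considerably
in how strongly the metric drives their discomfort).  Models compared by
likelihood-ratio test are fitted by maximum likelihood, not REML.

Also provided: single-step (Tukey-style) multiplicity-adjusted pairwise
contrasts between levels of a factor, percentile-bootstrap Spearman
confidence intervals and correlation-difference tests, and the two-sample
Kolmogorov–Smirnov comparison of metric distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelFit",
    "LRTResult",
    "exclude_invariant_observers",
    "fit_discomfort_lmm",
    "fit_level_lmm",
    "likelihood_ratio_test",
    "tukey_level_contrasts",
    "spearman_bootstrap",
    "spearman_difference_test",
    "ks_two_sample",
]


@dataclass
class ModelFit:
    """Summary of a fitted linear mixed model.

    ``n_params`` counts fixed effects + free random-effect (co)variances +
    the residual variance, so that AIC = 2·n_params − 2·loglik holds as an
    identity.  ``fe_raw`` holds slopes rescaled back to raw covariate
    units when covariates were standardized before fitting."""

    fe_params: dict
    fe_conf_int: dict
    fe_raw: dict
    loglik: float
    aic: float
    bic: float
    n_params: int
    converged: bool
    singular: bool
    formula: str
    result: object = field(repr=False, default=None)
    scales: dict = field(default_factory=dict)


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def exclude_invariant_observers(table: pd.DataFrame):
    """Drop observers whose ratings show zero variance.

    A constant response across all images signals disengagement from the
    task; such observers carry no information about the covariate effect.
    Returns (filtered table, list of excluded observer ids)."""
    var = table.groupby("observer_id")["rating"].var(ddof=0)
    excluded = sorted(var.index[var == 0].tolist())
    kept = table[~table["observer_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def _count_params(res) -> int:
    k_fe = len(res.fe_params)
    q = res.k_re
    k_re_cov = q * (q + 1) // 2
    k_vc = getattr(res.model, "k_vc", 0)
    return k_fe + k_re_cov + k_vc + 1  # + residual variance


def _summarize(res, formula, fe_raw=None, scales=None) -> ModelFit:
    k = _count_params(res)
    ll = float(res.llf)
    n = res.model.nobs
    fe = {name: float(res.fe_params[name]) for name in res.fe_params.index}
    # t-based 95% CIs on group-count degrees of freedom: Wald z intervals
    # are anticonservative with a modest number of observers
    n_groups = res.model.n_groups
    tcrit = stats.t.ppf(0.975, max(n_groups - 1, 1))
    bse = res.bse_fe
    fe_ci = {
        name: (
            float(fe[name] - tcrit * bse[name]),
            float(fe[name] + tcrit * bse[name]),
        )
        for name in res.fe_params.index
    }
    cov_re = np.asarray(res.cov_re)
    singular = bool(cov_re.size and np.linalg.matrix_rank(
        cov_re, tol=1e-8) < cov_re.shape[0])
    return ModelFit(
        fe_params=fe,
        fe_conf_int=fe_ci,
        fe_raw=fe_raw or {},
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        bic=np.log(n) * k - 2.0 * ll,
        n_params=k,
        converged=bool(res.converged),
        singular=singular,
        formula=formula,
        result=res,
        scales=scales or {},
    )


def _fit_mixedlm(formula, data, groups, re_formula, vc_formula=None,
                 reml=False):
    """Fit a MixedLM, trying several optimizers and keeping the best
    log-likelihood (boundary-singular fits are prone to poor local
    optima)."""
    model = smf.mixedlm(
        formula, data, groups=data[groups], re_formula=re_formula,
        vc_formula=vc_formula,
    )
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        # intercept-only RE is well-behaved: first converged fit is enough;
        # random-slope models are prone to boundary local optima, so every
        # optimizer is tried and the best likelihood kept
        simple = re_formula in ("1", "~1") and not vc_formula
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=reml, method=method)
            except Exception:
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
            if simple and best is not None and best.converged:
                break
    if best is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    return best


def fit_discomfort_lmm(
    table: pd.DataFrame,
    fixed,
    random_slopes=True,
    standardize: bool = True,
    reml: bool = False,
) -> ModelFit:
    """Gaussian LMM of numeric ratings on image-level metric covariates.

    ``fixed`` lists covariate columns of ``table`` (constant within
    image).  Covariates are z-scored across images by default, with the
    raw-unit slopes also reported.  ``random_slopes`` adds a correlated
    per-observer random slope for each covariate (with one covariate the
    null-vs-full LRT then has 3 degrees of freedom: the fixed slope plus
    the slope variance and intercept–slope covariance); it may also be a
    list of covariate columns, so a null model can keep a covariate's
    random slope while dropping its fixed effect (the interior df = 1
    test of the fixed effect).  Fit is ML by default so that nested fits
    feed a likelihood-ratio test.  Singular random-effect covariances are
    flagged on the returned fit, not silenced."""
    fixed = list(fixed)
    if isinstance(random_slopes, (list, tuple)):
        slope_cols = list(random_slopes)
    else:
        slope_cols = fixed if random_slopes else []
    data = table.copy()
    n_obs = data["observer_id"].nunique()
    n_img = data["image_id"].nunique()
    if n_obs < 2 or n_img < 2:
        raise ValueError("need at least 2 observers and 2 images")
    scales = {}
    if standardize:
        per_image = data.drop_duplicates("image_id")
        for c in dict.fromkeys(fixed + slope_cols):
            mu = float(per_image[c].mean())
            sd = float(per_image[c].std(ddof=1))
            if sd == 0:
                raise ValueError(f"covariate {c!r} is constant across images")
            data[c] = (data[c] - mu) / sd
            scales[c] = (mu, sd)
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"rating ~ {rhs}"
    re_formula = ("~" + " + ".join(slope_cols)) if slope_cols else "1"
    res = _fit_mixedlm(formula, data, "observer_id", re_formula, reml=reml)
    n_params_override = None
    if slope_cols:
        # The random-intercept-only solution is a point of the full
        # parameter space (slope variances and covariances at 0).  If the
        # slope optimizer lands below it, that boundary point is the
        # better ML solution for the full model — use it, but keep the
        # full structure's parameter count.
        res0 = _fit_mixedlm(formula, data, "observer_id", "1", reml=reml)
        if res0.llf > res.llf + 1e-9:
            n_params_override = _count_params(res)
            res = res0
    fe_raw = {}
    for c in fixed:
        if c in scales:
            fe_raw[c] = float(res.fe_params[c]) / scales[c][1]
    fit = _summarize(res, formula, fe_raw=fe_raw, scales=scales)
    if n_params_override is not None:
        fit.n_params = n_params_override
        fit.aic = 2.0 * n_params_override - 2.0 * fit.loglik
        fit.bic = (np.log(res.model.nobs) * n_params_override
                   - 2.0 * fit.loglik)
        fit.singular = True
    if fit.singular:
        warnings.warn("singular random-effects covariance in LMM fit")
    return fit


def fit_level_lmm(
    table: pd.DataFrame,
    level_col: str = "level",
    baseline: str = "low",
    triple_col: str | None = None,
    reml: bool = False,
) -> ModelFit:
    """LMM with a categorical metric-level fixed effect (triple designs).

    Observer is the random grouping; when ``triple_col`` is given, a
    variance component for triple identity is added within observers."""
    formula = f"rating ~ C({level_col}, Treatment('{baseline}'))"
    vc = None
    if triple_col is not None:
        vc = {"triple": f"0 + C({triple_col})"}
    res = _fit_mixedlm(formula, table, "observer_id", "1", vc_formula=vc,
                       reml=reml)
    return _summarize(res, formula)


def likelihood_ratio_test(null: ModelFit, full: ModelFit) -> LRTResult:
    """χ² LRT between nested maximum-likelihood fits on the same data.

    chi2 = 2·(ℓ_full − ℓ_null), df = parameter-count difference.  A chi2
    within numerical noise of zero is clamped to 0; a clearly negative
    value signals non-nested models or a convergence failure and raises."""
    chi2 = 2.0 * (full.loglik - null.loglik)
    df = full.n_params - null.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than null")
    if chi2 < -1e-2:
        raise ValueError(
            f"negative LRT statistic ({chi2:.4g}): models not nested or "
            "fit did not converge"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(float(chi2), int(df), p)


def tukey_level_contrasts(fit: ModelFit, factor: str = "level") -> pd.DataFrame:
    """All pairwise level contrasts with single-step adjusted p-values.

    Contrast estimates and their covariance come from the fitted model's
    fixed-effect covariance; each adjusted p is
    1 − P(max_j |Z_j| ≤ |z_k|) under the joint normal distribution of the
    standardized contrasts (the Tukey single-step procedure for general
    parametric models)."""
    res = fit.result
    names = list(res.fe_params.index)
    prefix = f"C({factor}"
    level_params = [n for n in names if n.startswith(prefix)]
    if not level_params:
        raise ValueError(f"no fixed-effect terms for factor {factor!r}")

    def _label(n):  # "C(level, Treatment('low'))[T.high]" -> "high"
        return n.split("[T.")[-1].rstrip("]")

    import re

    m = re.search(r"Treatment\('([^']+)'\)", level_params[0])
    baseline = m.group(1) if m else "baseline"
    levels = [baseline] + [_label(n) for n in level_params]
    p = len(names)
    # rows of the fe coefficient vector giving each level's mean offset
    rows = {baseline: np.zeros(p)}
    for n in level_params:
        e = np.zeros(p)
        e[names.index(n)] = 1.0
        rows[_label(n)] = e
    pairs = [
        (a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]
    ]
    C = np.array([rows[b] - rows[a] for a, b in pairs])
    beta = np.asarray(res.fe_params)
    V = np.asarray(res.cov_params())[:p, :p]
    est = C @ beta
    cov = C @ V @ C.T
    se = np.sqrt(np.diag(cov))
    z = est / se
    R = cov / np.outer(se, se)
    R = 0.5 * (R + R.T)
    R += 1e-10 * np.eye(len(pairs))
    mvn = stats.multivariate_normal(mean=np.zeros(len(pairs)), cov=R,
                                    allow_singular=True)
    p_adj = []
    for zk in z:
        a = abs(float(zk))
        inside = float(mvn.cdf(np.full(len(pairs), a),
                               lower_limit=np.full(len(pairs), -a)))
        p_adj.append(min(max(1.0 - inside, 0.0), 1.0))
    return pd.DataFrame(
        {
            "contrast": [f"{b} - {a}" for a, b in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_adj": p_adj,
        }
    )


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def spearman_point(x, y) -> float:
    """Spearman ρ; NaN when either vector is entirely tied (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(_pearson_rows(_rank_rows(x), _rank_rows(y)))


def spearman_bootstrap(x, y, B: int = 10_000, seed: int = 0):
    """Spearman ρ with a percentile bootstrap 95% CI over paired resamples.

    Items (pairs) are resampled with replacement ``B`` times; resamples
    whose ρ is undefined (all ties) are ignored in the percentiles.
    Returns (rho, ci_lo, ci_hi); rho is NaN when undefined on the data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rho = spearman_point(x, y)
    if np.isnan(rho):
        return float("nan"), float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    rb = _pearson_rows(_rank_rows(x[idx]), _rank_rows(y[idx]))
    if np.all(np.isnan(rb)):
        return rho, float("nan"), float("nan")
    lo, hi = np.nanpercentile(rb, [2.5, 97.5])
    return rho, float(lo), float(hi)


def spearman_difference_test(x, y1, y2, B: int = 10_000, seed: int = 0):
    """Bootstrap test of ρ(x, y1) = ρ(x, y2) on the same items.

    The bootstrap distribution of ρ₁ − ρ₂ is built over paired resamples
    (the same items enter both correlations in each replicate); the
    two-sided p is the fraction of resamples on the far side of 0 from
    the observed difference, doubled and capped at 1."""
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d_hat = spearman_point(x, y1) - spearman_point(x, y2)
    if np.isnan(d_hat):
        return float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    xr = _rank_rows(x[idx])
    d_b = _pearson_rows(xr, _rank_rows(y1[idx])) - _pearson_rows(
        xr, _rank_rows(y2[idx])
    )
    d_b = d_b[~np.isnan(d_b)]
    if d_b.size == 0:
        return float("nan")
    if d_hat >= 0:
        frac = float(np.mean(d_b <= 0.0))
    else:
        frac = float(np.mean(d_b >= 0.0))
    return min(1.0, 2.0 * frac)


def ks_two_sample(a, b):
    """Two-sample Kolmogorov–Smirnov: D = sup |ECDF_a − ECDF_b| with the
    asymptotic two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
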