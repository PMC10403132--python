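"""Per-parameter polynomial regression with VIF pruning and BIC degree choice.

For each biochemical parameter the significant features from the Spearman
screen are taken, multicollinear ones removed by stepwise maximum-VIF
elimination (threshold 10, skipped for a single feature), the linearity of
the degree-1 fit diagnosed, and either a degree-1 model (linear diagnosis)
or the BIC-preferred of degrees {2, 3} fitted by ordinary least squares.
Model quality is summarized by R^2, adjusted R^2 and the overall F-test.

Linearity diagnosis follows the global-validation framework for linear
models: four directional statistics — residual skewness n*b1^2/6, residual
kurtosis n*(b2-3)^2/24, a score test for a nonlinear link function
(squared fitted values added to the design) and a score test for
heteroscedasticity against an observation-index trend — each asymptotically
chi-square with 1 df, summed into a global 4-df statistic; plus the
Durbin-Watson statistic for residual independence with a normal-
approximation p-value.  The relationship is called linear only when every
null is retained at the configured level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson

from .association import screen_pairs

__all__ = [
    "ModelConfig",
    "DiagnosisResult",
    "PolyModelFit",
    "vif_scores",
    "prune_multicollinear",
    "diagnose_linearity",
    "fit_polynomial",
    "select_degree",
    "model_parameter",
    "build_models",
]

VIF_THRESHOLD = 10.0


@dataclass(frozen=True)
class ModelConfig:
    """Thresholds of the screening-to-model pipeline."""

    rho_threshold: float = 0.5
    p_threshold: float = 0.05
    vif_threshold: float = VIF_THRESHOLD
    diagnosis_alpha: float = 0.05
    candidate_degrees: tuple = (2, 3)
    well_predicted_adj_r2: float = 0.5
    well_predicted_f_p: float = 0.05


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(X.shape[1])])


def vif_scores(design) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) for every feature.

    R^2_j comes from regressing feature j on all other features plus an
    intercept.  Exact collinearity yields +inf, never an exception.
    """
    X = _as_frame(design)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 features")
    if n <= p + 1:
        raise ValueError(f"VIF needs n > p + 1 (got n={n}, p={p})")
    out = {}
    arr = X.to_numpy(float)
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def prune_multicollinear(design, threshold: float = VIF_THRESHOLD):
    """Stepwise removal of the max-VIF feature while max VIF > threshold.

    Returns (retained feature names, removal log of (name, vif) tuples).
    With fewer than 2 features the diagnosis is skipped and the design is
    returned unchanged, mirroring the untested single-feature case.
    """
    X = _as_frame(design)
    removal_log: list[tuple[str, float]] = []
    cols = list(X.columns)
    if len(cols) < 2:
        return cols, removal_log
    while len(cols) >= 2:
        vifs = vif_scores(X[cols])
        # ties (e.g. several infinite VIFs) drop the last-listed feature, so
        # callers ordering columns by association strength lose the weakest
        worst = vifs.iloc[::-1].idxmax()
        if vifs[worst] <= threshold:
            break
        removal_log.append((worst, float(vifs[worst])))
        cols.remove(worst)
    return cols, removal_log


@dataclass(frozen=True)
class DiagnosisResult:
    """Linearity diagnosis of the degree-1 fit (all stats with p-values)."""

    global_stat: float
    global_p: float
    skewness_stat: float
    skewness_p: float
    kurtosis_stat: float
    kurtosis_p: float
    link_stat: float
    link_p: float
    hetero_stat: float
    hetero_p: float
    durbin_watson: float
    durbin_watson_p: float
    alpha: float
    is_linear: bool


def diagnose_linearity(X, y, alpha: float = 0.05) -> DiagnosisResult:
    """Directional chi-square(1) tests + Durbin-Watson on the degree-1 fit.

    ``is_linear`` is True only when all six null hypotheses (global,
    skewness, kurtosis, link, heteroscedasticity, residual independence)
    are retained at ``alpha``.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n - p - 1 < 4:
        raise ValueError(
            f"too few observations for residual diagnostics (n={n}, p={p})"
        )
    design = sm.add_constant(X.to_numpy(float))
    fit = sm.OLS(y, design).fit()
    e = fit.resid
    yhat = fit.fittedvalues
    sigma2 = float(np.mean(e**2))
    if sigma2 <= 0:
        raise ValueError("residuals are exactly zero; diagnostics undefined")

    m3 = float(np.mean(e**3))
    m4 = float(np.mean(e**4))
    b1 = m3 / sigma2**1.5
    b2 = m4 / sigma2**2
    skew_stat = n * b1**2 / 6.0
    kurt_stat = n * (b2 - 3.0) ** 2 / 24.0

    # link: score (LM) test for the squared fitted values added to the design
    u = yhat**2
    aug = np.column_stack([design, u])
    if np.linalg.matrix_rank(aug) > np.linalg.matrix_rank(design):
        aux = sm.OLS(e, aug).fit()
        link_stat = n * float(aux.rsquared)
    else:
        link_stat = 0.0

    # heteroscedasticity: score test of Var(e) against an index trend
    t_idx = (np.arange(n) + 1.0) / n
    v = t_idx - t_idx.mean()
    hetero_stat = float(np.sum(v * (e**2 - sigma2))) ** 2 / (
        2.0 * sigma2**2 * float(np.sum(v**2))
    )

    global_stat = skew_stat + kurt_stat + link_stat + hetero_stat

    dw = float(durbin_watson(e))
    r1 = 1.0 - dw / 2.0
    dw_p = 2.0 * stats.norm.sf(abs(r1) * np.sqrt(n))

    chi1 = stats.chi2(1)
    ps = {
        "skew": float(chi1.sf(skew_stat)),
        "kurt": float(chi1.sf(kurt_stat)),
        "link": float(chi1.sf(link_stat)),
        "hetero": float(chi1.sf(hetero_stat)),
        "global": float(stats.chi2(4).sf(global_stat)),
        "dw": float(dw_p),
    }
    is_linear = all(pv > alpha for pv in ps.values())
    return DiagnosisResult(
        global_stat=global_stat, global_p=ps["global"],
        skewness_stat=skew_stat, skewness_p=ps["skew"],
        kurtosis_stat=kurt_stat, kurtosis_p=ps["kurt"],
        link_stat=link_stat, link_p=ps["link"],
        hetero_stat=hetero_stat, hetero_p=ps["hetero"],
        durbin_watson=dw, durbin_watson_p=ps["dw"],
        alpha=alpha, is_linear=is_linear,
    )


@dataclass(frozen=True)
class PolyModelFit:
    """A fitted per-parameter polynomial regression and its quality scores.

    ``bic`` is ln(n)*k − 2*lnL̂ with k counting all regression coefficients
    (including the intercept) plus the error variance, and lnL̂ the Gaussian
    log-likelihood at its maximum.  ``adj_r2`` applies the usual
    1 − (1−R²)(n−1)/(n−p−1) penalty with p the number of power terms.
    """

    parameter_name: str
    retained_features: tuple
    degree: int
    coefficients: pd.Series
    n: int
    k: int
    log_likelihood: float
    bic: float
    r2: float
    adj_r2: float
    f_pvalue: float


def _poly_design(X: pd.DataFrame, degree: int) -> pd.DataFrame:
    cols = {}
    for name in X.columns:
        x = X[name].to_numpy(float)
        for d in range(1, degree + 1):
            cols[name if d == 1 else f"{name}^{d}"] = x**d
    return pd.DataFrame(cols, index=X.index)


def fit_polynomial(X, y, degree: int, parameter_name: str = "") -> PolyModelFit:
    """OLS on per-feature power terms 1..degree plus an intercept.

    No cross-feature interaction terms are included.  A design left singular
    by the power expansion is rejected with the offending feature named.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    poly = _poly_design(X, degree)
    n, n_terms = poly.shape
    if n <= n_terms + 1:
        raise ValueError(
            f"need n > number of coefficients ({n_terms + 1}), got n={n}"
        )
    design = sm.add_constant(poly.to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for name in X.columns:
            sub = sm.add_constant(_poly_design(X[[name]], degree).to_numpy(float))
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise ValueError(
                    f"power expansion of feature {name!r} is singular at degree {degree}"
                )
        raise ValueError(
            f"singular design after power expansion of {list(X.columns)}"
        )
    fit = sm.OLS(y, design).fit()
    k = design.shape[1] + 1  # coefficients + error variance
    with np.errstate(divide="ignore"):
        llf = float(fit.llf)
    bic = np.log(n) * k - 2.0 * llf
    names = ["const"] + list(poly.columns)
    return PolyModelFit(
        parameter_name=parameter_name,
        retained_features=tuple(X.columns),
        degree=int(degree),
        coefficients=pd.Series(fit.params, index=names),
        n=int(n),
        k=int(k),
        log_likelihood=llf,
        bic=float(bic),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else np.nan,
    )


def select_degree(X, y, diagnosis: DiagnosisResult,
                  candidate_degrees=(2, 3)) -> int:
    """Degree 1 for a linear diagnosis, else the BIC-minimizing candidate.

    Ties are broken toward the lower degree.  Candidates whose power
    expansion holds more coefficients than the sample supports are dropped;
    if no candidate is feasible the degree falls back to 1.
    """
    if diagnosis.is_linear:
        return 1
    X = _as_frame(X)
    n, p = X.shape
    degrees = [d for d in sorted(candidate_degrees) if n > d * p + 1]
    if not degrees:
        return 1
    bics = [fit_polynomial(X, y, d).bic for d in degrees]
    return int(degrees[int(np.argmin(bics))])


def model_parameter(features: pd.DataFrame, panel: pd.DataFrame,
                    parameter_name: str, config: ModelConfig | None = None):
    """Full screen -> prune -> diagnose -> select -> fit for one parameter.

    Returns (PolyModelFit or None, provenance dict).  Parameters with no
    significant feature, or too few complete observations, are left
    unmodelled with the reason recorded; a single significant feature skips
    the multicollinearity stage (logged as "NA").
    """
    cfg = config or ModelConfig()
    if parameter_name not in panel.columns:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    prov: dict = {"parameter": parameter_name}

    screen = screen_pairs(
        features, panel[[parameter_name]],
        rho_threshold=cfg.rho_threshold, p_threshold=cfg.p_threshold,
    )
    prov["n_tests"] = screen.attrs["n_tests"]
    sig_rows = screen.loc[screen["significant"]].copy()
    # rank by association strength (name-alphabetical on exact ties)
    sig_rows = sig_rows.sort_values(
        ["rho", "feature"], key=lambda s: -s.abs() if s.name == "rho" else s
    )
    sig = sig_rows["feature"].tolist()
    prov["significant_features"] = sig
    if not sig:
        prov["reason"] = "no significantly associated features"
        return None, prov

    common = features.index.intersection(panel.index)
    data = features.loc[common, sig].join(panel.loc[common, [parameter_name]])
    data = data.dropna()
    y = data[parameter_name].to_numpy(float)
    prov["n"] = len(data)
    # the VIF regressions need n > p + 1; keep the strongest-associated
    # features when more are significant than the cohort can support
    cap = max(1, len(data) - 2)
    if len(sig) > cap:
        prov["capped_to"] = cap
        sig = sig[:cap]
    X = data[sig]

    if len(sig) < 2:
        retained, removal_log = list(sig), []
        prov["vif"] = "NA"
    else:
        try:
            retained, removal_log = prune_multicollinear(X, cfg.vif_threshold)
        except ValueError as exc:
            prov["reason"] = f"multicollinearity stage failed: {exc}"
            return None, prov
        prov["vif"] = "tested"
    prov["removed_features"] = [name for name, _ in removal_log]
    prov["removal_log"] = removal_log
    # residual diagnostics need n - p - 1 >= 4; keep the strongest features
    post_cap = max(1, len(data) - 5)
    if len(retained) > post_cap:
        prov["capped_after_prune"] = post_cap
        retained = retained[:post_cap]
    prov["retained_features"] = retained

    try:
        diagnosis = diagnose_linearity(X[retained], y, cfg.diagnosis_alpha)
        degree = select_degree(X[retained], y, diagnosis, cfg.candidate_degrees)
        fit = fit_polynomial(X[retained], y, degree, parameter_name)
    except ValueError as exc:
        prov["reason"] = f"insufficient data for model fitting: {exc}"
        return None, prov
    prov["diagnosis"] = diagnosis
    prov["is_linear"] = diagnosis.is_linear
    prov["degree"] = degree
    prov["well_predicted"] = bool(
        fit.adj_r2 > cfg.well_predicted_adj_r2
        and np.isfinite(fit.f_pvalue)
        and fit.f_pvalue < cfg.well_predicted_f_p
    )
    return fit, prov


def build_models(features: pd.DataFrame, panel: pd.DataFrame,
                 config: ModelConfig | None = None) -> pd.DataFrame:
    """Model every panel parameter; one summary row each (modelled or not)."""
    cfg = config or ModelConfig()
    rows = []
    for pname in panel.columns:
        fit, prov = model_parameter(features, panel, pname, cfg)
        row = {
            "parameter": pname,
            "modelled": fit is not None,
            "reason": prov.get("reason", ""),
            "significant_features": ";".join(prov.get("significant_features", [])),
            "vif_stage": prov.get("vif", "NA"),
            "removed_features": ";".join(prov.get("removed_features", [])),
            "retained_features": ";".join(prov.get("retained_features", [])),
        }
        if fit is not None:
            row.update(
                is_linear=prov["is_linear"], degree=fit.degree, n=fit.n,
                r2=fit.r2, adj_r2=fit.adj_r2, f_pvalue=fit.f_pvalue,
                bic=fit.bic, well_predicted=prov["well_predicted"],
                coefficients=";".join(
                    f"{t}={v:.10g}" for t, v in fit.coefficients.items()
                ),
            )
        else:
            row.update(
                is_linear=pd.NA, degree=pd.NA, n=pd.NA, r2=np.nan,
                adj_r2=np.nan, f_pvalue=np.nan, bic=np.nan,
                well_predicted=False, coefficients="",
            )
        rows.append(row)
    return pd.DataFrame(rows)
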