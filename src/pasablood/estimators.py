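"""scikit-learn estimator interfaces over the extraction and modeling layers.

``PulseFeatureExtractor`` is a stateless transformer turning a matrix of
replicate-averaged raw traces (one row per subject) into the 31 named
time/frequency features; ``PolynomialBICRegressor`` is a regressor running
the VIF-prune -> linearity-diagnosis -> BIC-degree -> OLS pipeline.  Both
compose with sklearn pipelines and model selection; the functional API in
the sibling modules remains the thin route for script use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .freq_features import FEATURE_NAMES, FeatureConfig, extract_all_features
from .modeling import (
    ModelConfig,
    diagnose_linearity,
    fit_polynomial,
    prune_multicollinear,
    select_degree,
    _as_frame,
    _poly_design,
)
from .prep import AveragedSignal, SignalTrace, select_steady_state, shift_baseline

__all__ = ["PulseFeatureExtractor", "PolynomialBICRegressor"]


class PulseFeatureExtractor(TransformerMixin, BaseEstimator):
    """Extract the 31 pulse features from rows of raw averaged traces.

    Parameters
    ----------
    dt : float
        Sampling interval in ms (default 0.002, i.e. 2500 samples / 5 ms).
    discard_ms : float
        Leading trigger-jitter window excluded from analysis.
    welch_divisor, prominence_threshold_db, sampling_rate_mode, changepoint_k :
        Forwarded to the feature configuration (see ``FeatureConfig``).
    modality : str
        Tag attached to the traces ("PA" or "AS"); affects labeling only.

    ``transform`` accepts an (n_subjects, n_samples) array of raw
    replicate-averaged traces, applies the baseline shift and steady-state
    selection per row, and returns an (n_subjects, 31) DataFrame.  Missing
    peak features are NaN.
    """

    def __init__(self, dt: float = 0.002, discard_ms: float = 0.5,
                 welch_divisor: int = 8, prominence_threshold_db: float = 10.0,
                 sampling_rate_mode: str = "paper_dims", changepoint_k: int = 10,
                 modality: str = "PA"):
        self.dt = dt
        self.discard_ms = discard_ms
        self.welch_divisor = welch_divisor
        self.prominence_threshold_db = prominence_threshold_db
        self.sampling_rate_mode = sampling_rate_mode
        self.changepoint_k = changepoint_k
        self.modality = modality

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            welch_divisor=self.welch_divisor,
            prominence_threshold_db=self.prominence_threshold_db,
            sampling_rate_mode=self.sampling_rate_mode,
            changepoint_k=self.changepoint_k,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D: one averaged trace per row")
        self.n_features_in_ = X.shape[1]
        self.feature_names_out_ = np.asarray(FEATURE_NAMES, dtype=object)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        index = None
        cfg = self._config()
        t = np.arange(X.shape[1]) * self.dt
        rows = []
        for y in X:
            trace = shift_baseline(
                SignalTrace(t=t, y=y, dt=self.dt, modality=self.modality)
            )
            avg = select_steady_state(
                AveragedSignal(trace=trace, n_replicates=1),
                discard_ms=self.discard_ms,
            )
            rows.append(extract_all_features(avg, cfg))
        return pd.DataFrame(rows, index=index).reset_index(drop=True)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return self.feature_names_out_


class PolynomialBICRegressor(RegressorMixin, BaseEstimator):
    """Polynomial regression with VIF pruning and diagnosis-driven degree.

    fit(X, y) removes multicollinear columns by stepwise max-VIF elimination
    (``vif_threshold``, skipped for a single column), diagnoses linearity of
    the degree-1 fit at ``alpha``, fixes degree 1 when linear and otherwise
    picks the BIC-minimizing degree among ``candidate_degrees``, then fits
    OLS on per-feature power terms (no interactions).

    Fitted attributes: ``retained_features_``, ``removal_log_``,
    ``diagnosis_``, ``degree_``, ``result_`` (the full fit record),
    ``coef_``, ``intercept_``, ``bic_``, ``r2_``, ``adj_r2_``,
    ``f_pvalue_``.
    """

    def __init__(self, vif_threshold: float = 10.0, alpha: float = 0.05,
                 candidate_degrees=(2, 3), prune: bool = True):
        self.vif_threshold = vif_threshold
        self.alpha = alpha
        self.candidate_degrees = candidate_degrees
        self.prune = prune

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)

        if self.prune and X.shape[1] >= 2:
            retained, log = prune_multicollinear(X, self.vif_threshold)
        else:
            retained, log = list(X.columns), []
        self.retained_features_ = tuple(retained)
        self.removal_log_ = tuple(log)

        Xr = X[retained]
        self.diagnosis_ = diagnose_linearity(Xr, y, self.alpha)
        self.degree_ = select_degree(Xr, y, self.diagnosis_, self.candidate_degrees)
        self.result_ = fit_polynomial(Xr, y, self.degree_)
        coefs = self.result_.coefficients
        self.intercept_ = float(coefs["const"])
        self.coef_ = coefs.drop("const").to_numpy()
        self.bic_ = self.result_.bic
        self.r2_ = self.result_.r2
        self.adj_r2_ = self.result_.adj_r2
        self.f_pvalue_ = self.result_.f_pvalue
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = _as_frame(X)
        if list(X.columns) == [f"x{i + 1}" for i in range(X.shape[1])] and (
            list(self.feature_names_in_) != list(X.columns)
        ):
            # plain array input: columns positionally match the fit-time ones
            X = X.set_axis(list(self.feature_names_in_), axis=1)
        poly = _poly_design(X[list(self.retained_features_)], self.degree_)
        return self.intercept_ + poly.to_numpy(float) @ self.coef_
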