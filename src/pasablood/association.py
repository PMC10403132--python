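"""Spearman association screening between imaging features and blood chemistry.

Each (feature, parameter) pair is scored by Spearman's rank correlation with
a two-sided p-value from the t approximation; a pair is called significant
when |rho| > 0.5 and p <= 0.05.  Pairs with fewer than 4 complete
observations or a constant variable are reported as untested rather than
failing the whole screen.  No multiple-testing correction is applied in the
headline screen (the number of tests is annotated instead); Benjamini-
Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spearman_with_p", "screen_pairs"]

RHO_THRESHOLD = 0.5
P_THRESHOLD = 0.05
MIN_PAIRS = 4


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided t-approximation p-value.

    Missing values are dropped pairwise.  rho is the Pearson correlation of
    mid-ranks (ties get average ranks); p comes from
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom, so |rho| = 1
    gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in ranks; correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def screen_pairs(
    features: pd.DataFrame,
    panel: pd.DataFrame,
    rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Score every (feature, parameter) pair on the shared subjects.

    Both tables must be indexed by subject id.  Returns a long-format frame
    with columns feature, parameter, n, rho, p_value, tested, significant;
    untested pairs (too few complete pairs, constant values) carry NaN
    statistics and are never significant.  ``adjust="fdr_bh"`` replaces raw
    p-values by Benjamini-Hochberg adjusted ones before thresholding.
    """
    common = features.index.intersection(panel.index)
    if len(common) == 0:
        raise ValueError("features and panel share no subjects")
    feats = features.loc[common]
    pan = panel.loc[common]

    rows = []
    for pname in pan.columns:
        for fname in feats.columns:
            x = feats[fname].to_numpy(float)
            y = pan[pname].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            try:
                rho, p = spearman_with_p(x, y)
                tested = True
            except ValueError:
                rho, p, tested = np.nan, np.nan, False
            rows.append(
                {"feature": fname, "parameter": pname, "n": n,
                 "rho": rho, "p_value": p, "tested": tested}
            )
    out = pd.DataFrame(rows)

    p_eff = out["p_value"].copy()
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        tested_mask = out["tested"].to_numpy()
        adj = np.full(len(out), np.nan)
        if tested_mask.any():
            adj[tested_mask] = multipletests(
                out.loc[tested_mask, "p_value"], method=adjust
            )[1]
        p_eff = pd.Series(adj, index=out.index)
    out["significant"] = (
        out["tested"]
        & (out["rho"].abs() > rho_threshold)
        & (p_eff <= p_threshold)
    )
    out.attrs["n_tests"] = int(out["tested"].sum())
    return out
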