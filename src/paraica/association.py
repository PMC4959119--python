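"""Loading-coefficient statistics: partial correlations between all
gene/brain component pairs with Bonferroni control, group-difference and
variance-equality tests, and exploratory clinical correlations.

The main pair test residualizes both loading columns on an intercept plus
covariates (age, sex, two ancestry eigenvectors, group), correlates the
residuals, and refers t = r sqrt(df / (1 - r^2)) with df = n - 2 - q to
the t distribution (two-tailed).  With 14 genetic and 9 brain components
the Bonferroni threshold is 0.05 / 126.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "partial_correlation",
    "test_all_pairs",
    "group_difference_tests",
    "clinical_correlations",
    "PairTestTable",
]


def _residualize(v: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    n = v.shape[0]
    design = np.ones((n, 1)) if Z is None or Z.size == 0 else np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, float, int, float]:
    """Partial Pearson correlation of x and y controlling for Z.

    Returns ``(r, t, df, p)`` with df = n - 2 - q (q = number of covariate
    columns) and two-tailed p from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.shape[0]
    Zm = None if Z is None or np.size(Z) == 0 else np.asarray(Z, dtype=float).reshape(n, -1)
    q = 0 if Zm is None else Zm.shape[1]
    df = n - 2 - q
    if df <= 0:
        raise ValueError(f"nonpositive degrees of freedom ({df})")
    rx = _residualize(x, Zm)
    ry = _residualize(y, Zm)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    tol_x = 1e-10 * max(np.linalg.norm(x), 1.0)
    tol_y = 1e-10 * max(np.linalg.norm(y), 1.0)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance after removing covariates")
    r = float(rx @ ry / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, np.inf * np.sign(r), df, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(t), int(df), float(p)


@dataclass
class PairTestTable:
    table: pd.DataFrame  # gene, brain, r, t, df, p, significant
    threshold: float
    alpha: float

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)


def test_all_pairs(
    gene_loadings: np.ndarray,
    brain_loadings: np.ndarray,
    Z: np.ndarray | None,
    alpha: float = 0.05,
) -> PairTestTable:
    """Partial correlation of every (gene, brain) loading pair.

    The family-wise threshold is alpha / (K_gene * K_brain); pairs below it
    are flagged significant.  A pair whose test fails (e.g. degenerate
    loadings) is marked invalid (NaN statistics) rather than aborting.
    """
    G = np.asarray(gene_loadings, dtype=float)
    B = np.asarray(brain_loadings, dtype=float)
    if G.shape[0] != B.shape[0]:
        raise ValueError("loading matrices must share subjects")
    kg, kb = G.shape[1], B.shape[1]
    threshold = alpha / (kg * kb)
    rows = []
    for i in range(kg):
        for j in range(kb):
            try:
                r, t, df, p = partial_correlation(G[:, i], B[:, j], Z)
                rows.append({"gene": i, "brain": j, "r": r, "t": t, "df": df,
                             "p": p, "significant": p < threshold, "valid": True})
            except ValueError:
                rows.append({"gene": i, "brain": j, "r": np.nan, "t": np.nan,
                             "df": np.nan, "p": np.nan, "significant": False, "valid": False})
    return PairTestTable(table=pd.DataFrame(rows), threshold=threshold, alpha=alpha)


def group_difference_tests(loadings: np.ndarray, group: np.ndarray) -> pd.DataFrame:
    """Pooled-variance t-test and Levene's test per loading column.

    Levene's test uses the mean as the center (the classic form).  Group
    means are reported so bar plots of loading coefficients by diagnosis
    can be reproduced.
    """
    L = np.asarray(loadings, dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    a_idx, b_idx = g == levels[0], g == levels[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for k in range(L.shape[1]):
        a, b = L[a_idx, k], L[b_idx, k]
        if np.array_equal(a, b):
            t, p, w, lp = 0.0, 1.0, 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            w, lp = stats.levene(a, b, center="mean")
        rows.append({
            "component": k, "t": float(t), "p": float(p),
            "levene_W": float(w), "levene_p": float(lp),
            f"mean_group{levels[0]}": float(a.mean()),
            f"mean_group{levels[1]}": float(b.mean()),
        })
    return pd.DataFrame(rows)


def clinical_correlations(
    loadings: np.ndarray,
    clinical_scores: pd.DataFrame,
    Z_age_sex: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exploratory partial correlations of clinical scores with loadings.

    Controls for age and sex only; analysis is pairwise-complete over
    missing scores with the per-pair n reported.  P-values are uncorrected
    (flagged ``exploratory``); a ``bonferroni_survives`` column reports
    what would survive correction over the whole table.
    """
    L = np.asarray(loadings, dtype=float)
    Z = np.asarray(Z_age_sex, dtype=float).reshape(L.shape[0], -1)
    rows = []
    for score_name in clinical_scores.columns:
        s = clinical_scores[score_name].to_numpy(dtype=float)
        ok = ~np.isnan(s)
        for k in range(L.shape[1]):
            n_pair = int(ok.sum())
            if n_pair - 2 - Z.shape[1] <= 0:
                import warnings

                warnings.warn(f"score {score_name} x component {k}: too few complete pairs; skipped")
                continue
            r, t, df, p = partial_correlation(s[ok], L[ok, k], Z[ok])
            rows.append({"score": score_name, "component": k, "n": n_pair,
                         "r": r, "p_uncorrected": p, "exploratory": True})
    df_out = pd.DataFrame(rows)
    if len(df_out):
        m = len(df_out)
        df_out["bonferroni_survives"] = df_out["p_uncorrected"] < alpha / m
        df_out["significant_uncorrected"] = df_out["p_uncorrected"] < alpha
    return df_out
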