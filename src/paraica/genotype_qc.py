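"""SNP preprocessing: variant QC, LD pruning, stratification PCA, prefilter.

The chain mirrors standard exome-array practice: per-variant filters
(call rate, minor-allele frequency, Hardy-Weinberg exact test in controls),
greedy windowed LD pruning, EIGENSTRAT-style principal components of the
normalized dosage matrix, removal of ancestry axes by regression, and a
liberal per-SNP logistic pre-filter (uncorrected p < 0.1) that selects the
markers entering the fusion step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, expit

from .datatypes import GenotypeMatrix

__all__ = [
    "QcReport",
    "filter_variants",
    "hwe_exact_test",
    "ld_prune",
    "eigenstrat_pca",
    "select_ancestry_axes",
    "regress_out_covariates",
    "logistic_prefilter",
    "snp_maf",
    "mean_impute",
]


@dataclass
class QcReport:
    n_input: int
    removed: dict = field(default_factory=dict)  # filter name -> count
    retained_ids: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def __post_init__(self) -> None:
        if self.removed and sum(self.removed.values()) + self.n_retained != self.n_input:
            raise ValueError("removed + retained != input count")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


def snp_maf(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP minor-allele frequency from {0,1,2} dosages (NaN-aware)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1 - p)


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-SNP mean (fusion needs complete data)."""
    out = dosages.copy()
    means = np.nanmean(out, axis=0)
    idx = np.nonzero(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on one SNP's genotype counts.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed
    one (no mid-p correction).  Returns a p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype counts")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom_alt + n_het  # minor-or-major: symmetric in the formula
    rare = min(n_a, 2 * n - n_a)
    # support: het counts with the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.nonzero(hets == n_het)[0][0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def filter_variants(
    G: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply call-rate, MAF, and control-group HWE filters in that order.

    HWE is tested in the control subjects only (``group == 0``) when a
    ``group`` column is available, otherwise in everyone.
    """
    for name, thr in [("min_call_rate", min_call_rate), ("min_maf", min_maf), ("hwe_alpha", hwe_alpha)]:
        if not 0 < thr < 1:
            raise ValueError(f"{name} must be in (0,1), got {thr}")
    d = G.dosages
    n_input = G.n_snps
    keep = np.ones(n_input, dtype=bool)
    removed: dict[str, int] = {}

    call_rate = 1.0 - np.isnan(d).mean(axis=0)
    fail = keep & (call_rate < min_call_rate)
    removed["call_rate"] = int(fail.sum())
    keep &= ~fail
    if not keep.any():
        raise ValueError("call-rate filter removed every SNP")

    maf = snp_maf(d)
    fail = keep & (maf < min_maf)
    removed["maf"] = int(fail.sum())
    keep &= ~fail
    if not keep.any():
        raise ValueError("MAF filter removed every SNP")

    if "group" in G.sample_records:
        ctrl = G.sample_records["group"].to_numpy() == 0
    else:
        ctrl = np.ones(G.n_subjects, dtype=bool)
    hwe_fail = np.zeros(n_input, dtype=bool)
    for j in np.flatnonzero(keep):
        col = d[ctrl, j]
        col = col[~np.isnan(col)]
        counts = [(col == g).sum() for g in (0, 1, 2)]
        if sum(counts) == 0:
            continue
        if hwe_exact_test(*counts) < hwe_alpha:
            hwe_fail[j] = True
    removed["hwe"] = int(hwe_fail.sum())
    keep &= ~hwe_fail
    if not keep.any():
        raise ValueError("HWE filter removed every SNP")

    out = G.subset_snps(keep)
    report = QcReport(
        n_input=n_input,
        removed=removed,
        retained_ids=out.snp_records["snp_id"].tolist(),
        thresholds={
            "min_call_rate": min_call_rate,
            "min_maf": min_maf,
            "hwe_alpha": hwe_alpha,
        },
    )
    return out, report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return 0.0
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


def ld_prune(
    G: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.7,
) -> list[str]:
    """Greedy windowed LD pruning; returns retained SNP ids.

    Within each sliding window (advanced ``step_snps`` at a time per
    chromosome) any retained pair with squared dosage correlation above
    ``r2_max`` is broken by removing the lower-MAF member (tie: the
    later-positioned SNP).
    """
    if window_snps < 2:
        raise ValueError("window must span at least 2 SNPs")
    d = G.dosages
    maf = snp_maf(d)
    keep = np.ones(G.n_snps, dtype=bool)
    chroms = G.snp_records["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < idx.size:
            window = idx[start : start + window_snps]
            active = [j for j in window if keep[j]]
            changed = True
            while changed:
                changed = False
                for a_i in range(len(active)):
                    for b_i in range(a_i + 1, len(active)):
                        a, b = active[a_i], active[b_i]
                        if not (keep[a] and keep[b]):
                            continue
                        if _pairwise_r2(d[:, a], d[:, b]) > r2_max:
                            # drop lower MAF; ties drop the later position
                            drop = a if maf[a] < maf[b] else b if maf[b] < maf[a] else max(a, b)
                            keep[drop] = False
                            changed = True
                active = [j for j in active if keep[j]]
            if start + window_snps >= idx.size:
                break
            start += step_snps
    return G.snp_records.loc[keep, "snp_id"].tolist()


def eigenstrat_pca(G: GenotypeMatrix | np.ndarray, n_axes: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the EIGENSTRAT-normalized dosage matrix.

    Each SNP column is centered by twice the smoothed allele-frequency
    estimate p = (1 + allele count) / (2 + 2n) and scaled by
    sqrt(p (1 - p)); the eigendecomposition of the subject x subject
    covariance of the normalized matrix gives unit-norm eigenvectors and
    descending eigenvalues.
    """
    d = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    d = mean_impute(d)
    n = d.shape[0]
    counts = d.sum(axis=0)
    p_hat = (1.0 + counts) / (2.0 + 2.0 * n)
    if np.any(d.std(axis=0) == 0):
        bad = int(np.flatnonzero(d.std(axis=0) == 0)[0])
        raise ValueError(f"monomorphic SNP column {bad} has zero variance after normalization")
    X = (d - 2.0 * p_hat) / np.sqrt(p_hat * (1.0 - p_hat))
    cov = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_axes]
    return evecs[:, order], evals[order]


def select_ancestry_axes(
    eigenvectors: np.ndarray,
    ethnicity_labels: np.ndarray | pd.Series,
    n_keep: int = 2,
    alpha: float = 0.05,
) -> list[int]:
    """Axes significantly associated with self-reported ethnicity.

    One-way ANOVA of each axis against the labels; returns up to ``n_keep``
    axis indices ordered by ascending p among those with p < alpha.
    """
    labels = np.asarray(ethnicity_labels)
    levels = pd.unique(labels)
    if len(levels) < 2:
        warnings.warn("single ethnicity level: no ancestry axes selectable")
        return []
    if eigenvectors.shape[1] < n_keep:
        raise ValueError(f"only {eigenvectors.shape[1]} axes available, need {n_keep}")
    pvals = []
    for k in range(eigenvectors.shape[1]):
        groups = [eigenvectors[labels == lv, k] for lv in levels]
        pvals.append(stats.f_oneway(*groups).pvalue)
    pvals = np.asarray(pvals)
    qualifying = np.flatnonzero(pvals < alpha)
    order = qualifying[np.argsort(pvals[qualifying])]
    return [int(k) for k in order[:n_keep]]


def regress_out_covariates(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize every column of M on [intercept, covariates].

    Fails loudly on rank-deficient covariates, naming the collinear columns.
    """
    M = np.asarray(M, dtype=float)
    Z = np.column_stack([np.ones(M.shape[0]), np.asarray(covariates, dtype=float)])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        _, r = np.linalg.qr(Z)
        dep = [int(j) - 1 for j in range(Z.shape[1]) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise ValueError(f"rank-deficient covariates (collinear columns {dep})")
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Penalized (Firth) logistic fit; returns (beta, cov) or None."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(np.clip(eta, -30, 30))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None
        h = np.einsum("ij,jk,ik->i", X, info_inv, XtW.T)
        # score with Jeffreys-prior penalty
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            eta = X @ beta
            mu = expit(np.clip(eta, -30, 30))
            w = mu * (1 - mu)
            try:
                cov = np.linalg.inv((X.T * w) @ X)
            except np.linalg.LinAlgError:
                return None
            return beta, cov
    return None


def logistic_prefilter(
    G_resid: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray,
    alpha: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression of group on [dosage, covariates].

    Returns ``(retained_idx, pvalues, flags)`` where ``flags`` marks SNPs
    excluded for zero variance, non-convergence, or separation (those get
    p = NaN and are never retained).  Retention is strict: p < alpha.

    Non-convergent or separated fits fall back to a Firth-penalized fit;
    SNPs still unstable after that are excluded and flagged.
    """
    import statsmodels.api as sm

    G_resid = np.asarray(G_resid, dtype=float)
    y = np.asarray(group, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("group must be binary 0/1")
    n, m = G_resid.shape
    Z = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    pvals = np.full(m, np.nan)
    flags = np.zeros(m, dtype=bool)
    for j in range(m):
        x = G_resid[:, j]
        if np.nanstd(x) == 0:
            flags[j] = True
            warnings.warn(f"SNP column {j} is constant; excluded from prefilter")
            continue
        xj = np.where(np.isnan(x), np.nanmean(x), x)
        design = np.column_stack([xj, Z])
        ok = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
                se = np.sqrt(np.diag(fit.cov_params()))[0]
                if fit.mle_retvals.get("converged", False) and np.isfinite(se) and se < 50:
                    pvals[j] = fit.pvalues[0]
                    ok = True
            except Exception:
                pass
        if not ok:
            firth = _firth_logistic(design, y)
            if firth is not None:
                beta, cov = firth
                se = np.sqrt(cov[0, 0])
                if np.isfinite(se) and se < 50:
                    z = beta[0] / se
                    pvals[j] = 2 * stats.norm.sf(abs(z))
                    ok = True
            if not ok:
                flags[j] = True
    retained = np.flatnonzero(~flags & (pvals < alpha))
    return retained, pvals, flags
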