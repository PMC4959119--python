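"""Coupled independent component analysis of two subject-aligned modalities.

Model: each modality X (subjects x features) decomposes as X ~ A S with
per-subject loading coefficients A (subjects x K) and feature-space
sources S (K x features).  ICA treats the features as samples and the
subjects as channels: the data are reduced to K dimensions by PCA
whitening, an unmixing matrix W is learned by natural-gradient Infomax
with a logistic nonlinearity, and the sources are U = W X_whitened.

The parallel (coupled) variant alternates per-modality Infomax epochs
with a coupling step that nudges both unmixing matrices up the gradient
of corr^2 between the currently most-correlated pair of loading columns,
so genuinely linked components align across modalities without being
forced to.  With coupling weight 0 the two modalities evolve exactly as
two independent Infomax runs under the same seeds.

Model order K is chosen per modality by the Wax-Kailath minimum
description length criterion over covariance eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.special import expit

from .datatypes import ComponentModel, ParaIcaResult, ClusterTable

__all__ = [
    "estimate_order_mdl",
    "pca_whiten",
    "run_infomax",
    "decompose_single",
    "run_para_ica",
    "compute_loadings",
    "threshold_component_map",
    "match_components",
]


def estimate_order_mdl(X: np.ndarray) -> int:
    """Minimum-description-length model order from covariance eigenvalues.

    With n subjects as observations and eigenvalues l_1 >= ... >= l_p of
    the sample covariance (p = min(subjects, features)),

        MDL(k) = -n (p - k) log(GM_k / AM_k) + 0.5 k (2p - k) log n

    where GM_k and AM_k are the geometric and arithmetic means of the
    trailing p - k eigenvalues.  Returns argmin over k in [0, p-1].
    """
    X = np.asarray(X, dtype=float)
    n, n_feat = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    Xc = X - X.mean(axis=0)
    p = min(n, n_feat)
    sv = np.linalg.svd(Xc, compute_uv=False)
    evals = np.zeros(p)
    evals[: sv.size] = sv**2 / n
    evals = np.maximum(evals, 1e-300)
    if np.ptp(evals) == 0:
        raise ValueError("fewer than 2 distinct eigenvalues")
    mdl = np.empty(p)
    for k in range(p):
        tail = evals[k:]
        log_gm = np.mean(np.log(tail))
        am = np.mean(tail)
        mdl[k] = -n * (p - k) * (log_gm - np.log(am)) + 0.5 * k * (2 * p - k) * np.log(n)
    return int(np.argmin(mdl))


@dataclass
class Whitening:
    """PCA whitening of subjects x features data down to K channels."""

    whiten: np.ndarray  # K x subjects
    dewhiten: np.ndarray  # subjects x K
    row_means: np.ndarray  # per-subject means removed before whitening


def pca_whiten(X: np.ndarray, K: int) -> tuple[np.ndarray, Whitening]:
    """Whiten subjects x features data to K uncorrelated unit-variance rows.

    Each subject row is centered across features; the top-K principal
    directions of the subject x subject covariance define the whitening.
    Returns ``(X_white, transforms)`` with ``X_white`` K x features.
    """
    X = np.asarray(X, dtype=float)
    n, n_feat = X.shape
    means = X.mean(axis=1, keepdims=True)
    Xc = X - means
    cov = Xc @ Xc.T / n_feat
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-12))
    if K > rank:
        raise ValueError(f"K={K} exceeds data rank {rank}")
    d = np.sqrt(evals[:K])
    wh = (evecs[:, :K] / d).T  # K x subjects
    dw = evecs[:, :K] * d  # subjects x K
    return wh @ Xc, Whitening(whiten=wh, dewhiten=dw, row_means=means)


class _InfomaxState:
    """One modality's Infomax optimizer; stepped one epoch at a time.

    Natural-gradient update with logistic nonlinearity g(u) = 1/(1+e^-u):
        dW = lr * (I + (1 - 2 g(U)) U^T / B) W
    over randomized mini-batches.  The learning rate anneals when the
    angle between successive weight-change directions exceeds 60 degrees.
    Converged when the relative Frobenius change of W over an epoch drops
    below ``tol``.
    """

    def __init__(self, K: int, lr: float, tol: float, seed: int, batch_size: int = 256,
                 anneal: float = 0.9, max_lr_angle_deg: float = 60.0):
        self.W = np.eye(K)
        self.lr = lr
        self.tol = tol
        self.rng = np.random.default_rng(seed)
        self.batch_size = batch_size
        self.anneal = anneal
        self.cos_thresh = np.cos(np.deg2rad(max_lr_angle_deg))
        self.prev_delta: np.ndarray | None = None
        self.converged = False
        self.epoch = 0

    def step(self, Xw: np.ndarray) -> float:
        """Run one epoch over ``Xw`` (K x samples); returns data log-likelihood proxy."""
        if self.converged:
            return self.entropy(Xw)
        K, n_samp = Xw.shape
        W0 = self.W.copy()
        perm = self.rng.permutation(n_samp)
        with np.errstate(over="ignore", invalid="ignore"):
            for start in range(0, n_samp, self.batch_size):
                batch = Xw[:, perm[start : start + self.batch_size]]
                B = batch.shape[1]
                U = self.W @ batch
                Y = expit(U)
                grad = (np.eye(K) + (1.0 - 2.0 * Y) @ U.T / B) @ self.W
                self.W = self.W + self.lr * grad
                if not np.all(np.isfinite(self.W)):
                    raise FloatingPointError(
                        f"Infomax diverged at epoch {self.epoch}; retry with a smaller "
                        "learning rate or a different seed"
                    )
        delta = self.W - W0
        if self.prev_delta is not None:
            num = float(np.sum(delta * self.prev_delta))
            den = float(np.linalg.norm(delta) * np.linalg.norm(self.prev_delta))
            if den > 0 and num / den < self.cos_thresh:
                self.lr *= self.anneal
        self.prev_delta = delta
        self.epoch += 1
        rel = np.linalg.norm(delta) / max(np.linalg.norm(W0), 1e-300)
        if rel < self.tol:
            self.converged = True
        return self.entropy(Xw)

    def entropy(self, Xw: np.ndarray) -> float:
        """Infomax objective: log|det W| + mean log g'(u) per sample."""
        U = self.W @ Xw
        Y = expit(np.clip(U, -30, 30))
        sign, logdet = np.linalg.slogdet(self.W)
        if sign == 0:
            return -np.inf
        return float(logdet + np.mean(np.sum(np.log(Y * (1 - Y) + 1e-300), axis=0)))


def run_infomax(
    X_whitened: np.ndarray,
    max_epochs: int = 400,
    lr: float = 0.01,
    tol: float = 1e-6,
    seed: int = 0,
    batch_size: int = 256,
) -> np.ndarray:
    """Infomax ICA on whitened K x samples data; returns the unmixing W."""
    K = X_whitened.shape[0]
    state = _InfomaxState(K, lr=lr, tol=tol, seed=seed, batch_size=batch_size)
    for _ in range(max_epochs):
        state.step(X_whitened)
        if state.converged:
            break
    return state.W


def compute_loadings(X: np.ndarray, sources: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares loadings of X (subjects x features) on sources (K x features).

    Returns ``(loadings, r2)`` with per-component reconstruction R^2
    (variance of X explained by each component's rank-1 term).
    """
    X = np.asarray(X, dtype=float)
    S = np.asarray(sources, dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise ValueError("sources are rank-deficient; loadings are not identified")
    A = X @ np.linalg.pinv(S)
    tot = np.sum((X - X.mean()) ** 2)
    r2 = np.array([np.sum(np.outer(A[:, k], S[k]) ** 2) / tot if tot > 0 else 0.0
                   for k in range(S.shape[0])])
    return A, r2


def _loading_columns(W: np.ndarray, wh: Whitening) -> np.ndarray:
    """Subject-space loading matrix implied by unmixing W: A = dewhiten W^-1."""
    return wh.dewhiten @ np.linalg.inv(W)


def _corr_and_grad(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """corr(a,b) plus gradients of corr^2 w.r.t. a and b."""
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    r = float(ac @ bc / (na * nb))
    dr_da = (bc / (na * nb) - r * ac / na**2)
    dr_db = (ac / (na * nb) - r * bc / nb**2)
    return r, 2 * r * dr_da, 2 * r * dr_db


def _coupling_gradients(
    Wg: np.ndarray, Wb: np.ndarray, whg: Whitening, whb: Whitening,
    gi: int, bi: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gradients of corr^2(a_g[:,gi], a_b[:,bi]) w.r.t. Wg and Wb.

    Loadings are A = dewhiten @ inv(W); with M = inv(W) and G = dJ/dM,
    dJ/dW = -M^T G M^T.
    """
    Mg, Mb = np.linalg.inv(Wg), np.linalg.inv(Wb)
    Ag = whg.dewhiten @ Mg
    Ab = whb.dewhiten @ Mb
    r, dJ_dag, dJ_dab = _corr_and_grad(Ag[:, gi], Ab[:, bi])
    Gg = np.zeros_like(Mg)
    Gg[:, gi] = whg.dewhiten.T @ dJ_dag
    Gb = np.zeros_like(Mb)
    Gb[:, bi] = whb.dewhiten.T @ dJ_dab
    dJ_dWg = -Mg.T @ Gg @ Mg.T
    dJ_dWb = -Mb.T @ Gb @ Mb.T
    return dJ_dWg, dJ_dWb, r


def _finalize_model(X: np.ndarray, W: np.ndarray, wh: Whitening, modality: str) -> ComponentModel:
    sources = W @ (wh.whiten @ (X - X.mean(axis=1, keepdims=True)))
    # fix scale/sign: unit-norm source rows, positive skewness
    norms = np.linalg.norm(sources, axis=1)
    norms[norms == 0] = 1.0
    sources = sources / norms[:, None]
    skew_sign = np.sign(np.sum(sources**3, axis=1))
    skew_sign[skew_sign == 0] = 1.0
    sources = sources * skew_sign[:, None]
    loadings, r2 = compute_loadings(X, sources)
    order = np.argsort(r2)[::-1]
    return ComponentModel(
        loadings=loadings[:, order],
        sources=sources[order],
        modality=modality,
        explained_variance=r2[order],
    )


def decompose_single(
    X: np.ndarray,
    K: int,
    max_epochs: int = 400,
    lr: float = 0.01,
    tol: float = 1e-6,
    seed: int = 0,
    batch_size: int = 256,
    modality: str = "single",
) -> ComponentModel:
    """Uncoupled decomposition of one modality: whiten, Infomax, finalize.

    This is exactly the computation each modality undergoes inside
    :func:`run_para_ica` when the coupling weight is zero, so
    ``run_para_ica(..., lambda_couple=0)`` reproduces two calls of this
    function bit-for-bit (gene with ``seed``, brain with ``seed + 1``).
    """
    Xw, wh = pca_whiten(X, K)
    W = run_infomax(Xw, max_epochs=max_epochs, lr=lr, tol=tol, seed=seed, batch_size=batch_size)
    return _finalize_model(X, W, wh, modality)


def run_para_ica(
    X_gene: np.ndarray,
    X_brain: np.ndarray,
    K_gene: int,
    K_brain: int,
    lambda_couple: float | None = None,
    tau_link: float = 0.25,
    r_cap: float = 0.95,
    max_epochs: int = 400,
    lr: float = 0.01,
    tol: float = 1e-6,
    seed: int = 0,
    batch_size: int = 256,
    n_coupled_pairs: int = 1,
) -> ParaIcaResult:
    """Coupled Infomax ICA of two subject-aligned matrices.

    Alternates one Infomax epoch per modality with a coupling step that
    ascends the gradient of corr^2 for the currently strongest loading
    pair(s) with |r| >= tau_link, skipping pairs already tighter than
    ``r_cap`` (which would collapse within-modality independence).

    ``lambda_couple=None`` chooses the coupling step adaptively so its
    gradient norm is at most 10% of the first epoch's Infomax weight
    change; ``lambda_couple=0`` disables coupling entirely, reproducing
    two independent :func:`run_infomax` runs bit-for-bit (the gene run
    with seed ``seed``, the brain run with ``seed + 1``).
    """
    X_gene = np.asarray(X_gene, dtype=float)
    X_brain = np.asarray(X_brain, dtype=float)
    if X_gene.shape[0] != X_brain.shape[0]:
        raise ValueError("modalities must share subjects (same row count/order)")

    Xg_w, whg = pca_whiten(X_gene, K_gene)
    Xb_w, whb = pca_whiten(X_brain, K_brain)
    sg = _InfomaxState(K_gene, lr=lr, tol=tol, seed=seed, batch_size=batch_size)
    sb = _InfomaxState(K_brain, lr=lr, tol=tol, seed=seed + 1, batch_size=batch_size)

    lam = lambda_couple
    trace_rows = []
    for epoch in range(max_epochs):
        Wg_before, Wb_before = sg.W.copy(), sb.W.copy()
        ent_g = sg.step(Xg_w)
        ent_b = sb.step(Xb_w)
        couple_term = 0.0
        if lam is None or lam > 0:
            Ag = _loading_columns(sg.W, whg)
            Ab = _loading_columns(sb.W, whb)
            C = np.corrcoef(Ag.T, Ab.T)[:K_gene, K_gene:]
            flat = np.argsort(np.abs(C), axis=None)[::-1]
            applied = 0
            for f in flat:
                if applied >= n_coupled_pairs:
                    break
                gi, bi = np.unravel_index(f, C.shape)
                r = C[gi, bi]
                if abs(r) < tau_link:
                    break
                if abs(r) > r_cap:
                    continue
                dWg, dWb, r_now = _coupling_gradients(sg.W, sb.W, whg, whb, gi, bi)
                if lam is None:
                    infomax_step = np.linalg.norm(sg.W - Wg_before) + np.linalg.norm(sb.W - Wb_before)
                    grad_norm = np.linalg.norm(dWg) + np.linalg.norm(dWb)
                    lam = 0.1 * infomax_step / max(grad_norm, 1e-12)
                sg.W = sg.W + lam * dWg
                sb.W = sb.W + lam * dWb
                couple_term += r_now**2
                applied += 1
        trace_rows.append(
            {"epoch": epoch, "entropy_gene": ent_g, "entropy_brain": ent_b,
             "coupling": couple_term, "lr_gene": sg.lr, "lr_brain": sb.lr}
        )
        if sg.converged and sb.converged:
            break

    gene_model = _finalize_model(X_gene, sg.W, whg, "gene")
    brain_model = _finalize_model(X_brain, sb.W, whb, "brain")
    C = np.corrcoef(gene_model.loadings.T, brain_model.loadings.T)[:K_gene, K_gene:]
    linked = []
    for gi in range(K_gene):
        bi = int(np.argmax(np.abs(C[gi])))
        linked.append((gi, bi, float(C[gi, bi])))
    linked.sort(key=lambda t: -abs(t[2]))
    return ParaIcaResult(
        gene_model=gene_model,
        brain_model=brain_model,
        linked_pairs=linked,
        objective_trace=pd.DataFrame(trace_rows),
        config={
            "K_gene": K_gene, "K_brain": K_brain,
            "lambda": lam if lam is not None else 0.0,
            "tau_link": tau_link, "r_cap": r_cap, "lr": lr, "tol": tol,
            "max_epochs": max_epochs, "batch_size": batch_size, "seed": seed,
            "n_coupled_pairs": n_coupled_pairs,
        },
        converged=sg.converged and sb.converged,
    )


_CONNECTIVITY = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_component_map(
    source_row: np.ndarray,
    mask: np.ndarray,
    z_thresh: float = 1.5,
    min_cluster: int = 50,
    connectivity: int = 26,
) -> ClusterTable:
    """Suprathreshold clusters of one component map.

    The source is z-scored over in-mask voxels; voxels with |z| above
    ``z_thresh`` are grouped into 3-D connected components (26-neighbor by
    default) and clusters larger than ``min_cluster`` voxels are returned,
    sorted by peak |z|.
    """
    from .phenotype import unflatten_map

    source_row = np.asarray(source_row, dtype=float)
    sd = source_row.std()
    if sd == 0:
        raise ValueError("zero-variance source row cannot be z-scored")
    z = (source_row - source_row.mean()) / sd
    zvol = unflatten_map(z, mask)
    supra = (np.abs(zvol) > z_thresh) & np.asarray(mask, dtype=bool)
    labels, n_lab = ndimage.label(supra, structure=_CONNECTIVITY[connectivity])
    rows = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        if vox.shape[0] <= min_cluster:
            continue
        absz = np.abs(zvol[tuple(vox.T)])
        peak = vox[int(np.argmax(absz))]
        rows.append(
            {"size": int(vox.shape[0]), "peak_abs_z": float(absz.max()),
             "peak_ijk": tuple(int(c) for c in peak), "voxels": [tuple(map(int, v)) for v in vox]}
        )
    rows.sort(key=lambda r: -r["peak_abs_z"])
    df = pd.DataFrame(rows, columns=["size", "peak_abs_z", "peak_ijk", "voxels"])
    return ClusterTable(clusters=df, z_thresh=z_thresh, min_cluster=min_cluster)


def match_components(
    sources_a: np.ndarray, sources_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of two source sets by |correlation|.

    Returns ``(permutation, signs, matched_corrs)`` such that
    ``sources_b[permutation[i]] * signs[i]`` corresponds to
    ``sources_a[i]`` and ``matched_corrs[i]`` is the (positive) matched
    correlation.  If the sets differ in size, only min(Ka, Kb) rows of a
    are matched (the assignment still maximizes total |correlation|).
    """
    A = np.asarray(sources_a, dtype=float)
    B = np.asarray(sources_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("source sets must share the feature dimension")
    ka, kb = A.shape[0], B.shape[0]
    C = np.corrcoef(A, B)[:ka, ka:]
    C = np.nan_to_num(C)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.full(ka, -1)
    signs = np.ones(ka)
    corrs = np.full(ka, np.nan)
    for r, c in zip(rows, cols):
        perm[r] = c
        signs[r] = 1.0 if C[r, c] >= 0 else -1.0
        corrs[r] = abs(C[r, c])
    return perm, signs, corrs
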