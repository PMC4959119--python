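"""Gene-level interpretation of a genetic component.

Coordinate-overlap SNP-to-gene annotation, a Monte-Carlo gene-based test
in the VEGAS style (sum of per-SNP 1-df chi-squares calibrated against
multivariate-normal draws from the SNPs' LD correlation matrix, which
removes the bias toward large genes), selection of dominant genes at
p < 0.05, and hypergeometric pathway enrichment with Benjamini-Hochberg
FDR over a GMT pathway database.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneModel",
    "EnrichmentResult",
    "read_gene_bed",
    "read_gmt",
    "annotate_snps_to_genes",
    "component_snp_pvalues",
    "gene_based_test",
    "gene_tests_for_component",
    "select_component_genes",
    "hypergeometric_enrichment",
    "bh_fdr",
]


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class GeneModel:
    """Gene intervals (1-based inclusive) keyed by symbol."""

    genes: pd.DataFrame  # symbol, chrom, start, end

    def __post_init__(self) -> None:
        g = self.genes
        if (g["start"] > g["end"]).any():
            bad = g[g["start"] > g["end"]]["symbol"].iloc[0]
            raise ValueError(f"gene {bad}: start > end")
        self.genes = g.assign(chrom=g["chrom"].map(_norm_chrom))


def read_gene_bed(path: str | Path) -> GeneModel:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "symbol"], usecols=range(4),
                     dtype={"chrom": str})
    return GeneModel(genes=pd.DataFrame({
        "symbol": df["symbol"], "chrom": df["chrom"],
        "start": df["start"].astype(int) + 1, "end": df["end"].astype(int),
    }))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read pathway gene sets from a GMT file (name, description, genes...)."""
    pathways: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def annotate_snps_to_genes(snp_records: pd.DataFrame, gene_model: GeneModel) -> pd.DataFrame:
    """Assign each SNP to every gene whose interval contains its position.

    Inclusive on both boundaries; chromosome names are normalized (``chr1``
    and ``1`` match).  Returns a table with one row per (snp, gene)
    assignment plus rows with ``symbol = NaN`` for unassigned SNPs.
    """
    snps = snp_records.assign(chrom=snp_records["chrom"].map(_norm_chrom))
    rows = []
    genes = gene_model.genes
    for rec in snps.itertuples(index=False):
        hits = genes[
            (genes["chrom"] == rec.chrom)
            & (genes["start"] <= rec.pos)
            & (genes["end"] >= rec.pos)
        ]
        if len(hits) == 0:
            rows.append({"snp_id": rec.snp_id, "symbol": np.nan})
        else:
            for sym in hits["symbol"]:
                rows.append({"snp_id": rec.snp_id, "symbol": sym})
    return pd.DataFrame(rows)


def component_snp_pvalues(gene_component_weights: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values from standardized component weights.

    Weights are z-scored over the component (invariant to rescaling) and
    converted to p = 2 Phi(-|z|).  When per-SNP trait p-values from an
    external association scan are available they can be fed to
    :func:`gene_based_test` directly instead.
    """
    w = np.asarray(gene_component_weights, dtype=float)
    sd = w.std()
    if sd == 0:
        raise ValueError("zero-variance weight vector")
    z = (w - w.mean()) / sd
    return 2.0 * stats.norm.sf(np.abs(z))


def _nearest_psd(S: np.ndarray, eps: float = 1e-10) -> tuple[np.ndarray, float]:
    evals, evecs = np.linalg.eigh(S)
    clipped = np.maximum(evals, eps)
    repaired = (evecs * clipped) @ evecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    return repaired, float(np.max(np.abs(repaired - S)))


def gene_based_test(
    snp_pvalues: np.ndarray,
    ld_correlation: np.ndarray,
    n_sims: int = 10_000,
    seed: int = 0,
    max_sims: int = 1_000_000,
    psd_tol: float = 0.1,
) -> tuple[float, float, float, int]:
    """Monte-Carlo gene-based p-value correcting for gene size and LD.

    The gene statistic is T = sum_i invchi2(1 - p_i, df=1).  Null draws
    take z ~ MVN(0, Sigma_LD) and T' = sum z_i^2; the gene p-value is
    (1 + #{T' >= T}) / (1 + n_sims).  Simulations escalate (doubling, up
    to ``max_sims``) while p * n_sims < 10 so small p-values keep adequate
    Monte-Carlo resolution.

    Returns ``(T, p, mc_se, n_sims_used)``.
    """
    p_in = np.asarray(snp_pvalues, dtype=float)
    if np.any((p_in < 0) | (p_in > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000")
    m = p_in.size
    S = np.asarray(ld_correlation, dtype=float).reshape(m, m)
    min_eig = float(np.linalg.eigvalsh(S)[0])
    if min_eig < -1e-10:
        S, adj = _nearest_psd(S)
        if adj > psd_tol:
            raise ValueError(f"LD matrix too far from PSD (adjustment {adj:.3g})")
    T = float(np.sum(stats.chi2.isf(np.clip(p_in, 1e-300, 1.0), df=1)))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(S + 1e-12 * np.eye(m))
    sims = int(n_sims)
    exceed = 0
    total = 0
    while True:
        chunk = 100_000
        done = 0
        while done < sims:
            b = min(chunk, sims - done)
            z = rng.standard_normal((b, m)) @ L.T
            exceed += int(np.sum(np.sum(z**2, axis=1) >= T))
            done += b
        total += sims
        p = (1 + exceed) / (1 + total)
        if p * total >= 10 or total >= max_sims:
            break
        sims = total  # double
    mc_se = float(np.sqrt(p * (1 - p) / total))
    return T, float(p), mc_se, total


def gene_tests_for_component(
    weights: np.ndarray,
    snp_records: pd.DataFrame,
    assignments: pd.DataFrame,
    dosages: np.ndarray,
    n_sims: int = 10_000,
    seed: int = 0,
    snp_pvalues: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene-based p-values for every annotated gene of one component.

    Per-SNP p-values default to the component-weight z conversion; pass
    ``snp_pvalues`` to use external trait-association values instead.  The
    LD matrix per gene is the dosage correlation matrix of its SNPs
    estimated from the analysis cohort.
    """
    if snp_pvalues is None:
        snp_pvalues = component_snp_pvalues(weights)
    snp_index = {s: i for i, s in enumerate(snp_records["snp_id"])}
    rows = []
    rng = np.random.default_rng(seed)
    for sym, grp in assignments.dropna(subset=["symbol"]).groupby("symbol"):
        idx = np.array([snp_index[s] for s in grp["snp_id"] if s in snp_index])
        if idx.size == 0:
            continue
        sub = dosages[:, idx]
        if idx.size == 1:
            S = np.ones((1, 1))
        else:
            sd = sub.std(axis=0)
            sd[sd == 0] = 1.0
            S = np.corrcoef(sub.T)
            S = np.nan_to_num(S, nan=0.0)
            np.fill_diagonal(S, 1.0)
        T, p, se, used = gene_based_test(
            snp_pvalues[idx], S, n_sims=n_sims, seed=int(rng.integers(2**31))
        )
        rows.append({"symbol": sym, "n_snps": int(idx.size), "T": T,
                     "p": p, "mc_se": se, "n_sims": used})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def select_component_genes(gene_pvalues: pd.DataFrame | np.ndarray, alpha: float = 0.05):
    """Genes with gene-based p strictly below alpha, ascending by p."""
    if isinstance(gene_pvalues, pd.DataFrame):
        sel = gene_pvalues[gene_pvalues["p"] < alpha].sort_values("p")
        return sel["symbol"].tolist()
    p = np.asarray(gene_pvalues, dtype=float)
    return list(np.argsort(p, kind="stable")[np.sort(p, kind="stable") < alpha])


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # pathway, pathway_size, overlap, genes, p, q
    n_background: int
    n_query: int


def hypergeometric_enrichment(
    query_genes: list[str],
    pathway_db: dict[str, list[str]],
    background_genes: list[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene list over pathways.

    For each pathway with at least one overlapping gene,
    p = P(X >= k) with population N = |background|, successes
    K = |pathway ∩ background|, draws n = |query| and observed overlap k;
    q-values by Benjamini-Hochberg over all tested pathways.
    """
    background = set(background_genes)
    query = set(query_genes)
    missing = sorted(query - background)
    if missing:
        raise ValueError(f"query genes absent from background: {missing}")
    N, n = len(background), len(query)
    rows = []
    for name, genes in pathway_db.items():
        members = set(genes) & background
        overlap = sorted(members & query)
        k = len(overlap)
        if k == 0:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "pathway_size": K, "overlap": k,
                     "genes": ";".join(overlap), "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "genes", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p").reset_index(drop=True)
    return EnrichmentResult(table=df, n_background=N, n_query=n)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
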