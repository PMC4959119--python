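"""Synthetic linked genotype + volumetric data with known ground truth.

The generator emulates the statistical structure the fusion analysis
assumes: each modality is a noisy linear mixture of a few sparse,
non-Gaussian sources; subject loadings of designated component pairs are
correlated across modalities; a patient group shifts the loadings of the
linked components; genotypes carry two-subpopulation Balding-Nichols
structure and block-exchangeable LD.

Two modes:

* latent mode (``discretize=False``) keeps the genetic modality continuous,
  so ``loadings @ sources + noise`` holds exactly — used to test the fusion
  core under its own model;
* dosage mode discretizes the latent genetic matrix to {0,1,2} per SNP by
  within-subpopulation empirical quantile cuts that reproduce Hardy-Weinberg
  genotype frequencies at the SNP's (subpopulation-shifted) allele frequency.
  The cut is monotone in the latent value, so component signal survives into
  the dosages while the marginal minor-allele frequency is controlled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PhenotypeMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_spatial_sources",
    "make_snp_sources",
    "generate_linked_dataset",
    "write_dataset",
    "hudson_fst",
]


@dataclass
class SyntheticConfig:
    """Data-generating parameters.

    Defaults mirror the study conditions the analysis was designed for:
    ~200 adolescents split ~1:2 patients:controls, an exome-chip-scale SNP
    panel reduced to ~1000 markers, a small smooth gray-matter grid, a few
    components per modality with one cross-modality linked pair at r = 0.6,
    and a patient-group loading shift of about half a standard deviation.
    """

    n_subjects: int = 200
    n_snps: int = 1000
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    k_gene: int = 4
    k_brain: int = 3
    linked_pairs: list = field(default_factory=lambda: [(0, 0, 0.6)])
    group_effect: float = 0.5
    group_fraction: float = 0.32  # 63 / 198
    fst: float = 0.0
    subpop_fraction: float = 0.5
    ld_block_size: int = 10
    ld_within_r: float = 0.0
    snp_sparsity: float = 0.05
    blob_radius_vox: float = 2.0
    noise_sd_gene: float = 0.5
    noise_sd_brain: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    discretize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for gi, bi, r in self.linked_pairs:
            if not (0 <= gi < self.k_gene and 0 <= bi < self.k_brain):
                raise ValueError(f"linked pair ({gi},{bi}) outside component ranges")
            if not abs(r) < 1:
                raise ValueError(f"link correlation {r} must satisfy |r| < 1")
        if not 0 < self.group_fraction < 1:
            raise ValueError("group_fraction must be in (0,1)")
        if not 0 <= self.fst < 0.5:
            raise ValueError("fst must be in [0, 0.5)")
        if not 0 <= self.ld_within_r < 1:
            raise ValueError("ld_within_r must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests."""

    gene_sources: np.ndarray
    brain_sources: np.ndarray
    gene_loadings: np.ndarray
    brain_loadings: np.ndarray
    group_labels: np.ndarray
    subpop_labels: np.ndarray
    realized_link_correlations: list
    target_maf: np.ndarray = None  # type: ignore[assignment]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def make_spatial_sources(
    grid_dims: tuple[int, int, int],
    k: int,
    blob_radius_vox: float = 2.0,
    seed: int = 0,
    n_blobs_range: tuple[int, int] = (1, 3),
) -> np.ndarray:
    """Sparse positive Gaussian-blob sources on a 3-D grid, row-normalized.

    Each of the ``k`` sources is 1-3 smooth blobs on an otherwise-zero grid.
    Blob centers are drawn without replacement from a coarse lattice whose
    spacing keeps blobs of different sources disjoint, so source rows are
    nearly uncorrelated.  Rows are flattened in Fortran (x-fastest) order.
    """
    if blob_radius_vox < 1:
        raise ValueError("blob radius must be at least 1 voxel")
    dims = tuple(int(d) for d in grid_dims)
    n_vox = int(np.prod(dims))
    if k == 0:
        return np.zeros((0, n_vox))
    rng = np.random.default_rng(seed)
    margin = max(1, int(np.floor(blob_radius_vox / 2)))
    axes = [np.arange(margin, d - margin) for d in dims]
    if any(a.size == 0 for a in axes):
        raise ValueError(f"grid {dims} too small for blobs of radius {blob_radius_vox}")
    candidates = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T.astype(float)
    # greedy selection keeping blob centers >= 3 sigma apart (3-D distance),
    # which makes blobs of different sources essentially disjoint
    min_dist = 3.0 * blob_radius_vox
    need = k * n_blobs_range[0]
    centers: list[np.ndarray] = []
    for _ in range(20):  # greedy packing is shuffle-sensitive; restart a few times
        order = rng.permutation(candidates.shape[0])
        trial: list[np.ndarray] = []
        for idx in order:
            c = candidates[idx]
            if all(np.linalg.norm(c - prev) >= min_dist for prev in trial):
                trial.append(c)
        if len(trial) > len(centers):
            centers = trial
        if len(centers) >= k * n_blobs_range[1]:
            break
    if len(centers) < need:
        raise ValueError(
            f"grid {dims} too small to place {k} disjoint blobs of radius {blob_radius_vox}"
        )
    max_blobs = min(n_blobs_range[1], len(centers) // k)
    coords = np.stack(
        np.meshgrid(*[np.arange(d) for d in dims], indexing="ij"), axis=-1
    ).astype(float)
    sources = np.zeros((k, n_vox))
    cursor = 0
    for comp in range(k):
        n_blobs = int(rng.integers(n_blobs_range[0], max_blobs + 1))
        vol = np.zeros(dims)
        for _ in range(n_blobs):
            center = centers[cursor]
            cursor += 1
            d2 = np.sum((coords - center) ** 2, axis=-1)
            vol += np.exp(-d2 / (2 * blob_radius_vox**2))
        row = vol.reshape(-1, order="F")
        sources[comp] = row / np.linalg.norm(row)
    return sources


def make_snp_sources(
    n_snps: int, k: int, sparsity: float, seed: int = 0
) -> np.ndarray:
    """Sparse heavy-tailed SNP-weight sources, unit-normalized rows.

    Each row has ``round(sparsity * n_snps)`` nonzero weights drawn from a
    Laplace distribution.  Supports are drawn preferring indices no earlier
    row used, which keeps pairwise support overlap below 20% whenever the
    grid of free indices allows it.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    n_active = int(round(sparsity * n_snps))
    if n_active < 1:
        raise ValueError(f"sparsity {sparsity} x {n_snps} SNPs < 1 nonzero weight")
    rng = np.random.default_rng(seed)
    used = np.zeros(n_snps, dtype=bool)
    sources = np.zeros((k, n_snps))
    for comp in range(k):
        free = np.flatnonzero(~used)
        if free.size >= n_active:
            support = rng.choice(free, size=n_active, replace=False)
        else:  # not enough fresh indices; top up from already-used ones
            taken = rng.choice(np.flatnonzero(used), size=n_active - free.size, replace=False)
            support = np.concatenate([free, taken])
        used[support] = True
        weights = rng.laplace(size=n_active)
        row = np.zeros(n_snps)
        row[support] = weights
        sources[comp] = row / np.linalg.norm(row)
    return sources


def _hwe_cutpoint_dosages(latent: np.ndarray, p_alt: float) -> np.ndarray:
    """Discretize one SNP's latent column to {0,1,2} by empirical quantiles.

    The largest-latent subjects get dosage 2 with Hardy-Weinberg proportions
    P(2)=p^2, P(1)=2p(1-p), P(0)=(1-p)^2 where p is the minor-allele
    frequency.  Monotone in the latent value, so the cut preserves the
    ordering induced by the component signal.
    """
    n = latent.size
    n2 = min(int(round(n * p_alt**2)), n)
    n1 = min(int(round(n * 2 * p_alt * (1 - p_alt))), n - n2)
    order = np.argsort(latent, kind="stable")
    dos = np.zeros(n)
    if n1 > 0:
        dos[order[n - n2 - n1 : n - n2]] = 1.0
    if n2 > 0:
        dos[order[n - n2 :]] = 2.0
    return dos


def generate_linked_dataset(
    config: SyntheticConfig,
) -> tuple[GenotypeMatrix, PhenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a linked genotype/volume dataset plus its ground truth.

    Returns ``(genotypes, phenotypes, covariates, truth)``.  In latent mode
    (``discretize=False``) the "dosage" matrix is the continuous latent
    genetic matrix; its metadata is still a valid SNP table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_subjects, cfg.n_snps

    gene_sources = make_snp_sources(
        m, cfg.k_gene, cfg.snp_sparsity, seed=int(rng.integers(2**31))
    )
    brain_sources = make_spatial_sources(
        cfg.grid_dims, cfg.k_brain, cfg.blob_radius_vox, seed=int(rng.integers(2**31))
    )

    gene_loadings = rng.standard_normal((n, cfg.k_gene))
    brain_loadings = rng.standard_normal((n, cfg.k_brain))
    for gi, bi, r in cfg.linked_pairs:
        eps = rng.standard_normal(n)
        brain_loadings[:, bi] = r * gene_loadings[:, gi] + np.sqrt(1 - r**2) * eps

    group = (rng.random(n) < cfg.group_fraction).astype(int)
    subpop = (rng.random(n) < cfg.subpop_fraction).astype(int)
    for gi, bi, _ in cfg.linked_pairs:
        gene_loadings[:, gi] += cfg.group_effect * group
        brain_loadings[:, bi] += cfg.group_effect * group

    realized = [
        (gi, bi, _corr(gene_loadings[:, gi], brain_loadings[:, bi]))
        for gi, bi, _ in cfg.linked_pairs
    ]

    # Brain modality: mixture + homoscedastic Gaussian noise.  Noise scales
    # are relative to the RMS of the signal matrix, so noise_sd=0.5 means
    # "noise at half the typical signal amplitude" regardless of grid size
    # or SNP panel width (source rows are unit-norm, which spreads one unit
    # of signal variance over all features).
    brain_vals = brain_loadings @ brain_sources
    if cfg.noise_sd_brain > 0:
        rms = np.sqrt(np.mean(brain_vals**2))
        brain_vals = brain_vals + cfg.noise_sd_brain * rms * rng.standard_normal(brain_vals.shape)
    mask = np.ones(cfg.grid_dims, dtype=bool)
    phen = PhenotypeMatrix(values=brain_vals, mask=mask)

    # Genetic modality: mixture + block-exchangeable noise (induces LD among
    # null SNPs), then optional quantile discretization with subpopulation
    # allele-frequency shifts.
    latent = gene_loadings @ gene_sources
    if cfg.noise_sd_gene > 0:
        rho = cfg.ld_within_r
        noise = rng.standard_normal((n, m))
        if rho > 0:
            n_blocks = int(np.ceil(m / cfg.ld_block_size))
            block_of = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:m]
            shared = rng.standard_normal((n, n_blocks))
            noise = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1 - rho) * noise
        rms = np.sqrt(np.mean((gene_loadings @ gene_sources) ** 2))
        latent = latent + cfg.noise_sd_gene * rms * noise

    p0 = rng.uniform(*cfg.maf_range, size=m)
    # polymorphism floor: below this the expected heterozygote count rounds
    # to zero in a subpopulation and the SNP cannot be discretized
    n_sub_min = max(int(min((subpop == 0).sum(), (subpop == 1).sum())), 1)
    p_floor = 1.0 / (2.0 * n_sub_min)
    if cfg.discretize and np.any(p0 < p_floor):
        j = int(np.flatnonzero(p0 < p_floor)[0])
        raise ValueError(
            f"SNP {j}: requested MAF {p0[j]:.4g} is monomorphic at subpopulation "
            f"size {n_sub_min} (needs MAF >= {p_floor:.4g})"
        )
    if cfg.fst > 0:
        a = p0 * (1 - cfg.fst) / cfg.fst
        b = (1 - p0) * (1 - cfg.fst) / cfg.fst
        p_sub = np.stack([rng.beta(a, b), rng.beta(a, b)])  # 2 x m
        p_sub = np.clip(p_sub, p_floor, 1 - p_floor)
    else:
        p_sub = np.stack([p0, p0])

    frac = np.array([(subpop == 0).mean(), (subpop == 1).mean()])
    p_mix = frac @ p_sub
    target_maf = np.minimum(p_mix, 1 - p_mix)

    if cfg.discretize:
        dosages = np.empty((n, m))
        for j in range(m):
            col = np.empty(n)
            for s in (0, 1):
                idx = subpop == s
                if idx.any():
                    col[idx] = _hwe_cutpoint_dosages(latent[idx, j], p_sub[s, j])
            if col.min() == col.max():
                raise ValueError(
                    f"SNP {j}: allele frequency {p_mix[j]:.4g} gives a "
                    "monomorphic column at this sample size"
                )
            dosages[:, j] = col
    else:
        dosages = latent

    snp_records = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    age = rng.uniform(8, 18, size=n).round(1)
    sex = rng.integers(0, 2, size=n)
    sample_records = pd.DataFrame(
        {
            "sample_id": [f"subj{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "group": group,
            "ethnicity": np.where(subpop == 1, "pop2", "pop1"),
        }
    )
    geno = GenotypeMatrix(dosages=dosages, snp_records=snp_records, sample_records=sample_records)

    # Two clinical scores tied to the brain loading of the first linked pair
    # (attention-like and omission-like measures), plus the covariates the
    # association stage adjusts for.
    driver = brain_loadings[:, cfg.linked_pairs[0][1]] if cfg.linked_pairs else brain_loadings[:, 0]
    dz = (driver - driver.mean()) / driver.std()
    covariates = sample_records.copy()
    covariates["score_attention"] = (50 + 8 * dz + 6 * rng.standard_normal(n)).round(2)
    covariates["score_omission"] = (50 + 6 * dz + 8 * rng.standard_normal(n)).round(2)
    covariates["subpop"] = subpop

    truth = SyntheticTruth(
        gene_sources=gene_sources,
        brain_sources=brain_sources,
        gene_loadings=gene_loadings,
        brain_loadings=brain_loadings,
        group_labels=group,
        subpop_labels=subpop,
        realized_link_correlations=realized,
        target_maf=target_maf,
    )
    return geno, phen, covariates, truth


def hudson_fst(dosages: np.ndarray, subpop: np.ndarray) -> float:
    """Hudson FST estimator (ratio of averages) from {0,1,2} dosages."""
    subpop = np.asarray(subpop)
    g1 = dosages[subpop == 0]
    g2 = dosages[subpop == 1]
    n1, n2 = 2 * g1.shape[0], 2 * g2.shape[0]
    p1 = g1.mean(axis=0) / 2
    p2 = g2.mean(axis=0) / 2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())


def write_dataset(
    out_dir: str | Path,
    geno: GenotypeMatrix,
    phen: PhenotypeMatrix,
    covariates: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> dict:
    """Write a generated dataset to standard formats under ``out_dir``.

    PLINK1 BED/BIM/FAM for dosages, per-subject NIfTI volumes + mask NIfTI,
    covariates TSV, and (optionally) a compressed truth bundle with a JSON
    manifest.  Returns a dict of the paths written.
    """
    from . import plink
    from .phenotype import unflatten_map, save_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    plink.write_plink(out / "genotypes", geno)
    paths["plink_prefix"] = str(out / "genotypes")

    vol_dir = out / "volumes"
    vol_dir.mkdir(exist_ok=True)
    for i, sid in enumerate(covariates["sample_id"]):
        vol = unflatten_map(phen.values[i], phen.mask)
        save_nifti(vol, vol_dir / f"{sid}.nii", voxel_size_mm=phen.voxel_size_mm)
    save_nifti(phen.mask.astype(np.uint8), out / "mask.nii", voxel_size_mm=phen.voxel_size_mm)
    paths["volumes_dir"] = str(vol_dir)
    paths["mask"] = str(out / "mask.nii")

    covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    paths["covariates"] = str(out / "covariates.tsv")

    if truth is not None:
        np.savez_compressed(
            out / "truth.npz",
            gene_sources=truth.gene_sources,
            brain_sources=truth.brain_sources,
            gene_loadings=truth.gene_loadings,
            brain_loadings=truth.brain_loadings,
            group_labels=truth.group_labels,
            subpop_labels=truth.subpop_labels,
            target_maf=truth.target_maf,
        )
        manifest = {
            "arrays": "truth.npz",
            "realized_link_correlations": [
                [int(g), int(b), float(r)] for g, b, r in truth.realized_link_correlations
            ],
        }
        (out / "truth.json").write_text(json.dumps(manifest, indent=2))
        paths["truth"] = str(out / "truth.npz")
    return paths
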