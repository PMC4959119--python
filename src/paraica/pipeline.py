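"""End-to-end orchestration: simulate -> QC -> prep -> fuse -> stability ->
association -> gene tests -> enrichment, with every threshold in one
config object, a run directory of stage outputs, and a manifest that
makes the run reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plink
from .datatypes import GenotypeMatrix, PhenotypeMatrix
from .synthetic import SyntheticConfig, generate_linked_dataset, write_dataset
from . import genotype_qc as qc
from .phenotype import gaussian_smooth, mask_and_flatten, load_nifti, unflatten_map, save_nifti
from .fusion import estimate_order_mdl, run_para_ica, threshold_component_map
from .stability import loo_stability
from .association import test_all_pairs, group_difference_tests, clinical_correlations
from . import genomics

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "read_genotypes", "run_pipeline"]

_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serialized into each run directory."""

    out_dir: str = "paraica_run"
    seed: int = 0

    # inputs; when simulate=True they are generated under the run directory
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    plink_prefix: str | None = None
    dosage_tsv: str | None = None
    volumes_dir: str | None = None
    mask_path: str | None = None
    covariates_tsv: str | None = None
    gene_bed: str | None = None
    pathway_gmt: str | None = None

    # QC
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.7
    n_pca_axes: int = 10
    n_ancestry_axes: int = 2
    prefilter_alpha: float = 0.1

    # phenotype prep
    fwhm_mm: float = 4.0

    # fusion
    k_gene: int | None = None  # None -> MDL estimate
    k_brain: int | None = None
    lambda_couple: float | None = None  # None -> adaptive
    tau_link: float = 0.25
    r_cap: float = 0.95
    max_epochs: int = 400
    lr: float = 0.01
    tol: float = 1e-6
    z_thresh: float = 1.5
    min_cluster: int = 50

    # stability
    stability_repeats: int = 10
    holdout_frac: float = 0.05
    tau_stab: float = 0.8
    run_stability: bool = True

    # association / genomics
    assoc_alpha: float = 0.05
    gene_alpha: float = 0.05
    gene_test_sims: int = 10_000
    run_genomics: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    version: str
    seed: int
    stage_timings: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a PLINK1 prefix or a dosage TSV."""
    p = Path(path)
    if p.suffix in {".tsv", ".txt"} and p.exists():
        return plink.read_dosage_tsv(p)
    return plink.read_plink(p)


def _load_phenotypes(cfg: PipelineConfig, sample_ids: list[str]) -> PhenotypeMatrix:
    mask, _, zooms = None, None, (1.0, 1.0, 1.0)
    mask_data, _, zooms = load_nifti(cfg.mask_path)
    mask = mask_data > 0
    vols = []
    vdir = Path(cfg.volumes_dir)
    for sid in sample_ids:
        vol, _, _ = load_nifti(vdir / f"{sid}.nii")
        vols.append(gaussian_smooth(vol, cfg.fwhm_mm, zooms))
    return mask_and_flatten(vols, mask, zooms)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis chain under ``config.out_dir``.

    Stages: simulate (optional) -> qc -> prep -> fuse -> stability ->
    associate -> gene tests -> enrich.  Every stage writes its outputs
    under a stage subdirectory; the echoed config and a manifest with
    checksums, seeds and timings make the run re-executable.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    manifest = RunManifest(version=_VERSION, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)

    def _stage(name):
        t0 = time.time()
        logger.info("stage %s", name)
        return t0

    def _done(name, t0):
        manifest.stage_timings[name] = round(time.time() - t0, 3)
        manifest.completed_stages.append(name)
        manifest.save(out / "manifest.json")

    try:
        # ---- simulate / load --------------------------------------------
        t0 = _stage("input")
        truth = None
        if cfg.simulate:
            scfg = SyntheticConfig(**{"seed": int(rng.integers(2**31)), **cfg.synthetic})
            geno, phen_raw, covars, truth = generate_linked_dataset(scfg)
            sim_dir = out / "simulated"
            write_dataset(sim_dir, geno, phen_raw, covars, truth)
            manifest.outputs["simulated"] = str(sim_dir)
            # smooth the simulated volumes exactly as real data would be
            vols = [
                gaussian_smooth(unflatten_map(phen_raw.values[i], phen_raw.mask),
                                cfg.fwhm_mm, phen_raw.voxel_size_mm)
                for i in range(phen_raw.n_subjects)
            ]
            phen = mask_and_flatten(vols, phen_raw.mask, phen_raw.voxel_size_mm)
        else:
            src = cfg.plink_prefix or cfg.dosage_tsv
            if src is None:
                raise FileNotFoundError("no genotype input configured")
            geno = read_genotypes(src)
            covars = pd.read_csv(cfg.covariates_tsv, sep="\t")
            geno.sample_records = covars.copy()
            phen = _load_phenotypes(cfg, covars["sample_id"].tolist())
            for f in [cfg.covariates_tsv, cfg.mask_path]:
                if f:
                    manifest.input_checksums[str(f)] = _sha256(Path(f))
        _done("input", t0)

        # ---- qc ----------------------------------------------------------
        t0 = _stage("qc")
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        geno_f, report = qc.filter_variants(geno, cfg.min_call_rate, cfg.min_maf, cfg.hwe_alpha)
        retained = qc.ld_prune(geno_f, cfg.ld_window, cfg.ld_step, cfg.ld_r2_max)
        geno_p = geno_f.subset_snps(geno_f.snp_records["snp_id"].isin(retained).to_numpy())
        evecs, evals = qc.eigenstrat_pca(geno_p, n_axes=cfg.n_pca_axes)
        axes = qc.select_ancestry_axes(
            evecs, geno.sample_records.get("ethnicity", pd.Series(["x"] * geno.n_subjects)),
            n_keep=cfg.n_ancestry_axes,
        )
        anc = evecs[:, axes] if axes else np.empty((geno.n_subjects, 0))
        dos_complete = qc.mean_impute(geno_p.dosages)
        dos_resid = qc.regress_out_covariates(dos_complete, anc) if axes else dos_complete
        group = covars["group"].to_numpy()
        covar_cols = np.column_stack([covars["age"].to_numpy(float), covars["sex"].to_numpy(float), anc])
        kept_idx, prefilter_p, flags = qc.logistic_prefilter(
            dos_resid, group, covar_cols, alpha=cfg.prefilter_alpha
        )
        X_gene = dos_resid[:, kept_idx]
        gene_snps = geno_p.snp_records.iloc[kept_idx].reset_index(drop=True)
        report.to_frame().to_csv(qc_dir / "qc_report.tsv", sep="\t", index=False)
        (qc_dir / "qc_report.json").write_text(json.dumps({
            "n_input": report.n_input, "removed": report.removed,
            "n_after_filters": report.n_retained, "n_after_ld_prune": len(retained),
            "n_after_prefilter": int(kept_idx.size), "ancestry_axes": axes,
            "thresholds": report.thresholds,
        }, indent=2))
        pd.DataFrame({"snp_id": geno_p.snp_records["snp_id"], "p": prefilter_p,
                      "flagged": flags}).to_csv(qc_dir / "prefilter.tsv", sep="\t", index=False)
        manifest.outputs["qc"] = str(qc_dir)
        _done("qc", t0)

        # ---- fuse --------------------------------------------------------
        t0 = _stage("fuse")
        fuse_dir = out / "fusion"
        fuse_dir.mkdir(exist_ok=True)
        k_gene = cfg.k_gene if cfg.k_gene is not None else max(1, estimate_order_mdl(X_gene))
        k_brain = cfg.k_brain if cfg.k_brain is not None else max(1, estimate_order_mdl(phen.values))
        fusion_kwargs = dict(
            K_gene=k_gene, K_brain=k_brain, lambda_couple=cfg.lambda_couple,
            tau_link=cfg.tau_link, r_cap=cfg.r_cap, max_epochs=cfg.max_epochs,
            lr=cfg.lr, tol=cfg.tol,
        )
        fuse_seed = int(rng.integers(2**31))
        result = run_para_ica(X_gene, phen.values, seed=fuse_seed, **fusion_kwargs)
        pd.DataFrame(result.gene_model.loadings,
                     columns=[f"G{k+1}" for k in range(k_gene)]).to_csv(
            fuse_dir / "gene_loadings.tsv", sep="\t", index=False)
        pd.DataFrame(result.brain_model.loadings,
                     columns=[f"S{k+1}" for k in range(k_brain)]).to_csv(
            fuse_dir / "brain_loadings.tsv", sep="\t", index=False)
        pd.DataFrame(result.linked_pairs, columns=["gene", "brain", "r"]).to_csv(
            fuse_dir / "linked_pairs.tsv", sep="\t", index=False)
        result.objective_trace.to_json(fuse_dir / "trace.json", orient="records")
        cluster_rows = []
        for k in range(k_brain):
            zrow = result.brain_model.sources[k]
            zmap = unflatten_map((zrow - zrow.mean()) / zrow.std(), phen.mask)
            save_nifti(zmap, fuse_dir / f"brain_component_{k+1}_z.nii",
                       voxel_size_mm=phen.voxel_size_mm)
            ct = threshold_component_map(zrow, phen.mask, cfg.z_thresh, cfg.min_cluster)
            for _, row in ct.clusters.iterrows():
                cluster_rows.append({"component": k, "size": row["size"],
                                     "peak_abs_z": row["peak_abs_z"],
                                     "peak_ijk": row["peak_ijk"]})
        pd.DataFrame(cluster_rows, columns=["component", "size", "peak_abs_z", "peak_ijk"]).to_csv(
            fuse_dir / "clusters.tsv", sep="\t", index=False)
        manifest.outputs["fusion"] = str(fuse_dir)
        _done("fuse", t0)

        # ---- stability ---------------------------------------------------
        if cfg.run_stability:
            t0 = _stage("stability")
            rep = loo_stability(
                X_gene, phen.values, {**fusion_kwargs, "seed": fuse_seed},
                holdout_frac=cfg.holdout_frac, repeats=cfg.stability_repeats,
                tau_stab=cfg.tau_stab, seed=int(rng.integers(2**31)),
                full_result=result,
            )
            stab_dir = out / "stability"
            stab_dir.mkdir(exist_ok=True)
            rep.to_frame().to_csv(stab_dir / "stability.tsv", sep="\t", index=False)
            (stab_dir / "stability.json").write_text(json.dumps({
                "percent_stable": rep.percent_stable,
                "mean_correlation": rep.mean_correlation,
                "repeats": rep.repeats_done, "holdout_frac": rep.holdout_frac,
                "tau_stab": rep.tau_stab}, indent=2))
            manifest.outputs["stability"] = str(stab_dir)
            _done("stability", t0)

        # ---- associate ---------------------------------------------------
        t0 = _stage("associate")
        assoc_dir = out / "association"
        assoc_dir.mkdir(exist_ok=True)
        Z = np.column_stack([covars["age"].to_numpy(float), covars["sex"].to_numpy(float),
                             anc, group.astype(float)])
        pairs = test_all_pairs(result.gene_model.loadings, result.brain_model.loadings,
                               Z, alpha=cfg.assoc_alpha)
        pairs.table.to_csv(assoc_dir / "pair_tests.tsv", sep="\t", index=False)
        gd_gene = group_difference_tests(result.gene_model.loadings, group)
        gd_brain = group_difference_tests(result.brain_model.loadings, group)
        gd_gene.to_csv(assoc_dir / "group_diff_gene.tsv", sep="\t", index=False)
        gd_brain.to_csv(assoc_dir / "group_diff_brain.tsv", sep="\t", index=False)
        score_cols = [c for c in covars.columns if c.startswith("score_")]
        if score_cols:
            clin = clinical_correlations(
                result.brain_model.loadings, covars[score_cols],
                np.column_stack([covars["age"].to_numpy(float), covars["sex"].to_numpy(float)]),
            )
            clin.to_csv(assoc_dir / "clinical_correlations.tsv", sep="\t", index=False)
        (assoc_dir / "significant_pairs.json").write_text(
            pairs.significant_pairs().to_json(orient="records"))
        manifest.outputs["association"] = str(assoc_dir)
        _done("associate", t0)

        # ---- genes + enrich ---------------------------------------------
        if cfg.run_genomics and cfg.gene_bed:
            t0 = _stage("genes")
            gen_dir = out / "genomics"
            gen_dir.mkdir(exist_ok=True)
            gene_model = genomics.read_gene_bed(cfg.gene_bed)
            assign = genomics.annotate_snps_to_genes(gene_snps, gene_model)
            sig = pairs.significant_pairs()
            comp = int(sig["gene"].iloc[0]) if len(sig) else 0
            gene_tbl = genomics.gene_tests_for_component(
                result.gene_model.sources[comp], gene_snps, assign, X_gene,
                n_sims=cfg.gene_test_sims, seed=int(rng.integers(2**31)))
            gene_tbl.to_csv(gen_dir / "gene_tests.tsv", sep="\t", index=False)
            selected = genomics.select_component_genes(gene_tbl, alpha=cfg.gene_alpha)
            if cfg.pathway_gmt:
                db = genomics.read_gmt(cfg.pathway_gmt)
                background = gene_tbl["symbol"].tolist()
                enr = genomics.hypergeometric_enrichment(selected, db, background)
                enr.table.to_csv(gen_dir / "enrichment.tsv", sep="\t", index=False)
            manifest.outputs["genomics"] = str(gen_dir)
            _done("genes", t0)
    except Exception:
        manifest.save(out / "manifest.json")
        raise
    manifest.save(out / "manifest.json")
    return manifest
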