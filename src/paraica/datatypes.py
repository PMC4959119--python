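"""Core in-memory containers shared across the pipeline stages.

Conventions
-----------
* Dosage matrices are subjects x SNPs, entries in {0, 1, 2} counting minor
  (A1) alleles, with ``numpy.nan`` for missing calls.
* Voxel matrices are subjects x in-mask voxels, flattened in Fortran order
  (x-fastest) over the grid; ``PhenotypeMatrix.voxel_index_map`` records the
  linear indices so maps can be reconstructed bit-for-bit.
* Component models store per-subject loading coefficients (subjects x K)
  and feature-space sources (K x features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "ComponentModel",
    "ParaIcaResult",
    "ClusterTable",
]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosages with per-SNP and per-subject metadata.

    ``snp_records`` columns: ``snp_id, chrom, pos, a1, a2`` (position 1-based,
    strictly increasing within each chromosome).  ``sample_records`` columns
    include at least ``sample_id``; QC and association stages expect ``age``,
    ``sex``, ``group`` and ``ethnicity`` when present.
    """

    dosages: np.ndarray
    snp_records: pd.DataFrame
    sample_records: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D subjects x SNPs matrix")
        if self.dosages.shape[1] != len(self.snp_records):
            raise ValueError(
                f"dosage columns ({self.dosages.shape[1]}) != snp records "
                f"({len(self.snp_records)})"
            )
        if self.dosages.shape[0] != len(self.sample_records):
            raise ValueError(
                f"dosage rows ({self.dosages.shape[0]}) != sample records "
                f"({len(self.sample_records)})"
            )
        for chrom, grp in self.snp_records.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to SNP columns ``keep`` (bool mask or indices)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep].copy(),
            snp_records=self.snp_records.iloc[keep].reset_index(drop=True),
            sample_records=self.sample_records.copy(),
        )


@dataclass
class PhenotypeMatrix:
    """Subjects x in-mask voxels with the geometry needed to rebuild maps."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    voxel_index_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        support = np.flatnonzero(self.mask.reshape(-1, order="F"))
        if self.voxel_index_map is None:
            self.voxel_index_map = support
        elif not np.array_equal(np.sort(self.voxel_index_map), support):
            raise ValueError("voxel_index_map is not a bijection onto the mask support")
        if self.values.shape[1] != support.size:
            raise ValueError(
                f"value columns ({self.values.shape[1]}) != mask support ({support.size})"
            )

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class ComponentModel:
    """One modality's decomposition into loadings and sources.

    ``loadings`` are the per-subject loading coefficients (subjects x K),
    ``sources`` the feature-space patterns (K x features).  Components are
    ordered by descending explained variance of the reconstruction.
    """

    loadings: np.ndarray
    sources: np.ndarray
    modality: str
    explained_variance: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.sources = np.asarray(self.sources, dtype=float)
        if self.loadings.shape[1] != self.sources.shape[0]:
            raise ValueError("loadings and sources disagree on K")
        if self.explained_variance is None:
            recon = self.loadings @ self.sources
            tot = np.sum(recon**2)
            ev = np.array(
                [np.sum((np.outer(self.loadings[:, k], self.sources[k])) ** 2) for k in range(self.k)]
            )
            self.explained_variance = ev / tot if tot > 0 else ev

    @property
    def k(self) -> int:
        return self.sources.shape[0]

    def reorder(self, order: np.ndarray) -> "ComponentModel":
        return ComponentModel(
            loadings=self.loadings[:, order],
            sources=self.sources[order],
            modality=self.modality,
            explained_variance=np.asarray(self.explained_variance)[order],
        )


@dataclass
class ParaIcaResult:
    """Paired decompositions plus the linked-pair table and convergence trace."""

    gene_model: ComponentModel
    brain_model: ComponentModel
    linked_pairs: list  # (gene index, brain index, loading correlation)
    objective_trace: pd.DataFrame
    config: dict
    converged: bool = True


@dataclass
class ClusterTable:
    """Suprathreshold clusters of one component z-map, sorted by peak |z|."""

    clusters: pd.DataFrame  # columns: size, peak_abs_z, peak_ijk, voxels
    z_thresh: float
    min_cluster: int

    def __len__(self) -> int:
        return len(self.clusters)
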