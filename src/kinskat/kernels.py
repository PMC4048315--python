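"""SNP weights and regional kernel matrices.

A region's kernel ``K`` measures pairwise genotype similarity over the m
SNPs of the region.  The weighted linear kernel ``K = G W W G^T`` is the
workhorse (and the one with a fast m-by-m eigenvalue path); polynomial
and IBS kernels are also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger("kinskat")

__all__ = [
    "RegionGenotypes",
    "WeightScheme",
    "KernelSpec",
    "clean_region",
    "compute_weights",
    "build_kernel",
]


@dataclass
class RegionGenotypes:
    """Cleaned n-by-m dosage matrix for one region.

    After :func:`clean_region`: no missing entries, no monomorphic
    columns, ``maf`` holds the sample minor-allele frequency per retained
    SNP.  ``m = 0`` marks an untestable region (all columns dropped).
    """

    G: np.ndarray
    snp_ids: list[str]
    region_id: str
    maf: np.ndarray
    dropped_snps: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.G.shape[1] if self.G.size else 0

    @property
    def untestable(self) -> bool:
        return self.m == 0


@dataclass
class WeightScheme:
    """Per-SNP weight rule: beta density on MAF (default Beta(1, 25)),
    Madsen–Browning ``1/sqrt(maf (1 - maf))``, uniform, or custom values."""

    kind: str = "beta"
    a: float = 1.0
    b: float = 25.0
    custom: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "madsen_browning", "uniform", "custom"):
            raise ValueError(f"unknown weight scheme {self.kind!r}")


@dataclass
class KernelSpec:
    kind: str = "linear_weighted"
    degree: int = 1
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear_weighted", "ibs", "polynomial"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.offset < 0:
            raise ValueError("polynomial offset must be >= 0")


def clean_region(
    G_raw: np.ndarray,
    snp_ids: list[str],
    region_id: str,
    maf_lower: float = 0.0,
    maf_upper: float = 0.5,
) -> RegionGenotypes:
    """Impute missing dosages, drop monomorphic SNPs, apply optional MAF window.

    Missing entries are imputed to the column mean dosage.  The MAF window
    is inclusive and defaults to (0, 0.5], i.e. no filtering beyond the
    monomorphic drop.  A region losing every column is returned with
    ``m = 0`` (untestable), never raised.
    """
    G = np.array(G_raw, dtype=float)
    if G.ndim != 2 or G.shape[1] != len(snp_ids):
        raise ValueError("G_raw shape does not match snp_ids")
    out = (G < 0) | (G > 2)
    if np.any(out[~np.isnan(G)]):
        raise ValueError(f"region {region_id}: dosages outside [0, 2]")
    col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    all_nan = np.isnan(col_mean)
    col_mean = np.where(all_nan, 0.0, col_mean)
    G = np.where(np.isnan(G), col_mean, G)
    p = G.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    poly = G.std(axis=0) > 0
    keep = poly & (maf >= maf_lower) & (maf <= maf_upper)
    dropped = [s for s, k in zip(snp_ids, keep) if not k]
    if dropped:
        logger.info("region %s: dropped %d/%d SNPs (monomorphic or outside MAF window)",
                    region_id, len(dropped), len(snp_ids))
    return RegionGenotypes(
        G=G[:, keep],
        snp_ids=[s for s, k in zip(snp_ids, keep) if k],
        region_id=region_id,
        maf=maf[keep],
        dropped_snps=dropped,
    )


def compute_weights(scheme: WeightScheme, maf: np.ndarray) -> np.ndarray:
    """Evaluate the weight rule on the sample minor-allele frequencies."""
    maf = np.asarray(maf, dtype=float)
    if maf.size and (np.any(maf <= 0) or np.any(maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if scheme.kind == "beta":
        w = stats.beta.pdf(maf, scheme.a, scheme.b)
    elif scheme.kind == "madsen_browning":
        w = 1.0 / np.sqrt(maf * (1.0 - maf))
    elif scheme.kind == "uniform":
        w = np.ones_like(maf)
    else:
        w = np.asarray(scheme.custom, dtype=float)
        if w.shape != maf.shape:
            raise ValueError("custom weights length does not match SNP count")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be strictly positive and finite")
    return w


def build_kernel(region: RegionGenotypes, w: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Assemble the n-by-n kernel matrix for a cleaned region.

    linear_weighted: ``K = G diag(w)^2 G^T``
    polynomial:      ``K_ij = (g_i^T diag(w)^2 g_j + c)^d``
    ibs:             ``K_ij = sum_k w_k^2 (2 - |g_ik - g_jk|) / sum_k 2 w_k^2``
    """
    if region.untestable:
        raise ValueError(f"region {region.region_id} has no testable SNPs")
    w = np.asarray(w, dtype=float)
    if w.shape[0] != region.m:
        raise ValueError("weight vector length does not match SNP count")
    Gw = region.G * w
    if spec.kind == "linear_weighted":
        K = Gw @ Gw.T
    elif spec.kind == "polynomial":
        K = (Gw @ Gw.T + spec.offset) ** spec.degree
    else:  # ibs
        w2 = w**2
        # sum_k w_k^2 |g_ik - g_jk| via per-SNP absolute differences
        n = region.G.shape[0]
        D = np.zeros((n, n))
        for k in range(region.m):
            D += w2[k] * np.abs(region.G[:, k, None] - region.G[None, :, k])
        K = (2.0 * w2.sum() - D) / (2.0 * w2.sum())
    return 0.5 * (K + K.T)
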