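"""Relationship (twice-kinship) matrices from pedigrees or dense genotypes.

The polygenic covariance structure of a quantitative trait in a family
sample is ``sigma_b^2 * R`` where ``R = 2 * Phi`` and ``Phi`` is the matrix
of kinship coefficients.  ``R`` can be built from a pedigree (expected
genome sharing) or estimated from a panel of common markers (realized
genome sharing, a VanRaden-type centered-and-scaled cross-product).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("kinskat")

__all__ = ["Pedigree", "KinshipMatrix", "PedigreeError", "pedigree_kinship", "genomic_kinship"]

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown parent, duplicate id)."""


@dataclass
class Pedigree:
    """A set of (possibly disconnected) pedigrees.

    Parent ids equal to ``"0"``/``None`` mean "founder on that side".  Sex is
    coded 1 = male, 2 = female, 0 = unknown; it is carried for file
    round-trips but plays no role in (autosomal) kinship.
    """

    individual_ids: list[str]
    father_ids: list[str | None]
    mother_ids: list[str | None]
    sex: list[int]
    family_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        if len(set(self.individual_ids)) != n:
            raise PedigreeError("duplicate individual ids in pedigree")
        if not self.family_ids:
            self.family_ids = ["fam1"] * n
        self.father_ids = [None if f in (MISSING_PARENT, None, "") else f for f in self.father_ids]
        self.mother_ids = [None if m in (MISSING_PARENT, None, "") else m for m in self.mother_ids]
        known = set(self.individual_ids)
        for pid in self.father_ids + self.mother_ids:
            if pid is not None and pid not in known:
                raise PedigreeError(f"parent id {pid!r} does not appear as an individual")

    def __len__(self) -> int:
        return len(self.individual_ids)

    @property
    def founder_mask(self) -> np.ndarray:
        return np.array(
            [f is None and m is None for f, m in zip(self.father_ids, self.mother_ids)]
        )

    def topological_order(self) -> list[int]:
        """Indices ordered parents-before-offspring (Kahn's algorithm).

        Raises :class:`PedigreeError` naming an individual on a cycle.
        """
        idx = {iid: i for i, iid in enumerate(self.individual_ids)}
        n = len(self)
        n_pending = np.zeros(n, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for pid in (self.father_ids[i], self.mother_ids[i]):
                if pid is not None:
                    n_pending[i] += 1
                    children[idx[pid]].append(i)
        queue = deque(i for i in range(n) if n_pending[i] == 0)
        order: list[int] = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children[i]:
                n_pending[c] -= 1
                if n_pending[c] == 0:
                    queue.append(c)
        if len(order) < n:
            bad = next(i for i in range(n) if n_pending[i] > 0)
            raise PedigreeError(
                f"cycle in pedigree involving individual {self.individual_ids[bad]!r}"
            )
        return order


@dataclass
class KinshipMatrix:
    """Square relationship matrix ``R`` aligned to ``sample_ids``."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in kinship matrix")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"kinship matrix is not symmetric (max asymmetry {asym:.3g})")
        self.values = 0.5 * (self.values + self.values.T)

    def subset(self, sample_ids: list[str]) -> "KinshipMatrix":
        """Reorder/subset to ``sample_ids`` (join by id, never by position)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from kinship matrix: {missing[:5]}")
        take = np.array([pos[s] for s in sample_ids])
        return KinshipMatrix(list(sample_ids), self.values[np.ix_(take, take)])


def pedigree_kinship(ped: Pedigree, order: list[str] | None = None) -> KinshipMatrix:
    """Expected relationship matrix ``R = 2 * Phi`` from pedigree structure.

    Uses the recursive (tabular) method over a topological ordering:
    ``Phi_ii = (1 + Phi_fm) / 2`` and ``Phi_ij = (Phi_jf + Phi_jm) / 2``
    for ``j`` preceding ``i``.  Founders are assumed non-inbred and
    mutually unrelated, so the result is block-diagonal across
    disconnected pedigrees.
    """
    topo = ped.topological_order()
    n = len(ped)
    idx = {iid: i for i, iid in enumerate(ped.individual_ids)}
    phi = np.zeros((n, n))
    seen: list[int] = []
    for i in topo:
        f, m = ped.father_ids[i], ped.mother_ids[i]
        fi = idx[f] if f is not None else None
        mi = idx[m] if m is not None else None
        if seen:
            prev = np.array(seen)
            row = np.zeros(len(seen))
            if fi is not None:
                row += phi[fi, prev]
            if mi is not None:
                row += phi[mi, prev]
            row *= 0.5
            phi[i, prev] = row
            phi[prev, i] = row
        self_k = 0.5
        if fi is not None and mi is not None:
            self_k = 0.5 * (1.0 + phi[fi, mi])
        phi[i, i] = self_k
        seen.append(i)
    km = KinshipMatrix(list(ped.individual_ids), 2.0 * phi)
    if order is not None:
        km = km.subset(list(order))
    return km


def genomic_kinship(
    G_common: np.ndarray,
    sample_ids: list[str],
    min_maf: float = 0.01,
) -> KinshipMatrix:
    """Realized relationship matrix from a dense common-marker panel.

    Centered-and-scaled cross-product averaged over retained markers:
    ``R_ij = mean_k (g_ik - 2 p_k)(g_jk - 2 p_k) / (2 p_k (1 - p_k))``
    with ``p_k`` the sample allele frequency.  Markers that are
    monomorphic or have minor-allele frequency below ``min_maf`` are
    excluded; missing dosages are imputed to ``2 p_k``.
    """
    G = np.array(G_common, dtype=float)
    if G.ndim != 2:
        raise ValueError("G_common must be a 2-D dosage matrix")
    n, m = G.shape
    if len(sample_ids) != n:
        raise ValueError("sample_ids length does not match G_common rows")
    obs = ~np.isnan(G)
    all_missing = ~obs.any(axis=1)
    if all_missing.any():
        bad = sample_ids[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"sample {bad!r} has no observed genotypes")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (maf >= min_maf) & (maf > 0.0)
    if not keep.any():
        raise ValueError("no polymorphic markers above the MAF threshold")
    n_dropped = int(m - keep.sum())
    if n_dropped:
        logger.info("genomic_kinship: dropped %d/%d markers (maf < %g)", n_dropped, m, min_maf)
    G = G[:, keep]
    p = p[keep]
    # impute missing to the marker mean dosage 2p, then center
    Z = np.where(np.isnan(G), 2.0 * p, G) - 2.0 * p
    Z /= np.sqrt(2.0 * p * (1.0 - p))
    R = (Z @ Z.T) / keep.sum()
    return KinshipMatrix(list(sample_ids), R)
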