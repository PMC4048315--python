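"""Shared fixtures: small family samples with fitted null models.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import kinskat as ks
from kinskat.null_model import precompute_invariants


@pytest.fixture(scope="session")
def fam7():
    """7 three-generation families (n = 126) with kinship and cached eigen."""
    ped = ks.make_pedigrees(7)
    R = ks.pedigree_kinship(ped)
    d, U = np.linalg.eigh(R.values)
    return {"ped": ped, "R": R, "eig": (np.clip(d, 0.0, None), U), "n": len(ped)}


@pytest.fixture(scope="session")
def fitted7(fam7):
    """A trait realization on fam7 with its fitted null model and invariants."""
    ped, R, eig = fam7["ped"], fam7["R"], fam7["eig"]
    n = fam7["n"]
    X = np.ones((n, 1))
    spec = ks.TraitSimulationSpec(alpha=np.array([0.0]), h2=0.44, seed=3)
    y = ks.simulate_trait(R, X, spec, eigen_R=eig)
    pheno = ks.PhenotypeData(y, X, ped.individual_ids)
    null = ks.fit_null(pheno, R, eigen_R=eig)
    pre = precompute_invariants(null, pheno, R)
    return {"pheno": pheno, "null": null, "pre": pre, **fam7}


@pytest.fixture(scope="session")
def rare_region7(fam7):
    """A 10-SNP rare-variant region gene-dropped on fam7."""
    G, snps = ks.gene_drop(fam7["ped"], (0.01, 0.12), 10, seed=11)
    region = ks.clean_region(G, snps.snp_id.tolist(), "r1")
    return {"G": G, "snps": snps, "region": region}


def random_family_fixture(rng, n_range=(30, 200), m_range=(1, 20), p_cov=2):
    """A random relatedness structure, covariates, trait and region.

    R is a dense PSD matrix (normalized random Gram matrix plus a ridge),
    standing in for an arbitrary relationship matrix; the trait is drawn
    from the mixed model at random variance components.
    """
    n = int(rng.integers(*n_range))
    m = int(rng.integers(m_range[0], m_range[1] + 1))
    B = rng.standard_normal((n, 2 * n))
    R = B @ B.T / (2 * n) + 0.2 * np.eye(n)
    scale = np.sqrt(np.diag(R))
    R = R / np.outer(scale, scale)
    ids = [f"s{i}" for i in range(n)]
    km = ks.KinshipMatrix(ids, R)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p_cov)])
    alpha = rng.normal(0, 1, X.shape[1])
    sb, se = rng.uniform(0.3, 1.5), rng.uniform(0.3, 1.5)
    d, U = np.linalg.eigh(R)
    y = (
        X @ alpha
        + np.sqrt(sb) * (U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(n)))
        + np.sqrt(se) * rng.standard_normal(n)
    )
    pheno = ks.PhenotypeData(y, X, ids)
    maf = rng.uniform(0.02, 0.5, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    region = ks.clean_region(G, [f"v{j}" for j in range(m)], "rx")
    return km, pheno, region
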