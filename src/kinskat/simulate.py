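"""Pedigree, genotype and trait simulation with known variance components.

Everything the association pipeline consumes can be generated here:
replicated family blocks, gene-dropped unlinked SNPs (founder alleles
Bernoulli(p), fair Mendelian transmission), and quantitative traits drawn
from ``y = X alpha + G beta + b + eps`` with ``b ~ N(0, sigma_b^2 R)``
and ``eps ~ N(0, sigma_e^2 I)``.  A single integer seed expands into
independent substreams per component via ``numpy.random.SeedSequence``.

Writers emit the package's own input dialects (FAM pedigree, genotype
matrix TSV, minimal VCF, phenotype TSV, SetID-style region TSV) so that
end-to-end tests consume only generated files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix, Pedigree

__all__ = [
    "TraitSimulationSpec",
    "make_pedigrees",
    "gene_drop",
    "simulate_trait",
    "make_regions",
    "write_fam",
    "write_genotype_matrix",
    "write_vcf",
    "write_phenotypes",
    "write_regions",
    "make_dataset",
]


@dataclass
class TraitSimulationSpec:
    """Generative description of a quantitative trait.

    ``alpha`` are covariate effects (first entry = intercept), ``h2`` the
    polygenic heritability of the residual (non-regional) variance,
    ``total_var`` the residual variance ``sigma_b^2 + sigma_e^2``, and
    ``causal`` a list of ``(snp_id, beta)`` regional fixed effects.
    """

    alpha: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    h2: float = 0.44
    total_var: float = 1.0
    causal: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must lie in [0, 1)")
        if self.total_var <= 0:
            raise ValueError("total_var must be positive")


def _three_generation(fam: str) -> tuple[list, list, list, list]:
    """18-member family: 2 grandparents, 4 children + 4 married-in
    founders, 2 grandchildren per couple."""
    ids, fa, mo, sex = [], [], [], []

    def add(name, f, m, s):
        ids.append(f"{fam}_{name}")
        fa.append(f"{fam}_{f}" if f else None)
        mo.append(f"{fam}_{m}" if m else None)
        sex.append(s)

    add("gf", None, None, 1)
    add("gm", None, None, 2)
    for c in range(1, 5):
        s = 1 if c % 2 else 2
        add(f"c{c}", "gf", "gm", s)
        add(f"s{c}", None, None, 2 if s == 1 else 1)
        father = f"c{c}" if s == 1 else f"s{c}"
        mother = f"s{c}" if s == 1 else f"c{c}"
        for g in range(1, 3):
            add(f"g{c}{g}", father, mother, 1 if g % 2 else 2)
    return ids, fa, mo, sex


def _nuclear(fam: str, n_children: int = 2) -> tuple[list, list, list, list]:
    ids = [f"{fam}_dad", f"{fam}_mom"]
    fa: list = [None, None]
    mo: list = [None, None]
    sex = [1, 2]
    for c in range(1, n_children + 1):
        ids.append(f"{fam}_kid{c}")
        fa.append(f"{fam}_dad")
        mo.append(f"{fam}_mom")
        sex.append(1 if c % 2 else 2)
    return ids, fa, mo, sex


def make_pedigrees(
    n_families: int,
    template: str = "three_generation",
    seed: int = 0,
    n_children: int = 2,
) -> Pedigree:
    """Replicated disconnected family blocks; deterministic per seed.

    ``three_generation`` blocks have 18 members; ``nuclear`` blocks have
    2 parents plus ``n_children``.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    ids, fa, mo, sex, fams = [], [], [], [], []
    for k in range(1, n_families + 1):
        fam = f"fam{k}"
        if template == "three_generation":
            i, f, m, s = _three_generation(fam)
        elif template == "nuclear":
            i, f, m, s = _nuclear(fam, n_children)
        else:
            raise ValueError(f"unknown template {template!r}")
        ids += i
        fa += f
        mo += m
        sex += s
        fams += [fam] * len(i)
    return Pedigree(ids, fa, mo, sex, family_ids=fams)


def gene_drop(
    ped: Pedigree,
    maf_spectrum,
    m_snps: int,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop unlinked SNPs through the pedigree.

    ``maf_spectrum`` is either an array of m founder allele frequencies
    or a ``(low, high)`` tuple sampled uniformly.  Founder haplotypes are
    Bernoulli(p); each transmission picks one parental allele at random.
    Returns the n-by-m dosage matrix (rows in pedigree order) and a SNP
    table with ids, founder frequencies and sample frequencies.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    if isinstance(maf_spectrum, tuple) and len(maf_spectrum) == 2:
        p = rng.uniform(maf_spectrum[0], maf_spectrum[1], size=m_snps)
    else:
        p = np.asarray(maf_spectrum, dtype=float)
        if p.shape != (m_snps,):
            raise ValueError("maf_spectrum array must have length m_snps")
    if np.any(p <= 0) or np.any(p > 0.5):
        raise ValueError("founder allele frequencies must lie in (0, 0.5]")
    n = len(ped)
    idx = {iid: i for i, iid in enumerate(ped.individual_ids)}
    hap = np.zeros((n, 2, m_snps), dtype=np.int8)
    for i in ped.topological_order():
        f, m = ped.father_ids[i], ped.mother_ids[i]
        for slot, parent in enumerate((f, m)):
            if parent is None:
                hap[i, slot] = rng.random(m_snps) < p
            else:
                pick = rng.integers(0, 2, size=m_snps)
                hap[i, slot] = hap[idx[parent], pick, np.arange(m_snps)]
    G = hap.sum(axis=1).astype(float)
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(m_snps)],
            "founder_freq": p,
            "sample_freq": G.mean(axis=0) / 2.0,
        }
    )
    return G, snps


def simulate_trait(
    R: KinshipMatrix,
    X: np.ndarray,
    spec: TraitSimulationSpec,
    G_causal: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    eigen_R: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Draw one trait realization ``y = X alpha + G beta + b + eps``.

    The polygenic term is drawn through the eigenfactor of R (which may
    be singular); variance split is ``sigma_b^2 = h2 * total_var``,
    ``sigma_e^2 = (1 - h2) * total_var``.  ``eigen_R`` may pass a cached
    eigendecomposition of R for replicate studies.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    n = len(R.sample_ids)
    X = np.atleast_2d(np.asarray(X, float))
    alpha = np.asarray(spec.alpha, float)
    if X.shape != (n, alpha.size):
        raise ValueError("X shape does not match alpha")
    y = X @ alpha
    if G_causal is not None and beta is not None and len(beta):
        y = y + np.asarray(G_causal, float) @ np.asarray(beta, float)
    sigma_b = np.sqrt(spec.h2 * spec.total_var)
    sigma_e = np.sqrt((1.0 - spec.h2) * spec.total_var)
    if sigma_b > 0:
        d, U = eigen_R if eigen_R is not None else np.linalg.eigh(R.values)
        d = np.clip(d, 0.0, None)
        z = np.random.default_rng(ss[1]).standard_normal(n)
        y = y + sigma_b * (U @ (np.sqrt(d) * z))
    y = y + sigma_e * np.random.default_rng(ss[2]).standard_normal(n)
    return y


def make_regions(
    snp_ids: list[str],
    seed: int = 0,
    min_size: int = 2,
    max_size: int = 102,
    median_size: int = 4,
) -> dict[str, list[str]]:
    """Partition SNPs into contiguous regions with a right-skewed size law.

    Sizes are drawn from a geometric-like distribution clipped to
    ``[min_size, max_size]`` with the requested median — mirroring
    exome-like region files where most genes carry a handful of SNPs and
    a few carry over a hundred.
    """
    rng = np.random.default_rng(seed)
    regions: dict[str, list[str]] = {}
    i, r = 0, 0
    # geometric with median ~ median_size - min_size + 1 above the floor
    geom_p = 1.0 - 0.5 ** (1.0 / max(median_size - min_size + 1, 1))
    while i < len(snp_ids):
        size = min_size + rng.geometric(geom_p) - 1
        size = int(min(size, max_size, len(snp_ids) - i))
        if size < min_size:
            break  # trailing SNPs shorter than the minimum are left out
        r += 1
        regions[f"region{r}"] = snp_ids[i : i + size]
        i += size
    return regions


# ---------------------------------------------------------------------------
# writers for the package's own input dialects


def write_fam(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for fam, iid, f, m, s in zip(
            ped.family_ids, ped.individual_ids, ped.father_ids, ped.mother_ids, ped.sex
        ):
            fh.write(f"{fam}\t{iid}\t{f or 0}\t{m or 0}\t{s}\t-9\n")


def write_genotype_matrix(G: np.ndarray, sample_ids, snp_ids, path) -> None:
    """Rows = samples, header = SNP ids, first column = sample id."""
    df = pd.DataFrame(G, columns=list(snp_ids))
    df.insert(0, "id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(G: np.ndarray, sample_ids, snp_ids, path, chrom: str = "1") -> None:
    """Minimal VCF v4.2 with GT-only diploid records, one per SNP."""
    G = np.asarray(G)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, sample_ids)) + "\n")
        for j, sid in enumerate(snp_ids):
            calls = [
                "./." if np.isnan(G[i, j]) else gt_map[int(round(G[i, j]))]
                for i in range(G.shape[0])
            ]
            fh.write(f"{chrom}\t{1000 + 10 * j}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def write_phenotypes(sample_ids, y, covariates: dict[str, np.ndarray], path) -> None:
    df = pd.DataFrame({"id": list(sample_ids), "trait": np.asarray(y, float)})
    for name, vals in covariates.items():
        df[name] = np.asarray(vals, float)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_regions(region_map: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for rid, snps in region_map.items():
            for s in snps:
                fh.write(f"{rid}\t{s}\n")


def make_dataset(
    out_dir,
    n_families: int = 7,
    template: str = "three_generation",
    m_snps: int = 300,
    maf_range: tuple[float, float] = (0.001, 0.5),
    h2: float = 0.44,
    seed: int = 0,
    causal: list[tuple[str, float]] | None = None,
    genotype_format: str = "tsv",
) -> dict[str, Path]:
    """Emit a complete, self-consistent input bundle for the pipeline.

    Defaults mimic an exome-like family study: replicated 18-member
    three-generation pedigrees, founder allele frequencies spanning
    0.001–0.5, a trait with residual heritability 0.44 and age and
    smoking covariate effects.
    """
    from .kinship import pedigree_kinship

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_drop, s_trait, s_cov, s_reg = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    ped = make_pedigrees(n_families, template=template, seed=seed)
    G, snps = gene_drop(ped, maf_range, m_snps, seed=s_drop)
    R = pedigree_kinship(ped)
    n = len(ped)

    rng = np.random.default_rng(s_cov)
    age = rng.uniform(20, 80, size=n)
    smoking = rng.integers(0, 2, size=n).astype(float)
    X = np.column_stack([np.ones(n), age, smoking])
    alpha = np.array([0.0, 0.02, 0.5])

    causal = causal or []
    beta = np.array([b for _, b in causal])
    if len(causal):
        cols = [snps.snp_id.tolist().index(s) for s, _ in causal]
        G_causal = G[:, cols]
    else:
        G_causal = None
    spec = TraitSimulationSpec(alpha=alpha, h2=h2, total_var=1.0, causal=causal, seed=s_trait)
    y = simulate_trait(R, X, spec, G_causal=G_causal, beta=beta if len(causal) else None)

    region_map = make_regions(snps.snp_id.tolist(), seed=s_reg)

    paths = {
        "fam": out / "pedigree.fam",
        "phenotypes": out / "phenotypes.tsv",
        "regions": out / "regions.tsv",
    }
    write_fam(ped, paths["fam"])
    write_phenotypes(ped.individual_ids, y, {"age": age, "smoking": smoking},
                     paths["phenotypes"])
    write_regions(region_map, paths["regions"])
    if genotype_format == "vcf":
        paths["genotypes"] = out / "genotypes.vcf"
        write_vcf(G, ped.individual_ids, snps.snp_id.tolist(), paths["genotypes"])
    else:
        paths["genotypes"] = out / "genotypes.tsv"
        write_genotype_matrix(G, ped.individual_ids, snps.snp_id.tolist(),
                              paths["genotypes"])
    return paths
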