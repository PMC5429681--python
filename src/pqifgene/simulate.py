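"""Synthetic longitudinal sequencing data for estimator evaluation.

Generates everything a gene-based longitudinal binary analysis needs:

* additive-coded SNP genotypes per gene (10 SNPs per gene, rare:common split
  6:4 under the MAF < 5% convention, Hardy-Weinberg binomial(2, MAF) draws);
* WSS-collapsed gene scores (via the `collapse` module);
* covariate processes: baseline age from a truncated normal matched to a
  population screening cohort (mean 53.30 y, sd 15.91 y, range 20.3-96.72 y)
  advancing deterministically by +3.9 y at exam 2 and +6.9 y at exam 3, and
  a smoking indicator with 22.9% baseline prevalence and a 1.45% per-exam
  quit probability (quitting is absorbing);
* correlated binary responses from a marginal logistic model via the
  Emrich-Piedmonte latent-Gaussian construction, whose pairwise
  correlations on the binary scale follow the requested structure
  (exchangeable: rho; AR(1): rho^|t-s|).

All covariates and gene scores are standardized (mean 0, sd 1) before the
linear predictor is formed, so the true coefficient vector refers to
standardized predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri, owens_t
from scipy.stats import truncnorm

from .collapse import GeneMap, GenotypeMatrix, GeneScoreTable, collapse_all
from .qif import LongitudinalDesign

# Baseline-age law (years): truncated normal matched to cohort summaries.
AGE_MEAN, AGE_SD = 53.30, 15.91
AGE_RANGE = (20.3, 96.72)
AGE_INCREMENTS = (0.0, 3.9, 6.9)      # added to baseline age at exams 1..3
SMOKE_BASELINE = 0.229                # smoker prevalence at exam 1
SMOKE_QUIT = 0.0145                   # per-exam quit probability


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SimulationScenario:
    """One cell of the simulation design.

    ``p`` counts the non-intercept predictors: age, smoking, and p-2 gene
    scores of which ``q - 1`` are causal (age is the remaining signal).
    ``beta_signal`` holds the q nonzero coefficients in the order
    (age, causal genes...); all other entries of the truth are zero.
    """

    n: int = 500
    p: int = 20
    q: int = 4
    T: int = 3
    rho: float = 0.4
    structure: str = "ar1"
    beta_signal: tuple = (0.9, -0.7, -0.6, 0.5)
    intercept: float = 0.0
    snps_per_gene: int = 10
    n_rare: int = 6
    rare_maf: tuple = (0.005, 0.05)
    common_maf: tuple = (0.05, 0.5)
    replicates: int = 200
    lambda_min: float = 0.01
    lambda_max: float | None = None
    grid_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if len(self.beta_signal) != self.q:
            raise ValueError("beta_signal must have q entries")
        if self.n_rare > self.snps_per_gene:
            raise ValueError("more rare SNPs than SNPs per gene")
        if self.p < self.q + 1:
            raise ValueError("p must leave room for smoking and noise genes")

    @property
    def n_genes(self) -> int:
        return self.p - 2

    @property
    def n_causal_genes(self) -> int:
        return self.q - 1

    @property
    def gene_names(self) -> list[str]:
        return [f"gene{j + 1:02d}" for j in range(self.n_genes)]

    @property
    def columns(self) -> list[str]:
        g = self.gene_names
        c = self.n_causal_genes
        return ["age"] + g[:c] + ["smoke"] + g[c:]

    @property
    def truth(self) -> np.ndarray:
        # layout: age, causal genes, then smoke and noise genes (all zero)
        beta = np.zeros(self.p)
        beta[: self.q] = self.beta_signal
        return beta

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.truth)

    @property
    def support_names(self) -> list[str]:
        cols = self.columns
        return [cols[j] for j in self.support]

    @property
    def noise_gene_indices(self) -> np.ndarray:
        """Indices (within the p covariates) of the zero-effect gene scores."""
        cols = self.columns
        causal = set(self.support_names)
        return np.array(
            [j for j, c in enumerate(cols) if c.startswith("gene") and c not in causal]
        )


def scenario_one(n: int = 500, p: int = 20, rho: float = 0.4, **kw) -> SimulationScenario:
    """Four true signals (age + 3 genes), beta = (0.9, -0.7, -0.6, 0.5)."""
    return SimulationScenario(
        n=n, p=p, q=4, rho=rho, beta_signal=(0.9, -0.7, -0.6, 0.5), **kw
    )


def scenario_two(n: int = 500, p: int = 40, rho: float = 0.7, **kw) -> SimulationScenario:
    """Six true signals (age + 5 genes), beta = (0.9, -0.7, -0.7, -0.6, -0.6, 0.5)."""
    return SimulationScenario(
        n=n, p=p, q=6, rho=rho,
        beta_signal=(0.9, -0.7, -0.7, -0.6, -0.6, 0.5), **kw
    )


def default_lambda_max(n: int) -> float:
    """Grid upper end by sample size (0.35 / 0.25 / 0.2 for small/mid/large n)."""
    if n <= 200:
        return 0.35
    if n <= 300:
        return 0.25
    return 0.2


# ---------------------------------------------------------------------------
# Genotypes and covariates


def simulate_genotypes(
    n: int,
    n_genes: int,
    rng,
    snps_per_gene: int = 10,
    n_rare: int = 6,
    rare_maf: tuple = (0.005, 0.05),
    common_maf: tuple = (0.05, 0.5),
    gene_names: list[str] | None = None,
) -> tuple[GenotypeMatrix, GeneMap]:
    """Hardy-Weinberg genotypes for ``n_genes`` genes with a rare:common split."""
    rng = _rng(rng)
    if gene_names is None:
        gene_names = [f"gene{j + 1:02d}" for j in range(n_genes)]
    variants, cols, gmap = [], [], {}
    for gene in gene_names:
        mafs = np.concatenate(
            [
                rng.uniform(*rare_maf, size=n_rare),
                rng.uniform(*common_maf, size=snps_per_gene - n_rare),
            ]
        )
        vids = [f"{gene}_snp{k + 1}" for k in range(snps_per_gene)]
        gmap[gene] = vids
        variants.extend(vids)
        cols.append(rng.binomial(2, mafs[None, :], size=(n, snps_per_gene)))
    geno = GenotypeMatrix(
        individuals=[f"ind{i + 1}" for i in range(n)],
        variants=variants,
        dosages=np.concatenate(cols, axis=1).astype(float),
    )
    return geno, GeneMap(genes=gmap)


def simulate_covariates(n: int, T: int = 3, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Age and smoking panels over the exam grid (T = 3 by design).

    Ages increase deterministically between exams; smoking starts Bernoulli
    at exam 1 and each smoker independently quits with a small probability at
    every later exam, never resuming.
    """
    if T != len(AGE_INCREMENTS):
        raise ValueError(f"covariate process is defined for T={len(AGE_INCREMENTS)} exams")
    rng = _rng(rng)
    a, b = AGE_RANGE
    lo, hi = (a - AGE_MEAN) / AGE_SD, (b - AGE_MEAN) / AGE_SD
    base = truncnorm.rvs(lo, hi, loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=rng)
    age = base[:, None] + np.asarray(AGE_INCREMENTS)[None, :]
    smoke = np.zeros((n, T))
    smoke[:, 0] = rng.random(n) < SMOKE_BASELINE
    for t in range(1, T):
        keeps = rng.random(n) >= SMOKE_QUIT
        smoke[:, t] = smoke[:, t - 1] * keeps
    return age, smoke


# ---------------------------------------------------------------------------
# Emrich-Piedmonte correlated binary responses


def _bvn_cdf(h, k, r):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal, via Owen's T."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    r = np.asarray(r, dtype=float)
    # nudge exact zeros/unit correlations off the singular points
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    s = np.sqrt(1.0 - r * r)
    a1 = (k - r * h) / (h * s)
    a2 = (h - r * k) / (k * s)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a1) - owens_t(k, a2)
    return out - np.where(h * k < 0, 0.5, 0.0)


def binary_correlation_bounds(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    """Frechet bounds on the correlation of two Bernoulli margins."""
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    q1, q2 = 1.0 - p1, 1.0 - p2
    hi = np.minimum(np.sqrt(p1 * q2 / (p2 * q1)), np.sqrt(p2 * q1 / (p1 * q2)))
    lo = np.maximum(-np.sqrt(p1 * p2 / (q1 * q2)), -np.sqrt(q1 * q2 / (p1 * p2)))
    return lo, hi


def solve_latent_correlation(p1, p2, rho, n_bisect: int = 60) -> np.ndarray:
    """Latent-normal correlation reproducing a binary-scale correlation.

    Solves Phi2(z1, z2; r) = p1 p2 + rho sqrt(p1 q1 p2 q2) by monotone
    bisection (vectorized over margins).  Raises if rho is outside the
    admissible Frechet bounds for the given margins.
    """
    p1, p2 = np.atleast_1d(np.asarray(p1, float)), np.atleast_1d(np.asarray(p2, float))
    rho = np.broadcast_to(np.asarray(rho, float), np.broadcast(p1, p2).shape).copy()
    lo_b, hi_b = binary_correlation_bounds(p1, p2)
    bad = (rho < lo_b - 1e-12) | (rho > hi_b + 1e-12)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"target binary correlation {rho.flat[i]:.4f} outside the admissible "
            f"range [{lo_b.flat[i]:.4f}, {hi_b.flat[i]:.4f}] for margins "
            f"({p1.flat[i]:.4f}, {p2.flat[i]:.4f})"
        )
    z1, z2 = ndtri(p1), ndtri(p2)
    target = p1 * p2 + rho * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo = np.full(rho.shape, -1.0 + 1e-10)
    hi = np.full(rho.shape, 1.0 - 1e-10)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        val = _bvn_cdf(z1, z2, mid)
        take_hi = val < target
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return 0.5 * (lo + hi)


def target_correlation(structure: str, rho: float, T: int) -> np.ndarray:
    """Binary-scale working correlation matrix implied by the structure."""
    if structure == "independent":
        return np.eye(T)
    t = np.arange(T)
    if structure == "exchangeable":
        R = np.full((T, T), rho)
    elif structure == "ar1":
        R = rho ** np.abs(t[:, None] - t[None, :]).astype(float)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.fill_diagonal(R, 1.0)
    return R


def simulate_responses(mu: np.ndarray, structure: str, rho: float, rng) -> np.ndarray:
    """Correlated binary panel with marginal means ``mu`` (n x T).

    Emrich-Piedmonte: per subject, solve for the latent multivariate-normal
    correlation whose dichotomization at Phi^{-1}(mu_it) reproduces the
    requested binary-scale correlations, then draw and threshold.
    """
    rng = _rng(rng)
    mu = np.asarray(mu, dtype=float)
    n, T = mu.shape
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("marginal probabilities must lie strictly inside (0, 1)")
    z = ndtri(mu)
    R_target = target_correlation(structure, rho, T)
    if structure == "independent" or rho == 0.0:
        return (rng.standard_normal((n, T)) <= z).astype(float)
    lat = np.tile(np.eye(T), (n, 1, 1))
    for t in range(T):
        for s in range(t + 1, T):
            r = solve_latent_correlation(mu[:, t], mu[:, s], R_target[t, s])
            lat[:, t, s] = r
            lat[:, s, t] = r
    try:
        L = np.linalg.cholesky(lat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "latent correlation matrix not positive definite; the requested "
            "(margins, rho) combination is not jointly attainable"
        ) from exc
    eps = rng.standard_normal((n, T, 1))
    Z = (L @ eps)[..., 0]
    return (Z <= z).astype(float)


# ---------------------------------------------------------------------------
# End-to-end dataset


@dataclass
class SimulatedDataset:
    """One replicate: genotypes, scores, design and the generating truth."""

    design: LongitudinalDesign
    genotypes: GenotypeMatrix
    gene_map: GeneMap
    scores: GeneScoreTable
    truth: np.ndarray            # aligned to design covariates (no intercept)
    support: np.ndarray
    scenario: SimulationScenario
    mu: np.ndarray = field(repr=False, default=None)


def write_dataset(ds: "SimulatedDataset", outdir) -> None:
    """Write one simulated replicate in the formats the fitting CLI reads.

    Produces genotypes.tsv (additive dosages), genemap.tsv, scores.tsv with
    its provenance sidecar, and phenotypes.csv (long format, unstandardized
    age/smoke so the CLI's own standardization applies).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = ds.genotypes
    pd.DataFrame(
        geno.dosages, index=geno.individuals, columns=geno.variants
    ).rename_axis("individual").to_csv(outdir / "genotypes.tsv", sep="\t")
    with open(outdir / "genemap.tsv", "w") as fh:
        for gene, vids in ds.gene_map.genes.items():
            for v in vids:
                fh.write(f"{gene}\t{v}\n")
    ds.scores.write(outdir / "scores.tsv", outdir / "scores.provenance.json")
    design = ds.design
    rows = []
    for i, sid in enumerate(design.subjects):
        for t in range(design.T):
            if not design.mask[i, t]:
                continue
            rows.append({
                "subject_id": sid,
                "visit": t + 1,
                "response": int(design.y[i, t]),
                **{c: design.X[i, t, j + 1]
                   for j, c in enumerate(design.columns[1:])},
            })
    pd.DataFrame(rows).to_csv(outdir / "phenotypes.csv", index=False)


def build_dataset(scenario: SimulationScenario, rng=None) -> SimulatedDataset:
    """Compose genotypes -> WSS scores -> covariates -> responses."""
    rng = _rng(scenario.seed if rng is None else rng)
    geno, gmap = simulate_genotypes(
        scenario.n,
        scenario.n_genes,
        rng,
        snps_per_gene=scenario.snps_per_gene,
        n_rare=scenario.n_rare,
        rare_maf=scenario.rare_maf,
        common_maf=scenario.common_maf,
        gene_names=scenario.gene_names,
    )
    table = collapse_all(geno, gmap)
    age, smoke = simulate_covariates(scenario.n, scenario.T, rng)

    n, T, p = scenario.n, scenario.T, scenario.p
    cols = scenario.columns
    X = np.empty((n, T, p + 1))
    X[:, :, 0] = 1.0
    score_df = table.scores
    for j, name in enumerate(cols, start=1):
        if name == "age":
            X[:, :, j] = age
        elif name == "smoke":
            X[:, :, j] = smoke
        else:
            X[:, :, j] = score_df[name].to_numpy()[:, None]
    flat = X[:, :, 1:].reshape(n * T, p)
    mu_c, sd_c = flat.mean(axis=0), flat.std(axis=0)
    if np.any(sd_c == 0):
        raise ValueError("degenerate (constant) simulated predictor; increase n")
    X[:, :, 1:] = (X[:, :, 1:] - mu_c) / sd_c

    truth = scenario.truth
    eta = scenario.intercept + X[:, :, 1:] @ truth
    mu = expit(eta)
    y = simulate_responses(mu, scenario.structure, scenario.rho, rng)

    design = LongitudinalDesign(
        y=y,
        X=X,
        mask=np.ones((n, T), dtype=bool),
        columns=["intercept"] + cols,
        subjects=list(geno.individuals),
        link="logit",
    )
    return SimulatedDataset(
        design=design,
        genotypes=geno,
        gene_map=gmap,
        scores=table,
        truth=truth,
        support=scenario.support,
        scenario=scenario,
        mu=mu,
    )
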