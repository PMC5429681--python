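"""Weighted-sum collapsing of rare and common variants into per-gene scores.

A gene-based (burden) analysis replaces the J individual variants of a gene
by a single score per individual,

    C_i = sum_j w_j G_ij,

where ``G_ij`` in {0, 1, 2} is the additive-coded count of the minor allele
and the weight ``w_j = 1 / sqrt(p_j (1 - p_j))`` is the inverse standard
deviation of a single draw of the minor allele with frequency ``p_j``.  Rare
variants (MAF < 5% by convention) therefore receive large weights and
dominate the score, while common variants still contribute.

Genotypes may come from a VCF (biallelic sites only) or a plain additive-coded
TSV; the gene-to-variant map is a two-column TSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RARE_MAF_THRESHOLD = 0.05


class CollapseError(ValueError):
    """Raised when a variant or gene cannot be collapsed."""


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes: individuals x variants, NaN = missing."""

    individuals: list[str]
    variants: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = [str(s) for s in self.individuals]
        self.variants = [str(v) for v in self.variants]
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, j = self.dosages.shape
        if n < 1 or j < 1:
            raise ValueError("genotype matrix must have at least one individual and one variant")
        if len(self.individuals) != n:
            raise ValueError("individual count does not match dosage rows")
        if len(self.variants) != j:
            raise ValueError("variant count does not match dosage columns")
        if len(set(self.variants)) != j:
            raise ValueError("variant IDs must be unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        self._variant_idx = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def column(self, variant: str) -> np.ndarray:
        try:
            return self.dosages[:, self._variant_idx[variant]]
        except KeyError:
            raise CollapseError(f"variant {variant!r} not present in genotype matrix") from None


@dataclass
class GeneMap:
    """Gene symbol -> ordered list of variant IDs."""

    genes: dict[str, list[str]]

    def __post_init__(self) -> None:
        for gene, vids in self.genes.items():
            if not vids:
                raise ValueError(f"gene {gene!r} maps to no variants")

    def validate(self, geno: GenotypeMatrix) -> None:
        known = set(geno.variants)
        for gene, vids in self.genes.items():
            missing = [v for v in vids if v not in known]
            if missing:
                raise CollapseError(f"gene {gene!r} references unknown variants: {missing}")


@dataclass
class GeneScore:
    """Collapsed score for one gene, with the MAF/weight provenance."""

    gene: str
    variants: list[str]
    mafs: np.ndarray
    weights: np.ndarray
    scores: np.ndarray
    n_rare: int
    n_common: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class GeneScoreTable:
    """Per-individual collapsed scores for every gene in a map."""

    individuals: list[str]
    genes: dict[str, GeneScore]

    @property
    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(
            {g: gs.scores for g, gs in self.genes.items()}, index=self.individuals
        )

    def provenance(self) -> dict:
        return {
            g: {
                "variants": gs.variants,
                "maf": gs.mafs.tolist(),
                "weight": gs.weights.tolist(),
                "n_rare": gs.n_rare,
                "n_common": gs.n_common,
                "dropped_monomorphic": gs.dropped,
            }
            for g, gs in self.genes.items()
        }

    def write(self, scores_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        self.scores.rename_axis("individual").to_csv(scores_path, sep="\t")
        if sidecar_path is not None:
            Path(sidecar_path).write_text(json.dumps(self.provenance(), indent=1))


def compute_maf(geno: GenotypeMatrix, variant: str) -> float:
    """Folded minor-allele frequency of one variant, estimated from the sample.

    Returns ``min(f, 1-f)`` with ``f`` the frequency of the coded allele, so
    the result does not depend on which allele was designated.
    """
    col = geno.column(variant)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise CollapseError(f"variant {variant!r} has no non-missing genotypes")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def wss_weights(mafs) -> np.ndarray:
    """Inverse-standard-deviation weights w_j = 1/sqrt(p_j (1-p_j)).

    Strictly decreasing in the MAF on (0, 0.5]; monomorphic variants
    (p = 0) have no defined weight and must be excluded upstream.
    """
    p = np.atleast_1d(np.asarray(mafs, dtype=float))
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise CollapseError("WSS weights require MAFs strictly inside (0, 1)")
    return 1.0 / np.sqrt(p * (1.0 - p))


def collapse_gene(
    geno: GenotypeMatrix,
    gene: str,
    variant_ids: list[str],
    rare_threshold: float = RARE_MAF_THRESHOLD,
) -> GeneScore:
    """Collapse one gene's variants into a per-individual weighted sum.

    Monomorphic variants are dropped with a warning; missing dosages
    contribute 0 (homozygous-reference imputation).
    """
    mafs, kept, dropped = [], [], []
    for vid in variant_ids:
        p = compute_maf(geno, vid)
        if p == 0.0:
            dropped.append(vid)
        else:
            kept.append(vid)
            mafs.append(p)
    if dropped:
        warnings.warn(
            f"gene {gene!r}: dropped monomorphic variants {dropped}", stacklevel=2
        )
    if not kept:
        raise CollapseError(f"gene {gene!r} has no polymorphic variants to collapse")
    mafs_arr = np.array(mafs)
    w = wss_weights(mafs_arr)
    dos = np.column_stack([np.nan_to_num(geno.column(v), nan=0.0) for v in kept])
    scores = dos @ w
    n_rare = int((mafs_arr < rare_threshold).sum())
    return GeneScore(
        gene=gene,
        variants=kept,
        mafs=mafs_arr,
        weights=w,
        scores=scores,
        n_rare=n_rare,
        n_common=len(kept) - n_rare,
        dropped=dropped,
    )


def collapse_all(
    geno: GenotypeMatrix,
    gene_map: GeneMap,
    rare_threshold: float = RARE_MAF_THRESHOLD,
) -> GeneScoreTable:
    """Collapse every gene in the map; scores aligned to the individual order."""
    gene_map.validate(geno)
    out: dict[str, GeneScore] = {}
    for gene, vids in gene_map.genes.items():
        out[gene] = collapse_gene(geno, gene, vids, rare_threshold=rare_threshold)
    return GeneScoreTable(individuals=list(geno.individuals), genes=out)


# ---------------------------------------------------------------------------
# File formats


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read an additive-coded TSV: header of variant IDs, first column IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        individuals=[str(i) for i in df.index],
        variants=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF, converting GT calls to additive alt-allele dosages.

    Multi-allelic sites are rejected: the additive {0,1,2} coding is only
    defined against a single alternate allele.
    """
    from cyvcf2 import VCF

    reader = VCF(str(path))
    individuals = list(reader.samples)
    variants: list[str] = []
    cols: list[np.ndarray] = []
    for var in reader:
        if len(var.ALT) != 1:
            raise CollapseError(
                f"multi-allelic site at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}); split or drop it before collapsing"
            )
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        variants.append(vid)
        cols.append(dos)
    if not variants:
        raise CollapseError(f"no variants found in {path}")
    return GenotypeMatrix(individuals, variants, np.column_stack(cols))


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_genotype_tsv(path)


def read_gene_map(path: str | Path) -> GeneMap:
    """Read a two-column TSV (gene, variant_id), one row per pair."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "variant"],
                     dtype=str, comment="#")
    genes: dict[str, list[str]] = {}
    for gene, variant in df.itertuples(index=False):
        genes.setdefault(gene, []).append(variant)
    return GeneMap(genes=genes)
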