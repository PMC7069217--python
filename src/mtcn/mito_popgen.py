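"""Population-genetic checks on haploid mtDNA genotypes.

Private-variant detection, an equal-contribution haploid genetic
relatedness matrix (GRM), its principal components, and one-vs-rest
haplogroup association with normalized copy number.

The GRM standardizes each SNP by its observed haploid variance p(1-p) —
not the diploid Hardy-Weinberg expectation — so every SNP contributes
equally to the genetic covariance regardless of allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaploidGenotypeMatrix",
    "GRM",
    "PCAResult",
    "private_variants",
    "haploid_grm",
    "grm_pca",
    "haplogroup_onevsrest",
    "write_vcf",
    "read_vcf",
]

MISSING = -1  # sentinel in the int8 call matrix


@dataclass
class HaploidGenotypeMatrix:
    """Individuals x biallelic mtDNA SNPs with haploid 0/1 calls.

    ``calls`` is an (n, m) int8 array; -1 marks a missing genotype.
    """

    ids: list[str]
    variant_ids: list[str]
    positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n, m = self.calls.shape
        if len(self.ids) != n or len(self.variant_ids) != m:
            raise ValueError("matrix shape does not match id lists")
        if len(self.positions) != m:
            raise ValueError("positions length does not match variants")
        bad = ~np.isin(self.calls, [0, 1, MISSING])
        if bad.any():
            raise ValueError("calls must be 0, 1 or -1 (missing): biallelic only")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def filter_missingness(self, max_missing: float = 0.05) -> "HaploidGenotypeMatrix":
        """Drop variants whose missingness exceeds ``max_missing``."""
        miss = (self.calls == MISSING).mean(axis=0)
        keep = miss <= max_missing
        return HaploidGenotypeMatrix(
            self.ids,
            [v for v, k in zip(self.variant_ids, keep) if k],
            self.positions[keep],
            self.calls[:, keep],
        )

    def drop_variants(self, variant_ids) -> "HaploidGenotypeMatrix":
        drop = set(variant_ids)
        keep = np.array([v not in drop for v in self.variant_ids])
        return HaploidGenotypeMatrix(
            self.ids,
            [v for v, k in zip(self.variant_ids, keep) if k],
            self.positions[keep],
            self.calls[:, keep],
        )


@dataclass
class GRM:
    """Genetic relatedness matrix with the per-pair variant counts used."""

    values: np.ndarray
    n_variants: int
    pair_counts: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


@dataclass
class PCAResult:
    """Top-k eigenpairs of a GRM; scores are eigenvectors scaled by
    sqrt(eigenvalue), eigenvalues in nonincreasing order."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False, default=None)


def private_variants(
    matrix: HaploidGenotypeMatrix, labels, group: str
) -> list[str]:
    """Variants with at least one carrier, all of whose carriers belong to
    ``group``.  ``labels`` maps individual id -> group label (mapping,
    Series, or aligned sequence)."""
    lab = _align_labels(matrix, labels)
    if group not in set(lab):
        raise ValueError(f"unknown group label {group!r}")
    in_group = np.array([g == group for g in lab])
    carriers = matrix.calls == 1
    any_carrier = carriers.any(axis=0)
    outside = (carriers & ~in_group[:, None]).any(axis=0)
    private = any_carrier & ~outside
    return [v for v, p in zip(matrix.variant_ids, private) if p]


def haploid_grm(matrix: HaploidGenotypeMatrix) -> GRM:
    """Equal-weight haploid GRM.

    Each variant is centered by its observed allele frequency and divided
    by its observed (population-denominator) standard deviation
    sqrt(p(1-p)), then GRM = Z Z' / m.  Missing genotypes are handled by
    pairwise-complete products with per-pair variant counts.  Monomorphic
    variants are dropped with a warning.
    """
    calls = matrix.calls.astype(float)
    obs = matrix.calls != MISSING
    calls[~obs] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(calls, axis=0)
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono == matrix.n_variants:
        raise ValueError("all variants monomorphic: GRM undefined")
    if n_mono:
        warnings.warn(f"dropping {n_mono} monomorphic variants", stacklevel=2)
    calls = calls[:, poly]
    obs = obs[:, poly]
    p = p[poly]

    z = (calls - p) / np.sqrt(p * (1 - p))
    z[~obs] = 0.0
    num = z @ z.T
    counts = obs.astype(float) @ obs.astype(float).T
    if (counts == 0).any():
        raise ValueError("some individual pairs share no observed variants")
    return GRM(values=num / counts, n_variants=int(poly.sum()),
               pair_counts=counts.astype(int))


def grm_pca(grm: GRM, k: int) -> PCAResult:
    """Top-k eigendecomposition of a GRM.

    Returns scores (eigenvectors scaled by sqrt(max(eigenvalue, 0))) and
    eigenvalues in nonincreasing order.
    """
    values = grm.values
    n = values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds matrix size {n}")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("GRM must be symmetric")
    eigval, eigvec = np.linalg.eigh(values)
    order = np.argsort(eigval)[::-1][:k]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scores = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    return PCAResult(scores=scores, eigenvalues=eigval, eigenvectors=eigvec)


def haplogroup_onevsrest(
    cn,
    labels,
    covariates: pd.DataFrame | None = None,
    min_carriers: int = 2,
) -> pd.DataFrame:
    """OLS of normalized copy number on a one-vs-rest indicator per
    haplogroup, optionally with covariates.

    Returns a frame (haplogroup, n, beta, se, p) ordered by beta
    descending.  Haplogroups with fewer than ``min_carriers`` members are
    omitted; a haplogroup spanning the whole cohort is skipped with a
    warning (its indicator is constant).
    """
    y = np.asarray(cn, dtype=float)
    lab = np.asarray(list(labels))
    if len(y) != len(lab):
        raise ValueError("cn and labels length mismatch")
    if covariates is not None and len(covariates) != len(y):
        raise ValueError("covariates length mismatch")

    rows = []
    for hg in pd.unique(lab):
        indicator = (lab == hg).astype(float)
        n_in = int(indicator.sum())
        if n_in < min_carriers:
            continue
        if n_in == len(y):
            warnings.warn(f"haplogroup {hg} spans whole cohort; skipped",
                          stacklevel=2)
            continue
        X = [np.ones_like(y), indicator]
        if covariates is not None:
            X.extend(np.asarray(covariates[c], dtype=float)
                     for c in covariates.columns)
        X = np.column_stack(X)
        beta, se, p = _ols_term(y, X, term_index=1)
        rows.append({"haplogroup": hg, "n": n_in, "beta": beta, "se": se, "p": p})

    out = pd.DataFrame(rows, columns=["haplogroup", "n", "beta", "se", "p"])
    return out.sort_values("beta", ascending=False).reset_index(drop=True)


def _ols_term(y, X, term_index: int) -> tuple[float, float, float]:
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough observations for OLS")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("collinear design")
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[term_index, term_index]))
    t = beta[term_index] / se
    p = float(2 * stats.t.sf(abs(t), n - k))
    return float(beta[term_index]), se, p


def _align_labels(matrix: HaploidGenotypeMatrix, labels) -> list[str]:
    if isinstance(labels, pd.Series):
        labels = labels.to_dict() if not labels.index.equals(
            pd.RangeIndex(len(labels))) else list(labels)
    if isinstance(labels, dict):
        missing = [i for i in matrix.ids if i not in labels]
        if missing:
            raise ValueError(f"{len(missing)} individuals unlabelled, e.g. {missing[0]}")
        return [labels[i] for i in matrix.ids]
    labels = list(labels)
    if len(labels) != matrix.n_individuals:
        raise ValueError("labels length does not match individuals")
    return labels


# ---------------------------------------------------------------------------
# VCF I/O (haploid GT, one ALT per record)

def write_vcf(matrix: HaploidGenotypeMatrix, path, chrom: str = "MT",
              contig_length: int = 16569) -> None:
    """Write haploid genotypes as an uncompressed VCF (GT only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.ids) + "\n")
        order = np.argsort(matrix.positions, kind="stable")
        gt_char = {0: "0", 1: "1", MISSING: "."}
        for j in order:
            calls = "\t".join(gt_char[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{chrom}\t{matrix.positions[j]}\t{matrix.variant_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> HaploidGenotypeMatrix:
    """Read a haploid single-ALT VCF into a genotype matrix (via pysam)."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        ids = list(vcf.header.samples)
        variant_ids, positions, columns = [], [], []
        for rec in vcf.fetch():
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"variant at {rec.pos} is not biallelic")
            variant_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            positions.append(rec.pos)
            col = np.empty(len(ids), dtype=np.int8)
            for i, s in enumerate(ids):
                gt = rec.samples[s]["GT"]
                allele = gt[0] if gt else None
                col[i] = MISSING if allele is None else int(allele)
            columns.append(col)
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(ids), 0), dtype=np.int8))
    return HaploidGenotypeMatrix(ids, variant_ids, np.array(positions), calls)
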