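"""Shared in-memory data model for the association-mapping pipeline.

Genotypes are held as minor-allele counts (0/1/2, NaN = missing call) in an
individuals x SNPs matrix; phenotypes, expression and population-structure
covariates are thin wrappers over pandas objects keyed by identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

@dataclass
class SNPRecord:
    """A biallelic SNP: identity, location, alleles and cohort MAF.

    ``ref_allele``/``alt_allele`` follow the source VCF; the genotype coding
    in :class:`GenotypeMatrix` counts the *minor* allele of the loaded
    cohort, which may be either of the two.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_id: str = ""
    maf: float = float("nan")
    minor_is_alt: bool = True

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1 (got {self.pos})")

    @property
    def minor_allele(self) -> str:
        return self.alt_allele if self.minor_is_alt else self.ref_allele

    @property
    def major_allele(self) -> str:
        return self.ref_allele if self.minor_is_alt else self.alt_allele


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of minor-allele counts.

    ``calls[i, j]`` is the number of copies of SNP j's minor allele carried
    by individual i (0, 1, 2) or NaN for a missing call.
    """

    individual_ids: list[str]
    snps: list[SNPRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = self.calls.shape
        if n != len(self.individual_ids):
            raise ValueError("calls rows != number of individuals")
        if m != len(self.snps):
            raise ValueError("calls columns != number of SNPs")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids not unique")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("snp ids not unique")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be in {0, 1, 2, NaN}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        return self.calls[:, j]

    def recompute_maf(self) -> np.ndarray:
        """MAF per SNP from the stored calls (complete cases per column).

        Also re-orients columns so the coded allele is the minor one: if a
        column's coded-allele frequency exceeds 0.5 the codes are flipped
        (x -> 2 - x) and ``minor_is_alt`` is toggled.
        """
        mafs = np.empty(self.n_snps)
        for j in range(self.n_snps):
            col = self.calls[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                mafs[j] = np.nan
                continue
            freq = obs.sum() / (2 * obs.size)
            if freq > 0.5:
                self.calls[:, j] = np.where(np.isnan(col), np.nan, 2.0 - col)
                self.snps[j].minor_is_alt = not self.snps[j].minor_is_alt
                freq = 1.0 - freq
            mafs[j] = freq
            self.snps[j].maf = freq
        return mafs

    def monomorphic_mask(self) -> np.ndarray:
        """True for columns with no variation among observed calls."""
        out = np.zeros(self.n_snps, dtype=bool)
        for j in range(self.n_snps):
            obs = self.calls[~np.isnan(self.calls[:, j]), j]
            out[j] = obs.size == 0 or np.all(obs == obs[0])
        return out

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), self.snps, self.calls[rows, :])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            self.individual_ids, [self.snps[j] for j in idx], self.calls[:, idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.individual_ids, columns=self.snp_ids
        )


@dataclass
class PhenotypeTable:
    """Individuals x quantitative traits (NaN allowed)."""

    individual_ids: list[str]
    traits: pd.DataFrame  # index = individual_ids, columns = trait names

    def __post_init__(self) -> None:
        if len(self.traits) != len(self.individual_ids):
            raise ValueError("trait table length != individual_ids")
        if self.traits.columns.duplicated().any():
            raise ValueError("duplicate trait names")
        self.traits.index = pd.Index(self.individual_ids)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def trait(self, name: str) -> np.ndarray:
        return self.traits[name].to_numpy(dtype=float)

    def subset_individuals(self, ids: list[str]) -> "PhenotypeTable":
        return PhenotypeTable(list(ids), self.traits.loc[list(ids)].copy())


@dataclass
class ExpressionMatrix:
    """Genes x conditions non-negative expression values."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("values shape mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids not unique")
        if np.nanmin(self.values) < 0:
            raise ValueError("expression values must be non-negative")

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id), :]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.condition_ids
        )


@dataclass
class PromoterSet:
    """Promoter sequences keyed by gene.

    Position convention: offsets count bp upstream of the TSS, 1-based, with
    position 1 the base immediately 5' of the TSS — i.e. the *last* base of
    the stored sequence.  Sequences are uppercase over {A, C, G, T, N}.
    """

    sequences: dict[str, str]
    promoter_length: int = 2000

    def __post_init__(self) -> None:
        clean = {}
        for gid, seq in self.sequences.items():
            s = seq.upper()
            if set(s) - set("ACGTN"):
                raise ValueError(f"{gid}: non-ACGTN characters in promoter")
            if len(s) > self.promoter_length:
                raise ValueError(
                    f"{gid}: sequence longer than promoter length "
                    f"{self.promoter_length}"
                )
            clean[gid] = s
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class StructureCovariates:
    """Population-structure membership covariates (Q matrix)."""

    individual_ids: list[str]
    q: np.ndarray  # individuals x k components

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if self.q.shape[0] != len(self.individual_ids):
            raise ValueError("Q rows != individual_ids")
        if np.isnan(self.q).any():
            raise ValueError("Q matrix may not contain missing values")

    @property
    def k(self) -> int:
        return self.q.shape[1]

    def subset_individuals(self, ids: list[str]) -> "StructureCovariates":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = [index[i] for i in ids]
        return StructureCovariates(list(ids), self.q[rows, :])


@dataclass
class Cohort:
    """Genotypes, phenotypes and covariates restricted to common individuals."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    covariates: StructureCovariates | None
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def individual_ids(self) -> list[str]:
        return self.genotypes.individual_ids
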