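"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates biallelic SNP panels under Hardy-Weinberg equilibrium with optional
haplotype-copying LD blocks, quantitative phenotypes from additive + dominance
+ pairwise-epistatic genetic values plus structure effects and Gaussian noise,
small multi-tissue expression matrices with planted hub correlations, and
promoter sequences with motifs planted at exact upstream offsets.

Everything is deterministic given the spec's seed.  The generators emulate an
association panel of unrelated individuals (default size 435, ten traits);
they do not attempt coalescent realism or RNA-seq count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import additive_code, dominance_code
from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    PromoterSet,
    SNPRecord,
    StructureCovariates,
)

import pandas as pd


@dataclass
class LDBlock:
    """SNP indices that copy the first (anchor) SNP's haplotypes with prob rho."""

    snp_indices: list[int]
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass
class SimulationSpec:
    """Panel layout for :func:`simulate_genotypes`."""

    n_individuals: int
    n_snps: int
    maf: float | tuple[float, float] | list[float] = (0.1, 0.5)
    ld_blocks: list[LDBlock] = field(default_factory=list)
    gene_of_snp: list[str] | None = None  # per-SNP gene assignment
    chrom: str = "chr1"
    positions: list[int] | None = None  # 1-based; default 1 SNP / 24 bp
    seed: int = 0

    def snp_mafs(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.maf, (int, float)):
            mafs = np.full(self.n_snps, float(self.maf))
        elif isinstance(self.maf, tuple):
            lo, hi = self.maf
            mafs = rng.uniform(lo, hi, size=self.n_snps)
        else:
            mafs = np.asarray(self.maf, dtype=float)
            if mafs.size != self.n_snps:
                raise ValueError("per-SNP MAF list length != n_snps")
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise ValueError("MAFs must be in (0, 0.5]")
        return mafs


@dataclass
class EpistaticTerm:
    snp_id1: str
    snp_id2: str
    effect_type: str  # AxA | AxD | DxA | DxD
    coefficient: float

    def __post_init__(self) -> None:
        if self.effect_type not in ("AxA", "AxD", "DxA", "DxD"):
            raise ValueError(f"unknown effect type {self.effect_type!r}")


@dataclass
class EffectModel:
    """Generative trait model: y = mu + a'x + d'z + epistasis + Q beta + noise.

    ``additive`` maps snp_id -> a (trait units per minor-allele copy on the
    {-1, 0, +1} scale, i.e. half the homozygote difference); ``dominance``
    maps snp_id -> d (heterozygote deviation on the {-1/2, +1/2} scale).
    """

    mu: float = 0.0
    additive: dict[str, float] = field(default_factory=dict)
    dominance: dict[str, float] = field(default_factory=dict)
    epistasis: list[EpistaticTerm] = field(default_factory=list)
    structure_effects: np.ndarray | None = None
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw a diploid SNP panel under HWE with optional LD blocks.

    Each SNP is built from two haplotype vectors of Bernoulli(MAF) allele
    indicators.  Within an LD block every non-anchor SNP copies the anchor's
    haplotype with probability rho per haplotype (independent redraw
    otherwise), which gives pairwise r^2 ~= rho^2 for equal MAFs and exactly
    1 at rho = 1.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = spec.snp_mafs(rng)
    n, m = spec.n_individuals, spec.n_snps
    hap1 = np.empty((n, m))
    hap2 = np.empty((n, m))
    for j in range(m):
        hap1[:, j] = rng.random(n) < mafs[j]
        hap2[:, j] = rng.random(n) < mafs[j]
    for block in spec.ld_blocks:
        idx = block.snp_indices
        anchor = idx[0]
        for j in idx[1:]:
            if j == anchor:
                continue
            for hap in (hap1, hap2):
                copy = rng.random(n) < block.rho
                hap[:, j] = np.where(copy, hap[:, anchor], hap[:, j])
    calls = hap1 + hap2
    if spec.positions is not None:
        positions = list(spec.positions)
    else:
        positions = [1 + 24 * j for j in range(m)]
    genes = spec.gene_of_snp or [""] * m
    bases = ("A", "G")
    snps = [
        SNPRecord(
            snp_id=f"snp{j + 1}",
            chrom=spec.chrom,
            pos=positions[j],
            ref_allele=bases[0],
            alt_allele=bases[1],
            gene_id=genes[j],
        )
        for j in range(m)
    ]
    ids = [f"ind{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(ids, snps, calls)
    gm.recompute_maf()
    return gm


def genetic_values(gm: GenotypeMatrix, model: EffectModel) -> np.ndarray:
    """Deterministic genetic value of each individual under the model."""
    ids = gm.snp_ids
    for sid in list(model.additive) + list(model.dominance):
        if sid not in ids:
            raise KeyError(f"model references unknown SNP {sid!r}")
    g = np.full(gm.n_individuals, model.mu, dtype=float)
    for sid, a in model.additive.items():
        g += a * additive_code(gm.column(sid))
    for sid, d in model.dominance.items():
        g += d * dominance_code(gm.column(sid))
    for term in model.epistasis:
        c1, c2 = gm.column(term.snp_id1), gm.column(term.snp_id2)
        left = additive_code(c1) if term.effect_type[0] == "A" else dominance_code(c1)
        right = additive_code(c2) if term.effect_type[2] == "A" else dominance_code(c2)
        g += term.coefficient * left * right
    return g


def simulate_phenotype(
    gm: GenotypeMatrix,
    model: EffectModel,
    covariates: StructureCovariates | None = None,
    seed: int = 0,
    trait_name: str = "trait",
) -> PhenotypeTable:
    """Phenotype = genetic value + Q*beta + Normal(0, sigma^2) noise."""
    rng = np.random.default_rng(seed)
    y = genetic_values(gm, model)
    if model.structure_effects is not None:
        if covariates is None:
            raise ValueError("structure_effects given but no covariates")
        y = y + covariates.q @ np.asarray(model.structure_effects, dtype=float)
    y = y + rng.normal(0.0, model.sigma, size=gm.n_individuals)
    df = pd.DataFrame({trait_name: y}, index=gm.individual_ids)
    return PhenotypeTable(list(gm.individual_ids), df)


def simulate_structure(
    individual_ids: list[str], k: int = 3, seed: int = 0
) -> StructureCovariates:
    """Dirichlet-like membership proportions over k subpopulations."""
    rng = np.random.default_rng(seed)
    raw = rng.gamma(1.0, 1.0, size=(len(individual_ids), k))
    q = raw / raw.sum(axis=1, keepdims=True)
    return StructureCovariates(list(individual_ids), q)


def simulate_expression(
    gene_ids: list[str],
    hub_gene: str,
    target_correlations: dict[str, float],
    n_conditions: int = 4,
    condition_ids: list[str] | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression profiles with planted Pearson correlations to a hub gene.

    The hub profile is standard normal; each target is
    r* x (standardised hub) + sqrt(1 - r*^2) x noise.  All profiles are then
    shifted by a per-gene constant to be positive, which leaves Pearson
    correlations untouched.  The realised r converges to r* as the number of
    conditions grows and equals +-1 exactly at r* = +-1.
    """
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    for g, r in target_correlations.items():
        if abs(r) > 1:
            raise ValueError(f"invalid target correlation {r} for {g}")
    rng = np.random.default_rng(seed)
    if condition_ids is None:
        condition_ids = [f"tissue{i + 1}" for i in range(n_conditions)]
    hub = rng.normal(size=n_conditions)
    hub_std = (hub - hub.mean()) / hub.std()
    rows = []
    for gid in gene_ids:
        if gid == hub_gene:
            prof = hub.copy()
        elif gid in target_correlations:
            r = target_correlations[gid]
            noise = rng.normal(size=n_conditions)
            prof = r * hub_std + np.sqrt(max(0.0, 1 - r * r)) * noise
        else:
            prof = rng.normal(size=n_conditions)
        rows.append(prof - prof.min() + 0.5)  # positive shift, r preserved
    return ExpressionMatrix(list(gene_ids), list(condition_ids), np.array(rows))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def plant_promoters(
    gene_ids: list[str],
    motif_plan: dict[str, list[tuple[str, int]]],
    background_gc: float = 0.4,
    length: int = 2000,
    seed: int = 0,
    max_redraws: int = 10_000,
) -> PromoterSet:
    """Random promoters with motifs written at exact upstream offsets.

    Offsets follow the package convention: the offset is the 1-based upstream
    position of the motif base closest to the TSS.  The background is i.i.d.
    at the given GC content and guaranteed free of spurious occurrences of
    any planted motif string (or its reverse complement) by redrawing
    collision windows.
    """
    rng = np.random.default_rng(seed)
    p_base = np.array(
        [
            (1 - background_gc) / 2,  # A
            background_gc / 2,  # C
            background_gc / 2,  # G
            (1 - background_gc) / 2,  # T
        ]
    )
    alphabet = np.array(list("ACGT"))
    all_motifs = sorted(
        {m for plan in motif_plan.values() for m, _ in plan}
    )
    forbidden = sorted({s for m in all_motifs for s in (m, _revcomp(m))})
    seqs: dict[str, str] = {}
    for gid in gene_ids:
        plan = sorted(motif_plan.get(gid, []), key=lambda x: -x[1])
        # planted intervals in sequence coordinates (0-based, [start, end))
        planted: list[tuple[int, int, str]] = []
        for motif, offset in plan:
            if offset < 1 or offset + len(motif) - 1 > length:
                raise ValueError(
                    f"{gid}: motif {motif} at offset {offset} exceeds promoter"
                )
            start = length - offset - len(motif) + 1
            end = start + len(motif)
            for s0, e0, _ in planted:
                if start < e0 and s0 < end:
                    raise ValueError(f"{gid}: overlapping planted motifs")
            planted.append((start, end, motif))
        seq = alphabet[rng.choice(4, size=length, p=p_base)]
        for start, end, motif in planted:
            seq[start:end] = list(motif)
        text = "".join(seq)
        planted_set = {(s, e) for s, e, _ in planted}
        for _ in range(max_redraws):
            collision = _find_spurious(text, forbidden, planted_set)
            if collision is None:
                break
            s, e = collision
            # redraw only background positions inside the collision window
            for i in range(s, e):
                if not any(ps <= i < pe for ps, pe in planted_set):
                    text = text[:i] + rng.choice(alphabet, p=p_base) + text[i + 1:]
        else:
            raise RuntimeError(f"{gid}: could not purge spurious motif hits")
        seqs[gid] = text
    return PromoterSet(seqs, promoter_length=length)


def _find_spurious(
    text: str, forbidden: list[str], planted: set[tuple[int, int]]
) -> tuple[int, int] | None:
    for motif in forbidden:
        start = 0
        while True:
            i = text.find(motif, start)
            if i < 0:
                break
            span = (i, i + len(motif))
            if span not in planted:
                return span
            start = i + 1
    return None
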