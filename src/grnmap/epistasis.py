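"""Pairwise SNP x SNP epistasis: the four-way A x A, A x D, D x A, D x D
decomposition of two-locus interaction, Kempthorne-style.

The two-locus genotypic value is partitioned on the 8-column genetic design

    y ~ Q + x1 + z1 + x2 + z2 + x1*x2 + x1*z2 + z1*x2 + z1*z2

with the single-locus codings of :mod:`grnmap.coding`.  Under exactly
balanced 3x3 genotype counts the eight genetic columns are mutually
orthogonal — the orthogonal partition that the extended (unequal-frequency)
model generalises; here the generalisation is ordinary least squares on the
observed, unbalanced design.  Each interaction coefficient gets a 1-df
full-vs-reduced F test; a joint 4-df test covers the whole interaction
block.  Coefficients aliased by empty cells are reported as non-estimable,
never as zero.

Interpretation of the four terms: A x A is an allele x allele interaction,
A x D allele x genotype, D x A genotype x allele, and D x D genotype x
genotype; :func:`combination_effects` reports the corresponding
allele/genotype-combination phenotype deviations and frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from ._ols import column_estimable, fit_sse, nested_f_test
from .association import bh_adjust
from .coding import additive_code, dominance_code
from .datatypes import Cohort

__all__ = [
    "EFFECT_TYPES",
    "OccupancyRule",
    "TwoLocusModel",
    "EpistasisResults",
    "CombinationEffectRow",
    "two_locus_design",
    "combination_effects",
    "combination_deviations",
    "scan_epistasis",
    "hub_target_pairs",
]

EFFECT_TYPES = ("AxA", "AxD", "DxA", "DxD")


def two_locus_design(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genetic design columns for a complete-case two-locus panel.

    Returns (design, cell_counts): the design has columns x1, z1, x2, z2,
    x1x2, x1z2, z1x2, z1z2; cell_counts is the 3x3 genotype-count table with
    rows indexed by the code of locus 1 and columns by locus 2.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if np.isnan(g1).any() or np.isnan(g2).any():
        raise ValueError("two_locus_design expects complete cases")
    x1, z1 = additive_code(g1), dominance_code(g1)
    x2, z2 = additive_code(g2), dominance_code(g2)
    design = pd.DataFrame(
        {
            "x1": x1, "z1": z1, "x2": x2, "z2": z2,
            "x1x2": x1 * x2, "x1z2": x1 * z2,
            "z1x2": z1 * x2, "z1z2": z1 * z2,
        }
    )
    counts = np.zeros((3, 3), dtype=int)
    for a, b in zip(g1.astype(int), g2.astype(int)):
        counts[a, b] += 1
    return design, counts


@dataclass
class OccupancyRule:
    """Minimum data requirements for a two-locus test.

    Defaults: every marginal genotype class at each locus has at least
    ``min_marginal_n`` individuals, and at least ``min_cells`` of the nine
    two-locus cells are occupied.
    """

    min_marginal_n: int = 3
    min_cells: int = 5

    def check(self, counts: np.ndarray) -> str:
        row_ok = (counts.sum(axis=1) >= self.min_marginal_n).all()
        col_ok = (counts.sum(axis=0) >= self.min_marginal_n).all()
        if not (row_ok and col_ok):
            return (
                f"marginal genotype class below n={self.min_marginal_n} "
                "at one locus"
            )
        if (counts > 0).sum() < self.min_cells:
            return f"fewer than {self.min_cells} of 9 cells occupied"
        return ""


@dataclass
class EpistasisResults:
    """Estimates and tests from a fitted :class:`TwoLocusModel`."""

    snp_id1: str
    snp_id2: str
    trait: str
    n_used: int
    cell_means: pd.DataFrame  # 3x3 adjusted means, NaN for empty cells
    effects: dict[str, tuple[float, float]]  # type -> (estimate, p); NaN est = non-estimable
    overall_pair_p: float
    skipped: bool = False
    reason: str = ""
    qvalues: dict[str, float] = field(default_factory=dict)

    def estimate(self, effect_type: str) -> float:
        return self.effects[effect_type][0]

    def pvalue(self, effect_type: str) -> float:
        return self.effects[effect_type][1]

    def summary(self) -> str:
        lines = [
            f"Two-locus epistasis: {self.snp_id1} x {self.snp_id2} ~ {self.trait}",
            f"  n used        {self.n_used}",
        ]
        if self.skipped:
            lines.append(f"  SKIPPED: {self.reason}")
            return "\n".join(lines)
        for t in EFFECT_TYPES:
            est, p = self.effects[t]
            shown = "non-estimable" if np.isnan(est) else f"{est:.4g} (p = {p:.3g})"
            lines.append(f"  {t:5s}        {shown}")
        lines.append(f"  joint 4-df    p = {self.overall_pair_p:.3g}")
        return "\n".join(lines)


class TwoLocusModel:
    """Least-squares two-locus interaction model for one quantitative trait."""

    _INTERACTIONS = {"AxA": "x1x2", "AxD": "x1z2", "DxA": "z1x2", "DxD": "z1z2"}

    def __init__(
        self,
        y: np.ndarray,
        g1: np.ndarray,
        g2: np.ndarray,
        covariates: np.ndarray | None = None,
        occupancy: OccupancyRule | None = None,
        snp_id1: str = "snp1",
        snp_id2: str = "snp2",
        trait: str = "trait",
    ) -> None:
        self.y_raw = np.asarray(y, dtype=float)
        self.g1_raw = np.asarray(g1, dtype=float)
        self.g2_raw = np.asarray(g2, dtype=float)
        self.Q = (
            np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates is not None
            else None
        )
        self.occupancy = occupancy or OccupancyRule()
        self.snp_id1, self.snp_id2, self.trait = snp_id1, snp_id2, trait

    def _complete_cases(self):
        mask = (
            ~np.isnan(self.y_raw)
            & ~np.isnan(self.g1_raw)
            & ~np.isnan(self.g2_raw)
        )
        if self.Q is not None:
            mask &= ~np.isnan(self.Q).any(axis=1)
        Q = self.Q[mask] if self.Q is not None else None
        return self.y_raw[mask], self.g1_raw[mask], self.g2_raw[mask], Q

    def fit(self) -> EpistasisResults:
        y, g1, g2, Q = self._complete_cases()
        n = y.size
        empty_means = pd.DataFrame(np.full((3, 3), np.nan))

        def _skip(reason: str) -> EpistasisResults:
            return EpistasisResults(
                self.snp_id1, self.snp_id2, self.trait, n, empty_means,
                {t: (np.nan, np.nan) for t in EFFECT_TYPES}, np.nan,
                skipped=True, reason=reason,
            )

        if n == 0:
            return _skip("no complete cases")
        if np.all(g1 == g1[0]) or np.all(g2 == g2[0]):
            return _skip("monomorphic locus")
        design, counts = two_locus_design(g1, g2)
        reason = self.occupancy.check(counts)
        if reason:
            return _skip(reason)

        base = [np.ones(n)]
        if Q is not None:
            base.append(Q - Q.mean(axis=0))
        X_base = np.column_stack(base)
        main = design[["x1", "z1", "x2", "z2"]].to_numpy()
        inter = design[["x1x2", "x1z2", "z1x2", "z1z2"]].to_numpy()
        X_main = np.column_stack([X_base, main])
        X_full = np.column_stack([X_base, main, inter])
        beta_full, sse_full, rank_full = fit_sse(X_full, y)
        _, sse_main, rank_main = fit_sse(X_main, y)
        _, overall_p = nested_f_test(sse_main, rank_main, sse_full, rank_full, n)

        effects: dict[str, tuple[float, float]] = {}
        n_base_cols = X_base.shape[1] + 4
        full_column_rank = rank_full == X_full.shape[1]
        for k, t in enumerate(EFFECT_TYPES):
            col = n_base_cols + k
            if not full_column_rank and not column_estimable(X_full, col):
                effects[t] = (np.nan, np.nan)
                continue
            X_drop = np.delete(X_full, col, axis=1)
            _, sse_drop, rank_drop = fit_sse(X_drop, y)
            _, p = nested_f_test(sse_drop, rank_drop, sse_full, rank_full, n)
            effects[t] = (float(beta_full[col]), p)

        cell_means = self._adjusted_cell_means(y, g1, g2, X_base, counts)
        return EpistasisResults(
            self.snp_id1, self.snp_id2, self.trait, n, cell_means,
            effects, overall_p,
        )

    @staticmethod
    def _adjusted_cell_means(y, g1, g2, X_base, counts) -> pd.DataFrame:
        occupied = [(i, j) for i, j in product(range(3), range(3)) if counts[i, j]]
        dummies = np.column_stack(
            [((g1 == i) & (g2 == j)).astype(float) for i, j in occupied]
        )
        X = np.column_stack([dummies, X_base[:, 1:]])  # cell means + centred Q
        beta, _, _ = fit_sse(X, y)
        means = np.full((3, 3), np.nan)
        for k, (i, j) in enumerate(occupied):
            means[i, j] = beta[k]
        return pd.DataFrame(means, index=[0, 1, 2], columns=[0, 1, 2])


@dataclass
class CombinationEffectRow:
    """Allele/genotype-combination deviation and frequency (Table-style row)."""

    combination: str
    effect: float
    frequency: float


def _genotype_label(code: int, alleles: tuple[str, str]) -> str:
    major, minor = alleles
    return {0: major + major, 1: major + minor, 2: minor + minor}[int(code)]


def _allele_copies(code: int, alleles: tuple[str, str]) -> list[str]:
    major, minor = alleles
    return {0: [major, major], 1: [major, minor], 2: [minor, minor]}[int(code)]


def combination_effects(
    y: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    effect_type: str,
    alleles1: tuple[str, str] = ("A", "a"),
    alleles2: tuple[str, str] = ("B", "b"),
) -> list[CombinationEffectRow]:
    """Combination-level phenotype deviations for one epistatic effect type.

    * AxA: each individual contributes its 2x2 ordered allele pairings (one
      allele per locus), each with weight 1/4;
    * AxD: allele at locus 1 (weight 1/2 per copy) x genotype at locus 2;
    * DxA: genotype at locus 1 x allele at locus 2;
    * DxD: genotype-genotype cells with weight 1.

    A combination's effect is its weighted mean phenotype minus the grand
    mean; its frequency is its share of total weight.  Frequencies sum to 1
    and the frequency-weighted effects sum to 0.  Rows are sorted by effect,
    descending.  ``alleles*`` give (major, minor) display letters.
    """
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"unknown effect type {effect_type!r}")
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(g1) & ~np.isnan(g2)
    y, g1, g2 = y[mask], g1[mask], g2[mask]
    if y.size == 0:
        return []
    grand = y.mean()
    weight: dict[str, float] = {}
    wsum_y: dict[str, float] = {}
    for yi, a, b in zip(y, g1.astype(int), g2.astype(int)):
        if effect_type == "AxA":
            contribs = [
                (f"{u}-{v}", 0.25)
                for u in _allele_copies(a, alleles1)
                for v in _allele_copies(b, alleles2)
            ]
        elif effect_type == "AxD":
            geno2 = _genotype_label(b, alleles2)
            contribs = [
                (f"{u}-{geno2}", 0.5) for u in _allele_copies(a, alleles1)
            ]
        elif effect_type == "DxA":
            geno1 = _genotype_label(a, alleles1)
            contribs = [
                (f"{geno1}-{v}", 0.5) for v in _allele_copies(b, alleles2)
            ]
        else:  # DxD
            contribs = [
                (f"{_genotype_label(a, alleles1)}-{_genotype_label(b, alleles2)}", 1.0)
            ]
        for key, w in contribs:
            weight[key] = weight.get(key, 0.0) + w
            wsum_y[key] = wsum_y.get(key, 0.0) + w * yi
    total = sum(weight.values())
    rows = [
        CombinationEffectRow(
            combination=key,
            effect=wsum_y[key] / w - grand,
            frequency=w / total,
        )
        for key, w in weight.items()
    ]
    rows.sort(key=lambda r: -r.effect)
    return rows


def combination_deviations(
    y: np.ndarray, g1: np.ndarray, g2: np.ndarray
) -> pd.DataFrame:
    """Raw 3x3 two-locus cell means minus the grand mean (NaN = empty cell)."""
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(g1) & ~np.isnan(g2)
    y, g1, g2 = y[mask], g1[mask], g2[mask]
    out = np.full((3, 3), np.nan)
    if y.size:
        grand = y.mean()
        for i, j in product(range(3), range(3)):
            sel = (g1 == i) & (g2 == j)
            if sel.any():
                out[i, j] = y[sel].mean() - grand
    return pd.DataFrame(out, index=[0, 1, 2], columns=[0, 1, 2])


def hub_target_pairs(
    hub_snp_ids: list[str], target_snp_ids: list[str]
) -> list[tuple[str, str]]:
    """All hub-SNP x target-SNP pairs (the hub-centred scan design)."""
    return [(h, t) for h in hub_snp_ids for t in target_snp_ids]


_PAIR_COLUMNS = [
    "snp1", "gene1", "snp2", "gene2", "trait", "effect_type",
    "estimate", "p", "q", "n", "cells_occupied", "overall_p", "flags",
    "significant",
]


def scan_epistasis(
    cohort: Cohort,
    pairs: list[tuple[str, str]] | str = "all-pairs",
    traits: list[str] | None = None,
    alpha: float = 0.01,
    fdr_max: float = 0.1,
    occupancy: OccupancyRule | None = None,
    include_covariates: bool = True,
) -> pd.DataFrame:
    """Run two-locus tests over requested pairs x traits, long-format output.

    ``pairs`` is an explicit list of (snp_id1, snp_id2) or "all-pairs".
    One output row per (pair, trait, effect type); BH adjustment within each
    (trait, effect-type) family; a row is significant when p <= alpha and
    q <= fdr_max.  Skipped pairs keep their reason in ``flags``.
    """
    gm = cohort.genotypes
    traits = traits or cohort.phenotypes.trait_names
    if pairs == "all-pairs":
        pairs = list(combinations(gm.snp_ids, 2))
    Q = (
        cohort.covariates.q
        if (include_covariates and cohort.covariates is not None)
        else None
    )
    gene_of = {s.snp_id: s.gene_id for s in gm.snps}
    columns = {sid: gm.column(sid) for sid in set(p for pr in pairs for p in pr)}
    records = []
    for trait in traits:
        y = cohort.phenotypes.trait(trait)
        for s1, s2 in pairs:
            res = TwoLocusModel(
                y, columns[s1], columns[s2], Q, occupancy=occupancy,
                snp_id1=s1, snp_id2=s2, trait=trait,
            ).fit()
            cells = int((~res.cell_means.isna()).to_numpy().sum())
            for t in EFFECT_TYPES:
                est, p = res.effects[t]
                records.append(
                    dict(snp1=s1, gene1=gene_of[s1], snp2=s2, gene2=gene_of[s2],
                         trait=trait, effect_type=t, estimate=est, p=p,
                         n=res.n_used, cells_occupied=cells,
                         overall_p=res.overall_pair_p,
                         flags=res.reason if res.skipped else "")
                )
    if not records:
        return pd.DataFrame(columns=_PAIR_COLUMNS)
    df = pd.DataFrame.from_records(records)
    df["q"] = np.nan
    for trait in traits:
        for t in EFFECT_TYPES:
            sel = (df["trait"] == trait) & (df["effect_type"] == t)
            p = df.loc[sel, "p"].to_numpy()
            if p.size:
                df.loc[sel, "q"] = bh_adjust(p)
    df["significant"] = (df["p"] <= alpha) & (df["q"] <= fdr_max)
    return df[_PAIR_COLUMNS]
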