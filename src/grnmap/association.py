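"""Single-locus association: genotypic (m), additive (a) and dominance (d)
effects per SNP and trait, with fixed-effect population-structure adjustment.

The model follows the classical candidate-gene least-squares test for
unrelated individuals: for a trait y and a SNP with minor-allele counts g,

    genotypic (m):  y ~ Q + genotype-class factor   (2-df F test vs y ~ Q)
    additive/dominance:  y ~ Q + x + z,  x = g - 1,  z = +-1/2

where Q are population-structure membership covariates entered as fixed
effects.  With no covariates the coefficient estimates have the closed forms
a = (mean2 - mean0)/2 and d = mean1 - (mean0 + mean2)/2.

Multiple testing across a scan is controlled per (trait, effect-type) family
with the Benjamini-Hochberg step-up procedure, and p-values are reported
alongside the significance transform log10(1/p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import fit_sse, nested_f_test
from .coding import additive_code, dominance_code
from .datatypes import Cohort

__all__ = [
    "SingleLocusModel",
    "SingleLocusResults",
    "DeviationRow",
    "significance_transform",
    "bh_adjust",
    "genotype_deviations",
    "scan_single",
]


def significance_transform(p: float | np.ndarray) -> float | np.ndarray:
    """Significance = log10(1/p); requires 0 < p <= 1."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    out = np.log10(1.0 / p)
    return float(out) if out.ndim == 0 else out

def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, permutation-invariant).

    NaN entries are ignored (returned as NaN) and do not count toward the
    family size.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[mask] = qv
    return q


@dataclass
class DeviationRow:
    """Raw genotype-class mean and its deviation from the grand mean."""

    genotype: str
    mean: float
    deviation: float
    n: int


@dataclass
class SingleLocusResults:
    """Estimates and tests from a fitted :class:`SingleLocusModel`."""

    snp_id: str
    trait: str
    n_used: int
    genotype_means: dict[int, float]  # adjusted class means keyed by code
    m_p: float
    m_f: float
    r2_explained: float
    a_hat: float
    a_p: float
    d_hat: float
    d_p: float
    skipped: bool = False
    reason: str = ""
    q_m: float = float("nan")
    q_a: float = float("nan")
    q_d: float = float("nan")

    def significance(self, which: str = "m") -> float:
        p = {"m": self.m_p, "a": self.a_p, "d": self.d_p}[which]
        return float(np.log10(1.0 / p)) if p > 0 else float("inf")

    def summary(self) -> str:
        lines = [
            f"Single-locus association: {self.snp_id} ~ {self.trait}",
            f"  n used           {self.n_used}",
        ]
        if self.skipped:
            lines.append(f"  SKIPPED: {self.reason}")
            return "\n".join(lines)
        means = ", ".join(
            f"g={k}: {v:.4g}" for k, v in sorted(self.genotype_means.items())
        )
        lines += [
            f"  adjusted means   {means}",
            f"  genotypic (m)    F = {self.m_f:.4g}, p = {self.m_p:.3g}",
            f"  R^2 explained    {self.r2_explained:.4g}",
            f"  additive (a)     {self.a_hat:.4g} (p = {self.a_p:.3g})",
            f"  dominance (d)    {self.d_hat:.4g} (p = {self.d_p:.3g})",
        ]
        return "\n".join(lines)


class SingleLocusModel:
    """Least-squares single-SNP model for one quantitative trait.

    Parameters
    ----------
    y : trait values (NaN = missing).
    genotypes : minor-allele counts {0, 1, 2, NaN}.
    covariates : optional individuals x k structure matrix (Q).
    min_class_n : a genotype class needs at least this many individuals to
        enter the test; smaller classes are excluded (complete-case analysis
        drops their individuals) and the fit degrades gracefully from the
        3-class a+d model to a 2-class additive-only model, or is skipped.
    """

    def __init__(
        self,
        y: np.ndarray,
        genotypes: np.ndarray,
        covariates: np.ndarray | None = None,
        min_class_n: int = 3,
        snp_id: str = "snp",
        trait: str = "trait",
    ) -> None:
        self.y_raw = np.asarray(y, dtype=float)
        self.g_raw = np.asarray(genotypes, dtype=float)
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != self.y_raw.size:
                raise ValueError("covariate rows != n individuals")
        self.Q = covariates
        self.min_class_n = int(min_class_n)
        self.snp_id = snp_id
        self.trait = trait

    def _complete_cases(self):
        mask = ~np.isnan(self.y_raw) & ~np.isnan(self.g_raw)
        if self.Q is not None:
            mask &= ~np.isnan(self.Q).any(axis=1)
        y = self.y_raw[mask]
        g = self.g_raw[mask]
        Q = self.Q[mask] if self.Q is not None else None
        return y, g, Q

    def fit(self) -> SingleLocusResults:
        y, g, Q = self._complete_cases()
        # keep only genotype classes with enough individuals
        codes, counts = np.unique(g, return_counts=True)
        good = {c for c, n in zip(codes, counts) if n >= self.min_class_n}
        keep = np.isin(g, sorted(good))
        y, g = y[keep], g[keep]
        Q = Q[keep] if Q is not None else None
        classes = sorted(good)
        n = y.size

        def _skip(reason: str) -> SingleLocusResults:
            return SingleLocusResults(
                self.snp_id, self.trait, n, {}, np.nan, np.nan, np.nan,
                np.nan, np.nan, np.nan, np.nan, skipped=True, reason=reason,
            )

        if len(classes) < 2:
            return _skip(f"fewer than 2 genotype classes with n >= {self.min_class_n}")

        base = [np.ones(n)]
        if Q is not None:
            base.append(Q - Q.mean(axis=0))  # centred so means stay on trait scale
        X_red = np.column_stack(base)
        _, sse_red, rank_red = fit_sse(X_red, y)

        # --- genotypic 2-df (or 1-df) test: class factor vs covariates only
        dummies = np.column_stack([(g == c).astype(float) for c in classes])
        X_fac = np.column_stack([dummies] + base[1:])  # cell-means coding
        beta_fac, sse_fac, rank_fac = fit_sse(X_fac, y)
        m_f, m_p = nested_f_test(sse_red, rank_red, sse_fac, rank_fac, n)
        ss_total = float(((y - y.mean()) ** 2).sum())
        r2 = (sse_red - sse_fac) / ss_total if ss_total > 0 else np.nan
        genotype_means = {int(c): float(beta_fac[i]) for i, c in enumerate(classes)}

        # --- additive / dominance decomposition
        x = additive_code(g)
        z = dominance_code(g)
        a_hat = a_p = d_hat = d_p = np.nan
        if len(classes) == 3:
            X_full = np.column_stack([X_red, x, z])
            beta, sse_full, rank_full = fit_sse(X_full, y)
            a_hat, d_hat = float(beta[-2]), float(beta[-1])
            X_no_a = np.column_stack([X_red, z])
            _, sse_no_a, rank_no_a = fit_sse(X_no_a, y)
            _, a_p = nested_f_test(sse_no_a, rank_no_a, sse_full, rank_full, n)
            X_no_d = np.column_stack([X_red, x])
            _, sse_no_d, rank_no_d = fit_sse(X_no_d, y)
            _, d_p = nested_f_test(sse_no_d, rank_no_d, sse_full, rank_full, n)
        else:
            # two classes: additive effect only, d not estimable
            X_a = np.column_stack([X_red, x])
            beta, sse_a, rank_a = fit_sse(X_a, y)
            a_hat = float(beta[-1])
            _, a_p = nested_f_test(sse_red, rank_red, sse_a, rank_a, n)

        reason = "" if len(classes) == 3 else "2 genotype classes: d not estimable"
        return SingleLocusResults(
            self.snp_id, self.trait, n, genotype_means,
            m_p, m_f, float(r2), a_hat, a_p, d_hat, d_p,
            skipped=False, reason=reason,
        )


def genotype_deviations(
    y: np.ndarray,
    genotypes: np.ndarray,
    labels: dict[int, str] | None = None,
) -> list[DeviationRow]:
    """Raw genotype-class means minus the grand mean (complete cases).

    The count-weighted deviations sum to zero by construction.  ``labels``
    maps genotype codes to display labels (e.g. {0: "AA", 1: "AG", 2: "GG"}).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(g)
    y, g = y[mask], g[mask]
    grand = y.mean()
    rows = []
    for c in sorted(np.unique(g)):
        sel = g == c
        label = labels.get(int(c), str(int(c))) if labels else str(int(c))
        rows.append(
            DeviationRow(label, float(y[sel].mean()),
                         float(y[sel].mean() - grand), int(sel.sum()))
        )
    return rows


_SCAN_COLUMNS = [
    "snp", "gene", "trait", "n", "m_p", "a_hat", "a_p", "d_hat", "d_p",
    "r2", "q_m", "q_a", "q_d", "significant_a", "significant_d", "flags",
]


def scan_single(
    cohort: Cohort,
    traits: list[str] | None = None,
    snp_ids: list[str] | None = None,
    alpha: float = 0.01,
    fdr_max: float = 0.1,
    min_class_n: int = 3,
) -> pd.DataFrame:
    """All SNP x trait single-locus tests with per-family BH adjustment.

    The BH family is all SNPs within one (trait, effect-type) combination.
    A result is flagged significant when p <= alpha and q <= fdr_max.
    Skipped tests are retained with a reason in ``flags``.
    """
    gm = cohort.genotypes
    traits = traits if traits is not None else cohort.phenotypes.trait_names
    snp_ids = snp_ids if snp_ids is not None else gm.snp_ids
    Q = cohort.covariates.q if cohort.covariates is not None else None
    gene_of = {s.snp_id: s.gene_id for s in gm.snps}
    mono = dict(zip(gm.snp_ids, gm.monomorphic_mask()))
    records = []
    for trait in traits:
        y = cohort.phenotypes.trait(trait)
        for sid in snp_ids:
            if mono[sid]:
                records.append(
                    dict(snp=sid, gene=gene_of[sid], trait=trait, n=0,
                         m_p=np.nan, a_hat=np.nan, a_p=np.nan, d_hat=np.nan,
                         d_p=np.nan, r2=np.nan, flags="monomorphic")
                )
                continue
            res = SingleLocusModel(
                y, gm.column(sid), Q, min_class_n=min_class_n,
                snp_id=sid, trait=trait,
            ).fit()
            records.append(
                dict(snp=sid, gene=gene_of[sid], trait=trait, n=res.n_used,
                     m_p=res.m_p, a_hat=res.a_hat, a_p=res.a_p,
                     d_hat=res.d_hat, d_p=res.d_p, r2=res.r2_explained,
                     flags=res.reason if (res.skipped or res.reason) else "")
            )
    if not records:
        return pd.DataFrame(columns=_SCAN_COLUMNS)
    df = pd.DataFrame.from_records(records)
    for col in ("q_m", "q_a", "q_d"):
        df[col] = np.nan
    for trait in traits:
        sel = df["trait"] == trait
        for eff in ("m", "a", "d"):
            p = df.loc[sel, f"{eff}_p"].to_numpy()
            if p.size:
                df.loc[sel, f"q_{eff}"] = bh_adjust(p)
    df["significant_a"] = (df["a_p"] <= alpha) & (df["q_a"] <= fdr_max)
    df["significant_d"] = (df["d_p"] <= alpha) & (df["q_d"] <= fdr_max)
    return df[_SCAN_COLUMNS]
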