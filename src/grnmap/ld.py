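"""SNP summaries and linkage-disequilibrium decay.

LD between two SNPs is the composite (genotypic) r^2: the squared Pearson
correlation of minor-allele-count vectors over individuals with both calls
present — the standard choice for unphased diploid data.

The decay of r^2 with physical distance is fitted with the Hill-Weir
expectation for the sample-size-adjusted E(r^2) curve.  With C = rho * d the
population recombination parameter scaled by distance d and n the sample
size,

    E(r^2) = [ (10 + C) / ((2 + C)(11 + C)) ]
             * [ 1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C)) ]

which starts near 0.45 at C = 0 and decays to the finite-sample floor ~1/n.
The single free parameter rho (per-bp) is estimated by nonlinear least
squares; the fitted curve is monotone non-increasing in distance, so the
distance at which it crosses a threshold (default r^2 = 0.1) is well
defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import GenotypeMatrix

__all__ = [
    "LDPair",
    "LDDecayFit",
    "filter_common",
    "filter_missingness",
    "snp_density",
    "ld_r2",
    "pairwise_ld",
    "expected_r2",
    "fit_ld_decay",
]


def filter_common(gm: GenotypeMatrix, maf_min: float = 0.10) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly greater than ``maf_min`` (order preserved)."""
    mafs = gm.recompute_maf()
    keep = mafs > maf_min
    if not keep.any():
        warnings.warn("no SNPs pass the MAF filter")
    return gm.subset_snps(keep)


def filter_missingness(gm: GenotypeMatrix, max_missing: float = 0.20) -> GenotypeMatrix:
    """Keep SNPs whose fraction of missing calls is <= ``max_missing``."""
    return gm.subset_snps(gm.missing_fraction() <= max_missing)


def snp_density(n_snps: int, total_bp: int) -> float:
    """Average bp per SNP (e.g. 100 SNPs over 2400 bp -> one SNP per 24 bp)."""
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    if n_snps <= 0:
        raise ValueError("n_snps must be > 0")
    return total_bp / n_snps


@dataclass(frozen=True)
class LDPair:
    snp_id1: str
    snp_id2: str
    distance_bp: int
    r2: float
    n_used: int


def ld_r2(gm: GenotypeMatrix, snp_id1: str, snp_id2: str) -> LDPair:
    """Composite genotypic r^2 between two SNPs on complete cases.

    Raises if either SNP is monomorphic after complete-case restriction.
    Symmetric in SNP order and invariant to flipping which allele is coded.
    """
    c1, c2 = gm.column(snp_id1), gm.column(snp_id2)
    mask = ~np.isnan(c1) & ~np.isnan(c2)
    a, b = c1[mask], c2[mask]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError(
            f"{snp_id1} x {snp_id2}: monomorphic on the complete-case subset"
        )
    r = np.corrcoef(a, b)[0, 1]
    i = gm.snp_ids.index(snp_id1)
    j = gm.snp_ids.index(snp_id2)
    dist = abs(gm.snps[i].pos - gm.snps[j].pos)
    return LDPair(snp_id1, snp_id2, int(dist), float(r * r), int(a.size))


def pairwise_ld(
    gm: GenotypeMatrix, gene_id: str | None = None
) -> list[LDPair]:
    """All pairwise r^2 values, optionally restricted to one gene's SNPs."""
    ids = [
        s.snp_id
        for s in gm.snps
        if gene_id is None or s.gene_id == gene_id
    ]
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            try:
                pairs.append(ld_r2(gm, ids[i], ids[j]))
            except ValueError:
                continue  # monomorphic pair: undefined, skipped
    return pairs


def write_ld_pairs(pairs: list[LDPair], path) -> None:
    """Write pairs as TSV (snp1, snp2, distance_bp, r2, n)."""
    import pandas as pd

    pd.DataFrame(
        [
            dict(snp1=p.snp_id1, snp2=p.snp_id2, distance_bp=p.distance_bp,
                 r2=p.r2, n=p.n_used)
            for p in pairs
        ],
        columns=["snp1", "snp2", "distance_bp", "r2", "n"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def expected_r2(c: np.ndarray, n: int) -> np.ndarray:
    """Hill-Weir E(r^2) at scaled distance C = rho*d with sample size n."""
    c = np.asarray(c, dtype=float)
    term1 = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    term2 = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c * c)) / (
        n * (2.0 + c) * (11.0 + c)
    )
    return term1 * term2


@dataclass
class LDDecayFit:
    """Fitted decay curve; ``rho`` is the per-bp recombination parameter."""

    rho: float
    n: int
    sse: float
    n_pairs: int

    def curve(self, distances: np.ndarray) -> np.ndarray:
        return expected_r2(self.rho * np.asarray(distances, dtype=float), self.n)

    def crossing_bp(self, threshold: float = 0.1) -> float:
        """First distance where the fitted curve drops below ``threshold``.

        Returns +inf when the curve never reaches the threshold (either the
        fit sits at the rho -> 0 boundary or the threshold is below the
        finite-sample floor ~1/n).
        """
        if self.rho <= 0:
            return float("inf")
        f = lambda d: float(expected_r2(self.rho * d, self.n) - threshold)
        if f(0.0) <= 0:
            return 0.0
        hi = 1.0
        while f(hi) > 0:
            hi *= 10.0
            if hi > 1e12:
                return float("inf")
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-9, rtol=1e-12))


def fit_ld_decay(pairs: list[LDPair], n: int) -> LDDecayFit:
    """Least-squares fit of the expected-r^2 decay over observed pairs.

    Requires >= 5 pairs spanning >= 2 distinct distances.  The single
    parameter rho >= 0 is found by bounded scalar minimisation of the
    residual sum of squares, refined by a local least-squares polish.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 LD pairs to fit the decay curve")
    d = np.array([p.distance_bp for p in pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs], dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct distances")

    def sse(log_rho: float) -> float:
        resid = r2 - expected_r2(np.exp(log_rho) * d, n)
        return float(resid @ resid)

    # coarse log-scale grid then bounded local search: the objective is
    # smooth and unimodal in rho for realistic data but flat at both extremes
    grid = np.linspace(np.log(1e-12), np.log(1e3), 400)
    values = np.array([sse(g) for g in grid])
    k = int(np.argmin(values))
    lo = grid[max(k - 2, 0)]
    hi = grid[min(k + 2, grid.size - 1)]
    res = optimize.minimize_scalar(
        sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-13},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"LD decay fit failed to converge; best iterate {res.x}")
    rho = float(np.exp(res.x))
    sse_boundary = sse(np.log(1e-15))
    if sse_boundary <= res.fun:  # boundary: curve flat, rho -> 0
        return LDDecayFit(rho=0.0, n=n, sse=float(sse_boundary), n_pairs=len(pairs))
    return LDDecayFit(rho=rho, n=n, sse=float(res.fun), n_pairs=len(pairs))
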