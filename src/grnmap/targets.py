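"""TF-target discovery: exact promoter motif scanning intersected with
strong hub co-expression, plus motif positional summaries and the
differential-expression threshold screen.

The default motifs are the conserved WUS-binding site TCACGTGA and its
alternative core TAAT; a gene qualifies as motif-bearing if its promoter
carries at least one occurrence of any configured motif (either/or logic,
configurable to a single motif).  Target selection intersects motif presence
with |Pearson r| strictly greater than a threshold (default 0.8) against the
hub gene's expression profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, PromoterSet

__all__ = [
    "DEFAULT_MOTIFS",
    "MotifHit",
    "TargetCall",
    "DEFilterRow",
    "scan_motifs",
    "motif_position_distribution",
    "expression_correlation",
    "screen_de",
    "select_targets",
]

DEFAULT_MOTIFS = ("TCACGTGA", "TAAT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One exact motif occurrence in a promoter.

    ``upstream_start`` is the 1-based upstream offset (bp before the TSS) of
    the motif base closest to the TSS.
    """

    gene_id: str
    motif: str
    upstream_start: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    has_motif: bool
    pearson_r: float
    direction: str  # positive | negative | none
    selected: bool


@dataclass(frozen=True)
class DEFilterRow:
    gene_id: str
    fold_change: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")
        if not (0 <= self.p_value <= 1 and 0 <= self.q_value <= 1):
            raise ValueError("p and q must be in [0, 1]")


def _find_all(seq: str, motif: str) -> list[int]:
    """0-based start indices of all (overlapping) occurrences."""
    hits, start = [], 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def scan_motifs(
    promoters: PromoterSet,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    strand_mode: str = "both",
) -> list[MotifHit]:
    """Exact-string motif scan over promoter sequences.

    In ``both`` mode, reverse-complement matches are reported on strand '-';
    a motif that is its own reverse complement (e.g. TCACGTGA) is reported
    once, on the forward strand only.  Overlapping occurrences are all
    reported.  Promoters shorter than a motif are skipped with a warning.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    for m in motifs:
        if set(m) - set("ACGT"):
            raise ValueError(f"motif {m!r} contains non-ACGT characters")
    hits: list[MotifHit] = []
    for gid in promoters.gene_ids:
        seq = promoters[gid]
        length = len(seq)
        for motif in motifs:
            if len(motif) > length:
                warnings.warn(
                    f"motif {motif} longer than promoter of {gid}; gene skipped"
                )
                continue
            strands = [(motif, "+")]
            rc = reverse_complement(motif)
            if strand_mode == "both" and rc != motif:
                strands.append((rc, "-"))
            for pattern, strand in strands:
                for i in _find_all(seq, pattern):
                    # base closest to the TSS is the physical 3'-most base
                    upstream = length - (i + len(pattern) - 1)
                    hits.append(MotifHit(gid, motif, upstream, strand))
    return hits


def motif_position_distribution(
    hits: list[MotifHit], window_bins: list[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """Fraction of all hits whose upstream offset falls in each closed bin.

    Bins must not overlap; hits outside every bin stay in the denominator, so
    fractions sum to <= 1 (and to 1 when the bins tile the promoter).
    Raises on zero total hits (fractions undefined).
    """
    for i, (lo1, hi1) in enumerate(window_bins):
        if lo1 > hi1:
            raise ValueError(f"bin ({lo1}, {hi1}) is inverted")
        for lo2, hi2 in window_bins[i + 1:]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise ValueError("window bins overlap")
    if not hits:
        raise ValueError("no motif hits: positional fractions undefined")
    total = len(hits)
    return {
        (lo, hi): sum(lo <= h.upstream_start <= hi for h in hits) / total
        for lo, hi in window_bins
    }


def expression_correlation(
    expr: ExpressionMatrix, hub_gene: str
) -> dict[str, float]:
    """Pearson r of every gene's profile against the hub gene's profile.

    Genes with constant profiles are excluded with a warning (r undefined);
    a constant hub profile is an error.  Requires >= 3 conditions.
    """
    if hub_gene not in expr.gene_ids:
        raise KeyError(f"hub gene {hub_gene!r} not in expression matrix")
    if len(expr.condition_ids) < 3:
        raise ValueError("need at least 3 conditions for correlation")
    hub = expr.profile(hub_gene)
    if np.allclose(hub, hub[0]):
        raise ValueError("hub expression profile is constant")
    hub_c = hub - hub.mean()
    hub_ss = float(hub_c @ hub_c)
    out: dict[str, float] = {}
    for gid in expr.gene_ids:
        if gid == hub_gene:
            continue
        prof = expr.profile(gid)
        if np.allclose(prof, prof[0]):
            warnings.warn(f"constant expression profile for {gid}; r undefined")
            continue
        pc = prof - prof.mean()
        out[gid] = float(hub_c @ pc / np.sqrt(hub_ss * (pc @ pc)))
    return out


def screen_de(
    rows: list[DEFilterRow],
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    q_max: float = 0.10,
    p_max: float = 1.0e-3,
) -> set[str]:
    """Differential-expression threshold screen on supplied statistics.

    Keeps a gene iff (FC >= fc_up or FC <= fc_down) and q <= q_max and
    p <= p_max; all boundaries inclusive.
    """
    return {
        r.gene_id
        for r in rows
        if (r.fold_change >= fc_up or r.fold_change <= fc_down)
        and r.q_value <= q_max
        and r.p_value <= p_max
    }


def select_targets(
    hits: list[MotifHit],
    correlations: dict[str, float],
    r_threshold: float = 0.8,
) -> list[TargetCall]:
    """Motif-AND-co-expression target decision per gene.

    Selected iff the gene has at least one motif hit and |r| > r_threshold
    (strict, so r = 0.8 exactly is excluded).  One call per gene appearing in
    either input, sorted by gene id.
    """
    motif_genes = {h.gene_id for h in hits}
    genes = sorted(motif_genes | set(correlations))
    calls = []
    for gid in genes:
        r = correlations.get(gid, float("nan"))
        has_motif = gid in motif_genes
        strong = not np.isnan(r) and abs(r) > r_threshold
        direction = "none"
        if strong:
            direction = "positive" if r > 0 else "negative"
        calls.append(
            TargetCall(
                gene_id=gid,
                has_motif=has_motif,
                pearson_r=r,
                direction=direction,
                selected=has_motif and strong,
            )
        )
    return calls
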