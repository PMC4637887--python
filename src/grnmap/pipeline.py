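"""End-to-end orchestration: simulate (or load) -> discover targets ->
single-locus scan -> epistasis scan -> layered network.

Every stage reads its inputs from files in the run directory and writes its
outputs there, so any stage can be re-run standalone on prior-stage outputs
with identical results.  All randomness flows from one root seed through
named per-stage substreams, and a manifest records the config hash, seed and
row counts, so identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .association import scan_single
from .datatypes import GenotypeMatrix
from .epistasis import OccupancyRule, hub_target_pairs, scan_epistasis
from .ld import filter_common
from .network import (
    build_layers,
    collapse_to_gene_edges,
    connectivity_fraction,
    export_network,
)
from .simulate import (
    EffectModel,
    EpistaticTerm,
    LDBlock,
    SimulationSpec,
    plant_promoters,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotype,
    simulate_structure,
)
from .targets import (
    DEFAULT_MOTIFS,
    expression_correlation,
    motif_position_distribution,
    scan_motifs,
    select_targets,
)

__version__ = "0.1.0"

TRAITS = ["DBH", "H", "V", "HemC", "HolC", "CC", "LC", "FL", "FW", "MFA"]

STAGES = ("simulate", "discover-targets", "assoc-single", "assoc-epistasis", "network")


@dataclass
class DemoSimulation:
    """Bundled synthetic-study layout: a hub TF and its candidate targets.

    Defaults emulate the study conditions the analysis assumes: an
    association panel of 435 unrelated individuals, ten quantitative traits,
    a hub gene plus 53 candidate target genes, four-tissue expression
    profiles, and 2-kb promoters.  SNP counts per gene are kept at desk
    scale.
    """

    n_individuals: int = 435
    n_target_genes: int = 53
    snps_per_gene: int = 2
    hub_snps: int = 3
    n_decoy_genes: int = 10
    k_structure: int = 3
    sigma: float = 1.0
    n_conditions: int = 4
    promoter_length: int = 2000
    within_gene_ld_rho: float = 0.5
    traits: list[str] = field(default_factory=lambda: list(TRAITS))


@dataclass
class InputPaths:
    vcf: str
    phenotypes: str
    covariates: str = ""
    promoters: str = ""
    expression: str = ""


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    simulate: DemoSimulation | None = None
    inputs: InputPaths | None = None
    hub_gene: str = "HUB"
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    maf_min: float = 0.10
    r_threshold: float = 0.8
    alpha: float = 0.01
    fdr: float = 0.1
    fc_up: float = 2.0
    fc_down: float = 0.5
    de_p: float = 1.0e-3
    de_q: float = 0.10
    min_class_n: int = 3
    min_marginal_n: int = 3
    min_cells: int = 5
    max_layer: int = 3
    max_target_pairs: int = 3000
    epistasis_traits: list[str] | None = None  # None = all traits

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = DemoSimulation(**raw["simulate"])
        if "inputs" in raw and raw["inputs"] is not None:
            raw["inputs"] = InputPaths(**raw["inputs"])
        if "motifs" in raw:
            raw["motifs"] = tuple(raw["motifs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motifs"] = list(self.motifs)
        return d

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


_DEFAULTS = PipelineConfig(output_dir="")


def validate_config(config: PipelineConfig) -> dict:
    """Range/consistency checks; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    if (config.simulate is None) == (config.inputs is None):
        errors.append("exactly one of 'simulate' or 'inputs' must be given")
    for name, lo, hi in (
        ("alpha", 0.0, 1.0), ("fdr", 0.0, 1.0), ("de_p", 0.0, 1.0),
        ("de_q", 0.0, 1.0), ("maf_min", 0.0, 0.5), ("r_threshold", 0.0, 1.0),
    ):
        v = getattr(config, name)
        if not (lo <= v <= hi):
            errors.append(f"{name}={v} outside [{lo}, {hi}]")
    if config.fc_up <= 0 or config.fc_down <= 0:
        errors.append("fold-change bounds must be positive")
    if config.fc_down > config.fc_up:
        errors.append("fc_down must not exceed fc_up")
    if not config.hub_gene:
        errors.append("hub gene must be set")
    if config.max_layer < 2:
        errors.append("max_layer must be >= 2")
    for m in config.motifs:
        if set(m) - set("ACGT"):
            errors.append(f"motif {m!r} contains non-ACGT characters")
    for name in ("alpha", "fdr", "maf_min", "r_threshold", "fc_up", "fc_down",
                 "de_p", "de_q", "min_class_n"):
        if getattr(config, name) != getattr(_DEFAULTS, name):
            warnings_.append(f"non-default threshold {name}={getattr(config, name)}")
    return {"errors": errors, "warnings": warnings_}


def _substream(seed: int, stage: str) -> int:
    """Named per-stage seed derived from the root seed (below 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stage: simulate


def _demo_effect_models(
    sim: DemoSimulation, gm: GenotypeMatrix, seed: int
) -> dict[str, EffectModel]:
    """Per-trait generative models with planted additive, dominance and
    epistatic effects that tie the hub SNPs to rotating subsets of targets."""
    rng = np.random.default_rng(_substream(seed, "effects"))
    snp_ids = gm.snp_ids
    mafs = dict(zip(gm.snp_ids, gm.recompute_maf()))
    hub_ids = [s.snp_id for s in gm.snps if s.gene_id == "HUB"]
    target_ids = [s.snp_id for s in gm.snps if s.gene_id != "HUB"]
    # interactions are planted at common SNPs: at low MAF the interaction
    # columns are highly collinear with the main effects and the planted
    # signal would be mostly non-identifiable at this panel size
    common_hub = [s for s in hub_ids if mafs[s] >= 0.25] or hub_ids
    by_maf = sorted(target_ids, key=lambda s: -mafs[s])
    common_targets = [s for s in by_maf if mafs[s] >= 0.25]
    if len(common_targets) < 12:  # small panels: top up with the commonest SNPs
        common_targets = by_maf[: min(12, len(by_maf))]
    models: dict[str, EffectModel] = {}
    # genotype-level interactions are drawn larger than allele-level ones,
    # as combination-effect tables from two-locus scans typically show
    coef_range = {
        "AxA": (1.0, 1.5), "AxD": (1.3, 1.8), "DxA": (1.3, 1.8),
        "DxD": (1.8, 2.4),
    }
    types = ["AxA", "AxD", "DxA", "DxD"]
    for k, trait in enumerate(sim.traits):
        additive = {
            sid: float(rng.uniform(0.2, 0.5) * rng.choice([-1, 1]))
            for sid in rng.choice(snp_ids, size=4, replace=False)
        }
        dominance = {
            sid: float(rng.uniform(0.2, 0.4) * rng.choice([-1, 1]))
            for sid in rng.choice(snp_ids, size=3, replace=False)
        }
        terms = []
        hub_partners = rng.choice(
            common_targets, size=min(5, len(common_targets)), replace=False
        )
        for i, tid in enumerate(hub_partners):
            et = types[i % 4]
            terms.append(
                EpistaticTerm(
                    snp_id1=str(rng.choice(common_hub)),
                    snp_id2=str(tid),
                    effect_type=et,
                    coefficient=float(rng.uniform(*coef_range[et]) * rng.choice([-1, 1])),
                )
            )
        n_tt = min(6, len(common_targets)) // 2 * 2
        tt = rng.choice(common_targets, size=n_tt, replace=False)
        for i in range(0, n_tt, 2):
            et = types[(i // 2 + k) % 4]
            terms.append(
                EpistaticTerm(
                    snp_id1=str(tt[i]),
                    snp_id2=str(tt[i + 1]),
                    effect_type=et,
                    coefficient=float(rng.uniform(*coef_range[et]) * rng.choice([-1, 1])),
                )
            )
        models[trait] = EffectModel(
            mu=10.0 + 5.0 * k,
            additive=additive,
            dominance=dominance,
            epistasis=terms,
            structure_effects=rng.uniform(-1.0, 1.0, size=sim.k_structure),
            sigma=sim.sigma,
        )
    return models


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    """Generate the bundled synthetic study and write all input files."""
    sim = config.simulate
    if sim is None:
        raise ValueError("stage 'simulate' requires a simulation spec")
    seed = config.seed
    hub = config.hub_gene
    targets = [f"G{i + 1:03d}" for i in range(sim.n_target_genes)]
    decoys = [f"D{i + 1:02d}" for i in range(sim.n_decoy_genes)]

    # --- genotypes: hub SNPs + per-target-gene SNPs with intragenic LD
    gene_of, positions, blocks = [], [], []
    pos = 1
    idx = 0
    for g in [hub] + targets:
        n_g = sim.hub_snps if g == hub else sim.snps_per_gene
        block = list(range(idx, idx + n_g))
        for _ in range(n_g):
            gene_of.append(g)
            positions.append(pos)
            pos += 24
            idx += 1
        pos += 500  # intergenic gap
        if len(block) > 1 and sim.within_gene_ld_rho > 0:
            blocks.append(LDBlock(block, sim.within_gene_ld_rho))
    spec = SimulationSpec(
        n_individuals=sim.n_individuals,
        n_snps=len(gene_of),
        maf=(0.1, 0.5),
        ld_blocks=blocks,
        gene_of_snp=gene_of,
        positions=positions,
        seed=_substream(seed, "genotypes"),
    )
    gm = simulate_genotypes(spec)
    for j, s in enumerate(gm.snps):
        s.snp_id = f"{s.gene_id}-SNP{sum(1 for t in gene_of[: j + 1] if t == s.gene_id)}"
    cov = simulate_structure(
        gm.individual_ids, k=sim.k_structure, seed=_substream(seed, "structure")
    )

    # --- phenotypes
    models = _demo_effect_models(sim, gm, seed)
    frames = []
    for trait, model in models.items():
        pt = simulate_phenotype(
            gm, model, cov, seed=_substream(seed, f"trait:{trait}"),
            trait_name=trait,
        )
        frames.append(pt.traits)
    phenotypes = pd.concat(frames, axis=1)

    # --- expression: strong planted correlations for targets, weak for decoys
    rng = np.random.default_rng(_substream(seed, "expression"))
    n_pos = sim.n_target_genes // 2 + 1
    corr = {}
    for i, g in enumerate(targets):
        mag = rng.uniform(0.93, 0.99)
        corr[g] = mag if i < n_pos else -mag
    half = len(decoys) // 2
    for i, g in enumerate(decoys):
        # first half: motif-bearing but weakly correlated; second half:
        # strongly correlated but motif-free
        corr[g] = (
            float(rng.uniform(-0.4, 0.4)) if i < half
            else float(rng.uniform(0.93, 0.99))
        )
    expr = simulate_expression(
        [hub] + targets + decoys, hub, corr,
        n_conditions=sim.n_conditions,
        condition_ids=["leaf", "cambium", "developing_xylem", "mature_xylem"][
            : sim.n_conditions
        ] if sim.n_conditions <= 4 else None,
        seed=_substream(seed, "expression"),
    )

    # --- promoters with planted motifs for targets and motif-bearing decoys
    rng_p = np.random.default_rng(_substream(seed, "promoters"))
    plan: dict[str, list[tuple[str, int]]] = {}
    for g in targets + decoys[:half]:
        offset = int(rng_p.integers(50, sim.promoter_length - 100))
        plants = [(config.motifs[0], offset)]
        if len(config.motifs) > 1 and rng_p.random() < 0.5:
            off2 = int(rng_p.integers(50, sim.promoter_length - 100))
            if abs(off2 - offset) > 20:
                plants.append((config.motifs[1], off2))
        plan[g] = plants
    promoters = plant_promoters(
        [hub] + targets + decoys, plan,
        background_gc=0.4, length=sim.promoter_length,
        seed=_substream(seed, "promoter-bg"),
    )

    gio.write_vcf(gm, outdir / "genotypes.vcf")
    from .datatypes import PhenotypeTable

    gio.write_table(
        PhenotypeTable(list(gm.individual_ids), phenotypes), outdir / "phenotypes.tsv"
    )
    gio.write_table(cov, outdir / "covariates.tsv")
    gio.write_table(expr, outdir / "expression.tsv")
    gio.write_promoters_fasta(promoters, outdir / "promoters.fasta")
    return {
        "n_individuals": gm.n_individuals,
        "n_snps": gm.n_snps,
        "n_traits": len(models),
        "n_genes": 1 + len(targets) + len(decoys),
    }


# ---------------------------------------------------------------------------
# stage: discover-targets


def stage_discover_targets(config: PipelineConfig, outdir: Path) -> dict:
    promoters = gio.read_promoters_fasta(outdir / "promoters.fasta")
    expr = gio.read_table(outdir / "expression.tsv", "expression")
    hits = scan_motifs(promoters, config.motifs, strand_mode="both")
    corr = expression_correlation(expr, config.hub_gene)
    calls = select_targets(hits, corr, r_threshold=config.r_threshold)
    hits_df = pd.DataFrame(
        [
            dict(gene=h.gene_id, motif=h.motif, upstream_start=h.upstream_start,
                 strand=h.strand)
            for h in sorted(hits, key=lambda h: (h.gene_id, h.upstream_start, h.motif))
        ],
        columns=["gene", "motif", "upstream_start", "strand"],
    )
    hits_df.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    calls_df = pd.DataFrame(
        [
            dict(gene=c.gene_id, has_motif=c.has_motif,
                 pearson_r=round(c.pearson_r, 10), direction=c.direction,
                 selected=c.selected)
            for c in calls
        ],
        columns=["gene", "has_motif", "pearson_r", "direction", "selected"],
    )
    calls_df.to_csv(outdir / "target_calls.tsv", sep="\t", index=False)
    bins = [(300, 600), (650, 950)]
    windows = motif_position_distribution(hits, bins) if hits else {}
    selected = sorted(c.gene_id for c in calls if c.selected)
    summary = {
        "n_motif_hits": len(hits),
        "n_motif_genes": int(hits_df["gene"].nunique()),
        "n_selected_targets": len(selected),
        "n_positive": sum(1 for c in calls if c.selected and c.direction == "positive"),
        "n_negative": sum(1 for c in calls if c.selected and c.direction == "negative"),
        "window_fractions": {f"{a}-{b}": windows[(a, b)] for a, b in bins}
        if windows else {},
    }
    (outdir / "targets_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


# ---------------------------------------------------------------------------
# stage: assoc-single


def _load_cohort(config: PipelineConfig, outdir: Path):
    gm = gio.read_vcf(outdir / "genotypes.vcf")
    phen = gio.read_table(outdir / "phenotypes.tsv", "phenotype")
    cov = gio.read_table(outdir / "covariates.tsv", "covariates")
    return gio.align_cohort(gm, phen, cov)


def stage_assoc_single(config: PipelineConfig, outdir: Path) -> dict:
    cohort = _load_cohort(config, outdir)
    cohort.genotypes = filter_common(cohort.genotypes, config.maf_min)
    table = scan_single(
        cohort, alpha=config.alpha, fdr_max=config.fdr,
        min_class_n=config.min_class_n,
    )
    table.to_csv(outdir / "assoc_single.tsv", sep="\t", index=False,
                 float_format="%.10g")
    n_sig = int((table["significant_a"] | table["significant_d"]).sum())
    return {
        "n_tests": len(table),
        "n_snps": int(table["snp"].nunique()),
        "n_significant_add_or_dom": n_sig,
    }


# ---------------------------------------------------------------------------
# stage: assoc-epistasis


def stage_assoc_epistasis(config: PipelineConfig, outdir: Path) -> dict:
    cohort = _load_cohort(config, outdir)
    cohort.genotypes = filter_common(cohort.genotypes, config.maf_min)
    gm = cohort.genotypes
    calls = pd.read_csv(outdir / "target_calls.tsv", sep="\t")
    selected_genes = set(calls.loc[calls["selected"], "gene"])
    hub_snps = [s.snp_id for s in gm.snps if s.gene_id == config.hub_gene]
    target_snps = [s.snp_id for s in gm.snps if s.gene_id in selected_genes]
    pairs = hub_target_pairs(hub_snps, target_snps)
    # target x target pairs, capped deterministically
    tt = [
        (a, b)
        for i, a in enumerate(target_snps)
        for b in target_snps[i + 1:]
    ]
    # drop within-gene pairs early: they never form network edges
    gene_of = {s.snp_id: s.gene_id for s in gm.snps}
    tt = [(a, b) for a, b in tt if gene_of[a] != gene_of[b]]
    if len(tt) > config.max_target_pairs:
        rng = np.random.default_rng(_substream(config.seed, "pair-cap"))
        idx = rng.choice(len(tt), size=config.max_target_pairs, replace=False)
        tt = [tt[i] for i in sorted(idx)]
    pairs = pairs + tt
    traits = config.epistasis_traits or cohort.phenotypes.trait_names
    table = scan_epistasis(
        cohort, pairs, traits=traits, alpha=config.alpha, fdr_max=config.fdr,
        occupancy=OccupancyRule(config.min_marginal_n, config.min_cells),
    )
    table.to_csv(outdir / "assoc_epistasis.tsv", sep="\t", index=False,
                 float_format="%.10g")
    _write_combination_tables(cohort, table, outdir)
    return {
        "n_pairs_attempted": len(pairs),
        "n_tests": len(table),
        "n_significant": int(table["significant"].sum()),
    }


def _write_combination_tables(
    cohort, table: pd.DataFrame, outdir: Path, max_rows: int = 60
) -> None:
    """Allele/genotype combination effect-frequency tables for the most
    significant pairs (deviation from grand mean, weight share)."""
    from .epistasis import combination_effects

    gm = cohort.genotypes
    snp_of = {s.snp_id: s for s in gm.snps}
    sig = table[table["significant"].fillna(False)].sort_values("p")
    sig = sig.head(max_rows)
    records = []
    for row in sig.itertuples(index=False):
        s1, s2 = snp_of[row.snp1], snp_of[row.snp2]
        y = cohort.phenotypes.trait(row.trait)
        rows = combination_effects(
            y, gm.column(row.snp1), gm.column(row.snp2), row.effect_type,
            alleles1=(s1.major_allele, s1.minor_allele),
            alleles2=(s2.major_allele, s2.minor_allele),
        )
        for r in rows:
            records.append(
                dict(snp1=row.snp1, snp2=row.snp2, trait=row.trait,
                     test_type=row.effect_type, test_effect=row.estimate,
                     p_value=row.p, combination=r.combination,
                     effect=r.effect, frequency=r.frequency)
            )
    pd.DataFrame(
        records,
        columns=["snp1", "snp2", "trait", "test_type", "test_effect",
                 "p_value", "combination", "effect", "frequency"],
    ).to_csv(outdir / "combination_tables.tsv", sep="\t", index=False,
             float_format="%.10g")


# ---------------------------------------------------------------------------
# stage: network


def stage_network(config: PipelineConfig, outdir: Path) -> dict:
    table = pd.read_csv(outdir / "assoc_epistasis.tsv", sep="\t")
    calls = pd.read_csv(outdir / "target_calls.tsv", sep="\t")
    universe = sorted(calls.loc[calls["selected"], "gene"])
    sig = table[table["significant"].fillna(False)]
    edges = collapse_to_gene_edges(sig)
    # the hub participates via its own SNP pairs; declare it regardless
    net = build_layers(edges, config.hub_gene, max_layer=config.max_layer)
    export_network(net, outdir / "network.sif", "sif")
    export_network(net, outdir / "network_edges.tsv", "tsv")
    export_network(net, outdir / "network.graphml", "graphml")
    layers_df = pd.DataFrame(
        sorted(net.layer_of.items()), columns=["gene", "layer"]
    )
    layers_df.to_csv(outdir / "network_layers.tsv", sep="\t", index=False)
    # per-trait networks and their gene-set overlap
    from .network import network_overlap, trait_networks

    per_trait = trait_networks(sig, config.hub_gene, config.max_layer)
    trait_rows = [
        dict(trait=t, gene=g, layer=l)
        for t, n in per_trait.items()
        for g, l in sorted(n.layer_of.items())
    ]
    pd.DataFrame(trait_rows, columns=["trait", "gene", "layer"]).to_csv(
        outdir / "network_layers_by_trait.tsv", sep="\t", index=False
    )
    network_overlap(per_trait).to_csv(
        outdir / "network_overlap.tsv", sep="\t", index_label="trait"
    )
    summary = connectivity_fraction(net, universe) if universe else None
    out = {
        "n_edges": len(net.edges),
        "n_genes_layer2": len(net.genes_in_layer(2)),
        "n_genes_layer3": len(net.genes_in_layer(3)),
        "n_universe": summary.n_universe if summary else 0,
        "connectivity_fraction": summary.fraction_connected if summary else float("nan"),
    }
    (outdir / "connectivity.json").write_text(json.dumps(out, indent=2))
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "discover-targets": stage_discover_targets,
    "assoc-single": stage_assoc_single,
    "assoc-epistasis": stage_assoc_epistasis,
    "network": stage_network,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order and write a run manifest."""
    report = validate_config(config)
    if report["errors"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": report["warnings"],
    }
    for stage in stages:
        try:
            manifest["stages"][stage] = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            (outdir / "manifest.partial.json").write_text(
                json.dumps(manifest, indent=2)
            )
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def default_demo_config(output_dir: str, seed: int = 0, **overrides) -> PipelineConfig:
    """The bundled demo: simulated study at the default conditions."""
    sim_kwargs = overrides.pop("simulate", {})
    return PipelineConfig(
        output_dir=output_dir,
        seed=seed,
        simulate=DemoSimulation(**sim_kwargs),
        **overrides,
    )
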