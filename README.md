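# grnmap

Hub-centred genetic-regulatory-network mapping from candidate-gene
association scans.

`grnmap` is aimed at quantitative geneticists working on natural populations
of unrelated individuals (its motivating use case is association panels of
forest trees) who want to go from a transcription factor of interest to a
layered gene–gene interaction network, using nothing but genotypes,
phenotypes, promoter sequences and a small expression matrix. It provides:

* **Target discovery** — exact-string promoter scanning for TF-binding
  motifs (defaults: the conserved WUS-binding site `TCACGTGA` and its
  alternative core `TAAT`, both strands, overlapping hits), intersected with
  strong hub co-expression (|Pearson r| > 0.8 across tissues), plus motif
  positional summaries and a fold-change/FDR differential-expression screen.
* **Single-locus association** — per SNP and trait, the genotypic effect
  *m* (2-df F test of the genotype factor), the additive effect *a* and the
  dominance effect *d*, by least squares with population-structure (Q
  matrix) fixed covariates.
* **Epistasis** — per SNP pair, the four-way decomposition of two-locus
  interaction into A×A, A×D, D×A and D×D components (the extended
  Kempthorne partition realised as OLS on the 8-column genetic design),
  with allele/genotype combination effect–frequency tables and
  genotype-combination deviation summaries.
* **Multiple testing** — Benjamini–Hochberg q-values per (trait, effect
  type) family, and the `significance = log10(1/p)` transform.
* **LD** — composite genotypic r², and the Hill–Weir expected-r² decay
  curve fitted by nonlinear least squares, with the distance at which the
  fitted curve crosses r² = 0.1.
* **Networks** — significant SNP pairs collapsed to gene-level edges and
  layered by BFS distance from the hub (hub = layer 1, direct interactors =
  layer 2, indirect = layer 3), exported as SIF / GraphML / TSV.
* **Synthetic data** — generators for genotypes under HWE with LD blocks,
  phenotypes from additive + dominance + epistatic genetic values plus
  structure effects, expression profiles with planted hub correlations, and
  promoters with motifs planted at exact offsets, so the whole pipeline is
  testable end to end without any external download.

## The model

Genotypes are coded as minor-allele counts g ∈ {0, 1, 2}. The single-locus
model for trait y with structure covariates Q is

    y = μ + Qβ + a·x + d·z + ε,   x = g − 1 ∈ {−1, 0, +1},
                                  z = +½ (het), −½ (either homozygote)

so that *a* is half the homozygote difference and *d* the heterozygote
deviation from the homozygote midpoint; without covariates,
a = (ȳ₂ − ȳ₀)/2 and d = ȳ₁ − (ȳ₀ + ȳ₂)/2 exactly. The two-locus model adds
the four products

    x₁x₂ (A×A), x₁z₂ (A×D), z₁x₂ (D×A), z₁z₂ (D×D)

and tests each with a 1-df full-vs-reduced F test (plus a joint 4-df test);
under 1:2:1 × 1:2:1 genotype proportions these eight columns are mutually
orthogonal, and with unequal observed frequencies the OLS fit is the
corresponding frequency-weighted partition. Coefficients aliased by empty
two-locus cells are reported as non-estimable, never as zero.

## Worked example

```python
from grnmap import (SimulationSpec, EffectModel, EpistaticTerm,
                    simulate_genotypes, simulate_phenotype,
                    SingleLocusModel, TwoLocusModel)

gm = simulate_genotypes(SimulationSpec(n_individuals=435, n_snps=2,
                                       maf=[0.35, 0.5], seed=7))
truth = EffectModel(
    mu=40.0,
    additive={"snp1": 0.5},          # half the homozygote difference
    dominance={"snp1": 0.25},        # heterozygote deviation
    epistasis=[EpistaticTerm("snp1", "snp2", "AxA", 0.8)],
    sigma=1.0,
)
y = simulate_phenotype(gm, truth, seed=1).trait("trait")

print(SingleLocusModel(y, gm.column("snp1"), snp_id="snp1").fit().summary())
print(TwoLocusModel(y, gm.column("snp1"), gm.column("snp2"),
                    snp_id1="snp1", snp_id2="snp2").fit().summary())
```

prints

```
Single-locus association: snp1 ~ trait
  n used           435
  adjusted means   g=0: 39.42, g=1: 40.04, g=2: 40.39
  genotypic (m)    F = 28.75, p = 1.89e-12
  R^2 explained    0.1175
  additive (a)     0.488 (p = 4.04e-10)
  dominance (d)    0.132 (p = 0.207)
Two-locus epistasis: snp1 x snp2 ~ trait
  n used        435
  AxA          0.6132 (p = 2.88e-08)
  AxD          -0.0003765 (p = 0.998)
  DxA          0.2006 (p = 0.161)
  DxD          0.224 (p = 0.25)
  joint 4-df    p = 1.15e-10
```

The additive effect (0.488) recovers the planted 0.5; the dominance
estimate (0.132, p = 0.21) correctly fails to reach significance at this
effect size and n; the planted A×A interaction is detected at p ≈ 3×10⁻⁸
(the estimate 0.61 sits within two standard errors of the planted 0.8 —
across replicates the estimator is unbiased). The 2-df genotypic test and
its R² quantify the overall SNP effect.

## The pipeline

A single config drives the five stages end to end:

```bash
grnmap run --output-dir demo_run --seed 1       # bundled synthetic demo
grnmap run --config my_config.yaml              # your own study
grnmap validate --config my_config.yaml
```

The demo simulates a 435-individual panel (a hub TF plus 53 candidate
target genes, ten quantitative traits, four-tissue expression, 2-kb
promoters), then discovers targets, runs the single-locus and hub-centred
epistasis scans (BH FDR at p ≤ 0.01, q ≤ 0.1), and builds the layered
network. Every stage writes plain-text tables (VCF/TSV/FASTA/SIF) into the
run directory, any stage can be re-run standalone on prior-stage outputs,
and identical config + seed reproduces byte-identical results (the manifest
records the config hash and per-stage row counts).

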