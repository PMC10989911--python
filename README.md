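# panfactor

Strain-level deconvolution of pangenome abundance profiles: given a
gene-family × sample abundance matrix produced by mapping metagenomic reads
against a species pangenome, `panfactor` simultaneously reconstructs **which
strains coexist in the samples**, **how abundant each strain is per sample**,
and **which gene families each strain carries**.

## Who this is for

Microbiome researchers who have multi-sample shotgun metagenomic data (for
example longitudinal stool samples) and want to resolve within-species
variation — subspecies succession, strain engraftment after transplantation,
strain-specific functional potential — without assembling genomes or relying
on SNV haplotypes as a proxy for gene content. The package starts from the
pangenome coverage profile (e.g. a PanPhlAn-style RPKM table); it does not
perform read mapping.

## The model

The observed gene-family abundance matrix **D** (N families × S samples,
RPKM) is modelled as the product

```
D ≈ P · S
```

- **P** (N × K): binary gene-content profiles — `P[i, j] = 1` iff gene
  family *i* is present in strain *j*;
- **S** (K × S): strain composition — `S[i, j]` is the relative abundance of
  strain *i* in sample *j*, columns sum to 1.

The factors are estimated by sparse nonnegative matrix factorization
(alternating nonnegative least squares with a squared-L1 sparsity penalty on
the composition columns and a weak ridge on the content factor, both
subproblems solved exactly by block principal pivoting). The continuous
content factor is binarized per strain: the kernel-density peak of its
weights whose right tail matches the expected per-genome gene-family count
(`g_expected`, from the reference pangenome) locates the "present" mode
`p_max`; families with weight ≥ `θ = 0.5 · p_max` are called present and
every call gets a confidence score (1 when ≥ θ, decaying linearly to 1 again
at weight 0 for confident absences). The number of strains K is selected
automatically over a candidate range (1–12 by default) by rejecting ranks
that produce an implausible strain: mean relative abundance ≤ τ₂ = 0.1,
called profile ≤ τ₃ · g_min = 0.5 · g_min gene families, or a strain pair
with Jaccard distance ≤ τ₁ = 0.1.

Benchmark metrics mirror standard practice for strain profilers:
Jensen–Shannon divergence (base-2, on sorted zero-padded compositions),
Matthews correlation for strain detection, per-strain precision/recall and
confidence-ranked AUPRC for gene content, plus a random-profile AUPRC
baseline.

## Worked example

```python
from panfactor import (SimConfig, FactorizeParams, simulate_dataset,
                       synthetic_membership, trim_and_filter, decompose)

D, truth = simulate_dataset(SimConfig(n_families=800, n_strains=3,
                                      n_samples=12, seed=4))
stats = synthetic_membership(truth)
Dp, log = trim_and_filter(D, stats)          # RPKM trim + coverage filter
result = decompose(Dp, stats, FactorizeParams(seed=4))
print(result.selected_rank)
print(result.composition.mean_abundance.round(3))
print(result.gene_content.gene_counts)
```

prints

```
3
[0.404 0.308 0.287]
[573 562 557]
```

Three strains are selected (ranks 4–12 are rejected because the surplus
strain falls below the τ₂ = 0.1 mean-abundance floor); the three recovered
strains average 40/31/29 % across samples and carry 573/562/557 gene
families — in this simulation exactly the true profiles (Jaccard distance 0
to truth, per-sample composition JSD ≈ 0). The `examples/` directory walks
through simulation, decomposition, evaluation and the random baseline, one
short script per capability.

The same pipeline is available from the shell:

```bash
panfactor simulate  --n-strains 3 --n-samples 12 --seed 4 --out sim/
panfactor decompose --matrix sim/D.tsv --pangenome sim/membership.tsv \
                    --seed 4 --out run/
panfactor evaluate  --result run/ --truth sim/ --out report.json
```

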